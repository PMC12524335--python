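"""End-to-end query-based detector assembly, inference, and training.

The detector follows the hybrid-encoder design of real-time detection
transformers: a convolutional backbone emits stride-{8,16,32} maps; an
intra-scale attention stage (the polar linear-attention block, or a
plain softmax-attention layer in the baseline) runs on the stride-32
level only; a cross-scale fusion pyramid (top-down + bottom-up CSP-style
fusion) mixes the three levels; and a query decoder turns the fused
tokens into a fixed set of box/score predictions.  Inference is
NMS-free: detections are a pure function of the per-query outputs.

Queries are initialized from encoder proposals: every token predicts a
score and a box around its grid anchor, the top-K tokens seed the
query content and reference boxes, and each decoder layer refines the
references through inverse-sigmoid deltas.  Training applies the
Hungarian-matched composite loss at the encoder proposal stage and at
every decoder layer.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass

import numpy as np
from PIL import Image

from .config import DetectorConfig, config_from_dict, config_to_dict
from .engine import nn
from .engine import tensor as T
from .engine.optim import AdamW
from .engine.tensor import Tensor
from .inception_conv import Backbone, ResidualBlock
from .losses import total_loss
from .metrics import map50
from .polar_encoder import (BaselineEncoderLayer, PolarEncoderLayer,
                            grid_centers, sincos_xy)

__all__ = [
    "DetectionResult", "FlockDetector", "build_detector", "forward_detect",
    "preprocess_images", "train", "save_checkpoint", "load_checkpoint",
]


@dataclass
class DetectionResult:
    boxes: np.ndarray          # (n, 4) corner format, absolute pixels
    scores: np.ndarray         # (n,) descending
    labels: np.ndarray         # (n,) class ids


class FusionBlock(nn.Module):
    """1x1 fuse of two concatenated levels into a working width, a stack
    of residual blocks at that width, and a 1x1 projection back."""

    def __init__(self, dim: int, depth: int, hidden: int | None = None):
        super().__init__()
        h = hidden or dim
        self.fuse = nn.ConvBNAct(2 * dim, h, 1)
        self.blocks = nn.Sequential(*[ResidualBlock(h) for _ in range(depth)])
        self.out = nn.ConvBNAct(h, dim, 1, act=False)

    def forward(self, x):
        return self.out(self.blocks(self.fuse(x)))


class HybridEncoder(nn.Module):
    def __init__(self, in_channels: tuple[int, int, int], cfg):
        super().__init__()
        d = cfg.embed_dim
        self.dim = d
        self.proj = nn.ModuleList(
            [nn.ConvBNAct(c, d, 1, act=False) for c in in_channels])
        if cfg.variant == "polar":
            self.top = PolarEncoderLayer(cfg.polar_stage())
        else:
            self.top = BaselineEncoderLayer(d, cfg.num_heads, cfg.aifi_ffn_dim)
        f = cfg.fusion_depths
        h = cfg.fusion_hidden
        self.lat5 = nn.ConvBNAct(d, d, 1)
        self.lat4 = nn.ConvBNAct(d, d, 1)
        self.td4 = FusionBlock(d, f[0], h)
        self.td3 = FusionBlock(d, f[1], h)
        self.down3 = nn.ConvBNAct(d, d, 3, stride=2)
        self.down4 = nn.ConvBNAct(d, d, 3, stride=2)
        self.bu4 = FusionBlock(d, f[2], h)
        self.bu5 = FusionBlock(d, f[3], h)

    def forward(self, feats):
        p3, p4, p5 = [proj(f) for proj, f in zip(self.proj, feats)]
        p5 = self.top(p5)
        t5 = self.lat5(p5)
        p4 = self.td4(T.concat([T.upsample_nearest2x(t5), p4], axis=1))
        t4 = self.lat4(p4)
        p3 = self.td3(T.concat([T.upsample_nearest2x(t4), p3], axis=1))
        n4 = self.bu4(T.concat([self.down3(p3), t4], axis=1))
        n5 = self.bu5(T.concat([self.down4(n4), t5], axis=1))
        return [p3, n4, n5]


class MLP(nn.Module):
    def __init__(self, din, hidden, dout, layers=3, zero_last: bool = False):
        super().__init__()
        dims = [din] + [hidden] * (layers - 1) + [dout]
        self.layers = nn.ModuleList(
            [nn.Linear(a, b) for a, b in zip(dims[:-1], dims[1:])])
        if zero_last:
            self.layers[-1].weight.data[:] = 0.0

    def forward(self, x):
        for i, l in enumerate(self.layers):
            x = l(x)
            if i < len(self.layers) - 1:
                x = T.relu(x)
        return x


class DecoderLayer(nn.Module):
    def __init__(self, dim, heads, ffn_dim):
        super().__init__()
        self.self_attn = nn.MultiHeadAttention(dim, heads)
        self.norm1 = nn.LayerNorm(dim)
        self.cross_attn = nn.MultiHeadAttention(dim, heads)
        self.norm2 = nn.LayerNorm(dim)
        self.fc1 = nn.Linear(dim, ffn_dim)
        self.fc2 = nn.Linear(ffn_dim, dim)
        self.fc2.weight.data[:] = 0.0
        self.norm3 = nn.LayerNorm(dim)

    def forward(self, content, qpos, memory, mpos, cross_bias=None):
        q = content + qpos
        content = self.norm1(content + self.self_attn(q, q, content))
        content = self.norm2(content + self.cross_attn(
            content + qpos, memory + mpos, memory, bias=cross_bias))
        content = self.norm3(content + self.fc2(T.relu(self.fc1(content))))
        return content


def _inverse_sigmoid(x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    x = np.clip(x, eps, 1.0 - eps)
    return np.log(x / (1.0 - x))


class QueryDecoder(nn.Module):
    """Proposal-seeded query decoder over concatenated pyramid tokens."""

    ANCHOR_BASE = 0.05           # box prior at stride 8, doubling per level

    def __init__(self, cfg):
        super().__init__()
        d, ncls = cfg_dim(cfg), cfg.decoder.num_classes
        dec = cfg.decoder
        self.num_queries = dec.num_queries
        self.level_embed = nn.Parameter(
            np.zeros((3, d), dtype=np.float32))
        self.enc_score = nn.Linear(d, ncls)
        self.enc_box = MLP(d, d, 4, 3, zero_last=True)
        self.query_proj = nn.Linear(d, d)
        self.ref_embed = nn.Linear(d, d)      # over sincos of the ref center
        self.layers = nn.ModuleList(
            [DecoderLayer(d, dec.num_heads, dec.ffn_dim)
             for _ in range(dec.num_layers)])
        self.score_head = nn.Linear(d, ncls)
        self.box_head = MLP(d, d, 4, 3, zero_last=True)
        # low-probability prior on foreground scores stabilizes the
        # early all-negative classification signal
        self.enc_score.bias.data[:] = -4.6
        self.score_head.bias.data[:] = -4.6

    def _anchors(self, shapes) -> np.ndarray:
        anchors = []
        for lvl, (h, w) in enumerate(shapes):
            cxy = grid_centers(h, w)
            wh = np.full((len(cxy), 2), self.ANCHOR_BASE * (2 ** lvl),
                         dtype=np.float32)
            anchors.append(np.concatenate([cxy, wh], axis=1))
        return np.concatenate(anchors, axis=0)

    def forward(self, pyramid):
        dim = pyramid[0].shape[1]
        tokens, poss, shapes = [], [], []
        for lvl, f in enumerate(pyramid):
            b, c, h, w = f.shape
            t = T.transpose(f.reshape((b, c, h * w)), (0, 2, 1))
            tokens.append(t)
            poss.append(sincos_xy(grid_centers(h, w), dim))
            shapes.append((h, w))
        memory = T.concat(tokens, axis=1)                       # (B, N, D)
        # the learnable level embedding enters on the memory side
        lvl_rows = np.concatenate(
            [np.full(h * w, i) for i, (h, w) in enumerate(shapes)]).astype(int)
        memory = memory + self.level_embed[lvl_rows]
        mpos = Tensor(np.concatenate(poss, axis=0))

        B, N, D = memory.shape
        anchors = self._anchors(shapes)                          # (N, 4)
        enc_logits = self.enc_score(memory)                      # (B, N, ncls)
        enc_delta = self.enc_box(memory)
        enc_boxes = T.sigmoid(enc_delta + Tensor(_inverse_sigmoid(anchors)))

        K = min(self.num_queries, N)
        obj = enc_logits.data.max(axis=-1)                       # (B, N)
        idx = np.argpartition(-obj, K - 1, axis=1)[:, :K]        # (B, K)
        rows = np.arange(B)[:, None]
        sel_mem = memory[rows, idx]                              # (B, K, D)
        sel_boxes = enc_boxes[rows, idx]

        # dense proposal output: every token is supervised, so the
        # selection scores become meaningful quickly
        outputs = [(T.sigmoid(enc_logits), enc_boxes)]
        content = self.query_proj(sel_mem)
        token_xy = np.concatenate([grid_centers(h, w) for h, w in shapes])
        refs = sel_boxes.data.copy()                             # detached
        for layer in self.layers:
            ref_pos = sincos_xy(refs[..., :2].reshape(-1, 2), D).reshape(B, K, D)
            qpos = self.ref_embed(Tensor(ref_pos))
            # Gaussian locality prior centred on each query's reference
            # box: the analogue of deformable sampling for dense attention
            d2 = ((refs[:, :, None, :2] - token_xy[None, None, :, :]) ** 2).sum(-1)
            sigma2 = np.maximum(refs[..., 2] * refs[..., 3], 1e-4) / 4.0
            cross_bias = Tensor((-d2 / (2.0 * sigma2[..., None]))[:, None])
            content = layer(content, qpos, memory, mpos, cross_bias)
            delta = self.box_head(content)
            boxes = T.sigmoid(delta + Tensor(_inverse_sigmoid(refs)))
            scores = T.sigmoid(self.score_head(content))
            outputs.append((scores, boxes))
            refs = boxes.data.copy()
        return outputs


def cfg_dim(cfg: DetectorConfig) -> int:
    return cfg.encoder.embed_dim


class FlockDetector(nn.Module):
    def __init__(self, cfg: DetectorConfig):
        super().__init__()
        self.cfg = cfg
        self.backbone = Backbone(cfg.backbone)
        self.encoder = HybridEncoder(self.backbone.out_channels, cfg.encoder)
        self.decoder = QueryDecoder(cfg)

    def forward(self, images: Tensor):
        """images: (B, 3, S, S) float in [0, 1].  Returns the list of
        (scores, boxes) outputs: encoder proposals first, then one entry
        per decoder layer; the last entry is the final prediction."""
        feats = self.backbone(images)
        pyramid = self.encoder(feats)
        return self.decoder(pyramid)


def build_detector(cfg: DetectorConfig) -> FlockDetector:
    nn.seed_init(cfg.init_seed)
    return FlockDetector(cfg)


# ---------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------

def preprocess_images(images, input_size: int) -> tuple[Tensor, list]:
    """uint8 HxWx3 arrays -> (B, 3, S, S) float tensor in [0,1] plus the
    original (H, W) per image."""
    batch, sizes = [], []
    for img in images:
        arr = np.asarray(img)
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise ValueError("each image must be HxWx3 RGB")
        sizes.append(arr.shape[:2])
        if arr.shape[:2] != (input_size, input_size):
            arr = np.asarray(Image.fromarray(arr).resize(
                (input_size, input_size), Image.BILINEAR))
        batch.append(arr.astype(np.float32).transpose(2, 0, 1) / 255.0)
    return Tensor(np.stack(batch)), sizes


def forward_detect(model: FlockDetector, images, score_threshold: float = 0.5
                   ) -> list[DetectionResult]:
    """Threshold-and-sort the final query outputs; no NMS anywhere."""
    was_training = model.training
    model.eval()
    x, sizes = preprocess_images(images, model.cfg.input_size)
    with T.no_grad():
        scores, boxes = model(x)[-1]
    if was_training:
        model.train()
    results = []
    for i, (h, w) in enumerate(sizes):
        s = scores.data[i]                       # (Q, ncls)
        labels = s.argmax(axis=-1)
        conf = s.max(axis=-1)
        keep = conf >= score_threshold
        b = boxes.data[i][keep]
        conf, labels = conf[keep], labels[keep]
        corners = np.stack([
            (b[:, 0] - b[:, 2] / 2) * w, (b[:, 1] - b[:, 3] / 2) * h,
            (b[:, 0] + b[:, 2] / 2) * w, (b[:, 1] + b[:, 3] / 2) * h], axis=1)
        corners[:, 0::2] = corners[:, 0::2].clip(0, w)
        corners[:, 1::2] = corners[:, 1::2].clip(0, h)
        order = np.argsort(-conf, kind="stable")
        results.append(DetectionResult(
            boxes=corners[order], scores=conf[order], labels=labels[order]))
    return results


# ---------------------------------------------------------------------
# training
# ---------------------------------------------------------------------

def _targets_from(ann) -> np.ndarray:
    """Normalized cxcywh targets from an annotated image."""
    h, w = ann.image.shape[:2]
    b = ann.boxes
    if len(b) == 0:
        return np.zeros((0, 4), dtype=np.float32)
    return np.stack([
        (b[:, 0] + b[:, 2]) / 2 / w, (b[:, 1] + b[:, 3]) / 2 / h,
        (b[:, 2] - b[:, 0]) / w, (b[:, 3] - b[:, 1]) / h], axis=1)


def _clip_grads(params, max_norm: float):
    total = 0.0
    grads = [p.grad for p in params if p.grad is not None]
    for g in grads:
        total += float((g * g).sum())
    norm = total ** 0.5
    if max_norm > 0 and norm > max_norm:
        scale = max_norm / (norm + 1e-12)
        for g in grads:
            g *= scale
    return norm


def train(model: FlockDetector, train_set, cfg: DetectorConfig | None = None,
          val_set=None, seed: int = 0, epochs: int | None = None,
          verbose: bool = False) -> dict:
    """AdamW training with per-layer auxiliary losses.

    Returns a history dict with per-epoch mean loss, validation
    mAP@0.5 (if a validation set is given), the best-epoch index and
    the best state dict (by validation mAP, else final).
    """
    cfg = cfg or model.cfg
    if len(train_set) == 0:
        raise ValueError("empty training dataset")
    opt_cfg = cfg.optimizer
    epochs = epochs or opt_cfg.epochs
    x_all, _ = preprocess_images([a.image for a in train_set], cfg.input_size)
    x_all = x_all.data
    targets_all = [_targets_from(a) for a in train_set]

    nn.Dropout.seed(seed + 1)
    opt = AdamW(model.parameters(), lr=opt_cfg.lr,
                betas=(opt_cfg.beta1, opt_cfg.beta2),
                weight_decay=opt_cfg.weight_decay)
    order_rng = np.random.default_rng(seed)
    history = {"loss": [], "val_map50": [], "components": []}
    best = {"map50": -1.0, "epoch": -1, "state": None}

    n = len(train_set)
    bs = opt_cfg.batch_size
    for epoch in range(epochs):
        if opt_cfg.schedule == "cosine":
            opt.lr = opt_cfg.lr * 0.5 * (1 + np.cos(np.pi * epoch / epochs))
        model.train()
        order = order_rng.permutation(n)
        losses, comps_acc = [], []
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            x = Tensor(x_all[idx])
            targets = [targets_all[i] for i in idx]
            outputs = model(x)
            loss = None
            for scores, boxes in outputs:
                l, comps = total_loss(
                    scores.reshape(scores.shape[:2]) if scores.shape[-1] == 1
                    else scores[..., 0],
                    boxes, targets, cfg.loss)
                loss = l if loss is None else loss + l
            model.zero_grad()
            loss.backward()
            _clip_grads(model.parameters(), opt_cfg.grad_clip)
            opt.step()
            losses.append(float(loss.data) / len(outputs))
            comps_acc.append(comps)
        history["loss"].append(float(np.mean(losses)))
        history["components"].append(comps_acc[-1])

        if val_set is not None:
            m = evaluate_map50(model, val_set)
            history["val_map50"].append(m)
            if m > best["map50"]:
                best.update(map50=m, epoch=epoch, state=model.state_dict())
        if verbose:
            tail = f" val mAP50 {history['val_map50'][-1]:.3f}" if val_set else ""
            print(f"epoch {epoch + 1}/{epochs} loss {history['loss'][-1]:.4f}{tail}")

    if best["state"] is None:
        best.update(epoch=epochs - 1, state=model.state_dict())
    history["best_epoch"] = best["epoch"]
    history["best_state"] = best["state"]
    history["best_map50"] = best["map50"]
    return history


def evaluate_map50(model: FlockDetector, dataset, score_threshold: float = 0.05,
                   batch_size: int = 8) -> float:
    """mAP@0.5 (0-1 scale) of the model on an annotated dataset."""
    dets, gts = [], []
    for start in range(0, len(dataset), batch_size):
        chunk = dataset[start : start + batch_size]
        res = forward_detect(model, [a.image for a in chunk], score_threshold)
        for r, a in zip(res, chunk):
            dets.append((r.boxes, r.scores))
            gts.append(a.boxes)
    return map50(dets, gts) / 100.0


# ---------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------

def save_checkpoint(model: FlockDetector, path) -> None:
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(config_to_dict(model.cfg)).encode(), dtype=np.uint8)
    np.savez(path, **state)


def load_checkpoint(path) -> FlockDetector:
    data = np.load(path, allow_pickle=False)
    cfg = config_from_dict(json.loads(bytes(data["__config__"]).decode()))
    model = build_detector(cfg)
    state = {k: data[k] for k in data.files if k != "__config__"}
    model.load_state_dict(state)
    return model
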