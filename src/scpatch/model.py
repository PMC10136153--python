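"""Pre-norm transformer encoder with a patch-embedding front end and MLP head.

The model treats each cell as a sequence of gene patches (see
:mod:`scpatch.patches`): tokens are linear projections of P^2 gene values,
a learnable class token is prepended, learned position embeddings are added,
and the sequence passes through ``depth`` encoder blocks of multi-head
self-attention and a GELU MLP, each pre-LayerNormed with residual
connections. A three-layer MLP head maps the pooled representation to K
per-class confidences via softmax.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.special import erf

from . import _autograd as ag
from ._autograd import Tensor
from .io import ExpressionMatrix, LabelMap
from .patches import PatchLayout, batch_to_patches

CHECKPOINT_VERSION = "1.0.0"


def gelu(x):
    """Exact GELU, x * Phi(x) with Phi the standard-normal CDF (via erf)."""
    x = np.asarray(x, dtype=np.float64)
    out = x * 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
    return out if out.ndim else float(out)


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    The depth-12 encoder and patch size 16 are the reference configuration;
    embedding width, head count, MLP ratio and classifier widths are free
    choices exposed here. ``pooling`` selects whether the class-token row or
    the token mean feeds the classifier.
    """

    n_classes: int
    patch_size: int = 16
    embed_dim: int = 192
    depth: int = 12
    n_heads: int = 3
    mlp_ratio: float = 4.0
    classifier_hidden: tuple[int, int] = (128, 64)
    dropout: float = 0.1
    input_dropout: float = 0.0
    pooling: str = "class_token"

    def __post_init__(self):
        self.classifier_hidden = tuple(self.classifier_hidden)
        if self.embed_dim % self.n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.n_classes < 1:
            raise ValueError("need at least one class")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if not 0 <= self.input_dropout < 1:
            raise ValueError("input_dropout must be in [0, 1)")
        if self.pooling not in {"class_token", "mean"}:
            raise ValueError("pooling must be 'class_token' or 'mean'")

    @classmethod
    def desk_preset(cls, n_classes: int, **overrides) -> "ModelConfig":
        """Small configuration for laptop-scale experiments and tests."""
        kw = dict(patch_size=16, embed_dim=32, depth=2, n_heads=2,
                  mlp_ratio=2.0, classifier_hidden=(64, 32), dropout=0.1,
                  input_dropout=0.3)
        kw.update(overrides)
        return cls(n_classes=n_classes, **kw)

    @classmethod
    def full_preset(cls, n_classes: int, **overrides) -> "ModelConfig":
        """Full-scale reference configuration (12 encoder blocks, patch 16)."""
        return cls(n_classes=n_classes, **overrides)


@dataclass
class ModelState:
    """All learnable tensors plus the frozen layout, label map and config."""

    params: dict[str, Tensor]
    layout: PatchLayout
    label_map: LabelMap
    config: ModelConfig
    reference_genes: list[str] = field(default_factory=list)

    def parameters(self) -> dict[str, Tensor]:
        return self.params

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


def _init_params(cfg: ModelConfig, layout: PatchLayout,
                 rng: np.random.Generator) -> dict[str, Tensor]:
    d, p2 = cfg.embed_dim, cfg.patch_size ** 2
    hidden = int(np.ceil(cfg.mlp_ratio * d))

    def w(*shape):
        # fan-in scaled gaussian for linear maps keeps activations O(1)
        return Tensor(rng.normal(0.0, 1.0 / np.sqrt(shape[-1]), size=shape),
                      requires_grad=True)

    def emb(*shape):
        return Tensor(rng.normal(0.0, 0.02, size=shape), requires_grad=True)

    def zeros(*shape):
        return Tensor(np.zeros(shape), requires_grad=True)

    def ones(*shape):
        return Tensor(np.ones(shape), requires_grad=True)

    params: dict[str, Tensor] = {
        "patch_proj.weight": w(d, p2),
        "patch_proj.bias": zeros(d),
        "class_token": emb(d),
        # unit-scale positions keep patches distinguishable from the start,
        # which matters for attention routing when N is large
        "pos_table": Tensor(rng.normal(0.0, 1.0, size=(layout.n_patches + 1, d)),
                            requires_grad=True),
        "final_ln.gamma": ones(d),
        "final_ln.beta": zeros(d),
    }
    for i in range(cfg.depth):
        b = f"blocks.{i}."
        params[b + "ln1.gamma"] = ones(d)
        params[b + "ln1.beta"] = zeros(d)
        for name in ("wq", "wk", "wv", "wo"):
            params[b + "attn." + name] = w(d, d)
        for name in ("bq", "bk", "bv", "bo"):
            params[b + "attn." + name] = zeros(d)
        params[b + "ln2.gamma"] = ones(d)
        params[b + "ln2.beta"] = zeros(d)
        params[b + "mlp.w1"] = w(hidden, d)
        params[b + "mlp.b1"] = zeros(hidden)
        params[b + "mlp.w2"] = w(d, hidden)
        params[b + "mlp.b2"] = zeros(d)
    c1, c2 = cfg.classifier_hidden
    params["head.w1"] = w(c1, d)
    params["head.b1"] = zeros(c1)
    params["head.w2"] = w(c2, c1)
    params["head.b2"] = zeros(c2)
    params["head.w3"] = w(cfg.n_classes, c2)
    params["head.b3"] = zeros(cfg.n_classes)
    return params


def build_model(
    n_genes: int,
    label_map: LabelMap,
    config: ModelConfig,
    seed: int = 0,
    reference_genes: list[str] | None = None,
) -> ModelState:
    """Initialise a ModelState with seeded gaussian weights."""
    if len(label_map) != config.n_classes:
        raise ValueError("label_map size does not match config.n_classes")
    layout = PatchLayout(patch_size=config.patch_size, n_genes=n_genes)
    rng = np.random.default_rng(seed)
    params = _init_params(config, layout, rng)
    return ModelState(params=params, layout=layout, label_map=label_map,
                      config=config, reference_genes=list(reference_genes or []))


# ------------------------------------------------------------------ forward
def _linear(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    return x @ w.transpose(1, 0) + b


def _dropout(x: Tensor, p: float, rng: np.random.Generator | None) -> Tensor:
    if p <= 0 or rng is None:
        return x
    mask = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * Tensor(mask)


def multi_head_attention(
    x: Tensor,
    weights: dict[str, Tensor],
    n_heads: int,
    dropout: float = 0.0,
    rng: np.random.Generator | None = None,
    return_attn: bool = False,
):
    """Scaled dot-product self-attention over ``n_heads`` heads.

    ``x`` is (B, T, D). Softmax rows of each head's T x T attention matrix
    sum to one. When ``return_attn`` is set, the (B, H, T, T) probability
    array is returned alongside the output.
    """
    bsz, t, d = x.shape
    dh = d // n_heads
    q = _linear(x, weights["wq"], weights["bq"])
    k = _linear(x, weights["wk"], weights["bk"])
    v = _linear(x, weights["wv"], weights["bv"])

    def split(h: Tensor) -> Tensor:  # (B,T,D) -> (B,H,T,dh)
        return h.reshape(bsz, t, n_heads, dh).transpose(0, 2, 1, 3)

    q, k, v = split(q), split(k), split(v)
    scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
    attn = ag.softmax(scores, axis=-1)
    attn_d = _dropout(attn, dropout, rng)
    out = (attn_d @ v).transpose(0, 2, 1, 3).reshape(bsz, t, d)
    out = _linear(out, weights["wo"], weights["bo"])
    if return_attn:
        return out, attn.data
    return out


def encoder_block(
    h: Tensor | np.ndarray,
    weights: dict[str, Tensor],
    n_heads: int,
    dropout: float = 0.0,
    rng: np.random.Generator | None = None,
) -> Tensor:
    """One pre-norm block: h += MHSA(LN(h)); h += MLP(LN(h))."""
    if not isinstance(h, Tensor):
        h = Tensor(h)
    squeeze = h.data.ndim == 2
    if squeeze:
        h = h.reshape(1, *h.shape)
    attn_in = ag.layer_norm(h, weights["ln1.gamma"], weights["ln1.beta"])
    attn_w = {k.split(".", 1)[1]: v for k, v in weights.items()
              if k.startswith("attn.")}
    h = h + _dropout(
        multi_head_attention(attn_in, attn_w, n_heads, dropout, rng),
        dropout, rng)
    mlp_in = ag.layer_norm(h, weights["ln2.gamma"], weights["ln2.beta"])
    hid = ag.gelu(_linear(mlp_in, weights["mlp.w1"], weights["mlp.b1"]))
    hid = _dropout(hid, dropout, rng)
    h = h + _dropout(_linear(hid, weights["mlp.w2"], weights["mlp.b2"]),
                     dropout, rng)
    if squeeze:
        h = h.reshape(*h.shape[1:])
    return h


def forward_logits(
    values: np.ndarray,
    state: ModelState,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> Tensor:
    """Batch forward pass: (B, G) aligned expression -> (B, K) logits."""
    cfg, p = state.config, state.params
    drop_rng = rng if training else None
    drop = cfg.dropout if training else 0.0
    values = np.atleast_2d(values)
    if training and cfg.input_dropout > 0 and rng is not None:
        # gene-level dropout: emulates capture dropout as augmentation
        keep = rng.random(values.shape) >= cfg.input_dropout
        values = values * keep / (1.0 - cfg.input_dropout)
    patches = batch_to_patches(values, state.layout)
    bsz, n, _ = patches.shape
    tokens = _linear(Tensor(patches), p["patch_proj.weight"], p["patch_proj.bias"])
    cls = p["class_token"].reshape(1, 1, -1) + Tensor(np.zeros((bsz, 1, cfg.embed_dim)))
    h = ag.concatenate([cls, tokens], axis=1) + p["pos_table"]
    h = _dropout(h, drop, drop_rng)
    for i in range(cfg.depth):
        block = {k[len(f"blocks.{i}."):]: v for k, v in p.items()
                 if k.startswith(f"blocks.{i}.")}
        h = encoder_block(h, block, cfg.n_heads, drop, drop_rng)
    h = ag.layer_norm(h, p["final_ln.gamma"], p["final_ln.beta"])
    pooled = h[:, 0, :] if cfg.pooling == "class_token" else h.mean(axis=1)
    z = ag.gelu(_linear(pooled, p["head.w1"], p["head.b1"]))
    z = ag.gelu(_linear(z, p["head.w2"], p["head.b2"]))
    return _linear(z, p["head.w3"], p["head.b3"])


def forward(cell_vector: np.ndarray, state: ModelState) -> np.ndarray:
    """Inference forward for one cell: length-G vector -> K-class probabilities."""
    v = np.asarray(cell_vector, dtype=np.float64).reshape(-1)
    if v.shape[0] != state.layout.n_genes:
        raise ValueError(
            f"vector length {v.shape[0]} != model n_genes {state.layout.n_genes}")
    logits = forward_logits(v[None, :], state, training=False).data[0]
    z = logits - logits.max()
    e = np.exp(z)
    return e / e.sum()


def predict_proba(m: ExpressionMatrix, state: ModelState,
                  batch_size: int = 256) -> np.ndarray:
    """Class-probability matrix (C, K) for an aligned, normalised matrix."""
    if m.gene_ids != (state.reference_genes or m.gene_ids):
        raise ValueError("matrix genes are not aligned to the model's reference")
    if m.n_genes != state.layout.n_genes:
        raise ValueError("gene count does not match the model layout")
    out = np.empty((m.n_cells, state.config.n_classes))
    for lo in range(0, m.n_cells, batch_size):
        logits = forward_logits(m.values[lo:lo + batch_size], state).data
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        out[lo:lo + batch_size] = e / e.sum(axis=1, keepdims=True)
    return out


def predict_labels(
    m: ExpressionMatrix, state: ModelState,
) -> list[tuple[str, str, float]]:
    """Per-cell (cell_id, predicted type, confidence); argmax ties -> lowest index."""
    if m.n_cells == 0:
        return []
    proba = predict_proba(m, state)
    idx = proba.argmax(axis=1)
    return [(cid, state.label_map.names[i], float(proba[r, i]))
            for r, (cid, i) in enumerate(zip(m.cell_ids, idx))]


# --------------------------------------------------------------- checkpoint
def save_checkpoint(state: ModelState, path) -> None:
    """Write a checkpoint directory: weights.npz + meta.json."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.savez(path / "weights.npz",
             **{k: v.data for k, v in state.params.items()})
    meta = {
        "version": CHECKPOINT_VERSION,
        "config": asdict(state.config),
        "layout": state.layout.to_dict(),
        "label_map": state.label_map.names,
        "reference_genes": state.reference_genes,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path) -> ModelState:
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    cfg_d = dict(meta["config"])
    cfg_d["classifier_hidden"] = tuple(cfg_d["classifier_hidden"])
    cfg = ModelConfig(**cfg_d)
    layout = PatchLayout.from_dict(meta["layout"])
    with np.load(path / "weights.npz") as npz:
        params = {k: Tensor(npz[k].copy(), requires_grad=True) for k in npz.files}
    return ModelState(params=params, layout=layout,
                      label_map=LabelMap(meta["label_map"]), config=cfg,
                      reference_genes=list(meta.get("reference_genes", [])))
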