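"""Gene patching: lay a cell's gene vector into a 2D grid of P x P patches.

Each cell's G-gene expression vector is placed row-major into a vector padded
to the smallest multiple of P^2, then cut into N = ceil(G / P^2) flattened
patches of P^2 values each — the token sequence the transformer consumes.
The gene -> slot assignment is a fixed bijection frozen with the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class PatchLayout:
    """Deterministic assignment of G genes to slots in N patches of P^2 slots."""

    patch_size: int
    n_genes: int
    padded_length: int = field(init=False)
    n_patches: int = field(init=False)

    def __post_init__(self):
        if self.patch_size < 1:
            raise ValueError("patch_size must be >= 1")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        p2 = self.patch_size ** 2
        self.n_patches = -(-self.n_genes // p2)  # ceil division
        self.padded_length = self.n_patches * p2

    def slot_of_gene(self, gene_index: int) -> int:
        """Row-major layout: gene j occupies slot j."""
        if not 0 <= gene_index < self.n_genes:
            raise IndexError("gene index out of range")
        return gene_index

    def to_dict(self) -> dict:
        return {
            "version": 1,
            "patch_size": self.patch_size,
            "n_genes": self.n_genes,
            "padded_length": self.padded_length,
            "n_patches": self.n_patches,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PatchLayout":
        layout = cls(patch_size=d["patch_size"], n_genes=d["n_genes"])
        if (layout.padded_length != d["padded_length"]
                or layout.n_patches != d["n_patches"]):
            raise ValueError("inconsistent serialized layout")
        return layout


@dataclass
class PatchSequence:
    """One cell's N x P^2 patch matrix plus the layout that produced it."""

    patches: np.ndarray
    layout: PatchLayout

    def __post_init__(self):
        self.patches = np.asarray(self.patches, dtype=np.float64)
        p2 = self.layout.patch_size ** 2
        if self.patches.shape != (self.layout.n_patches, p2):
            raise ValueError("patch matrix shape inconsistent with layout")

    def flatten_to_genes(self) -> np.ndarray:
        """Concatenate patches and drop padding: exact inverse of to_patches."""
        return self.patches.reshape(-1)[: self.layout.n_genes].copy()


def build_layout(n_genes: int, patch_size: int) -> PatchLayout:
    return PatchLayout(patch_size=patch_size, n_genes=n_genes)


def to_patches(cell_vector: np.ndarray, layout: PatchLayout) -> PatchSequence:
    """Chunk one cell's gene vector into flattened patches, zero-padding the tail."""
    v = np.asarray(cell_vector, dtype=np.float64).reshape(-1)
    if v.shape[0] != layout.n_genes:
        raise ValueError(
            f"vector length {v.shape[0]} != layout n_genes {layout.n_genes}")
    padded = np.zeros(layout.padded_length)
    padded[: layout.n_genes] = v
    p2 = layout.patch_size ** 2
    return PatchSequence(padded.reshape(layout.n_patches, p2), layout)


def batch_to_patches(values: np.ndarray, layout: PatchLayout) -> np.ndarray:
    """Vectorised to_patches for a C x G matrix -> C x N x P^2 array."""
    values = np.asarray(values, dtype=np.float64)
    if values.shape[1] != layout.n_genes:
        raise ValueError("column count does not match layout")
    c = values.shape[0]
    padded = np.zeros((c, layout.padded_length))
    padded[:, : layout.n_genes] = values
    p2 = layout.patch_size ** 2
    return padded.reshape(c, layout.n_patches, p2)


def embed_patches(
    seq: PatchSequence,
    weight: np.ndarray,
    bias: np.ndarray,
    position_table: np.ndarray,
    class_token: np.ndarray,
) -> np.ndarray:
    """Project patches to D-dim tokens, prepend the class token, add positions.

    Row 0 of the output is ``class_token + position_table[0]``; row k >= 1 is
    ``patches[k-1] @ weight.T + bias + position_table[k]``. A stride-P
    convolution over the gene grid computes exactly this per-patch linear map.
    """
    weight = np.asarray(weight, dtype=np.float64)
    bias = np.asarray(bias, dtype=np.float64)
    position_table = np.asarray(position_table, dtype=np.float64)
    class_token = np.asarray(class_token, dtype=np.float64)
    n, p2 = seq.patches.shape
    d = weight.shape[0]
    if weight.shape[1] != p2:
        raise ValueError("projection input arity must equal P^2")
    if bias.shape != (d,) or class_token.shape != (d,):
        raise ValueError("bias/class_token dimension mismatch")
    if position_table.shape != (n + 1, d):
        raise ValueError("position_table must have N+1 rows of width D")
    tokens = np.empty((n + 1, d))
    tokens[0] = class_token
    tokens[1:] = seq.patches @ weight.T + bias
    return tokens + position_table
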