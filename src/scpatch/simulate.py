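"""Synthetic labelled scRNA-seq counts with marker-gene cell-type structure.

The generator draws counts from a negative binomial (the standard
overdispersed model for UMI counts): gene g in a cell of type k has mean
``base_mean * marker_fold`` if g is one of type k's markers and
``base_mean`` otherwise, with a shared dispersion. Each count is then
independently zeroed with probability ``dropout_rate`` to emulate capture
dropout on top of the sampling zeros. Cells are allocated to types by exact
largest-remainder apportionment of ``type_proportions`` so fixture sizes are
reproducible, and marker sets of distinct types are disjoint.

This emulates the regime the classifier targets — noisy, high-dimensional,
highly sparse counts with imbalanced classes — not batch effects, cell
cycles, or trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ExpressionMatrix, log_normalize, split_train_test


@dataclass
class SyntheticSpec:
    n_cells: int = 400
    n_genes: int = 1024
    n_types: int = 4
    markers_per_type: int = 100
    marker_fold: float = 10.0
    base_mean: float = 0.3
    dispersion: float = 2.0
    dropout_rate: float = 0.3
    type_proportions: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.type_proportions is None:
            self.type_proportions = tuple([1.0 / self.n_types] * self.n_types)
        self.type_proportions = tuple(self.type_proportions)
        if len(self.type_proportions) != self.n_types:
            raise ValueError("type_proportions must have n_types entries")
        if abs(sum(self.type_proportions) - 1.0) > 1e-9:
            raise ValueError("type_proportions must sum to 1")
        if self.markers_per_type * self.n_types > self.n_genes:
            raise ValueError("marker sets exceed the gene count")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if min(self.marker_fold, self.base_mean, self.dispersion) <= 0:
            raise ValueError("marker_fold, base_mean, dispersion must be > 0")


def allocate_counts(proportions, n: int) -> np.ndarray:
    """Largest-remainder apportionment of n cells to the given proportions."""
    raw = np.asarray(proportions) * n
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:remainder]] += 1
    return counts


def marker_genes(spec: SyntheticSpec) -> dict[int, np.ndarray]:
    """Disjoint marker sets scattered over the gene list (seeded draw).

    Marker genes are spread across the gene ordering rather than clustered,
    as in real data where the input gene order is unrelated to cell-type
    biology; derived from ``spec.seed`` so the assignment is reproducible.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7919]))
    m = spec.markers_per_type
    chosen = rng.choice(spec.n_genes, size=m * spec.n_types, replace=False)
    return {k: np.sort(chosen[k * m:(k + 1) * m]) for k in range(spec.n_types)}


def generate(spec: SyntheticSpec) -> ExpressionMatrix:
    """Draw a labelled raw-count matrix; deterministic given spec.seed."""
    rng = np.random.default_rng(spec.seed)
    counts_per_type = allocate_counts(spec.type_proportions, spec.n_cells)
    markers = marker_genes(spec)

    values = np.empty((spec.n_cells, spec.n_genes))
    labels: list[str] = []
    row = 0
    for k, n_k in enumerate(counts_per_type):
        mean = np.full(spec.n_genes, spec.base_mean)
        mean[markers[k]] *= spec.marker_fold
        # negative binomial with mean m and dispersion r: p = r / (r + m)
        r = spec.dispersion
        p = r / (r + mean)
        block = rng.negative_binomial(r, p, size=(n_k, spec.n_genes))
        if spec.dropout_rate > 0:
            keep = rng.random(block.shape) >= spec.dropout_rate
            block = block * keep
        values[row:row + n_k] = block
        labels.extend([f"type_{k}"] * n_k)
        row += n_k
    cell_ids = [f"cell_{i:05d}" for i in range(spec.n_cells)]
    return ExpressionMatrix(values, [f"gene_{j:04d}" for j in range(spec.n_genes)],
                            cell_ids, labels=labels)


PRESETS: dict[str, SyntheticSpec] = {
    # four well-separated types: rich disjoint marker programs, equal sizes
    "separable": SyntheticSpec(n_cells=400, n_genes=1024, n_types=4,
                               markers_per_type=100, marker_fold=10.0,
                               base_mean=0.3, dispersion=2.0, dropout_rate=0.3,
                               seed=20230328),
    # minority class with <= 25 training cells after an 8:2 split
    "imbalanced": SyntheticSpec(n_cells=500, n_genes=1024, n_types=4,
                                markers_per_type=100, marker_fold=2.5,
                                base_mean=0.3, dispersion=2.0, dropout_rate=0.4,
                                type_proportions=(0.47, 0.28, 0.20, 0.05),
                                seed=20230329),
    # heavier zero-inflation than the separable preset
    "sparse": SyntheticSpec(n_cells=400, n_genes=1024, n_types=4,
                            markers_per_type=100, marker_fold=10.0,
                            base_mean=0.3, dispersion=2.0, dropout_rate=0.8,
                            seed=20230330),
    # degenerate one-type dataset to exercise the accuracy-only metric path
    "single_class": SyntheticSpec(n_cells=100, n_genes=256, n_types=1,
                                  markers_per_type=50, marker_fold=10.0,
                                  base_mean=0.3, dispersion=2.0,
                                  dropout_rate=0.3, seed=20230331),
}


def make_fixture(
    preset: str, normalize: bool = True, split_seed: int = 7,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Generate a named preset and return a seeded 8:2 train/test split."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset: {preset!r}; "
                         f"choose from {sorted(PRESETS)}")
    m = generate(PRESETS[preset])
    if normalize:
        m = log_normalize(m)
    return split_train_test(m, train_fraction=0.8, seed=split_seed)
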