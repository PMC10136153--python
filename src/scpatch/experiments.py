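"""Desk-scale experimental protocols: replicated splits, gene-order
permutation robustness, and patch-size ablation.

Each protocol trains fresh models per condition x replicate with seeds
derived deterministically from a base seed, evaluates on the held-out 20%
of an 8:2 split, and aggregates mean +/- sample standard deviation of
accuracy per condition.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, LabelMap, split_train_test
from .metrics import MetricReport, build_confusion, compute_metrics, replicate_std
from .model import ModelConfig, predict_labels
from .train import TrainConfig, train_model


@dataclass
class RunRecord:
    condition: str
    replicate: int
    seed: int
    report: MetricReport


@dataclass
class ExperimentResult:
    runs: list[RunRecord]

    def summary(self) -> pd.DataFrame:
        """Per-condition mean and replicate std of test accuracy."""
        rows = []
        df = pd.DataFrame([{"condition": r.condition,
                            "accuracy": r.report.accuracy} for r in self.runs])
        for cond, grp in df.groupby("condition", sort=False):
            accs = grp["accuracy"].to_numpy()
            rows.append({
                "condition": cond,
                "n_replicates": len(accs),
                "mean_accuracy": float(accs.mean()),
                "std_accuracy": replicate_std(accs) if len(accs) >= 2 else None,
            })
        return pd.DataFrame(rows)


def derive_seed(base_seed: int, *indices: int) -> int:
    """Deterministic per-run seed below 2**31."""
    state = np.random.SeedSequence([int(base_seed), *map(int, indices)])
    return int(state.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


def _one_run(m: ExpressionMatrix, model_cfg: ModelConfig,
             train_cfg: TrainConfig, seed: int) -> MetricReport:
    train, test = split_train_test(m, train_fraction=0.8, seed=seed)
    cfg = dc_replace(train_cfg, seed=seed)
    state, _ = train_model(train, model_cfg, cfg)
    preds = predict_labels(test, state)
    predicted = [p[1] for p in preds]
    label_map = LabelMap(sorted(set(m.labels)))
    cm = build_confusion(test.labels, predicted, label_map)
    return compute_metrics(cm)


def run_replicated(
    m: ExpressionMatrix,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    n_replicates: int = 5,
    base_seed: int = 0,
    condition: str = "default",
) -> ExperimentResult:
    """Train/evaluate over ``n_replicates`` independent random 8:2 splits."""
    if m.labels is None:
        raise ValueError("replicated runs require labels")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    runs = []
    for r in range(n_replicates):
        seed = derive_seed(base_seed, r)
        report = _one_run(m, model_cfg, train_cfg, seed)
        runs.append(RunRecord(condition, r, seed, report))
    return ExperimentResult(runs)


def permute_genes(m: ExpressionMatrix, perm: np.ndarray) -> ExpressionMatrix:
    """Reorder gene columns by ``perm`` (applied identically to ids)."""
    perm = np.asarray(perm)
    from dataclasses import replace
    return replace(m, values=m.values[:, perm],
                   gene_ids=[m.gene_ids[j] for j in perm])


def permutation_robustness(
    m: ExpressionMatrix,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    n_permutations: int = 4,
    n_replicates: int = 3,
    base_seed: int = 0,
) -> ExperimentResult:
    """Retrain under fixed random gene orderings; pattern 0 is the identity.

    Each pattern's permutation is applied to the whole matrix before
    splitting, so train and test share the same gene layout; a well-behaved
    model's accuracy should be insensitive to the input ordering.
    """
    runs = []
    for p in range(n_permutations):
        if p == 0:
            perm = np.arange(m.n_genes)
        else:
            perm = np.random.default_rng(derive_seed(base_seed, 1000 + p)
                                         ).permutation(m.n_genes)
        mp = permute_genes(m, perm)
        for r in range(n_replicates):
            seed = derive_seed(base_seed, r)  # same split seeds per pattern
            report = _one_run(mp, model_cfg, train_cfg, seed)
            runs.append(RunRecord(f"pattern_{p}", r, seed, report))
    return ExperimentResult(runs)


def patch_size_ablation(
    m: ExpressionMatrix,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    sizes: list[int] = (4, 8, 16),
    n_replicates: int = 1,
    base_seed: int = 0,
) -> ExperimentResult:
    """Sweep the patch edge length with everything else held fixed."""
    if any(s < 1 for s in sizes):
        raise ValueError("patch sizes must be >= 1")
    runs = []
    for s in sizes:
        cfg = dc_replace(model_cfg, patch_size=int(s))
        for r in range(n_replicates):
            seed = derive_seed(base_seed, r)
            report = _one_run(m, cfg, train_cfg, seed)
            runs.append(RunRecord(f"patch_{s}", r, seed, report))
    return ExperimentResult(runs)
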