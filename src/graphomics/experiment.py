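"""Benchmark harness: stratified splits, evaluation metrics, hyperparameter
grid search, the multi-seed benchmark over all six graph constructions and
both ablations, and the statistical comparison protocol (paired two-tailed
t-tests, 95% confidence intervals, Cohen's d).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.metrics import roc_auc_score

from .classify import MultiOmicsGCNClassifier
from .graphs import METRICS, SimilarityConfig

__all__ = [
    "TrainConfig",
    "SplitPlan",
    "stratified_split",
    "evaluate",
    "confusion_counts",
    "paired_ttest",
    "cohens_d",
    "ci95",
    "candidate_configs",
    "grid_search",
    "run_benchmark",
    "BenchmarkReport",
    "DEFAULT_GAMMA_GRID",
    "DEFAULT_WEIGHT_GRID",
]

DEFAULT_GAMMA_GRID = (1e-4, 1e-3, 1e-2, 1e-1, 1.0, 10.0)
DEFAULT_WEIGHT_GRID = (0.1, 0.3, 0.5, 0.7, 0.9)

METRIC_COLUMNS = (
    "accuracy",
    "sensitivity",
    "specificity",
    "precision",
    "f1_macro",
    "f1_weighted",
    "auc_macro",
)


@dataclass
class TrainConfig:
    """Training protocol parameters (optimizer, stopping, split sizes, seeds)."""

    learning_rate: float = 1e-3
    weight_decay: float = 5e-4
    max_epochs: int = 2500
    patience: int = 20
    train_fraction: float = 0.7
    validation_fraction_of_train: float = 0.1
    seeds: tuple = (0, 1, 2, 3, 4)
    k: int = 10
    hidden_dim: int = 64

    def __post_init__(self):
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass
class SplitPlan:
    """Disjoint, exhaustive train/val/test index sets for one seed."""

    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    seed: int

    @property
    def train_side(self) -> np.ndarray:
        """Training-side indices (train + validation)."""
        return np.sort(np.concatenate([self.train_idx, self.val_idx]))


def stratified_split(
    labels,
    train_fraction: float = 0.7,
    seed: int = 0,
    val_fraction_of_train: float = 0.0,
) -> SplitPlan:
    """Per-class proportional train/test allocation with a seeded shuffle.

    Each class contributes round(train_fraction * n_c) samples to the
    training side (so per-class train/test ratios match the global ratio to
    within one sample); a stratified validation subset is then carved from
    the training side.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train, val, test = [], [], []
    for c in np.unique(labels):
        idx_c = np.flatnonzero(labels == c)
        if len(idx_c) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 members; cannot stratify")
        idx_c = rng.permutation(idx_c)
        n_train = int(round(train_fraction * len(idx_c)))
        n_train = min(max(n_train, 1), len(idx_c) - 1)
        side, tst = idx_c[:n_train], idx_c[n_train:]
        if val_fraction_of_train > 0:
            n_val = int(round(val_fraction_of_train * len(side)))
            n_val = min(max(n_val, 1), len(side) - 1)
        else:
            n_val = 0
        val.extend(side[:n_val])
        train.extend(side[n_val:])
        test.extend(tst)
    return SplitPlan(
        train_idx=np.sort(np.asarray(train, dtype=int)),
        val_idx=np.sort(np.asarray(val, dtype=int)),
        test_idx=np.sort(np.asarray(test, dtype=int)),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def confusion_counts(y_true, y_pred, positive) -> dict:
    """One-vs-rest TP/TN/FP/FN counts for one class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos_t = y_true == positive
    pos_p = y_pred == positive
    return {
        "TP": int(np.sum(pos_t & pos_p)),
        "TN": int(np.sum(~pos_t & ~pos_p)),
        "FP": int(np.sum(~pos_t & pos_p)),
        "FN": int(np.sum(pos_t & ~pos_p)),
    }


def _safe_div(num, den):
    return num / den if den > 0 else np.nan


def evaluate(probs, labels, test_idx=None, classes=None) -> dict:
    """Classification metrics on the evaluated subset.

    accuracy, one-vs-rest macro sensitivity/specificity/precision, macro and
    class-frequency-weighted F1, and macro one-vs-rest AUC from the
    probability columns.  Classes absent from the evaluated subset are
    excluded from macro averages with a warning.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    if test_idx is not None:
        test_idx = np.asarray(test_idx, dtype=int)
        probs = probs[test_idx]
        labels = labels[test_idx]
    if classes is None:
        classes = np.arange(probs.shape[1])
    classes = np.asarray(classes)
    preds = classes[np.argmax(probs, axis=1)]

    sens, spec, prec, f1s, supports = [], [], [], [], []
    for ci, c in enumerate(classes):
        counts = confusion_counts(labels, preds, c)
        support = counts["TP"] + counts["FN"]
        if support == 0:
            warnings.warn(f"class {c!r} absent from evaluation set; excluded from macros")
            continue
        r = _safe_div(counts["TP"], counts["TP"] + counts["FN"])
        p = _safe_div(counts["TP"], counts["TP"] + counts["FP"])
        s = _safe_div(counts["TN"], counts["TN"] + counts["FP"])
        if np.isnan(p):  # class never predicted: precision/F1 count as 0
            p_for_f1 = 0.0
        else:
            p_for_f1 = p
        f1 = 0.0 if (p_for_f1 + r) == 0 else 2 * p_for_f1 * r / (p_for_f1 + r)
        sens.append(r)
        spec.append(s)
        prec.append(0.0 if np.isnan(p) else p)
        f1s.append(f1)
        supports.append(support)

    supports = np.asarray(supports, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN macro slices
        out = {
            "accuracy": float(np.mean(preds == labels)),
            "sensitivity": float(np.nanmean(sens)),
            "specificity": float(np.nanmean(spec)),
            "precision": float(np.nanmean(prec)),
            "f1_macro": float(np.mean(f1s)),
            "f1_weighted": float(np.sum(np.asarray(f1s) * supports / supports.sum())),
            "auc_macro": _macro_auc(probs, labels, classes),
        }
    return out


def _macro_auc(probs, labels, classes) -> float:
    aucs = []
    for ci, c in enumerate(classes):
        pos = labels == c
        if pos.all() or not pos.any():
            continue
        scores = probs[:, ci]
        if np.allclose(scores, scores[0]):
            aucs.append(0.5)  # constant scores carry no ranking information
        else:
            aucs.append(roc_auc_score(pos.astype(int), scores))
    return float(np.mean(aucs)) if aucs else np.nan


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def paired_ttest(a, b) -> float:
    """Two-tailed paired t-test p-value on per-split scores.

    Degenerate cases: all-zero differences give p = 1; zero-variance nonzero
    differences give the p → 0 limit.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired samples must have equal length >= 2")
    d = a - b
    if np.allclose(d, 0.0):
        return 1.0
    if np.isclose(d.std(ddof=1), 0.0):
        return 0.0
    return float(scipy.stats.ttest_rel(a, b).pvalue)


def cohens_d(a, b) -> float:
    """Pooled-SD standardized mean difference (n1+n2−2 denominator)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    diff = a.mean() - b.mean()
    pooled = np.sqrt(
        ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    )
    if pooled == 0:
        return 0.0 if diff == 0 else float(np.sign(diff) * np.inf)
    return float(diff / pooled)


def ci95(values) -> tuple:
    """mean ± t_{0.975, n−1} · sd/√n confidence interval for the mean."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    mean = float(values.mean())
    if n < 2:
        return (mean, mean)
    half = float(scipy.stats.t.ppf(0.975, n - 1) * values.std(ddof=1) / np.sqrt(n))
    return (mean - half, mean + half)


# ---------------------------------------------------------------------------
# hyperparameter grid search
# ---------------------------------------------------------------------------


def candidate_configs(
    metric: str,
    gamma_grid=DEFAULT_GAMMA_GRID,
    weight_grid=DEFAULT_WEIGHT_GRID,
    k: int = 10,
) -> list:
    """Enumerate grid candidates for a metric family.

    Cosine metrics have no tunable kernel parameters (single candidate);
    RBF metrics vary gamma; hybrid metrics vary gamma × weight.  Candidates
    are ordered by ascending gamma then ascending weight, which makes
    "first best wins" equivalent to the tie rule (smaller gamma, then
    smaller weight).
    """
    if metric in ("cosine_similarity", "cosine_distance"):
        return [SimilarityConfig(metric=metric, k=k)]
    if metric in ("rbf_similarity", "rbf_distance"):
        return [SimilarityConfig(metric=metric, gamma=g, k=k) for g in sorted(gamma_grid)]
    configs = []
    for g, w in product(sorted(gamma_grid), sorted(weight_grid)):
        if metric == "hybrid_similarity":
            configs.append(SimilarityConfig(metric=metric, gamma=g, beta=w, k=k))
        elif metric == "hybrid_distance":
            configs.append(SimilarityConfig(metric=metric, gamma=g, alpha=w, k=k))
        else:
            raise ValueError(f"unknown metric {metric!r}")
    return configs


def grid_search(
    views,
    labels,
    train_idx,
    metric: str,
    gamma_grid=DEFAULT_GAMMA_GRID,
    weight_grid=DEFAULT_WEIGHT_GRID,
    k: int = 10,
    seed: int = 0,
    **fit_kwargs,
) -> SimilarityConfig:
    """Select the best graph configuration using the training split only.

    An inner stratified validation subset is carved from ``train_idx``; each
    candidate is trained with labels masked outside the inner-training set
    and scored by validation accuracy.  Ties go to the smaller gamma, then
    the smaller weight (via candidate enumeration order).
    """
    labels = np.asarray(labels)
    train_idx = np.asarray(train_idx, dtype=int)
    configs = candidate_configs(metric, gamma_grid, weight_grid, k)
    if len(configs) == 1:
        return configs[0]

    inner = stratified_split(labels[train_idx], 0.8, seed=seed)
    inner_train = train_idx[inner.train_side]
    inner_val = train_idx[inner.test_idx]

    y_masked = np.full(labels.shape, -1, dtype=labels.dtype)
    y_masked[inner_train] = labels[inner_train]

    best_cfg, best_acc = None, -np.inf
    for cfg in configs:
        clf = MultiOmicsGCNClassifier(
            metric=cfg.metric,
            gamma=cfg.gamma,
            beta=cfg.beta,
            alpha=cfg.alpha,
            k=cfg.k,
            random_state=seed,
            **fit_kwargs,
        )
        clf.fit(views, y_masked)
        acc = float(np.mean(clf.transduction_[inner_val] == labels[inner_val]))
        if acc > best_acc:  # strict: earlier (smaller-parameter) candidate wins ties
            best_acc, best_cfg = acc, cfg
    return best_cfg


# ---------------------------------------------------------------------------
# benchmark
# ---------------------------------------------------------------------------


@dataclass
class BenchmarkReport:
    """Per-split metrics, mean ± SD summaries and pairwise comparisons."""

    per_split: pd.DataFrame
    summary: pd.DataFrame
    comparisons: pd.DataFrame

    def to_csv(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        kw = dict(index=False, float_format="%.10g", lineterminator="\n")
        self.per_split.to_csv(outdir / "per_split.csv", **kw)
        self.summary.to_csv(outdir / "summary.csv", **kw)
        self.comparisons.to_csv(outdir / "comparisons.csv", **kw)


def run_single(
    views,
    labels,
    config: SimilarityConfig,
    variant: str,
    train_config: TrainConfig,
    seed: int,
):
    """One dataset × metric × variant × seed run; returns (metrics, history)."""
    labels = np.asarray(labels)
    plan = stratified_split(
        labels,
        train_config.train_fraction,
        seed=seed,
        val_fraction_of_train=train_config.validation_fraction_of_train,
    )
    y_masked = np.full(labels.shape, -1, dtype=labels.dtype)
    y_masked[plan.train_side] = labels[plan.train_side]
    clf = MultiOmicsGCNClassifier(
        metric=config.metric,
        gamma=config.gamma,
        beta=config.beta,
        alpha=config.alpha,
        k=config.k,
        variant=variant,
        hidden_dim=train_config.hidden_dim,
        learning_rate=train_config.learning_rate,
        weight_decay=train_config.weight_decay,
        max_epochs=train_config.max_epochs,
        patience=train_config.patience,
        random_state=seed,
    )
    clf.fit(views, y_masked, val_idx=plan.val_idx)
    metrics = evaluate(clf.probabilities_, labels, plan.test_idx, classes=clf.classes_)
    return metrics, clf.history_


def run_benchmark(
    views,
    labels,
    configs: dict | None = None,
    variants=("full",),
    train_config: TrainConfig | None = None,
    baseline: str = "cosine_similarity",
    log=None,
) -> BenchmarkReport:
    """Run every metric × variant over the configured seeds.

    ``configs`` maps metric name to a SimilarityConfig (default: all six
    metrics with median-heuristic gamma and the default k).  Comparisons are
    paired against the baseline metric within the ``full`` variant, and
    across variants within the baseline metric.
    """
    train_config = train_config or TrainConfig()
    if configs is None:
        configs = {m: SimilarityConfig(metric=m, k=train_config.k) for m in METRICS}

    rows = []
    for metric_name, cfg in configs.items():
        for variant in variants:
            if variant == "no_gcn" and metric_name != baseline:
                continue  # graph-free ablation does not depend on the metric
            for seed in train_config.seeds:
                try:
                    metrics, history = run_single(
                        views, labels, cfg, variant, train_config, seed
                    )
                except Exception as exc:
                    raise RuntimeError(
                        f"benchmark failed at metric={metric_name} "
                        f"variant={variant} seed={seed}"
                    ) from exc
                row = {"metric": metric_name, "variant": variant, "seed": seed}
                row.update(metrics)
                row["stopped_epoch"] = history.stopped_epoch
                row["best_epoch"] = history.best_epoch
                rows.append(row)
                if log is not None:
                    log(row)
    per_split = pd.DataFrame(rows)

    summary_rows = []
    for (metric_name, variant), grp in per_split.groupby(["metric", "variant"], sort=True):
        for col in METRIC_COLUMNS:
            vals = grp[col].to_numpy(dtype=float)
            lo, hi = ci95(vals)
            summary_rows.append(
                {
                    "metric": metric_name,
                    "variant": variant,
                    "measure": col,
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                    "ci95_low": lo,
                    "ci95_high": hi,
                }
            )
    summary = pd.DataFrame(summary_rows)

    comp_rows = []
    base_grp = per_split[
        (per_split["metric"] == baseline) & (per_split["variant"] == variants[0])
    ].sort_values("seed")
    if len(base_grp):
        for (metric_name, variant), grp in per_split.groupby(["metric", "variant"], sort=True):
            if metric_name == baseline and variant == variants[0]:
                continue
            grp = grp.sort_values("seed")
            if list(grp["seed"]) != list(base_grp["seed"]) or len(grp) < 2:
                continue
            for col in ("accuracy", "f1_macro", "auc_macro"):
                a = base_grp[col].to_numpy(dtype=float)
                b = grp[col].to_numpy(dtype=float)
                comp_rows.append(
                    {
                        "baseline": baseline,
                        "metric": metric_name,
                        "variant": variant,
                        "measure": col,
                        "mean_baseline": float(a.mean()),
                        "mean_other": float(b.mean()),
                        "p_value": paired_ttest(a, b),
                        "cohens_d": cohens_d(a, b),
                    }
                )
    comparisons = pd.DataFrame(comp_rows)
    return BenchmarkReport(per_split=per_split, summary=summary, comparisons=comparisons)
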