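"""Supervised disease-subtype stratification from pathway PRSs.

Enriched pathway PRSs (competitive P < alpha on training data, each at its
best predictive P-value threshold) feed a lasso-regularized linear model
of the 0/1 subtype label; the penalty is chosen by k-fold cross-validated
mean squared error and performance is the squared Pearson correlation
between predictions and labels in a held-out test split.  Enrichment,
threshold optimization and lasso fitting all happen inside the training
split only.  A matched negative control repeats the pipeline with gene
annotations displaced by 5 Mb.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LassoCV, LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

from .annotate import MembershipFlags, build_membership, shift_annotation
from .io import GeneSetCollection, GeneTable, HarmonizedStudy
from .prs import (
    DEFAULT_R2,
    DEFAULT_THRESHOLD_GRID,
    DEFAULT_WINDOW_BP,
    PathwayScoreMatrix,
    clump_pathways,
    fit_association,
    score_pathways,
    select_best_threshold,
)
from .enrichment import enrich_all

__all__ = [
    "SubtypeDataset",
    "StratificationModel",
    "StratifyConfig",
    "StratificationOutcome",
    "split_train_test",
    "split_leave_one_cohort_out",
    "train_subtype_model",
    "evaluate_model",
    "run_stratification",
    "run_shift_control",
    "predict_single_trait",
]


@dataclass
class SubtypeDataset:
    """Train/test split scaffolding with stratified CV folds."""

    individuals: list[str]
    labels: np.ndarray  # 0/1 per individual
    train_idx: np.ndarray
    test_idx: np.ndarray
    fold_ids: np.ndarray  # fold per *training* individual
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_idx) & set(self.test_idx):
            raise ValueError("train and test individuals overlap")
        train_labels = self.labels[self.train_idx]
        if len(np.unique(train_labels)) < 2:
            raise ValueError("training split must contain both subtype labels")


@dataclass
class StratificationModel:
    pathways: list[str]
    coef: np.ndarray
    intercept: float
    alpha: float  # chosen penalty strength
    family: str = "linear"
    seed: int = 0
    k_folds: int = 5

    def selected(self, tol: float = 1e-10) -> list[str]:
        return [p for p, c in zip(self.pathways, self.coef) if abs(c) > tol]

    def predict(self, scores: pd.DataFrame) -> np.ndarray:
        X = scores[self.pathways].to_numpy(float)
        return X @ self.coef + self.intercept


@dataclass
class StratifyConfig:
    train_fraction: float = 0.8
    k_folds: int = 5
    enrich_alpha: float = 0.05
    n_perm: int = 1000
    r2_threshold: float = DEFAULT_R2
    window_bp: int = DEFAULT_WINDOW_BP
    threshold_grid: tuple = DEFAULT_THRESHOLD_GRID
    family: str = "linear"
    seed: int = 0


@dataclass
class StratificationOutcome:
    model: StratificationModel
    enriched: list[str]
    thresholds: dict[str, float]
    test_r2: float
    train_scores: PathwayScoreMatrix | None = None
    test_scores: PathwayScoreMatrix | None = None
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------


def split_train_test(
    individuals: list[str],
    labels,
    train_fraction: float = 0.8,
    k_folds: int = 5,
    seed: int = 0,
) -> SubtypeDataset:
    """Stratified-by-label train/test split with stratified CV folds
    inside the training set; reproducible given ``seed``."""
    labels = np.asarray(labels, dtype=int)
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie strictly in (0, 1)")
    classes, counts = np.unique(labels), np.bincount(labels)
    if len(classes) != 2:
        raise ValueError("labels must contain exactly two classes")
    if counts.min() < k_folds:
        raise ValueError(
            f"smallest class has {counts.min()} members < k_folds={k_folds}"
        )
    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    for c in classes:
        idx = np.nonzero(labels == c)[0]
        idx = rng.permutation(idx)
        n_train = int(round(train_fraction * len(idx)))
        train_parts.append(idx[:n_train])
        test_parts.append(idx[n_train:])
    train_idx = np.sort(np.concatenate(train_parts))
    test_idx = np.sort(np.concatenate(test_parts))
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=int(seed) % (2**32))
    fold_ids = np.empty(len(train_idx), dtype=int)
    for f, (_, hold) in enumerate(skf.split(train_idx[:, None], labels[train_idx])):
        fold_ids[hold] = f
    return SubtypeDataset(list(individuals), labels, train_idx, test_idx, fold_ids, int(seed))


def split_leave_one_cohort_out(
    individuals: list[str],
    labels,
    cohorts,
    k_folds: int = 5,
    seed: int = 0,
) -> list[SubtypeDataset]:
    """Leave-one-cohort-out splits: each cohort is the test set exactly
    once while the remaining cohorts train (useful when the target sample
    is a collection of genotyping cohorts)."""
    labels = np.asarray(labels, dtype=int)
    cohorts = np.asarray(cohorts)
    datasets = []
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=int(seed) % (2**32))
    for cohort in pd.unique(cohorts):
        test_idx = np.nonzero(cohorts == cohort)[0]
        train_idx = np.nonzero(cohorts != cohort)[0]
        fold_ids = np.empty(len(train_idx), dtype=int)
        for f, (_, hold) in enumerate(skf.split(train_idx[:, None], labels[train_idx])):
            fold_ids[hold] = f
        datasets.append(
            SubtypeDataset(list(individuals), labels, train_idx, test_idx, fold_ids, int(seed))
        )
    return datasets


# ---------------------------------------------------------------------------
# model fitting and evaluation
# ---------------------------------------------------------------------------


def train_subtype_model(
    scores: pd.DataFrame,
    labels,
    fold_ids: np.ndarray,
    family: str = "linear",
    seed: int = 0,
    rule: str = "min",
) -> StratificationModel:
    """Lasso over pathway PRS columns; penalty by minimal CV MSE.

    The default 'linear' family fits a Gaussian lasso on the 0/1 label
    with mean-squared-error cross-validation; 'logistic' fits an
    L1-penalized logistic regression instead.  ``rule='1se'`` picks the
    sparsest penalty within one standard error of the CV-MSE minimum
    instead of the minimum itself (more conservative under pure noise).
    """
    X = scores.to_numpy(float)
    y = np.asarray(labels, dtype=float)
    fold_ids = np.asarray(fold_ids)
    k = len(np.unique(fold_ids))
    cv = [(np.nonzero(fold_ids != f)[0], np.nonzero(fold_ids == f)[0]) for f in sorted(set(fold_ids))]
    if X.shape[1] == 0:
        warnings.warn("no enriched pathway: intercept-only model", stacklevel=2)
        return StratificationModel([], np.zeros(0), float(y.mean()), np.inf, family, seed, k)
    if family == "linear":
        fit = LassoCV(cv=cv, alphas=100, max_iter=50_000, tol=1e-6).fit(X, y)
        alpha = float(fit.alpha_)
        coef, intercept = fit.coef_.copy(), float(fit.intercept_)
        if rule == "1se":
            mean_mse = fit.mse_path_.mean(axis=1)
            se = fit.mse_path_.std(axis=1, ddof=1) / np.sqrt(fit.mse_path_.shape[1])
            best = int(np.argmin(mean_mse))
            ok = mean_mse <= mean_mse[best] + se[best]
            alpha = float(fit.alphas_[ok].max())
            from sklearn.linear_model import Lasso

            refit = Lasso(alpha=alpha, max_iter=50_000, tol=1e-6).fit(X, y)
            coef, intercept = refit.coef_.copy(), float(refit.intercept_)
        elif rule != "min":
            raise ValueError(f"unknown rule {rule!r}")
        return StratificationModel(
            list(scores.columns), coef, intercept, alpha, family, seed, k,
        )
    if family == "logistic":
        fit = LogisticRegressionCV(
            Cs=20, cv=k, penalty="l1", solver="saga", max_iter=10_000,
            random_state=int(seed) % (2**32),
        ).fit(X, y.astype(int))
        return StratificationModel(
            list(scores.columns), fit.coef_[0].copy(), float(fit.intercept_[0]),
            float(1.0 / fit.C_[0]), family, seed, k,
        )
    raise ValueError(f"unknown family {family!r}")


def evaluate_model(model: StratificationModel, scores: pd.DataFrame, labels) -> float:
    """Test-set R^2: squared Pearson correlation between predictions and
    the 0/1 labels.  Constant predictions give R^2 = 0 with a warning."""
    y = np.asarray(labels, dtype=float)
    if model.pathways:
        missing = [p for p in model.pathways if p not in scores.columns]
        if missing:
            raise KeyError(f"test scores lack model pathways: {missing[:5]}")
        pred = model.predict(scores)
    else:
        pred = np.full(len(y), model.intercept)
    if np.std(pred) == 0 or np.std(y) == 0:
        warnings.warn("constant predictions or labels: R^2 defined as 0", stacklevel=2)
        return 0.0
    r = float(np.corrcoef(pred, y)[0, 1])
    return r * r


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------


def run_stratification(
    study: HarmonizedStudy,
    flags: MembershipFlags,
    labels,
    config: StratifyConfig | None = None,
    dataset: SubtypeDataset | None = None,
) -> StratificationOutcome:
    """Full train/test stratification pipeline.

    Enrichment (competitive P < alpha), per-pathway threshold optimization
    and lasso fitting are performed on the training split only; the test
    split enters only at final evaluation.  Standardization parameters are
    estimated on the training scores and applied to the test scores.
    """
    cfg = config or StratifyConfig()
    labels = np.asarray(labels, dtype=int)
    if dataset is None:
        dataset = split_train_test(
            study.panel.samples, labels, cfg.train_fraction, cfg.k_folds, cfg.seed
        )
    train_study = study.subset_samples(dataset.train_idx)
    y_train = labels[dataset.train_idx].astype(float)
    clump = clump_pathways(train_study, flags, cfg.r2_threshold, cfg.window_bp)
    enr = enrich_all(
        train_study, flags, y_train, N=cfg.n_perm, seed=cfg.seed, clump=clump
    )
    enriched = [r.pathway for r in enr if r.p_competitive < cfg.enrich_alpha]
    thresholds: dict[str, float] = {}
    for k in enriched:
        try:
            thr, _ = select_best_threshold(
                train_study, clump.retained[k], y_train, cfg.threshold_grid, k
            )
        except ValueError:
            continue
        thresholds[k] = thr
    enriched = [k for k in enriched if k in thresholds]

    if not enriched:
        model = train_subtype_model(
            pd.DataFrame(index=[study.panel.samples[i] for i in dataset.train_idx]),
            y_train, dataset.fold_ids, cfg.family, cfg.seed,
        )
        return StratificationOutcome(model, [], {}, 0.0, extras={"enrichment": enr})

    sub_clump_train = {k: clump.retained[k] for k in enriched}
    raw_train = score_pathways(
        train_study,
        _restricted(clump, sub_clump_train),
        thresholds,
        standardized=False,
    )
    test_study = study.subset_samples(dataset.test_idx)
    raw_test = score_pathways(
        test_study, _restricted(clump, sub_clump_train), thresholds, standardized=False
    )
    mu = raw_train.values.mean(axis=0)
    sd = raw_train.values.std(axis=0, ddof=1).replace(0.0, 1.0)
    train_scores = (raw_train.values - mu) / sd
    test_scores = (raw_test.values - mu) / sd

    model = train_subtype_model(train_scores, y_train, dataset.fold_ids, cfg.family, cfg.seed)
    test_r2 = evaluate_model(model, test_scores, labels[dataset.test_idx])
    return StratificationOutcome(
        model,
        enriched,
        thresholds,
        test_r2,
        PathwayScoreMatrix(train_scores, thresholds, True),
        PathwayScoreMatrix(test_scores, thresholds, True),
        extras={"enrichment": enr, "dataset": dataset},
    )


def _restricted(clump, retained: dict[str, list[str]]):
    from .prs import ClumpResult

    return ClumpResult(
        retained, clump.background, clump.r2_threshold, clump.window_bp, clump.p_ceiling
    )


def run_shift_control(
    study: HarmonizedStudy,
    genes_extended: GeneTable,
    sets: GeneSetCollection,
    labels,
    chrom_lengths: dict[str, int],
    shift_bp: int = 5_000_000,
    config: StratifyConfig | None = None,
    min_genes: int = 10,
    max_genes: int = 2000,
    exclude=None,
) -> tuple[float, float]:
    """Paired test R^2 of the true pipeline vs the 5 Mb-shifted negative
    control, run on identical splits and seeds.  Returns
    (r2_unshifted, r2_shifted)."""
    cfg = config or StratifyConfig()
    labels = np.asarray(labels, dtype=int)
    dataset = split_train_test(
        study.panel.samples, labels, cfg.train_fraction, cfg.k_folds, cfg.seed
    )
    flags = build_membership(study, genes_extended, sets, exclude, min_genes, max_genes)
    shifted_genes, _ = shift_annotation(genes_extended, shift_bp, chrom_lengths)
    flags_shift = build_membership(study, shifted_genes, sets, exclude, min_genes, max_genes)
    out = run_stratification(study, flags, labels, cfg, dataset)
    out_shift = run_stratification(study, flags_shift, labels, cfg, dataset)
    return out.test_r2, out_shift.test_r2


def predict_single_trait(
    study: HarmonizedStudy,
    flags: MembershipFlags,
    case_control,
    config: StratifyConfig | None = None,
) -> StratificationOutcome:
    """Single-trait prediction: the stratification machinery with
    case/control status as the label."""
    return run_stratification(study, flags, case_control, config)


def genome_wide_ct_r2(
    study: HarmonizedStudy,
    labels,
    dataset: SubtypeDataset,
    r2_threshold: float = DEFAULT_R2,
    window_bp: int = DEFAULT_WINDOW_BP,
    grid=DEFAULT_THRESHOLD_GRID,
) -> float:
    """Baseline: genome-wide clumping + thresholding PRS, threshold chosen
    on training, evaluated as squared correlation on the test split."""
    labels = np.asarray(labels, dtype=float)
    train_study = study.subset_samples(dataset.train_idx)
    all_ids = list(study.snp_ids)
    flags_all = MembershipFlags(
        study.snp_ids,
        ["__genome__"],
        np.ones((len(all_ids), 1), bool),
        np.ones(len(all_ids), bool),
        {"__genome__": 0},
    )
    clump = clump_pathways(train_study, flags_all, r2_threshold, window_bp)
    thr, _ = select_best_threshold(
        train_study, clump.retained["__genome__"], labels[dataset.train_idx], grid
    )
    from .prs import compute_prs

    test_study = study.subset_samples(dataset.test_idx)
    scores, _ = compute_prs(test_study, clump.retained["__genome__"], thr)
    if np.std(scores) == 0:
        return 0.0
    return fit_association(labels[dataset.test_idx], scores).r2
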