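"""Pathway-aware clumping + thresholding and pathway PRS computation.

The pathway PRS of individual *i* for pathway *k* is

    PRS_ik = sum_j beta_j * G_ij

over the pathway's clumped SNPs *j* passing the P-value threshold, where
``beta_j`` is the GWAS effect size and ``G_ij`` the dosage.  Clumping is
performed on each pathway independently so that SNPs shared between
pathways contribute to every pathway they belong to.  A single-pass
bit-flag algorithm makes this cheap: each SNP carries one membership bit
per pathway, and an index SNP clears bits of linked SNPs only in the
pathways it itself belongs to, which is provably identical to running
greedy clumping separately per pathway (the per-pathway greedy routine is
kept as an oracle and exposed as :func:`clump_greedy`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotate import MembershipFlags
from .io import HarmonizedStudy

__all__ = [
    "BACKGROUND",
    "DEFAULT_R2",
    "DEFAULT_WINDOW_BP",
    "DEFAULT_THRESHOLD_GRID",
    "ClumpResult",
    "PathwayScoreMatrix",
    "AssociationResult",
    "clump_pathways",
    "clump_greedy",
    "pairwise_r2",
    "compute_prs",
    "score_pathways",
    "standardize",
    "residualize_phenotype",
    "fit_association",
    "select_best_threshold",
]

#: Name of the implicit genic-background "pathway".
BACKGROUND = "__background__"

DEFAULT_R2 = 0.1
DEFAULT_WINDOW_BP = 250_000
DEFAULT_THRESHOLD_GRID = (5e-8, 1e-5, 1e-3, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 1.0)


@dataclass
class ClumpResult:
    """Clumped ("independent") SNPs per pathway plus the genic background."""

    retained: dict[str, list[str]]  # pathway -> SNP ids, panel order
    background: list[str]
    r2_threshold: float
    window_bp: int
    p_ceiling: float

    def m(self, pathway: str) -> int:
        return len(self.retained[pathway])


@dataclass
class PathwayScoreMatrix:
    """Individuals x pathways PRS values.

    ``thresholds`` records the P-value threshold that produced each
    column; ``standardized`` is True once columns are mean-0 / sd-1.
    """

    values: pd.DataFrame
    thresholds: dict[str, float]
    standardized: bool = False

    @property
    def pathways(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class AssociationResult:
    pathway: str
    threshold: float
    r2: float
    p: float
    n: int
    n_snps: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.r2 <= 1:
            raise ValueError(f"R^2 out of [0,1]: {self.r2}")
        if not 0 < self.p <= 1:
            raise ValueError(f"P out of (0,1]: {self.p}")


# ---------------------------------------------------------------------------
# LD and clumping
# ---------------------------------------------------------------------------


def pairwise_r2(dosages: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between columns of a dosage matrix.

    Missing values must already be mean-imputed.  Monomorphic columns get
    r^2 = 0 against everything.
    """
    X = np.asarray(dosages, dtype=float)
    Xc = X - X.mean(axis=0)
    norm = np.sqrt((Xc**2).sum(axis=0))
    safe = np.where(norm == 0, 1.0, norm)
    Xn = Xc / safe
    r = Xn.T @ Xn
    r[norm == 0, :] = 0.0
    r[:, norm == 0] = 0.0
    np.fill_diagonal(r, 1.0)
    return r**2


def _clump_order(p: np.ndarray, pos: np.ndarray, ids: np.ndarray) -> np.ndarray:
    """Total processing order: ascending P, ties by position then id."""
    return np.lexsort((ids, pos, p))


def clump_pathways(
    study: HarmonizedStudy,
    flags: MembershipFlags,
    r2_threshold: float = DEFAULT_R2,
    window_bp: int = DEFAULT_WINDOW_BP,
    p_ceiling: float = 1.0,
) -> ClumpResult:
    """Single-pass bit-flag clumping of every pathway and the background.

    Processing SNPs by ascending GWAS P, a SNP that still carries any
    membership bit acts as index for exactly those pathways; linked SNPs
    (same chromosome, within ``window_bp``, r^2 >= ``r2_threshold``) lose
    the bits they share with the index.  A SNP's final bits equal its bits
    at its own processing time, so the retained set of each pathway is
    identical to greedy clumping run on that pathway alone.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    if not np.array_equal(flags.snp_ids, study.snp_ids):
        raise ValueError("membership flags not aligned with study SNPs")
    p = study.gwas_p
    pos = study.panel.snps["pos"].to_numpy(np.int64)
    chrom = study.panel.snps["chrom"].astype(str).to_numpy()
    ids = study.snp_ids
    n = len(ids)

    work = np.column_stack([flags.membership, flags.background]).copy()
    eligible = p <= p_ceiling
    work[~eligible] = False

    X = study.panel.imputed_dosages()
    Xc = X - X.mean(axis=0)
    norms = np.sqrt((Xc**2).sum(axis=0))
    norms = np.where(norms == 0, np.inf, norms)
    Xn = Xc / norms

    order = _clump_order(p, pos, ids)
    rank = np.empty(n, dtype=np.int64)
    rank[order] = np.arange(n)
    for s in order:
        fs = work[s]
        if not fs.any():
            continue
        cand = np.nonzero(
            (chrom == chrom[s])
            & (np.abs(pos - pos[s]) <= window_bp)
            & (rank > rank[s])
            & work.any(axis=1)
        )[0]
        if cand.size == 0:
            continue
        r = Xn[:, cand].T @ Xn[:, s]
        hit = cand[r**2 >= r2_threshold]
        work[hit] &= ~fs

    pathways = flags.pathways
    retained = {
        k: [ids[i] for i in np.nonzero(work[:, j] & eligible)[0]]
        for j, k in enumerate(pathways)
    }
    background = [ids[i] for i in np.nonzero(work[:, -1] & eligible)[0]]
    return ClumpResult(retained, background, r2_threshold, window_bp, p_ceiling)


def clump_greedy(
    member_ids: list[str],
    p: dict[str, float],
    pos: dict[str, int],
    chrom: dict[str, str],
    r2: "pd.DataFrame",
    r2_threshold: float,
    window_bp: int,
    p_ceiling: float = 1.0,
) -> list[str]:
    """Reference greedy clumping of a single SNP set.

    Repeatedly takes the remaining member with the smallest P <= ceiling
    (ties: position, then id) as index, retains it, and discards members
    within the window with r^2 >= threshold.  Used as the independent
    oracle for the bit-flag pass.
    """
    remaining = [s for s in member_ids if p[s] <= p_ceiling]
    retained = []
    while remaining:
        index = min(remaining, key=lambda s: (p[s], pos[s], s))
        retained.append(index)
        remaining = [
            s
            for s in remaining
            if s != index
            and not (
                chrom[s] == chrom[index]
                and abs(pos[s] - pos[index]) <= window_bp
                and r2.at[s, index] >= r2_threshold
            )
        ]
    return sorted(retained, key=lambda s: member_ids.index(s))


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def compute_prs(
    study: HarmonizedStudy,
    retained: list[str],
    threshold: float = 1.0,
    missing: str = "mean",
) -> tuple[np.ndarray, int]:
    """Raw pathway PRS: sum of beta_j * dosage_ij over retained SNPs with
    GWAS P <= threshold.  Missing dosages are mean-imputed by default
    (``missing='skip'`` drops the missing terms from the sum instead).
    Returns the score vector and the number of SNPs actually summed (a
    zero vector with count 0, plus a warning, when no SNP passes)."""
    if not retained:
        warnings.warn("no retained SNPs: returning zero scores", stacklevel=2)
        return np.zeros(study.panel.n_samples), 0
    sub = study.subset_snps(retained)
    use = sub.gwas_p <= threshold
    if not use.any():
        warnings.warn(
            f"no SNP passes threshold {threshold}: returning zero scores", stacklevel=2
        )
        return np.zeros(study.panel.n_samples), 0
    if missing == "mean":
        X = sub.panel.imputed_dosages()[:, use]
    elif missing == "skip":
        X = np.nan_to_num(sub.panel.dosages[:, use], nan=0.0)
    else:
        raise ValueError(f"unknown missing-dosage policy {missing!r}")
    beta = sub.beta[use]
    return X @ beta, int(use.sum())


def score_pathways(
    study: HarmonizedStudy,
    clump: ClumpResult,
    thresholds: dict[str, float] | float = 1.0,
    standardized: bool = True,
) -> PathwayScoreMatrix:
    """PRS matrix for every clumped pathway, optionally standardized."""
    cols = {}
    thr_used: dict[str, float] = {}
    for k, snps in clump.retained.items():
        thr = thresholds if isinstance(thresholds, (int, float)) else thresholds.get(k, 1.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scores, _ = compute_prs(study, snps, thr)
        cols[k] = scores
        thr_used[k] = float(thr)
    mat = PathwayScoreMatrix(
        pd.DataFrame(cols, index=study.panel.samples), thr_used, standardized=False
    )
    return standardize(mat) if standardized else mat


def standardize(matrix: PathwayScoreMatrix) -> PathwayScoreMatrix:
    """Column-wise z-scores (sample sd, ddof=1); constant columns become 0
    with a warning.  Idempotent."""
    vals = matrix.values.to_numpy(float)
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1) if len(vals) > 1 else np.zeros(vals.shape[1])
    out = np.zeros_like(vals)
    const = sd == 0
    if const.any():
        names = [c for c, f in zip(matrix.values.columns, const) if f]
        warnings.warn(f"constant PRS columns set to 0: {names[:5]}", stacklevel=2)
    nz = ~const
    out[:, nz] = (vals[:, nz] - mean[nz]) / sd[nz]
    df = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return PathwayScoreMatrix(df, dict(matrix.thresholds), standardized=True)


# ---------------------------------------------------------------------------
# association
# ---------------------------------------------------------------------------


def residualize_phenotype(
    pheno: np.ndarray,
    covariates: pd.DataFrame | np.ndarray,
    family: str = "linear",
    residual_type: str = "deviance",
) -> np.ndarray:
    """Regress covariates out of the phenotype before PRS association.

    ``linear`` returns ordinary least-squares residuals.  ``logistic``
    fits covariates-only logistic regression on a binary outcome and
    returns pseudo-residuals: deviance residuals by default, response
    residuals (y - fitted probability) with ``residual_type='response'``.
    """
    import statsmodels.api as sm

    y = np.asarray(pheno, dtype=float)
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if np.isnan(y).any() or np.isnan(X).any():
        raise ValueError("missing values: apply listwise deletion first")
    X1 = sm.add_constant(X, has_constant="add")
    if family == "linear":
        fit = sm.OLS(y, X1).fit()
        return np.asarray(fit.resid)
    if family == "logistic":
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise ValueError("logistic family requires a 0/1 outcome")
        try:
            fit = sm.GLM(y, X1, family=sm.families.Binomial()).fit()
        except Exception as exc:  # pragma: no cover - statsmodels raises various types
            raise RuntimeError(
                "logistic covariate fit failed (possible separation); "
                "remove or coarsen the offending covariate"
            ) from exc
        if not np.all(np.isfinite(fit.params)) or np.abs(fit.params).max() > 1e3:
            raise RuntimeError(
                "logistic covariate fit did not converge (possible separation); "
                "remove or coarsen the offending covariate"
            )
        if residual_type == "deviance":
            return np.asarray(fit.resid_deviance)
        if residual_type == "response":
            return np.asarray(fit.resid_response)
        raise ValueError(f"unknown residual_type {residual_type!r}")
    raise ValueError(f"unknown family {family!r}")


def fit_association(
    residual_pheno: np.ndarray, prs: np.ndarray, pathway: str = "", threshold: float = 1.0
) -> AssociationResult:
    """OLS of the (residualized) phenotype on a PRS: R^2 and two-sided
    slope P-value.  Equivalent to the Pearson correlation t-test, so the
    result is invariant to PRS standardization."""
    y = np.asarray(residual_pheno, dtype=float)
    x = np.asarray(prs, dtype=float)
    if len(y) != len(x):
        raise ValueError("length mismatch between phenotype and PRS")
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0:
        raise ValueError("constant PRS: association undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    r2 = min(r * r, 1.0)
    if r2 >= 1.0:
        p = np.nextafter(0, 1)
    else:
        t = r * np.sqrt((n - 2) / (1 - r2))
        p = float(2 * sps.t.sf(abs(t), df=n - 2))
    return AssociationResult(pathway, threshold, r2, max(p, np.nextafter(0, 1)), n)


def select_best_threshold(
    study: HarmonizedStudy,
    retained: list[str],
    residual_pheno: np.ndarray,
    grid=DEFAULT_THRESHOLD_GRID,
    pathway: str = "",
) -> tuple[float, AssociationResult]:
    """P-value threshold maximizing training R^2 (ties -> larger threshold)."""
    grid = sorted(set(float(g) for g in grid))
    if not grid:
        raise ValueError("empty threshold grid")
    best: tuple[float, AssociationResult] | None = None
    for thr in grid:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scores, n_snps = compute_prs(study, retained, thr)
        if n_snps == 0 or np.std(scores) == 0:
            continue
        res = fit_association(residual_pheno, scores, pathway, thr)
        res.n_snps = n_snps
        if best is None or res.r2 >= best[1].r2:
            best = (thr, res)
    if best is None:
        raise ValueError("no threshold in the grid retains any SNP")
    return best
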