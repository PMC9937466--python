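"""Competitive pathway enrichment via size-matched permutation.

A pathway's observed association P-value (P0) is compared against N null
"pathways", each formed by drawing the same number m of independent SNPs
from the clumped genic background.  The competitive P-value is

    P_comp = ( #{n : P_n < P0} + 1 ) / (N + 1)

with a pseudo-count of 1 in numerator and denominator, so the smallest
achievable value is 1/(N+1).  Ties P_n = P0 do not count (strict <).

Null associations are computed through an exact algebraic shortcut: with
centered beta-weighted dosage columns w_j, the null PRS of a SNP set S is
sum_{j in S} w_j, so its correlation with the phenotype needs only the
per-SNP phenotype covariances and the background Gram matrix.  The
resulting P-values are identical to scoring each null set explicitly and
regressing the phenotype on the standardized PRS (unit-tested).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .annotate import MembershipFlags
from .io import HarmonizedStudy
from .prs import (
    DEFAULT_R2,
    DEFAULT_WINDOW_BP,
    ClumpResult,
    clump_pathways,
    compute_prs,
    fit_association,
)

__all__ = [
    "EnrichmentResult",
    "build_background",
    "sample_null_sets",
    "competitive_pvalue",
    "enrich_all",
    "pathway_seed",
]

DEFAULT_PERMUTATIONS = 10_000


@dataclass
class EnrichmentResult:
    pathway: str
    m: int  # post-clump SNP count
    p_observed: float
    p_competitive: float
    n_perm: int
    seed: int

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("enrichment result requires m >= 1")
        lo = 1.0 / (self.n_perm + 1)
        if not lo - 1e-12 <= self.p_competitive <= 1 + 1e-12:
            raise ValueError(f"competitive P {self.p_competitive} outside [1/(N+1), 1]")


def build_background(clump: ClumpResult) -> list[str]:
    """The clumped genic background: the pool of independent genic SNPs
    from which null sets are drawn."""
    if not clump.background:
        raise ValueError("empty clumped background: no genic SNPs available")
    return list(clump.background)


def pathway_seed(seed: int, pathway: str) -> np.random.SeedSequence:
    """Deterministic per-pathway random substream, order-independent."""
    return np.random.SeedSequence([int(seed), zlib.crc32(pathway.encode())])


def sample_null_sets(
    background: list[str] | np.ndarray, m: int, N: int, seed
) -> np.ndarray:
    """N uniform without-replacement draws of m background indices.

    Returns an (N, m) integer array of positions into ``background``.
    ``seed`` may be an int or a numpy SeedSequence/Generator.
    """
    size = len(background)
    if m > size:
        raise ValueError(f"cannot draw m={m} SNPs from a background of {size}")
    if N < 1:
        raise ValueError("need at least one null set")
    rng = np.random.default_rng(seed)
    u = rng.random((N, size))
    return np.argpartition(u, m - 1, axis=1)[:, :m]


def competitive_pvalue(p_observed: float, p_nulls) -> float:
    """(#{P_n < P0} + 1) / (N + 1); strict inequality, pseudo-count 1."""
    p_nulls = np.asarray(p_nulls, dtype=float)
    if p_nulls.size == 0:
        raise ValueError("empty null P-value list")
    if not 0 < p_observed <= 1 or ((p_nulls <= 0) | (p_nulls > 1)).any():
        raise ValueError("P-values must lie in (0, 1]")
    return (int((p_nulls < p_observed).sum()) + 1) / (p_nulls.size + 1)


def enrich_all(
    study: HarmonizedStudy,
    flags: MembershipFlags,
    residual_pheno: np.ndarray,
    N: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
    clump: ClumpResult | None = None,
    r2_threshold: float = DEFAULT_R2,
    window_bp: int = DEFAULT_WINDOW_BP,
    fast: bool = True,
) -> list[EnrichmentResult]:
    """Competitive enrichment for every pathway.

    For each pathway: P0 from the regression of the residualized phenotype
    on its (threshold-1) PRS; N null sets of matched size m drawn from the
    clumped background, scored and regressed the same way; competitive P
    from the formula above.  Pathways with no clumped SNPs are skipped.
    Results are sorted by competitive P, ties broken by P0.
    """
    if N < 1:
        raise ValueError("need at least one permutation")
    y = np.asarray(residual_pheno, dtype=float)
    if len(y) != study.panel.n_samples:
        raise ValueError("phenotype length does not match panel samples")
    if clump is None:
        clump = clump_pathways(study, flags, r2_threshold, window_bp, p_ceiling=1.0)
    background = build_background(clump)
    bg_pos = study.panel.snps.index.get_indexer(background)

    X = study.panel.imputed_dosages()
    beta = study.beta
    W = (X[:, bg_pos] - X[:, bg_pos].mean(axis=0)) * beta[bg_pos]
    yc = y - y.mean()
    var_y = float(yc @ yc)
    cov_wy = W.T @ yc  # per-SNP covariance numerators
    gram = W.T @ W if fast else None
    n = len(y)

    results: list[EnrichmentResult] = []
    for pathway in flags.pathways:
        snps = clump.retained[pathway]
        m = len(snps)
        if m == 0:
            continue
        scores, _ = compute_prs(study, snps, threshold=1.0)
        if np.std(scores) == 0:
            continue
        p0 = fit_association(y, scores, pathway).p
        child = pathway_seed(seed, pathway)
        draws = sample_null_sets(background, m, N, child)
        if fast:
            num = cov_wy[draws].sum(axis=1)
            var_s = gram[draws[:, :, None], draws[:, None, :]].sum(axis=(1, 2))
            p_nulls = _corr_pvalues(num, var_s, var_y, n)
        else:
            p_nulls = np.empty(N)
            for i in range(N):
                ids = [background[j] for j in draws[i]]
                s, _ = compute_prs(study, ids, threshold=1.0)
                p_nulls[i] = fit_association(y, s).p if np.std(s) > 0 else 1.0
        results.append(
            EnrichmentResult(
                pathway, m, p0, competitive_pvalue(p0, p_nulls), N, int(seed)
            )
        )
    results.sort(key=lambda r: (r.p_competitive, r.p_observed))
    return results


def _corr_pvalues(num: np.ndarray, var_s: np.ndarray, var_y: float, n: int) -> np.ndarray:
    """Two-sided OLS slope P-values from correlation components."""
    out = np.ones_like(num, dtype=float)
    ok = var_s > 0
    r2 = np.zeros_like(num, dtype=float)
    r2[ok] = num[ok] ** 2 / (var_s[ok] * var_y)
    r2 = np.clip(r2, 0.0, 1.0)
    exact = ok & (r2 >= 1.0)
    mid = ok & ~exact
    t = np.sqrt(r2[mid] * (n - 2) / (1 - r2[mid]))
    out[mid] = 2 * sps.t.sf(t, df=n - 2)
    out[exact] = np.nextafter(0, 1)
    return np.maximum(out, np.nextafter(0, 1))
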