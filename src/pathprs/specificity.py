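"""Tissue/cell-type expression-specificity pathways and relevance scoring.

Expression specificity of a gene in a tissue is its expression divided by
its total expression across tissues (0 = not expressed, 1 = exclusively
expressed there).  Per tissue, genes are split into 11 quantile sets:
quantile 1 holds all non-expressed genes, quantiles 2-11 hold equal-count
bins of increasing specificity; each quantile becomes one gene set that
the enrichment machinery can test.  Two read-outs: the competitive P of
the top quantile alone, and a one-sided linear trend of -log10 competitive
P on quantile rank.

Also here: rank-normalized disease relevance scores for genes ((r+1)/(n+1)
over the n scored genes, unscored genes 0), their pathway-level mean, the
tie-corrected Kendall tau-b agreement statistic, and Fisher's method for
combining enrichment P-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import GeneSetCollection, ValidationError

__all__ = [
    "SpecificityMatrix",
    "RelevanceScoreTable",
    "compute_specificity",
    "build_quantile_sets",
    "top_quantile_test",
    "linear_trend_test",
    "relevance_scores",
    "kendall_agreement",
    "fisher_combine",
]

N_QUANTILES = 11


@dataclass
class SpecificityMatrix:
    """Gene x tissue specificity values plus per-tissue quantile labels."""

    values: pd.DataFrame  # genes x tissues, rows sum to 1
    quantiles: pd.DataFrame | None = None  # same shape, ints 1..n_quantiles


@dataclass
class RelevanceScoreTable:
    genes: pd.DataFrame  # index gene; columns raw, normalized
    pathways: pd.Series  # pathway -> relevance score


def compute_specificity(expression: pd.DataFrame) -> SpecificityMatrix:
    """Row-normalize a gene x tissue expression matrix.

    Genes with zero total expression must be removed beforehand; negative
    expression is rejected.
    """
    vals = expression.to_numpy(float)
    if (vals < 0).any():
        raise ValidationError("negative expression values")
    totals = vals.sum(axis=1)
    if (totals == 0).any():
        dead = expression.index[totals == 0][:5].tolist()
        raise ValidationError(f"genes expressed in no tissue (remove first): {dead}")
    return SpecificityMatrix(expression.div(totals, axis=0))


def build_quantile_sets(
    spec: SpecificityMatrix, n_quantiles: int = N_QUANTILES
) -> dict[str, GeneSetCollection]:
    """Per-tissue quantile gene sets named ``tissue@qK``.

    Quantile 1 = zero-specificity genes of the tissue; the remaining genes
    are split into ``n_quantiles - 1`` equal-count bins by increasing
    specificity (ties and remainders resolved by sorting on (specificity,
    gene id), so the single most specific gene always lands in the top
    bin).
    """
    if n_quantiles < 2:
        raise ValueError("need at least 2 quantiles")
    values = spec.values
    out: dict[str, GeneSetCollection] = {}
    qdf = pd.DataFrame(0, index=values.index, columns=values.columns, dtype=int)
    for tissue in values.columns:
        col = values[tissue]
        zero = col.index[col == 0.0]
        pos = col[col > 0.0]
        n_bins = n_quantiles - 1
        if len(pos) == 0:
            raise ValidationError(f"all genes have zero expression in tissue {tissue!r}")
        if len(pos) < n_bins:
            raise ValidationError(
                f"tissue {tissue!r}: {len(pos)} expressed genes < {n_bins} bins"
            )
        order = pos.sort_values(kind="mergesort").index  # stable; id breaks ties
        order = sorted(order, key=lambda g: (pos[g], str(g)))
        bins = np.array_split(np.array(order, dtype=object), n_bins)
        sets: dict[str, list[str]] = {}
        if len(zero):
            sets[f"{tissue}@q1"] = [str(g) for g in zero]
            qdf.loc[zero, tissue] = 1
        for b, members in enumerate(bins, start=2):
            sets[f"{tissue}@q{b}"] = [str(g) for g in members]
            qdf.loc[list(members), tissue] = b
        out[tissue] = GeneSetCollection(sets, {k: "specificity" for k in sets})
    spec.quantiles = qdf
    return out


def top_quantile_test(
    results: dict[str, float], tissue: str, n_quantiles: int = N_QUANTILES
) -> float:
    """Pass through the competitive P of the tissue's top quantile set.

    ``results`` maps gene-set names (``tissue@qK``) to competitive
    P-values.
    """
    key = f"{tissue}@q{n_quantiles}"
    if key not in results:
        raise KeyError(f"no enrichment result for top quantile set {key!r}")
    return float(results[key])


def linear_trend_test(p_by_quantile: dict[int, float] | pd.Series) -> float:
    """One-sided P for a positive linear trend of -log10 competitive P on
    quantile rank (signal increasing with expression specificity).

    Constant -log10 P values give P = 0.5 with a warning.
    """
    s = pd.Series(p_by_quantile).sort_index()
    if len(s) < 3:
        raise ValueError("need at least 3 quantile results")
    y = -np.log10(s.to_numpy(float))
    x = s.index.to_numpy(float)
    if np.allclose(y, y[0]):
        warnings.warn("constant -log10 P across quantiles: P = 0.5", stacklevel=2)
        return 0.5
    fit = sps.linregress(x, y)
    # one-sided P for slope > 0 from the two-sided t-test
    p_one = fit.pvalue / 2 if fit.slope > 0 else 1 - fit.pvalue / 2
    return float(p_one)


def relevance_scores(
    raw: dict[str, float] | pd.Series,
    sets: GeneSetCollection,
    ascending: bool = True,
) -> RelevanceScoreTable:
    """Rank-normalized gene relevance scores and their pathway means.

    The n genes with a raw score (> 0 treated as scored; 0/absent =
    unscored) are ranked and assigned (r+1)/(n+1).  With the default
    ascending convention the largest raw score gets r = n, hence a
    normalized score of 1; ``ascending=False`` reverses the ranking.
    Unscored genes get 0.  A pathway's relevance score is the mean
    normalized score over its member genes.
    """
    raw = pd.Series(raw, dtype=float)
    if (raw < 0).any():
        raise ValidationError("raw relevance scores must be >= 0")
    scored = raw[raw > 0]
    n = len(scored)
    normalized = pd.Series(0.0, index=raw.index)
    if n:
        ranks = scored.rank(method="average", ascending=ascending)
        normalized.loc[scored.index] = np.minimum((ranks + 1) / (n + 1), 1.0)
    genes = pd.DataFrame({"raw": raw, "normalized": normalized})
    pathway_scores = {}
    for name, members in sets.sets.items():
        vals = [float(normalized.get(g, 0.0)) for g in members]
        pathway_scores[name] = float(np.mean(vals)) if vals else 0.0
    return RelevanceScoreTable(genes, pd.Series(pathway_scores, name="relevance"))


def kendall_agreement(x, y) -> tuple[float, float]:
    """Kendall tau-b (tie-corrected) and its two-sided P-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("tau-b undefined: one input is entirely tied")
    tau, p = sps.kendalltau(x, y)  # scipy default is tau-b
    return float(tau), float(p)


def fisher_combine(pvalues) -> float:
    """Fisher's method: X^2 = -2 sum ln p against chi-square with 2k df."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("no P-values to combine")
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("P-values must lie in (0, 1]")
    stat = -2.0 * np.log(p).sum()
    return float(sps.chi2.sf(stat, df=2 * p.size))
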