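"""Synthetic data generation and the pathway-enrichment simulation study.

Genotypes come from a haplotype copy model organized in LD blocks: within
a block every SNP shares one minor-allele frequency and each haplotype
allele copies its left neighbour with probability ``q = sqrt(r2)``, so
adjacent genotypes have squared correlation ``r2`` in expectation while
blocks are mutually independent.  Quantitative traits follow a
point-normal architecture, ``Y = X beta + eps`` with column-standardized
genotypes ``X``, causal effects ``beta ~ N(0, h2)`` confined to SNPs of
"causal" pathways (each pathway assigned an enrichment fraction drawn
from {1%, ..., 30%}), and noise scaled so the genetic variance fraction
equals the target heritability h2.

The benchmark loop mirrors the enrichment evaluation design: base and
target samples are disjoint, a GWAS is run on the base sample, pathway
PRS competitive P-values are computed on the target sample, and agreement
with the true enrichment ranking is summarized by Kendall's tau.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import brentq

from .annotate import MembershipFlags, build_membership, extend_gene_bounds
from .enrichment import enrich_all
from .io import GenotypePanel, GeneSetCollection, GeneTable, SummaryStats, harmonize

__all__ = [
    "SimulationTruth",
    "SubtypeTruth",
    "ENRICHMENT_LEVELS",
    "simulate_genotypes",
    "simulate_gene_annotation",
    "simulate_gene_sets",
    "assign_causal_pathways",
    "simulate_phenotype",
    "run_gwas",
    "benchmark_enrichment",
    "simulate_subtypes",
    "simulate_subtype_scores",
    "membership_snp_sets",
]

#: Enrichment fractions assigned to causal pathways: 1..30% in 1% steps.
ENRICHMENT_LEVELS = np.round(np.arange(0.01, 0.301, 0.01), 2)


@dataclass
class SimulationTruth:
    """Ground truth of one simulated architecture."""

    causal_pathways: dict[str, float]  # pathway -> enrichment fraction
    causal_snps: list[str]
    true_enrichment: pd.Series  # causal-member fraction per pathway (spillover included)
    true_rank: pd.Series  # rank 1 = most enriched (average ranks on ties)
    seed: int
    h2: float | None = None
    beta: pd.Series | None = None  # per-SNP effect, 0 for non-causal
    genetic_values: np.ndarray | None = None  # X_std @ beta per individual


@dataclass
class SubtypeTruth:
    driver_pathways: list[str]
    shift: float
    labels: np.ndarray
    seed: int
    scale: float = 0.0
    genetic_score: np.ndarray | None = None


# ---------------------------------------------------------------------------
# genotypes and annotation
# ---------------------------------------------------------------------------


def simulate_genotypes(
    n_individuals: int,
    n_snps: int,
    block_size: int = 10,
    within_block_r2: float = 0.8,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
    spacing_bp: int = 2_000,
    chrom: str = "1",
) -> GenotypePanel:
    """LD-blocked diploid dosages via a haplotype copy model.

    Within each block of ``block_size`` consecutive SNPs, sharing one MAF
    drawn from ``maf_range``, a haplotype allele copies its left
    neighbour with probability sqrt(within_block_r2); blocks are
    independent.  SNPs sit ``spacing_bp`` apart on one chromosome.
    """
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError(f"maf_range must lie within (0, 0.5], got {maf_range}")
    if not 0 <= within_block_r2 <= 1:
        raise ValueError("within_block_r2 must lie in [0, 1]")
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    rng = np.random.default_rng(seed)
    q = float(np.sqrt(within_block_r2))
    n_blocks = (n_snps + block_size - 1) // block_size
    block_of = np.repeat(np.arange(n_blocks), block_size)[:n_snps]
    maf = rng.uniform(lo, hi, n_blocks)[block_of]

    H = np.empty((2 * n_individuals, n_snps), dtype=np.int8)
    fresh = (rng.random((2 * n_individuals, n_snps)) < maf).astype(np.int8)
    copy = rng.random((2 * n_individuals, n_snps)) < q
    first = np.zeros(n_snps, dtype=bool)
    first[np.searchsorted(block_of, np.arange(n_blocks))] = True
    H[:, 0] = fresh[:, 0]
    for j in range(1, n_snps):
        if first[j]:
            H[:, j] = fresh[:, j]
        else:
            H[:, j] = np.where(copy[:, j], H[:, j - 1], fresh[:, j])
    dosages = (H[0::2] + H[1::2]).astype(float)

    width = len(str(n_snps))
    ids = [f"snp{j:0{width}d}" for j in range(1, n_snps + 1)]
    meta = pd.DataFrame(
        {
            "chrom": [chrom] * n_snps,
            "pos": np.arange(1, n_snps + 1, dtype=np.int64) * spacing_bp,
            "a1": ["A"] * n_snps,
            "a2": ["G"] * n_snps,
        },
        index=pd.Index(ids, name="snp"),
    )
    samples = [f"ind{i:06d}" for i in range(n_individuals)]
    return GenotypePanel(samples, meta, dosages)


def simulate_gene_annotation(
    panel: GenotypePanel, n_genes: int, seed: int = 0
) -> GeneTable:
    """Tile the panel's SNPs into ``n_genes`` contiguous genes.

    Gene boundaries cover consecutive runs of SNP positions (so every SNP
    is genic before any region exclusion); strands are drawn at random.
    """
    rng = np.random.default_rng(seed)
    pos = panel.snps["pos"].to_numpy()
    chrom = panel.snps["chrom"].astype(str).to_numpy()
    chunks = np.array_split(np.arange(panel.n_snps), n_genes)
    rows = []
    width = len(str(n_genes))
    for g, idx in enumerate(chunks, 1):
        if len(idx) == 0:
            continue
        rows.append(
            (
                f"gene{g:0{width}d}",
                chrom[idx[0]],
                int(pos[idx[0]]),
                int(pos[idx[-1]]),
                "+" if rng.random() < 0.5 else "-",
            )
        )
    df = pd.DataFrame(rows, columns=["gene", "chrom", "start", "end", "strand"]).set_index("gene")
    return GeneTable(df)


def simulate_gene_sets(
    genes: GeneTable, n_sets: int, genes_per_set: int = 15, seed: int = 0
) -> GeneSetCollection:
    """Random gene sets (uniform without replacement within each set)."""
    rng = np.random.default_rng(seed)
    gene_ids = genes.gene_ids
    if genes_per_set > len(gene_ids):
        raise ValueError("genes_per_set exceeds the number of genes")
    width = len(str(n_sets))
    sets = {
        f"pathway{k:0{width}d}": sorted(
            rng.choice(gene_ids, size=genes_per_set, replace=False).tolist()
        )
        for k in range(1, n_sets + 1)
    }
    return GeneSetCollection(sets, {k: "synthetic" for k in sets})


def membership_snp_sets(flags: MembershipFlags) -> dict[str, list[str]]:
    """Pathway -> member SNP id lists from a membership matrix."""
    return {k: list(flags.members_of(k)) for k in flags.pathways}


# ---------------------------------------------------------------------------
# causal architecture and phenotype
# ---------------------------------------------------------------------------


def assign_causal_pathways(
    snp_sets: dict[str, list[str]],
    k_causal: int,
    seed: int = 0,
    levels: np.ndarray = ENRICHMENT_LEVELS,
) -> SimulationTruth:
    """Draw causal pathways and their causal SNPs.

    ``k_causal`` pathways are drawn without replacement; each receives an
    enrichment fraction drawn uniformly from ``levels`` and
    round(fraction * members) causal SNPs (minimum 1).  The true
    enrichment of *every* pathway is its causal-member fraction, which
    includes spillover through SNPs shared with causal pathways; the true
    rank (1 = most enriched, average on ties) is derived from it.
    """
    names = [k for k in snp_sets if len(snp_sets[k]) > 0]
    skipped = [k for k in snp_sets if len(snp_sets[k]) == 0]
    if k_causal > len(names):
        raise ValueError(f"k_causal={k_causal} exceeds {len(names)} non-empty pathways")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(np.array(names, dtype=object), size=k_causal, replace=False)
    fractions = rng.choice(levels, size=k_causal, replace=True)
    causal: set[str] = set()
    causal_pathways: dict[str, float] = {}
    for name, frac in zip(chosen, fractions):
        members = snp_sets[name]
        n_pick = max(1, int(round(frac * len(members))))
        picked = rng.choice(np.array(members, dtype=object), size=n_pick, replace=False)
        causal.update(picked.tolist())
        causal_pathways[str(name)] = float(frac)
    enrich = pd.Series(
        {k: len(causal.intersection(snp_sets[k])) / len(snp_sets[k]) for k in names},
        name="true_enrichment",
    )
    rank = enrich.rank(ascending=False, method="average")
    truth = SimulationTruth(causal_pathways, sorted(causal), enrich, rank, int(seed))
    if skipped:
        truth.__dict__.setdefault("log", skipped)
    return truth


def simulate_phenotype(
    panel: GenotypePanel, truth: SimulationTruth, h2: float, seed: int = 0
) -> np.ndarray:
    """Point-normal quantitative trait at target heritability.

    Y = X beta + eps with X the column-standardized dosage matrix, causal
    beta ~ N(0, h2) i.i.d., non-causal beta = 0, and noise variance
    var(X beta) * (1 - h2) / h2 so that the realized genetic variance
    fraction is h2 (up to the sampling error of the noise draw).
    """
    if not 0 < h2 < 1:
        raise ValueError("h2 must lie strictly in (0, 1)")
    if not truth.causal_snps:
        raise ValueError("no causal SNPs in the simulation truth")
    rng = np.random.default_rng(seed)
    beta = pd.Series(0.0, index=panel.snps.index)
    beta.loc[truth.causal_snps] = rng.normal(0.0, np.sqrt(h2), len(truth.causal_snps))
    X = panel.imputed_dosages()
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    g = ((X - mu) / sd) @ beta.to_numpy()
    var_g = float(np.var(g))
    if var_g == 0:
        raise ValueError("zero genetic variance: all causal SNPs monomorphic")
    eps = rng.normal(0.0, np.sqrt(var_g * (1 - h2) / h2), panel.n_samples)
    truth.h2 = float(h2)
    truth.beta = beta
    truth.genetic_values = g
    return g + eps


def run_gwas(panel: GenotypePanel, phenotype) -> SummaryStats:
    """Per-SNP simple linear regression of the phenotype on dosage.

    Returns beta, two-sided P (and the shared sample size) per SNP;
    monomorphic SNPs are reported with beta = 0, P = 1.
    """
    y = np.asarray(phenotype, dtype=float)
    n = panel.n_samples
    if n < 10:
        raise ValueError("need at least 10 individuals for a GWAS")
    if len(y) != n:
        raise ValueError("phenotype length does not match the panel")
    X = panel.imputed_dosages()
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    ss_x = (Xc**2).sum(axis=0)
    mono = ss_x == 0
    ss_x_safe = np.where(mono, 1.0, ss_x)
    beta = (Xc.T @ yc) / ss_x_safe
    resid_ss = (yc @ yc) - beta**2 * ss_x_safe
    resid_ss = np.maximum(resid_ss, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(resid_ss / (n - 2) / ss_x_safe)
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2 * sps.t.sf(np.abs(t), df=n - 2)
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    beta[mono] = 0.0
    p[mono] = 1.0
    table = panel.snps.copy()
    table = table.rename(columns={"a1": "effect_allele", "a2": "other_allele"})
    table["beta"] = beta
    table["p"] = p
    table["n"] = n
    return SummaryStats(table[["chrom", "pos", "effect_allele", "other_allele", "beta", "p", "n"]])


# ---------------------------------------------------------------------------
# benchmark
# ---------------------------------------------------------------------------


def benchmark_enrichment(
    h2_list=(0.1, 0.5),
    n_base: int = 10_000,
    n_target: int = 5_000,
    n_snps: int = 5_000,
    n_genes: int = 1_000,
    n_sets: int = 300,
    genes_per_set: int = 15,
    k_causal: int = 50,
    n_perm: int = 1_000,
    reps: int = 6,
    block_size: int = 10,
    within_block_r2: float = 0.8,
    min_genes: int = 2,
    seed: int = 0,
    progress: bool = False,
) -> pd.DataFrame:
    """Simulation benchmark of pathway enrichment recovery.

    For each (h2, rep): simulate genotypes for disjoint base and target
    samples, assign causal pathways, simulate the trait, run the GWAS on
    the base sample, compute competitive P-values on the target sample,
    and record Kendall's tau-b between -log10 competitive P and the true
    enrichment ranking.  Returns a long-format table with one row per
    (h2, rep).
    """
    rows = []
    ss = np.random.SeedSequence(int(seed))
    rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(reps)]
    for rep, rep_seed in enumerate(rep_seeds):
        panel = simulate_genotypes(
            n_base + n_target, n_snps, block_size, within_block_r2, seed=rep_seed
        )
        genes = simulate_gene_annotation(panel, n_genes, seed=rep_seed + 1)
        sets = simulate_gene_sets(genes, n_sets, genes_per_set, seed=rep_seed + 2)
        ext = extend_gene_bounds(genes, 0, 0)
        flags_all = build_membership(panel, ext, sets, min_genes=min_genes, max_genes=10**6)
        snp_sets = membership_snp_sets(flags_all)
        for h2 in h2_list:
            truth = assign_causal_pathways(snp_sets, k_causal, seed=rep_seed + 3)
            y = simulate_phenotype(panel, truth, h2, seed=rep_seed + 4)
            rng = np.random.default_rng(rep_seed + 5)
            perm = rng.permutation(panel.n_samples)
            base_idx, target_idx = perm[:n_base], perm[n_base : n_base + n_target]
            stats = run_gwas(panel.subset_samples(base_idx), y[base_idx])
            study = harmonize(stats, panel.subset_samples(target_idx))
            flags = build_membership(study, ext, sets, min_genes=min_genes, max_genes=10**6)
            y_target = y[target_idx] - y[target_idx].mean()
            enr = enrich_all(study, flags, y_target, N=n_perm, seed=rep_seed + 6)
            tau = _tau_vs_truth(enr, truth)
            rows.append(
                {"h2": h2, "n_base": n_base, "n_target": n_target, "rep": rep,
                 "seed": rep_seed, "tau": tau}
            )
            if progress:  # pragma: no cover
                print(f"h2={h2} rep={rep} tau={tau:.3f}", flush=True)
    return pd.DataFrame(rows)


def _tau_vs_truth(enrichment_results, truth: SimulationTruth) -> float:
    """Kendall tau-b between -log10 competitive P and true enrichment."""
    names = [r.pathway for r in enrichment_results]
    neglogp = np.array([-np.log10(r.p_competitive) for r in enrichment_results])
    true_vals = truth.true_enrichment.loc[names].to_numpy()
    tau, _ = sps.kendalltau(neglogp, true_vals)
    return float(tau)


# ---------------------------------------------------------------------------
# subtypes
# ---------------------------------------------------------------------------


def simulate_subtypes(
    panel: GenotypePanel,
    flags: MembershipFlags,
    driver_pathways: list[str],
    beta: pd.Series,
    shift: float,
    seed: int = 0,
) -> SubtypeTruth:
    """Binary subtype labels driven by chosen pathways.

    The linear predictor is the true-effect genetic score restricted to
    the driver pathways' SNPs, standardized; labels are Bernoulli with
    logistic probability sigma(c * g), with c calibrated so that the
    standardized score differs between the two labels by ``shift`` sd in
    expectation.  ``shift = 0`` gives labels independent of genotype.
    """
    if shift < 0:
        raise ValueError("shift must be >= 0")
    missing = [p for p in driver_pathways if p not in flags.pathways]
    if missing:
        raise KeyError(f"driver pathways not in membership: {missing}")
    rng = np.random.default_rng(seed)
    n = panel.n_samples
    if shift == 0:
        labels = rng.integers(0, 2, n)
        return SubtypeTruth(list(driver_pathways), 0.0, labels, int(seed), 0.0)
    member = np.zeros(flags.n_snps, dtype=bool)
    for p in driver_pathways:
        member |= flags.membership[:, flags.pathways.index(p)]
    ids = flags.snp_ids[member]
    X = panel.subset_snps(list(ids)).imputed_dosages()
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    g = ((X - X.mean(axis=0)) / sd) @ beta.loc[ids].to_numpy()
    if np.std(g) == 0:
        raise ValueError("driver pathways carry no genetic variance")
    g = (g - g.mean()) / g.std()

    def mean_diff(c: float) -> float:
        pr = 1.0 / (1.0 + np.exp(-c * g))
        p1 = pr.mean()
        if p1 in (0.0, 1.0):
            return 2 * np.abs(g).max()
        return float((g * pr).mean() / p1 - (g * (1 - pr)).mean() / (1 - p1))

    hi = 1.0
    while mean_diff(hi) < shift:
        hi *= 2
        if hi > 1e4:
            raise ValueError(f"requested shift {shift} is unattainable for this score")
    c = brentq(lambda v: mean_diff(v) - shift, 0.0, hi)
    labels = (rng.random(n) < 1.0 / (1.0 + np.exp(-c * g))).astype(int)
    return SubtypeTruth(list(driver_pathways), float(shift), labels, int(seed), float(c), g)


def simulate_subtype_scores(
    n: int, n_noise: int, shift: float, seed: int = 0, driver: str = "driver"
) -> tuple[pd.DataFrame, np.ndarray]:
    """Score-level subtype generator: standardized pathway PRS columns
    where only the driver column is shifted by ``shift`` sd in subtype 1.

    Convenience for studying the lasso stage in isolation.
    """
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, 2, n)
    cols = {driver: rng.normal(0, 1, n) + shift * labels}
    for k in range(1, n_noise + 1):
        cols[f"noise{k:03d}"] = rng.normal(0, 1, n)
    df = pd.DataFrame(cols, index=[f"ind{i:06d}" for i in range(n)])
    df = (df - df.mean()) / df.std(ddof=1)
    return df, labels
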