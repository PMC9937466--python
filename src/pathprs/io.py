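"""Readers, writers, genotype QC and base/target harmonization.

Supported external formats
--------------------------
* PLINK-1 ``bed``/``bim``/``fam`` triplets (SNP-major, 2-bit codes).
* Plain dosage TSV: header ``sample<TAB>snp1<TAB>snp2...``, one row per
  sample, dosages in ``[0, 2]``, empty field or ``NA`` for missing.
* GWAS summary statistics as whitespace/tab-delimited text with a
  configurable column map.
* GTF gene models (1-based inclusive coordinates) and GMT gene sets.

All containers are thin dataclasses around pandas/numpy objects so that
downstream modules can operate on plain arrays.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypePanel",
    "SummaryStats",
    "GeneTable",
    "GeneSetCollection",
    "HarmonizedStudy",
    "FormatError",
    "ValidationError",
    "HarmonizationError",
    "read_genotypes",
    "write_genotypes",
    "qc_filter",
    "hwe_exact_test",
    "read_summary_stats",
    "write_summary_stats",
    "read_gtf",
    "read_gmt",
    "write_gmt",
    "harmonize",
]

_PLINK_MAGIC = b"\x6c\x1b\x01"
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class FormatError(ValueError):
    """A file does not conform to its declared on-disk format."""


class ValidationError(ValueError):
    """Parsed data violate a container invariant."""


class HarmonizationError(ValueError):
    """Base and target data cannot be reconciled."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class GenotypePanel:
    """Target genotypes: samples x SNPs additive dosages in [0, 2].

    ``dosages[i, j]`` counts copies of allele ``a1`` of SNP ``j`` carried by
    sample ``i``; missing genotypes are NaN.  ``snps`` is indexed by SNP id
    with columns ``chrom``, ``pos`` (1-based), ``a1``, ``a2``.
    """

    samples: list[str]
    snps: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.snps)):
            raise ValidationError(
                f"dosage matrix {self.dosages.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        if self.snps.index.duplicated().any():
            dup = self.snps.index[self.snps.index.duplicated()][0]
            raise ValidationError(f"duplicate SNP id {dup!r}")
        if (self.snps["pos"] <= 0).any():
            raise ValidationError("SNP positions must be strictly positive")
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if bad.any():
            raise ValidationError("dosages outside [0, 2]")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.snps.index.to_numpy()

    def missingness(self) -> np.ndarray:
        """Per-SNP fraction of missing genotypes."""
        return np.isnan(self.dosages).mean(axis=0)

    def allele_freq(self) -> np.ndarray:
        """Per-SNP frequency of the counted allele a1 (ignoring missing)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        f = self.allele_freq()
        return np.minimum(f, 1.0 - f)

    def imputed_dosages(self) -> np.ndarray:
        """Dosages with missing values replaced by the per-SNP mean.

        Used for scoring and LD only; QC statistics always see the raw
        missingness.
        """
        out = self.dosages.copy()
        nan = np.isnan(out)
        if nan.any():
            means = np.nanmean(np.where(nan, np.nan, out), axis=0)
            means = np.where(np.isnan(means), 0.0, means)
            idx = np.nonzero(nan)
            out[idx] = means[idx[1]]
        return out

    def subset_snps(self, ids) -> "GenotypePanel":
        ids = list(ids)
        pos = self.snps.index.get_indexer(ids)
        if (pos < 0).any():
            missing = [i for i, p in zip(ids, pos) if p < 0]
            raise KeyError(f"SNPs not in panel: {missing[:5]}")
        return GenotypePanel(self.samples, self.snps.iloc[pos].copy(), self.dosages[:, pos])

    def subset_samples(self, idx) -> "GenotypePanel":
        idx = np.asarray(idx)
        samples = [self.samples[i] for i in idx]
        return GenotypePanel(samples, self.snps.copy(), self.dosages[idx])


@dataclass
class SummaryStats:
    """GWAS summary statistics, one row per SNP (indexed by SNP id).

    Columns: ``chrom``, ``pos``, ``effect_allele``, ``other_allele``,
    ``beta`` (additive log-odds or linear scale), ``p``, optionally ``n``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t.index.duplicated().any():
            dup = t.index[t.index.duplicated()][0]
            raise ValidationError(f"duplicate SNP id {dup!r} in summary statistics")
        if ((t["p"] <= 0) | (t["p"] > 1)).any():
            raise ValidationError("P-values must lie in (0, 1]")
        if (t["effect_allele"] == t["other_allele"]).any():
            raise ValidationError("effect allele equals other allele")

    @property
    def snp_ids(self) -> np.ndarray:
        return self.table.index.to_numpy()

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class GeneTable:
    """Gene models with 1-based inclusive [start, end] and strand."""

    table: pd.DataFrame  # index gene id; columns chrom, start, end, strand

    def __post_init__(self) -> None:
        t = self.table
        if (t["start"] > t["end"]).any():
            raise ValidationError("gene start > end")
        if not t["strand"].isin(["+", "-"]).all():
            raise ValidationError("strand must be '+' or '-'")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def gene_ids(self) -> np.ndarray:
        return self.table.index.to_numpy()


@dataclass
class GeneSetCollection:
    """Named gene sets (pathways) with a source label per set."""

    sets: dict[str, list[str]]
    source: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class HarmonizedStudy:
    """Summary statistics aligned to a genotype panel.

    Both components share one SNP index (identical order) and every beta
    refers to the panel's counted allele ``a1``.  ``drop_log`` records each
    SNP removed during harmonization with its reason.
    """

    panel: GenotypePanel
    stats: SummaryStats
    drop_log: pd.DataFrame

    def __post_init__(self) -> None:
        if not np.array_equal(self.panel.snp_ids, self.stats.snp_ids):
            raise ValidationError("panel and stats SNP indices differ")

    @property
    def snp_ids(self) -> np.ndarray:
        return self.panel.snp_ids

    @property
    def beta(self) -> np.ndarray:
        return self.stats.table["beta"].to_numpy(float)

    @property
    def gwas_p(self) -> np.ndarray:
        return self.stats.table["p"].to_numpy(float)

    def subset_snps(self, ids) -> "HarmonizedStudy":
        ids = list(ids)
        panel = self.panel.subset_snps(ids)
        stats = SummaryStats(self.stats.table.loc[ids].copy())
        return HarmonizedStudy(panel, stats, self.drop_log)

    def subset_samples(self, idx) -> "HarmonizedStudy":
        return HarmonizedStudy(self.panel.subset_samples(idx), self.stats, self.drop_log)


# ---------------------------------------------------------------------------
# genotype I/O
# ---------------------------------------------------------------------------


def read_genotypes(path: str, format: str = "plink1") -> GenotypePanel:
    """Read a genotype panel from ``plink1`` (bed/bim/fam prefix) or
    ``dosage-tsv`` (single file)."""
    if format == "plink1":
        return _read_plink1(path)
    if format == "dosage-tsv":
        return _read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotypes(panel: GenotypePanel, path: str, format: str = "plink1") -> None:
    if format == "plink1":
        _write_plink1(panel, path)
    elif format == "dosage-tsv":
        _write_dosage_tsv(panel, path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")


def _read_dosage_tsv(path: str) -> GenotypePanel:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""])
    snp_ids = list(df.columns)
    meta = pd.DataFrame(
        {
            "chrom": ["1"] * len(snp_ids),
            "pos": np.arange(1, len(snp_ids) + 1),
            "a1": ["A"] * len(snp_ids),
            "a2": ["G"] * len(snp_ids),
        },
        index=pd.Index(snp_ids, name="snp"),
    )
    return GenotypePanel([str(s) for s in df.index], meta, df.to_numpy(float))


def _write_dosage_tsv(panel: GenotypePanel, path: str) -> None:
    df = pd.DataFrame(panel.dosages, index=panel.samples, columns=panel.snp_ids)
    df.index.name = "sample"
    df.to_csv(path, sep="\t", na_rep="NA")


def _read_plink1(prefix: str) -> GenotypePanel:
    bim = pd.read_csv(
        prefix + ".bim",
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "snp": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(prefix + ".fam", sep=r"\s+", header=None, dtype=str)
    n, m = len(fam), len(bim)
    bytes_per_snp = (n + 3) // 4
    expected = 3 + bytes_per_snp * m
    size = os.path.getsize(prefix + ".bed")
    with open(prefix + ".bed", "rb") as fh:
        magic = fh.read(3)
        if magic != _PLINK_MAGIC:
            raise FormatError(f"{prefix}.bed: bad magic bytes {magic!r} (expect SNP-major PLINK-1)")
        if size != expected:
            raise FormatError(
                f"{prefix}.bed: size {size} != 3 + ceil({n}/4)*{m} = {expected}"
            )
        raw = np.frombuffer(fh.read(), dtype=np.uint8).reshape(m, bytes_per_snp)
    # unpack 2-bit codes, sample-fastest within each byte
    codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (raw >> (2 * k)) & 0b11
    codes = codes[:, :n]
    # 00 hom a1 -> 2 copies of a1; 10 het -> 1; 11 hom a2 -> 0; 01 missing
    lut = np.array([2.0, np.nan, 1.0, 0.0])
    dosages = lut[codes].T
    meta = bim.set_index("snp")[["chrom", "pos", "a1", "a2"]]
    samples = [
        fid if fid == iid else f"{fid}_{iid}"
        for fid, iid in zip(fam[0].astype(str), fam[1].astype(str))
    ]
    return GenotypePanel(samples, meta, dosages)


def _write_plink1(panel: GenotypePanel, prefix: str) -> None:
    n, m = panel.n_samples, panel.n_snps
    hard = np.round(panel.dosages)
    code = np.full((m, n), 0b01, dtype=np.uint8)  # missing
    d = hard.T
    code[d == 2] = 0b00
    code[d == 1] = 0b10
    code[d == 0] = 0b11
    bytes_per_snp = (n + 3) // 4
    padded = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)
    padded[:, :n] = code
    out = np.zeros((m, bytes_per_snp), dtype=np.uint8)
    for k in range(4):
        out |= padded[:, k::4] << (2 * k)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_PLINK_MAGIC)
        fh.write(out.tobytes())
    bim = panel.snps.reset_index()
    bim.columns = ["snp", "chrom", "pos", "a1", "a2"]
    bim["cm"] = 0
    bim[["chrom", "snp", "cm", "pos", "a1", "a2"]].to_csv(
        prefix + ".bim", sep="\t", header=False, index=False
    )
    with open(prefix + ".fam", "w") as fh:
        for s in panel.samples:
            fid, _, iid = s.partition("_")
            fh.write(f"{fid}\t{iid or fid}\t0\t0\t0\t-9\n")


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


def hwe_exact_test(n_het: int, n_hom1: int, n_hom2: int, midp: bool = True) -> float:
    """Exact Hardy-Weinberg equilibrium test on genotype counts.

    Conditional on the minor-allele count, enumerates all heterozygote
    counts of the right parity and sums the probabilities of configurations
    no more likely than the observed one (mid-P: half weight on ties).
    """
    if min(n_het, n_hom1, n_hom2) < 0:
        raise ValueError("negative genotype count")
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    rare = 2 * min(n_hom1, n_hom2) + n_het
    hets = np.arange(rare % 2, min(rare, 2 * n - rare) + 1, 2)
    # log P(het = h | rare allele count) up to a constant
    homr = (rare - hets) // 2
    homc = n - hets - homr
    logp = (
        hets * math.log(2)
        - _lgamma_arr(hets + 1)
        - _lgamma_arr(homr + 1)
        - _lgamma_arr(homc + 1)
    )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    obs = prob[np.nonzero(hets == n_het)[0][0]]
    tol = 1e-12
    if midp:
        p = prob[prob < obs - tol].sum() + 0.5 * prob[np.abs(prob - obs) <= tol].sum()
    else:
        p = prob[prob <= obs + tol].sum()
    return float(min(p, 1.0))


def _lgamma_arr(x: np.ndarray) -> np.ndarray:
    from scipy.special import gammaln

    return gammaln(np.asarray(x, dtype=float))


def qc_filter(
    panel: GenotypePanel,
    miss_max: float = 0.02,
    maf_min: float = 0.01,
    hwe_p_min: float = 1e-8,
) -> tuple[GenotypePanel, pd.DataFrame]:
    """Remove SNPs failing missingness, MAF or HWE thresholds.

    Defaults follow common GWAS practice: drop SNPs with missingness
    > 0.02, MAF < 0.01 or HWE exact P < 1e-8.  HWE is tested on hard calls
    (dosages rounded to {0, 1, 2}).  Returns the filtered panel plus a drop
    log with one row per removed SNP.
    """
    for name, v in [("miss_max", miss_max), ("maf_min", maf_min), ("hwe_p_min", hwe_p_min)]:
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    miss = panel.missingness()
    maf = panel.maf()
    hard = np.round(panel.dosages)
    reasons: list[tuple[str, str]] = []
    keep = np.ones(panel.n_snps, dtype=bool)
    for j, snp in enumerate(panel.snp_ids):
        if miss[j] > miss_max:
            keep[j] = False
            reasons.append((snp, f"missingness {miss[j]:.4g} > {miss_max}"))
            continue
        if np.isnan(maf[j]) or maf[j] < maf_min:
            keep[j] = False
            reasons.append((snp, f"MAF {maf[j]:.4g} < {maf_min}"))
            continue
        col = hard[:, j]
        col = col[~np.isnan(col)]
        n_hom1 = int((col == 2).sum())
        n_het = int((col == 1).sum())
        n_hom2 = int((col == 0).sum())
        p_hwe = hwe_exact_test(n_het, n_hom1, n_hom2)
        if p_hwe < hwe_p_min:
            keep[j] = False
            reasons.append((snp, f"HWE P {p_hwe:.4g} < {hwe_p_min}"))
    if not keep.any():
        raise ValidationError("QC removed every SNP in the panel")
    log = pd.DataFrame(reasons, columns=["snp", "reason"])
    kept = GenotypePanel(panel.samples, panel.snps.loc[keep].copy(), panel.dosages[:, keep])
    return kept, log


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

_MANDATORY_ROLES = {"snp", "chrom", "pos", "effect_allele", "other_allele", "p"}


def read_summary_stats(path: str, column_map: dict[str, str]) -> tuple[SummaryStats, int]:
    """Read GWAS summary statistics.

    ``column_map`` maps file column names to roles: snp, chrom, pos,
    effect_allele, other_allele, beta or odds_ratio, p, n (optional).
    Odds ratios are converted to betas by natural log.  Rows with
    non-finite beta or P outside (0, 1] are dropped; the count of dropped
    rows is returned alongside the table.
    """
    roles = set(column_map.values())
    missing = _MANDATORY_ROLES - roles
    if missing:
        raise KeyError(f"column map lacks mandatory roles: {sorted(missing)}")
    if not ({"beta", "odds_ratio"} & roles):
        raise KeyError("column map must assign a 'beta' or 'odds_ratio' column")
    df = pd.read_csv(path, sep=r"\s+", dtype={c: str for c in column_map
                                              if column_map[c] in
                                              ("snp", "chrom", "effect_allele", "other_allele")})
    absent = [c for c in column_map if c not in df.columns]
    if absent:
        raise KeyError(f"mapped columns not present in file: {absent}")
    df = df.rename(columns=column_map)
    if "odds_ratio" in df.columns:
        orr = pd.to_numeric(df["odds_ratio"], errors="coerce")
        if (orr <= 0).any():
            raise ValidationError("odds ratios must be positive")
        df["beta"] = np.log(orr)
    df["beta"] = pd.to_numeric(df["beta"], errors="coerce")
    df["p"] = pd.to_numeric(df["p"], errors="coerce")
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce").astype("Int64")
    ok = np.isfinite(df["beta"]) & (df["p"] > 0) & (df["p"] <= 1)
    n_dropped = int((~ok).sum())
    df = df.loc[ok].copy()
    df["pos"] = df["pos"].astype(int)
    for c in ("effect_allele", "other_allele"):
        df[c] = df[c].str.upper()
    cols = ["chrom", "pos", "effect_allele", "other_allele", "beta", "p"]
    if "n" in df.columns:
        cols.append("n")
    table = df.set_index("snp")[cols]
    return SummaryStats(table), n_dropped


def write_summary_stats(stats: SummaryStats, path: str) -> None:
    out = stats.table.reset_index()
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene models and gene sets
# ---------------------------------------------------------------------------


def read_gtf(path: str, id_field: str = "gene_id", feature: str = "gene") -> GeneTable:
    """Parse gene records from a GTF file.

    Uses rows whose feature equals ``feature`` when present, otherwise
    aggregates min/max coordinates over all rows per gene.  ``id_field``
    selects the attribute used as the gene identifier (``gene_id`` or
    ``gene_name``).
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise FormatError(f"GTF line with {len(f)} fields (expect 9): {line[:60]!r}")
            attrs = _parse_gtf_attrs(f[8])
            gid = attrs.get(id_field)
            if gid is None:
                continue
            rows.append((gid, f[0], f[2], int(f[3]), int(f[4]), f[6]))
    if not rows:
        raise FormatError(f"no usable records with attribute {id_field!r} in {path}")
    df = pd.DataFrame(rows, columns=["gene", "chrom", "feature", "start", "end", "strand"])
    if (df["feature"] == feature).any():
        df = df[df["feature"] == feature]
        df = df.drop_duplicates("gene").set_index("gene")
    else:
        df = (
            df.groupby("gene")
            .agg(chrom=("chrom", "first"), start=("start", "min"),
                 end=("end", "max"), strand=("strand", "first"))
        )
    return GeneTable(df[["chrom", "start", "end", "strand"]])


def _parse_gtf_attrs(s: str) -> dict[str, str]:
    attrs = {}
    for chunk in s.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, val = chunk.partition(" ")
        attrs[key] = val.strip().strip('"')
    return attrs


def read_gmt(path: str, source: str | None = None) -> GeneSetCollection:
    """Read gene sets in GMT format: name, description, tab-separated genes."""
    sets: dict[str, list[str]] = {}
    src: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                raise FormatError(f"GMT line needs >= 3 fields: {line[:60]!r}")
            name, desc, genes = f[0], f[1], [g for g in f[2:] if g]
            if name in sets:
                raise ValidationError(f"duplicate gene set name {name!r}")
            sets[name] = genes
            src[name] = source or desc
    return GeneSetCollection(sets, src)


def write_gmt(sets: GeneSetCollection, path: str) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.sets.items():
            desc = sets.source.get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------


def _is_ambiguous(a: str, b: str) -> bool:
    return {a, b} in ({"A", "T"}, {"C", "G"})


def harmonize(stats: SummaryStats, panel: GenotypePanel) -> HarmonizedStudy:
    """Align summary statistics with a genotype panel on a shared SNP index.

    Keeps the intersection by SNP id, drops strand-ambiguous (A/T, G/C)
    SNPs, flips the sign of beta when the effect allele matches the panel's
    uncounted allele (directly or after strand complement), and drops SNPs
    whose alleles match in no orientation.  The returned study's betas all
    refer to the panel's counted allele a1.
    """
    if len(stats) == 0 or panel.n_snps == 0:
        raise HarmonizationError("empty summary statistics or genotype panel")
    drops: list[tuple[str, str]] = []
    panel_ids = set(panel.snp_ids)
    for snp in stats.snp_ids:
        if snp not in panel_ids:
            drops.append((snp, "absent from genotype panel"))
    stats_ids = set(stats.snp_ids)
    for snp in panel.snp_ids:
        if snp not in stats_ids:
            drops.append((snp, "absent from summary statistics"))
    shared = [s for s in panel.snp_ids if s in stats_ids]
    keep: list[str] = []
    flip: dict[str, float] = {}
    st = stats.table
    pm = panel.snps
    for snp in shared:
        ea = str(st.at[snp, "effect_allele"]).upper()
        oa = str(st.at[snp, "other_allele"]).upper()
        a1 = str(pm.at[snp, "a1"]).upper()
        a2 = str(pm.at[snp, "a2"]).upper()
        if _is_ambiguous(ea, oa) or _is_ambiguous(a1, a2):
            drops.append((snp, "strand-ambiguous alleles"))
            continue
        sign = _orientation(ea, oa, a1, a2)
        if sign == 0:
            drops.append((snp, f"allele mismatch {ea}/{oa} vs {a1}/{a2}"))
            continue
        keep.append(snp)
        flip[snp] = sign
    if not keep:
        raise HarmonizationError("no SNP survived harmonization")
    sub_panel = panel.subset_snps(keep)
    sub = st.loc[keep].copy()
    signs = np.array([flip[s] for s in keep])
    sub["beta"] = sub["beta"].to_numpy(float) * signs
    # rewrite stats alleles in the panel's orientation so re-harmonizing is a no-op
    sub["effect_allele"] = sub_panel.snps["a1"].to_numpy()
    sub["other_allele"] = sub_panel.snps["a2"].to_numpy()
    log = pd.DataFrame(drops, columns=["snp", "reason"])
    return HarmonizedStudy(sub_panel, SummaryStats(sub), log)


def _orientation(ea: str, oa: str, a1: str, a2: str) -> float:
    """+1 if (ea, oa) matches (a1, a2), -1 if it matches (a2, a1), else 0.

    Strand complement is attempted before declaring a mismatch.
    """
    if (ea, oa) == (a1, a2):
        return 1.0
    if (ea, oa) == (a2, a1):
        return -1.0
    cea = _COMPLEMENT.get(ea)
    coa = _COMPLEMENT.get(oa)
    if cea and coa:
        if (cea, coa) == (a1, a2):
            return 1.0
        if (cea, coa) == (a2, a1):
            return -1.0
    return 0.0
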