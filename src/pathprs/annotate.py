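"""SNP-to-gene-to-pathway annotation.

Builds the SNP x pathway boolean membership matrix used by pathway-aware
clumping: a SNP belongs to a pathway iff it falls inside the extended
window of any gene of that pathway and outside every excluded region.
Gene windows are extended asymmetrically (default 35 kb upstream, 10 kb
downstream, strand-aware), regions such as the MHC (chr6:25-34 Mb) can be
excluded, pathways are filtered to 10-2000 mappable genes, and a shifted
annotation (default 5 Mb, wrapping at chromosome ends) provides a
biology-free negative control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GeneSetCollection, GeneTable, HarmonizedStudy, ValidationError

__all__ = [
    "GenomicRegion",
    "MembershipFlags",
    "MHC_GRCH37",
    "APOE_GRCH37",
    "read_regions",
    "extend_gene_bounds",
    "shift_annotation",
    "build_membership",
]

#: Major histocompatibility complex, GRCh37 (excluded in all analyses).
MHC_GRCH37 = ("6", 25_000_000, 34_000_000, "MHC")
#: APOE region, GRCh37 (excluded for Alzheimer's disease analyses).
APOE_GRCH37 = ("19", 44_000_000, 46_000_000, "APOE")


@dataclass(frozen=True)
class GenomicRegion:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"region {self.label or self.chrom}: start > end")

    def contains(self, chrom, pos) -> np.ndarray:
        chrom = np.asarray(chrom, dtype=str)
        pos = np.asarray(pos)
        return (chrom == str(self.chrom)) & (pos >= self.start) & (pos <= self.end)


@dataclass
class MembershipFlags:
    """SNP x pathway boolean membership with genic background flags.

    ``membership[s, p]`` is True iff SNP ``s`` is annotated to pathway
    ``p``; ``background[s]`` is True iff the SNP lies in any extended gene
    (and outside excluded regions).  ``gene_counts`` holds the number of
    mappable genes per retained pathway.
    """

    snp_ids: np.ndarray
    pathways: list[str]
    membership: np.ndarray  # bool, n_snps x n_pathways
    background: np.ndarray  # bool, n_snps
    gene_counts: dict[str, int]
    log: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["item", "reason"]))

    def __post_init__(self) -> None:
        self.membership = np.asarray(self.membership, dtype=bool)
        self.background = np.asarray(self.background, dtype=bool)
        if self.membership.shape != (len(self.snp_ids), len(self.pathways)):
            raise ValidationError("membership matrix shape mismatch")
        if self.background.shape != (len(self.snp_ids),):
            raise ValidationError("background flag length mismatch")
        if (self.membership & ~self.background[:, None]).any():
            raise ValidationError("pathway member SNP flagged non-genic")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def members_of(self, pathway: str) -> np.ndarray:
        j = self.pathways.index(pathway)
        return self.snp_ids[self.membership[:, j]]

    def snp_counts(self) -> pd.Series:
        return pd.Series(self.membership.sum(axis=0), index=self.pathways, name="n_snps")

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_genes": [self.gene_counts[p] for p in self.pathways],
                "n_snps": self.membership.sum(axis=0),
            },
            index=pd.Index(self.pathways, name="pathway"),
        )


def read_regions(path: str) -> list[GenomicRegion]:
    """Read exclusion regions from a BED-like TSV.

    Columns: chrom, start, end[, label], 0-based half-open as in BED;
    converted to 1-based inclusive on read.  Lines starting with '#' are
    skipped.
    """
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValidationError(f"BED line needs >= 3 fields: {line[:60]!r}")
            label = f[3] if len(f) > 3 else ""
            regions.append(GenomicRegion(f[0], int(f[1]) + 1, int(f[2]), label))
    return regions


def extend_gene_bounds(
    genes: GeneTable, upstream_bp: int = 35_000, downstream_bp: int = 10_000
) -> GeneTable:
    """Extend gene windows to capture flanking regulatory variation.

    Upstream means 5': a plus-strand gene [s, e] becomes
    [max(1, s - up), e + down]; a minus-strand gene becomes
    [max(1, s - down), e + up].
    """
    if upstream_bp < 0 or downstream_bp < 0:
        raise ValueError("window extensions must be non-negative")
    t = genes.table.copy()
    plus = (t["strand"] == "+").to_numpy()
    start = t["start"].to_numpy(dtype=np.int64)
    end = t["end"].to_numpy(dtype=np.int64)
    new_start = np.where(plus, start - upstream_bp, start - downstream_bp)
    new_end = np.where(plus, end + downstream_bp, end + upstream_bp)
    t["start"] = np.maximum(1, new_start)
    t["end"] = new_end
    return GeneTable(t)


def shift_annotation(
    genes: GeneTable, shift_bp: int, chrom_lengths: dict[str, int]
) -> tuple[GeneTable, pd.DataFrame]:
    """Displace every gene by ``shift_bp`` to void its biological meaning.

    Coordinates wrap modulo the chromosome length so the number of SNPs
    falling in gene windows stays comparable; a gene whose shifted window
    straddles the chromosome end is mapped to the wrapped start position
    and logged (it is not split).
    """
    if shift_bp <= 0:
        raise ValueError("shift_bp must be positive")
    t = genes.table.copy()
    missing = set(t["chrom"].astype(str)) - set(map(str, chrom_lengths))
    if missing:
        raise KeyError(f"chromosome lengths missing for: {sorted(missing)}")
    wrapped = []
    starts, ends = [], []
    for gene, row in t.iterrows():
        length = int(chrom_lengths[str(row["chrom"])])
        span = int(row["end"]) - int(row["start"])
        did_wrap = int(row["start"]) - 1 + shift_bp >= length
        new_start = (int(row["start"]) - 1 + shift_bp) % length + 1
        new_end = new_start + span
        if new_end > length:
            # window straddles the end: move it whole to the chromosome start
            new_start = 1
            new_end = 1 + span
            did_wrap = True
        if did_wrap:
            wrapped.append((gene, f"wrapped past end of chr{row['chrom']}"))
        starts.append(new_start)
        ends.append(new_end)
    t["start"] = starts
    t["end"] = ends
    log = pd.DataFrame(wrapped, columns=["item", "reason"])
    return GeneTable(t), log


def build_membership(
    study,
    genes: GeneTable,
    sets: GeneSetCollection,
    exclude: list[GenomicRegion] | None = None,
    min_genes: int = 10,
    max_genes: int = 2000,
) -> MembershipFlags:
    """Annotate SNPs to pathways via extended gene windows.

    ``study`` is a :class:`~pathprs.io.HarmonizedStudy` or a bare
    :class:`~pathprs.io.GenotypePanel`.  Pathways are filtered to
    ``[min_genes, max_genes]`` mappable genes (genes present in the gene
    table), counted before SNP mapping, so that over-specific and
    over-broad sets are excluded.  Pathways with zero overlapping SNPs are
    dropped and logged.  ``genes`` must already carry any window
    extension.
    """
    if min_genes > max_genes:
        raise ValueError("min_genes > max_genes")
    exclude = exclude or []
    panel = study.panel if isinstance(study, HarmonizedStudy) else study
    snp_ids = panel.snp_ids
    chrom = panel.snps["chrom"].astype(str).to_numpy()
    pos = panel.snps["pos"].to_numpy(dtype=np.int64)
    excluded = np.zeros(len(snp_ids), dtype=bool)
    for region in exclude:
        excluded |= region.contains(chrom, pos)

    gt = genes.table
    gene_snps = _map_genes_to_snps(gt, chrom, pos, excluded)
    known_genes = set(gt.index)

    log_rows: list[tuple[str, str]] = []
    pathways: list[str] = []
    gene_counts: dict[str, int] = {}
    columns: list[np.ndarray] = []
    background = np.zeros(len(snp_ids), dtype=bool)
    for idx in gene_snps.values():
        background[idx] = True

    for name, members in sets.sets.items():
        mappable = [g for g in members if g in known_genes]
        n_genes = len(set(mappable))
        if not (min_genes <= n_genes <= max_genes):
            log_rows.append((name, f"{n_genes} mappable genes outside [{min_genes}, {max_genes}]"))
            continue
        col = np.zeros(len(snp_ids), dtype=bool)
        for g in mappable:
            idx = gene_snps.get(g)
            if idx is not None:
                col[idx] = True
        if not col.any():
            log_rows.append((name, "no overlapping SNPs"))
            continue
        pathways.append(name)
        gene_counts[name] = n_genes
        columns.append(col)

    if not pathways:
        raise ValidationError("no pathway survived gene-count and SNP-overlap filters")
    membership = np.column_stack(columns)
    log = pd.DataFrame(log_rows, columns=["item", "reason"])
    return MembershipFlags(snp_ids, pathways, membership, background, gene_counts, log)


def _map_genes_to_snps(
    gt: pd.DataFrame, chrom: np.ndarray, pos: np.ndarray, excluded: np.ndarray
) -> dict[str, np.ndarray]:
    """For each gene, the indices of non-excluded SNPs inside its window.

    Closed-interval overlap on 1-based coordinates, per chromosome, via
    sorted-position binary search.
    """
    out: dict[str, np.ndarray] = {}
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for c in np.unique(chrom):
        mask = (chrom == c) & ~excluded
        idx = np.nonzero(mask)[0]
        order = np.argsort(pos[idx], kind="stable")
        idx = idx[order]
        by_chrom[c] = (pos[idx], idx)
    for gene, row in gt.iterrows():
        entry = by_chrom.get(str(row["chrom"]))
        if entry is None:
            continue
        p, idx = entry
        lo = np.searchsorted(p, int(row["start"]), side="left")
        hi = np.searchsorted(p, int(row["end"]), side="right")
        if hi > lo:
            out[gene] = idx[lo:hi]
    return out
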