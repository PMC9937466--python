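"""Pipeline orchestration: configuration, run manifests and output tables.

Every run records a machine-readable manifest (inputs hashed, every
parameter with its resolved value, seed, wall time, warnings) so that any
result can be replayed from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import annotate, enrichment, io, prs, simulate, stratify

__all__ = ["RunConfig", "run_pipeline", "read_config", "ConfigError"]

SUBCOMMANDS = ("score", "enrich", "stratify", "specificity", "simulate", "benchmark")

_SCHEMA: dict[str, dict[str, object]] = {
    "common": {"seed": 0, "out_dir": "pathprs_out"},
    "score": {
        "genotypes": "", "genotype_format": "plink1", "sumstats": "",
        "column_map": "SNP=snp,CHR=chrom,BP=pos,A1=effect_allele,A2=other_allele,BETA=beta,P=p",
        "gtf": "", "gmt": "", "id_field": "gene_id",
        "upstream_bp": 35_000, "downstream_bp": 10_000,
        "min_genes": 10, "max_genes": 2000,
        "r2": prs.DEFAULT_R2, "window_bp": prs.DEFAULT_WINDOW_BP,
        "p_ceiling": 1.0, "standardize": True,
    },
    "enrich": {"phenotype": "", "permutations": enrichment.DEFAULT_PERMUTATIONS},
    "stratify": {
        "phenotype": "", "train_fraction": 0.8, "folds": 5,
        "enrich_alpha": 0.05, "permutations": 1000, "shift_control": False,
        "shift_bp": 5_000_000,
    },
    # enrich and stratify consume the same study inputs as score
    "_inherits": {"enrich": "score", "stratify": "score"},
    "specificity": {"expression": "", "relevance": "", "n_quantiles": 11},
    "simulate": {
        "n_individuals": 1000, "n_snps": 1000, "block_size": 10,
        "within_block_r2": 0.8, "n_genes": 200, "n_sets": 50,
        "genes_per_set": 15, "k_causal": 10, "h2": 0.5,
    },
    "benchmark": {
        "h2_list": "0.1,0.5", "n_base": 10_000, "n_target": 5_000,
        "n_snps": 5_000, "n_sets": 300, "k_causal": 50,
        "permutations": 1_000, "reps": 6,
    },
}


class ConfigError(ValueError):
    """Unknown key or unusable value in a run configuration."""


@dataclass
class RunConfig:
    subcommand: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.subcommand not in SUBCOMMANDS:
            raise ConfigError(f"unknown subcommand {self.subcommand!r}")
        allowed = {**_SCHEMA["common"], **_SCHEMA[self.subcommand]}
        parent = _SCHEMA["_inherits"].get(self.subcommand)
        if parent:
            allowed = {**_SCHEMA[parent], **allowed}
        unknown = set(self.params) - set(allowed)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        resolved = dict(allowed)
        for k, v in self.params.items():
            resolved[k] = _coerce(v, allowed[k])
        self.params = resolved  # every parameter has a recorded value


def _coerce(value, template):
    if isinstance(template, bool):
        return str(value).lower() in ("1", "true", "yes") if isinstance(value, str) else bool(value)
    if isinstance(template, int) and not isinstance(template, bool):
        return int(value)
    if isinstance(template, float):
        return float(value)
    return value


def read_config(path: str, subcommand: str) -> RunConfig:
    """Parse a plain ``key=value`` config file (one pair per line, '#'
    comments)."""
    params: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"config line is not key=value: {line!r}")
            key, _, val = line.partition("=")
            params[key.strip()] = val.strip()
    return RunConfig(subcommand, params)


def _hash_file(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_pipeline(config: RunConfig) -> str:
    """Execute a subcommand and write outputs plus a run manifest.

    Returns the output directory.  Any module error propagates after
    partial outputs are removed.
    """
    p = config.params
    out_dir = str(p["out_dir"])
    os.makedirs(out_dir, exist_ok=True)
    t0 = time.time()
    manifest: dict = {
        "subcommand": config.subcommand,
        "parameters": {k: v for k, v in p.items()},
        "seed": int(p["seed"]),
        "inputs": {},
        "outputs": [],
        "warnings": [],
    }
    written: list[str] = []

    def emit(name: str, df: pd.DataFrame) -> None:
        path = os.path.join(out_dir, name)
        with open(path, "w") as fh:
            fh.write("# pathprs schema v1\n")
            df.to_csv(fh, sep="\t")
        written.append(path)
        manifest["outputs"].append(name)

    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            _dispatch(config, emit, manifest)
        manifest["warnings"] = [str(w.message) for w in caught]
    except Exception:
        for path in written:
            if os.path.exists(path):
                os.remove(path)
        raise
    manifest["wall_time_s"] = round(time.time() - t0, 3)
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return out_dir


def _load_study(p: dict, manifest: dict):
    panel = io.read_genotypes(p["genotypes"], p["genotype_format"])
    cmap = dict(kv.split("=") for kv in str(p["column_map"]).split(","))
    stats, _ = io.read_summary_stats(p["sumstats"], cmap)
    for key in ("sumstats", "gtf", "gmt"):
        if p.get(key):
            manifest["inputs"][key] = _hash_file(p[key])
    study = io.harmonize(stats, panel)
    genes = io.read_gtf(p["gtf"], id_field=p["id_field"])
    ext = annotate.extend_gene_bounds(genes, p["upstream_bp"], p["downstream_bp"])
    sets = io.read_gmt(p["gmt"])
    flags = annotate.build_membership(
        study, ext, sets, min_genes=p["min_genes"], max_genes=p["max_genes"]
    )
    return study, ext, sets, flags


def _dispatch(config: RunConfig, emit, manifest: dict) -> None:
    p = config.params
    sub = config.subcommand
    if sub == "score":
        study, _, _, flags = _load_study(p, manifest)
        clump = prs.clump_pathways(study, flags, p["r2"], p["window_bp"], p["p_ceiling"])
        scores = prs.score_pathways(study, clump, 1.0, standardized=p["standardize"])
        emit("pathway_scores.tsv", scores.values)
        emit("membership_summary.tsv", flags.summary())
    elif sub == "enrich":
        study, _, _, flags = _load_study(p, manifest)
        pheno = pd.read_csv(p["phenotype"], sep="\t", index_col=0).iloc[:, 0]
        y = pheno.loc[study.panel.samples].to_numpy(float)
        results = enrichment.enrich_all(
            study, flags, y - y.mean(), N=p["permutations"], seed=p["seed"]
        )
        emit(
            "enrichment.tsv",
            pd.DataFrame(
                [
                    {"pathway": r.pathway, "m_snps": r.m, "p_observed": r.p_observed,
                     "p_competitive": r.p_competitive, "n_perm": r.n_perm}
                    for r in results
                ]
            ).set_index("pathway"),
        )
    elif sub == "stratify":
        study, ext, sets, flags = _load_study(p, manifest)
        pheno = pd.read_csv(p["phenotype"], sep="\t", index_col=0).iloc[:, 0]
        labels = pheno.loc[study.panel.samples].to_numpy(int)
        cfg = stratify.StratifyConfig(
            train_fraction=p["train_fraction"], k_folds=p["folds"],
            enrich_alpha=p["enrich_alpha"], n_perm=p["permutations"], seed=p["seed"],
        )
        out = stratify.run_stratification(study, flags, labels, cfg)
        emit(
            "model.tsv",
            pd.DataFrame({"coefficient": out.model.coef}, index=out.model.pathways),
        )
        emit("metrics.tsv", pd.DataFrame({"test_r2": [out.test_r2]}))
    elif sub == "specificity":
        from . import specificity as spc

        expr = pd.read_csv(p["expression"], sep="\t", index_col=0)
        expr = expr[expr.sum(axis=1) > 0]
        spec = spc.compute_specificity(expr)
        per_tissue = spc.build_quantile_sets(spec, p["n_quantiles"])
        rows = [
            {"tissue": t, "set": name, "n_genes": len(genes)}
            for t, coll in per_tissue.items()
            for name, genes in coll.sets.items()
        ]
        emit("quantile_sets.tsv", pd.DataFrame(rows).set_index("set"))
    elif sub == "simulate":
        panel = simulate.simulate_genotypes(
            p["n_individuals"], p["n_snps"], p["block_size"],
            p["within_block_r2"], seed=p["seed"],
        )
        genes = simulate.simulate_gene_annotation(panel, p["n_genes"], p["seed"])
        sets = simulate.simulate_gene_sets(genes, p["n_sets"], p["genes_per_set"], p["seed"])
        flags = annotate.build_membership(
            panel, genes, sets, min_genes=1, max_genes=10**6
        )
        truth = simulate.assign_causal_pathways(
            simulate.membership_snp_sets(flags), p["k_causal"], p["seed"]
        )
        y = simulate.simulate_phenotype(panel, truth, p["h2"], p["seed"])
        stats = simulate.run_gwas(panel, y)
        io.write_genotypes(panel, os.path.join(p["out_dir"], "panel"), "plink1")
        io.write_summary_stats(stats, os.path.join(p["out_dir"], "gwas.tsv"))
        manifest["outputs"] += ["panel.bed", "panel.bim", "panel.fam", "gwas.tsv"]
        emit(
            "truth.tsv",
            pd.DataFrame(
                {"true_enrichment": truth.true_enrichment, "true_rank": truth.true_rank}
            ),
        )
    elif sub == "benchmark":
        h2_list = [float(v) for v in str(p["h2_list"]).split(",")]
        table = simulate.benchmark_enrichment(
            h2_list=h2_list, n_base=p["n_base"], n_target=p["n_target"],
            n_snps=p["n_snps"], n_sets=p["n_sets"], k_causal=p["k_causal"],
            n_perm=p["permutations"], reps=p["reps"], seed=p["seed"],
        )
        emit("benchmark.tsv", table.set_index(["h2", "rep"]))
        emit(
            "benchmark_median.tsv",
            table.groupby("h2")["tau"].median().to_frame().assign(
                overall=np.median(table["tau"])
            ),
        )
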