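"""Subtype stratification: splitting, lasso, evaluation, shift control."""

import numpy as np
import pandas as pd
import pytest

from pathprs.simulate import (
    assign_causal_pathways,
    membership_snp_sets,
    simulate_gene_annotation,
    simulate_gene_sets,
    simulate_genotypes,
    simulate_phenotype,
    simulate_subtype_scores,
    simulate_subtypes,
    run_gwas,
)
from pathprs.annotate import build_membership, extend_gene_bounds
from pathprs.io import harmonize
from pathprs.stratify import (
    StratificationModel,
    StratifyConfig,
    evaluate_model,
    run_shift_control,
    run_stratification,
    split_train_test,
    train_subtype_model,
)

# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------


def test_split_preserves_proportions():
    labels = np.array([0] * 60 + [1] * 40)
    ids = [f"i{k}" for k in range(100)]
    ds = split_train_test(ids, labels, 0.8, 5, seed=3)
    assert len(ds.train_idx) == 80 and len(ds.test_idx) == 20
    assert abs(labels[ds.train_idx].sum() - 32) <= 1
    assert set(ds.train_idx) | set(ds.test_idx) == set(range(100))


def test_split_deterministic_and_validates():
    labels = np.array([0, 1] * 30)
    ids = [f"i{k}" for k in range(60)]
    a = split_train_test(ids, labels, 0.8, 5, seed=9)
    b = split_train_test(ids, labels, 0.8, 5, seed=9)
    np.testing.assert_array_equal(a.train_idx, b.train_idx)
    np.testing.assert_array_equal(a.fold_ids, b.fold_ids)
    with pytest.raises(ValueError):
        split_train_test(ids, labels, 1.0, 5, seed=0)
    with pytest.raises(ValueError):
        split_train_test(ids[:8], labels[:8], 0.8, 5, seed=0)  # class < k folds


# ---------------------------------------------------------------------------
# lasso training
# ---------------------------------------------------------------------------


def test_driver_pathway_recovered():
    hits = 0
    for seed in range(10):
        df, labels = simulate_subtype_scores(2000, 50, shift=1.0, seed=seed)
        ds = split_train_test(list(df.index), labels, 0.8, 5, seed)
        model = train_subtype_model(
            df.iloc[ds.train_idx], labels[ds.train_idx], ds.fold_ids, seed=seed
        )
        hits += "driver" in model.selected()
    assert hits >= 9


def test_permuted_labels_select_nothing_useful():
    """Under label permutation the fit carries no signal: near-zero test
    R^2 for the min-MSE rule, and the one-SE rule returns intercept-only
    in most seeds."""
    empty_1se, r2s = 0, []
    for seed in range(10):
        df, labels = simulate_subtype_scores(2000, 50, shift=1.0, seed=seed)
        rng = np.random.default_rng(500 + seed)
        perm = rng.permutation(labels)
        ds = split_train_test(list(df.index), perm, 0.8, 5, seed)
        model = train_subtype_model(
            df.iloc[ds.train_idx], perm[ds.train_idx], ds.fold_ids, seed=seed
        )
        r2s.append(evaluate_model(model, df.iloc[ds.test_idx], perm[ds.test_idx]))
        m1 = train_subtype_model(
            df.iloc[ds.train_idx], perm[ds.train_idx], ds.fold_ids, seed=seed, rule="1se"
        )
        empty_1se += len(m1.selected()) == 0
    assert np.median(r2s) < 0.01
    assert empty_1se >= 8


def test_single_pathway_sign_matches_univariate():
    df, labels = simulate_subtype_scores(1000, 0, shift=0.8, seed=1)
    ds = split_train_test(list(df.index), labels, 0.8, 5, seed=1)
    model = train_subtype_model(
        df.iloc[ds.train_idx], labels[ds.train_idx], ds.fold_ids
    )
    uni = np.corrcoef(df["driver"].iloc[ds.train_idx], labels[ds.train_idx])[0, 1]
    assert np.sign(model.coef[0]) == np.sign(uni)


def test_duplicated_pathway_columns_give_identical_predictions():
    df, labels = simulate_subtype_scores(1500, 10, shift=1.0, seed=4)
    dup = df.copy()
    dup["driver_copy"] = df["driver"]
    ds = split_train_test(list(df.index), labels, 0.8, 5, seed=4)
    m_a = train_subtype_model(df.iloc[ds.train_idx], labels[ds.train_idx], ds.fold_ids)
    m_b = train_subtype_model(dup.iloc[ds.train_idx], labels[ds.train_idx], ds.fold_ids)
    pred_a = m_a.predict(df.iloc[ds.test_idx])
    pred_b = m_b.predict(dup.iloc[ds.test_idx])
    np.testing.assert_allclose(pred_a, pred_b, atol=1e-3)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def test_evaluate_perfect_and_constant():
    labels = np.array([0, 1, 0, 1, 1])
    model = StratificationModel(["P"], np.array([1.0]), 0.0, 0.1)
    scores = pd.DataFrame({"P": labels.astype(float)})
    assert evaluate_model(model, scores, labels) == pytest.approx(1.0)
    const = StratificationModel([], np.zeros(0), 0.4, 0.1)
    with pytest.warns(UserWarning):
        assert evaluate_model(const, scores, labels) == 0.0


def test_evaluate_matches_point_biserial_limit():
    """Test R^2 approaches d^2/(d^2+4) for a single informative score with
    standardized mean difference d between balanced groups."""
    d = 0.4
    df, labels = simulate_subtype_scores(20_000, 0, shift=d, seed=7)
    ds = split_train_test(list(df.index), labels, 0.8, 5, seed=7)
    model = train_subtype_model(df.iloc[ds.train_idx], labels[ds.train_idx], ds.fold_ids)
    r2 = evaluate_model(model, df.iloc[ds.test_idx], labels[ds.test_idx])
    assert r2 == pytest.approx(d**2 / (d**2 + 4), abs=0.02)


def test_no_leakage_between_splits():
    df, labels = simulate_subtype_scores(800, 5, shift=1.0, seed=2)
    ds = split_train_test(list(df.index), labels, 0.8, 5, seed=2)
    assert not set(ds.train_idx) & set(ds.test_idx)
    assert len(ds.fold_ids) == len(ds.train_idx)
    assert set(ds.fold_ids) == set(range(5))


# ---------------------------------------------------------------------------
# genotype-level pipeline and shift control
# ---------------------------------------------------------------------------


def _subtype_world(seed, n_base=3000, n_target=1500, n_snps=900, n_sets=30):
    """Simulated case cohort whose subtype is driven by one causal pathway."""
    panel = simulate_genotypes(n_base + n_target, n_snps, block_size=6,
                               within_block_r2=0.7, seed=seed)
    genes = simulate_gene_annotation(panel, 150, seed=seed)
    sets = simulate_gene_sets(genes, n_sets, genes_per_set=5, seed=seed)
    ext = extend_gene_bounds(genes, 0, 0)
    flags_all = build_membership(panel, ext, sets, min_genes=1, max_genes=10**6)
    snp_sets = membership_snp_sets(flags_all)
    driver = flags_all.pathways[0]
    truth = assign_causal_pathways(
        {driver: snp_sets[driver]}, 1, seed=seed, levels=np.array([1.0])
    )
    y = simulate_phenotype(panel, truth, h2=0.5, seed=seed)
    rng = np.random.default_rng(seed + 13)
    perm = rng.permutation(panel.n_samples)
    base_idx, target_idx = perm[:n_base], perm[n_base:]
    stats = run_gwas(panel.subset_samples(base_idx), y[base_idx])
    study = harmonize(stats, panel.subset_samples(target_idx))
    flags_target = build_membership(study, ext, sets, min_genes=1, max_genes=10**6)
    sub = simulate_subtypes(
        study.panel, flags_target, [driver], truth.beta, shift=1.0, seed=seed + 7
    )
    return study, flags_target, ext, sets, sub, driver


def test_pipeline_recovers_driver_and_beats_shift_control():
    study, flags, ext, sets, sub, driver = _subtype_world(seed=5)
    cfg = StratifyConfig(n_perm=200, seed=5)
    out = run_stratification(study, flags, sub.labels, cfg)
    assert driver in out.enriched
    assert out.test_r2 > 0.02
    chrom_len = {"1": int(study.panel.snps["pos"].max() + 10_000)}
    r2_true, r2_shift = run_shift_control(
        study, ext, sets, sub.labels, chrom_len, 5_000_000, cfg,
        min_genes=1, max_genes=10**6,
    )
    assert r2_shift <= r2_true


def test_shift_by_full_chromosome_identical_membership():
    study, flags, ext, sets, sub, driver = _subtype_world(seed=6, n_base=400,
                                                          n_target=300, n_snps=300,
                                                          n_sets=10)
    from pathprs.annotate import shift_annotation

    chrom_len = {"1": int(study.panel.snps["pos"].max())}
    shifted, _ = shift_annotation(ext, chrom_len["1"], chrom_len)
    f1 = build_membership(study, ext, sets, min_genes=1, max_genes=10**6)
    f2 = build_membership(study, shifted, sets, min_genes=1, max_genes=10**6)
    np.testing.assert_array_equal(f1.membership, f2.membership)


def test_null_shift_labels_independent():
    study, flags, ext, sets, _, driver = _subtype_world(seed=8, n_base=400,
                                                        n_target=400, n_snps=300,
                                                        n_sets=10)
    sub = simulate_subtypes(study.panel, flags, [driver],
                            pd.Series(1.0, index=study.panel.snps.index),
                            shift=0.0, seed=1)
    cfg = StratifyConfig(n_perm=100, seed=1, k_folds=3)
    out = run_stratification(study, flags, sub.labels, cfg)
    assert out.test_r2 < 0.05


def test_leave_one_cohort_out_covers_each_cohort_once():
    from pathprs.stratify import split_leave_one_cohort_out

    rng = np.random.default_rng(3)
    n = 300
    labels = rng.integers(0, 2, n)
    cohorts = np.repeat(["c1", "c2", "c3"], n // 3)
    ids = [f"i{k}" for k in range(n)]
    datasets = split_leave_one_cohort_out(ids, labels, cohorts, k_folds=3, seed=3)
    assert len(datasets) == 3
    tested = []
    for ds in datasets:
        assert not set(ds.train_idx) & set(ds.test_idx)
        test_cohorts = set(cohorts[ds.test_idx])
        assert len(test_cohorts) == 1
        tested.append(test_cohorts.pop())
    assert sorted(tested) == ["c1", "c2", "c3"]


def test_pathway_lasso_competitive_with_genome_wide_ct():
    """With all causal SNPs confined to one pathway, the pathway-lasso
    pipeline matches or beats a genome-wide clumping+thresholding PRS
    (median over seeds)."""
    from pathprs.stratify import genome_wide_ct_r2, split_train_test

    pw, gw = [], []
    for seed in range(6):
        study, flags, ext, sets, sub, driver = _subtype_world(seed=seed)
        cfg = StratifyConfig(n_perm=200, seed=seed)
        out = run_stratification(study, flags, sub.labels, cfg)
        ds = out.extras.get("dataset") or split_train_test(
            study.panel.samples, sub.labels, 0.8, 5, seed
        )
        pw.append(out.test_r2)
        gw.append(genome_wide_ct_r2(study, sub.labels, ds))
    assert np.median(pw) >= np.median(gw)
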