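"""Pathway clumping, PRS computation, association and threshold search."""

import numpy as np
import pandas as pd
import pytest

from pathprs.annotate import MembershipFlags
from pathprs.prs import (
    AssociationResult,
    PathwayScoreMatrix,
    clump_greedy,
    clump_pathways,
    compute_prs,
    fit_association,
    pairwise_r2,
    residualize_phenotype,
    score_pathways,
    select_best_threshold,
    standardize,
)
from conftest import make_study


def make_flags(study, memberships: dict[str, list[str]], background=None):
    ids = study.snp_ids
    pathways = list(memberships)
    mat = np.zeros((len(ids), len(pathways)), dtype=bool)
    for j, k in enumerate(pathways):
        mat[:, j] = np.isin(ids, memberships[k])
    bg = mat.any(axis=1) if background is None else np.isin(ids, background)
    bg |= mat.any(axis=1)
    return MembershipFlags(ids, pathways, mat, bg, {k: 1 for k in pathways})


def random_instance(seed):
    """Random clumping instance: LD-structured dosages, random membership."""
    rng = np.random.default_rng(seed)
    n_snps = rng.integers(10, 61)
    n_paths = rng.integers(1, 9)
    n_ind = 80
    # blocks of correlated SNPs: duplicate a base column with noise
    base = rng.binomial(2, 0.3, size=(n_ind, n_snps)).astype(float)
    for j in range(1, n_snps):
        if rng.random() < 0.5:  # correlate with previous SNP
            copy_mask = rng.random(n_ind) < 0.9
            base[copy_mask, j] = base[copy_mask, j - 1]
    p = rng.uniform(0.001, 1.0, n_snps)
    if rng.random() < 0.3:  # inject ties in P
        p[rng.integers(0, n_snps)] = p[rng.integers(0, n_snps)]
    pos = np.sort(rng.choice(np.arange(1, 2_000_000, 1000), n_snps, replace=False))
    chrom = np.where(rng.random(n_snps) < 0.8, "1", "2")
    study = make_study(base, beta=rng.normal(0, 0.1, n_snps), p=p,
                       chrom=list(chrom), pos=list(pos))
    memberships = {}
    for k in range(n_paths):
        size = rng.integers(1, max(2, n_snps // 2))
        memberships[f"P{k}"] = list(rng.choice(study.snp_ids, size, replace=False))
    flags = make_flags(study, memberships)
    r2_thr = rng.choice([0.1, 0.2, 0.5, 0.8])
    window = int(rng.choice([50_000, 250_000, 1_000_000]))
    p_ceil = float(rng.choice([0.5, 1.0]))
    return study, flags, r2_thr, window, p_ceil


def greedy_reference(study, flags, r2_thr, window, p_ceil):
    """Independent per-pathway greedy clumping over pathways + background."""
    ids = list(study.snp_ids)
    p = dict(zip(ids, study.gwas_p))
    pos = dict(zip(ids, study.panel.snps["pos"]))
    chrom = dict(zip(ids, study.panel.snps["chrom"].astype(str)))
    r2 = pd.DataFrame(pairwise_r2(study.panel.imputed_dosages()), index=ids, columns=ids)
    out = {}
    for j, k in enumerate(flags.pathways):
        members = [s for s, m in zip(ids, flags.membership[:, j]) if m]
        out[k] = clump_greedy(members, p, pos, chrom, r2, r2_thr, window, p_ceil)
    bg_members = [s for s, m in zip(ids, flags.background) if m]
    bg = clump_greedy(bg_members, p, pos, chrom, r2, r2_thr, window, p_ceil)
    return out, bg


# ---------------------------------------------------------------------------
# clumping
# ---------------------------------------------------------------------------


def test_clump_index_strips_shared_memberships_only():
    """Worked multi-set case: the index (set G1 only) removes linked SNP b
    entirely and strips G1 (but not G2) from linked SNP a."""
    col = np.array([0.0, 1, 2, 0, 1, 2, 1, 1])
    dos = np.column_stack([col, col, col])  # r^2 = 1 between all three
    study = make_study(dos, beta=[0.1, 0.1, 0.1], p=[0.001, 0.01, 0.02],
                       pos=[1000, 2000, 3000])
    flags = make_flags(study, {"G1": ["rs1", "rs2", "rs3"], "G2": ["rs2"]})
    res = clump_pathways(study, flags, r2_threshold=0.5, window_bp=10_000)
    assert res.retained["G1"] == ["rs1"]
    assert res.retained["G2"] == ["rs2"]  # 'a' keeps its other membership
    assert "rs3" not in {s for v in res.retained.values() for s in v}


def test_clump_no_ld_retains_everything(rng):
    dos = rng.binomial(2, 0.4, size=(200, 6)).astype(float)
    study = make_study(dos, beta=np.zeros(6), p=rng.uniform(size=6))
    flags = make_flags(study, {"A": ["rs1", "rs3", "rs5"], "B": ["rs2", "rs3"]})
    res = clump_pathways(study, flags, r2_threshold=0.99, window_bp=10_000)
    assert set(res.retained["A"]) == {"rs1", "rs3", "rs5"}
    assert set(res.retained["B"]) == {"rs2", "rs3"}


@pytest.mark.parametrize("seed", range(40))
def test_bitflag_equals_greedy_oracle(seed):
    """Bit-flag single-pass clumping is bitwise-identical to independent
    per-pathway greedy clumping on random overlapping instances."""
    study, flags, r2_thr, window, p_ceil = random_instance(seed)
    res = clump_pathways(study, flags, r2_thr, window, p_ceil)
    oracle, bg = greedy_reference(study, flags, r2_thr, window, p_ceil)
    for k in flags.pathways:
        assert res.retained[k] == oracle[k], f"pathway {k} differs (seed {seed})"
    assert res.background == bg


def test_retained_pairs_unlinked(rng):
    study, flags, r2_thr, window, p_ceil = random_instance(123)
    res = clump_pathways(study, flags, r2_thr, window, p_ceil)
    r2 = pd.DataFrame(
        pairwise_r2(study.panel.imputed_dosages()),
        index=study.snp_ids, columns=study.snp_ids,
    )
    pos = dict(zip(study.snp_ids, study.panel.snps["pos"]))
    chrom = dict(zip(study.snp_ids, study.panel.snps["chrom"].astype(str)))
    for k, snps in res.retained.items():
        for i, a in enumerate(snps):
            for b in snps[i + 1:]:
                if chrom[a] == chrom[b] and abs(pos[a] - pos[b]) <= window:
                    assert r2.at[a, b] < r2_thr


def test_pairwise_r2_equals_corrcoef(rng):
    X = rng.normal(size=(50, 5))
    X[:, 4] = 1.0  # constant column
    r2 = pairwise_r2(X)
    expected = np.corrcoef(X[:, :4], rowvar=False) ** 2
    np.testing.assert_allclose(r2[:4, :4], expected, atol=1e-12)
    assert (r2[4, :4] == 0).all() and r2[4, 4] == 1.0


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def test_prs_single_snp_dosage_scaling():
    study = make_study(np.array([[0.0], [1.0], [2.0]]), beta=[0.5], p=[0.01])
    scores, n = compute_prs(study, ["rs1"])
    np.testing.assert_allclose(scores, [0.0, 0.5, 1.0])
    assert n == 1


def test_prs_hand_dot_product():
    dos = np.array([[2.0, 1.0, 0.0], [0.0, 2.0, 1.0]])
    study = make_study(dos, beta=[0.1, -0.2, 0.3], p=[0.01] * 3)
    scores, _ = compute_prs(study, ["rs1", "rs2", "rs3"])
    np.testing.assert_allclose(scores, [0.0, -0.1])


def test_prs_zero_effects_zero_scores(rng):
    dos = rng.integers(0, 3, size=(10, 4)).astype(float)
    study = make_study(dos, beta=np.zeros(4), p=np.full(4, 0.5))
    scores, _ = compute_prs(study, list(study.snp_ids))
    np.testing.assert_array_equal(scores, np.zeros(10))


def test_prs_threshold_filters_and_warns():
    study = make_study(np.array([[0.0, 2.0], [2.0, 0.0]]), beta=[1.0, 1.0], p=[1e-9, 0.5])
    scores, n = compute_prs(study, ["rs1", "rs2"], threshold=1e-4)
    assert n == 1
    np.testing.assert_allclose(scores, [0.0, 2.0])
    with pytest.warns(UserWarning):
        scores, n = compute_prs(study, ["rs1", "rs2"], threshold=1e-12)
    assert n == 0 and (scores == 0).all()


def test_prs_linear_in_disjoint_snp_sets(rng):
    dos = rng.integers(0, 3, size=(30, 8)).astype(float)
    study = make_study(dos, beta=rng.normal(size=8), p=rng.uniform(size=8))
    ids = list(study.snp_ids)
    whole, _ = compute_prs(study, ids)
    part1, _ = compute_prs(study, ids[:3])
    part2, _ = compute_prs(study, ids[3:])
    np.testing.assert_allclose(whole, part1 + part2, atol=1e-12)


def test_prs_invariant_to_snp_and_sample_order(rng):
    dos = rng.integers(0, 3, size=(20, 6)).astype(float)
    study = make_study(dos, beta=rng.normal(size=6), p=rng.uniform(size=6))
    ids = list(study.snp_ids)
    base, _ = compute_prs(study, ids)
    shuffled, _ = compute_prs(study, ids[::-1])
    np.testing.assert_allclose(base, shuffled)
    perm = rng.permutation(20)
    perm_scores, _ = compute_prs(study.subset_samples(perm), ids)
    np.testing.assert_allclose(perm_scores, base[perm])


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------


def test_standardize_sample_sd_and_idempotence():
    mat = PathwayScoreMatrix(
        pd.DataFrame({"P": [1.0, 2.0, 3.0], "C": [5.0, 5.0, 5.0]}), {"P": 1.0, "C": 1.0}
    )
    with pytest.warns(UserWarning, match="constant"):
        z = standardize(mat)
    np.testing.assert_allclose(z.values["P"], [-1.0, 0.0, 1.0])
    np.testing.assert_array_equal(z.values["C"], [0.0, 0.0, 0.0])
    z2 = standardize(z)
    np.testing.assert_allclose(z2.values["P"], z.values["P"], atol=1e-12)


# ---------------------------------------------------------------------------
# residualization and association
# ---------------------------------------------------------------------------


def test_linear_residuals_orthogonal_covariate(rng):
    y = rng.normal(size=200)
    y -= y.mean()
    x = rng.normal(size=200)
    x -= x.mean()
    x -= x @ y / (y @ y) * y  # force exact orthogonality
    resid = residualize_phenotype(y, x, family="linear")
    np.testing.assert_allclose(resid, y, atol=1e-10)


def test_outcome_on_itself_zero_residuals(rng):
    y = rng.normal(size=50)
    resid = residualize_phenotype(y, y, family="linear")
    np.testing.assert_allclose(resid, 0.0, atol=1e-10)


def test_logistic_residuals_uncorrelated_with_covariates(rng):
    n = 10_000
    x = rng.normal(size=n)
    p = 1 / (1 + np.exp(-(0.5 + 0.8 * x)))
    y = (rng.random(n) < p).astype(float)
    # response residuals are exactly orthogonal to fitted covariates
    resid = residualize_phenotype(y, x, family="logistic", residual_type="response")
    assert abs(np.corrcoef(resid, x)[0, 1]) < 0.02
    # deviance residuals remove most, but not all, covariate signal
    dev = residualize_phenotype(y, x, family="logistic", residual_type="deviance")
    assert abs(np.corrcoef(dev, x)[0, 1]) < abs(np.corrcoef(y, x)[0, 1]) / 2


def test_association_perfect_predictor(rng):
    y = rng.normal(size=30)
    res = fit_association(y, y)
    assert res.r2 == pytest.approx(1.0)
    assert res.p < 1e-30


def test_association_null_p_uniform(rng):
    n, reps, hits = 2_000, 500, 0
    for _ in range(reps):
        res = fit_association(rng.normal(size=n), rng.normal(size=n))
        hits += res.p < 0.05
    assert hits / reps == pytest.approx(0.05, abs=0.02)


def test_association_r2_matches_variance_decomposition(rng):
    n = 100_000
    x = rng.normal(size=n)
    y = 2 * x + rng.normal(scale=2.0, size=n)  # var explained = 4 / (4 + 4) = 0.5
    res = fit_association(y, x)
    assert res.r2 == pytest.approx(0.50, abs=0.01)


def test_association_constant_prs_rejected():
    with pytest.raises(ValueError, match="constant"):
        fit_association(np.arange(5.0), np.ones(5))


def test_association_matches_statsmodels_ols(rng):
    import statsmodels.api as sm

    x = rng.normal(size=60)
    y = 0.3 * x + rng.normal(size=60)
    res = fit_association(y, x)
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    assert res.r2 == pytest.approx(fit.rsquared, abs=1e-10)
    assert res.p == pytest.approx(fit.pvalues[1], rel=1e-8)


# ---------------------------------------------------------------------------
# threshold selection
# ---------------------------------------------------------------------------


def test_singleton_grid_returns_full_pathway(rng):
    dos = rng.integers(0, 3, size=(50, 5)).astype(float)
    study = make_study(dos, beta=rng.normal(size=5), p=rng.uniform(size=5))
    y = rng.normal(size=50)
    thr, res = select_best_threshold(study, list(study.snp_ids), y, grid=[1.0])
    assert thr == 1.0
    assert res.n_snps == 5


def test_duplicate_grid_equals_deduplicated(rng):
    dos = rng.integers(0, 3, size=(50, 5)).astype(float)
    study = make_study(dos, beta=rng.normal(size=5), p=rng.uniform(size=5))
    y = rng.normal(size=50)
    a = select_best_threshold(study, list(study.snp_ids), y, grid=[0.5, 1.0])
    b = select_best_threshold(study, list(study.snp_ids), y, grid=[0.5, 1.0, 0.5, 1.0])
    assert a[0] == b[0] and a[1].r2 == b[1].r2


def test_threshold_search_finds_causal_cutoff():
    """When only SNPs with small GWAS P carry signal, 0.05 beats 1.0 in
    most seeded replicates."""
    wins = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        n, m = 400, 20
        dos = rng.binomial(2, 0.3, size=(n, m)).astype(float)
        causal = np.arange(5)
        beta = np.zeros(m)
        beta[causal] = 0.4
        y = dos[:, causal] @ beta[causal] + rng.normal(size=n)
        p = np.where(np.isin(np.arange(m), causal), 0.01, 0.5)
        noise_beta = np.where(np.isin(np.arange(m), causal), beta, rng.normal(0, 0.5, m))
        study = make_study(dos, beta=noise_beta, p=p)
        thr, _ = select_best_threshold(
            study, list(study.snp_ids), y, grid=[0.05, 1.0]
        )
        wins += thr == 0.05
    assert wins >= 9


def test_score_pathways_standardized_columns(rng):
    from pathprs.prs import ClumpResult

    dos = rng.integers(0, 3, size=(40, 6)).astype(float)
    study = make_study(dos, beta=rng.normal(size=6), p=rng.uniform(size=6))
    clump = ClumpResult(
        {"A": ["rs1", "rs2"], "B": ["rs4", "rs5", "rs6"]}, ["rs1"], 0.1, 250_000, 1.0
    )
    mat = score_pathways(study, clump)
    assert mat.standardized
    np.testing.assert_allclose(mat.values.mean(), 0.0, atol=1e-10)
    np.testing.assert_allclose(mat.values.std(ddof=1), 1.0, atol=1e-8)


def test_threshold_tie_prefers_larger(rng):
    # every SNP has GWAS P = 0.01, so both grid points give the same PRS
    dos = rng.integers(0, 3, size=(60, 4)).astype(float)
    study = make_study(dos, beta=rng.normal(size=4), p=np.full(4, 0.01))
    y = rng.normal(size=60)
    thr, _ = select_best_threshold(study, list(study.snp_ids), y, grid=[0.05, 1.0])
    assert thr == 1.0


def test_missing_dosage_policy():
    dos = np.array([[2.0, np.nan], [0.0, 1.0], [1.0, 1.0]])
    study = make_study(dos, beta=[1.0, 1.0], p=[0.01, 0.01])
    mean_scores, _ = compute_prs(study, ["rs1", "rs2"], missing="mean")
    skip_scores, _ = compute_prs(study, ["rs1", "rs2"], missing="skip")
    assert mean_scores[0] == pytest.approx(2.0 + 1.0)  # imputed column mean
    assert skip_scores[0] == pytest.approx(2.0)  # missing term dropped
    with pytest.raises(ValueError):
        compute_prs(study, ["rs1"], missing="bogus")
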