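"""Kinship, REML mixed model, the P3D scan and the 32-combination layout."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import lxthet as lx
from lxthet.errors import AnalysisError

from conftest import random_band_matrix


# ---------------------------------------------------------------------------
# Kinship


def test_kinship_identical_rows_and_anchor():
    data = pd.DataFrame([[1, 0, 1, 0], [1, 0, 1, 0], [0, 1, 0, 1]],
                        index=["a", "b", "c"], columns=list("WXYZ"), dtype=float)
    K = lx.kinship(lx.BandMatrix(data))
    assert K.at["a", "b"] == pytest.approx(1.0)
    assert K.at["a", "c"] == 0.0          # the S_min pair anchors zero
    assert np.allclose(np.diag(K), 1.0, atol=1e-5)


def test_kinship_matches_brute_force_enumeration():
    rng = np.random.default_rng(17)
    bm = random_band_matrix(rng, n=5, n_bands=12, missing=0.2)
    X = bm.data.to_numpy()
    S = np.zeros((5, 5))
    for i in range(5):
        for j in range(5):
            both = ~(np.isnan(X[i]) | np.isnan(X[j]))
            S[i, j] = (X[i][both] == X[j][both]).mean()
    smin = S[~np.eye(5, dtype=bool)].min()
    expect = np.clip((S - smin) / (1 - smin), 0, None)
    np.fill_diagonal(expect, 1.0)
    K = lx.kinship(bm).to_numpy()
    assert K == pytest.approx(expect, abs=1e-6)


def test_kinship_all_missing_individual_named():
    data = pd.DataFrame([[1.0, 0.0], [np.nan, np.nan]],
                        index=["ok", "ghost"], columns=["B1", "B2"])
    with pytest.raises(AnalysisError, match="ghost"):
        lx.kinship(lx.BandMatrix(data))


# ---------------------------------------------------------------------------
# REML / scan


def ols_p(y, x):
    return sm.OLS(y, sm.add_constant(x)).fit().f_pvalue


def test_identity_kinship_reduces_to_ols():
    rng = np.random.default_rng(2)
    n = 60
    ids = [f"I{i}" for i in range(n)]
    bmat = random_band_matrix(rng, n=n, n_bands=10, missing=0.0)
    bmat.data.index = ids
    y = pd.Series(rng.normal(size=n), index=ids)
    K = pd.DataFrame(np.eye(n), index=ids, columns=ids)
    model = lx.reml_fit(y, np.ones((n, 1)), K)
    recs = lx.mlm_scan(model, bmat)
    for r in recs.itertuples():
        assert r.p == pytest.approx(ols_p(y.to_numpy(),
                                          bmat.data[r.band].to_numpy()), abs=1e-6)


def test_reml_rejects_degenerate_phenotypes():
    n = 20
    K = pd.DataFrame(np.eye(n))
    with pytest.raises(AnalysisError, match="constant"):
        lx.reml_fit(pd.Series(np.ones(n)), np.ones((n, 1)), K)
    bad = pd.Series(np.ones(n)); bad.iloc[0] = np.nan
    with pytest.raises(AnalysisError, match="non-finite"):
        lx.reml_fit(bad, np.ones((n, 1)), K)


def test_reml_recovers_heritability():
    """Polygenic phenotype with h2 = 0.5 on 200 individuals: the fitted
    variance ratio lands within simulation error of the truth."""
    rng = np.random.default_rng(23)
    n = 200
    A = rng.normal(size=(n, 300)) / np.sqrt(300)
    K = A @ A.T
    dscale = np.mean(np.diag(K))
    K = K / dscale
    Lc = np.linalg.cholesky(K + 1e-8 * np.eye(n))
    ratios = []
    for _ in range(5):
        u = Lc @ rng.normal(size=n)
        e = rng.normal(size=n)
        y = pd.Series(u + e)
        m = lx.reml_fit(y, np.ones((n, 1)), pd.DataFrame(K))
        ratios.append(m.sigma2_g / (m.sigma2_g + m.sigma2_e))
    est = np.mean(ratios)
    assert abs(est - 0.5) < 3 * np.std(ratios, ddof=1) / np.sqrt(len(ratios)) + 0.05


def test_collinear_covariates_dropped():
    rng = np.random.default_rng(4)
    n = 40
    x = rng.normal(size=n)
    X = np.column_stack([np.ones(n), x, 2 * x])  # third column collinear
    y = pd.Series(x + rng.normal(size=n))
    m = lx.reml_fit(y, X, pd.DataFrame(np.eye(n)))
    assert m.X.shape[1] == 2


def test_scan_skips_monomorphic_and_flags_significant(demo_ctx):
    recs = demo_ctx.records
    assert (recs["p"] > 0).all() and (recs["p"] <= 1).all()
    assert (recs["r2"].dropna() >= 0).all() and (recs["r2"].dropna() <= 1).all()
    sig = lx.filter_significant(recs, 3.0)
    assert (sig["neglog10p"] > 3.0).all()


def test_scan_finds_planted_additive_qtl(demo, demo_ctx):
    """The additive FL QTL planted on M001 tops the GCA-variable scan."""
    truth = demo["truth"]
    causal = truth.marker_map.markers[0]
    gca = demo_ctx.records[(demo_ctx.records["variable"] == "GCA")
                           & (demo_ctx.records["trait"] == "FL")
                           & (demo_ctx.records["combination"] == 12)]
    best = gca.loc[gca["p"].idxmin(), "marker"]
    assert best == causal


def test_scan_null_rate_small():
    """Permuted phenotype: about 0.1% of band tests at -log10 p > 3."""
    rng = np.random.default_rng(3)
    n = 120
    bmat = random_band_matrix(rng, n=n, n_bands=60, missing=0.0)
    K = pd.DataFrame(np.eye(n), index=bmat.individuals, columns=bmat.individuals)
    nsig = ntest = 0
    for rep in range(20):
        y = pd.Series(rng.normal(size=n), index=bmat.individuals)
        m = lx.reml_fit(y, np.ones((n, 1)), K)
        recs = lx.mlm_scan(m, bmat)
        ntest += len(recs)
        nsig += int((recs["neglog10p"] > 3).sum())
    assert ntest >= 1000
    assert nsig / ntest < 0.005


# ---------------------------------------------------------------------------
# The 32 combinations


def test_build_variables_emits_exactly_32(demo, demo_means, demo_ca, demo_het):
    combos = lx.build_variables(demo["design"], demo_means, demo_ca, demo_het)
    assert [c.id for c in combos] == list(range(1, 33))
    by_var = pd.Series([c.variable for c in combos]).value_counts()
    assert by_var["phenotype"] == 11
    assert by_var["GCA"] == 6
    assert by_var["SCA"] == 5
    assert by_var["heterosis"] == 10


def test_combination_contracts(demo, demo_means, demo_ca, demo_het):
    design = demo["design"]
    combos = {c.id: c for c in
              lx.build_variables(design, demo_means, demo_ca, demo_het)}
    # combination 11: parents' genotype x parents' own trait means
    c11 = combos[11]
    assert c11.genotype == "PS" and c11.tester is None
    s = c11.frames[("FL", "value")]
    assert list(s.index) == design.lines
    assert s.equals(demo_means["FL"].reindex(design.lines))
    # combination 18: F1 set of the first tester x SCA of those crosses
    c18 = combos[18]
    t0 = design.testers[0]
    assert c18.genotype == t0 and c18.variable == "SCA"
    f1 = design.f1s_of_tester(t0)[0]
    line = design.parents_of(f1)[0]
    assert c18.frames[("FL", "value")][f1] == demo_ca["FL"].sca.at[line, t0]
    # combination 13: F1 genotypes carry the maternal line's GCA as phenotype
    c13 = combos[13]
    assert c13.frames[("FL", "value")][f1] == demo_ca["FL"].gca_line[line]
    # heterosis combinations carry all five metrics per trait
    c23 = combos[23]
    metrics = {m for (_, m) in c23.frames}
    assert metrics == set(lx.HETEROSIS_METRICS)
    # total scan count: 22 single-metric combos x traits + 10 x traits x 5
    n_frames = sum(len(c.frames) for c in combos.values())
    assert n_frames == 22 * 10 + 10 * 10 * 5


def test_run_all_deterministic(demo, demo_means, demo_ca, demo_het, demo_ctx):
    truth, design = demo["truth"], demo["design"]
    again = lx.run_all(truth.all_bands(), truth.marker_map, design,
                       demo_means, demo_ca, demo_het, lx.AssocConfig())
    pd.testing.assert_frame_equal(demo_ctx.records, again.records)
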