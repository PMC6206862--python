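"""LD: hand-computed 2x2 examples, rare-band masking, permutation test,
background percentile and the logarithmic decay fit."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import lxthet as lx
from lxthet.errors import AnalysisError
from lxthet.ld import band_ld


def bm(cols: dict):
    n = len(next(iter(cols.values())))
    return lx.BandMatrix(pd.DataFrame(
        {k: np.asarray(v, float) for k, v in cols.items()},
        index=[f"I{i}" for i in range(n)]))


def two_locus_map(chrom_b=1, pos_a=100_000, pos_b=500_000, bands_a=("A-1",),
                  bands_b=("B-1",)):
    return lx.MarkerMap(pd.DataFrame({
        "marker": ["A", "B"], "chrom": [1, chrom_b], "pos_bp": [pos_a, pos_b],
        "bands": [bands_a, bands_b]}))


def test_band_ld_hand_examples():
    # perfect LD of identical columns
    assert band_ld(np.array([1, 1, 0, 0.0]), np.array([1, 1, 0, 0.0])) == \
        pytest.approx((1.0, 1.0))
    # independence at equal frequencies
    r2, _ = band_ld(np.array([1, 1, 0, 0.0]), np.array([1, 0, 1, 0.0]))
    assert r2 == pytest.approx(0.0)
    # asymmetric 2x2 table: D = 0.125, r2 = 1/3, D' = 1
    r2, dp = band_ld(np.array([1, 1, 1, 0.0]), np.array([1, 1, 0, 0.0]))
    assert r2 == pytest.approx(1 / 3)
    assert dp == pytest.approx(1.0)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)),
                min_size=6, max_size=24),
       st.booleans(), st.booleans())
def test_r2_invariant_to_presence_absence_relabelling(pairs, flip_a, flip_b):
    a = np.array([p[0] for p in pairs], float)
    b = np.array([p[1] for p in pairs], float)
    base = band_ld(a, b)
    flipped = band_ld(1 - a if flip_a else a, 1 - b if flip_b else b)
    if base is None or flipped is None:
        assert base is None and flipped is None
    else:
        assert flipped[0] == pytest.approx(base[0], abs=1e-12)


def test_mask_rare_boundaries():
    n = 100
    rare = np.zeros(n); rare[0] = 1                 # frequency 0.01 < 0.05
    at_edge = np.zeros(n); at_edge[:5] = 1          # exactly 0.05: untouched
    common = (np.arange(n) % 2).astype(float)
    out = lx.mask_rare(bm({"r": rare, "e": at_edge, "c": common}))
    assert np.isnan(out.data["r"][rare == 1]).all()
    assert (out.data["r"][rare == 0] == 0).all()    # absences stay observed
    assert (out.data["e"] == at_edge).all()
    assert (out.data["c"] == common).all()


def test_pairwise_ld_perfect_and_distances():
    mat = bm({"A-1": [1, 1, 0, 0, 1, 0, 1, 0, 1, 0],
              "B-1": [1, 1, 0, 0, 1, 0, 1, 0, 1, 0]})
    pairs = lx.pairwise_ld(mat, two_locus_map(), shuffles=200, seed=1)
    row = pairs.iloc[0]
    assert row["r2"] == pytest.approx(1.0)
    assert row["Dprime"] == pytest.approx(1.0)
    assert row["linked"] and row["distance_bp"] == 400_000
    assert row["p_perm"] <= 0.05

    pairs_short = lx.pairwise_ld(
        bm({"A-1": [1, 1, 0, 0, 1, 0], "B-1": [1, 1, 0, 0, 1, 0]}),
        two_locus_map(), shuffles=200, seed=1)
    assert pairs_short.iloc[0]["r2"] == pytest.approx(1.0)
    inter = lx.pairwise_ld(mat, two_locus_map(chrom_b=14), shuffles=0, seed=1)
    assert not inter.iloc[0]["linked"]
    assert np.isnan(inter.iloc[0]["distance_bp"])


def test_locus_level_equals_band_level_for_single_band_loci():
    rng = np.random.default_rng(6)
    a = (rng.random(40) < 0.5).astype(float)
    b = (rng.random(40) < 0.4).astype(float)
    pairs = lx.pairwise_ld(bm({"A-1": a, "B-1": b}), two_locus_map(),
                           shuffles=0, seed=0)
    assert pairs.iloc[0]["r2"] == pytest.approx(band_ld(a, b)[0])


def test_multiband_locus_weighted_average():
    rng = np.random.default_rng(9)
    cols = {"A-1": (rng.random(60) < 0.5).astype(float),
            "A-2": (rng.random(60) < 0.3).astype(float),
            "B-1": (rng.random(60) < 0.6).astype(float)}
    mm = two_locus_map(bands_a=("A-1", "A-2"))
    pairs = lx.pairwise_ld(bm(cols), mm, shuffles=0, seed=0)
    w1 = np.mean(cols["A-1"]) * np.mean(cols["B-1"])
    w2 = np.mean(cols["A-2"]) * np.mean(cols["B-1"])
    r1 = band_ld(cols["A-1"], cols["B-1"])[0]
    r2 = band_ld(cols["A-2"], cols["B-1"])[0]
    expect = (w1 * r1 + w2 * r2) / (w1 + w2)
    assert pairs.iloc[0]["r2"] == pytest.approx(expect)


def test_too_few_complete_pairs_skipped():
    mat = bm({"A-1": [1, 0, np.nan, np.nan, np.nan, np.nan],
              "B-1": [1, 0, 1, 0, 1, 0]})
    pairs = lx.pairwise_ld(mat, two_locus_map(), shuffles=0, seed=0)
    assert pairs.empty


def test_background_percentile():
    base = {"locusA": "A", "locusB": "B", "linked": False}
    tab = pd.DataFrame([{**base, "r2": v} for v in np.arange(100) / 100.0])
    assert lx.background_ld(tab) == pytest.approx(0.9801)
    zeros = pd.DataFrame([{**base, "r2": 0.0}] * 10)
    assert lx.background_ld(zeros) == 0.0
    with pytest.raises(AnalysisError, match="unlinked"):
        lx.background_ld(pd.DataFrame([{**base, "linked": True, "r2": 0.5}]))


def test_decay_fit_closed_form_recovery():
    """Points generated exactly on r2 = 0.9 - 0.1 ln(d_kb): coefficients
    recovered to 1e-6 and the 0.2 crossing at exp(7) kb."""
    d = np.array([1.0, 5.0, 20.0, 100.0, 400.0, 1000.0])
    r2 = 0.9 - 0.1 * np.log(d)
    fit = lx.decay_fit_xy(d, r2, threshold=0.2)
    assert fit.intercept == pytest.approx(0.9, abs=1e-6)
    assert fit.slope == pytest.approx(-0.1, abs=1e-6)
    assert fit.decay_distance == pytest.approx(np.exp(7.0), rel=1e-6)


def test_decay_fit_zero_distance_and_flat_curve():
    d = np.array([0.0, 10.0, 100.0, 1000.0])
    fit = lx.decay_fit_xy(d, 0.5 - 0.02 * np.log(np.where(d == 0, 1e-7, d)),
                          threshold=0.2)
    assert np.isfinite(fit.intercept)  # the zero distance got the 1e-7 floor
    rising = lx.decay_fit_xy(np.array([1.0, 10.0, 100.0]),
                             np.array([0.1, 0.12, 0.2]))
    assert np.isnan(rising.decay_distance)
    with pytest.raises(AnalysisError):
        lx.decay_fit_xy(np.array([1.0, 1.0, 1.0]), np.array([0.1, 0.2, 0.3]))


def test_decay_fit_from_pair_table_filters():
    rows = []
    rng = np.random.default_rng(1)
    for i, d in enumerate(np.geomspace(1e3, 2e6, 12)):
        rows.append({"locusA": f"A{i}", "locusB": f"B{i}", "linked": True,
                     "distance_bp": d, "r2": 0.8 - 0.08 * np.log(d / 1000),
                     "p_perm": 0.0005})
    rows.append({"locusA": "X", "locusB": "Y", "linked": True,
                 "distance_bp": 5e4, "r2": 0.9, "p_perm": 0.5})  # filtered out
    fit = lx.decay_fit(pd.DataFrame(rows))
    assert fit.n_pairs == 12
    assert fit.intercept == pytest.approx(0.8, abs=1e-6)
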