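"""Summary stats, RCBD ANOVA (vs a direct sums-of-squares oracle),
entry means, correlations and PCA."""

import numpy as np
import pandas as pd
import pytest

import lxthet as lx
from lxthet.errors import AnalysisError


def long_table(values, trait="FL", location="AN", year=2012):
    rows = []
    for (ind, rep), v in values.items():
        rows.append((ind, trait, location, year, rep, v))
    return pd.DataFrame(rows, columns=["individual", "trait", "location",
                                       "year", "replicate", "value"])


def test_summarize_quartiles_and_single_value():
    tab = long_table({(f"I{i}", 1): v for i, v in enumerate([1, 2, 3, 4, 5])})
    s = lx.summarize(tab).iloc[0]
    assert (s["1st Q"], s["Med."], s["3rd Q"]) == (2, 3, 4)
    assert (s["Min"], s["Max."], s["Mean"]) == (1, 5, 3)

    one = lx.summarize(long_table({("I1", 1): 7.0})).iloc[0]
    assert one["Min"] == one["Max."] == one["Mean"] == 7.0 and one["S.D"] == 0.0


def test_summarize_monte_carlo_mean():
    rng = np.random.default_rng(12)
    vals = rng.normal(50, 5, size=1000)
    tab = long_table({(f"I{i}", 1): v for i, v in enumerate(vals)})
    s = lx.summarize(tab).iloc[0]
    assert abs(s["Mean"] - 50) < 3 * 5 / np.sqrt(1000)


def rcbd_oracle(df):
    """Independent direct sums-of-squares partition for a balanced RCBD."""
    y = df["value"].to_numpy(float)
    grand = y.mean()
    g = df.groupby("individual")["value"].mean()
    b = df.groupby("replicate")["value"].mean()
    reps, genos = df["replicate"].nunique(), df["individual"].nunique()
    ss_g = reps * ((g - grand) ** 2).sum()
    ss_b = genos * ((b - grand) ** 2).sum()
    ss_t = ((y - grand) ** 2).sum()
    return ss_g, ss_b, ss_t - ss_g - ss_b


def test_rcbd_matches_direct_partition_oracle():
    rng = np.random.default_rng(5)
    vals = {(f"G{g}", r): rng.normal(10 + g, 1.0)
            for g in range(3) for r in (1, 2, 3)}
    tab = long_table(vals)
    out = lx.rcbd_anova(tab, "FL", "AN", 2012)
    ss_g, ss_b, ss_e = rcbd_oracle(tab)
    assert out.at["genotype", "SS"] == pytest.approx(ss_g, rel=1e-10)
    assert out.at["replication", "SS"] == pytest.approx(ss_b, rel=1e-10)
    assert out.at["error", "SS"] == pytest.approx(ss_e, rel=1e-10)
    assert out.at["genotype", "df"] == 2 and out.at["error", "df"] == 4
    # partition closes: strata sum to the total SS
    total = out.loc[["genotype", "replication", "error"], "SS"].sum()
    assert total == pytest.approx(((tab["value"] - tab["value"].mean()) ** 2).sum(),
                                  rel=1e-8)


def test_rcbd_all_equal_and_replication_guard():
    tab = long_table({(f"G{g}", r): 5.0 for g in range(3) for r in (1, 2)})
    out = lx.rcbd_anova(tab, "FL", "AN", 2012)
    assert (out.loc[["genotype", "replication", "error"], "SS"] == 0).all()
    assert np.isnan(out.at["genotype", "F"])

    single = long_table({(f"G{g}", 1): float(g) for g in range(3)})
    with pytest.raises(AnalysisError, match="replication"):
        lx.rcbd_anova(single, "FL", "AN", 2012)


def test_rcbd_detects_genotype_effect_in_simulation():
    rng = np.random.default_rng(31)
    hits = 0
    for _ in range(10):
        effects = rng.normal(0, 5.0, size=8)
        vals = {(f"G{g}", r): 20 + effects[g] + rng.normal(0, 0.5)
                for g in range(8) for r in (1, 2, 3)}
        out = lx.rcbd_anova(long_table(vals), "FL", "AN", 2012)
        hits += out.at["genotype", "p"] < 0.01
    assert hits >= 9


def test_entry_means_raw_and_shrunk_edges():
    tab = long_table({("I1", 1): 3.0, ("I2", 1): 5.0})
    raw = lx.entry_means(tab, "raw")
    assert raw.at["I1", "FL"] == 3.0
    # zero residual variance within genotypes -> shrunk equals raw
    tab2 = long_table({("I1", 1): 3.0, ("I1", 2): 3.0,
                       ("I2", 1): 5.0, ("I2", 2): 5.0})
    shrunk = lx.entry_means(tab2, "shrunk")
    assert shrunk.at["I1", "FL"] == pytest.approx(3.0)
    assert shrunk.at["I2", "FL"] == pytest.approx(5.0)


def test_shrunk_means_beat_raw_in_mse():
    rng = np.random.default_rng(8)
    n, r = 60, 3
    truth = rng.normal(0, 1.0, size=n)
    rows = {}
    for i in range(n):
        for rep in range(1, r + 1):
            rows[(f"I{i:02d}", rep)] = 30 + truth[i] + rng.normal(0, 2.0)
    tab = long_table(rows)
    raw = lx.entry_means(tab, "raw")["FL"].to_numpy() - 30
    shr = lx.entry_means(tab, "shrunk")["FL"].to_numpy() - 30
    assert ((shr - truth) ** 2).mean() < ((raw - truth) ** 2).mean()


def test_correlations_identities_and_monte_carlo():
    rng = np.random.default_rng(21)
    n = 500
    x = rng.normal(size=n)
    y = 0.5 * x + np.sqrt(1 - 0.25) * rng.normal(size=n)
    means = pd.DataFrame({"FL": x, "FS": y, "MIC": -x},
                         index=[f"I{i}" for i in range(n)])
    r, p = lx.correlations(means)
    assert r.at["FL", "FL"] == 1.0
    assert r.at["FL", "MIC"] == pytest.approx(-1.0)
    se = 1 / np.sqrt(n - 3)
    assert abs(np.arctanh(r.at["FL", "FS"]) - np.arctanh(0.5)) < 3 * se
    assert p.at["FL", "FS"] < 1e-10


def test_pca_degenerate_and_oracle():
    # two perfectly correlated traits -> eigenvalues (2, 0)
    x = np.array([1.0, 2.0, 3.0, 4.0])
    res = lx.pca(pd.DataFrame({"FL": x, "FS": 2 * x}, index=list("abcd")))
    assert res.eigenvalues == pytest.approx([2.0, 0.0], abs=1e-12)
    # exactly uncorrelated columns -> identity correlation, all eigenvalues 1
    res2 = lx.pca(pd.DataFrame({"FL": [1, -1, 1, -1], "FS": [1, 1, -1, -1]},
                               index=list("abcd"), dtype=float))
    assert res2.eigenvalues == pytest.approx([1.0, 1.0])

    rng = np.random.default_rng(2)
    data = pd.DataFrame(rng.normal(size=(40, 10)), columns=list(lx.TRAITS))
    res3 = lx.pca(data)
    z = (data - data.mean()) / data.std(ddof=1)
    w = np.sort(np.linalg.eigvalsh(np.corrcoef(z.T)))[::-1]
    assert res3.eigenvalues == pytest.approx(w, abs=1e-8)
    assert res3.percent.sum() == pytest.approx(100.0)
    assert (np.diff(res3.cumulative_percent) >= -1e-9).all()
    assert res3.eigenvalues.sum() == pytest.approx(10.0)
    # sign convention: each component's largest-magnitude loading positive
    for c in res3.loadings.columns:
        col = res3.loadings[c]
        assert col.iloc[np.argmax(np.abs(col.to_numpy()))] > 0


def test_pca_excludes_constant_trait():
    rng = np.random.default_rng(3)
    data = pd.DataFrame({"FL": rng.normal(size=10), "FS": rng.normal(size=10),
                         "MIC": np.ones(10)})
    res = lx.pca(data)
    assert res.dropped_traits == ["MIC"]
    assert list(res.loadings.index) == ["FL", "FS"]
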