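"""Significance filtering, stable-QTL consensus, effect typing,
pleiotropy/subgenome summaries and the allele-effect statistic."""

import numpy as np
import pandas as pd
import pytest

import lxthet as lx
from lxthet.qtl import ALL_VARIABLES, CORE_VARIABLES


def record(trait="FL", marker="M001", variable="phenotype", tester="TA",
           nlp=4.0, band=None, combination=1, metric="value"):
    return {"combination": combination, "genotype": "PS", "variable": variable,
            "variable_class": variable, "metric": metric, "trait": trait,
            "tester": tester, "marker": marker, "band": band or marker + "-1",
            "effect": 0.1, "p": 10 ** -nlp, "neglog10p": nlp, "r2": 0.05, "n": 50}


def table(rows):
    return pd.DataFrame(rows)


def dummy_design():
    return lx.build_design([f"L{i}" for i in range(3)],
                           ["TA", "TB", "TC", "TD", "TE"])


def test_filter_threshold_is_strict():
    tab = table([record(nlp=3.0), record(nlp=3.01), record(nlp=2.0)])
    out = lx.filter_significant(tab, 3.0)
    assert len(out) == 1 and out.iloc[0]["neglog10p"] == 3.01
    assert lx.filter_significant(pd.DataFrame(), 3.0).empty


def test_stable_qtl_tester_counting():
    design = dummy_design()
    three = table([record(tester=t) for t in ("TA", "TB", "TC")])
    qtls = lx.stable_qtls(three, design)
    assert len(qtls) == 1 and qtls[0].n_testers == 3

    two = table([record(tester=t) for t in ("TA", "TB")])
    assert lx.stable_qtls(two, design) == []

    five = table([record(tester=t, variable=v) for t, v in
                  zip(("TA", "TB", "TC", "TD", "TE"),
                      ("GCA", "HB", "GCA", "HB", "GCA"))])
    qtls = lx.stable_qtls(five, design)
    assert qtls[0].n_testers == 5
    assert qtls[0].effect_type == "both"   # GCA + HB support

    # duplicate testers only count once
    dup = table([record(tester="TA"), record(tester="TA"), record(tester="TB"),
                 record(tester="TC")])
    assert lx.stable_qtls(dup, design)[0].n_testers == 3


def test_stable_qtl_whitelist_presets():
    design = dummy_design()
    rows = table([record(tester=t, variable="HI") for t in ("TA", "TB", "TC")])
    assert len(lx.stable_qtls(rows, design, variables=ALL_VARIABLES)) == 1
    # HI is outside the narrow five-variable preset
    assert lx.stable_qtls(rows, design, variables=CORE_VARIABLES) == []


@pytest.mark.parametrize("support,expected,lowconf", [
    ({"GCA"}, "additive", False),
    ({"SCA", "MP"}, "dominance", False),
    ({"GCA", "HB"}, "both", False),
    ({"phenotype"}, "both", True),
    ({"K3"}, "dominance", False),
])
def test_effect_typing_rules(support, expected, lowconf):
    etype, flag = lx.effect_type(support)
    assert etype == expected and flag == lowconf


def test_effect_typing_is_monotone():
    """Adding a supporting variable never removes an assigned type."""
    rng = np.random.default_rng(0)
    variables = list(lx.VARIABLES)
    rank = {"additive": {"additive"}, "dominance": {"dominance"},
            "both": {"additive", "dominance"}}
    for _ in range(200):
        base = set(rng.choice(variables, size=rng.integers(1, 5), replace=False))
        extra = base | {rng.choice(variables)}
        t1 = rank[lx.effect_type(base)[0]] if lx.effect_type(base)[1] is False else set()
        t2 = rank[lx.effect_type(extra)[0]] if lx.effect_type(extra)[1] is False else set()
        if t1 and t2:
            assert t1 <= t2 or t2 == {"additive", "dominance"} or t1 == t2


def brute_force_stable(records, threshold, whitelist, min_testers):
    """Independent enumeration oracle for filter -> stable -> type."""
    out = {}
    for r in records.to_dict("records"):
        if r["neglog10p"] <= threshold or r["variable"] not in whitelist:
            continue
        key = (r["trait"], r["marker"])
        out.setdefault(key, {"testers": set(), "vars": set()})
        if r["tester"] is not None and not pd.isna(r["tester"]):
            out[key]["testers"].add(r["tester"])
        out[key]["vars"].add(r["variable"])
    result = {}
    for key, v in out.items():
        if len(v["testers"]) >= min_testers:
            result[key] = lx.effect_type(v["vars"])[0]
    return result


def random_association_table(rng, n=40):
    testers = ["TA", "TB", "TC", "TD", "TE"]
    rows = []
    for _ in range(n):
        rows.append(record(
            trait=rng.choice(["FL", "FS", "BW"]),
            marker=f"M{rng.integers(1, 6):03d}",
            variable=rng.choice(list(lx.VARIABLES)),
            tester=rng.choice(testers + [None]),
            nlp=float(rng.uniform(1.0, 6.0)),
        ))
    return table(rows)


def test_pipeline_equals_brute_force_on_random_tables():
    rng = np.random.default_rng(77)
    design = dummy_design()
    for _ in range(100):
        tab = random_association_table(rng)
        got = {(q.trait, q.marker): q.effect_type
               for q in lx.stable_qtls(lx.filter_significant(tab, 3.0), design)}
        want = brute_force_stable(tab, 3.0, ALL_VARIABLES, 3)
        assert got == want


def test_pleiotropy_and_subgenome_partition():
    mm = lx.MarkerMap(pd.DataFrame({
        "marker": ["Ma", "Mb", "Mc"], "chrom": [5, 20, 25],
        "pos_bp": [1, 2, 3], "bands": [("Ma-1",), ("Mb-1",), ("Mc-1",)]}))
    qtls = [lx.StableQTL("FL", "Ma", [("GCA", "TA")], 3, "additive"),
            lx.StableQTL("FS", "Ma", [("HB", "TB")], 3, "dominance"),
            lx.StableQTL("FL", "Mb", [("MP", "TC")], 3, "dominance"),
            lx.StableQTL("BW", "Mc", [("K3", "TD")], 4, "dominance")]
    summary = lx.pleiotropy_and_subgenome(qtls, mm)
    assert summary["pleiotropic"] == {"Ma": ["FL", "FS"]}
    assert summary["subgenome_counts"] == {"A": 1, "D": 2, "unplaced": 0}
    assert summary["fraction_D"] == pytest.approx(2 / 3)
    empty = lx.pleiotropy_and_subgenome([], mm)
    assert empty["pleiotropic"] == {} and np.isnan(empty["fraction_D"])


def test_allele_effect_worked_example():
    """Accessions valued {10,20,30,40}; carriers are those at {30,40}:
    ai = 35 - 25 = +10."""
    pheno = pd.Series([10.0, 20.0, 30.0, 40.0], index=list("abcd"))
    band = pd.Series([0.0, 0.0, 1.0, 1.0], index=list("abcd"), name="B-1")
    eff = lx.allele_effect(band, pheno, trait="FL")
    assert eff.ai == pytest.approx(10.0)
    assert (eff.ni, eff.nk) == (2, 4)
    assert eff.favorable


def test_allele_effect_edges_and_direction():
    pheno = pd.Series([10.0, 20.0, 30.0], index=list("abc"))
    allc = lx.allele_effect(pd.Series([1.0, 1.0, 1.0], index=list("abc"), name="B"),
                            pheno)
    assert allc.ai == 0.0
    none = lx.allele_effect(pd.Series([0.0, 0.0, 0.0], index=list("abc"), name="B"),
                            pheno)
    assert np.isnan(none.ai)
    # for micronaire a negative effect is the favorable one
    mic = lx.allele_effect(pd.Series([1.0, 0.0, 0.0], index=list("abc"), name="B"),
                           pheno, trait="MIC", direction=-1)
    assert mic.ai < 0 and mic.favorable


def test_allele_effect_weighted_zero_sum():
    """Carrier and non-carrier deviations from the overall mean cancel:
    ni*ai_carrier + (nk-ni)*ai_complement = 0."""
    rng = np.random.default_rng(5)
    for _ in range(25):
        n = rng.integers(5, 40)
        pheno = pd.Series(rng.normal(size=n), index=[f"I{i}" for i in range(n)])
        b = pd.Series((rng.random(n) < 0.5).astype(float), index=pheno.index,
                      name="B")
        if b.sum() in (0, n):
            continue
        eff = lx.allele_effect(b, pheno)
        comp = lx.allele_effect(1 - b, pheno)
        assert eff.ni * eff.ai + comp.ni * comp.ai == pytest.approx(0.0, abs=1e-8)


def test_favorable_alleles_end_to_end(demo, demo_ctx):
    sig = lx.filter_significant(demo_ctx.records, 3.0)
    effects, extremes, tally = lx.favorable_alleles(
        sig, demo_ctx.combinations, demo_ctx.panels)
    if effects.empty:
        pytest.skip("no significant records in this demo draw")
    assert {"ai", "ni", "nk", "favorable"} <= set(effects.columns)
    assert (effects["ni"] <= effects["nk"]).all()
    for _, row in extremes.iterrows():
        assert row["max_ai"] >= row["min_ai"]
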