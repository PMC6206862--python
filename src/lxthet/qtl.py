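"""Post-scan inference: stable heterosis-QTL consensus and allele mining.

A marker-trait pair is a *stable QTL* when significant associations
support it in F1 families descending from at least three of the five
testers. Effect typing follows the variable that carried the signal:
GCA support indicates additive action; SCA or any heterosis statistic
indicates dominance; both together give "both". Favorable alleles are
scored with the allele-effect statistic

    ai = (mean phenotype of carriers of band i) − (mean phenotype of all)

with the sign read against the trait's desired direction.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AnalysisError
from .io import BandMatrix, LxTDesign, MarkerMap
from .traits import DEFAULT_DIRECTIONS, DOMINANCE_VARIABLES, VARIABLES, check_direction_table

log = logging.getLogger(__name__)

#: All eight dependent variables (default stable-QTL whitelist).
ALL_VARIABLES: frozenset[str] = frozenset(VARIABLES)

#: The narrower five-variable preset for stable-QTL support.
CORE_VARIABLES: frozenset[str] = frozenset({"phenotype", "GCA", "HB", "MP", "K4"})


def filter_significant(records: pd.DataFrame, threshold: float = 3.0) -> pd.DataFrame:
    """Keep records with −log10 p strictly above the threshold."""
    if records.empty:
        return records
    return records[records["neglog10p"] > threshold].reset_index(drop=True)


@dataclasses.dataclass
class StableQTL:
    trait: str
    marker: str
    support: list[tuple[str, str]]   # (variable, tester)
    n_testers: int
    effect_type: str                 # additive | dominance | both
    low_confidence: bool = False


def effect_type(support_variables: Iterable[str]) -> tuple[str, bool]:
    """Classify a stable QTL's gene action from its supporting variables.

    Returns ``(type, low_confidence)``; trait-phenotype support alone is
    classified "both" with the low-confidence flag set, since phenotype
    detects every type of effect.
    """
    vs = set(support_variables)
    additive = "GCA" in vs
    dominance = bool(vs & DOMINANCE_VARIABLES)
    if additive and dominance:
        return "both", False
    if additive:
        return "additive", False
    if dominance:
        return "dominance", False
    return "both", True


def stable_qtls(significant: pd.DataFrame, design: LxTDesign, *,
                variables: Iterable[str] = ALL_VARIABLES,
                min_testers: int = 3) -> list[StableQTL]:
    """Group significant records by (trait, marker) and keep the pairs
    supported by F1 families from at least ``min_testers`` distinct
    testers. Records without tester attribution (parents-only
    combinations) contribute supporting variables but no tester count."""
    if significant.empty:
        return []
    allowed = set(variables)
    sub = significant[significant["variable"].isin(allowed)]
    out: list[StableQTL] = []
    for (trait, marker), grp in sub.groupby(["trait", "marker"], sort=True):
        testers = {t for t in grp["tester"] if t is not None and not pd.isna(t)}
        if len(testers) < min_testers:
            continue
        support = sorted({(r.variable, r.tester if r.tester is not None
                           and not pd.isna(r.tester) else "")
                          for r in grp.itertuples(index=False)})
        etype, lowconf = effect_type(grp["variable"])
        out.append(StableQTL(trait=trait, marker=marker, support=support,
                             n_testers=len(testers), effect_type=etype,
                             low_confidence=lowconf))
    return out


def stable_qtl_table(qtls: Sequence[StableQTL]) -> pd.DataFrame:
    rows = [{
        "trait": q.trait, "marker": q.marker, "n_testers": q.n_testers,
        "effect_type": q.effect_type, "low_confidence": q.low_confidence,
        "support": ";".join(f"{v}@{t}" if t else v for v, t in q.support),
    } for q in qtls]
    return pd.DataFrame(rows, columns=["trait", "marker", "n_testers",
                                       "effect_type", "low_confidence", "support"])


def pleiotropy_and_subgenome(qtls: Sequence[StableQTL],
                             marker_map: MarkerMap) -> dict:
    """Pleiotropic markers (stable for ≥2 traits) and the A/D subgenome
    tally (A = chromosomes 1–13, D = 14–26, the standard upland-cotton
    convention)."""
    by_marker: dict[str, set[str]] = {}
    for q in qtls:
        by_marker.setdefault(q.marker, set()).add(q.trait)
    pleiotropic = {m: sorted(ts) for m, ts in by_marker.items() if len(ts) >= 2}
    tally = {"A": 0, "D": 0, "unplaced": 0}
    for m in by_marker:
        try:
            chrom = marker_map.chrom_of(m)
        except KeyError:
            log.warning("pleiotropy_and_subgenome: unmapped marker %s", m)
            tally["unplaced"] += 1
            continue
        tally["A" if chrom <= 13 else "D"] += 1
    placed = tally["A"] + tally["D"]
    return {
        "pleiotropic": pleiotropic,
        "subgenome_counts": tally,
        "fraction_D": tally["D"] / placed if placed else float("nan"),
    }


# ---------------------------------------------------------------------------
# Allele effects


@dataclasses.dataclass
class AlleleEffect:
    band: str
    trait: str
    ai: float
    ni: int
    nk: int
    favorable: bool


def allele_effect(band_col: pd.Series, pheno: pd.Series, *, trait: str = "",
                  direction: int = 1) -> AlleleEffect:
    """ai = carrier mean − overall mean, over accessions with phenotype.

    Carriers are accessions with a non-missing presence (1) of the band.
    No carriers (or an all-missing band) leaves ai NaN with a warning.
    A band carried by every accession gives ai = 0 exactly.
    """
    joined = pd.concat([band_col.rename("band"), pheno.rename("y")],
                       axis=1, join="inner").dropna(subset=["y"])
    b = joined["band"]
    y = joined["y"]
    nk = int(y.notna().sum())
    if nk < 1:
        raise AnalysisError("allele_effect: no accessions with phenotype")
    carriers = b == 1.0
    ni = int(carriers.sum())
    if b.isna().all() or ni == 0:
        log.warning("allele_effect: band %s has no observed carriers -> NA",
                    band_col.name)
        return AlleleEffect(band=str(band_col.name), trait=trait, ai=float("nan"),
                            ni=ni, nk=nk, favorable=False)
    ai = float(y[carriers].mean() - y.mean())
    return AlleleEffect(band=str(band_col.name), trait=trait, ai=ai, ni=ni, nk=nk,
                        favorable=bool(ai * direction > 0))


def favorable_alleles(significant: pd.DataFrame, combinations,
                      panels: Mapping[str, BandMatrix],
                      directions: dict[str, int] | None = None):
    """Allele effects for every significant band × trait within its own
    genotype/phenotype combination.

    Returns ``(effects, extremes, tester_tally)``: the full per-record
    table; per trait the maximum-positive and minimum-negative effect; and
    the count of favorable alleles contributed per tester's combinations.
    """
    directions = check_direction_table(dict(directions or DEFAULT_DIRECTIONS))
    by_id = {c.id: c for c in combinations}
    rows = []
    for r in significant.itertuples(index=False):
        combo = by_id.get(r.combination)
        if combo is None:
            continue
        series = combo.frames.get((r.trait, r.metric))
        if series is None:
            continue
        pheno = series.dropna().rename("value")
        bandcol = panels[combo.genotype].data[r.band]
        eff = allele_effect(bandcol, pheno, trait=r.trait,
                            direction=directions.get(r.trait, 1))
        rows.append({
            "combination": r.combination, "genotype": combo.genotype,
            "variable": r.variable, "metric": r.metric, "tester": combo.tester,
            "trait": r.trait, "marker": r.marker, "band": r.band,
            "ai": eff.ai, "ni": eff.ni, "nk": eff.nk, "favorable": eff.favorable,
        })
    effects = pd.DataFrame(rows)
    if effects.empty:
        return effects, pd.DataFrame(), pd.Series(dtype=int)
    extremes_rows = []
    for trait, grp in effects.dropna(subset=["ai"]).groupby("trait"):
        imax, imin = grp["ai"].idxmax(), grp["ai"].idxmin()
        extremes_rows.append({
            "trait": trait,
            "max_ai": grp.at[imax, "ai"], "max_band": grp.at[imax, "band"],
            "min_ai": grp.at[imin, "ai"], "min_band": grp.at[imin, "band"],
        })
    extremes = pd.DataFrame(extremes_rows)
    fav = effects[effects["favorable"]]
    tally = fav.groupby("tester", dropna=False).size()
    return effects, extremes, tally
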