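"""Line × Tester combining-ability decomposition and heterosis statistics.

The L×T decomposition writes each cross mean as

    x̄_ij = μ + g_i + g_j + s_ij

with line GCA ``g_i``, tester GCA ``g_j`` and SCA ``s_ij``, each summing to
zero over its index. With replicated data the crosses stratum of the ANOVA
is partitioned into lines, testers and line×tester; lines and testers are
tested against the L×T mean square, crosses and L×T against error — the
convention of classical L×T variance analysis.

Five heterosis statistics are computed per cross × trait:

    MP  = 100·(F1 − MPv)/MPv,  MPv = (P1 + P2)/2
    HB  = 100·(F1 − BP)/BP,    BP  = better parent in the desired direction
    HI  = 100·F1/MPv
    K3  = 100·(F1 − check3)/check3   (environment-matched, then averaged)
    K4  = likewise for the second check
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError
from .io import LxTDesign
from .traits import DEFAULT_DIRECTIONS, HETEROSIS_METRICS, TRAITS, check_direction_table

log = logging.getLogger(__name__)


@dataclasses.dataclass
class CombiningAbility:
    """GCA/SCA decomposition for one trait."""

    trait: str
    mu: float
    gca_line: pd.Series            # indexed by line
    gca_tester: pd.Series          # indexed by tester
    sca: pd.DataFrame              # lines x testers
    cross_means: pd.DataFrame      # lines x testers
    anova: pd.DataFrame | None     # strata x (df, SS, MS, F, p)
    sigma2_gca: float
    sigma2_sca: float

    def reconstruct(self, line: str, tester: str) -> float:
        return (self.mu + self.gca_line[line] + self.gca_tester[tester]
                + self.sca.at[line, tester])


def _cross_mean_table(pheno: pd.DataFrame, design: LxTDesign, trait: str) -> pd.DataFrame:
    sub = pheno[(pheno["trait"] == trait) & pheno["individual"].isin(design.f1s)]
    m = sub.groupby("individual")["value"].mean()
    tab = pd.DataFrame(index=design.lines, columns=design.testers, dtype=float)
    missing = []
    for r in design.crosses.itertuples(index=False):
        if r.f1 in m.index:
            tab.at[r.line, r.tester] = m[r.f1]
        else:
            missing.append((r.line, r.tester))
    if missing:
        raise AnalysisError(f"combining_ability: missing cross mean(s) {missing[:5]}")
    return tab


def combining_ability(data, design: LxTDesign, trait: str) -> CombiningAbility:
    """L×T combining-ability analysis for one trait.

    ``data`` is either a long phenotype table (replicated ANOVA; every
    location × year × replicate combination is treated as one replication
    block of the crosses trial) or an individuals × traits entry-mean
    DataFrame (means-only decomposition, no error stratum).
    """
    if len(design.testers) < 2:
        raise AnalysisError("combining_ability: single tester -> testers stratum undefined")
    if len(design.lines) < 2:
        raise AnalysisError("combining_ability: need >= 2 lines")

    long_format = "value" in getattr(data, "columns", [])
    if long_format:
        tab = _cross_mean_table(data, design, trait)
    else:
        if trait not in data.columns:
            raise AnalysisError(f"combining_ability: trait {trait!r} not in means")
        m = data[trait]
        tab = pd.DataFrame(index=design.lines, columns=design.testers, dtype=float)
        missing = []
        for r in design.crosses.itertuples(index=False):
            v = m.get(r.f1, np.nan)
            if np.isnan(v):
                missing.append((r.line, r.tester))
            tab.at[r.line, r.tester] = v
        if missing:
            raise AnalysisError(f"combining_ability: missing cross mean(s) {missing[:5]}")

    mu = float(tab.to_numpy().mean())
    g_line = tab.mean(axis=1) - mu
    g_tester = tab.mean(axis=0) - mu
    sca = tab.sub(tab.mean(axis=1), axis=0).sub(tab.mean(axis=0), axis=1) + mu

    anova = None
    s2_gca = s2_sca = float("nan")
    if long_format:
        sub = data[(data["trait"] == trait) & data["individual"].isin(design.f1s)].copy()
        sub["block"] = (sub["location"].astype(str) + "/" + sub["year"].astype(str)
                        + "/r" + sub["replicate"].astype(str))
        r = sub["block"].nunique()
        if r >= 2:
            anova, s2_gca, s2_sca = _lxt_anova(sub, design, tab, mu, r)
    return CombiningAbility(trait=trait, mu=mu, gca_line=g_line, gca_tester=g_tester,
                            sca=sca, cross_means=tab, anova=anova,
                            sigma2_gca=s2_gca, sigma2_sca=s2_sca)


def _lxt_anova(sub: pd.DataFrame, design: LxTDesign, cross_means: pd.DataFrame,
               mu: float, r: int):
    l, t = len(design.lines), len(design.testers)
    counts = sub.groupby(["individual", "block"]).size()
    if (counts != 1).any() or len(counts) != l * t * r:
        raise AnalysisError("combining_ability: unbalanced cross x block layout")
    y = sub["value"].to_numpy(float)
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    block_means = sub.groupby("block")["value"].mean()
    ss_rep = float(l * t * ((block_means - grand) ** 2).sum())
    cm = cross_means.to_numpy()
    ss_cross = float(r * ((cm - grand) ** 2).sum())
    ss_lines = float(r * t * ((cm.mean(axis=1) - grand) ** 2).sum())
    ss_testers = float(r * l * ((cm.mean(axis=0) - grand) ** 2).sum())
    ss_lxt = ss_cross - ss_lines - ss_testers
    ss_err = ss_total - ss_rep - ss_cross

    dfs = {"replications": r - 1, "crosses": l * t - 1, "lines": l - 1,
           "testers": t - 1, "line_x_tester": (l - 1) * (t - 1),
           "error": (l * t - 1) * (r - 1)}
    sss = {"replications": ss_rep, "crosses": ss_cross, "lines": ss_lines,
           "testers": ss_testers, "line_x_tester": ss_lxt, "error": ss_err}
    ms = {k: sss[k] / dfs[k] if dfs[k] > 0 else np.nan for k in dfs}

    def ftest(num: str, den: str):
        if ms[den] in (0.0,) or not np.isfinite(ms[den]):
            return np.nan, np.nan
        f = ms[num] / ms[den]
        return f, float(stats.f.sf(f, dfs[num], dfs[den]))

    rows = {}
    rows["replications"] = (*ftest("replications", "error"),)
    rows["crosses"] = (*ftest("crosses", "error"),)
    rows["lines"] = (*ftest("lines", "line_x_tester"),)
    rows["testers"] = (*ftest("testers", "line_x_tester"),)
    rows["line_x_tester"] = (*ftest("line_x_tester", "error"),)
    rows["error"] = (np.nan, np.nan)
    anova = pd.DataFrame(
        {"df": [dfs[k] for k in dfs], "SS": [sss[k] for k in dfs],
         "MS": [ms[k] for k in dfs],
         "F": [rows[k][0] for k in dfs], "p": [rows[k][1] for k in dfs]},
        index=list(dfs))

    s2_sca = (ms["line_x_tester"] - ms["error"]) / r
    s2_gca = 0.5 * ((ms["lines"] - ms["line_x_tester"]) / (r * t)
                    + (ms["testers"] - ms["line_x_tester"]) / (r * l))
    for name, val in (("sigma2_sca", s2_sca), ("sigma2_gca", s2_gca)):
        if val < 0:
            log.info("combining_ability: negative %s estimate clamped to 0", name)
    return anova, max(s2_gca, 0.0), max(s2_sca, 0.0)


# ---------------------------------------------------------------------------
# Heterosis


def heterosis(f1: float, line: float, tester: float, metric: str,
              check: float | None = None, direction: int = 1) -> float:
    """One heterosis statistic for one cross.

    ``metric`` is MP, HB, HI, K3 or K4 (K3/K4 need ``check``); ``direction``
    is +1 when higher trait values are desired, -1 otherwise (affects which
    parent is "better" for HB). Zero denominators or missing inputs give NaN.
    """
    if metric not in HETEROSIS_METRICS:
        raise AnalysisError(f"heterosis: unknown metric {metric!r}")
    if metric in ("K3", "K4"):
        if check is None or not np.isfinite(check) or not np.isfinite(f1):
            return float("nan")
        if check == 0:
            log.warning("heterosis: zero check denominator -> NA")
            return float("nan")
        return 100.0 * (f1 - check) / check
    if any(not np.isfinite(v) for v in (f1, line, tester)):
        return float("nan")
    mpv = 0.5 * (line + tester)
    if metric == "MP":
        if mpv == 0:
            log.warning("heterosis: zero mid-parent denominator -> NA")
            return float("nan")
        return 100.0 * (f1 - mpv) / mpv
    if metric == "HI":
        if mpv == 0:
            return float("nan")
        return 100.0 * f1 / mpv
    bp = max(line, tester) if direction > 0 else min(line, tester)
    if bp == 0:
        log.warning("heterosis: zero better-parent denominator -> NA")
        return float("nan")
    return 100.0 * (f1 - bp) / bp


def heterosis_table(pheno: pd.DataFrame, design: LxTDesign,
                    directions: dict[str, int] | None = None) -> pd.DataFrame:
    """All five heterosis statistics per cross × trait.

    MP/HB/HI use overall entry means of the F1 and its parents. Standard
    heterosis (K3/K4) uses the check's environment-matched mean — the ratio
    is formed within each location × year and then averaged — so genotype ×
    environment differences in the check do not leak into the statistic.
    Missing check records leave K3/K4 as NaN with a warning.
    """
    directions = check_direction_table(dict(directions or DEFAULT_DIRECTIONS))
    overall = pheno.groupby(["individual", "trait"])["value"].mean()
    env_means = pheno.groupby(["individual", "trait", "location", "year"])["value"].mean()

    rows = []
    for trait in sorted(pheno["trait"].unique(), key=TRAITS.index):
        d = directions.get(trait, 1)
        for r in design.crosses.itertuples(index=False):
            f1v = overall.get((r.f1, trait), np.nan)
            lv = overall.get((r.line, trait), np.nan)
            tv = overall.get((r.tester, trait), np.nan)
            rec = {"f1": r.f1, "line": r.line, "tester": r.tester, "trait": trait}
            rec["MP"] = heterosis(f1v, lv, tv, "MP")
            rec["HB"] = heterosis(f1v, lv, tv, "HB", direction=d)
            rec["HI"] = heterosis(f1v, lv, tv, "HI")
            for label in ("K3", "K4"):
                chk_id = design.checks.get(label)
                if chk_id is None:
                    rec[label] = np.nan
                    continue
                try:
                    f1_env = env_means.loc[r.f1, trait]
                    chk_env = env_means.loc[chk_id, trait]
                except KeyError:
                    log.warning("heterosis_table: no %s records -> NA", label)
                    rec[label] = np.nan
                    continue
                joined = pd.concat([f1_env, chk_env], axis=1, join="inner")
                joined = joined[(joined.iloc[:, 1] != 0)]
                if joined.empty:
                    rec[label] = np.nan
                else:
                    ratio = 100.0 * (joined.iloc[:, 0] - joined.iloc[:, 1]) / joined.iloc[:, 1]
                    rec[label] = float(ratio.mean())
            rows.append(rec)
    return pd.DataFrame(rows)
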