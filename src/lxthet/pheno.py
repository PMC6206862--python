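"""Descriptive statistics, RCBD ANOVA, entry means, correlations and PCA.

These are the phenotype-side preliminaries of the pipeline: per-trait
summaries of the multi-environment trial, a randomized-complete-block
analysis of variance within each environment, adjusted entry means used
downstream as association phenotypes, trait-trait Pearson correlations and
a correlation-matrix PCA of the trait space.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError, SchemaError

log = logging.getLogger(__name__)

SUMMARY_COLUMNS = ["Min", "1st Q", "Med.", "3rd Q", "Max.", "Mean", "S.D"]


def summarize(pheno: pd.DataFrame,
              by: tuple[str, ...] = ("trait", "location", "year")) -> pd.DataFrame:
    """Per-group min, quartiles, max, mean and SD of phenotype values.

    Quartiles use linear interpolation (type-7); SD uses the n-1
    denominator. Empty groups are simply absent.
    """
    rows = []
    for key, grp in pheno.groupby(list(by), sort=True):
        v = grp["value"].to_numpy(float)
        if v.size == 0:  # pragma: no cover - groupby yields no empty groups
            log.warning("summarize: empty group %s omitted", key)
            continue
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        sd = v.std(ddof=1) if v.size > 1 else 0.0
        rows.append((*np.atleast_1d(key), v.min(), q1, med, q3, v.max(), v.mean(), sd))
    return pd.DataFrame(rows, columns=[*by, *SUMMARY_COLUMNS])


def rcbd_anova(pheno: pd.DataFrame, trait: str, location, year) -> pd.DataFrame:
    """RCBD ANOVA within one environment: genotype + replication + error.

    Fits the additive two-way OLS model through statsmodels and returns the
    type-I partition (exact for a balanced layout). With every value equal
    the sums of squares are 0 and F is undefined (NaN).
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = pheno[(pheno["trait"] == trait) & (pheno["location"] == location)
               & (pheno["year"] == year)].copy()
    if df.empty:
        raise AnalysisError(f"rcbd_anova: no records for {trait} @ {location}/{year}")
    reps = df["replicate"].nunique()
    if reps < 2:
        raise AnalysisError("RCBD requires replication (>= 2 replicates)")
    counts = df.groupby(["individual", "replicate"]).size()
    if (counts != 1).any() or df.groupby("individual")["replicate"].nunique().nunique() != 1:
        raise SchemaError("rcbd_anova: genotype x replicate layout is not balanced")

    df["individual"] = df["individual"].astype(str)
    df["replicate"] = df["replicate"].astype(str)
    if np.ptp(df["value"].to_numpy()) == 0.0:
        n = len(df)
        g = df["individual"].nunique()
        out = pd.DataFrame(
            {"df": [g - 1, reps - 1, (g - 1) * (reps - 1)],
             "SS": [0.0, 0.0, 0.0], "MS": [0.0, 0.0, 0.0],
             "F": [np.nan] * 3, "p": [np.nan] * 3},
            index=["genotype", "replication", "error"])
        out.loc["total"] = [n - 1, 0.0, 0.0, np.nan, np.nan]
        return out

    fit = smf.ols("value ~ C(individual) + C(replicate)", data=df).fit()
    tab = anova_lm(fit, typ=1)
    out = pd.DataFrame({
        "df": [tab.loc["C(individual)", "df"], tab.loc["C(replicate)", "df"],
               tab.loc["Residual", "df"]],
        "SS": [tab.loc["C(individual)", "sum_sq"], tab.loc["C(replicate)", "sum_sq"],
               tab.loc["Residual", "sum_sq"]],
    }, index=["genotype", "replication", "error"])
    out["MS"] = out["SS"] / out["df"]
    mse = out.at["error", "MS"]
    out["F"] = np.where(out.index == "error", np.nan, out["MS"] / mse)
    out["p"] = [stats.f.sf(out.at[k, "F"], out.at[k, "df"], out.at["error", "df"])
                if k != "error" else np.nan for k in out.index]
    out.loc["total"] = [out["df"].sum(), out["SS"].sum(), np.nan, np.nan, np.nan]
    return out


def _variance_components(values: pd.Series, groups: pd.Series) -> tuple[float, float, float]:
    """One-way random-effects components (sigma2_g, sigma2_res, r0)."""
    df = pd.DataFrame({"y": values, "g": groups})
    n = len(df)
    k = df["g"].nunique()
    if k < 2 or n <= k:
        return 0.0, 0.0, 1.0
    grand = df["y"].mean()
    gm = df.groupby("g")["y"].agg(["mean", "count"])
    ssb = float((gm["count"] * (gm["mean"] - grand) ** 2).sum())
    ssw = float(((df["y"] - df["g"].map(gm["mean"])) ** 2).sum())
    msb = ssb / (k - 1)
    msw = ssw / (n - k)
    r0 = (n - (gm["count"] ** 2).sum() / n) / (k - 1)
    s2g = (msb - msw) / r0
    if s2g < 0:
        log.info("entry_means: negative sigma2_g estimate clamped to 0")
        s2g = 0.0
    return s2g, msw, float(r0)


def entry_means(pheno: pd.DataFrame, mode: str = "raw") -> pd.DataFrame:
    """Individual × trait adjusted means.

    ``raw``: arithmetic mean over environments/replicates. ``shrunk``:
    BLUP-style shrinkage of each entry mean toward the grand mean with
    weight ``sigma2_g / (sigma2_g + sigma2_res / n_i)``, with variance
    components from a one-way random-effects decomposition per trait.
    """
    if mode not in ("raw", "shrunk"):
        raise SchemaError(f"entry_means: unknown mode {mode!r}")
    raw = pheno.pivot_table(index="individual", columns="trait", values="value",
                            aggfunc="mean")
    if mode == "raw":
        return raw
    out = raw.copy()
    counts = pheno.pivot_table(index="individual", columns="trait", values="value",
                               aggfunc="count")
    for trait in raw.columns:
        sub = pheno[pheno["trait"] == trait]
        s2g, s2w, _ = _variance_components(sub["value"], sub["individual"])
        grand = sub["value"].mean()
        ni = counts[trait].reindex(raw.index).fillna(0)
        if s2w == 0.0:
            w = pd.Series(1.0, index=raw.index)
        elif s2g == 0.0:
            w = pd.Series(0.0, index=raw.index)
        else:
            w = s2g / (s2g + s2w / ni.clip(lower=1))
        out[trait] = grand + w * (raw[trait] - grand)
    return out


def correlations(means: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r between traits with two-sided p-values.

    Pairwise-complete individuals; a zero-variance trait yields NaN with a
    warning. The diagonal is exactly 1 (p = 0).
    """
    traits = list(means.columns)
    r = pd.DataFrame(np.eye(len(traits)), index=traits, columns=traits)
    p = pd.DataFrame(np.zeros((len(traits), len(traits))), index=traits, columns=traits)
    for i, a in enumerate(traits):
        for j in range(i + 1, len(traits)):
            b = traits[j]
            sub = means[[a, b]].dropna()
            if len(sub) < 3:
                raise AnalysisError(f"correlations: <3 complete pairs for {a}/{b}")
            if sub[a].std(ddof=1) == 0 or sub[b].std(ddof=1) == 0:
                log.warning("correlations: zero variance in %s or %s -> NA", a, b)
                rv, pv = np.nan, np.nan
            else:
                rv, pv = stats.pearsonr(sub[a], sub[b])
            r.loc[a, b] = r.loc[b, a] = rv
            p.loc[a, b] = p.loc[b, a] = pv
    return r, p


@dataclasses.dataclass
class PcaResult:
    eigenvalues: np.ndarray
    loadings: pd.DataFrame        # traits x components
    scores: pd.DataFrame          # individuals x components
    percent: np.ndarray
    cumulative_percent: np.ndarray
    dropped_traits: list[str]


def pca(means: pd.DataFrame) -> PcaResult:
    """PCA of the trait correlation matrix.

    Individuals with any missing trait are dropped; constant traits are
    excluded with a warning. Scores are the standardized data projected on
    the eigenvectors; each component's sign is fixed so its largest-
    magnitude loading is positive. Eigenvalues sum to the number of traits.
    """
    data = means.dropna()
    if data.shape[1] < 2 or data.shape[0] < 3:
        raise AnalysisError("pca: need >= 2 traits and >= 3 complete individuals")
    sd = data.std(ddof=1)
    dropped = list(sd.index[sd == 0])
    if dropped:
        log.warning("pca: constant trait(s) excluded: %s", dropped)
        data = data.drop(columns=dropped)
    z = (data - data.mean()) / data.std(ddof=1)
    corr = np.asarray(z.T @ z) / (len(z) - 1)
    w, v = np.linalg.eigh(corr)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    w = np.clip(w, 0.0, None)
    for k in range(v.shape[1]):
        if v[np.argmax(np.abs(v[:, k])), k] < 0:
            v[:, k] = -v[:, k]
    comps = [f"PC{k + 1}" for k in range(len(w))]
    loadings = pd.DataFrame(v, index=data.columns, columns=comps)
    scores = pd.DataFrame(z.to_numpy() @ v, index=data.index, columns=comps)
    pct = 100.0 * w / w.sum()
    return PcaResult(eigenvalues=w, loadings=loadings, scores=scores,
                     percent=pct, cumulative_percent=np.cumsum(pct),
                     dropped_traits=dropped)
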