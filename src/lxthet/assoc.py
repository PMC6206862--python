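"""Q+K mixed linear model association mapping over the L×T combinations.

The model is the unified mixed model of association mapping:

    y = Xβ + Zu + e,   u ~ N(0, σ²_g K),   e ~ N(0, σ²_e I)

with fixed effects X (intercept, optional Q-matrix columns, and the tested
band), and kinship K as the random-effect covariance. Variance components
are estimated once per phenotype by REML through a spectral decomposition
of K and a one-dimensional search over δ = σ²_e/σ²_g (the P3D shortcut),
then every band is tested by generalized least squares with the fitted
covariance held fixed.

The dependent variables scanned are the 32 genotype/phenotype combinations
of the L×T design: trait phenotype (11), GCA (6), SCA (5) and heterosis
(10, each carrying the five heterosis statistics as separate scans).
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import AnalysisError
from .io import BandMatrix, LxTDesign, MarkerMap
from .lxt import CombiningAbility
from .traits import HETEROSIS_METRICS, TRAITS

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Kinship


def kinship(bands: BandMatrix) -> pd.DataFrame:
    """Simple-matching kinship for dominant band data.

    Pairwise similarity S = fraction of bands with identical 0/1 state over
    bands non-missing in both individuals, rescaled so the least-related
    pair anchors 0: K = (S − S_min)/(1 − S_min), clipped at 0, diagonal 1.
    If the result is not positive semidefinite a ridge of 1e-6·I is added
    (logged).
    """
    X = bands.data.to_numpy(float)
    obs = ~np.isnan(X)
    nobs = obs.sum(axis=1)
    if (nobs == 0).any():
        bad = bands.individuals[int(np.argmin(nobs))]
        raise AnalysisError(f"kinship: individual {bad!r} has all-missing genotype")
    A1 = np.where(obs, X == 1.0, 0.0)
    A0 = np.where(obs, X == 0.0, 0.0)
    O = obs.astype(float)
    matches = A1 @ A1.T + A0 @ A0.T
    counts = O @ O.T
    if (counts == 0).any():
        raise AnalysisError("kinship: a pair of individuals shares no observed band")
    S = matches / counts
    n = S.shape[0]
    off = ~np.eye(n, dtype=bool)
    s_min = S[off].min() if n > 1 else 0.0
    if s_min >= 1.0:
        K = np.ones_like(S)
    else:
        K = np.clip((S - s_min) / (1.0 - s_min), 0.0, None)
    np.fill_diagonal(K, 1.0)
    evmin = float(np.linalg.eigvalsh(K).min())
    ridge = 0.0
    while evmin < -1e-8 and ridge < 1e-3:
        ridge += 1e-6
        evmin = float(np.linalg.eigvalsh(K + ridge * np.eye(n)).min())
    if ridge:
        log.info("kinship: added ridge %.1e to restore PSD", ridge)
        K = K + ridge * np.eye(n)
    return pd.DataFrame(K, index=bands.individuals, columns=bands.individuals)


# ---------------------------------------------------------------------------
# REML


@dataclasses.dataclass
class MlmModel:
    """Fitted variance components plus the cached spectral pieces the
    per-marker scan needs (P3D: components held fixed across markers)."""

    individuals: list[str]
    sigma2_g: float
    sigma2_e: float
    delta: float              # sigma2_e / sigma2_g
    loglik: float
    U: np.ndarray             # eigenvectors of K
    d: np.ndarray             # eigenvalues of K
    X: np.ndarray             # fixed covariates (transformed space not applied)
    y: np.ndarray
    rss0: float               # GLS residual SS of the covariate-only model

    @property
    def weights(self) -> np.ndarray:
        return self.d + self.delta


def _drop_collinear(X: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(X)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    if not keep.all():
        log.info("reml_fit: dropped %d collinear fixed-effect column(s)",
                 (~keep).sum())
        X = X[:, keep]
    return X


def reml_fit(y, X, K) -> MlmModel:
    """Single-random-effect REML via spectral decomposition of K.

    ``y``: phenotype Series/array; ``X``: fixed covariates including the
    intercept (and Q columns); ``K``: kinship DataFrame/array over the same
    individuals. δ is optimised on a log10 grid-bounded Brent search over
    [1e-5, 1e5]; boundary candidates are also evaluated.
    """
    ids = list(y.index) if isinstance(y, pd.Series) else None
    yv = np.asarray(y, float)
    if not np.isfinite(yv).all():
        raise AnalysisError("reml_fit: non-finite phenotype value")
    if yv.std() == 0:
        raise AnalysisError("reml_fit: constant phenotype, variance components undefined")
    Kv = K.to_numpy(float) if isinstance(K, pd.DataFrame) else np.asarray(K, float)
    Xv = np.asarray(X, float)
    if Xv.ndim == 1:
        Xv = Xv[:, None]
    Xv = _drop_collinear(Xv)
    n, p = Xv.shape
    if n < p + 2:
        raise AnalysisError("reml_fit: need n >= #fixed effects + 2")
    d, U = np.linalg.eigh(Kv)
    d = np.clip(d, 0.0, None)
    yt = U.T @ yv
    Xt = U.T @ Xv
    _, logdet_xx = np.linalg.slogdet(Xv.T @ Xv)

    def neg_rll(log10_delta: float) -> float:
        delta = 10.0 ** log10_delta
        w = d + delta
        sw = np.sqrt(w)
        Xw = Xt / sw[:, None]
        yw = yt / sw
        beta, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
        resid = yw - Xw @ beta
        rss = float(resid @ resid)
        s2g = rss / (n - p)
        _, logdet_xhx = np.linalg.slogdet(Xw.T @ Xw)
        ll = -0.5 * ((n - p) * (np.log(2 * np.pi * s2g) + 1.0)
                     + np.log(w).sum() + logdet_xhx - logdet_xx)
        return -ll

    res = optimize.minimize_scalar(neg_rll, bounds=(-5.0, 5.0), method="bounded",
                                   options={"xatol": 1e-6})
    candidates = [(-5.0, neg_rll(-5.0)), (5.0, neg_rll(5.0)), (res.x, res.fun)]
    best = min(candidates, key=lambda t: t[1])
    delta = 10.0 ** best[0]
    w = d + delta
    sw = np.sqrt(w)
    Xw = Xt / sw[:, None]
    yw = yt / sw
    beta, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    rss0 = float(((yw - Xw @ beta) ** 2).sum())
    s2g = rss0 / (n - p)
    return MlmModel(individuals=ids or list(range(n)), sigma2_g=s2g,
                    sigma2_e=s2g * delta, delta=delta, loglik=-best[1],
                    U=U, d=d, X=Xv, y=yv, rss0=rss0)


# ---------------------------------------------------------------------------
# Scan


def mlm_scan(model: MlmModel, bands: BandMatrix,
             marker_map: MarkerMap | None = None,
             meta: Mapping[str, object] | None = None) -> pd.DataFrame:
    """Test every band with GLS at the fitted covariance (P3D).

    Missing band entries are mean-imputed per band; bands monomorphic on
    the panel are skipped with a warning. Per band the record carries the
    F-test p, −log10 p, the fraction of generalized residual sum of
    squares explained (r²) and the signed presence-effect estimate.
    """
    data = bands.data.loc[model.individuals]
    sw = np.sqrt(model.weights)
    Xw = (model.U.T @ model.X) / sw[:, None]
    yw = (model.U.T @ model.y) / sw
    n, p = Xw.shape
    rss0 = model.rss0
    df_den = n - p - 1
    if df_den < 1:
        raise AnalysisError("mlm_scan: too few individuals for the band test")
    records = []
    meta = dict(meta or {})
    for band in data.columns:
        col = data[band].to_numpy(float)
        m = np.isnan(col)
        if m.all():
            continue
        if m.any():
            col = np.where(m, np.nanmean(col), col)
        if col.std() == 0:
            continue
        bw = (model.U.T @ col) / sw
        Xa = np.column_stack([Xw, bw])
        beta, _, rank, _ = np.linalg.lstsq(Xa, yw, rcond=None)
        if rank < Xa.shape[1]:
            continue
        resid = yw - Xa @ beta
        rss1 = float(resid @ resid)
        fstat = max(rss0 - rss1, 0.0) / (rss1 / df_den) if rss1 > 0 else np.inf
        pval = float(stats.f.sf(fstat, 1, df_den)) if np.isfinite(fstat) else 0.0
        pval = max(pval, np.finfo(float).tiny)
        rec = dict(meta)
        rec.update({
            "marker": marker_map.band_to_marker.get(band, band) if marker_map else band,
            "band": band,
            "effect": float(beta[-1]),
            "p": pval,
            "neglog10p": float(-np.log10(pval)),
            "r2": float(max(rss0 - rss1, 0.0) / rss0) if rss0 > 0 else np.nan,
            "n": n,
        })
        records.append(rec)
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# The 32 combinations


@dataclasses.dataclass
class Combination:
    """One genotype/phenotype pairing of the L×T association design."""

    id: int
    genotype: str                 # "PS" or a tester id
    variable: str                 # phenotype | GCA | SCA | heterosis
    tester: str | None            # tester attribution for stable-QTL counting
    frames: dict[tuple[str, str], pd.Series]  # (trait, metric) -> phenotype vector

    @property
    def label(self) -> str:
        return f"{self.id}:{self.genotype}x{self.variable}" + (
            f"[{self.tester}]" if self.tester else "")


def build_variables(design: LxTDesign, means: pd.DataFrame,
                    combining: Mapping[str, CombiningAbility],
                    het: pd.DataFrame) -> list[Combination]:
    """Emit the 32 genotype/phenotype combinations.

    Layout (genotype panel × dependent variable):

    * 1–5   maternal-line genotypes × F1 trait phenotype per tester
    * 6–10  F1 genotypes × own trait phenotype per tester
    * 11    maternal lines × own trait phenotype
    * 12    maternal lines × line GCA
    * 13–17 F1 genotypes × maternal-line GCA per tester
    * 18–22 F1 genotypes × cross SCA per tester
    * 23–27 maternal lines × F1 heterosis (5 metrics) per tester
    * 28–32 F1 genotypes × own heterosis (5 metrics) per tester
    """
    traits = [t for t in TRAITS if t in means.columns]
    testers = design.testers
    het_idx = het.set_index(["f1", "trait"]) if not het.empty else None
    combos: list[Combination] = []

    def f1_pheno_on_lines(tester: str, trait: str) -> pd.Series:
        vals = {l: means.at[design.f1_of(l, tester), trait]
                if design.f1_of(l, tester) in means.index else np.nan
                for l in design.lines}
        return pd.Series(vals)

    cid = 1
    for t in testers:  # 1-5
        frames = {(tr, "value"): f1_pheno_on_lines(t, tr) for tr in traits}
        combos.append(Combination(cid, "PS", "phenotype", t, frames))
        cid += 1
    for t in testers:  # 6-10
        f1s = design.f1s_of_tester(t)
        frames = {(tr, "value"): means[tr].reindex(f1s) for tr in traits}
        combos.append(Combination(cid, t, "phenotype", t, frames))
        cid += 1
    # 11: PS x PS
    frames = {(tr, "value"): means[tr].reindex(design.lines) for tr in traits}
    combos.append(Combination(cid, "PS", "phenotype", None, frames))
    cid += 1
    # 12: PS x line GCA
    frames = {(tr, "value"): combining[tr].gca_line.reindex(design.lines)
              for tr in traits if tr in combining}
    combos.append(Combination(cid, "PS", "GCA", None, frames))
    cid += 1
    for t in testers:  # 13-17: F1 genotypes, maternal-line GCA
        f1s = design.f1s_of_tester(t)
        frames = {}
        for tr in traits:
            if tr not in combining:
                continue
            g = combining[tr].gca_line
            frames[(tr, "value")] = pd.Series(
                {f1: g[design.parents_of(f1)[0]] for f1 in f1s})
        combos.append(Combination(cid, t, "GCA", t, frames))
        cid += 1
    for t in testers:  # 18-22: SCA
        f1s = design.f1s_of_tester(t)
        frames = {}
        for tr in traits:
            if tr not in combining:
                continue
            s = combining[tr].sca
            frames[(tr, "value")] = pd.Series(
                {f1: s.at[design.parents_of(f1)[0], t] for f1 in f1s})
        combos.append(Combination(cid, t, "SCA", t, frames))
        cid += 1
    for t in testers:  # 23-27: heterosis on maternal-line genotypes
        frames = {}
        for tr in traits:
            for metric in HETEROSIS_METRICS:
                vals = {}
                for l in design.lines:
                    f1 = design.f1_of(l, t)
                    try:
                        vals[l] = het_idx.at[(f1, tr), metric] if het_idx is not None else np.nan
                    except KeyError:
                        vals[l] = np.nan
                frames[(tr, metric)] = pd.Series(vals)
        combos.append(Combination(cid, "PS", "heterosis", t, frames))
        cid += 1
    for t in testers:  # 28-32: heterosis on F1 genotypes
        f1s = design.f1s_of_tester(t)
        frames = {}
        for tr in traits:
            for metric in HETEROSIS_METRICS:
                vals = {}
                for f1 in f1s:
                    try:
                        vals[f1] = het_idx.at[(f1, tr), metric] if het_idx is not None else np.nan
                    except KeyError:
                        vals[f1] = np.nan
                frames[(tr, metric)] = pd.Series(vals)
        combos.append(Combination(cid, t, "heterosis", t, frames))
        cid += 1
    return combos


# ---------------------------------------------------------------------------
# Orchestration


@dataclasses.dataclass
class AssocConfig:
    """Knobs of the association stage."""

    significance_neglog10: float = 3.0
    q_matrices: dict[str, pd.DataFrame] = dataclasses.field(default_factory=dict)
    use_q: bool = True
    min_panel: int = 10


@dataclasses.dataclass
class AssocContext:
    """Everything downstream stages need to revisit a scan."""

    combinations: list[Combination]
    panels: dict[str, BandMatrix]
    kinships: dict[str, pd.DataFrame]
    records: pd.DataFrame
    counts_by_variable: pd.Series


def _panel_bands(genotype: str, all_bands: BandMatrix, design: LxTDesign) -> BandMatrix:
    ids = design.lines if genotype == "PS" else design.f1s_of_tester(genotype)
    return all_bands.subset(ids)


def run_all(all_bands: BandMatrix, marker_map: MarkerMap, design: LxTDesign,
            means: pd.DataFrame, combining: Mapping[str, CombiningAbility],
            het: pd.DataFrame, config: AssocConfig | None = None) -> AssocContext:
    """Run the full 32-combination Q+K scan.

    Kinship is computed per genotype panel (maternal lines, or each
    tester's F1 family). Q covariates, if provided in
    ``config.q_matrices`` keyed by panel name ("PS" or tester id), enter
    with their last column dropped to avoid intercept collinearity.
    Variance components are re-estimated per phenotype vector and then
    held fixed across bands (P3D).
    """
    config = config or AssocConfig()
    combos = build_variables(design, means, combining, het)
    panel_names = {"PS", *design.testers}
    panels = {name: _panel_bands(name, all_bands, design) for name in panel_names}
    kinships = {name: kinship(bm) for name, bm in panels.items()}

    all_records = []
    for combo in combos:
        bm = panels[combo.genotype]
        Kp = kinships[combo.genotype]
        Q = config.q_matrices.get(combo.genotype) if config.use_q else None
        for (trait, metric), series in combo.frames.items():
            s = series.dropna()
            s = s[np.isfinite(s.to_numpy(float))]
            if len(s) < config.min_panel:
                log.warning("run_all: combination %s %s/%s has %d usable values, skipped",
                            combo.label, trait, metric, len(s))
                continue
            if s.std() == 0:
                log.warning("run_all: constant phenotype for %s %s/%s, skipped",
                            combo.label, trait, metric)
                continue
            ids = list(s.index)
            sub = bm.subset(ids)
            Ksub = Kp.loc[ids, ids]
            X = [np.ones(len(ids))]
            if Q is not None:
                qs = Q.loc[ids].to_numpy(float)
                if qs.shape[1] > 1:
                    X.append(qs[:, :-1])
            Xmat = np.column_stack(X)
            try:
                model = reml_fit(s, Xmat, Ksub)
            except AnalysisError as exc:
                log.warning("run_all: %s %s/%s: %s", combo.label, trait, metric, exc)
                continue
            variable = metric if combo.variable == "heterosis" else combo.variable
            recs = mlm_scan(model, sub, marker_map, meta={
                "combination": combo.id, "genotype": combo.genotype,
                "variable": variable, "variable_class": combo.variable,
                "metric": metric, "trait": trait, "tester": combo.tester,
            })
            if not recs.empty:
                all_records.append(recs)
    records = (pd.concat(all_records, ignore_index=True)
               if all_records else pd.DataFrame())
    if not records.empty:
        sig = records[records["neglog10p"] > config.significance_neglog10]
        counts = sig.groupby("variable_class").size()
    else:
        counts = pd.Series(dtype=int)
    return AssocContext(combinations=combos, panels=panels, kinships=kinships,
                        records=records, counts_by_variable=counts)
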