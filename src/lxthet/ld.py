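"""Pairwise linkage disequilibrium among multi-band SSR loci.

Band presence is treated as a haploid two-state locus (individuals as
gametes): for bands A and B with presence frequencies ``pA``, ``pB`` and
joint presence ``pAB``,

    D  = pAB − pA·pB
    r² = D² / (pA·(1−pA)·pB·(1−pB))
    D′ = |D| / Dmax

Locus-level r² and D′ are weighted averages over the locus pair's band
pairs, weighted by the product of marginal band frequencies (normalised) —
the common multi-allelic convention. Significance comes from a permutation
test shuffling one locus's individual labels; rare bands (presence
frequency < 0.05) can be masked to missing first; background LD is the
99th percentile of unlinked-pair r²; decay is a least-squares fit of
r² on ln(distance), with the decay distance solving a + b·ln(d) = r²
threshold (0.2 by default).
"""

from __future__ import annotations

import dataclasses
import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError
from .io import BandMatrix, MarkerMap

log = logging.getLogger(__name__)


def mask_rare(bands: BandMatrix, threshold: float = 0.05) -> BandMatrix:
    """Set the presences of rare bands (frequency strictly below
    ``threshold`` among non-missing entries) to missing."""
    data = bands.data.copy()
    freq = np.nanmean(data.to_numpy(), axis=0)
    for j, f in enumerate(freq):
        if np.isfinite(f) and f < threshold:
            col = data.columns[j]
            data.loc[data[col] == 1.0, col] = np.nan
    return BandMatrix(data)


def band_ld(a: np.ndarray, b: np.ndarray) -> tuple[float, float] | None:
    """(r², D′) for one band pair on complete cases; None when fewer than
    4 complete observations or either band is monomorphic there."""
    m = ~(np.isnan(a) | np.isnan(b))
    if m.sum() < 4:
        return None
    a, b = a[m], b[m]
    pA, pB = a.mean(), b.mean()
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        return None
    pAB = (a * b).mean()
    D = pAB - pA * pB
    r2 = D * D / (pA * (1 - pA) * pB * (1 - pB))
    if D >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    dprime = abs(D) / dmax if dmax > 0 else np.nan
    return float(r2), float(dprime)


def _locus_ld(A: np.ndarray, B: np.ndarray) -> tuple[float, float] | None:
    """Weighted locus-level (r², D′) over polymorphic band pairs."""
    vals, weights = [], []
    for i in range(A.shape[1]):
        for j in range(B.shape[1]):
            res = band_ld(A[:, i], B[:, j])
            if res is None:
                continue
            w = np.nanmean(A[:, i]) * np.nanmean(B[:, j])
            vals.append(res)
            weights.append(w)
    if not vals:
        return None
    w = np.asarray(weights)
    w = w / w.sum()
    r2 = float(np.dot(w, [v[0] for v in vals]))
    dp = float(np.dot(w, [v[1] for v in vals]))
    return r2, dp


def pairwise_ld(bands: BandMatrix, marker_map: MarkerMap, *, shuffles: int = 1000,
                seed: int = 0) -> pd.DataFrame:
    """All locus-pair LD with permutation p-values.

    Per pair, the permutation test shuffles the second locus's individual
    labels (bands moving together) ``shuffles`` times on the pair's
    complete-case submatrix; p = (1 + #{r²_perm > r²_obs} + ½·#{ties})
    / (shuffles+1). Ties are counted half (mid-p) because band data make
    the permutation distribution of r² heavily discrete; the conservative
    all-ties count would bias the null p away from uniform. Pairs on the
    same chromosome are flagged linked and carry their physical distance
    in bp.
    """
    bands.validate_against(marker_map)
    markers = [m for m in marker_map.markers
               if any(b in bands.data.columns for b in marker_map.table.at[m, "bands"])]
    if len(markers) < 2:
        raise AnalysisError("pairwise_ld: need >= 2 loci")
    cols = {m: [b for b in marker_map.table.at[m, "bands"] if b in bands.data.columns]
            for m in markers}
    rng = np.random.default_rng(seed)
    X = bands.data
    rows = []
    for ma, mb in itertools.combinations(markers, 2):
        A_full = X[cols[ma]].to_numpy(float)
        B_full = X[cols[mb]].to_numpy(float)
        complete = ~(np.isnan(A_full).any(axis=1) | np.isnan(B_full).any(axis=1))
        if complete.sum() < 4:
            log.warning("pairwise_ld: <4 complete observations for %s/%s, skipped", ma, mb)
            continue
        A, B = A_full[complete], B_full[complete]
        obs = _locus_ld(A, B)
        if obs is None:
            log.warning("pairwise_ld: monomorphic locus pair %s/%s skipped", ma, mb)
            continue
        r2_obs, dp_obs = obs
        n = A.shape[0]
        if shuffles > 0:
            perm_r2 = _permuted_locus_r2(A, B, shuffles, rng)
            gt = int((perm_r2 > r2_obs + 1e-12).sum())
            ties = int((np.abs(perm_r2 - r2_obs) <= 1e-12).sum())
            p = (1 + gt + 0.5 * ties) / (shuffles + 1)
        else:
            p = np.nan
        ca, cb = marker_map.chrom_of(ma), marker_map.chrom_of(mb)
        rows.append({
            "locusA": ma, "locusB": mb, "chromA": ca, "chromB": cb,
            "distance_bp": marker_map.distance_bp(ma, mb),
            "r2": r2_obs, "Dprime": dp_obs, "p_perm": p, "linked": ca == cb,
            "n": n,
        })
    return pd.DataFrame(rows)


def _permuted_locus_r2(A: np.ndarray, B: np.ndarray, shuffles: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Locus-level r² under `shuffles` row permutations of B.

    Marginal band frequencies (hence weights and denominators) are
    permutation-invariant; only joint frequencies pAB change, so each band
    pair reduces to a matrix product over the permutation index matrix.
    """
    n = A.shape[0]
    idx = np.argsort(rng.random((shuffles, n)), axis=1)
    out = np.zeros(shuffles)
    wsum = 0.0
    for i in range(A.shape[1]):
        a = A[:, i]
        pA = a.mean()
        if pA in (0.0, 1.0):
            continue
        for j in range(B.shape[1]):
            b = B[:, j]
            pB = b.mean()
            if pB in (0.0, 1.0):
                continue
            w = pA * pB
            pAB = (b[idx] @ a) / n  # (shuffles,)
            D = pAB - pA * pB
            r2 = D * D / (pA * (1 - pA) * pB * (1 - pB))
            out += w * r2
            wsum += w
    return out / wsum if wsum > 0 else out


def background_ld(pairs: pd.DataFrame) -> float:
    """99th percentile (linear interpolation) of r² over unlinked pairs."""
    unl = pairs.loc[~pairs["linked"].astype(bool), "r2"].dropna()
    if unl.empty:
        raise AnalysisError("background_ld: no unlinked pairs")
    return float(np.percentile(unl.to_numpy(), 99))


@dataclasses.dataclass
class LDDecayFit:
    intercept: float
    slope: float
    threshold: float
    decay_distance: float  # in the unit the distances were given in
    n_pairs: int
    background: float | None = None


def decay_fit_xy(distances: np.ndarray, r2: np.ndarray, *, threshold: float = 0.2,
                 zero_distance: float = 1e-7) -> LDDecayFit:
    """Least-squares fit of r² = a + b·ln(distance) and the distance where
    the fitted curve crosses ``threshold``.

    Zero distances are replaced by ``zero_distance`` before the log
    transform. A non-negative slope leaves the decay distance NaN with a
    warning. Units of the decay distance follow the input distances.
    """
    d = np.asarray(distances, float).copy()
    y = np.asarray(r2, float)
    if len(d) < 3 or len(np.unique(d)) < 3:
        raise AnalysisError("decay_fit: need >= 3 pairs at distinct distances")
    d[d == 0.0] = zero_distance
    res = stats.linregress(np.log(d), y)
    a, b = float(res.intercept), float(res.slope)
    if b >= 0:
        log.warning("decay_fit: non-negative slope, decay distance undefined")
        decay = float("nan")
    else:
        decay = float(np.exp((threshold - a) / b))
    return LDDecayFit(intercept=a, slope=b, threshold=threshold,
                      decay_distance=decay, n_pairs=len(d))


def decay_fit(pairs: pd.DataFrame, *, threshold: float = 0.2, p_max: float = 0.001,
              unit_bp: float = 1000.0) -> LDDecayFit:
    """Decay fit on linked, permutation-significant pairs.

    ``unit_bp`` converts bp distances before fitting (default kb, so the
    decay distance is reported in kb).
    """
    sel = pairs[pairs["linked"].astype(bool) & (pairs["p_perm"] < p_max)
                & pairs["distance_bp"].notna()]
    if len(sel) < 3:
        raise AnalysisError(
            f"decay_fit: only {len(sel)} linked pairs with p < {p_max}")
    return decay_fit_xy(sel["distance_bp"].to_numpy() / unit_bp,
                        sel["r2"].to_numpy(), threshold=threshold)
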