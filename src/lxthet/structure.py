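"""Admixture-model Bayesian clustering of binary band data.

A Gibbs sampler over the classic admixture model: each individual ``i``
has membership proportions ``q_i ~ Dirichlet(alpha)``; each band
observation draws a cluster of origin ``z_il ~ Cat(q_i)`` and then a
presence/absence from that cluster's band frequency ``p_kl``. Band rows
are treated as haploid observations (one allele draw per individual per
band), matching the single-row 0/1 coding of dominant PAGE fragments —
a diploid dominant-genotype likelihood is not reconstructible from that
encoding.

Cluster frequencies carry a correlated-frequency prior: Beta centred on
the empirical ancestral frequency with drift parameter ``F`` (default
0.05). The data log-probability estimator is mean(ln L) − ½·var(ln L) of
the post-burn-in log-likelihood samples — the quantity the Evanno ΔK
statistic consumes. Default chain lengths are 100,000 burn-in plus
100,000 retained sweeps; pass shorter values for desk-scale work.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AnalysisError
from .io import BandMatrix

log = logging.getLogger(__name__)


@dataclasses.dataclass
class StructureRun:
    K: int
    seed: int
    burnin: int
    reps: int
    lnpd: float
    q: pd.DataFrame  # individuals x K


def admixture_mcmc(bands: BandMatrix, K: int, *, burnin: int = 100_000,
                   reps: int = 100_000, seed: int = 0, alpha: float = 1.0,
                   drift: float = 0.05) -> StructureRun:
    """Run the Gibbs sampler and return posterior-mean Q and LnP(D).

    Deterministic under ``seed``. All-missing band columns are dropped
    with a warning; ``K`` larger than the number of individuals is an
    error.
    """
    X = bands.data.to_numpy(float)
    n = X.shape[0]
    if K < 1:
        raise AnalysisError("admixture_mcmc: K must be >= 1")
    if K > n:
        raise AnalysisError(f"admixture_mcmc: K={K} exceeds {n} individuals")
    obs = ~np.isnan(X)
    keep = obs.any(axis=0)
    if not keep.all():
        log.warning("admixture_mcmc: dropping %d all-missing band column(s)",
                    (~keep).sum())
        X, obs = X[:, keep], obs[:, keep]
    poly = np.nanstd(X, axis=0) > 0
    if poly.sum() < 2:
        raise AnalysisError("admixture_mcmc: need >= 2 polymorphic band columns")
    L = X.shape[1]
    x1 = (X == 1.0)

    rng = np.random.default_rng(seed)
    pA = np.clip(np.nanmean(X, axis=0), 0.01, 0.99)
    ba = pA * (1 - drift) / drift
    bb = (1 - pA) * (1 - drift) / drift

    P = rng.beta(ba[:, None], bb[:, None], size=(L, K))
    q = np.full((n, K), 1.0 / K)

    qsum = np.zeros((n, K))
    lls: list[float] = []
    for it in range(burnin + reps):
        like = np.where(x1[:, :, None], P[None, :, :], 1.0 - P[None, :, :])
        like[~obs] = 1.0
        w = q[:, None, :] * like
        wsum = w.sum(axis=2, keepdims=True)
        u = rng.random((n, L, 1)) * wsum
        z = (np.cumsum(w, axis=2) < u).sum(axis=2)  # (n, L)

        counts = np.empty((n, K))
        for k in range(K):
            mk = (z == k) & obs
            n1 = (mk & x1).sum(axis=0)
            n0 = (mk & ~x1).sum(axis=0)
            P[:, k] = rng.beta(ba + n1, bb + n0)
            counts[:, k] = mk.sum(axis=1)
        g = rng.standard_gamma(alpha + counts)
        q = g / g.sum(axis=1, keepdims=True)

        if it >= burnin:
            lls.append(float(np.log(np.maximum(wsum[:, :, 0], 1e-300)).sum()))
            qsum += q

    ll = np.asarray(lls)
    var = ll.var(ddof=1) if len(ll) > 1 else 0.0
    lnpd = float(ll.mean() - 0.5 * var)
    Q = qsum / len(ll)
    Q = Q / Q.sum(axis=1, keepdims=True)
    qdf = pd.DataFrame(Q, index=bands.individuals,
                       columns=[f"Q{k + 1}" for k in range(K)])
    return StructureRun(K=K, seed=seed, burnin=burnin, reps=reps, lnpd=lnpd, q=qdf)


@dataclasses.dataclass
class EvannoResult:
    table: pd.DataFrame  # per K: mean_lnpd, sd_lnpd, lprime, lsecond, delta_k
    selected_k: int
    fallback: bool = False


def evanno(runs: Mapping[int, Sequence[StructureRun]]) -> EvannoResult:
    """Evanno ΔK model selection over replicate runs per K.

    ΔK(K) = mean over paired runs of |LnPD(K+1) − 2·LnPD(K) + LnPD(K−1)|
    divided by the SD of LnPD at K. Defined for interior K with SD > 0;
    the selected K is the argmax of ΔK. If no ΔK is defined (e.g. LnPD
    exactly linear in K) the smallest K is returned as a logged fallback.
    """
    ks = sorted(runs)
    if len(ks) < 3 or any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise AnalysisError("evanno: need >= 3 consecutive K values")
    nruns = min(len(runs[k]) for k in ks)
    if nruns < 2:
        raise AnalysisError("evanno: need >= 2 runs per K")
    lnpd = np.array([[runs[k][j].lnpd for k in ks] for j in range(nruns)])  # runs x K
    mean = lnpd.mean(axis=0)
    sd = lnpd.std(axis=0, ddof=1)
    lprime = np.full(len(ks), np.nan)
    lprime[1:] = mean[1:] - mean[:-1]
    lsecond = np.full(len(ks), np.nan)
    delta = np.full(len(ks), np.nan)
    for idx in range(1, len(ks) - 1):
        sec = np.abs(lnpd[:, idx + 1] - 2 * lnpd[:, idx] + lnpd[:, idx - 1]).mean()
        lsecond[idx] = sec
        if sd[idx] > 0:
            delta[idx] = sec / sd[idx]
        else:
            log.warning("evanno: SD=0 at K=%d, delta-K undefined there", ks[idx])
    table = pd.DataFrame({"K": ks, "mean_lnpd": mean, "sd_lnpd": sd,
                          "lprime": lprime, "lsecond": lsecond, "delta_k": delta})
    finite = np.isfinite(delta) & (delta > 0)
    if finite.any():
        return EvannoResult(table=table, selected_k=int(ks[int(np.nanargmax(delta))]))
    log.warning("evanno: no delta-K peak; falling back to smallest K")
    return EvannoResult(table=table, selected_k=ks[0], fallback=True)


def assign_subpops(q: pd.DataFrame, threshold: float = 0.5) -> pd.Series:
    """Assign each individual to its argmax cluster if membership exceeds
    the threshold (strictly), else label it ``admixed``."""
    arr = q.to_numpy(float)
    best = arr.argmax(axis=1)
    labels = [q.columns[b] if arr[i, b] > threshold else "admixed"
              for i, b in enumerate(best)]
    return pd.Series(labels, index=q.index, name="subpop")
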