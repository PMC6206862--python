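"""Synthetic Line × Tester populations with known genetic architecture.

The generator emulates the study system this package targets: a panel of
inbred upland-cotton lines crossed to a handful of elite testers, genotyped
with multi-band dominant SSR markers spread over 26 chromosomes, and
phenotyped for ten yield/fiber traits in replicated RCBD trials across
location × year environments. Latent subpopulation structure follows a
correlated-allele-frequency model; traits are controlled by a configurable
mix of additive (``a``) and dominance (``d``) QTL placed on named markers.

Because every downstream stage (combining ability, heterosis, structure,
LD, Q+K association, stable-QTL calling, allele mining) is exercised
against this ground truth, the generator is first-class tested code, not a
fixture.

Genetic-value coding (dominant band markers; parents are inbred):

* a parent carrying the causal band contributes ``2a``; a non-carrier 0;
* an F1 whose parents both carry contributes ``2a``; exactly one parent
  carrying gives ``a + d`` (the band is heterozygous); neither gives 0.

This is the minimal coding under which mid-parent heterosis responds to
``d`` and general combining ability to ``a``.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, SchemaError
from .io import BandMatrix, LxTDesign, MarkerMap, validate_phenotypes
from .traits import TRAITS

#: Trait grand means in trait units, on the scale typical of a Chinese
#: upland-cotton multi-environment trial.
DEFAULT_TRAIT_MEANS: dict[str, float] = {
    "PH": 95.0, "BW": 5.1, "LP": 35.7, "BN": 18.9, "FL": 29.9,
    "FS": 29.5, "MIC": 4.8, "FU": 85.7, "FE": 6.8, "FUI": 143.8,
}

#: Residual (plot-level) SDs per trait, of the order of the within-
#: environment spread seen in such trials.
DEFAULT_RESID_SD: dict[str, float] = {
    "PH": 10.0, "BW": 0.6, "LP": 3.0, "BN": 5.5, "FL": 1.8,
    "FS": 2.5, "MIC": 0.55, "FU": 1.4, "FE": 0.28, "FUI": 15.0,
}


@dataclasses.dataclass
class QTL:
    """A causal band: marker index, affected trait, additive and dominance
    effects in trait units. ``band`` selects which band of the marker is
    causal (default the first)."""

    marker: int
    trait: str
    a: float
    d: float
    band: int = 0


@dataclasses.dataclass
class SimConfig:
    """Configuration of the synthetic L×T study.

    Defaults reproduce the study conditions this package is built around:
    284 lines × 5 testers, 203 multi-band SSRs over 26 chromosomes
    (≈7.6 markers/chromosome), three latent subpopulations, and an RCBD
    with 3 replications in 2 locations × 2 years.
    """

    n_lines: int = 284
    n_testers: int = 5
    n_markers: int = 203
    bands_per_marker: tuple[int, int] = (2, 6)
    n_chromosomes: int = 26
    chrom_length_bp: int = 100_000_000
    n_subpops: int = 3
    admixture_alpha: float = 0.5
    membership_weight: float = 5.0
    drift: float = 0.15
    qtl_spec: list[QTL] = dataclasses.field(default_factory=list)
    locations: int = 2
    years: int = 2
    replicates: int = 3
    env_sd_frac: float = 1.0
    block_sd_frac: float = 0.25
    polygenic_sd_frac: float = 1.0
    trait_means: dict[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_TRAIT_MEANS))
    resid_sd: dict[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_RESID_SD))
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> "SimConfig":
        if self.n_lines < 1:
            raise ConfigError("n_lines: must be >= 1")
        if self.n_testers < 1:
            raise ConfigError("n_testers: must be >= 1")
        if self.n_markers < 1:
            raise ConfigError("n_markers: must be >= 1")
        lo, hi = self.bands_per_marker
        if not (1 <= lo <= hi):
            raise ConfigError("bands_per_marker: need 1 <= lo <= hi")
        if not (1 <= self.n_chromosomes <= 26):
            raise ConfigError("n_chromosomes: must be in [1, 26]")
        if self.n_subpops < 1:
            raise ConfigError("n_subpops: must be >= 1")
        if self.admixture_alpha <= 0:
            raise ConfigError("admixture_alpha: must be positive")
        if not (0 < self.drift < 1):
            raise ConfigError("drift: must be in (0, 1)")
        for q in self.qtl_spec:
            if not (0 <= q.marker < self.n_markers):
                raise ConfigError(f"qtl_spec: marker index {q.marker} >= n_markers")
            if q.trait not in TRAITS:
                raise ConfigError(f"qtl_spec: unknown trait {q.trait!r}")
        if self.replicates < 2:
            raise ConfigError("replicates: RCBD stages require >= 2")
        if min(self.locations, self.years) < 1:
            raise ConfigError("locations/years: must be >= 1")
        for name in ("env_sd_frac", "block_sd_frac", "polygenic_sd_frac",
                     "missing_rate"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name}: must be >= 0")
        for t in TRAITS:
            if t not in self.trait_means:
                raise ConfigError(f"trait_means: missing trait {t}")
            if t not in self.resid_sd or self.resid_sd[t] < 0:
                raise ConfigError(f"resid_sd: missing or negative for trait {t}")
        return self


def demo_config(seed: int = 0, **overrides) -> SimConfig:
    """A desk-scale preset: 60 lines × 5 testers, 30 SSRs on 26 chromosomes,
    3 subpopulations, 2 locations × 1 year × 3 replicates. Used by the
    examples and the acceptance script; the full-scale defaults live on
    :class:`SimConfig` itself."""
    base = dict(
        n_lines=60, n_testers=5, n_markers=30, bands_per_marker=(2, 4),
        locations=2, years=1, replicates=3, seed=seed,
    )
    base.update(overrides)
    return SimConfig(**base).validate()


@dataclasses.dataclass
class TruthSet:
    """Ground truth of a simulated study."""

    marker_map: MarkerMap
    line_bands: BandMatrix
    tester_bands: BandMatrix
    f1_bands: BandMatrix
    check_bands: BandMatrix
    subpop_labels: pd.Series  # per line
    qtl_spec: list[QTL]
    config: SimConfig

    def causal_band_id(self, qtl: QTL) -> str:
        marker = self.marker_map.markers[qtl.marker]
        return self.marker_map.table.at[marker, "bands"][qtl.band]

    def all_bands(self) -> BandMatrix:
        return self.line_bands.concat(self.tester_bands).concat(
            self.f1_bands).concat(self.check_bands)


# ---------------------------------------------------------------------------


def _marker_map(config: SimConfig, rng: np.random.Generator) -> MarkerMap:
    n = config.n_markers
    chroms = (np.arange(n) % config.n_chromosomes) + 1
    pos = rng.integers(1, config.chrom_length_bp + 1, size=n)
    lo, hi = config.bands_per_marker
    nbands = rng.integers(lo, hi + 1, size=n)
    rows = []
    for i in range(n):
        name = f"M{i + 1:03d}"
        bands = tuple(f"{name}-{b + 1}" for b in range(nbands[i]))
        rows.append((name, int(chroms[i]), int(pos[i]), bands))
    return MarkerMap(pd.DataFrame(rows, columns=["marker", "chrom", "pos_bp", "bands"]))


def simulate_parents(config: SimConfig):
    """Simulate the marker map, line and tester band matrices, and latent
    subpopulation labels.

    Band frequencies follow a correlated-frequency model: each band has an
    ancestral frequency ``p0 ~ U(0.1, 0.9)``; subpopulation frequencies are
    Beta-distributed around ``p0`` with drift parameter ``config.drift``.
    Each line has admixture proportions drawn from a Dirichlet concentrated
    on its home subpopulation; its band-presence probability mixes the
    subpopulation frequencies accordingly. Bands are independent dominant
    markers — presence of at least one band per marker is not enforced.

    Returns ``(marker_map, line_bands, tester_bands, labels)``.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_map, rng_freq, rng_geno = [np.random.default_rng(c) for c in ss.spawn(3)]

    marker_map = _marker_map(config, rng_map)
    band_ids = marker_map.band_order
    L = len(band_ids)
    K = config.n_subpops

    p0 = rng_freq.uniform(0.1, 0.9, size=L)
    F = config.drift
    if K == 1:
        pk = p0[None, :]
    else:
        a = p0 * (1 - F) / F
        b = (1 - p0) * (1 - F) / F
        pk = rng_freq.beta(a[None, :], b[None, :], size=(K, L))

    labels = np.arange(config.n_lines) % K
    conc = np.full((config.n_lines, K), config.admixture_alpha)
    conc[np.arange(config.n_lines), labels] += config.membership_weight
    g = rng_geno.standard_gamma(conc)
    q = g / g.sum(axis=1, keepdims=True)
    probs = q @ pk
    line_mat = (rng_geno.random((config.n_lines, L)) < probs).astype(float)

    tester_probs = np.broadcast_to(p0, (config.n_testers, L))
    tester_mat = (rng_geno.random((config.n_testers, L)) < tester_probs).astype(float)

    line_ids = [f"L{i + 1:03d}" for i in range(config.n_lines)]
    tester_ids = [f"T{chr(ord('A') + j)}" for j in range(config.n_testers)]
    lines = BandMatrix(pd.DataFrame(line_mat, index=line_ids, columns=band_ids))
    testers = BandMatrix(pd.DataFrame(tester_mat, index=tester_ids, columns=band_ids))
    lab = pd.Series(labels, index=line_ids, name="subpop")
    return marker_map, lines, testers, lab


def make_f1_bands(line_row: pd.Series, tester_row: pd.Series) -> pd.Series:
    """Dominant-band inheritance: F1 band present iff present in either
    parent; missing only when both parents are missing."""
    if list(line_row.index) != list(tester_row.index):
        raise SchemaError("make_f1_bands: parent band columns differ")
    a, b = line_row.to_numpy(float), tester_row.to_numpy(float)
    out = np.where((a == 1) | (b == 1), 1.0,
                   np.where(np.isnan(a) & np.isnan(b), np.nan, 0.0))
    return pd.Series(out, index=line_row.index)


def build_design(lines: Sequence[str], testers: Sequence[str]) -> LxTDesign:
    """Full factorial L×T cross map with K3/K4 check ids."""
    rows = [(l, t, f"F_{l}_{t}") for l in lines for t in testers]
    crosses = pd.DataFrame(rows, columns=["line", "tester", "f1"])
    return LxTDesign(lines=list(lines), testers=list(testers), crosses=crosses,
                     checks={"K3": "CHK3", "K4": "CHK4"})


def _f1_matrix(lines: BandMatrix, testers: BandMatrix, design: LxTDesign) -> BandMatrix:
    a = lines.data.to_numpy(float)
    b = testers.data.to_numpy(float)
    li = {l: i for i, l in enumerate(lines.individuals)}
    ti = {t: i for i, t in enumerate(testers.individuals)}
    rows, ids = [], []
    for r in design.crosses.itertuples(index=False):
        x, y = a[li[r.line]], b[ti[r.tester]]
        rows.append(np.where((x == 1) | (y == 1), 1.0,
                             np.where(np.isnan(x) & np.isnan(y), np.nan, 0.0)))
        ids.append(r.f1)
    return BandMatrix(pd.DataFrame(np.asarray(rows), index=ids, columns=lines.bands))


def _genetic_values(truth: TruthSet, design: LxTDesign) -> dict[str, dict[str, float]]:
    """Per-individual, per-trait genetic value under the a/d band coding."""
    gv: dict[str, dict[str, float]] = {}
    ind_sets = {
        **{i: ("parent", i) for i in truth.line_bands.individuals},
        **{i: ("parent", i) for i in truth.tester_bands.individuals},
        **{i: ("parent", i) for i in truth.check_bands.individuals},
    }
    all_parent = pd.concat([truth.line_bands.data, truth.tester_bands.data,
                            truth.check_bands.data])

    def add(ind: str, trait: str, val: float) -> None:
        gv.setdefault(ind, {t: 0.0 for t in TRAITS})
        gv[ind][trait] += val

    for q in truth.qtl_spec:
        band = truth.causal_band_id(q)
        carrier = all_parent[band]
        for ind in ind_sets:
            c = carrier.get(ind, 0.0)
            add(ind, q.trait, 2.0 * q.a if c == 1.0 else 0.0)
        for r in design.crosses.itertuples(index=False):
            cl = truth.line_bands.data.at[r.line, band]
            ct = truth.tester_bands.data.at[r.tester, band]
            n_carrier = int(cl == 1.0) + int(ct == 1.0)
            if n_carrier == 2:
                val = 2.0 * q.a
            elif n_carrier == 1:
                val = q.a + q.d
            else:
                val = 0.0
            add(r.f1, q.trait, val)
    # individuals untouched by any QTL still need an entry
    for ind in list(ind_sets) + design.f1s:
        gv.setdefault(ind, {t: 0.0 for t in TRAITS})
    return gv


def _add_polygenic_background(gv: dict, truth: TruthSet, design: LxTDesign,
                              config: SimConfig, rng: np.random.Generator) -> None:
    """Additive polygenic background: every parent (and check) draws an
    independent genetic value N(0, polygenic_sd_frac · resid_sd) per trait
    and an F1 inherits the parental average. Keeps every trait heritable
    even without explicit QTL; contributes no heterosis (F1 = mid-parent)."""
    if config.polygenic_sd_frac == 0:
        return
    parents = (truth.line_bands.individuals + truth.tester_bands.individuals
               + truth.check_bands.individuals)
    for trait in TRAITS:
        sd = config.resid_sd[trait] * config.polygenic_sd_frac
        if sd == 0:
            continue
        vals = dict(zip(parents, rng.normal(0.0, sd, size=len(parents))))
        for ind, v in vals.items():
            gv[ind][trait] += v
        for r in design.crosses.itertuples(index=False):
            gv[r.f1][trait] += 0.5 * (vals[r.line] + vals[r.tester])


def simulate_phenotypes(truth: TruthSet, design: LxTDesign,
                        config: SimConfig) -> pd.DataFrame:
    """RCBD phenotypes: value = μ_trait + genetic value + environment
    (location × year) effect + block effect + residual.

    The genetic value combines the configured QTL (a/d coding above) with
    an additive polygenic background so every trait is heritable.
    Environment effects are drawn once per (location, year) and shared by
    all genotypes, matching RCBD assumptions; blocks are nested in
    environments. Checks are grown in every environment.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss.spawn(5)[4])
    rng_poly = np.random.default_rng(ss.spawn(7)[6])
    gv = _genetic_values(truth, design)
    _add_polygenic_background(gv, truth, design, config, rng_poly)
    individuals = (truth.line_bands.individuals + truth.tester_bands.individuals
                   + design.f1s + truth.check_bands.individuals)
    envs = [(f"LOC{l + 1}", 2012 + y)
            for l in range(config.locations) for y in range(config.years)]
    n_ind = len(individuals)
    records = []
    for trait in TRAITS:
        mu = config.trait_means[trait]
        sd = config.resid_sd[trait]
        env_sd = sd * config.env_sd_frac
        block_sd = sd * config.block_sd_frac
        g = np.array([gv[i][trait] for i in individuals])
        for loc, year in envs:
            e = rng.normal(0.0, env_sd) if env_sd > 0 else 0.0
            for rep in range(1, config.replicates + 1):
                b = rng.normal(0.0, block_sd) if block_sd > 0 else 0.0
                resid = rng.normal(0.0, sd, size=n_ind) if sd > 0 else np.zeros(n_ind)
                vals = mu + g + e + b + resid
                records.append(pd.DataFrame({
                    "individual": individuals, "trait": trait, "location": loc,
                    "year": year, "replicate": rep, "value": vals,
                }))
    return validate_phenotypes(pd.concat(records, ignore_index=True))


def simulate_dataset(config: SimConfig):
    """One-call generator: returns ``(truth, design, phenotypes)``.

    Checks K3/K4 are two fixed genotypes drawn from the ancestral band
    frequencies, grown in every environment so standard heterosis has
    per-environment check means.
    """
    config.validate()
    marker_map, lines, testers, labels = simulate_parents(config)
    design = build_design(lines.individuals, testers.individuals)
    f1 = _f1_matrix(lines, testers, design)

    ss = np.random.SeedSequence(config.seed)
    rng_chk = np.random.default_rng(ss.spawn(4)[3])
    freq = np.nanmean(lines.data.to_numpy(), axis=0)
    chk = (rng_chk.random((2, len(lines.bands))) < freq).astype(float)
    checks = BandMatrix(pd.DataFrame(chk, index=["CHK3", "CHK4"], columns=lines.bands))

    truth = TruthSet(marker_map=marker_map, line_bands=lines, tester_bands=testers,
                     f1_bands=f1, check_bands=checks, subpop_labels=labels,
                     qtl_spec=list(config.qtl_spec), config=config)

    if config.missing_rate > 0:
        rng_miss = np.random.default_rng(ss.spawn(6)[5])
        for bm in (truth.line_bands, truth.tester_bands, truth.f1_bands):
            mask = rng_miss.random(bm.data.shape) < config.missing_rate
            bm.data.values[mask] = np.nan

    pheno = simulate_phenotypes(truth, design, config)
    return truth, design, pheno
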