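"""End-to-end orchestration: simulate/load → analyze → report.

Stages run in dependency order (phenotype statistics → combining ability
and heterosis → population structure → LD → association → stable QTLs and
favorable alleles), each persisting its tables into a result bundle
directory, with a manifest recording the config hash, seeds and per-stage
row counts. All randomness flows from named per-stage seeds derived from
one master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc, ld, lxt, pheno, qtl, simulate, structure
from .errors import ConfigError, LxthetError
from .io import (BandMatrix, LxTDesign, MarkerMap, read_band_matrix, read_design,
                 read_marker_map, read_phenotypes, write_band_matrix,
                 write_design, write_marker_map, write_phenotypes)
from .traits import TRAITS

log = logging.getLogger(__name__)

STAGES = ("phenostats", "lxt_heterosis", "popstructure", "ld", "association",
          "qtl_alleles")


@dataclasses.dataclass
class PipelineConfig:
    """Configuration for a full pipeline run.

    Either ``sim`` is set (a :class:`~lxthet.simulate.SimConfig`) or the
    four input paths are. Thresholds default to the study constants:
    significance −log10 p > 3, rare-band frequency 0.05, LD decay r² 0.2,
    Q-assignment 0.5, stable-QTL tester minimum 3.
    """

    sim: simulate.SimConfig | None = None
    band_matrix_path: str | None = None
    band_matrix_dialect: str = "structure"
    marker_map_path: str | None = None
    phenotype_path: str | None = None
    design_path: str | None = None

    stages: dict[str, bool] = dataclasses.field(
        default_factory=lambda: {s: True for s in STAGES})
    significance_neglog10: float = 3.0
    rare_threshold: float = 0.05
    ld_decay_threshold: float = 0.2
    ld_p_max: float = 0.001
    ld_shuffles: int = 1000
    q_threshold: float = 0.5
    min_testers: int = 3
    stable_variables: str = "all"    # "all" or "core"
    entry_mean_mode: str = "shrunk"

    structure_kmin: int = 1
    structure_kmax: int = 4
    structure_runs: int = 2
    structure_burnin: int = 300
    structure_reps: int = 500
    structure_panels: tuple[str, ...] = ("PS",)

    seed: int = 0
    outdir: str = "lxthet_results"

    def validate(self) -> "PipelineConfig":
        if self.sim is None and not all([self.band_matrix_path, self.marker_map_path,
                                         self.phenotype_path, self.design_path]):
            raise ConfigError("pipeline: need either sim config or all four input paths")
        for name, val, lo, hi in [
            ("significance_neglog10", self.significance_neglog10, 0, np.inf),
            ("rare_threshold", self.rare_threshold, 0, 1),
            ("ld_decay_threshold", self.ld_decay_threshold, 0, 1),
            ("q_threshold", self.q_threshold, 0, 1),
            ("min_testers", self.min_testers, 1, np.inf),
        ]:
            if not (lo <= val <= hi):
                raise ConfigError(f"pipeline: {name}={val} outside [{lo}, {hi}]")
        if self.stable_variables not in ("all", "core"):
            raise ConfigError("pipeline: stable_variables must be 'all' or 'core'")
        return self

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        if self.sim is not None:
            d["sim"]["qtl_spec"] = [dataclasses.asdict(q) for q in self.sim.qtl_spec]
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        sim = d.pop("sim", None)
        cfg = cls(**{k: v for k, v in d.items() if k in
                     {f.name for f in dataclasses.fields(cls)}})
        if sim:
            qtls = [simulate.QTL(**q) for q in sim.pop("qtl_spec", [])]
            for tup in ("bands_per_marker",):
                if tup in sim and isinstance(sim[tup], list):
                    sim[tup] = tuple(sim[tup])
            cfg.sim = simulate.SimConfig(**sim, qtl_spec=qtls)
        if isinstance(cfg.stages, dict):
            merged = {s: True for s in STAGES}
            merged.update(cfg.stages)
            cfg.stages = merged
        return cfg.validate()


def _stage_seed(master: int, stage: str) -> int:
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31 - 1)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the pipeline; returns the bundle directory."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": hashlib.sha256(config.to_yaml().encode()).hexdigest()[:16],
        "seed": config.seed, "stages": {},
    }

    # --- inputs
    if config.sim is not None:
        truth, design, phenotypes = simulate.simulate_dataset(config.sim)
        marker_map = truth.marker_map
        all_bands = truth.all_bands()
        write_marker_map(marker_map, out / "marker_map.tsv")
        write_band_matrix(all_bands, out / "bands.structure.tsv", "structure", marker_map)
        write_phenotypes(phenotypes, out / "phenotypes.tsv")
        write_design(design, out / "design.tsv")
    else:
        marker_map = read_marker_map(config.marker_map_path)
        all_bands = read_band_matrix(config.band_matrix_path, config.band_matrix_dialect)
        phenotypes = read_phenotypes(config.phenotype_path)
        design = read_design(config.design_path)
        truth = None

    try:
        ctx = _run_stages(config, out, manifest, marker_map, all_bands,
                          phenotypes, design)
    except LxthetError:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out


def _run_stages(config, out, manifest, marker_map, all_bands, phenotypes, design):
    means = None
    combining: dict[str, lxt.CombiningAbility] = {}
    het = pd.DataFrame()
    q_matrices: dict[str, pd.DataFrame] = {}

    if config.stages.get("phenostats", True):
        summary = pheno.summarize(phenotypes)
        summary.to_csv(out / "trait_summary.tsv", sep="\t", index=False)
        means = pheno.entry_means(phenotypes, mode=config.entry_mean_mode)
        means.to_csv(out / "entry_means.tsv", sep="\t")
        corr, corr_p = pheno.correlations(means)
        corr.to_csv(out / "trait_correlations.tsv", sep="\t")
        pres = pheno.pca(means)
        pd.DataFrame({"eigenvalue": pres.eigenvalues, "percent": pres.percent,
                      "cumulative": pres.cumulative_percent}).to_csv(
            out / "pca_eigenvalues.tsv", sep="\t", index=False)
        manifest["stages"]["phenostats"] = {"summary_rows": len(summary),
                                            "individuals": len(means)}
    else:
        means = pheno.entry_means(phenotypes, mode=config.entry_mean_mode)

    if config.stages.get("lxt_heterosis", True):
        rows = []
        for trait in [t for t in TRAITS if t in means.columns]:
            ca = lxt.combining_ability(phenotypes, design, trait)
            combining[trait] = ca
            rows.append({"trait": trait, "mu": ca.mu,
                         "sigma2_gca": ca.sigma2_gca, "sigma2_sca": ca.sigma2_sca})
        pd.DataFrame(rows).to_csv(out / "combining_ability.tsv", sep="\t", index=False)
        het = lxt.heterosis_table(phenotypes, design)
        het.to_csv(out / "heterosis.tsv", sep="\t", index=False)
        manifest["stages"]["lxt_heterosis"] = {"traits": len(combining),
                                               "heterosis_rows": len(het)}

    if config.stages.get("popstructure", True):
        seed0 = _stage_seed(config.seed, "structure")
        evanno_rows = []
        for panel in config.structure_panels:
            ids = design.lines if panel == "PS" else design.f1s_of_tester(panel)
            bm = all_bands.subset(ids)
            runs: dict[int, list[structure.StructureRun]] = {}
            for K in range(config.structure_kmin, config.structure_kmax + 1):
                runs[K] = [structure.admixture_mcmc(
                    bm, K, burnin=config.structure_burnin, reps=config.structure_reps,
                    seed=seed0 + 1000 * K + j) for j in range(config.structure_runs)]
            ev = structure.evanno(runs)
            best_k = ev.selected_k
            best_run = max(runs[best_k], key=lambda r: r.lnpd)
            q_matrices[panel] = best_run.q
            best_run.q.to_csv(out / f"qmatrix_{panel}.tsv", sep="\t")
            tab = ev.table.copy()
            tab.insert(0, "panel", panel)
            evanno_rows.append(tab)
            labels = structure.assign_subpops(best_run.q, config.q_threshold)
            labels.to_csv(out / f"subpops_{panel}.tsv", sep="\t")
        pd.concat(evanno_rows).to_csv(out / "evanno.tsv", sep="\t", index=False)
        manifest["stages"]["popstructure"] = {
            "panels": list(config.structure_panels),
            "selected_k": {p: int(q_matrices[p].shape[1]) for p in q_matrices}}
    else:
        log.info("popstructure disabled: association runs with K-only model")

    if config.stages.get("ld", True):
        masked = ld.mask_rare(all_bands.subset(design.lines), config.rare_threshold)
        pairs = ld.pairwise_ld(masked, marker_map, shuffles=config.ld_shuffles,
                               seed=_stage_seed(config.seed, "ld"))
        pairs.to_csv(out / "ld_pairs.tsv", sep="\t", index=False)
        ld_report: dict = {"n_pairs": len(pairs)}
        try:
            ld_report["background_r2"] = ld.background_ld(pairs)
        except LxthetError as exc:
            log.warning("ld: %s", exc)
        try:
            fit = ld.decay_fit(pairs, threshold=config.ld_decay_threshold,
                               p_max=config.ld_p_max)
            ld_report.update({"decay_kb": fit.decay_distance,
                              "intercept": fit.intercept, "slope": fit.slope})
        except LxthetError as exc:
            log.warning("ld: %s", exc)
        pd.DataFrame([ld_report]).to_csv(out / "ld_decay.tsv", sep="\t", index=False)
        manifest["stages"]["ld"] = ld_report

    ctx = None
    if config.stages.get("association", True):
        acfg = assoc.AssocConfig(significance_neglog10=config.significance_neglog10,
                                 q_matrices=q_matrices, use_q=bool(q_matrices))
        ctx = assoc.run_all(all_bands, marker_map, design, means, combining, het, acfg)
        ctx.records.to_csv(out / "associations.tsv", sep="\t", index=False)
        ctx.counts_by_variable.rename("n_significant").to_csv(
            out / "significant_counts.tsv", sep="\t")
        manifest["stages"]["association"] = {
            "records": len(ctx.records),
            "significant": int(ctx.counts_by_variable.sum())}

    if config.stages.get("qtl_alleles", True):
        if ctx is None:
            raise ConfigError("pipeline: qtl_alleles requires the association stage")
        sig = qtl.filter_significant(ctx.records, config.significance_neglog10)
        whitelist = (qtl.ALL_VARIABLES if config.stable_variables == "all"
                     else qtl.CORE_VARIABLES)
        stables = qtl.stable_qtls(sig, design, variables=whitelist,
                                  min_testers=config.min_testers)
        qtl.stable_qtl_table(stables).to_csv(out / "stable_qtls.tsv", sep="\t",
                                             index=False)
        summary = qtl.pleiotropy_and_subgenome(stables, marker_map)
        (out / "qtl_summary.json").write_text(json.dumps(summary, indent=2, default=str))
        effects, extremes, tally = qtl.favorable_alleles(
            sig, ctx.combinations, ctx.panels)
        if not effects.empty:
            effects.to_csv(out / "allele_effects.tsv", sep="\t", index=False)
            extremes.to_csv(out / "allele_extremes.tsv", sep="\t", index=False)
            tally.rename("n_favorable").to_csv(out / "favorable_by_tester.tsv", sep="\t")
        manifest["stages"]["qtl_alleles"] = {
            "significant": len(sig), "stable_qtls": len(stables),
            "favorable_alleles": int(effects["favorable"].sum()) if not effects.empty else 0}
    return ctx


def report(bundle: str | Path) -> str:
    """Human-readable summary of a result bundle."""
    bundle = Path(bundle)
    manifest_path = bundle / "manifest.json"
    if not manifest_path.exists():
        return f"{bundle}: no stages have run (no manifest)"
    manifest = json.loads(manifest_path.read_text())
    lines = [f"lxthet result bundle {bundle}",
             f"  config hash {manifest.get('config_hash')}  seed {manifest.get('seed')}"]
    done = manifest.get("stages", {})
    missing = [s for s in STAGES if s not in done]
    for stage, info in done.items():
        lines.append(f"  {stage}: " + ", ".join(f"{k}={v}" for k, v in info.items()))
    sig_path = bundle / "significant_counts.tsv"
    if sig_path.exists():
        counts = pd.read_csv(sig_path, sep="\t", index_col=0)
        for cls, row in counts.iterrows():
            lines.append(f"  significant associations [{cls}]: {int(row.iloc[0])}")
    stq = bundle / "stable_qtls.tsv"
    if stq.exists():
        tab = pd.read_csv(stq, sep="\t")
        lines.append(f"  stable QTLs: {len(tab)}")
        if not tab.empty:
            per_trait = tab.groupby("trait").size()
            lines.append("    per trait: "
                         + ", ".join(f"{t}={n}" for t, n in per_trait.items()))
    fav = bundle / "favorable_by_tester.tsv"
    if fav.exists():
        tab = pd.read_csv(fav, sep="\t", index_col=0)
        lines.append("  favorable alleles per tester: "
                     + ", ".join(f"{t}={int(v.iloc[0])}" for t, v in tab.iterrows()))
    if missing:
        lines.append("  missing stages: " + ", ".join(missing))
    return "\n".join(lines)
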