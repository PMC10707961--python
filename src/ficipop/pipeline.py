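"""End-to-end orchestration of the two study arms.

``run_ficifolia_arm`` takes a diploid crop VCF through the filtering
cascade, diversity summary, folded SFS (projected to 18 haploid copies by
default), three-model demographic model selection, and parametric
bootstrap intervals for the winning model.

``run_five_taxa_arm`` takes the five-taxon VCF through filtering, the
joint unfolded SFS, two stages of coalescent model selection (wild-group
topology, then crop-wild gene flow) and the ABBA-BABA trio table.

Every stochastic stage draws its seed from one root seed through named
substreams, so stages are individually reproducible and the full report
is byte-identical across reruns with the same configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import diversity, dstat, filtering, models, sfs
from .fitting import FitSettings, bootstrap_ci, fit_model, rank_models
from .genotypes import read_bed, read_genotypes, read_pop_map


@dataclass
class PipelineConfig:
    """Inputs, thresholds (defaults = the study's printed settings) and
    run sizes for the pipeline."""

    vcf: str = ""
    pop_map: str = ""
    bed: str = ""
    # filter thresholds
    max_missing: float = 0.30
    thin_bp: int = 250
    hwe_p: float | None = 1e-4
    r2_max: float = 0.25
    ld_window_bp: int = 100_000
    ld_step_bp: int = 100
    # SFS / fitting
    projection_size: int = 18
    seed: int = 1
    n_starts: int = 20
    n_replicates: int = 5000
    maxiter: int = 200
    n_boot: int = 100
    ci_level: float = 0.95
    # five-taxa specifics
    outgroup: str = "cordata"
    run_stage_one: bool = True
    trios: list[tuple[str, str, str]] = field(default_factory=list)
    n_blocks: int = 20
    alpha: float = 0.05
    # time conversion
    m_t: int = 44_143
    mu_per_myr_bounds: tuple[float, float] = (0.0061, 0.0032)

    def validate(self) -> None:
        if not 0 <= self.max_missing <= 1:
            raise ValueError("max_missing outside [0, 1]")
        if self.hwe_p is not None and not 0 <= self.hwe_p <= 1:
            raise ValueError("hwe_p outside [0, 1]")
        if self.projection_size < 2:
            raise ValueError("projection_size must be >= 2")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "trios" in raw:
            raw["trios"] = [tuple(t) for t in raw["trios"]]
        if "mu_per_myr_bounds" in raw:
            raw["mu_per_myr_bounds"] = tuple(raw["mu_per_myr_bounds"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _substream(root_seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def _settings(cfg: PipelineConfig) -> FitSettings:
    return FitSettings(
        n_starts=cfg.n_starts, n_replicates=cfg.n_replicates, maxiter=cfg.maxiter
    )


def _apply_cascade(gm, cfg: PipelineConfig):
    log = {"input": gm.n_sites}
    gm = filtering.filter_missingness(gm, cfg.max_missing)
    log["missingness"] = gm.n_sites
    gm = filtering.thin_by_distance(gm, cfg.thin_bp)
    log["thinning"] = gm.n_sites
    if cfg.hwe_p is not None:
        gm = filtering.filter_hwe(gm, cfg.hwe_p)
    log["hwe"] = gm.n_sites
    gm = filtering.ld_prune(gm, cfg.r2_max, cfg.ld_window_bp, cfg.ld_step_bp)
    log["ld_prune"] = gm.n_sites
    return gm, log


def run_ficifolia_arm(cfg: PipelineConfig, out_dir) -> dict:
    """Filters -> diversity summary -> folded SFS -> model selection ->
    bootstrap CIs; returns the report dict and writes text/TSV reports."""
    cfg.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_hash": cfg.hash(), "seed": cfg.seed, "stages": {}}

    try:
        gm = read_genotypes(cfg.vcf, read_pop_map(cfg.pop_map), ploidy=2)
    except Exception as e:
        raise RuntimeError(f"stage 'input' failed: {e}") from e

    gm, filter_log = _apply_cascade(gm, cfg)
    report["stages"]["filter"] = filter_log

    table = diversity.site_stats(gm)
    summary = diversity.summarize(table)
    try:
        summary.fst = diversity.fst_among_groups(gm)
    except ValueError:
        summary.fst = None
    summary.to_frame().to_csv(out_dir / "diversity_summary.tsv", sep="\t", index=False)
    report["stages"]["diversity"] = {
        "pi_mean": summary.pi_mean, "he_mean": summary.he_mean,
        "ho_mean": summary.ho_mean, "fis_mean": summary.fis_mean,
        "fst_among_groups": summary.fst, "n_sites": summary.n_sites,
    }

    spectrum = sfs.build_sfs(gm, fold=True, project_to=cfg.projection_size)
    spectrum.write(out_dir / "folded_sfs.txt")
    report["stages"]["sfs"] = {
        "n": spectrum.n, "n_snps": spectrum.n_snps, "folded": True,
    }

    catalog = models.single_population_catalog()
    settings = _settings(cfg)
    fits = []
    for spec in catalog:
        fit_seed = _substream(cfg.seed, f"fit:{spec.name}")
        fits.append(fit_model(spectrum, spec, settings, seed=fit_seed))
    ranking = rank_models(fits)
    ranking.to_csv(out_dir / "model_selection.tsv", sep="\t", index=False)
    report["stages"]["demography"] = {
        "ranking": ranking.to_dict(orient="records"),
        "seeds": {s.name: _substream(cfg.seed, f"fit:{s.name}") for s in catalog},
    }

    best = min(fits, key=lambda f: (f.aic, f.k))
    best_spec = next(s for s in catalog if s.name == best.model_name)
    if cfg.n_boot >= 10:
        ci, n_fail = bootstrap_ci(
            spectrum, best_spec, best.params, n_boot=cfg.n_boot,
            level=cfg.ci_level, settings=settings,
            seed=_substream(cfg.seed, "bootstrap"),
        )
        report["stages"]["bootstrap"] = {
            "model": best.model_name, "ci": {k: list(v) for k, v in ci.items()},
            "n_failures": n_fail, "n_boot": cfg.n_boot,
        }
    else:
        report["stages"]["bootstrap"] = {
            "note": "bootstrap disabled (n_boot < 10); CIs omitted"
        }
    report["best_model"] = {
        "name": best.model_name,
        "params": {k: float(v) for k, v in best.params.items()},
        "lnl": best.lnl, "aic": best.aic,
    }
    _write_report(report, out_dir / "report_ficifolia.txt")
    return report


def run_five_taxa_arm(cfg: PipelineConfig, out_dir) -> dict:
    """Filters -> joint unfolded SFS -> two-stage model selection ->
    ABBA-BABA trio table with Bonferroni threshold."""
    cfg.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_hash": cfg.hash(), "seed": cfg.seed, "stages": {}}

    gm = read_genotypes(cfg.vcf, read_pop_map(cfg.pop_map), ploidy=2)
    gm, filter_log = _apply_cascade(gm, cfg)
    report["stages"]["filter"] = filter_log

    taxa = [models.FIC, models.RAD, models.PED, models.FOE, models.SCA]
    joint = sfs.build_joint_sfs(gm, taxa, outgroup_label=cfg.outgroup)
    joint.write(out_dir / "joint_sfs.txt")
    report["stages"]["sfs"] = {"axes": joint.axes, "n_snps": joint.n_snps}

    settings = _settings(cfg)
    if cfg.run_stage_one:
        group = sfs.build_joint_sfs(
            gm, [models.FOE, models.SCA, models.PED], outgroup_label=cfg.outgroup
        )
        fits1 = []
        for spec in models.hybrid_group_catalog():
            fits1.append(
                fit_model(group, spec, settings,
                          seed=_substream(cfg.seed, f"stage1:{spec.name}"))
            )
        rank1 = rank_models(fits1)
        rank1.to_csv(out_dir / "stage_one_models.tsv", sep="\t", index=False)
        report["stages"]["stage_one"] = rank1.to_dict(orient="records")

    fits2 = []
    for spec in models.crop_wild_catalog():
        fits2.append(
            fit_model(joint, spec, settings,
                      seed=_substream(cfg.seed, f"stage2:{spec.name}"))
        )
    rank2 = rank_models(fits2)
    rank2.to_csv(out_dir / "stage_two_models.tsv", sep="\t", index=False)
    report["stages"]["stage_two"] = rank2.to_dict(orient="records")

    if cfg.trios:
        labels = sorted(set(gm.pop_labels.values()))
        groups = {t: [t] for t in labels}
        groups["foetscabri"] = [models.FOE, models.SCA]
        results, threshold = dstat.trio_table(
            gm, groups, cfg.trios, outgroup=cfg.outgroup,
            n_blocks=cfg.n_blocks, alpha=cfg.alpha,
        )
        frame = dstat.trio_table_frame(results, threshold)
        frame.to_csv(out_dir / "dstat_trios.tsv", sep="\t", index=False)
        report["stages"]["dstat"] = {
            "trios": frame.to_dict(orient="records"),
            "bonferroni_threshold": threshold,
        }
    else:
        report["stages"]["dstat"] = {"note": "no trios configured; D stage skipped"}

    _write_report(report, out_dir / "report_five_taxa.txt")
    return report


def _write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write(json.dumps(report, indent=2, sort_keys=True, default=str))
        fh.write("\n")
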