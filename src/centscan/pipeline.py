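"""Pipeline orchestration: simulate -> associate -> PRS -> power from one config.

A run is described by a :class:`RunConfig` (plain YAML on disk).  Stages run
in dependency order, every output table goes through the deterministic TSV
writer, and a manifest records the config, its hash, the seed, and per-file
checksums — identical config + seed reproduces byte-identical outputs.
The single global seed is expanded into independent per-stage substreams so
toggling one stage does not perturb another's draws.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, power, prs
from .io import (CohortDataset, ReferencePanel, ValidationError,
                 read_dosages, read_reference_table, write_dataset,
                 write_results, write_reference_table)
from .simulate import CohortSpec, default_panel, simulate_cohorts

STAGES = ("simulate", "assoc", "prs", "power")
POWER_DEFAULTS = {"n_cases": 8000, "alpha": 0.05, "target_power": 0.8,
                  "step": 200, "ratio_threshold": 2.0, "maf_min": 0.01,
                  "require_match_in": "both"}


@dataclass
class RunConfig:
    """One pipeline run: paths, seed, and per-stage settings."""

    out_dir: str = "centscan-run"
    seed: int = 0
    panel_path: str | None = None      # None -> built-in synthetic default panel
    panel_snps: int = 86
    data_dir: str | None = None        # pre-existing dataset; None -> simulate
    genotype_format: str = "tsv"       # output format of the simulate stage
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    simulate: dict = field(default_factory=dict)   # CohortSpec overrides
    contrasts: list[str] = field(default_factory=lambda: [
        "ad-vs-centenarian", "ad-vs-control", "control-vs-centenarian"])
    prs_by_sex: bool = False
    power: dict = field(default_factory=dict)      # POWER_DEFAULTS overrides

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def validate(self) -> None:
        bad = set(self.stages) - set(STAGES)
        if bad:
            raise ValidationError(f"unknown stage(s) {sorted(bad)}")
        valid = set(association.CONTRASTS) | {association.EARLY_VS_LATE}
        bad = set(self.contrasts) - valid
        if bad:
            raise ValidationError(f"unknown contrast name(s) {sorted(bad)}")
        bad = set(self.power) - set(POWER_DEFAULTS)
        if bad:
            raise ValidationError(f"unknown power option(s) {sorted(bad)}")
        if self.data_dir is not None and not Path(self.data_dir).exists():
            raise ValidationError(f"data_dir does not exist: {self.data_dir}")
        if self.panel_path is not None and not Path(self.panel_path).exists():
            raise ValidationError(f"panel_path does not exist: {self.panel_path}")


def _stage_seeds(seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {stage: int(child.generate_state(1)[0] % (2 ** 31))
            for stage, child in zip(STAGES, children)}


def _load_panel(config: RunConfig) -> ReferencePanel:
    if config.panel_path is not None:
        return read_reference_table(config.panel_path)
    return default_panel(config.panel_snps)


def _load_dataset(config: RunConfig, panel: ReferencePanel) -> CohortDataset:
    data_dir = Path(config.data_dir)
    vcf = data_dir / "dosages.vcf"
    tsv = data_dir / "dosages.tsv"
    geno = vcf if vcf.exists() else tsv
    if not geno.exists():
        raise ValidationError(f"no dosages.vcf or dosages.tsv in {data_dir}")
    return read_dosages(geno, panel, data_dir / "samples.tsv")


def run_all(config: RunConfig, overwrite: bool = False) -> dict:
    """Execute enabled stages in order and return the run manifest.

    Validation happens before any compute or output; a stage failure aborts
    the run with the failing stage named.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest: dict = {"config": config.to_dict(),
                      "config_hash": config.config_hash(),
                      "seed": config.seed, "stages": {}}
    panel = _load_panel(config)
    write_reference_table(panel, out_dir / "panel.tsv")
    dataset: CohortDataset | None = None
    scans: dict[str, pd.DataFrame] = {}
    summaries: dict[str, dict] = {}

    stage = None
    try:
        if "simulate" in config.stages and config.data_dir is None:
            stage = "simulate"
            spec = CohortSpec(**{**config.simulate, "seed": seeds["simulate"]})
            sim = simulate_cohorts(panel, spec)
            dataset = sim.dataset
            data_dir = out_dir / "data"
            files = write_dataset(dataset, data_dir, panel,
                                  fmt=config.genotype_format)
            sim.truth.reset_index().to_csv(data_dir / "truth.tsv", sep="\t",
                                           index=False, float_format="%.10g")
            files["truth"] = str(data_dir / "truth.tsv")
            manifest["stages"]["simulate"] = {
                "files": files, "counts": dataset.counts(),
                "seed": seeds["simulate"]}
        if dataset is None:
            stage = "load"
            if config.data_dir is None:
                raise ValidationError(
                    "no dataset: enable the simulate stage or set data_dir")
            dataset = _load_dataset(config, panel)

        if "assoc" in config.stages:
            stage = "assoc"
            tables = {}
            for contrast in config.contrasts:
                results, summary = association.run_pairwise_scan(
                    dataset, panel, contrast)
                key = f"assoc_{contrast.replace('-', '_')}"
                tables[key] = results
                scans[contrast] = results
                summaries[contrast] = summary.to_dict()
            m = write_results(tables, out_dir / "assoc",
                              summary={"contrast_summaries": summaries,
                                       "config_hash": config.config_hash()},
                              overwrite=overwrite)
            manifest["stages"]["assoc"] = {"files": m["files"],
                                           "summaries": summaries}

        if "prs" in config.stages:
            stage = "prs"
            comparisons = prs.prs_analysis(dataset, panel,
                                           by_sex=config.prs_by_sex)
            scores = pd.DataFrame({
                "sample_id": dataset.samples.index,
                "prs_with_apoe": prs.compute_prs(
                    dataset, panel, prs.PRSConfig(include_apoe=True)).to_numpy(),
                "prs_without_apoe": prs.compute_prs(
                    dataset, panel, prs.PRSConfig(include_apoe=False)).to_numpy(),
            })
            m = write_results({"prs_comparisons": comparisons,
                               "prs_scores": scores},
                              out_dir / "prs",
                              summary={"config_hash": config.config_hash()},
                              overwrite=overwrite)
            manifest["stages"]["prs"] = {
                "files": m["files"],
                "comparisons": comparisons.to_dict(orient="records")}

        if "power" in config.stages:
            stage = "power"
            opts = {**POWER_DEFAULTS, **config.power}
            for needed in ("ad-vs-control", "ad-vs-centenarian"):
                if needed not in scans:
                    scans[needed], _ = association.run_pairwise_scan(
                        dataset, panel, needed)
            eligible = power.direction_filter(
                scans["ad-vs-control"], scans["ad-vs-centenarian"], panel,
                maf_min=opts["maf_min"],
                require_match_in=opts["require_match_in"])
            escalations = power.escalate_panel(
                panel, scans["ad-vs-control"], scans["ad-vs-centenarian"],
                eligible, n_cases=opts["n_cases"], alpha=opts["alpha"],
                target_power=opts["target_power"], step=opts["step"])
            summary = power.equivalence_summary(
                escalations, ratio_threshold=opts["ratio_threshold"])
            ratios = summary.ratios.reset_index()
            shortlist = pd.DataFrame({"snp_id": summary.shortlist})
            eq = {"n_eligible": len(eligible),
                  "n_excluded_nonconverged": summary.n_excluded_nonconverged,
                  "mean_ratio": summary.mean, "sd_ratio": summary.sd,
                  "median_ratio": summary.median,
                  "iqr_low": summary.iqr[0], "iqr_high": summary.iqr[1],
                  "n_shortlist": len(summary.shortlist),
                  "ratio_threshold": summary.ratio_threshold}
            m = write_results({"escalations": escalations,
                               "equivalence_ratios": ratios,
                               "shortlist": shortlist},
                              out_dir / "power",
                              summary={"equivalence": eq,
                                       "options": opts,
                                       "config_hash": config.config_hash()},
                              overwrite=overwrite)
            manifest["stages"]["power"] = {"files": m["files"],
                                           "equivalence": eq}
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest


def render_report(manifest: dict | str | Path) -> str:
    """Human-readable run summary: scans, PRS table, equivalence, shortlist."""
    if not isinstance(manifest, dict):
        with open(Path(manifest) if not str(manifest).endswith(".json")
                  else manifest) as fh:
            manifest = json.load(fh)
    lines = ["# centscan run report",
             f"config hash: {manifest.get('config_hash', 'unknown')}",
             f"seed: {manifest.get('seed', 'unknown')}", ""]
    recomputed = RunConfig(**manifest["config"]).config_hash() \
        if "config" in manifest else None
    if recomputed is not None and recomputed != manifest.get("config_hash"):
        lines.append("WARNING: config hash mismatch — outputs may not match "
                     "the embedded config\n")
    stages = manifest.get("stages", {})

    lines.append("## Association scans")
    if "assoc" in stages:
        for contrast, s in stages["assoc"]["summaries"].items():
            lines.append(
                f"- {contrast}: median change {s['median_change']:.2f} "
                f"(IQR {s['iqr_change_low']:.2f}-{s['iqr_change_high']:.2f}); "
                f"{s['n_change_gt1']}/{s['n_fit']} SNPs with change > 1 "
                f"(sign test P = {s['sign_test_p']:.2e})")
    else:
        lines.append("- section absent")

    lines.append("\n## PRS contrasts (OR per SD, 95% CI)")
    if "prs" in stages:
        for row in stages["prs"]["comparisons"]:
            apoe = "with APOE" if row["include_apoe"] else "without APOE"
            lines.append(
                f"- {row['group_a']} vs {row['group_b']} ({apoe}, "
                f"{row['stratum']}): OR = {row['or_per_sd']:.2f} "
                f"[{row['ci_low']:.2f}-{row['ci_high']:.2f}], "
                f"P = {row['p_value']:.2e}")
    else:
        lines.append("- section absent")

    lines.append("\n## Centenarian equivalence")
    if "power" in stages:
        eq = stages["power"]["equivalence"]
        lines.append(
            f"- {eq['n_eligible']} eligible SNPs; "
            f"{eq['n_excluded_nonconverged']} converged in neither arm; "
            f"mean ratio {eq['mean_ratio']:.2f} "
            f"(median {eq['median_ratio']:.2f}, "
            f"IQR {eq['iqr_low']:.2f}-{eq['iqr_high']:.2f})")
        lines.append("\n## Functional shortlist")
        if eq["n_shortlist"] == 0:
            lines.append(f"- no SNPs with ratio > {eq['ratio_threshold']:g}")
        else:
            lines.append(f"- {eq['n_shortlist']} SNP(s) with ratio > "
                         f"{eq['ratio_threshold']:g}")
    else:
        lines.append("- section absent")
        lines.append("\n## Functional shortlist")
        lines.append("- section absent")
    return "\n".join(lines) + "\n"
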