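"""End-to-end orchestration: simulate/read -> filter -> prune ->
admixture -> AIM scoring, under one serialisable, seeded configuration.

Every run writes per-stage outputs (filter report, retained-site list,
Q matrix, AIM set and report), a combined per-sample table, a stacked
admixture plot, and a manifest of the seeds and thresholds sufficient
to re-run bit-identically.  When the input is synthetic, the truth is
joined in for parameter-recovery columns.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .aims import AIMFinder, aim_report
from .ancestry import AdmixtureEM, classify_purity, panel_frequencies, fit_supervised
from .filtering import SiteFilter
from .plotting import plot_admixture
from .pruning import LDPruner
from .simulate import SimConfig, generate_dataset
from .variants import SampleSheet, read_vcf

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All thresholds and seeds of one run, JSON/YAML round-trippable."""

    sim: dict | None = None            # SimConfig fields, or None for a real VCF
    vcf: str | None = None
    sample_sheet: str | None = None
    filter: dict = field(default_factory=dict)     # SiteFilter params
    prune: dict = field(default_factory=dict)      # LDPruner params
    ancestry: dict = field(default_factory=dict)   # AdmixtureEM params
    purity_threshold: float = 0.99
    aim_max_armigera_carriers: int = 1
    aim_dp_threshold: int = 5
    out_dir: str = "helihybrid_run"

    def to_dict(self) -> dict:
        return asdict(self)

    def dump(self, path) -> None:
        path = Path(path)
        text = (yaml.safe_dump(self.to_dict(), sort_keys=False)
                if path.suffix in (".yml", ".yaml")
                else json.dumps(self.to_dict(), indent=1))
        path.write_text(text)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = (yaml.safe_load(text) if str(path).endswith((".yml", ".yaml"))
                else json.loads(text))
        return cls(**data)


@dataclass
class RunReport:
    config: PipelineConfig
    per_sample: pd.DataFrame
    stage_counts: dict
    paths: dict


def run_pipeline(config: PipelineConfig) -> RunReport:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    truth = None

    # stage 1: input
    if config.sim is not None:
        sim_cfg = SimConfig(**config.sim)
        written = generate_dataset(sim_cfg, out / "simulated")
        ds = written.pop("dataset")
        table, sheet, truth = ds.table, ds.sheet, ds.truth
        paths.update({k: v for k, v in written.items()})
    elif config.vcf is not None:
        table = read_vcf(config.vcf)
        sheet = (SampleSheet.read(config.sample_sheet)
                 if config.sample_sheet else SampleSheet())
    else:
        raise ValueError("PipelineConfig needs either sim or vcf")
    log.info("input: %d samples x %d sites", table.n_samples, table.n_sites)

    # stage 2: site filters
    flt = SiteFilter(**config.filter)
    filtered = flt.fit_transform(table)
    flt.report_.to_frame().to_csv(out / "filter_report.tsv", sep="\t", index=False)
    paths["filter_report"] = out / "filter_report.tsv"
    log.info("filter: %d -> %d sites", table.n_sites, filtered.n_sites)

    # stage 3: LD pruning
    pruner = LDPruner(**config.prune)
    pruned = pruner.fit_transform(filtered)
    pruned.sites[["chrom", "pos"]].to_csv(
        out / "retained_sites.tsv", sep="\t", index=False)
    paths["retained_sites"] = out / "retained_sites.tsv"
    log.info("prune: removed %d SNPs", pruner.n_removed_)

    # stage 4: unsupervised admixture + purity classification
    model = AdmixtureEM(**config.ancestry)
    labels = sheet.labels_for(pruned.samples)
    model.fit(pruned.dosage, sample_labels=labels)
    qframe = model.estimate(pruned.samples)
    qframe.to_csv(out / "Q_matrix.tsv", sep="\t", index=False)
    paths["Q_matrix"] = out / "Q_matrix.tsv"
    pure_a, pure_z, hybrids = classify_purity(
        model.Q_, model.population_labels_, pruned.samples,
        threshold=config.purity_threshold)
    log.info("purity: %d armigera / %d zea / %d hybrid",
             len(pure_a), len(pure_z), len(hybrids))

    # stage 4b: supervised projection against pure-panel frequencies
    q_sup = np.full((pruned.n_samples, 2), np.nan)
    if pure_a and pure_z:
        F_ref = panel_frequencies(
            pruned.take_samples(pure_a).dosage,
            pruned.take_samples(pure_z).dosage)
        q_sup = fit_supervised(pruned.dosage, F_ref)

    # stage 5: AIMs (needs both reference panels)
    aim_frame = pd.DataFrame()
    n_aims = 0
    if pure_a and pure_z:
        finder = AIMFinder(config.aim_max_armigera_carriers)
        aims = finder.fit(pruned, pure_z, pure_a).aims_
        aims.to_bed_frame(pruned).to_csv(
            out / "aims.bed.tsv", sep="\t", index=False, header=False)
        paths["aims"] = out / "aims.bed.tsv"
        n_aims = len(aims)
        if n_aims:
            aim_frame = aim_report(pruned, aims, config.aim_dp_threshold)
        log.info("aims: %d diagnostic sites", n_aims)

    # stage 6: combined per-sample table, plot, manifest
    purity = {s: "pure_armigera" for s in pure_a}
    purity.update({s: "pure_zea" for s in pure_z})
    purity.update({s: "hybrid" for s in hybrids})
    combined = qframe.copy()
    combined["purity_class"] = [purity[s] for s in combined["sample_id"]]
    combined["q_armigera_supervised"] = q_sup[:, 0]
    combined["q_zea_supervised"] = q_sup[:, 1]
    if not aim_frame.empty:
        combined = combined.merge(aim_frame, on="sample_id", how="left")
    if truth is not None:
        combined = combined.merge(
            truth.q_true.rename(columns={"q_armigera": "q_armigera_true",
                                         "q_zea": "q_zea_true"}),
            on="sample_id", how="left")
        combined["abs_err_q_armigera"] = (
            combined["q_armigera"] - combined["q_armigera_true"]).abs()
    combined = combined.round(9)
    combined.to_csv(out / "per_sample.tsv", sep="\t", index=False)
    paths["per_sample"] = out / "per_sample.tsv"

    plot_admixture(model.Q_, pruned.samples, model.population_labels_,
                   out / "admixture.svg")
    paths["plot"] = out / "admixture.svg"

    stage_counts = {
        "n_input_sites": table.n_sites,
        "n_filtered_sites": filtered.n_sites,
        "n_pruned_removed": pruner.n_removed_,
        "n_analysis_sites": pruned.n_sites,
        "n_pure_armigera": len(pure_a),
        "n_pure_zea": len(pure_z),
        "n_hybrid": len(hybrids),
        "n_aims": n_aims,
        "admixture_iterations": model.n_iter_,
        "admixture_converged": bool(model.converged_),
    }
    manifest = {"config": config.to_dict(), "stage_counts": stage_counts,
                "outputs": {k: str(v) for k, v in paths.items()}}
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
    paths["manifest"] = out / "run_manifest.json"
    return RunReport(config=config, per_sample=combined,
                     stage_counts=stage_counts, paths=paths)
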