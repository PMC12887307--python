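"""Declarative end-to-end pipeline: simulate -> pressure -> dom ->
community -> couple -> report.

A :class:`StudyConfig` (built directly or from a YAML file) names the
inputs, the analysis parameters and the output directory;
:func:`run_pipeline` executes the configured stages in order, writing each
stage's outputs before the next starts and a machine-readable
:class:`RunReport` (JSON) last. Every stochastic step records its seed and
permutation count; the report payload contains no timestamps, so identical
configurations and seeds produce byte-identical reports.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import community as cm
from . import coupling as cp
from . import io as cio
from . import pressure as pr
from .dom import (AssignmentConfig, assign_peaklist, class_abundance,
                  chemodiversity, formula_to_string)
from .errors import CesdynError

__all__ = ["StudyConfig", "RunReport", "run_pipeline", "PipelineError"]

KNOWN_STAGES = ("simulate", "pressure", "dom", "community", "couple")


class PipelineError(CesdynError):
    def __init__(self, stage: str, cause: Exception | str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class StudyConfig:
    outdir: str
    stages: tuple[str, ...] = KNOWN_STAGES
    # inputs (filled automatically when the simulate stage runs)
    pressure_csv: str | None = None
    control_id: str = "CTRL"
    dom_dir: str | None = None
    asv_table: str | None = None
    samples_tsv: str | None = None
    # analysis parameters
    phases: tuple[tuple[int, int], ...] = ((1, 8), (31, 45), (46, 54))
    smoothing_window_s: float = pr.DEFAULT_SMOOTHING_WINDOW_S
    tolerance_ppm: float = 1.0
    n_permutations: int = 999
    bin_width: float = 50.0
    mass_range: tuple[float, float] = (200.0, 600.0)
    rho_threshold: float = 0.3
    top_genera: int = 20
    seed: int = 42

    def __post_init__(self):
        for stage in self.stages:
            if stage not in KNOWN_STAGES:
                raise CesdynError(
                    f"unknown stage {stage!r}; known stages: {KNOWN_STAGES}")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        extra = set(raw) - known
        if extra:
            raise CesdynError(f"unknown config keys: {sorted(extra)}")
        for key in ("stages", "phases", "mass_range"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(
                    tuple(v) if isinstance(v, list) else v for v in raw[key])
        return cls(**raw)


@dataclass
class RunReport:
    config: dict
    input_checksums: dict
    stages: dict
    warnings: list = field(default_factory=list)

    def to_payload(self) -> dict:
        return {"config": self.config, "input_checksums": self.input_checksums,
                "stages": self.stages, "warnings": self.warnings}


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _phase_payload(summary: pr.PhaseSummary) -> dict:
    return {
        "window": list(summary.window), "n_cycles": summary.n_cycles,
        "mean_amplitude_hPa": summary.mean_amplitude,
        "sd_amplitude_hPa": summary.sd_amplitude, "cv_percent": summary.cv,
        "mean_delta_p_net_hPa": summary.mean_delta_p_net,
        "sd_delta_p_net_hPa": summary.sd_delta_p_net,
        "t_statistic": summary.t_statistic, "p_value": summary.p_value,
    }


def run_pipeline(config: StudyConfig) -> RunReport:
    """Execute the configured stages in order; write the report last."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=asdict(config), input_checksums={}, stages={})
    state: dict = {}

    runners = {"simulate": _stage_simulate, "pressure": _stage_pressure,
               "dom": _stage_dom, "community": _stage_community,
               "couple": _stage_couple}
    for stage in config.stages:
        try:
            runners[stage](config, outdir, state, report)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, exc) from exc
    cio.write_json(report.to_payload(), outdir / "report.json")
    return report


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _stage_simulate(config: StudyConfig, outdir: Path, state, report) -> None:
    from .synthetic import gen_study_bundle

    bundle = gen_study_bundle(outdir / "inputs", seed=config.seed)
    config.pressure_csv = str(bundle.pressure_csv)
    config.dom_dir = str(bundle.root / "dom")
    config.asv_table = str(bundle.asv_tsv)
    config.samples_tsv = str(bundle.samples_tsv)
    report.stages["simulate"] = {
        "seed": config.seed,
        "outputs": {"pressure_csv": config.pressure_csv,
                    "dom_dir": config.dom_dir,
                    "asv_table": config.asv_table,
                    "samples_tsv": config.samples_tsv},
    }


def _stage_pressure(config: StudyConfig, outdir: Path, state, report) -> None:
    if config.pressure_csv is None:
        raise CesdynError("pressure stage needs pressure_csv")
    report.input_checksums["pressure_csv"] = _sha256(config.pressure_csv)
    traces = cio.read_pressure_csv(config.pressure_csv)
    if config.control_id not in traces:
        raise CesdynError(
            f"control unit {config.control_id!r} absent from "
            f"{config.pressure_csv}")
    control = traces.pop(config.control_id)
    frame, summaries, model = pr.analyze_pressure_experiment(
        list(traces.values()), control, config.phases,
        smoothing_window_s=config.smoothing_window_s)
    frame.to_csv(outdir / "cycle_metrics.tsv", sep="\t", index=False,
                 float_format="%.10g")
    payload = {
        "calibration": {"slope_hPa_per_C": model.slope,
                        "intercept_hPa": model.intercept,
                        "r_squared": model.r_squared,
                        "residual_sd_hPa": model.residual_sd,
                        "n_points": model.n_points},
        "smoothing_window_s": config.smoothing_window_s,
        "phases": {f"{a}-{b}": _phase_payload(s)
                   for (a, b), s in summaries.items()},
    }
    cio.write_json(payload, outdir / "phase_summary.json")
    state["pressure"] = payload
    report.stages["pressure"] = payload


def _stage_dom(config: StudyConfig, outdir: Path, state, report) -> None:
    if config.dom_dir is None:
        raise CesdynError("dom stage needs dom_dir")
    acfg = AssignmentConfig(tolerance_ppm=config.tolerance_ppm)
    assigned_by_sample = {}
    summary = {}
    dom_out = outdir / "dom"
    dom_out.mkdir(exist_ok=True)
    paths = sorted(Path(config.dom_dir).glob("*.csv"))
    if not paths:
        raise CesdynError(f"no peak-list CSVs in {config.dom_dir}")
    for path in paths:
        sample = path.stem
        report.input_checksums[f"dom/{path.name}"] = _sha256(path)
        peaks = cio.read_peaklist_csv(path)
        result = assign_peaklist(peaks, acfg)
        assigned_by_sample[sample] = result.assigned
        rows = [{
            "mz": a.mz, "intensity": a.intensity,
            "formula": formula_to_string(a.formula),
            "ppm_error": a.ppm_error, "hc": a.descriptors.hc_ratio,
            "oc": a.descriptors.oc_ratio, "dbe": a.descriptors.dbe,
            "nosc": a.descriptors.nosc, "series": a.descriptors.series,
            "class": a.compound_class,
        } for a in result.assigned]
        pd.DataFrame(rows).to_csv(dom_out / f"{sample}_assigned.tsv", sep="\t",
                                  index=False, float_format="%.10g")
        series_counts = pd.Series(
            [a.descriptors.series for a in result.assigned]).value_counts()
        summary[sample] = {
            "n_peaks": result.n_peaks,
            "n_assigned": len(result.assigned),
            "n_unassigned": len(result.unassigned),
            "series_counts": series_counts.to_dict(),
            "class_fractions_intensity":
                class_abundance(result.assigned, "intensity").to_dict(),
            "class_fractions_count":
                class_abundance(result.assigned, "count").to_dict(),
            "chemodiversity_nats": chemodiversity(result.assigned),
        }
    cio.write_json({"tolerance_ppm": config.tolerance_ppm, "samples": summary},
                   outdir / "dom_summary.json")
    state["dom_assigned"] = assigned_by_sample
    state["dom_summary"] = summary
    report.stages["dom"] = {"tolerance_ppm": config.tolerance_ppm,
                            "samples": summary}


def _read_manifest(config: StudyConfig) -> pd.DataFrame | None:
    if config.samples_tsv is None:
        return None
    return pd.read_csv(config.samples_tsv, sep="\t").set_index("sample")


def _stage_community(config: StudyConfig, outdir: Path, state, report) -> None:
    if config.asv_table is None:
        raise CesdynError("community stage needs asv_table")
    report.input_checksums["asv_table"] = _sha256(config.asv_table)
    manifest = _read_manifest(config)
    table = cio.read_asv_table(config.asv_table, sample_metadata=manifest)
    table = cm.filter_asv_table(table, min_total_reads=2)
    genus_rel = cm.genus_top_abundance(table, n=config.top_genera)
    genus_rel.to_csv(outdir / "genus_abundance.tsv", sep="\t",
                     float_format="%.10g")
    shannon = {s: cm.shannon(table.counts[s][table.counts[s] > 0])
               for s in table.samples}
    dm = cm.bray_curtis(table)
    cio.write_distance_matrix(dm, outdir / "bray_curtis.tsv")
    ord_res = cm.pcoa(dm)
    ord_res.coordinates.to_csv(outdir / "pcoa_coordinates.tsv", sep="\t",
                               float_format="%.10g")
    payload: dict = {"shannon_nats": shannon,
                     "n_asvs_after_filter": len(table.asv_ids)}
    if manifest is not None and "time_point" in manifest.columns:
        groups = [manifest.loc[s, "time_point"] for s in table.samples]
        perma = cm.permanova(dm, groups, config.n_permutations,
                             seed=config.seed)
        disp = cm.beta_dispersion(dm, groups, config.n_permutations,
                                  seed=config.seed)
        payload["permanova"] = {
            "pseudo_F": perma.pseudo_f, "r_squared": perma.r_squared,
            "p_value": perma.p_value,
            "n_permutations": perma.n_permutations, "seed": config.seed}
        payload["beta_dispersion"] = {
            "f_statistic": disp.f_statistic, "p_value": disp.p_value,
            "group_mean_distances": disp.group_means,
            "n_permutations": disp.n_permutations, "seed": config.seed}
        report.warnings.extend(disp.warnings)
    payload["pcoa_proportion_explained"] = \
        ord_res.proportion_explained[:3].tolist()
    cio.write_json(payload, outdir / "community_tests.json")
    state["community_table"] = table
    state["community_genus_rel"] = genus_rel
    state["community_shannon"] = shannon
    state["community_dm"] = dm
    report.stages["community"] = payload


def _stage_couple(config: StudyConfig, outdir: Path, state, report) -> None:
    if "dom_assigned" not in state or "community_table" not in state:
        raise CesdynError("couple stage requires dom and community stages")
    assigned = state["dom_assigned"]
    genus_rel = state["community_genus_rel"]
    manifest = _read_manifest(config)

    bins = cp.dom_series_bins(assigned, bin_width=config.bin_width,
                              mass_range=config.mass_range)
    grid = cp.genus_dom_correlation_grid(genus_rel, bins,
                                         threshold=config.rho_threshold)
    shown = grid.displayed()
    shown.columns = [f"{s}_{int(b)}" for s, b in shown.columns]
    shown.to_csv(outdir / "correlation_grid.tsv", sep="\t",
                 float_format="%.10g")

    shared = [s for s in genus_rel.columns if s in bins.columns]
    payload: dict = {}
    if len(shared) >= 4:
        dm_genus = cm.bray_curtis(genus_rel[shared])
        dm_dom = cp.profile_distance_matrix(bins[shared])
        man = cp.mantel(dm_genus, dm_dom, n_permutations=config.n_permutations,
                        seed=config.seed)
        payload["mantel"] = {
            "rho": man.rho, "p_value": man.p_value, "method": man.method,
            "n_permutations": man.n_permutations, "seed": config.seed}

    # NOSC distributions pooled per time point, all pairs compared
    if manifest is not None and "time_point" in manifest.columns:
        nosc: dict[str, list[float]] = {}
        for sample, peaks in assigned.items():
            if sample not in manifest.index:
                continue
            tp = manifest.loc[sample, "time_point"]
            nosc.setdefault(tp, []).extend(
                a.descriptors.nosc for a in peaks)
        tps = list(nosc)
        ks = {}
        for i, a in enumerate(tps):
            for b in tps[i + 1:]:
                res = cp.ks_two_sample(nosc[a], nosc[b])
                ks[f"{a}_vs_{b}"] = {"D": res.d_statistic,
                                     "p_value": res.p_value,
                                     "n": [res.n_x, res.n_y]}
        payload["ks_nosc"] = ks

    shannon = state.get("community_shannon", {})
    chem = {s: state["dom_summary"][s]["chemodiversity_nats"]
            for s in state.get("dom_summary", {})}
    paired = sorted(set(shannon) & set(chem))
    if len(paired) >= 3:
        fit = cp.diversity_fit([shannon[s] for s in paired],
                               [chem[s] for s in paired])
        payload["diversity_fit"] = {
            "pairs": paired,
            "linear": {"slope": fit.linear_slope,
                       "intercept": fit.linear_intercept,
                       "r_squared": fit.linear_r_squared, "p": fit.linear_p},
            "logarithmic": {"a": fit.log_a, "b": fit.log_b,
                            "r_squared": fit.log_r_squared, "p": fit.log_p},
            "preferred": fit.preferred,
        }
    cio.write_json(payload, outdir / "coupling_tests.json")
    report.stages["couple"] = payload
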