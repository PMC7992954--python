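"""Config-driven end-to-end runs: simulate → quantify → report.

A run is described by a YAML config with per-stage parameter blocks and a
single master seed; every stage derives its own seed from the master one,
so the whole run is a pure function of (config, seed).  Each output CSV
carries header comments with the tool version, a hash of the resolved
config, and the seed.  Stage failures abort the run with the stage name;
files already written by the failing stage are renamed with a
``.partial`` suffix.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .assays import delta_ct_fold_change, fit_4pl, normalize_viability, sensitivity_ratio
from .errors import StageError, ValidationError
from .growth import aggregate_index, fit_growth_rate, fructolytic_index, index_table
from .imaging import SegmentationConfig, compute_competition_trace
from .synthetic import (
    CellFieldSpec,
    CompetitionModel,
    GrowthModel,
    generate_competition_images,
    generate_confluency_series,
    generate_ct_table,
    generate_dose_response,
    generate_isotopologue_table,
)
from .tracer import compute_fractions, natural_abundance_correct, summarize_labeling

__all__ = ["RunConfig", "RunReport", "run_pipeline", "demo_config"]

log = logging.getLogger("fructolyze")

_SCHEMA: dict[str, set[str] | None] = {
    "output_dir": None,
    "seed": None,
    "log_level": None,
    "stages": None,
    "synthetic": {"growth", "competition", "dose_response", "qpcr", "tracer"},
    "imaging": {
        "small_cutoff", "large_cutoff", "threshold_method", "invert", "h",
        "min_area", "max_area", "red_threshold_factor",
    },
    "growth": {"epsilon", "window_h", "threshold"},
    "assays": {"welch"},
    "tracer": {"correct_na", "p13c"},
}

_SYNTH_KEYS = {
    "growth": {
        "cell_lines", "initial_pct", "interval_h", "duration_h", "noise_sd",
        "n_replicates",
    },
    "competition": {
        "f0", "r1", "r2", "times_h", "n0_cells", "field_size", "radius_mean",
        "radius_sd", "noise_sd", "touching_fraction",
    },
    "dose_response": {
        "ic50_glucose_mm", "ic50_fructose_mm", "hill", "bottom", "top",
        "concentrations_mm", "noise_sd", "n_replicates",
    },
    "qpcr": {"fold_changes", "noise_sd", "n_samples"},
    "tracer": {"fractions", "noise_sd", "n_replicates", "intensity_scale"},
}


@dataclass
class RunConfig:
    """Validated run configuration (see ``demo_config()`` for the shape)."""

    raw: dict
    path: Path | None = None

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ValidationError(f"config file not found: {path}")
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(raw=raw, path=path)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for key, sub in self.raw.items():
            if key not in _SCHEMA:
                raise ValidationError(f"unknown config key: {key!r}")
            allowed = _SCHEMA[key]
            if allowed is not None and isinstance(sub, dict):
                for k in sub:
                    if k not in allowed:
                        raise ValidationError(f"unknown config key: {key}.{k!r}")
        for name, sub in (self.raw.get("synthetic") or {}).items():
            for k in sub or {}:
                if k not in _SYNTH_KEYS[name]:
                    raise ValidationError(
                        f"unknown config key: synthetic.{name}.{k!r}"
                    )

    @property
    def seed(self) -> int:
        return int(self.raw.get("seed", 0))

    @property
    def output_dir(self) -> Path:
        return Path(self.raw.get("output_dir", "fructolyze_out"))

    def section(self, name: str) -> dict:
        return dict(self.raw.get(name) or {})

    def config_hash(self) -> str:
        canon = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _stage_seed(master: int, offset: int) -> int:
    return int((master * 10007 + offset) % (2**31 - 1))


@dataclass
class RunReport:
    config_hash: str
    seed: int
    stages: dict[str, dict] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": __version__,
                "config_hash": self.config_hash,
                "seed": self.seed,
                "stages": self.stages,
                "warnings": self.warnings,
                "outputs": self.outputs,
            },
            indent=2,
        )


def demo_config(output_dir: str = "demo_out", seed: int = 1) -> dict:
    """A small, fast end-to-end configuration exercising every stage."""
    return {
        "output_dir": output_dir,
        "seed": seed,
        "synthetic": {
            "growth": {
                "cell_lines": {
                    "HepG2": {"fructose": 1.8, "glucose": 2.0, "no_sugar": 0.2},
                    "PC3": {"fructose": 0.25, "glucose": 2.0, "no_sugar": 0.2},
                },
                "initial_pct": 5.0,
                "interval_h": 2.0,
                "duration_h": 40.0,
                "noise_sd": 0.5,
                "n_replicates": 3,
            },
            "competition": {
                "f0": 0.5,
                "r1": 0.05,
                "r2": 0.0,
                "times_h": [0.0, 24.0, 48.0],
                "n0_cells": 16,
                "field_size": 384,
                "radius_mean": 6.0,
                "radius_sd": 0.7,
                "noise_sd": 2.0,
                "touching_fraction": 0.05,
            },
            "dose_response": {
                "ic50_glucose_mm": 20.0,
                "ic50_fructose_mm": 2.0,
                "hill": 1.0,
                "bottom": 0.0,
                "top": 1.0,
                "concentrations_mm": [0.0, 0.4, 1.1, 3.0, 8.1, 22.0, 60.0, 163.0],
                "noise_sd": 0.05,
                "n_replicates": 3,
            },
            "qpcr": {
                "fold_changes": {"SLC2A5": 200.0, "KHK": 1.0},
                "noise_sd": 0.1,
                "n_samples": 3,
            },
            "tracer": {
                "fractions": {
                    "parental": {
                        "fructose": [0.9, 0, 0, 0, 0, 0, 0.1],
                        "lactate": [0.97, 0, 0, 0.03],
                    },
                    "trained": {
                        "fructose": [0.35, 0, 0, 0, 0, 0, 0.65],
                        "lactate": [0.45, 0, 0, 0.55],
                    },
                },
                "noise_sd": 0.05,
                "n_replicates": 3,
            },
        },
        "imaging": {"min_area": 20, "large_cutoff": 48.0},
        "growth": {"epsilon": 0.05, "threshold": 0.2},
        "tracer": {"correct_na": False, "p13c": 0.0107},
    }


def _seg_config(imaging_block: dict) -> SegmentationConfig:
    return SegmentationConfig(**imaging_block)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages in dependency order and write the run report."""
    outdir = config.output_dir
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    seed = config.seed
    report = RunReport(config_hash=chash, seed=seed)
    synth = config.section("synthetic")

    def _write(df: pd.DataFrame, name: str, stage_files: list) -> Path:
        path = io.write_table(df, outdir / name, __version__, chash, seed)
        stage_files.append(path)
        report.outputs.append(str(path))
        return path

    def _run_stage(name, fn):
        files: list[Path] = []
        try:
            info = fn(files)
            report.stages[name] = info
            log.info("stage %s: %s", name, info)
        except Exception as err:
            for f in files:
                if f.exists():
                    f.rename(f.with_suffix(f.suffix + ".partial"))
            raise StageError(name, str(err)) from err

    # ---- simulate ------------------------------------------------------
    conf_rows: list[pd.DataFrame] = []
    comp_series_holder: dict = {}

    def simulate(files):
        counts = {}
        g = synth.get("growth")
        if g:
            rows = []
            rep_seed = _stage_seed(seed, 11)
            for line, rates in g["cell_lines"].items():
                for rep in range(int(g.get("n_replicates", 3))):
                    for cond, rate in rates.items():
                        rep_seed += 1
                        model = GrowthModel(
                            initial_pct=float(g.get("initial_pct", 10.0)),
                            rate_pct_per_h=float(rate),
                            interval_h=float(g.get("interval_h", 2.0)),
                            duration_h=float(g.get("duration_h", 72.0)),
                            noise_sd=float(g.get("noise_sd", 0.5)),
                            seed=rep_seed,
                        )
                        s = generate_confluency_series(
                            model, condition=cond, well=f"{line}-{cond}-r{rep}",
                            cell_line=line, concentration_mm=10.0,
                        )
                        rows.append(
                            pd.DataFrame(
                                {
                                    "well": s.well,
                                    "cell_line": s.cell_line,
                                    "condition": s.condition,
                                    "concentration_mm": s.concentration_mm,
                                    "replicate": rep,
                                    "hours": s.times_h,
                                    "confluency_pct": s.confluency_pct,
                                }
                            )
                        )
            conf = pd.concat(rows, ignore_index=True)
            conf_rows.append(conf)
            _write(conf, "synthetic_confluency.csv", files)
            counts["confluency_rows"] = len(conf)
        comp = synth.get("competition")
        if comp:
            model = CompetitionModel(
                f0=float(comp.get("f0", 0.5)),
                r1=float(comp.get("r1", 0.05)),
                r2=float(comp.get("r2", 0.0)),
                times_h=tuple(comp.get("times_h", (0.0, 24.0, 48.0))),
                n0_cells=int(comp.get("n0_cells", 16)),
            )
            spec = CellFieldSpec(
                field_size=int(comp.get("field_size", 384)),
                radius_mean=float(comp.get("radius_mean", 6.0)),
                radius_sd=float(comp.get("radius_sd", 0.7)),
                noise_sd=float(comp.get("noise_sd", 2.0)),
                touching_fraction=float(comp.get("touching_fraction", 0.0)),
                seed=_stage_seed(seed, 23),
            )
            series, truth = generate_competition_images(model, spec)
            comp_series_holder["series"] = series
            img_dir = outdir / "competition_images"
            io.write_image_series(series, img_dir)
            _write(truth, "synthetic_competition_truth.csv", files)
            counts["competition_timepoints"] = len(series)
        dr = synth.get("dose_response")
        if dr:
            tables = []
            for sugar, key in (("glucose", "ic50_glucose_mm"),
                               ("fructose", "ic50_fructose_mm")):
                tables.append(
                    generate_dose_response(
                        bottom=float(dr.get("bottom", 0.0)),
                        top=float(dr.get("top", 1.0)),
                        ic50_mm=float(dr[key]),
                        hill=float(dr.get("hill", 1.0)),
                        concentrations_mm=np.asarray(dr["concentrations_mm"]),
                        noise_sd=float(dr.get("noise_sd", 0.05)),
                        n_replicates=int(dr.get("n_replicates", 3)),
                        sugar=sugar,
                        seed=_stage_seed(seed, 31 if sugar == "glucose" else 32),
                    )
                )
            plate = pd.concat(tables, ignore_index=True)
            _write(plate, "synthetic_viability.csv", files)
            counts["viability_rows"] = len(plate)
        q = synth.get("qpcr")
        if q:
            ct = generate_ct_table(
                fold_changes={k: float(v) for k, v in q["fold_changes"].items()},
                noise_sd=float(q.get("noise_sd", 0.1)),
                n_samples=int(q.get("n_samples", 3)),
                seed=_stage_seed(seed, 41),
            )
            _write(ct, "synthetic_ct.csv", files)
            counts["ct_rows"] = len(ct)
        tr = synth.get("tracer")
        if tr:
            iso = generate_isotopologue_table(
                {
                    g: {m: np.asarray(f, dtype=float) for m, f in mets.items()}
                    for g, mets in tr["fractions"].items()
                },
                noise_sd=float(tr.get("noise_sd", 0.05)),
                n_replicates=int(tr.get("n_replicates", 3)),
                intensity_scale=float(tr.get("intensity_scale", 1e6)),
                seed=_stage_seed(seed, 51),
            )
            _write(iso, "synthetic_isotopologues.csv", files)
            counts["isotopologue_rows"] = len(iso)
        return counts

    _run_stage("simulate", simulate)

    # ---- count (competition trace) -------------------------------------
    if comp_series_holder:

        def count(files):
            cfg = _seg_config(config.section("imaging"))
            trace = compute_competition_trace(comp_series_holder["series"], cfg)
            _write(trace.to_frame(), "competition_trace.csv", files)
            return {"timepoints": len(trace.times_h)}

        _run_stage("count", count)

    # ---- fructolytic index ---------------------------------------------
    if conf_rows:

        def index(files):
            gcfg = config.section("growth")
            eps = float(gcfg.get("epsilon", 0.05))
            conf = conf_rows[0]
            summaries = []
            for line, ldf in conf.groupby("cell_line"):
                reps = []
                for rep, rdf in ldf.groupby("replicate"):
                    rates = {}
                    for cond, cdf in rdf.groupby("condition"):
                        cdf = cdf.sort_values("hours")
                        from .growth import ConfluencyTimeSeries

                        rates[cond] = fit_growth_rate(
                            ConfluencyTimeSeries(
                                times_h=cdf["hours"].to_numpy(),
                                confluency_pct=cdf["confluency_pct"].to_numpy(),
                                condition=cond,
                                cell_line=line,
                            )
                        )
                    reps.append(
                        fructolytic_index(
                            rates["fructose"], rates["glucose"], rates["no_sugar"],
                            epsilon=eps,
                        )
                    )
                summaries.append(aggregate_index(reps, cell_line=str(line)))
            _write(index_table(summaries), "fructolytic_index.csv", files)
            return {"cell_lines": len(summaries)}

        _run_stage("index", index)

    # ---- ic50 ----------------------------------------------------------
    if synth.get("dose_response"):

        def ic50(files):
            plate = io.read_table(outdir / "synthetic_viability.csv")
            rows = []
            curves = {}
            for sugar, sdf in plate.groupby("sugar"):
                v = normalize_viability(
                    sdf["viability"].to_numpy(), sdf["concentration_mm"].to_numpy()
                )
                curve = fit_4pl(sdf["concentration_mm"].to_numpy(), v, sugar=sugar)
                curves[sugar] = curve
                if not curve.converged:
                    report.warnings.append(f"4PL fit did not converge for {sugar}")
                rows.append(
                    {
                        "sugar": sugar,
                        "bottom": curve.bottom,
                        "top": curve.top,
                        "ic50_mm": curve.ic50_mm,
                        "hill": curve.hill,
                        "residual_ss": curve.residual_ss,
                        "converged": curve.converged,
                    }
                )
            out = pd.DataFrame(rows)
            if {"glucose", "fructose"} <= set(curves):
                out["sensitivity_ratio_glc_over_fru"] = sensitivity_ratio(
                    curves["glucose"], curves["fructose"]
                )
            _write(out, "ic50.csv", files)
            return {"curves": len(rows)}

        _run_stage("ic50", ic50)

    # ---- qpcr ----------------------------------------------------------
    if synth.get("qpcr"):

        def qpcr(files):
            ct = io.read_table(outdir / "synthetic_ct.csv")
            folds = delta_ct_fold_change(ct, reference_group="parental")
            _write(folds, "qpcr_fold_change.csv", files)
            return {"genes": folds["gene"].nunique()}

        _run_stage("qpcr", qpcr)

    # ---- tracer --------------------------------------------------------
    if synth.get("tracer"):

        def tracer(files):
            tcfg = config.section("tracer")
            iso = io.read_table(outdir / "synthetic_isotopologues.csv")
            frac = compute_fractions(iso)
            if tcfg.get("correct_na", False):
                frac = natural_abundance_correct(
                    frac, p13c=float(tcfg.get("p13c", 0.0107))
                )
            _write(frac, "tracer_fractions.csv", files)
            summaries = []
            target_k = {"fructose": 6, "F1P": 6, "lactate": 3}
            for met in frac["metabolite"].unique():
                k = target_k.get(met, int(frac[frac["metabolite"] == met]
                                          ["isotopologue"].max()))
                s = summarize_labeling(frac, met, k)
                for g in sorted(s.group_means):
                    summaries.append(
                        {
                            "metabolite": met,
                            "isotopologue": k,
                            "group": g,
                            "mean_fraction": s.group_means[g],
                            "sem_fraction": s.group_sems[g],
                            "mean_abundance": s.abundance_means[g],
                            "p_fraction": (
                                s.fraction_test.p_value if s.fraction_test else np.nan
                            ),
                        }
                    )
            _write(pd.DataFrame(summaries), "tracer_summary.csv", files)
            return {"metabolites": frac["metabolite"].nunique()}

        _run_stage("tracer", tracer)

    (outdir / "run_report.json").write_text(report.to_json())
    return report
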