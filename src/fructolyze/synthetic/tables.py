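"""Synthetic tabular assay data with known ground truth.

Each generator emulates one of the study's tabular inputs — live-cell
confluency curves, 2-DG viability dilution series, LC/MS isotopologue
intensities, and qPCR Ct tables — under an explicit generative model, so
every downstream estimator has an exact recovery target.

Noise forms follow standard assay behaviour: additive Gaussian on
confluency, viability, and Ct; multiplicative lognormal on MS
intensities.  Confluency grows linearly (the analysis readout is a
linear-regression slope, so the generator's null satisfies the analysis
model exactly); a logistic option is available as a stress test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..assays import four_pl
from ..errors import ParameterError, ValidationError
from ..growth import ConfluencyTimeSeries
from ..tracer import BUILTIN_FORMULAS, carbon_count, convolve_natural_abundance

__all__ = [
    "GrowthModel",
    "generate_confluency_series",
    "generate_dose_response",
    "generate_isotopologue_table",
    "generate_ct_table",
]


@dataclass(frozen=True)
class GrowthModel:
    """Linear confluency growth: C(t) = clip(C0 + r·t + ε, 0, 100)."""

    initial_pct: float = 10.0
    rate_pct_per_h: float = 1.0
    interval_h: float = 2.0
    duration_h: float = 72.0
    noise_sd: float = 0.5
    logistic: bool = False  # stress-test variant, capacity 100%
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.initial_pct <= 100.0:
            raise ParameterError("initial confluency must be in [0, 100]%")
        if self.duration_h <= 0 or self.interval_h <= 0:
            raise ParameterError("duration and interval must be > 0")


def generate_confluency_series(
    model: GrowthModel,
    condition: str = "no_sugar",
    concentration_mm: float = 0.0,
    well: str = "A1",
    cell_line: str = "",
) -> ConfluencyTimeSeries:
    """One well's confluency time series under the given sugar condition."""
    rng = np.random.default_rng(model.seed)
    t = np.arange(0.0, model.duration_h + 0.5 * model.interval_h, model.interval_h)
    if model.logistic:
        c0 = max(model.initial_pct, 1e-3)
        k = model.rate_pct_per_h / max(c0, 1e-9)  # matched initial slope
        mean = 100.0 / (1.0 + (100.0 / c0 - 1.0) * np.exp(-k * t))
    else:
        mean = model.initial_pct + model.rate_pct_per_h * t
    noise = rng.normal(0.0, model.noise_sd, t.size) if model.noise_sd > 0 else 0.0
    conf = np.clip(mean + noise, 0.0, 100.0)
    return ConfluencyTimeSeries(
        times_h=t,
        confluency_pct=conf,
        well=well,
        cell_line=cell_line,
        condition=condition,
        concentration_mm=concentration_mm,
    )


def generate_dose_response(
    bottom: float,
    top: float,
    ic50_mm: float,
    hill: float,
    concentrations_mm: np.ndarray,
    noise_sd: float = 0.0,
    n_replicates: int = 1,
    sugar: str = "",
    seed: int = 0,
) -> pd.DataFrame:
    """Viability table from a 4PL curve plus additive Gaussian noise.

    Returns long-format rows (concentration_mm, sugar, replicate,
    viability); concentrations may include the zero-drug anchor.
    """
    c = np.asarray(concentrations_mm, dtype=float)
    if np.any(c < 0):
        raise ParameterError("concentrations must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    truth = four_pl(c, bottom, top, ic50_mm, hill)
    for rep in range(n_replicates):
        noise = rng.normal(0.0, noise_sd, c.size) if noise_sd > 0 else 0.0
        v = truth + noise
        for ci, vi in zip(c, v):
            rows.append(
                {"concentration_mm": ci, "sugar": sugar, "replicate": rep,
                 "viability": vi}
            )
    return pd.DataFrame(rows)


def generate_isotopologue_table(
    fractions_by_group: dict[str, dict[str, np.ndarray]],
    formulas: dict[str, str] | None = None,
    intensity_scale: float = 1e6,
    noise_sd: float = 0.0,
    n_replicates: int = 3,
    convolve_p13c: float | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Long-format isotopologue intensity table.

    ``fractions_by_group`` maps group → metabolite → true M+0..M+C
    fraction vector (must sum to 1 within 1e-6, length C+1).  Intensities
    are scale × fraction × lognormal(0, noise_sd) noise, optionally after
    convolution with natural 13C abundance ``convolve_p13c``.
    """
    formulas = {**BUILTIN_FORMULAS, **(formulas or {})}
    rng = np.random.default_rng(seed)
    rows = []
    for group, mets in fractions_by_group.items():
        for met, frac in mets.items():
            frac = np.asarray(frac, dtype=float)
            if met not in formulas:
                raise ValidationError(f"no formula for metabolite {met!r}")
            c = carbon_count(formulas[met])
            if frac.size != c + 1:
                raise ValidationError(
                    f"{met}: need {c + 1} fractions (C={c}), got {frac.size}"
                )
            if abs(frac.sum() - 1.0) > 1e-6:
                raise ValidationError(f"{met}: fractions must sum to 1")
            emitted = frac
            if convolve_p13c is not None:
                emitted = convolve_natural_abundance(frac, c, convolve_p13c)
            for rep in range(n_replicates):
                if noise_sd > 0:
                    noise = rng.lognormal(0.0, noise_sd, emitted.size)
                else:
                    noise = 1.0
                intens = intensity_scale * emitted * noise
                for k in range(c + 1):
                    rows.append(
                        {
                            "metabolite": met,
                            "formula": formulas[met],
                            "group": group,
                            "replicate": rep,
                            "isotopologue": k,
                            "intensity": float(np.atleast_1d(intens)[k]),
                        }
                    )
    return pd.DataFrame(rows)


def generate_ct_table(
    fold_changes: dict[str, float],
    reference_group: str = "parental",
    treated_group: str = "trained",
    control_gene: str = "ACTB",
    control_ct: float = 18.0,
    noise_sd: float = 0.0,
    n_samples: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """qPCR Ct table programmed so ΔΔCt recovers the given fold changes.

    Expression in the reference group is 1 (gene Ct = control Ct); in the
    treated group it is the programmed fold, so gene Ct = control Ct −
    log2(fold) + Gaussian noise.  Returns rows (sample, group, gene, ct,
    is_control).
    """
    for gene, fold in fold_changes.items():
        if fold <= 0:
            raise ParameterError(f"fold change for {gene!r} must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    for group, expr_of in (
        (reference_group, lambda f: 1.0),
        (treated_group, lambda f: f),
    ):
        for i in range(n_samples):
            sample = f"{group}_{i + 1}"
            rows.append(
                {
                    "sample": sample,
                    "group": group,
                    "gene": control_gene,
                    "ct": control_ct + float(rng.normal(0.0, noise_sd)) if noise_sd > 0 else control_ct,
                    "is_control": True,
                }
            )
            for gene, fold in fold_changes.items():
                ct = control_ct - np.log2(expr_of(fold))
                if noise_sd > 0:
                    ct += float(rng.normal(0.0, noise_sd))
                rows.append(
                    {
                        "sample": sample,
                        "group": group,
                        "gene": gene,
                        "ct": float(ct),
                        "is_control": False,
                    }
                )
    return pd.DataFrame(rows)
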