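"""Isotopologue distribution analysis for 13C tracer experiments.

Feeding cells uniformly 13C-labeled fructose and measuring metabolites by
LC/MS yields, per metabolite, an intensity for each mass isotopologue
M+0 … M+C (C = number of carbons).  Fully labeled hexoses appear as M+6
and glycolytic lactate as M+3.  This module computes isotopologue
fractions, optionally deconvolves the contribution of naturally occurring
13C (~1.07% of carbon), and summarizes the labeled fraction per group
with an unpaired t test between groups.

Natural-abundance model: if the true distribution is x and each of the
remaining 12C atoms of an M+i species independently happens to be 13C
with probability p, the observed distribution is M_obs = A·x with the
lower-triangular binomial matrix A[i+j, i] = C(C−i, j) p^j (1−p)^(C−i−j).
Correction solves this system by forward substitution.  Only carbon is
corrected; H/O/N isotope effects are ignored (a documented limitation,
adequate for carbon-skeleton tracing).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from pyteomics.mass import Composition

from .assays import TTestResult, compare_two_groups
from .errors import ParameterError, ValidationError

__all__ = [
    "BUILTIN_FORMULAS",
    "carbon_count",
    "compute_fractions",
    "convolve_natural_abundance",
    "natural_abundance_correct",
    "summarize_labeling",
    "LabeledSummary",
]

DEFAULT_P13C = 0.0107

# Metabolites named in the tracing readouts plus common TCA intermediates;
# extensible by passing extra {name: formula} entries to the readers.
BUILTIN_FORMULAS: dict[str, str] = {
    "fructose": "C6H12O6",
    "glucose": "C6H12O6",
    "fructose 1-phosphate": "C6H13O9P",
    "F1P": "C6H13O9P",
    "lactate": "C3H6O3",
    "pyruvate": "C3H4O3",
    "citrate": "C6H8O7",
    "alpha-ketoglutarate": "C5H6O5",
    "succinate": "C4H6O4",
    "fumarate": "C4H4O4",
    "malate": "C4H6O5",
    "oxaloacetate": "C4H4O5",
}


def carbon_count(formula: str) -> int:
    """Number of carbon atoms in a molecular formula such as C6H12O6."""
    n = Composition(formula=formula).get("C", 0)
    if n < 1:
        raise ParameterError(f"formula {formula!r} has no carbon")
    return int(n)


_REQUIRED = ["metabolite", "formula", "group", "replicate", "isotopologue", "intensity"]


def _check_table(table: pd.DataFrame) -> None:
    missing = [c for c in _REQUIRED if c not in table.columns]
    if missing:
        raise ValidationError(f"isotopologue table missing columns: {missing}")
    if (table["intensity"] < 0).any():
        raise ValidationError("intensities must be >= 0")


def compute_fractions(table: pd.DataFrame) -> pd.DataFrame:
    """Add per-record ``fraction`` and ``total_abundance`` columns.

    fraction(M+k) = intensity(M+k) / Σ_k intensity; the total is the sum
    over isotopologues within one (metabolite, group, replicate) record.
    Records whose intensities are all zero are rejected.
    """
    _check_table(table)
    out = table.copy()
    keys = ["metabolite", "group", "replicate"]
    totals = out.groupby(keys)["intensity"].transform("sum")
    if (totals <= 0).any():
        bad = out.loc[totals <= 0, keys].drop_duplicates()
        raise ValidationError(
            f"all-zero intensities for records: {bad.to_dict('records')}"
        )
    out["fraction"] = out["intensity"] / totals
    out["total_abundance"] = totals
    # structural check: C+1 isotopologues per record
    for (met, _, _), grp in out.groupby(keys):
        c = carbon_count(grp["formula"].iloc[0])
        idx = np.sort(grp["isotopologue"].to_numpy())
        if len(idx) != c + 1 or not np.array_equal(idx, np.arange(c + 1)):
            raise ValidationError(
                f"{met}: expected isotopologues M+0..M+{c}, got {idx.tolist()}"
            )
    return out


def _binomial_matrix(n_carbons: int, p: float) -> np.ndarray:
    c = n_carbons
    a = np.zeros((c + 1, c + 1))
    for i in range(c + 1):
        for j in range(c - i + 1):
            a[i + j, i] = comb(c - i, j) * p**j * (1.0 - p) ** (c - i - j)
    return a


def convolve_natural_abundance(
    fractions: np.ndarray, n_carbons: int, p: float = DEFAULT_P13C
) -> np.ndarray:
    """Forward model: observed distribution A·x given true fractions x."""
    x = np.asarray(fractions, dtype=float)
    if x.size != n_carbons + 1:
        raise ParameterError("fractions length must be carbon count + 1")
    return _binomial_matrix(n_carbons, p) @ x


def _correct_vector(obs: np.ndarray, n_carbons: int, p: float) -> np.ndarray:
    a = _binomial_matrix(n_carbons, p)
    x = np.zeros_like(obs, dtype=float)
    # forward substitution on the lower-triangular system
    for k in range(n_carbons + 1):
        x[k] = (obs[k] - a[k, :k] @ x[:k]) / a[k, k]
    if (x < -0.01).any():
        warnings.warn(
            "natural-abundance correction produced a large negative fraction; "
            "data inconsistent with the binomial model"
        )
    x = np.where((x < 0) & (x > -1e-6), 0.0, x)
    x = np.clip(x, 0.0, None) if (x < 0).any() else x
    s = x.sum()
    return x / s if s > 0 else x


def natural_abundance_correct(
    table: pd.DataFrame, p13c: float = DEFAULT_P13C
) -> pd.DataFrame:
    """Deconvolve natural 13C abundance from measured fractions.

    Requires ``fraction`` (run :func:`compute_fractions` first).  Small
    negative solutions (> −1e−6, numerical noise) are clipped to zero and
    the vector renormalized.  ``p13c`` must lie in [0, 0.5); at 0 the
    correction is the identity.
    """
    if not 0.0 <= p13c < 0.5:
        raise ParameterError("13C abundance must be in [0, 0.5)")
    if "fraction" not in table.columns:
        table = compute_fractions(table)
    out = table.copy()
    keys = ["metabolite", "group", "replicate"]
    for _, grp in out.groupby(keys):
        c = carbon_count(grp["formula"].iloc[0])
        ordered = grp.sort_values("isotopologue")
        corrected = _correct_vector(ordered["fraction"].to_numpy(), c, p13c)
        out.loc[ordered.index, "fraction"] = corrected
    return out


@dataclass(frozen=True)
class LabeledSummary:
    """Per-group labeling summary for one metabolite and isotopologue."""

    metabolite: str
    isotopologue: int
    group_means: dict[str, float]  # mean fraction M+k per group
    group_sems: dict[str, float]
    abundance_means: dict[str, float]  # mean total intensity per group
    abundance_sems: dict[str, float]
    fraction_test: TTestResult | None  # two-group comparison, else None
    abundance_test: TTestResult | None


def _mean_sem(values: np.ndarray) -> tuple[float, float]:
    m = float(values.mean())
    s = float(values.std(ddof=1) / np.sqrt(values.size)) if values.size > 1 else float("nan")
    return m, s


def summarize_labeling(
    table: pd.DataFrame,
    metabolite: str,
    isotopologue: int,
    groups: tuple[str, str] | None = None,
) -> LabeledSummary:
    """Group means ± SEM of fraction M+k and total abundance, with an
    unpaired two-tailed t test between two groups.

    ``groups`` selects the pair to compare (e.g. parental vs trained);
    with exactly two groups in the table it defaults to them, and with a
    single group no test is reported.
    """
    if "fraction" not in table.columns:
        table = compute_fractions(table)
    sub = table[table["metabolite"] == metabolite]
    if sub.empty:
        raise ValidationError(f"metabolite {metabolite!r} not in table")
    c = carbon_count(sub["formula"].iloc[0])
    if not 0 <= isotopologue <= c:
        raise ParameterError(f"isotopologue M+{isotopologue} exceeds carbon count {c}")
    sel = sub[sub["isotopologue"] == isotopologue]
    g_means, g_sems, a_means, a_sems = {}, {}, {}, {}
    frac_by_group, abund_by_group = {}, {}
    for g, grp in sel.groupby("group"):
        fr = grp["fraction"].to_numpy(dtype=float)
        ab = grp["total_abundance"].to_numpy(dtype=float)
        frac_by_group[g], abund_by_group[g] = fr, ab
        g_means[g], g_sems[g] = _mean_sem(fr)
        a_means[g], a_sems[g] = _mean_sem(ab)
    names = sorted(frac_by_group)
    ftest = atest = None
    if groups is None and len(names) == 2:
        groups = (names[0], names[1])
    if groups is not None:
        missing = [g for g in groups if g not in frac_by_group]
        if missing:
            raise ValidationError(f"groups not in table: {missing}")
        a, b = groups
        if len(frac_by_group[a]) >= 2 and len(frac_by_group[b]) >= 2:
            ftest = compare_two_groups(frac_by_group[a], frac_by_group[b])
            atest = compare_two_groups(abund_by_group[a], abund_by_group[b])
    return LabeledSummary(
        metabolite=metabolite,
        isotopologue=isotopologue,
        group_means=g_means,
        group_sems=g_sems,
        abundance_means=a_means,
        abundance_sems=a_sems,
        fraction_test=ftest,
        abundance_test=atest,
    )
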