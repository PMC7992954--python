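"""Dose-response fitting, qPCR quantification, and the study's statistics.

2-DG sensitivity: viability (ATP luminescence normalized to zero-drug
wells of the same sugar condition) versus inhibitor concentration is fit
with the four-parameter logistic

    v(c) = bottom + (top - bottom) / (1 + (c / IC50)^hill)

whose midpoint parameter is the (relative) IC50.  The sensitivity ratio
IC50_glucose / IC50_fructose exceeds 1 when cells in fructose are the
more 2-DG-sensitive — the signature of fructose flux through hexokinase.

qPCR: comparative ΔCt quantification with amplification efficiency fixed
at 2.  ΔCt = Ct_gene − mean Ct of the flagged endogenous-control genes
per sample; ΔΔCt = group mean ΔCt − reference group mean ΔCt; fold
change = 2^(−ΔΔCt).  The same arithmetic on genomic DNA against a
single-copy reference gene and a calibrator sample yields copy-number
ratios.

Hypothesis tests: Student's unpaired two-tailed t test (Welch via flag),
and a fixed-effects cell-means two-way ANOVA whose residual mean square
feeds Fisher's-LSD pairwise t tests (no multiplicity adjustment, by
definition of LSD).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import InsufficientDataError, ParameterError, ValidationError

__all__ = [
    "DoseResponseCurve",
    "TTestResult",
    "LsdResult",
    "normalize_viability",
    "fit_4pl",
    "sensitivity_ratio",
    "delta_ct_fold_change",
    "copy_number_ratio",
    "compare_two_groups",
    "cellmeans_anova_lsd",
]


# ---------------------------------------------------------------- dose-response

def four_pl(c: np.ndarray, bottom: float, top: float, ic50: float, hill: float):
    """Four-parameter logistic evaluated at concentrations ``c``."""
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(c > 0, (c / ic50) ** hill, 0.0 if hill > 0 else np.inf)
    return bottom + (top - bottom) / (1.0 + ratio)


@dataclass
class DoseResponseCurve:
    """Fitted 4PL curve for one sugar condition."""

    concentrations_mm: np.ndarray
    viability: np.ndarray
    sugar: str = ""
    bottom: float = np.nan
    top: float = np.nan
    ic50_mm: float = np.nan
    hill: float = np.nan
    residual_ss: float = np.nan
    converged: bool = False

    def predict(self, c) -> np.ndarray:
        return four_pl(c, self.bottom, self.top, self.ic50_mm, self.hill)


def normalize_viability(signal: np.ndarray, concentrations: np.ndarray) -> np.ndarray:
    """Fold change in viability: each well over the mean zero-drug well."""
    concentrations = np.asarray(concentrations, dtype=float)
    signal = np.asarray(signal, dtype=float)
    anchor = signal[concentrations == 0]
    if anchor.size == 0:
        raise ValidationError("no zero-drug anchor wells present")
    return signal / anchor.mean()


def _init_4pl(c: np.ndarray, v: np.ndarray) -> tuple[float, float, float, float]:
    bottom0, top0 = float(np.min(v)), float(np.max(v))
    mid = 0.5 * (bottom0 + top0)
    pos = c > 0
    if pos.any():
        order = np.argsort(c[pos])
        cp, vp = c[pos][order], v[pos][order]
        idx = int(np.argmin(np.abs(vp - mid)))
        ic50_0 = float(cp[idx]) if cp[idx] > 0 else float(np.median(cp))
    else:
        ic50_0 = 1.0
    # decreasing curves have hill > 0 under this parameterization
    slope_sign = 1.0 if v[np.argsort(c)][0] >= v[np.argsort(c)][-1] else -1.0
    return bottom0, top0, ic50_0, slope_sign


def fit_4pl(
    concentrations_mm: np.ndarray,
    viability: np.ndarray,
    sugar: str = "",
) -> DoseResponseCurve:
    """Least-squares 4PL fit with log-scale IC50 handling.

    Requires >= 5 distinct concentrations.  Initial values come from the
    data extremes and the dose nearest half-maximum; IC50 is fit on the
    log scale for stability across serially diluted designs.  Monotone
    flat data (no transition: range below 1% of the top) is rejected;
    optimizer failure is reported with ``converged=False``.
    """
    c = np.asarray(concentrations_mm, dtype=float)
    v = np.asarray(viability, dtype=float)
    if c.size != v.size:
        raise ParameterError("concentration/viability lengths differ")
    if np.any(c < 0):
        raise ParameterError("concentrations must be >= 0")
    if np.unique(c).size < 5:
        raise InsufficientDataError("need >= 5 distinct concentrations")
    if np.ptp(v) < 0.01 * max(abs(np.max(v)), 1e-12):
        raise ValidationError("flat viability data: no dose-response transition")

    b0, t0, ic0, h0 = _init_4pl(c, v)

    def model(cc, bottom, top, log_ic50, hill):
        return four_pl(cc, bottom, top, np.exp(log_ic50), hill)

    curve = DoseResponseCurve(concentrations_mm=c, viability=v, sugar=sugar)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = optimize.curve_fit(
                model,
                c,
                v,
                p0=[b0, t0, np.log(ic0), h0],
                maxfev=20000,
                xtol=1e-12,
                ftol=1e-12,
            )
    except (RuntimeError, optimize.OptimizeWarning):
        return curve
    bottom, top, log_ic50, hill = popt
    if hill < 0:  # canonical form: swap plateaus so hill > 0, same curve
        bottom, top, hill = top, bottom, -hill
    resid = v - four_pl(c, bottom, top, np.exp(log_ic50), hill)
    curve.bottom = float(bottom)
    curve.top = float(top)
    curve.ic50_mm = float(np.exp(log_ic50))
    curve.hill = float(hill)
    curve.residual_ss = float(np.sum(resid**2))
    curve.converged = bool(np.isfinite(popt).all())
    return curve


def sensitivity_ratio(
    glucose_curve: DoseResponseCurve, fructose_curve: DoseResponseCurve
) -> float:
    """IC50_glucose / IC50_fructose; > 1 means more 2-DG-sensitive in
    fructose.  NaN when either fit did not converge."""
    if not (glucose_curve.converged and fructose_curve.converged):
        return float("nan")
    return glucose_curve.ic50_mm / fructose_curve.ic50_mm


# ----------------------------------------------------------------------- qPCR

_CT_COLS = ["sample", "group", "gene", "ct", "is_control"]
LOW_CONFIDENCE_CT = 30.0


def _check_ct(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _CT_COLS if c not in records.columns]
    if missing:
        raise ValidationError(f"Ct table missing columns: {missing}")
    if not np.isfinite(records["ct"]).all():
        raise ValidationError("Ct values must be finite")
    return records


def delta_ct_fold_change(
    records: pd.DataFrame, reference_group: str
) -> pd.DataFrame:
    """Comparative-ΔCt fold changes per gene and group.

    Returns one row per (gene, group) with ``delta_ct_mean``,
    ``delta_ct_sem``, ``ddct``, ``fold_change`` (= 2^−ΔΔCt relative to
    ``reference_group``) and a delta-method ``fold_sem``.  Genes with any
    Ct above 30 are marked ``low_confidence``.
    """
    records = _check_ct(records)
    if reference_group not in set(records["group"]):
        raise ValidationError(f"reference group {reference_group!r} absent")
    controls = records[records["is_control"]]
    ctrl_by_sample = controls.groupby("sample")["ct"].mean()
    targets = records[~records["is_control"]].copy()
    missing = set(targets["sample"]) - set(ctrl_by_sample.index)
    if missing:
        raise ValidationError(f"samples lacking a control gene: {sorted(missing)}")
    targets["delta_ct"] = targets["ct"] - targets["sample"].map(ctrl_by_sample)

    rows = []
    for gene, gdf in targets.groupby("gene"):
        ref = gdf[gdf["group"] == reference_group]["delta_ct"]
        if ref.empty:
            raise ValidationError(f"gene {gene!r} missing from reference group")
        ref_mean = ref.mean()
        ref_sem = ref.std(ddof=1) / np.sqrt(len(ref)) if len(ref) > 1 else 0.0
        for group, grp in gdf.groupby("group"):
            dct = grp["delta_ct"].to_numpy(dtype=float)
            m = dct.mean()
            sem = dct.std(ddof=1) / np.sqrt(dct.size) if dct.size > 1 else 0.0
            ddct = m - ref_mean
            fold = 2.0 ** (-ddct)
            fold_sem = fold * np.log(2.0) * np.sqrt(sem**2 + ref_sem**2)
            rows.append(
                {
                    "gene": gene,
                    "group": group,
                    "n": dct.size,
                    "delta_ct_mean": m,
                    "delta_ct_sem": sem,
                    "ddct": ddct,
                    "fold_change": fold,
                    "fold_sem": fold_sem,
                    "low_confidence": bool((grp["ct"] > LOW_CONFIDENCE_CT).any()),
                }
            )
    return pd.DataFrame(rows)


def copy_number_ratio(
    records: pd.DataFrame, reference_gene: str, calibrator_sample: str
) -> pd.DataFrame:
    """Relative copy number from genomic-DNA qPCR.

    ΔCt = Ct_target − Ct_reference per sample (reference = single-copy
    control gene); ΔΔCt is taken against the calibrator sample and the
    ratio is 2^(−ΔΔCt), so the calibrator is 1 by construction.
    """
    needed = ["sample", "gene", "ct"]
    missing = [c for c in needed if c not in records.columns]
    if missing:
        raise ValidationError(f"gDNA table missing columns: {missing}")
    samples = set(records["sample"])
    if calibrator_sample not in samples:
        raise ValidationError(f"calibrator sample {calibrator_sample!r} absent")
    ref = records[records["gene"] == reference_gene].groupby("sample")["ct"].mean()
    targets = records[records["gene"] != reference_gene]
    if targets.empty:
        raise ValidationError("no target gene rows")
    rows = []
    for gene, gdf in targets.groupby("gene"):
        per_sample = gdf.groupby("sample")["ct"].mean()
        lacking = set(per_sample.index) - set(ref.index)
        if lacking or calibrator_sample not in per_sample.index:
            raise ValidationError(
                f"gene {gene!r}: samples missing reference/calibrator Cts"
            )
        dct = per_sample - ref.loc[per_sample.index]
        ddct = dct - dct.loc[calibrator_sample]
        for sample, val in ddct.items():
            rows.append(
                {"gene": gene, "sample": sample, "copy_ratio": 2.0 ** (-val)}
            )
    return pd.DataFrame(rows)


# ------------------------------------------------------------------ statistics

@dataclass(frozen=True)
class TTestResult:
    statistic: float
    p_value: float
    df: float
    degenerate: bool = False


def compare_two_groups(
    a: np.ndarray, b: np.ndarray, welch: bool = False
) -> TTestResult:
    """Unpaired two-tailed t test (Student's pooled-variance by default).

    Zero pooled variance is handled explicitly: equal means give p = 1,
    unequal means give p = 0 with the ``degenerate`` flag set.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs n >= 2")
    df = a.size + b.size - 2
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return TTestResult(0.0, 1.0, df, degenerate=True)
        return TTestResult(np.inf if a.mean() > b.mean() else -np.inf, 0.0, df,
                           degenerate=True)
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return TTestResult(float(res.statistic), float(res.pvalue), float(res.df))


@dataclass
class LsdResult:
    """Two-way cell-means ANOVA with Fisher's-LSD pairwise comparisons."""

    anova: pd.DataFrame  # source, ss, df, ms, F, p
    comparisons: pd.DataFrame  # cell_a, cell_b, diff, t, p
    mse: float
    residual_df: int
    cell_means: dict = field(default_factory=dict)


def cellmeans_anova_lsd(
    data: pd.DataFrame,
    factor_a: str,
    factor_b: str,
    value: str,
    comparisons: list[tuple[tuple, tuple]] | None = None,
) -> LsdResult:
    """Fixed-effects two-way ANOVA (with interaction) and Fisher's LSD.

    Every (factor_a, factor_b) cell needs >= 2 replicates.  The residual
    mean square pools the within-cell variance over all cells; each
    pairwise LSD comparison between cell means (i, j) is

        t = (ȳ_i − ȳ_j) / sqrt(MSE (1/n_i + 1/n_j)),  df = N − #cells

    with a two-sided p and, per the LSD definition, no multiplicity
    adjustment.  ``comparisons`` restricts the pairs; the default is all
    pairs of cells.  The ANOVA table (type-I SS on the balanced cell-means
    layout) is returned alongside.
    """
    for col in (factor_a, factor_b, value):
        if col not in data.columns:
            raise ValidationError(f"missing column {col!r}")
    levels_a = sorted(data[factor_a].unique())
    levels_b = sorted(data[factor_b].unique())
    if len(levels_a) < 2 or len(levels_b) < 2:
        raise ValidationError("need >= 2 levels per factor")
    cells: dict[tuple, np.ndarray] = {}
    for la in levels_a:
        for lb in levels_b:
            vals = data[(data[factor_a] == la) & (data[factor_b] == lb)][value]
            if len(vals) < 2:
                raise ValidationError(f"cell ({la}, {lb}) has < 2 replicates")
            cells[(la, lb)] = vals.to_numpy(dtype=float)

    n_total = sum(v.size for v in cells.values())
    k = len(cells)
    grand = np.concatenate(list(cells.values())).mean()
    ss_resid = sum(((v - v.mean()) ** 2).sum() for v in cells.values())
    df_resid = n_total - k
    mse = ss_resid / df_resid

    # factor and interaction SS (unweighted means on the cell layout)
    mean_a = {la: np.concatenate([cells[(la, lb)] for lb in levels_b]).mean()
              for la in levels_a}
    mean_b = {lb: np.concatenate([cells[(la, lb)] for la in levels_a]).mean()
              for lb in levels_b}
    n_a = {la: sum(cells[(la, lb)].size for lb in levels_b) for la in levels_a}
    n_b = {lb: sum(cells[(la, lb)].size for la in levels_a) for lb in levels_b}
    ss_a = sum(n_a[la] * (mean_a[la] - grand) ** 2 for la in levels_a)
    ss_b = sum(n_b[lb] * (mean_b[lb] - grand) ** 2 for lb in levels_b)
    ss_cells = sum(
        v.size * (v.mean() - grand) ** 2 for v in cells.values()
    )
    ss_ab = ss_cells - ss_a - ss_b
    df_a, df_b = len(levels_a) - 1, len(levels_b) - 1
    df_ab = df_a * df_b

    def _f_row(name, ss, df):
        ms = ss / df if df > 0 else np.nan
        if mse > 0:
            f = ms / mse
            p = float(stats.f.sf(f, df, df_resid))
        else:
            f, p = (np.inf, 0.0) if ss > 0 else (np.nan, 1.0)
        return {"source": name, "ss": ss, "df": df, "ms": ms, "F": f, "p": p}

    anova = pd.DataFrame(
        [
            _f_row(factor_a, ss_a, df_a),
            _f_row(factor_b, ss_b, df_b),
            _f_row(f"{factor_a}:{factor_b}", ss_ab, df_ab),
            {"source": "residual", "ss": ss_resid, "df": df_resid,
             "ms": mse, "F": np.nan, "p": np.nan},
        ]
    )

    if comparisons is None:
        comparisons = list(itertools.combinations(sorted(cells), 2))
    rows = []
    for ca, cb in comparisons:
        if ca not in cells or cb not in cells:
            raise ValidationError(f"unknown cell in comparison: {ca} vs {cb}")
        va, vb = cells[ca], cells[cb]
        diff = va.mean() - vb.mean()
        if mse > 0:
            t = diff / np.sqrt(mse * (1.0 / va.size + 1.0 / vb.size))
            p = float(2.0 * stats.t.sf(abs(t), df_resid))
        else:
            t, p = (0.0, 1.0) if diff == 0 else (np.inf * np.sign(diff), 0.0)
        rows.append({"cell_a": ca, "cell_b": cb, "diff": diff, "t": t, "p": p})
    comp = pd.DataFrame(rows)
    return LsdResult(
        anova=anova,
        comparisons=comp,
        mse=float(mse),
        residual_df=int(df_resid),
        cell_means={c: float(v.mean()) for c, v in cells.items()},
    )
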