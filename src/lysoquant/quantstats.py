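"""Non-image quantification and statistics on nested per-cell data.

Covers the ratiometric lysosomal pH calibration (linear 440/535-ratio
standard curve over the clamped 3.5-7.0 range, fitted ratio-on-pH and
inverted), cytosol-over-lysosome enzyme-activity normalization, the
optical-fractionator stereology estimate, DAB staining area-fraction
normalization, and the statistical comparisons appropriate for
cells-nested-within-animals designs: two-way fixed-effects ANOVA with
Tukey HSD, the unpaired two-tailed t-test, and a nested t-test in which
the animal — not the cell — is the independent unit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import ValidationError

__all__ = [
    "CalibrationCurve",
    "StatResult",
    "fit_ph_curve",
    "ratio_to_ph",
    "normalize_cytosolic_activity",
    "percent_of_control",
    "fractionator_estimate",
    "dab_area_fraction",
    "two_way_anova",
    "nested_t",
    "unpaired_t",
    "aggregate_per_animal",
    "kruskal_dunn",
]


@dataclass
class CalibrationCurve:
    """Linear ratiometric pH standard curve: ratio = slope*pH + intercept."""

    slope: float
    intercept: float
    fit_range_ph: tuple[float, float]
    residual_sd: float
    n_points: int

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValidationError("slope: flat curve is not invertible")
        lo, hi = self.fit_range_ph
        if not (3.0 <= lo <= hi <= 8.0):
            raise ValidationError("fit_range_ph must lie within [3.0, 8.0]")

    def predict_ratio(self, ph) -> np.ndarray:
        return self.slope * np.asarray(ph, dtype=float) + self.intercept


@dataclass
class StatResult:
    effect: str
    statistic: float
    df: tuple[float, float] | tuple[float]
    p_value: float
    posthoc: Optional[pd.DataFrame] = None
    info: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# pH calibration

def fit_ph_curve(table: pd.DataFrame) -> CalibrationCurve:
    """Ordinary least squares of emission ratio on calibration pH.

    The table needs ``ph`` and ``ratio`` columns with at least three
    distinct pH levels spanning one pH unit or more.  The curve is fitted
    ratio-on-pH (pH is the controlled, clamped variable; the ratio carries
    the noise) and inverted at read-out time.
    """
    if not {"ph", "ratio"}.issubset(table.columns):
        raise ValidationError("calibration table needs 'ph' and 'ratio' columns")
    ph = table["ph"].to_numpy(dtype=float)
    ratio = table["ratio"].to_numpy(dtype=float)
    levels = np.unique(ph)
    if levels.size < 3:
        raise ValidationError("need >= 3 distinct calibration pH levels")
    if levels.max() - levels.min() < 1.0:
        raise ValidationError("calibration levels must span >= 1 pH unit")
    slope, intercept = np.polyfit(ph, ratio, 1)
    resid = ratio - (slope * ph + intercept)
    dof = max(len(ph) - 2, 1)
    return CalibrationCurve(
        slope=float(slope),
        intercept=float(intercept),
        fit_range_ph=(float(levels.min()), float(levels.max())),
        residual_sd=float(np.sqrt((resid**2).sum() / dof)),
        n_points=int(len(ph)),
    )


def ratio_to_ph(
    curve: CalibrationCurve, ratio: float, warn_extrapolation: bool = True
) -> float:
    """Invert the standard curve: pH = (ratio - intercept) / slope.

    Values outside the calibration range are returned but flagged with a
    warning rather than rejected.
    """
    ph = (float(ratio) - curve.intercept) / curve.slope
    lo, hi = curve.fit_range_ph
    if warn_extrapolation and not (lo <= ph <= hi):
        warnings.warn(
            f"pH {ph:.2f} lies outside the calibration range [{lo}, {hi}] "
            "(extrapolated)",
            stacklevel=2,
        )
    return ph


# ---------------------------------------------------------------------------
# scalar estimators

def normalize_cytosolic_activity(cytosolic: float, lysosomal: float) -> float:
    """Cytosolic enzyme activity corrected by the lysosomal-fraction activity."""
    if lysosomal <= 0:
        raise ValidationError("lysosomal activity must be positive")
    if cytosolic < 0:
        raise ValidationError("cytosolic activity must be >= 0")
    return cytosolic / lysosomal


def percent_of_control(values: Sequence[float], control_mean: float) -> np.ndarray:
    """Rescale measurements to percent of a control-group mean."""
    if control_mean <= 0:
        raise ValidationError("control mean must be positive")
    return 100.0 * np.asarray(values, dtype=float) / control_mean


def fractionator_estimate(
    sum_counted: int,
    section_fraction: float,
    area_fraction: float = 1.0,
    thickness_fraction: float = 1.0,
) -> float:
    """Optical-fractionator total: counted objects over the sampling fractions.

    N = sum_counted / (ssf * asf * tsf), the unbiased stereological estimate
    of the total object number from systematic sampling (e.g. 1-of-4 serial
    sections gives ssf = 1/4).
    """
    if sum_counted < 0:
        raise ValidationError("sum_counted must be >= 0")
    for name, f in (
        ("section_fraction", section_fraction),
        ("area_fraction", area_fraction),
        ("thickness_fraction", thickness_fraction),
    ):
        if not 0 < f <= 1:
            raise ValidationError(f"{name} must lie in (0, 1]")
    return sum_counted / (section_fraction * area_fraction * thickness_fraction)


def dab_area_fraction(
    stain_mask_area: float,
    roi_area: float,
    contralateral_fraction: float,
    control_mean_fraction: float,
) -> float:
    """DAB staining burden, contralateral-normalized, in percent of control.

    100 * (stain/roi / contralateral_fraction) / control_mean_fraction.
    Scale-invariant in the areas: only the stained fraction matters.
    """
    if roi_area <= 0:
        raise ValidationError("roi_area must be positive")
    if contralateral_fraction <= 0:
        raise ValidationError("contralateral_fraction must be positive")
    if control_mean_fraction <= 0:
        raise ValidationError("control_mean_fraction must be positive")
    if stain_mask_area < 0:
        raise ValidationError("stain_mask_area must be >= 0")
    return 100.0 * (stain_mask_area / roi_area / contralateral_fraction) / control_mean_fraction


# ---------------------------------------------------------------------------
# statistics

def _check_records(records: pd.DataFrame, cols: Sequence[str]) -> None:
    missing = set(cols) - set(records.columns)
    if missing:
        raise ValidationError(f"records missing columns: {sorted(missing)}")


def two_way_anova(
    records: pd.DataFrame,
    value: str = "value",
    factor_a: str = "factor_a",
    factor_b: str = "factor_b",
    method: Literal["auto", "balanced", "regression"] = "auto",
    tukey: bool = False,
) -> list[StatResult]:
    """Two-way fixed-effects ANOVA with optional Tukey HSD post hoc.

    For balanced designs the classic sums-of-squares decomposition is used
    (SSA, SSB, SSAB, SSE with the usual dfs); unbalanced designs fall back
    to a regression (type-II) fit via statsmodels.  The Tukey table compares
    the a*b cell-of-design means using the studentized-range distribution
    with the ANOVA residual df.
    """
    _check_records(records, [value, factor_a, factor_b])
    y = records[value].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValidationError("values must be finite")
    fa = records[factor_a].astype(str).to_numpy()
    fb = records[factor_b].astype(str).to_numpy()
    a_levels = np.unique(fa)
    b_levels = np.unique(fb)
    if a_levels.size < 2 or b_levels.size < 2:
        raise ValidationError("each factor needs >= 2 levels")

    counts = records.groupby([factor_a, factor_b], observed=True).size()
    full = a_levels.size * b_levels.size
    if len(counts) < full or counts.min() < 1:
        raise ValidationError(
            "empty design cell: use method='regression' with a complete model "
            "or collect data for every factor combination"
        )
    balanced = counts.nunique() == 1

    if method == "auto":
        method = "balanced" if balanced else "regression"
    if method == "balanced" and not balanced:
        raise ValidationError(
            "design is unbalanced: use method='regression' (type-II SS)"
        )

    if method == "balanced":
        results = _anova_balanced(y, fa, fb, a_levels, b_levels)
    elif method == "regression":
        results = _anova_regression(records, value, factor_a, factor_b)
    else:
        raise ValidationError(f"unknown ANOVA method {method!r}")

    if tukey:
        results[0].posthoc = _tukey_cells(y, fa, fb)
        for r in results:
            r.info["posthoc"] = "tukey_hsd_on_design_cells"
    return results


def _anova_balanced(y, fa, fb, a_levels, b_levels) -> list[StatResult]:
    """Classic balanced-design SS decomposition (hand-rolled, exact)."""
    a_n, b_n = a_levels.size, b_levels.size
    n_tot = y.size
    n_cell = n_tot // (a_n * b_n)
    grand = y.mean()
    a_means = np.array([y[fa == a].mean() for a in a_levels])
    b_means = np.array([y[fb == b].mean() for b in b_levels])
    ss_a = b_n * n_cell * ((a_means - grand) ** 2).sum()
    ss_b = a_n * n_cell * ((b_means - grand) ** 2).sum()
    ss_e = 0.0
    ss_ab = 0.0
    for i, a in enumerate(a_levels):
        for j, b in enumerate(b_levels):
            cell = y[(fa == a) & (fb == b)]
            cm = cell.mean()
            ss_e += ((cell - cm) ** 2).sum()
            ss_ab += n_cell * (cm - a_means[i] - b_means[j] + grand) ** 2
    df_a, df_b = a_n - 1, b_n - 1
    df_ab = df_a * df_b
    df_e = n_tot - a_n * b_n
    if df_e < 1:
        raise ValidationError("need > 1 observation per design cell")
    ms_e = ss_e / df_e
    out = []
    for name, ss, df in (
        ("factor_a", ss_a, df_a),
        ("factor_b", ss_b, df_b),
        ("interaction", ss_ab, df_ab),
    ):
        if ms_e == 0:
            f_val, p = (0.0, 1.0) if ss == 0 else (math.inf, 0.0)
        else:
            f_val = (ss / df) / ms_e
            p = float(stats.f.sf(f_val, df, df_e))
        out.append(
            StatResult(
                effect=name,
                statistic=float(f_val),
                df=(float(df), float(df_e)),
                p_value=p,
                info={"ss": float(ss), "ms_error": float(ms_e), "method": "balanced"},
            )
        )
    return out


def _anova_regression(records, value, factor_a, factor_b) -> list[StatResult]:
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = records.rename(columns={value: "_y", factor_a: "_a", factor_b: "_b"})
    model = smf.ols("_y ~ C(_a) * C(_b)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    mapping = {"C(_a)": "factor_a", "C(_b)": "factor_b", "C(_a):C(_b)": "interaction"}
    out = []
    df_e = float(table.loc["Residual", "df"])
    for row, name in mapping.items():
        out.append(
            StatResult(
                effect=name,
                statistic=float(table.loc[row, "F"]),
                df=(float(table.loc[row, "df"]), df_e),
                p_value=float(table.loc[row, "PR(>F)"]),
                info={"method": "regression_type2"},
            )
        )
    return out


def _tukey_cells(y, fa, fb) -> pd.DataFrame:
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    labels = np.char.add(np.char.add(fa.astype(str), ":"), fb.astype(str))
    res = pairwise_tukeyhsd(y, labels)
    frame = pd.DataFrame(
        res.summary().data[1:], columns=[str(c) for c in res.summary().data[0]]
    )
    return frame.rename(
        columns={"group1": "level_1", "group2": "level_2", "meandiff": "difference",
                 "p-adj": "p_adjusted"}
    )


def nested_t(
    records: pd.DataFrame,
    value: str = "value",
    group: str = "group",
    animal: str = "animal",
    group_pair: Optional[tuple[str, str]] = None,
    weights: Literal["equal", "cells"] = "equal",
) -> StatResult:
    """Two-group comparison with cells nested within animals.

    Cell-level values are first averaged within each animal, then the two
    groups of animal means are compared by an unpaired two-tailed t-test
    with df = n_animals - 2.  For balanced data this equals the mixed-model
    nested t; unbalanced data are handled by weighting animal means equally
    (``weights='equal'``, the default) or by their cell counts.
    """
    _check_records(records, [value, group, animal])
    groups = sorted(records[group].astype(str).unique())
    if group_pair is None:
        if len(groups) != 2:
            raise ValidationError("nested_t compares exactly two groups; pass group_pair")
        group_pair = (groups[0], groups[1])
    sub = records[records[group].astype(str).isin(group_pair)]
    per_animal = aggregate_per_animal(sub, value=value, group=group, animal=animal)
    means, ns = [], []
    for g in group_pair:
        ga = per_animal[per_animal[group] == g]
        if len(ga) < 2:
            raise ValidationError(f"group {g!r} needs >= 2 animals")
        means.append(ga["mean"].to_numpy(dtype=float))
        ns.append(len(ga))
    if weights == "cells":
        m = [per_animal[per_animal[group] == g] for g in group_pair]
        return _weighted_t(m[0], m[1])
    if np.ptp(means[0]) == 0 and np.ptp(means[1]) == 0:
        if means[0].mean() != means[1].mean():
            raise ValidationError(
                "zero between-animal variance with unequal means: t undefined"
            )
        t_val, p = 0.0, 1.0
    else:
        t_val, p = stats.ttest_ind(means[0], means[1])
    df_val = ns[0] + ns[1] - 2
    return StatResult(
        effect=f"{group_pair[0]} vs {group_pair[1]} (nested)",
        statistic=float(t_val),
        df=(float(df_val),),
        p_value=float(p),
        info={"n_animals": tuple(ns), "weights": weights},
    )


def _weighted_t(ga: pd.DataFrame, gb: pd.DataFrame) -> StatResult:
    """Animal means weighted by their cell counts (documented alternative)."""

    def _wstats(g):
        w = g["n_cells"].to_numpy(dtype=float)
        x = g["mean"].to_numpy(dtype=float)
        wm = np.average(x, weights=w)
        n = len(x)
        var = np.average((x - wm) ** 2, weights=w) * n / (n - 1)
        return wm, var, n

    m1, v1, n1 = _wstats(ga)
    m2, v2, n2 = _wstats(gb)
    sp = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    t_val = (m1 - m2) / math.sqrt(sp * (1 / n1 + 1 / n2))
    df_val = n1 + n2 - 2
    p = 2 * stats.t.sf(abs(t_val), df_val)
    return StatResult(
        effect="nested (cell-weighted)",
        statistic=float(t_val),
        df=(float(df_val),),
        p_value=float(p),
        info={"weights": "cells"},
    )


def unpaired_t(values_a: Sequence[float], values_b: Sequence[float]) -> StatResult:
    """Classic unpaired two-tailed Student t-test (pooled variance)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each sample needs >= 2 values")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() != b.mean():
        raise ValidationError("zero pooled variance with unequal means: t undefined")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return StatResult(
            effect="unpaired t",
            statistic=0.0,
            df=(float(a.size + b.size - 2),),
            p_value=1.0,
        )
    t_val, p = stats.ttest_ind(a, b)
    return StatResult(
        effect="unpaired t",
        statistic=float(t_val),
        df=(float(a.size + b.size - 2),),
        p_value=float(p),
    )


def aggregate_per_animal(
    records: pd.DataFrame,
    value: str = "value",
    group: str = "group",
    animal: str = "animal",
) -> pd.DataFrame:
    """Mean and cell count per animal — the unit-of-analysis reduction."""
    _check_records(records, [value, group, animal])
    out = (
        records.groupby([group, animal], observed=True)[value]
        .agg(["mean", "size"])
        .reset_index()
        .rename(columns={"size": "n_cells"})
    )
    return out


def kruskal_dunn(
    records: pd.DataFrame,
    value: str = "value",
    group: str = "group",
    p_adjust: Literal["bonferroni", "none"] = "bonferroni",
) -> StatResult:
    """Kruskal-Wallis omnibus test with Dunn-style pairwise z comparisons.

    A thin rank-based one-way alternative for non-normal measurements; the
    pairwise z statistics use mean ranks from the pooled ranking with the
    large-sample normal approximation and optional Bonferroni adjustment.
    """
    _check_records(records, [value, group])
    groups = sorted(records[group].astype(str).unique())
    if len(groups) < 2:
        raise ValidationError("need >= 2 groups")
    samples = [records.loc[records[group].astype(str) == g, value].to_numpy() for g in groups]
    h_stat, p = stats.kruskal(*samples)
    all_vals = np.concatenate(samples)
    n_tot = all_vals.size
    ranks = stats.rankdata(all_vals)
    # tie correction factor for the Dunn variance
    _, tie_counts = np.unique(all_vals, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n_tot - 1))
    offsets = np.cumsum([0] + [s.size for s in samples])
    mean_ranks = [
        ranks[offsets[i]: offsets[i + 1]].mean() for i in range(len(samples))
    ]
    rows = []
    n_pairs = len(groups) * (len(groups) - 1) // 2
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = math.sqrt(
                (n_tot * (n_tot + 1) / 12.0 - tie_term)
                * (1.0 / samples[i].size + 1.0 / samples[j].size)
            )
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p_pair = 2 * stats.norm.sf(abs(z))
            if p_adjust == "bonferroni":
                p_pair = min(1.0, p_pair * n_pairs)
            rows.append(
                {
                    "level_1": groups[i],
                    "level_2": groups[j],
                    "z": z,
                    "p_adjusted": p_pair,
                }
            )
    return StatResult(
        effect="kruskal-wallis",
        statistic=float(h_stat),
        df=(float(len(groups) - 1),),
        p_value=float(p),
        posthoc=pd.DataFrame(rows),
        info={"p_adjust": p_adjust},
    )
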