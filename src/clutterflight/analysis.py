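"""The experiment's inference layer on the per-flight metrics table.

Covers: normality transforms of each response, Levene variance-
homogeneity checks, the eight-model variance-structure search (the
homoskedastic base plus every non-empty subset of {wind, direction,
field height} as varIdent strata, ranked by REML AIC), the three-model
altitude-definition comparison (continuous altitude-above-floor crossed
with field height, continuous altitude-above-obstacles, and the
categorical above/within route, ranked by ML AIC since the fixed
effects differ), estimated-marginal-mean contrasts with Tukey
studentized-range adjustment, and first-versus-last paired t-tests per
wind stratum.

The canonical metrics table has one row per kept flight with columns
``bee_id, flight_number, wind, direction, wind_class, field_height,
altitude_floor, altitude_range, altitude_obstacle, route, ground_speed,
lateral_excursion, speed_change, min_clearance, collision``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import stats

from .mixedlm import HeteroskedasticLMM, HeteroskedasticLMMResults

#: Response transform applied before model fitting, per metric.
TRANSFORMS = {
    "altitude_floor": ("square", lambda x: x ** 2),
    "altitude_range": ("log10", np.log10),
    "ground_speed": ("log10", np.log10),
    "lateral_excursion": ("cbrt", np.cbrt),
}

VARIANCE_FACTORS = ("wind", "direction", "field_height")


def transform_response(values, metric_name: str) -> np.ndarray:
    """Apply the metric's normality transform (identity if unlisted)."""
    values = np.asarray(values, dtype=float)
    if metric_name not in TRANSFORMS:
        return values
    name, fn = TRANSFORMS[metric_name]
    if name == "log10" and np.any(values <= 0):
        bad = int(np.flatnonzero(values <= 0)[0])
        raise ValueError(
            f"{metric_name}: non-positive value at row {bad} cannot be "
            f"log10-transformed")
    return fn(values)


def levene_test(values, groups, center: str = "mean"):
    """Levene's variance-homogeneity test across groups.

    Classic form uses absolute deviations from the group mean
    (``center="median"`` gives the Brown-Forsythe variant).  Returns
    ``(statistic, p_value)``.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    samples = [values[groups == g] for g in np.unique(groups)]
    if len(samples) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    stat, p = stats.levene(*samples, center=center)
    return float(stat), float(p)


@dataclass(frozen=True)
class ModelSpec:
    """One LMM to fit: response (pre-transform metric name), fixed-effects
    formula right-hand side, and variance strata (None = homoskedastic)."""

    response: str
    fixed: str
    variance_strata: tuple[str, ...] | None = None
    transform: bool = True

    @property
    def label(self) -> str:
        strata = "+".join(self.variance_strata) if self.variance_strata else "homoskedastic"
        return f"{self.response} ~ {self.fixed} | varIdent({strata})"


def fit_lmm(data: pd.DataFrame, spec: ModelSpec,
            method: str = "reml") -> HeteroskedasticLMMResults:
    """Fit one :class:`ModelSpec` on the metrics table."""
    df = data.copy()
    resp = f"_t_{spec.response}"
    df[resp] = (transform_response(df[spec.response], spec.response)
                if spec.transform else df[spec.response])
    model = HeteroskedasticLMM.from_formula(
        f"{resp} ~ {spec.fixed}", df, groups="bee_id",
        variance_strata=list(spec.variance_strata) if spec.variance_strata else None)
    return model.fit(method=method)


ALTITUDE_FORMULA = "wind * direction * C(field_height)"


def candidate_variance_models(data: pd.DataFrame, response: str,
                              fixed: str = ALTITUDE_FORMULA,
                              factors=VARIANCE_FACTORS):
    """The homoskedastic base model plus its seven varIdent updates.

    All eight share the fixed effects, so they are ranked by REML AIC,
    ascending; fit failures are recorded and skipped in the ranking.
    """
    specs = [ModelSpec(response, fixed, None)]
    for r in range(1, len(factors) + 1):
        for combo in itertools.combinations(factors, r):
            specs.append(ModelSpec(response, fixed, combo))
    fits, failures = [], []
    for spec in specs:
        try:
            fits.append((spec, fit_lmm(data, spec, method="reml")))
        except Exception as exc:  # ranking proceeds on successes
            failures.append((spec, repr(exc)))
    fits.sort(key=lambda sf: sf[1].aic)
    return fits, failures


#: The three altitude definitions entered into candidate performance models.
ALTITUDE_DEFINITIONS = {
    "floor_x_height": "altitude_floor * C(field_height) + altitude_floor * wind * direction",
    "obstacle": "altitude_obstacle * wind * direction",
    "route": "route * wind * direction",
}


def candidate_altitude_models(data: pd.DataFrame, performance_metric: str):
    """Fit the three performance models differing in their altitude term.

    Returns ``[(definition, ModelSpec, fit), ...]`` ranked by ML AIC
    (fixed effects differ between candidates, so REML AICs are not
    comparable); each fit also carries its REML twin criteria via
    ``fit.aic`` of a REML refit if wanted.
    """
    out = []
    for name, fixed in ALTITUDE_DEFINITIONS.items():
        spec = ModelSpec(performance_metric, fixed, None)
        out.append((name, spec, fit_lmm(data, spec, method="ml")))
    out.sort(key=lambda t: t[2].aic)
    return out


def marginal_contrasts(fit: HeteroskedasticLMMResults, factor: str,
                       adjust: str = "tukey") -> pd.DataFrame:
    """Pairwise contrasts of estimated marginal means for one factor.

    Marginal means average the model predictions over the observed
    levels of every other categorical term (equal weight per level) at
    the mean of any continuous covariate.  The Tukey adjustment uses the
    studentized-range distribution at containment denominator df.
    """
    model = fit.model
    if model.design_info is None or model.data is None:
        raise ValueError("marginal_contrasts needs a formula-built model")
    data = model.data
    if factor not in data.columns:
        raise ValueError(f"factor {factor!r} not in model data")
    factor_cols = [c for c in data.columns
                   if data[c].dtype == object or str(data[c].dtype) == "category"
                   or c in ("field_height",)]
    used = [c for c in factor_cols
            if any(c in name for name in model.exog_names) or c == factor]
    if factor not in used:
        raise ValueError(f"factor {factor!r} does not appear in the model")
    grid_axes = {c: sorted(data[c].unique()) for c in used}
    grid = pd.DataFrame(
        [dict(zip(grid_axes, combo))
         for combo in itertools.product(*grid_axes.values())])
    for c in data.columns:  # continuous covariates at their mean
        if c not in grid.columns and np.issubdtype(np.asarray(data[c]).dtype, np.number):
            grid[c] = float(np.mean(data[c]))
    (X_grid,) = patsy.build_design_matrices([model.design_info], grid)
    X_grid = np.asarray(X_grid)

    levels = grid_axes[factor]
    emm_rows = {lv: X_grid[(grid[factor] == lv).to_numpy()].mean(axis=0)
                for lv in levels}
    k = len(levels)
    rows = []
    for a, b in itertools.combinations(levels, 2):
        L = emm_rows[a] - emm_rows[b]
        est = float(L @ fit.params)
        se = float(np.sqrt(L @ fit.cov_params @ L))
        cols = list(np.flatnonzero(np.abs(L) > 1e-12))
        df = model.containment_df(cols)
        t = est / se
        if adjust == "tukey" and k > 2:
            p = float(stats.studentized_range.sf(abs(t) * np.sqrt(2.0), k, df))
        else:
            p = 2.0 * float(stats.t.sf(abs(t), df))
        rows.append({"contrast": f"{a} - {b}", "estimate": est, "se": se,
                     "t_ratio": t, "df": df, "p_adjusted": min(p, 1.0)})
    return pd.DataFrame(rows)


FIRST_LAST_METRICS = ("altitude_floor", "ground_speed", "lateral_excursion")


def first_last_paired_test(metrics: pd.DataFrame,
                           metric_names=FIRST_LAST_METRICS) -> pd.DataFrame:
    """Paired t-tests of each bee's first vs last flight, per wind stratum.

    Wind covaries with flight number in the block design, so still-air
    and windy flights are tested separately.  Strata with fewer than two
    contributing bees are skipped with a warning row (t/p = NaN).
    """
    rows = []
    for wind_level, sub in metrics.groupby("wind"):
        firsts = sub.sort_values("flight_number").groupby("bee_id").first()
        lasts = sub.sort_values("flight_number").groupby("bee_id").last()
        ok = firsts.index[(lasts.flight_number - firsts.flight_number) > 0]
        for m in metric_names:
            diffs = (lasts.loc[ok, m] - firsts.loc[ok, m]).to_numpy()
            if len(diffs) < 2:
                rows.append({"wind": wind_level, "metric": m, "n_bees": len(diffs),
                             "t": np.nan, "df": np.nan, "p": np.nan,
                             "note": "skipped: <2 paired bees"})
                continue
            if np.allclose(diffs, 0.0):
                t, p = 0.0, 1.0  # degenerate: no change for any bee
            else:
                t, p = stats.ttest_rel(lasts.loc[ok, m], firsts.loc[ok, m])
            rows.append({"wind": wind_level, "metric": m, "n_bees": len(diffs),
                         "t": float(t), "df": len(diffs) - 1, "p": float(p),
                         "note": ""})
    return pd.DataFrame(rows)


def effect_summary(metrics: pd.DataFrame) -> dict[str, float]:
    """Headline effect sizes from the metrics table, as percent differences
    of group medians (plus two absolute medians).

    Keys: ``speed_above_vs_within_pct``, ``excursion_above_vs_within_pct``,
    ``excursion_wind_vs_still_pct``, ``speed_tailwind_vs_still_down_pct``,
    ``still_air_ground_speed_m_s`` and ``median_altitudinal_range_mm``.
    """
    med = lambda s: float(np.median(s)) if len(s) else np.nan

    above = metrics[metrics.route == "above"]
    within = metrics[metrics.route == "within"]
    windy = metrics[metrics.wind == "wind"]
    still = metrics[metrics.wind == "still"]
    down = metrics[metrics.direction == "down_tunnel"]
    tail_down = down[down.wind == "wind"]
    still_down = down[down.wind == "still"]

    pct = lambda a, b: 100.0 * (med(a) / med(b) - 1.0)
    return {
        "speed_above_vs_within_pct": pct(above.ground_speed, within.ground_speed),
        "excursion_above_vs_within_pct": pct(above.lateral_excursion,
                                             within.lateral_excursion),
        "excursion_wind_vs_still_pct": pct(windy.lateral_excursion,
                                           still.lateral_excursion),
        "speed_tailwind_vs_still_down_pct": pct(tail_down.ground_speed,
                                                still_down.ground_speed),
        "still_air_ground_speed_m_s": med(still.ground_speed) / 1000.0,
        "median_altitudinal_range_mm": med(metrics.altitude_range),
    }
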