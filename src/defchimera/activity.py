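"""Four-parameter logistic dose-response analysis of colony-count assays.

Peptides are titrated (20, 10, 4, 2 ug/ml plus a 0-dose control) against
bacterial cultures; surviving colonies are counted and survival is
normalised to the 0-dose control.  A four-parameter logistic curve

    s(x) = lower + (upper - lower) / (1 + exp(slope * (ln x - ln midpoint)))

is fitted by least squares from a fixed multi-start grid (deterministic).
The IC50 is the dose at which *absolute* survival crosses 0.5 — "the dose
needed to kill 50% of the bacteria" — not the curve midpoint, although the
two coincide for a symmetric full-range curve.  Specific activity converts
IC50 to units per milligram: 1 U is the IC50 dose in the 1-ml assay, so
U/mg = 1000 / IC50(ug/ml).  The conversion formula is a package choice
(the assay volume is 1 ml); it is pluggable via ``activity_fn``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from itertools import product

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "Fit4PL",
    "fit_4pl",
    "ic50",
    "specific_activity",
    "aggregate_table",
    "ActivityTable",
    "dose_response_from_counts",
    "activity_table_from_counts",
    "logistic_4pl",
]

ASSAY_DOSES = (20.0, 10.0, 4.0, 2.0)


def logistic_4pl(x, lower, upper, slope, midpoint):
    """4PL survival curve; defined at x=0 by its limit."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore"):
        lx = np.where(x > 0, np.log(np.where(x > 0, x, 1.0)), -np.inf)
    z = slope * (lx - np.log(midpoint))
    # exp(-inf) -> 0 (slope>0 at x=0 gives upper); exp(+inf) -> inf gives lower
    with np.errstate(over="ignore"):
        e = np.exp(np.clip(z, -700, 700))
    return lower + (upper - lower) / (1.0 + e)


@dataclass(frozen=True)
class Fit4PL:
    lower: float
    upper: float
    slope: float
    midpoint: float
    sse: float
    stable: bool = True

    def predict(self, x):
        return logistic_4pl(x, self.lower, self.upper, self.slope, self.midpoint)


def fit_4pl(doses, survival) -> Fit4PL:
    """Least-squares 4PL fit, deterministic via a fixed multi-start grid.

    ``doses`` must contain at least 4 distinct values (a 0-dose control is
    allowed and handled by the curve's limit).  Starts combine slopes
    {+-0.5, +-1, +-2} with midpoints at the positive-dose quartiles; the
    best SSE wins, ties broken by the smallest midpoint.  Degenerate data
    (e.g. constant survival) are flagged ``stable=False``.
    """
    x = np.asarray(doses, dtype=float)
    y = np.asarray(survival, dtype=float)
    if x.size != y.size:
        raise ValueError("doses and survival differ in length")
    if np.unique(x).size < 4:
        raise ValueError("need at least 4 distinct doses")

    pos = np.unique(x[x > 0])
    mid_starts = np.quantile(pos, [0.25, 0.5, 0.75])
    lo0, hi0 = float(y.min()), float(y.max())

    def residuals(p):
        lower, upper, slope, ln_mid = p
        return logistic_4pl(x, lower, upper, slope, np.exp(ln_mid)) - y

    best: tuple[float, float, np.ndarray] | None = None  # (sse, midpoint, params)
    for slope0, mid0 in product((0.5, -0.5, 1.0, -1.0, 2.0, -2.0), mid_starts):
        try:
            res = least_squares(
                residuals, x0=[lo0, hi0, slope0, np.log(mid0)],
                method="lm", max_nfev=2000)
        except Exception:
            continue
        sse = float(2 * res.cost)
        midpoint = float(np.exp(res.x[3]))
        key = (round(sse, 12), midpoint)
        if best is None or key < best[0]:
            best = (key, res.x, sse)
    if best is None:
        raise RuntimeError("4PL fit failed from every start")
    p = best[1]
    lower, upper, slope, midpoint = float(p[0]), float(p[1]), float(p[2]), float(np.exp(p[3]))
    if lower > upper:
        # the 4PL is invariant under swapping asymptotes and negating the
        # slope; canonicalise to upper >= lower
        lower, upper, slope = upper, lower, -slope
    stable = abs(upper - lower) > 1e-3 * max(1.0, abs(hi0 - lo0), abs(hi0))
    if np.ptp(y) < 1e-12:
        stable = False
    return Fit4PL(lower=lower, upper=upper, slope=slope, midpoint=midpoint,
                  sse=best[2], stable=stable)


def ic50(fit: Fit4PL, max_dose: float | None = None) -> float | None:
    """Dose at which predicted absolute survival equals 0.5.

    Returns None (flagged undefined) when the curve never crosses 0.5
    within (0, 10 * max_dose].
    """
    u, lo, s, m = fit.upper, fit.lower, fit.slope, fit.midpoint
    num = u - 0.5
    den = 0.5 - lo
    if num <= 0 or den <= 0 or s == 0:
        return None
    x = m * np.exp(np.log(num / den) / s)
    if not np.isfinite(x) or x <= 0:
        return None
    if max_dose is not None and x > 10 * max_dose:
        return None
    return float(x)


def specific_activity(ic50_ug_per_ml: float | None,
                      assay_volume_ml: float = 1.0) -> float:
    """U/mg from IC50: 1 U = the IC50 dose in the assay volume.

    U/mg = 1000 / (IC50 * volume); undefined IC50 reports 0 activity.
    """
    if ic50_ug_per_ml is None:
        return 0.0
    if ic50_ug_per_ml <= 0:
        raise ValueError("IC50 must be positive")
    return 1000.0 / (ic50_ug_per_ml * assay_volume_ml)


def _round_half_up(x: float) -> int:
    return int(Decimal(repr(float(x))).quantize(0, rounding=ROUND_HALF_UP))


@dataclass
class ActivityTable:
    values: pd.DataFrame  # peptides x bacteria
    row_means: pd.Series
    col_means: pd.Series


def aggregate_table(values: pd.DataFrame) -> ActivityTable:
    """Row (per peptide) and column (per bacterium) mean specific activity.

    Means are arithmetic, rounded half-up to integers.  Missing cells are
    averaged over the available values with a warning.
    """
    df = pd.DataFrame(values).astype(float)
    if df.isna().any().any():
        warnings.warn("missing cells; means computed over available values")
    row_means = df.mean(axis=1, skipna=True).map(_round_half_up)
    col_means = df.mean(axis=0, skipna=True).map(_round_half_up)
    return ActivityTable(values=df, row_means=row_means, col_means=col_means)


# ---------------------------------------------------------------------------
# From raw colony counts


def _select_countable(group: pd.DataFrame, max_countable: int = 300) -> float:
    """Effective colony count for one (peptide, bacterium, dose).

    Uses the highest plated concentration (smallest dilution factor) whose
    plate still has individually distinguishable colonies, approximated by
    ``colonies <= max_countable``; the count is scaled by the dilution.
    """
    g = group.sort_values("dilution")  # 1 (undiluted) first, then 10, ...
    for _, row in g.iterrows():
        if row["colonies"] <= max_countable:
            return float(row["colonies"] * row["dilution"])
    last = g.iloc[-1]
    return float(last["colonies"] * last["dilution"])


def dose_response_from_counts(df: pd.DataFrame,
                              max_countable: int = 300) -> pd.DataFrame:
    """Survival fractions from a colony-count table.

    Input columns: peptide_id, bacterium, dose_ug_per_ml, dilution,
    colonies (replicate rows allowed).  Survival is the effective count
    divided by the 0-dose control of the same peptide/bacterium series.
    """
    need = {"peptide_id", "bacterium", "dose_ug_per_ml", "dilution", "colonies"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    rows = []
    for (pep, bact, dose), grp in df.groupby(
            ["peptide_id", "bacterium", "dose_ug_per_ml"]):
        rows.append((pep, bact, float(dose), _select_countable(grp, max_countable)))
    eff = pd.DataFrame(rows, columns=["peptide_id", "bacterium", "dose", "count"])
    out = []
    for (pep, bact), grp in eff.groupby(["peptide_id", "bacterium"]):
        ctrl = grp.loc[grp["dose"] == 0, "count"]
        if ctrl.empty or ctrl.iloc[0] <= 0:
            raise ValueError(f"{pep}/{bact}: missing or zero 0-dose control")
        c0 = ctrl.iloc[0]
        for _, row in grp.iterrows():
            out.append((pep, bact, row["dose"],
                        min(row["count"] / c0, 1.0)))
    return pd.DataFrame(out, columns=["peptide_id", "bacterium", "dose", "survival"])


def activity_table_from_counts(
    df: pd.DataFrame,
    max_countable: int = 300,
    activity_fn=specific_activity,
) -> tuple[ActivityTable, pd.DataFrame]:
    """Full pipeline: counts -> survival -> 4PL -> IC50 -> U/mg table.

    Returns the aggregated table and a diagnostics frame (fit parameters,
    IC50 and flags per peptide/bacterium).
    """
    surv = dose_response_from_counts(df, max_countable)
    diags = []
    cells: dict[str, dict[str, float]] = {}
    for (pep, bact), grp in surv.groupby(["peptide_id", "bacterium"]):
        fit = fit_4pl(grp["dose"].to_numpy(), grp["survival"].to_numpy())
        half = ic50(fit, max_dose=grp["dose"].max())
        act = activity_fn(half)
        cells.setdefault(pep, {})[bact] = act
        diags.append((pep, bact, fit.lower, fit.upper, fit.slope,
                      fit.midpoint, fit.sse, fit.stable,
                      np.nan if half is None else half, act))
    diag = pd.DataFrame(diags, columns=[
        "peptide_id", "bacterium", "lower", "upper", "slope", "midpoint",
        "sse", "stable", "ic50_ug_per_ml", "specific_activity"])
    table = aggregate_table(pd.DataFrame(cells).T)
    return table, diag
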