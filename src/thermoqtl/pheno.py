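"""Phenotype construction: TLE standardization, cumulative degree-minutes,
harvest-trait derivation with the 10-g consistency filter, descriptives."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import HeatingCurve


def standardize_rtle(
    table: pd.DataFrame, group_col: str = "group", rtle_col: str = "rtle"
) -> pd.DataFrame:
    """Within-group z-score of raw time to loss of equilibrium.

    Challenge groups were phenotyped one per day under slightly different
    heating timelines, so the raw times are centred to 0 and scaled to
    sample SD 1 (denominator n-1) within each group; the result is the
    analysis trait ``tle``.  Idempotent: standardizing an already
    standardized column returns it unchanged.
    """
    if table[rtle_col].isna().any() or not np.isfinite(table[rtle_col]).all():
        raise ValueError("every fish needs a finite raw time to loss of equilibrium")
    out = table.copy()
    tle = np.empty(len(table), dtype=np.float64)
    for g, grp in table.groupby(group_col, sort=False):
        if len(grp) < 2:
            raise ValueError(f"group {g!r} has a single fish; SD is undefined")
        x = grp[rtle_col].to_numpy(dtype=np.float64)
        sd = x.std(ddof=1)
        if sd == 0.0:
            raise ValueError(f"group {g!r} has zero raw-time variance")
        tle[table.index.get_indexer(grp.index)] = (x - x.mean()) / sd
    out["tle"] = tle
    return out


def cumulative_degrees(
    table: pd.DataFrame,
    heating_curves: dict[str, HeatingCurve],
    group_col: str = "group",
    rtle_col: str = "rtle",
) -> pd.Series:
    """Cumulative degree-minutes up to loss of equilibrium.

    For each fish, the excess of the water temperature over the initial
    temperature is summed at whole minutes t = 1..floor(rTLE); partial final
    minutes are truncated.  A constant-temperature challenge yields 0.
    """
    out = np.empty(len(table), dtype=np.float64)
    for g, grp in table.groupby(group_col, sort=False):
        if g not in heating_curves:
            raise KeyError(f"no heating curve for group {g!r}")
        curve = heating_curves[g]
        rtle = grp[rtle_col].to_numpy(dtype=np.float64)
        t_max = int(np.floor(rtle.max()))
        minutes = np.arange(1, t_max + 1, dtype=np.float64)
        excess = np.asarray(curve.temperature(minutes)) - curve.initial_temp
        cum = np.concatenate(([0.0], np.cumsum(excess)))
        out[table.index.get_indexer(grp.index)] = cum[np.floor(rtle).astype(np.int64)]
    return pd.Series(out, index=table.index, name="ctu")


def derive_and_filter_harvest(
    table: pd.DataFrame, threshold_g: float = 10.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Derive carcass yield and fat percentage; drop inconsistent weighings.

    HGC% = HGCW / BW2 x 100 and Fat% is the mean of the two fat-meter
    sites.  Records where body weight disagrees with the sum of carcass,
    head and viscera weights by more than ``threshold_g`` grams are removed
    (suspect BW2/HGCW measurements).  Returns the filtered table and a
    removal report (id, reason, discrepancy_g).
    """
    for col in ("bw2", "headw", "hgcw", "viscw"):
        if (table[col] < 0).any():
            raise ValueError(f"negative component weight in column {col!r}")
    if (table["bw2"] == 0).any():
        raise ValueError("BW2 = 0: carcass yield undefined")
    out = table.copy()
    out["hgc_pct"] = out["hgcw"] / out["bw2"] * 100.0
    out["fat_pct"] = (out["fat_ant"] + out["fat_post"]) / 2.0
    discrepancy = (out["bw2"] - (out["hgcw"] + out["headw"] + out["viscw"])).abs()
    bad = discrepancy > threshold_g
    removed = pd.DataFrame(
        {
            "id": out.loc[bad, "id"],
            "reason": "weight_sum_inconsistent",
            "discrepancy_g": discrepancy[bad],
        }
    ).reset_index(drop=True)
    return out.loc[~bad].reset_index(drop=True), removed


@dataclass
class Descriptives:
    n: int
    mean: float
    sd: float
    min: float
    max: float
    cv: float  # SD / mean x 100


def descriptives(values) -> Descriptives:
    """N, mean, sample SD, min, max and the coefficient of variation
    (SD/mean x 100)."""
    x = np.asarray(values, dtype=np.float64)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("need at least one finite value")
    mean = float(x.mean())
    sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
    if mean == 0.0:
        raise ValueError("mean is zero: CV undefined")
    return Descriptives(
        n=int(x.size), mean=mean, sd=sd, min=float(x.min()), max=float(x.max()),
        cv=sd / mean * 100.0,
    )


def pooled_group_mean(group_means, group_ns) -> float:
    """N-weighted pooled mean from per-group summaries (as printed in a
    group table)."""
    m = np.asarray(group_means, dtype=np.float64)
    n = np.asarray(group_ns, dtype=np.float64)
    if m.shape != n.shape or m.size == 0:
        raise ValueError("group means and sizes must align and be non-empty")
    return float(np.sum(m * n) / np.sum(n))


def cv_percent(mean: float, sd: float) -> float:
    if mean == 0.0:
        raise ValueError("mean is zero: CV undefined")
    return sd / mean * 100.0
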