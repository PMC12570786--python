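"""Diel actograms, daily and monthly time budgets, season labels, and the
head-up/head-down feeding split.

Conventions: "day" boundaries are local time (fixed UTC+2); species-level
means weight individuals equally (mean of individual means); per
individual-date the class proportions sum to 1.
"""

from __future__ import annotations

import warnings
from datetime import date

import numpy as np
import pandas as pd

from .astro import LOCAL_UTC_OFFSET_H

__all__ = [
    "FEEDING_CLASSES",
    "PITCH_SPLIT_DEG",
    "season_label",
    "apply_exclusions",
    "split_feeding_by_pitch",
    "daily_proportions",
    "diel_matrix",
    "monthly_budget",
    "plot_actogram",
]

#: Analysis classes that represent feeding and are re-split by pitch.
FEEDING_CLASSES = ("feeding-head-up", "feeding-head-down")
#: Neck-pitch boundary (deg): pitch >= -30 is head-up (boundary inclusive).
PITCH_SPLIT_DEG = -30.0
#: First days of each individual's record discarded (collaring recovery).
EXCLUDE_FIRST_DAYS = 10
#: Minimum bursts for a retained individual-day (75% of the 288 possible).
MIN_DAILY_COVERAGE = 216


def season_label(month: int) -> str:
    """Season of a calendar month: Nov-Dec early-green, Jan-Apr green,
    May-Oct dry."""
    if month in (11, 12):
        return "early-green"
    if 1 <= month <= 4:
        return "green"
    if 5 <= month <= 10:
        return "dry"
    raise ValueError(f"month out of range: {month}")


def _local_ts(series: pd.DataFrame) -> pd.Series:
    return pd.to_datetime(series["burst_start_utc"]) + pd.Timedelta(hours=LOCAL_UTC_OFFSET_H)


def apply_exclusions(series: pd.DataFrame) -> pd.DataFrame:
    """Drop each individual's first 10 calendar days and final local date.

    The 10-day window starts at the individual's first burst's local date;
    the final (typically incomplete) date is removed to avoid de-collaring
    and predation artefacts.  Windows are per individual, not global.
    Individuals left with no bursts are dropped with a warning.  The
    returned frame is flagged (``DataFrame.attrs``) so re-applying the
    exclusions is a no-op (idempotent).
    """
    if series.empty:
        raise ValueError("empty classified series")
    if series.attrs.get("exclusions_applied"):
        return series
    from datetime import timedelta

    out = []
    dropped = []
    local_date = _local_ts(series).dt.date
    for ind, grp_idx in series.groupby("individual_id").groups.items():
        dates = local_date.loc[grp_idx]
        cutoff = dates.min() + timedelta(days=EXCLUDE_FIRST_DAYS)
        keep = (dates >= cutoff) & (dates < dates.max())
        kept = series.loc[grp_idx][keep.to_numpy()]
        if kept.empty:
            dropped.append(ind)
        else:
            out.append(kept)
    if dropped:
        warnings.warn(f"individuals dropped by exclusion rules: {dropped}")
    if not out:
        result = series.iloc[0:0]
    else:
        result = (
            pd.concat(out)
            .sort_values(["individual_id", "burst_start_utc"])
            .reset_index(drop=True)
        )
    result.attrs["exclusions_applied"] = True
    return result


def split_feeding_by_pitch(series: pd.DataFrame) -> pd.DataFrame:
    """Reassign feeding bursts to head-up/head-down by static neck pitch.

    Bursts whose label is a feeding class become ``feeding-head-up`` iff
    ``static_pitch_deg`` >= -30 (asin(-0.5 G) exactly on the boundary is
    head-up), else ``feeding-head-down``; other classes are untouched.
    """
    out = series.copy()
    feeding = out["label"].isin(FEEDING_CLASSES)
    pitch = out.loc[feeding, "static_pitch_deg"]
    out.loc[feeding, "label"] = np.where(
        pitch >= PITCH_SPLIT_DEG, "feeding-head-up", "feeding-head-down"
    )
    return out


def daily_proportions(series: pd.DataFrame, min_coverage: int = MIN_DAILY_COVERAGE) -> pd.DataFrame:
    """Per individual and local date, the proportion of bursts per class.

    Days with fewer than ``min_coverage`` bursts (default 216 = 75% of the
    288 slots of a complete day) are dropped with a warning.  Returns tidy
    columns ``individual_id, date_local, label, proportion, n_bursts``; the
    proportions of one individual-date sum to 1.
    """
    df = series.copy()
    df["date_local"] = _local_ts(df).dt.date
    totals = df.groupby(["individual_id", "date_local"]).size().rename("n_bursts")
    thin = totals[totals < min_coverage]
    if len(thin):
        warnings.warn(f"dropping {len(thin)} individual-days below {min_coverage} bursts")
    good = totals[totals >= min_coverage]
    counts = (
        df.groupby(["individual_id", "date_local", "label"], observed=True)
        .size()
        .rename("n")
        .reset_index()
    )
    counts = counts.merge(good.reset_index(), on=["individual_id", "date_local"], how="inner")
    counts["proportion"] = counts["n"] / counts["n_bursts"]
    return counts[["individual_id", "date_local", "label", "proportion", "n_bursts"]]


def diel_matrix(series: pd.DataFrame, year: int) -> dict[str, pd.DataFrame]:
    """Actogram matrices: per class, mean proportion per 15-min local bin
    (rows, bin 0 = 00:00-00:14) by date of the year (columns).

    Per bin and date, each individual's within-bin class proportion is
    computed and then averaged across individuals with equal weight; bins
    with no data are missing (NaN), not zero.
    """
    local = _local_ts(series)
    sel = local.dt.year == year
    if not sel.any():
        raise ValueError(f"no bursts in year {year}")
    df = series.loc[sel].copy()
    loc = local.loc[sel]
    df["date_local"] = loc.dt.date
    df["bin15"] = loc.dt.hour * 4 + loc.dt.minute // 15
    dates = pd.date_range(date(year, 1, 1), date(year, 12, 31), freq="D").date
    labels = sorted(df["label"].unique())
    totals = df.groupby(["individual_id", "date_local", "bin15"]).size().rename("total")
    out: dict[str, pd.DataFrame] = {}
    counts_all = (
        df.groupby(["individual_id", "date_local", "bin15", "label"], observed=True)
        .size()
        .rename("n")
        .reset_index()
        .merge(totals.reset_index(), on=["individual_id", "date_local", "bin15"])
    )
    counts_all["proportion"] = counts_all["n"] / counts_all["total"]
    # fill absent label rows with 0 within observed individual-date-bins
    base = totals.reset_index()[["individual_id", "date_local", "bin15"]]
    for label in labels:
        sub = counts_all[counts_all["label"] == label][
            ["individual_id", "date_local", "bin15", "proportion"]
        ]
        merged = base.merge(sub, on=["individual_id", "date_local", "bin15"], how="left")
        merged["proportion"] = merged["proportion"].fillna(0.0)
        mean = (
            merged.groupby(["date_local", "bin15"])["proportion"].mean().reset_index()
        )
        mat = mean.pivot(index="bin15", columns="date_local", values="proportion")
        mat = mat.reindex(index=range(96), columns=dates)
        out[label] = mat
    return out


def monthly_budget(daily: pd.DataFrame) -> pd.DataFrame:
    """Monthly class means with season labels.

    Daily proportions are first averaged across days within an individual
    and month, then across individuals, so individuals are weighted equally.
    Columns: ``month, label, proportion, season``.
    """
    if daily.empty:
        raise ValueError("empty daily budget")
    df = daily.copy()
    df["month"] = pd.to_datetime(df["date_local"].astype(str)).dt.month
    per_ind = (
        df.groupby(["individual_id", "month", "label"], observed=True)["proportion"]
        .mean()
        .reset_index()
    )
    out = per_ind.groupby(["month", "label"], observed=True)["proportion"].mean().reset_index()
    out["season"] = out["month"].map(season_label)
    return out


def plot_actogram(
    matrices: dict[str, pd.DataFrame],
    path,
    lat: float | None = None,
    lon: float | None = None,
    full_moon_dates=None,
) -> None:
    """Actogram heatmaps (one panel per class) with optional sunrise/sunset
    curves and full-moon markers; written as PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from . import astro

    labels = list(matrices)
    fig, axes = plt.subplots(len(labels), 1, figsize=(10, 2.4 * len(labels)), squeeze=False)
    for ax, label in zip(axes[:, 0], labels):
        mat = matrices[label]
        im = ax.imshow(
            mat.to_numpy(dtype=float),
            aspect="auto",
            origin="lower",
            extent=(0, mat.shape[1], 0, 24),
            cmap="viridis",
            vmin=0,
            vmax=1,
        )
        if lat is not None and lon is not None:
            day_idx = np.arange(0, mat.shape[1], 7)
            rs, ss = [], []
            for i in day_idx:
                sunrise, sunset = astro.sun_events(lat, lon, mat.columns[i])
                rs.append((sunrise.hour + sunrise.minute / 60 + astro.LOCAL_UTC_OFFSET_H) % 24)
                ss.append((sunset.hour + sunset.minute / 60 + astro.LOCAL_UTC_OFFSET_H) % 24)
            ax.plot(day_idx, rs, color="w", lw=0.8)
            ax.plot(day_idx, ss, color="w", lw=0.8)
        if full_moon_dates is not None:
            cols = {d: i for i, d in enumerate(mat.columns)}
            xs = [cols[d] for d in full_moon_dates if d in cols]
            ax.scatter(xs, [0.5] * len(xs), s=8, color="yellow", zorder=3)
        ax.set_ylabel("local hour")
        ax.set_title(label)
        fig.colorbar(im, ax=ax, label="proportion")
    axes[-1, 0].set_xlabel("day of year")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
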