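"""Low-precision ephemeris: lunar illuminated fraction, sun events, night
classification, midnight-hour budgets, and the Wilcoxon rank-sum contrast.

The lunar fraction uses the short trigonometric series for geocentric solar
and lunar ecliptic longitude/latitude published in the Astronomical Almanac
(the classic "low precision" formulae).  That is deliberate: classifying a
night as moonlit (fraction > 0.9) or dark (< 0.1) needs only ~0.02 absolute
accuracy in the fraction, which the truncated series deliver with margin.
Sun events use the NOAA solar position algorithm (zenith 90.833 deg,
i.e. refraction plus solar radius), iterated once, good to about a minute.

All instants are naive UTC ``datetime``/``pandas.Timestamp`` values; local
time at the study site is a fixed UTC+2 offset (Namibia, no DST).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date, datetime, time, timedelta
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "MoonIllumination",
    "NightClass",
    "RankSumResult",
    "moon_fraction",
    "sun_events",
    "classify_nights",
    "midnight_hour_budget",
    "wilcoxon_rank_sum",
]

#: Fixed local-time offset of the study site (hours east of UTC).
LOCAL_UTC_OFFSET_H = 2

#: Default study-site coordinates (degrees; south/east positive-east).
SITE_LAT = -19.2
SITE_LON = 15.2

MOONLIT_THRESHOLD = 0.9
DARK_THRESHOLD = 0.1

_EPH_YEAR_MIN = 1990
_EPH_YEAR_MAX = 2030

_DEG = math.pi / 180.0


@dataclass(frozen=True)
class MoonIllumination:
    instant_utc: datetime
    fraction: float


@dataclass(frozen=True)
class NightClass:
    """Classification of the night assigned to the local date that
    contains its 00:00-00:59 window."""

    night_date_local: date
    fraction: float
    night_class: str  # 'moonlit' | 'dark' | 'excluded'


@dataclass(frozen=True)
class RankSumResult:
    """Two-sample rank-sum test result, W in the first-sample
    Mann-Whitney U convention (0 <= W <= n1*n2)."""

    W: float
    p_two_sided: float
    n1: int
    n2: int
    method: str  # 'exact' | 'normal'


# ---------------------------------------------------------------------------
# Julian day & ephemeris
# ---------------------------------------------------------------------------

def _to_utc_datetime(instant) -> datetime:
    if isinstance(instant, pd.Timestamp):
        if instant.tzinfo is not None:
            instant = instant.tz_convert("UTC").tz_localize(None)
        return instant.to_pydatetime()
    if isinstance(instant, datetime):
        if instant.tzinfo is not None:
            instant = instant.astimezone(tz=None).replace(tzinfo=None)
        return instant
    raise TypeError(f"cannot interpret {instant!r} as a UTC instant")


def julian_day(instant_utc) -> float:
    dt = _to_utc_datetime(instant_utc)
    unix = dt.replace(tzinfo=None) - datetime(1970, 1, 1)
    return unix.total_seconds() / 86400.0 + 2440587.5


def _check_year(dt: datetime) -> None:
    if not (_EPH_YEAR_MIN <= dt.year <= _EPH_YEAR_MAX):
        raise ValueError(
            f"instant {dt.isoformat()} outside supported ephemeris range "
            f"{_EPH_YEAR_MIN}-{_EPH_YEAR_MAX}"
        )


def _sun_ecliptic_longitude(n: float) -> float:
    """Geocentric apparent solar ecliptic longitude (deg), low precision.

    n is days since J2000.0.
    """
    L = 280.460 + 0.9856474 * n
    g = (357.528 + 0.9856003 * n) * _DEG
    return L + 1.915 * math.sin(g) + 0.020 * math.sin(2 * g)


def _moon_ecliptic(T: float) -> tuple[float, float]:
    """Geocentric lunar ecliptic longitude and latitude (deg).

    Truncated series (Astronomical Almanac low-precision formulae);
    T is Julian centuries since J2000.0.  Good to roughly 0.3 deg.
    """
    s = math.sin
    lam = (
        218.32
        + 481267.881 * T
        + 6.29 * s((135.0 + 477198.87 * T) * _DEG)
        - 1.27 * s((259.3 - 413335.36 * T) * _DEG)
        + 0.66 * s((235.7 + 890534.22 * T) * _DEG)
        + 0.21 * s((269.9 + 954397.74 * T) * _DEG)
        - 0.19 * s((357.5 + 35999.05 * T) * _DEG)
        - 0.11 * s((186.5 + 966404.03 * T) * _DEG)
    )
    beta = (
        5.13 * s((93.3 + 483202.02 * T) * _DEG)
        + 0.28 * s((228.2 + 960400.89 * T) * _DEG)
        - 0.28 * s((318.3 + 6003.15 * T) * _DEG)
        - 0.17 * s((217.6 - 407332.21 * T) * _DEG)
    )
    return lam, beta


def moon_fraction(instant_utc) -> MoonIllumination:
    """Fraction of the lunar disc illuminated at a UTC instant.

    Computes solar and lunar ecliptic positions from truncated series, the
    geocentric elongation ``psi`` with ``cos psi = cos(beta) cos(lam_m -
    lam_s)``, approximates the phase angle as ``i = 180 deg - psi`` (the
    Earth-Moon / Earth-Sun distance-ratio correction is below 0.2 deg and
    negligible at the documented 0.02 accuracy), and returns
    ``k = (1 + cos i) / 2``: 0 at new moon, 1 at full moon.
    """
    dt = _to_utc_datetime(instant_utc)
    _check_year(dt)
    jd = julian_day(dt)
    n = jd - 2451545.0
    T = n / 36525.0
    lam_s = _sun_ecliptic_longitude(n)
    lam_m, beta_m = _moon_ecliptic(T)
    cos_psi = math.cos(beta_m * _DEG) * math.cos((lam_m - lam_s) * _DEG)
    cos_psi = min(1.0, max(-1.0, cos_psi))
    # i = 180 - psi  =>  cos i = -cos psi
    k = (1.0 - cos_psi) / 2.0
    return MoonIllumination(instant_utc=dt, fraction=min(1.0, max(0.0, k)))


# ---------------------------------------------------------------------------
# Sun events (NOAA)
# ---------------------------------------------------------------------------

def _noaa_eqtime_decl(jd: float) -> tuple[float, float]:
    """Equation of time (minutes) and solar declination (radians), NOAA."""
    dt = datetime(1970, 1, 1) + timedelta(days=jd - 2440587.5)
    doy = dt.timetuple().tm_yday
    year_len = 366 if (dt.year % 4 == 0 and (dt.year % 100 != 0 or dt.year % 400 == 0)) else 365
    frac_hour = dt.hour + dt.minute / 60.0 + dt.second / 3600.0
    g = 2.0 * math.pi / year_len * (doy - 1 + (frac_hour - 12.0) / 24.0)
    eqtime = 229.18 * (
        0.000075
        + 0.001868 * math.cos(g)
        - 0.032077 * math.sin(g)
        - 0.014615 * math.cos(2 * g)
        - 0.040849 * math.sin(2 * g)
    )
    decl = (
        0.006918
        - 0.399912 * math.cos(g)
        + 0.070257 * math.sin(g)
        - 0.006758 * math.cos(2 * g)
        + 0.000907 * math.sin(2 * g)
        - 0.002697 * math.cos(3 * g)
        + 0.00148 * math.sin(3 * g)
    )
    return eqtime, decl


def sun_events(lat_deg: float, lon_deg: float, date_local: date) -> tuple[datetime, datetime]:
    """Sunrise and sunset (UTC) for a local calendar date.

    Uses the NOAA solar calculator equations at zenith 90.833 deg.  The hour
    angle is first evaluated at local solar noon and then re-evaluated at the
    provisional event times, which keeps the result within about a minute of
    a full ephemeris.  Raises for polar day/night (|lat| >= 66 deg refused).
    """
    if abs(lat_deg) >= 66.0:
        raise ValueError("latitude too close to the polar circles for this algorithm")
    if isinstance(date_local, datetime):
        date_local = date_local.date()
    lat = lat_deg * _DEG
    zenith = 90.833 * _DEG

    def _event_utc_minutes(jd_guess: float, rising: bool) -> float:
        eqtime, decl = _noaa_eqtime_decl(jd_guess)
        cos_ha = (math.cos(zenith) - math.sin(lat) * math.sin(decl)) / (
            math.cos(lat) * math.cos(decl)
        )
        if not (-1.0 <= cos_ha <= 1.0):
            raise ValueError("sun does not rise/set on this date at this latitude")
        ha_deg = math.degrees(math.acos(cos_ha))
        if not rising:
            ha_deg = -ha_deg
        return 720.0 - 4.0 * (lon_deg + ha_deg) - eqtime

    midnight_utc = datetime.combine(date_local, time()) - timedelta(hours=LOCAL_UTC_OFFSET_H)
    jd0 = julian_day(midnight_utc + timedelta(hours=12))
    utc_day_start = datetime.combine(date_local, time())
    out = []
    for rising in (True, False):
        minutes = _event_utc_minutes(jd0, rising)
        # refine once with eqtime/decl evaluated at the provisional event time
        minutes = _event_utc_minutes(julian_day(utc_day_start + timedelta(minutes=minutes)), rising)
        out.append(utc_day_start + timedelta(minutes=minutes))
    sunrise, sunset = out
    return sunrise, sunset


# ---------------------------------------------------------------------------
# Night classification & midnight-hour budgets
# ---------------------------------------------------------------------------

def classify_nights(
    dates: Iterable,
    thresholds: tuple[float, float] = (MOONLIT_THRESHOLD, DARK_THRESHOLD),
) -> list[NightClass]:
    """Classify nights as moonlit / dark / excluded by lunar fraction.

    The night labelled with local date ``d`` is the one containing the
    00:00-00:59 window of ``d``; its illumination is evaluated at the local
    midnight starting ``d`` (00:00 local = 22:00 UTC of the previous day).
    Strict inequalities: fraction > hi is moonlit, < lo is dark, anything
    else (including exactly the thresholds) is excluded.
    """
    hi, lo = thresholds
    out = []
    for d in dates:
        if isinstance(d, (pd.Timestamp, datetime)):
            d = pd.Timestamp(d).date()
        midnight_utc = datetime.combine(d, time()) - timedelta(hours=LOCAL_UTC_OFFSET_H)
        k = moon_fraction(midnight_utc).fraction
        if k > hi:
            cls = "moonlit"
        elif k < lo:
            cls = "dark"
        else:
            cls = "excluded"
        out.append(NightClass(night_date_local=d, fraction=k, night_class=cls))
    return out


def midnight_hour_budget(series: pd.DataFrame) -> pd.DataFrame:
    """Per-night per-class mean proportion over the hour after midnight.

    ``series`` is a classified-burst table with columns ``individual_id``,
    ``burst_start_utc`` and ``label``.  Bursts whose local time falls in
    [00:00, 01:00) are grouped by (night local date, individual); per-class
    proportions are computed per individual and then averaged across
    individuals with equal weight.  Returns a tidy frame with columns
    ``night_date_local, label, proportion, n_individuals``.
    """
    if series.empty:
        return pd.DataFrame(columns=["night_date_local", "label", "proportion", "n_individuals"])
    ts = pd.to_datetime(series["burst_start_utc"])
    local = ts + pd.Timedelta(hours=LOCAL_UTC_OFFSET_H)
    in_window = local.dt.hour == 0
    sub = series.loc[in_window].copy()
    if sub.empty:
        return pd.DataFrame(columns=["night_date_local", "label", "proportion", "n_individuals"])
    sub["night_date_local"] = local.loc[in_window].dt.date
    counts = (
        sub.groupby(["night_date_local", "individual_id", "label"], observed=True)
        .size()
        .rename("n")
        .reset_index()
    )
    totals = counts.groupby(["night_date_local", "individual_id"], observed=True)["n"].transform("sum")
    counts["proportion"] = counts["n"] / totals
    # complete missing classes with 0 within each individual-night
    labels = sorted(series["label"].unique())
    full = (
        counts.pivot_table(
            index=["night_date_local", "individual_id"],
            columns="label",
            values="proportion",
            fill_value=0.0,
        )
        .reindex(columns=labels, fill_value=0.0)
    )
    species_mean = full.groupby(level="night_date_local").mean()
    n_ind = full.groupby(level="night_date_local").size()
    tidy = species_mean.stack().rename("proportion").reset_index()
    tidy.columns = ["night_date_local", "label", "proportion"]
    tidy["n_individuals"] = tidy["night_date_local"].map(n_ind)
    return tidy


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

def _exact_u_sf_cdf(n1: int, n2: int, w: float) -> tuple[float, float]:
    """P(U <= w) and P(U >= w) under the exact null (no ties).

    Counts rank assignments by the standard recurrence on the number of
    partitions contributing each U value; equivalent to full enumeration of
    the C(n1+n2, n1) assignments.
    """
    max_u = n1 * n2
    # f[m, u] = number of rank assignments of m first-sample items among
    # m + n with U == u; recurrence f_{m,n}(u) = f_{m-1,n}(u-n) + f_{m,n-1}(u)
    f = np.zeros((n1 + 1, max_u + 1))
    f[:, 0] = 1.0  # n = 0: U is always 0
    for n2_cur in range(1, n2 + 1):
        g = np.zeros_like(f)
        g[0, 0] = 1.0
        for m in range(1, n1 + 1):
            g[m] = f[m]
            g[m, n2_cur:] += g[m - 1, : max_u + 1 - n2_cur]
        f = g
    freq = f[n1]
    total = freq.sum()
    w_floor = int(math.floor(w + 1e-12))
    w_ceil = int(math.ceil(w - 1e-12))
    p_le = freq[: w_floor + 1].sum() / total
    p_ge = freq[w_ceil:].sum() / total
    return p_le, p_ge


def wilcoxon_rank_sum(
    a: Sequence[float], b: Sequence[float], method: str = "auto"
) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test with midranks.

    ``W`` is the first-sample U statistic: the rank sum of ``a`` (midranks
    over the pooled sample) minus ``n1 (n1 + 1) / 2``.  The p-value is exact
    (by enumeration of rank assignments) when ``n1 * n2 <= 400`` and the
    pooled sample has no ties, otherwise a normal approximation with
    tie-corrected variance and a 0.5 continuity correction is used; pass
    ``method='exact'``/``'normal'`` to force one (exact refuses ties).  The
    two-sided p is ``min(1, 2 * min(lower tail, upper tail))``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = pd.Series(pooled).rank(method="average").to_numpy()
    W = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool((tie_counts > 1).any())
    if method == "exact" and has_ties:
        raise ValueError("exact enumeration is only defined without ties")

    use_exact = (
        method == "exact"
        if method != "auto"
        else (n1 * n2 <= 400 and not has_ties)
    )
    if use_exact:
        p_le, p_ge = _exact_u_sf_cdf(n1, n2, W)
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return RankSumResult(W=W, p_two_sided=p, n1=n1, n2=n2, method="exact")

    mean = n1 * n2 / 2.0
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return RankSumResult(W=W, p_two_sided=1.0, n1=n1, n2=n2, method="normal")
    sd = math.sqrt(var)
    p_le = norm.cdf((W - mean + 0.5) / sd)
    p_ge = norm.sf((W - mean - 0.5) / sd)
    p = min(1.0, 2.0 * min(p_le, p_ge))
    return RankSumResult(W=W, p_two_sided=p, n1=n1, n2=n2, method="normal")


def moonlight_contrast(
    midnight_budget: pd.DataFrame,
    night_classes: Sequence[NightClass] | None = None,
    thresholds: tuple[float, float] = (MOONLIT_THRESHOLD, DARK_THRESHOLD),
) -> pd.DataFrame:
    """Moonlit-vs-dark Wilcoxon contrast per behaviour class.

    Joins the per-night midnight-hour budget with night classifications and
    runs :func:`wilcoxon_rank_sum` on moonlit vs dark nights per behaviour.
    Returns one row per behaviour: medians, W, p, and group sizes.
    """
    if midnight_budget.empty:
        return pd.DataFrame(
            columns=["label", "median_moonlit", "median_dark", "W", "p", "n_moonlit", "n_dark"]
        )
    nights = sorted(midnight_budget["night_date_local"].unique())
    if night_classes is None:
        night_classes = classify_nights(nights, thresholds)
    cls_map = {nc.night_date_local: nc.night_class for nc in night_classes}
    df = midnight_budget.copy()
    df["night_class"] = df["night_date_local"].map(cls_map)
    rows = []
    for label, grp in df.groupby("label", observed=True):
        moonlit = grp.loc[grp["night_class"] == "moonlit", "proportion"].to_numpy()
        dark = grp.loc[grp["night_class"] == "dark", "proportion"].to_numpy()
        if len(moonlit) == 0 or len(dark) == 0:
            continue
        res = wilcoxon_rank_sum(moonlit, dark)
        rows.append(
            {
                "label": label,
                "median_moonlit": float(np.median(moonlit)),
                "median_dark": float(np.median(dark)),
                "W": res.W,
                "p": res.p_two_sided,
                "n_moonlit": len(moonlit),
                "n_dark": len(dark),
            }
        )
    return pd.DataFrame(rows)
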