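"""Independent high-order ephemeris used only as a test oracle.

Implements the classical high-accuracy trigonometric series for the lunar
position (the leading ~24 longitude / ~20 latitude / ~20 distance periodic
terms of the ELP truncation in Meeus, *Astronomical Algorithms*), the
full solar position with equation of center and distance, and the proper
phase-angle geometry including the Earth-Sun / Earth-Moon distance ratio.
Nothing here is imported by the package; the package's own ephemeris uses
a much shorter, independent series.
"""

from __future__ import annotations

import math
from datetime import date, datetime, time, timedelta

D2R = math.pi / 180.0

# Meeus table 47.A (truncated): D, M, M', F, coeff_longitude (1e-6 deg),
# coeff_distance (1e-3 km)
_LON_DIST_TERMS = [
    (0, 0, 1, 0, 6288774, -20905355),
    (2, 0, -1, 0, 1274027, -3699111),
    (2, 0, 0, 0, 658314, -2955968),
    (0, 0, 2, 0, 213618, -569925),
    (0, 1, 0, 0, -185116, 48888),
    (0, 0, 0, 2, -114332, -3149),
    (2, 0, -2, 0, 58793, 246158),
    (2, -1, -1, 0, 57066, -152138),
    (2, 0, 1, 0, 53322, -170733),
    (2, -1, 0, 0, 45758, -204586),
    (0, 1, -1, 0, -40923, -129620),
    (1, 0, 0, 0, -34720, 108743),
    (0, 1, 1, 0, -30383, 104755),
    (2, 0, 0, -2, 15327, 10321),
    (0, 0, 1, 2, -12528, 0),
    (0, 0, 1, -2, 10980, 79661),
    (4, 0, -1, 0, 10675, -34782),
    (0, 0, 3, 0, 10034, -23210),
    (4, 0, -2, 0, 8548, -21636),
    (2, 1, -1, 0, -7888, 24208),
    (2, 1, 0, 0, -6766, 30824),
    (1, 0, -1, 0, -5163, -8379),
    (1, 1, 0, 0, 4987, -16675),
    (2, -1, 1, 0, 4036, -12831),
]

# Meeus table 47.B (truncated): D, M, M', F, coeff_latitude (1e-6 deg)
_LAT_TERMS = [
    (0, 0, 0, 1, 5128122),
    (0, 0, 1, 1, 280602),
    (0, 0, 1, -1, 277693),
    (2, 0, 0, -1, 173237),
    (2, 0, -1, 1, 55413),
    (2, 0, -1, -1, 46271),
    (2, 0, 0, 1, 32573),
    (0, 0, 2, 1, 17198),
    (2, 0, 1, -1, 9266),
    (0, 0, 2, -1, 8822),
    (2, -1, 0, -1, 8216),
    (2, 0, -2, -1, 4324),
    (2, 0, 1, 1, 4200),
    (2, 1, 0, -1, -3359),
    (2, -1, -1, 1, 2463),
    (2, -1, 0, 1, 2211),
    (2, -1, -1, -1, 2065),
    (0, 1, -1, -1, -1870),
    (4, 0, -1, -1, 1828),
    (0, 1, 0, 1, -1794),
]


def julian_day(dt: datetime) -> float:
    unix = dt - datetime(1970, 1, 1)
    return unix.total_seconds() / 86400.0 + 2440587.5


def moon_position(dt: datetime) -> tuple[float, float, float]:
    """Geocentric lunar (longitude deg, latitude deg, distance km)."""
    T = (julian_day(dt) - 2451545.0) / 36525.0
    Lp = 218.3164477 + 481267.88123421 * T - 0.0015786 * T**2 + T**3 / 538841 - T**4 / 65194000
    D = 297.8501921 + 445267.1114034 * T - 0.0018819 * T**2 + T**3 / 545868 - T**4 / 113065000
    M = 357.5291092 + 35999.0502909 * T - 0.0001536 * T**2 + T**3 / 24490000
    Mp = 134.9633964 + 477198.8675055 * T + 0.0087414 * T**2 + T**3 / 69699 - T**4 / 14712000
    F = 93.2720950 + 483202.0175233 * T - 0.0036539 * T**2 - T**3 / 3526000 + T**4 / 863310000
    E = 1.0 - 0.002516 * T - 0.0000074 * T**2

    sl = 0.0
    sr = 0.0
    for d, m, mp, f, cl, cr in _LON_DIST_TERMS:
        arg = (d * D + m * M + mp * Mp + f * F) * D2R
        e = E ** abs(m)
        sl += cl * e * math.sin(arg)
        sr += cr * e * math.cos(arg)
    sb = 0.0
    for d, m, mp, f, cb in _LAT_TERMS:
        arg = (d * D + m * M + mp * Mp + f * F) * D2R
        sb += cb * (E ** abs(m)) * math.sin(arg)

    A1 = 119.75 + 131.849 * T
    A2 = 53.09 + 479264.290 * T
    A3 = 313.45 + 481266.484 * T
    sl += 3958 * math.sin(A1 * D2R) + 1962 * math.sin((Lp - F) * D2R) + 318 * math.sin(A2 * D2R)
    sb += (
        -2235 * math.sin(Lp * D2R)
        + 382 * math.sin(A3 * D2R)
        + 175 * math.sin((A1 - F) * D2R)
        + 175 * math.sin((A1 + F) * D2R)
        + 127 * math.sin((Lp - Mp) * D2R)
        - 115 * math.sin((Lp + Mp) * D2R)
    )
    lam = Lp + sl / 1e6
    beta = sb / 1e6
    dist = 385000.56 + sr / 1000.0
    return lam % 360.0, beta, dist


def sun_position(dt: datetime) -> tuple[float, float]:
    """Geocentric solar (true longitude deg, distance AU)."""
    T = (julian_day(dt) - 2451545.0) / 36525.0
    L0 = 280.46646 + 36000.76983 * T + 0.0003032 * T**2
    M = 357.52911 + 35999.05029 * T - 0.0001537 * T**2
    e = 0.016708634 - 0.000042037 * T - 0.0000001267 * T**2
    C = (
        (1.914602 - 0.004817 * T - 0.000014 * T**2) * math.sin(M * D2R)
        + (0.019993 - 0.000101 * T) * math.sin(2 * M * D2R)
        + 0.000289 * math.sin(3 * M * D2R)
    )
    true_lon = L0 + C
    nu = M + C
    R = 1.000001018 * (1 - e**2) / (1 + e * math.cos(nu * D2R))
    return true_lon % 360.0, R


def illuminated_fraction(dt: datetime) -> float:
    """Fraction of the lunar disc illuminated, with full phase-angle
    geometry (Meeus ch. 48)."""
    lam_m, beta_m, delta_km = moon_position(dt)
    lam_s, r_au = sun_position(dt)
    r_km = r_au * 149597870.7
    cos_psi = math.cos(beta_m * D2R) * math.cos((lam_m - lam_s) * D2R)
    cos_psi = min(1.0, max(-1.0, cos_psi))
    psi = math.acos(cos_psi)
    i = math.atan2(r_km * math.sin(psi), delta_km - r_km * math.cos(psi))
    return (1.0 + math.cos(i)) / 2.0


def _obliquity_and_nutation(T: float) -> tuple[float, float]:
    omega = (125.04 - 1934.136 * T) * D2R
    dpsi = -0.00478 * math.sin(omega)  # deg, leading nutation term
    eps = 23.4392911 - 0.0130042 * T + 0.00256 * math.cos(omega)
    return eps, dpsi


def sun_apparent_radec(dt: datetime) -> tuple[float, float]:
    """Apparent right ascension / declination of the Sun (deg)."""
    T = (julian_day(dt) - 2451545.0) / 36525.0
    true_lon, _ = sun_position(dt)
    eps, dpsi = _obliquity_and_nutation(T)
    omega = (125.04 - 1934.136 * T) * D2R
    lam_app = true_lon - 0.00569 - 0.00478 * math.sin(omega)
    eps_r = eps * D2R
    lam_r = lam_app * D2R
    alpha = math.atan2(math.cos(eps_r) * math.sin(lam_r), math.cos(lam_r)) / D2R
    delta = math.asin(math.sin(eps_r) * math.sin(lam_r)) / D2R
    return alpha % 360.0, delta


def equation_of_time_minutes(dt: datetime) -> float:
    """Apparent minus mean solar time (minutes)."""
    T = (julian_day(dt) - 2451545.0) / 36525.0
    L0 = (280.46646 + 36000.76983 * T + 0.0003032 * T**2) % 360.0
    alpha, _ = sun_apparent_radec(dt)
    eps, dpsi = _obliquity_and_nutation(T)
    E = L0 - 0.0057183 - alpha + dpsi * math.cos(eps * D2R)
    E = (E + 180.0) % 360.0 - 180.0
    return E * 4.0


def sun_events(lat_deg: float, lon_deg: float, d: date, tz_offset_h: float = 2.0):
    """Sunrise and sunset (UTC datetimes) by iterated hour-angle solution
    with the Sun's apparent position; altitude -0.833 deg."""
    out = []
    for rising in (True, False):
        # initial guess: 06:00 / 18:00 local
        guess = datetime.combine(d, time(6 if rising else 18)) - timedelta(hours=tz_offset_h)
        for _ in range(4):
            _, delta = sun_apparent_radec(guess)
            eot = equation_of_time_minutes(guess)
            h0 = -0.833 * D2R
            phi = lat_deg * D2R
            cos_H = (math.sin(h0) - math.sin(phi) * math.sin(delta * D2R)) / (
                math.cos(phi) * math.cos(delta * D2R)
            )
            cos_H = min(1.0, max(-1.0, cos_H))
            H = math.degrees(math.acos(cos_H))
            transit_min = 720.0 - 4.0 * lon_deg - eot
            minutes = transit_min + (-H if rising else H) * 4.0
            guess = datetime.combine(d, time()) + timedelta(minutes=minutes)
        out.append(guess)
    return out[0], out[1]
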