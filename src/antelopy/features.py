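"""Burst feature extraction: centering, axis harmonisation, yz-plane
magnitude, time- and frequency-domain features, and ODBA.

A burst is one short (3.3 s at 33 Hz -> 109 samples) tri-axial accelerometer
recording in raw collar units on a 0-4095 scale spanning -4..+4 G, i.e.
512 units per G around an offset of 2048.  Features are computed for the
x axis (surge, along the neck) and for the yz-plane magnitude, which is
invariant to collar rotation about the neck; ODBA uses all three axes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Burst",
    "CenteredBurst",
    "OrientationDecision",
    "RAW_OFFSET",
    "UNITS_PER_G",
    "ODBA_WINDOW",
    "FEATURE_NAMES",
    "center_burst",
    "decide_orientation",
    "time_features",
    "odba",
    "spectral_features",
    "extract_features",
    "feature_table",
]

RAW_OFFSET = 2048.0
UNITS_PER_G = 512.0
#: ODBA running-mean window in samples (0.67 s at 33 Hz).
ODBA_WINDOW = 22
#: Noise floor (G) below which axis means are not trusted for flipping.
ORIENTATION_EPS_G = 0.05

_TIME_NAMES = ("mean", "variance", "sd", "max", "min", "range")
_FREQ_NAMES = ("freqmain", "freqamp", "entropy")
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{axis}_{name}" for axis in ("x", "yz") for name in _TIME_NAMES + _FREQ_NAMES
) + ("odba",)


@dataclass(frozen=True)
class Burst:
    """One raw burst; integer samples in [0, 4095], equal lengths >= 8."""

    individual_id: str
    start_utc: object
    rate: float
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    def __post_init__(self):
        x = np.asarray(self.x)
        y = np.asarray(self.y)
        z = np.asarray(self.z)
        if not (len(x) == len(y) == len(z)):
            raise ValueError("axis length mismatch in burst")
        if len(x) < 8:
            raise ValueError("burst too short (< 8 samples)")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "z", z)


@dataclass(frozen=True)
class CenteredBurst:
    """Burst in G after removing the 2048 offset; yz is the plane magnitude."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    yz: np.ndarray


@dataclass(frozen=True)
class OrientationDecision:
    """Per-individual axis flips (constant over the individual's record)."""

    flip_x: bool = False
    flip_y: bool = False


def center_burst(burst: Burst) -> CenteredBurst:
    """Convert raw units to G ((raw - 2048) / 512) and add |yz|."""
    x = (np.asarray(burst.x, dtype=float) - RAW_OFFSET) / UNITS_PER_G
    y = (np.asarray(burst.y, dtype=float) - RAW_OFFSET) / UNITS_PER_G
    z = (np.asarray(burst.z, dtype=float) - RAW_OFFSET) / UNITS_PER_G
    return CenteredBurst(x=x, y=y, z=z, yz=np.hypot(y, z))


def decide_orientation(
    reference_axis_means: Sequence[float],
    individual_axis_means: Sequence[float],
    eps_g: float = ORIENTATION_EPS_G,
) -> OrientationDecision:
    """Decide x/y flips by comparing grand axis means (G) against a reference.

    An axis is flipped iff its mean and the reference mean have opposite
    signs and both magnitudes exceed the noise floor ``eps_g``; the z axis is
    never flipped (it enters only through the sign-insensitive yz magnitude
    and ODBA).
    """

    def _flip(ref: float, ind: float) -> bool:
        return abs(ref) > eps_g and abs(ind) > eps_g and (ref > 0) != (ind > 0)

    rx, ry = reference_axis_means[0], reference_axis_means[1]
    ix, iy = individual_axis_means[0], individual_axis_means[1]
    return OrientationDecision(flip_x=_flip(rx, ix), flip_y=_flip(ry, iy))


def time_features(series: np.ndarray) -> tuple[float, float, float, float, float, float]:
    """(mean, variance, sd, max, min, range); population (1/n) variance."""
    series = np.asarray(series, dtype=float)
    if series.size < 2:
        raise ValueError("time features need at least 2 samples")
    mean = float(series.mean())
    var = float(series.var())  # population variance
    mx = float(series.max())
    mn = float(series.min())
    return mean, var, math.sqrt(var), mx, mn, mx - mn


def _running_mean_sym(a: np.ndarray, window: int) -> np.ndarray:
    """Centered running mean at full window length; near the edges the
    window slides inward so it always covers ``window`` real samples (no
    padding).  With window == len(a) every position sees the global mean."""
    n = len(a)
    i = np.arange(n)
    lo = np.clip(i - (window - 1) // 2, 0, n - window)
    csum = np.concatenate([[0.0], np.cumsum(a)])
    return (csum[lo + window] - csum[lo]) / window


def odba(centered: CenteredBurst, window: int = ODBA_WINDOW) -> float:
    """Overall dynamic body acceleration (G).

    Per axis the static component is a centered running mean over ``window``
    samples; ODBA is the mean over samples of the summed absolute dynamic
    (signal minus static) components of the three axes.
    """
    n = len(centered.x)
    if n < window:
        raise ValueError(f"burst length {n} shorter than ODBA window {window}")
    total = np.zeros(n)
    for a in (centered.x, centered.y, centered.z):
        total += np.abs(a - _running_mean_sym(a, window))
    return float(total.mean())


def spectral_features(series: np.ndarray, rate: float) -> tuple[float, float, float]:
    """(freqmain, freqamp, entropy) of the mean-removed series.

    Power spectrum over positive-frequency DFT bins (DC excluded so posture
    cannot masquerade as a frequency).  ``freqmain`` is the bin-center
    frequency of maximal power, ``freqamp`` the amplitude 2|c|/n at that
    bin, and ``entropy`` the Shannon entropy of the normalised power
    spectrum divided by log(#bins), hence in [0, 1].  An (effectively)
    zero series returns (0, 0, 1).
    """
    series = np.asarray(series, dtype=float)
    n = series.size
    if n < 8:
        raise ValueError("spectral features need at least 8 samples")
    coeffs = np.fft.rfft(series - series.mean())
    power = np.abs(coeffs[1:]) ** 2  # DC excluded; Nyquist kept as ordinary bin
    total = power.sum()
    if total <= 0 or not np.isfinite(total):
        return 0.0, 0.0, 1.0
    k = int(np.argmax(power)) + 1
    freqmain = k * rate / n
    freqamp = 2.0 * float(np.abs(coeffs[k])) / n
    p = power / total
    with np.errstate(divide="ignore", invalid="ignore"):
        h = float(-(p * np.where(p > 0, np.log(p), 0.0)).sum())
    nbins = power.size
    entropy = h / math.log(nbins) if nbins > 1 else 0.0
    return float(freqmain), float(freqamp), float(min(max(entropy, 0.0), 1.0))


def static_pitch_deg(centered_x: np.ndarray) -> float:
    """Neck pitch (deg) from the mean static x (surge) acceleration.

    pitch = asin(mean x in G), clamped to [-1, 1] before asin; values beyond
    1 G can arise from dynamic motion and are flagged with a warning.
    """
    m = float(np.mean(centered_x))
    if abs(m) > 1.0:
        warnings.warn(f"mean static x = {m:.3f} G exceeds 1 G; clamped before asin")
        m = max(-1.0, min(1.0, m))
    return math.degrees(math.asin(m))


def extract_features(burst: Burst, orientation: OrientationDecision | None = None) -> dict:
    """The 19-feature vector of one burst, plus identifiers and pitch.

    Applies the orientation flips, centers to G, and computes 6 time-domain
    and 3 frequency-domain features on x and on the yz magnitude, plus ODBA:
    ``x_mean ... yz_entropy, odba``.
    """
    if orientation is None:
        orientation = OrientationDecision()
    centered = center_burst(burst)
    x = -centered.x if orientation.flip_x else centered.x
    y = -centered.y if orientation.flip_y else centered.y
    centered = CenteredBurst(x=x, y=y, z=centered.z, yz=np.hypot(y, centered.z))
    out: dict = {
        "individual_id": burst.individual_id,
        "start_utc": burst.start_utc,
    }
    for axis_name, series in (("x", centered.x), ("yz", centered.yz)):
        for name, value in zip(_TIME_NAMES, time_features(series)):
            out[f"{axis_name}_{name}"] = value
        for name, value in zip(_FREQ_NAMES, spectral_features(series, burst.rate)):
            out[f"{axis_name}_{name}"] = value
    out["odba"] = odba(centered)
    out["static_pitch_deg"] = static_pitch_deg(centered.x)
    return out


def feature_table(
    bursts: Sequence[Burst],
    orientations: dict[str, OrientationDecision] | None = None,
) -> pd.DataFrame:
    """Feature vectors for many bursts as a DataFrame (one row per burst).

    ``orientations`` maps individual id to its :class:`OrientationDecision`;
    missing individuals get the identity (no flips).
    """
    orientations = orientations or {}
    rows = [
        extract_features(b, orientations.get(b.individual_id)) for b in bursts
    ]
    return pd.DataFrame(rows)
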