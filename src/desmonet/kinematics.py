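"""Appendage kinematics from pose-tracking keypoints.

The larva's aciculae (chitin rods inside the parapodia) are tracked by two
keypoints each — a proximal tip and a more distal point — together with a
pharynx and a proctodeum point that define the longitudinal bodyline axis.
From these we compute, per video frame and per parapodium:

* the unsigned angle between each acicula and the bodyline;
* that angle normalised to [0, 100] within each acicula's own range of
  motion (for gait heatmaps);
* the signed inter-acicular angle between the notopodial and neuropodial
  acicula of the same parapodium.

Input coordinates are image coordinates (y grows downward).  All geometry
is computed after flipping to a mathematical y-up frame; the sign
convention for inter-acicular angles is the standard counterclockwise-
positive 2-D cross product in that frame.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "KeypointTrack",
    "SchemaError",
    "bodyline_axis",
    "acicular_angles",
    "normalize_range",
    "inter_acicular",
    "gait_heatmap",
    "fit_sinusoid",
    "phase_lag_deg",
]

ANCHOR_PARTS = ("pharynx", "proctodeum")
LOBES = ("not", "neu")
_PART_RE = re.compile(r"^(?P<pp>sg\d[lr])_(?P<lobe>not|neu)_(?P<end>prox|dist)$")

DEFAULT_LIKELIHOOD_THRESHOLD = 0.9
DEFAULT_MAX_GAP = 3


class SchemaError(ValueError):
    """Raised when a keypoint table lacks required body parts."""


@dataclass
class KeypointTrack:
    """Per-frame keypoint coordinates with tracking likelihoods.

    ``data`` is a wide table indexed by frame with columns
    ``<part>_x``, ``<part>_y``, ``<part>_likelihood`` for each body part.
    Required parts: ``pharynx`` and ``proctodeum`` plus, for each
    parapodium ``sg<N><l|r>``, the four acicular points
    ``<pp>_not_prox``, ``<pp>_not_dist``, ``<pp>_neu_prox``,
    ``<pp>_neu_dist``.
    """

    data: pd.DataFrame
    bodyparts: Tuple[str, ...] = field(default_factory=tuple)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "KeypointTrack":
        parts = []
        for col in df.columns:
            if col.endswith("_x"):
                parts.append(col[:-2])
        parts = tuple(dict.fromkeys(parts))
        missing = []
        for p in parts:
            for suffix in ("_x", "_y"):
                if p + suffix not in df.columns:
                    missing.append(p + suffix)
        if missing:
            raise SchemaError(f"incomplete coordinate columns: {missing}")
        for anchor in ANCHOR_PARTS:
            if anchor not in parts:
                raise SchemaError(f"missing required body part: {anchor!r}")
        pps = sorted({m.group("pp") for p in parts for m in [_PART_RE.match(p)] if m})
        if not pps:
            raise SchemaError(
                "no parapodium acicular points found (expected e.g. 'sg1l_not_prox')"
            )
        for pp in pps:
            for lobe in LOBES:
                for end in ("prox", "dist"):
                    name = f"{pp}_{lobe}_{end}"
                    if name not in parts:
                        raise SchemaError(f"missing required body part: {name!r}")
        df = df.copy()
        # likelihood columns are optional in the flat dialect: default to 1
        for p in parts:
            lk = p + "_likelihood"
            if lk not in df.columns:
                df[lk] = 1.0
        if not df.index.is_monotonic_increasing:
            raise SchemaError("frame index must be monotone increasing")
        return cls(data=df, bodyparts=parts)

    @property
    def n_frames(self) -> int:
        return len(self.data)

    @property
    def parapodia(self) -> Tuple[str, ...]:
        return tuple(
            sorted({m.group("pp") for p in self.bodyparts for m in [_PART_RE.match(p)] if m})
        )

    def xy(self, part: str) -> np.ndarray:
        """(n_frames, 2) image-coordinate array for one body part."""
        return self.data[[part + "_x", part + "_y"]].to_numpy(float)

    def likelihood(self, part: str) -> np.ndarray:
        return self.data[part + "_likelihood"].to_numpy(float)

    def xy_clean(
        self,
        part: str,
        threshold: float = DEFAULT_LIKELIHOOD_THRESHOLD,
        max_gap: int = DEFAULT_MAX_GAP,
    ) -> np.ndarray:
        """Coordinates with low-likelihood frames masked and short gaps
        (<= max_gap frames) linearly interpolated; longer gaps stay NaN."""
        xy = self.xy(part).copy()
        bad = self.likelihood(part) < threshold
        xy[bad] = np.nan
        if max_gap > 0 and bad.any() and not bad.all():
            xy = _interpolate_short_gaps(xy, max_gap)
        return xy

    def __len__(self) -> int:
        return self.n_frames


def _interpolate_short_gaps(xy: np.ndarray, max_gap: int) -> np.ndarray:
    out = xy.copy()
    n = len(xy)
    isnan = np.isnan(xy[:, 0])
    i = 0
    while i < n:
        if isnan[i]:
            j = i
            while j < n and isnan[j]:
                j += 1
            gap = j - i
            if gap <= max_gap and i > 0 and j < n:
                for k in range(i, j):
                    t = (k - (i - 1)) / (j - (i - 1))
                    out[k] = (1 - t) * xy[i - 1] + t * xy[j]
            i = j
        else:
            i += 1
    return out


def _to_yup(v: np.ndarray) -> np.ndarray:
    """Flip image coordinates (y-down) to a mathematical y-up frame."""
    out = np.asarray(v, float).copy()
    out[..., 1] = -out[..., 1]
    return out


def bodyline_axis(
    track: KeypointTrack,
    frame: int,
    threshold: float = DEFAULT_LIKELIHOOD_THRESHOLD,
) -> np.ndarray:
    """Unit vector from pharynx to proctodeum (y-up frame) at one frame."""
    i = track.data.index.get_loc(frame)
    for part in ANCHOR_PARTS:
        if track.likelihood(part)[i] < threshold:
            raise ValueError(f"frame {frame}: {part} below likelihood threshold")
    ph = _to_yup(track.xy("pharynx")[i])
    pr = _to_yup(track.xy("proctodeum")[i])
    v = pr - ph
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError(f"frame {frame}: pharynx and proctodeum coincide")
    return v / norm


def _bodyline_vectors(track: KeypointTrack, threshold: float, max_gap: int) -> np.ndarray:
    ph = _to_yup(track.xy_clean("pharynx", threshold, max_gap))
    pr = _to_yup(track.xy_clean("proctodeum", threshold, max_gap))
    return pr - ph


def _angle_between(a: np.ndarray, b: np.ndarray, signed: bool = False) -> np.ndarray:
    """Angle (degrees) between row vectors of a and b.

    Unsigned: [0, 180].  Signed: (-180, 180], positive when b is rotated
    counterclockwise from a (y-up frame).
    """
    dot = np.einsum("ij,ij->i", a, b)
    cross = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    ang = np.degrees(np.arctan2(cross, dot))
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    ang = np.where((na == 0) | (nb == 0), np.nan, ang)
    if signed:
        return ang
    return np.abs(ang)


def acicular_angles(
    track: KeypointTrack,
    parapodium: str,
    lobe: str = "not",
    threshold: float = DEFAULT_LIKELIHOOD_THRESHOLD,
    max_gap: int = DEFAULT_MAX_GAP,
    signed: bool = False,
) -> pd.Series:
    """Per-frame angle between one acicula and the bodyline axis.

    The acicula vector runs proximal tip -> distal point.  Unsigned by
    default (range-of-motion analyses); NaN where a needed keypoint fails
    the likelihood threshold.
    """
    if lobe not in LOBES:
        raise ValueError(f"lobe must be one of {LOBES}")
    if parapodium not in track.parapodia:
        raise KeyError(
            f"unknown parapodium {parapodium!r}; available: {track.parapodia}"
        )
    prox = _to_yup(track.xy_clean(f"{parapodium}_{lobe}_prox", threshold, max_gap))
    dist = _to_yup(track.xy_clean(f"{parapodium}_{lobe}_dist", threshold, max_gap))
    acic = dist - prox
    body = _bodyline_vectors(track, threshold, max_gap)
    ang = _angle_between(body, acic, signed=signed)
    out = pd.Series(ang, index=track.data.index, name=f"{parapodium}_{lobe}")
    if out.isna().all():
        raise ValueError(
            f"{parapodium}/{lobe}: no frame passes the likelihood threshold"
        )
    return out


def normalize_range(series: pd.Series) -> pd.Series:
    """Linearly map [min, max] of a series onto [0, 100].

    A constant series has an undefined range of motion: all values become
    NaN and a warning is emitted.  NaNs propagate.
    """
    values = series.to_numpy(float)
    finite = values[np.isfinite(values)]
    if finite.size < 2:
        raise ValueError("normalize_range needs at least two non-missing values")
    lo, hi = finite.min(), finite.max()
    if hi == lo:
        warnings.warn(
            "zero angular range: normalization undefined, series set to NaN",
            stacklevel=2,
        )
        return pd.Series(np.full_like(values, np.nan), index=series.index, name=series.name)
    return pd.Series((values - lo) / (hi - lo) * 100.0, index=series.index, name=series.name)


def inter_acicular(
    track: KeypointTrack,
    parapodium: str,
    threshold: float = DEFAULT_LIKELIHOOD_THRESHOLD,
    max_gap: int = DEFAULT_MAX_GAP,
) -> pd.Series:
    """Signed angle (degrees) from the notopodial to the neuropodial
    acicula vector, per frame.

    Positive when the neuropodial acicula is rotated counterclockwise from
    the notopodial one in the y-up frame; range (-180, 180].  The sign
    therefore flips under left-right mirroring of the image.
    """
    if parapodium not in track.parapodia:
        raise KeyError(
            f"unknown parapodium {parapodium!r}; available: {track.parapodia}"
        )
    vecs = {}
    for lobe in LOBES:
        prox = _to_yup(track.xy_clean(f"{parapodium}_{lobe}_prox", threshold, max_gap))
        dist = _to_yup(track.xy_clean(f"{parapodium}_{lobe}_dist", threshold, max_gap))
        vecs[lobe] = dist - prox
    lengths = {lobe: np.linalg.norm(v, axis=1) for lobe, v in vecs.items()}
    if any((lengths[lobe] == 0).any() for lobe in LOBES):
        warnings.warn("zero-length acicula vector in some frames: set to NaN", stacklevel=2)
    ang = _angle_between(vecs["not"], vecs["neu"], signed=True)
    return pd.Series(ang, index=track.data.index, name=parapodium)


# ---------------------------------------------------------------------------
# spectral helpers: sinusoid fits and inter-segment phase lags


def _filled(series: pd.Series) -> np.ndarray:
    v = series.to_numpy(float)
    if np.isnan(v).any():
        idx = np.arange(len(v))
        ok = np.isfinite(v)
        if ok.sum() < 2:
            raise ValueError("series too sparse for spectral analysis")
        v = np.interp(idx, idx[ok], v[ok])
    return v


def _lsq_at_freq(v: np.ndarray, freq: float):
    """Least-squares fit v ~ a sin(wt) + b cos(wt) + c at fixed freq.

    Returns (a, b, c, residual_sum_of_squares)."""
    t = np.arange(len(v))
    w = 2.0 * np.pi * freq
    design = np.column_stack([np.sin(w * t), np.cos(w * t), np.ones_like(t)])
    coef, *_ = np.linalg.lstsq(design, v, rcond=None)
    resid = float(np.sum((v - design @ coef) ** 2))
    return coef[0], coef[1], coef[2], resid


def _refine_frequency(v: np.ndarray) -> float:
    """Dominant frequency (cycles/frame): FFT peak refined by golden-
    section search on the least-squares residual.  A plain DFT bin
    readout leaks badly when the record holds a fractional number of
    cycles; the refinement removes that bias."""
    n = len(v)
    spec = np.abs(np.fft.rfft(v - v.mean()))
    k = int(np.argmax(spec[1:]) + 1)
    lo, hi = max(k - 1, 0.5) / n, min(k + 1, n // 2) / n
    from scipy.optimize import minimize_scalar

    res = minimize_scalar(
        lambda f: _lsq_at_freq(v, f)[3],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-7 / n},
    )
    return float(res.x)


def fit_sinusoid(series: pd.Series) -> dict:
    """Fit mean + amplitude * sin(2*pi*f*t + phase) by least squares.

    The frequency is located at the FFT peak and refined on the
    continuous axis, so records holding a non-integer number of cycles
    are fitted without spectral-leakage bias.  Returns dict with keys
    mean, amplitude (series units), freq (cycles/frame), phase (radians).
    """
    v = _filled(series)
    if len(v) < 4:
        raise ValueError("need at least 4 frames to fit a sinusoid")
    freq = _refine_frequency(v)
    a, b, c, _ = _lsq_at_freq(v, freq)
    # a sin(wt) + b cos(wt) = A sin(wt + phi), A = hypot(a, b),
    # phi = atan2(b, a)
    return {
        "mean": float(c),
        "amplitude": float(np.hypot(a, b)),
        "freq": freq,
        "phase": float(np.arctan2(b, a)),
    }


def phase_lag_deg(a: pd.Series, b: pd.Series) -> float:
    """Phase of b relative to a (degrees, (-180, 180]) at their dominant
    shared frequency.

    Positive means b lags a (b's oscillation occurs later in phase).
    Both series are fitted by least squares at the frequency refined on
    the first series; equivalent to the circular cross-correlation peak
    with sub-frame resolution for near-sinusoidal signals.
    """
    va, vb = _filled(a), _filled(b)
    n = min(len(va), len(vb))
    va, vb = va[:n], vb[:n]
    freq = _refine_frequency(va)
    sa, ca, _, _ = _lsq_at_freq(va, freq)
    sb, cb, _, _ = _lsq_at_freq(vb, freq)
    lag = np.degrees(np.arctan2(ca, sa) - np.arctan2(cb, sb))
    lag = (lag + 180.0) % 360.0 - 180.0
    if lag == -180.0:
        lag = 180.0
    return float(lag)


def gait_heatmap(series_set: Mapping[str, pd.Series]) -> Tuple[pd.DataFrame, Dict[str, float]]:
    """Normalised gait matrix plus inter-segment phase lags.

    Parameters
    ----------
    series_set
        Mapping parapodium -> bodyline-angle series (un-normalised is
        fine: each row is normalised to [0, 100] here).

    Returns
    -------
    (matrix, lags)
        ``matrix``: DataFrame, one row per parapodium, columns = frames,
        values in [0, 100].  ``lags``: phase (degrees) of each parapodium
        relative to the previous one on the same body side, keyed
        ``"<prev>-><next>"``.
    """
    if not series_set:
        raise ValueError("need at least one parapodium series")
    rows = {}
    for pp, series in series_set.items():
        rows[pp] = normalize_range(series)
    matrix = pd.DataFrame(rows).T
    lags: Dict[str, float] = {}
    by_side: Dict[str, list] = {}
    for pp in sorted(series_set):
        by_side.setdefault(pp[-1], []).append(pp)
    for side, pps in by_side.items():
        for prev, nxt in zip(pps, pps[1:]):
            lags[f"{prev}->{nxt}"] = phase_lag_deg(series_set[prev], series_set[nxt])
    return matrix, lags
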