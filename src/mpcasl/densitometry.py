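"""Quantitative autoradiography and immunohistochemistry utilities.

Film calibration against radioactive standards, tissue-activity mapping,
one-compartment Kety CBF computation from a terminal arterial sample,
projective alignment/down-sampling of film scans onto the MR grid,
positive-pixel vessel area fraction, and ROI summary statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq
from skimage import transform as sktransform

#: mL/g/s -> mL/100 g/min
F_UNIT = 6000.0

__all__ = [
    "CalibrationStandards",
    "CalibrationMapping",
    "ArterialInput",
    "fit_calibration",
    "quantify_activity",
    "kety_cbf",
    "align_downsample",
    "positive_pixel_fraction",
    "roi_stats",
    "film_response",
]


@dataclass
class CalibrationStandards:
    """Calibrated activity standards co-exposed with the film.

    ``activities`` in uCi/g (strictly increasing), ``readings`` in scanner
    units (monotone in activity, either direction).
    """

    activities: np.ndarray
    readings: np.ndarray

    def __post_init__(self) -> None:
        self.activities = np.asarray(self.activities, dtype=float)
        self.readings = np.asarray(self.readings, dtype=float)
        if self.activities.shape != self.readings.shape or self.activities.ndim != 1:
            raise ValueError("activities and readings must be matching 1-D arrays")
        if len(self.activities) < 3:
            raise ValueError("need at least 3 calibration standards")
        if np.any(np.diff(self.activities) <= 0):
            raise ValueError("activities must be strictly increasing")
        d = np.diff(self.readings)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("readings must be strictly monotone in activity")

    @classmethod
    def from_csv(cls, path) -> "CalibrationStandards":
        df = pd.read_csv(path)
        return cls(df["activity_uCi_g"].to_numpy(), df["reading"].to_numpy())


@dataclass
class CalibrationMapping:
    """Monotone, shape-preserving reading -> activity interpolant."""

    standards: CalibrationStandards
    _interp: PchipInterpolator = field(repr=False, default=None)

    def __post_init__(self) -> None:
        r = self.standards.readings
        a = self.standards.activities
        order = np.argsort(r)
        self._interp = PchipInterpolator(r[order], a[order], extrapolate=True)
        self._rmin = float(r.min())
        self._rmax = float(r.max())

    def __call__(self, readings):
        """Map readings to activities; returns (activity, extrapolated)."""
        r = np.asarray(readings, dtype=float)
        act = self._interp(r)
        extrap = (r < self._rmin) | (r > self._rmax)
        if act.ndim == 0:
            return float(act), bool(extrap)
        return act, extrap


@dataclass
class ArterialInput:
    """Arterial tracer input reconstructed from one terminal sample.

    ``ca_final`` (uCi/mL) is the concentration at the end of the uptake
    period ``exposure_time`` (s).  The default shape is a linear ramp
    from 0 to ``ca_final``; arbitrary sampled inputs are accepted via
    ``samples`` as (times, concentrations).
    """

    ca_final: float
    exposure_time: float = 120.0
    shape: str = "linear_ramp"
    samples: tuple | None = None

    def __post_init__(self) -> None:
        if self.ca_final < 0:
            raise ValueError("ca_final must be >= 0")
        if self.exposure_time <= 0:
            raise ValueError("exposure_time must be > 0")
        if self.shape not in ("linear_ramp", "custom"):
            raise ValueError("shape must be 'linear_ramp' or 'custom'")
        if self.shape == "custom" and self.samples is None:
            raise ValueError("custom shape requires samples")

    def concentration(self, t):
        t = np.asarray(t, dtype=float)
        if self.shape == "linear_ramp":
            out = self.ca_final * np.clip(t, 0.0, self.exposure_time) / self.exposure_time
        else:
            ts, cs = self.samples
            out = np.interp(t, ts, cs)
        return float(out) if out.ndim == 0 else out


def fit_calibration(standards: CalibrationStandards) -> CalibrationMapping:
    """Shape-preserving (PCHIP) monotone mapping from film reading to
    activity, exact at the standard points; queries outside the standard
    range are flagged as extrapolated."""
    return CalibrationMapping(standards)


def quantify_activity(film, calibration: CalibrationMapping, background: float = 0.0):
    """Per-pixel tissue activity (uCi/g) from a background-subtracted,
    calibrated film scan.

    Returns ``(activity, flags)``; flags mark pixels whose
    background-subtracted reading fell below the zero-activity standard
    (clamped to 0) or beyond the calibrated range (saturated).
    """
    if background < 0:
        raise ValueError("background must be >= 0")
    film = np.asarray(film, dtype=float)
    act, extrap = calibration(film - background)
    act = np.asarray(act, dtype=float)
    clamped = act < 0
    act = np.clip(act, 0.0, None)
    flags = np.asarray(extrap) | clamped
    return act, flags


def _uptake(k: float, inp: ArterialInput) -> float:
    """Tissue activity at T for clearance rate k: Ci(T) = k * int_0^T
    Ca(t) exp(-k (T - t)) dt."""
    T = inp.exposure_time
    if k <= 0:
        return 0.0
    if inp.shape == "linear_ramp":
        kt = k * T
        # k * Ca/T * int_0^T t e^{-k(T-t)} dt, closed form
        return inp.ca_final * (1.0 - (1.0 - np.exp(-kt)) / kt)
    ts = np.linspace(0.0, T, 2001)
    ca = inp.concentration(ts)
    return float(k * np.trapezoid(ca * np.exp(-k * (T - ts)), ts))


def kety_cbf(tissue_activity, inp: ArterialInput, lam: float = 0.8):
    """CBF (mL/100 g/min) from tissue activity via the one-compartment
    Kety operational equation.

    Solves ``Ci(T) = K int_0^T Ca(t) e^(-K(T-t)) dt`` for the clearance
    rate K by a monotone root-find, then ``f = K * lam * 6000``.  Tissue
    activity at or above the asymptotic maximum (the end-point arterial
    concentration for a ramp input) is unphysical and raises.
    """
    if lam <= 0:
        raise ValueError("lam must be > 0")
    ci = np.asarray(tissue_activity, dtype=float)
    scalar = ci.ndim == 0
    ci = np.atleast_1d(ci)
    if np.any(ci < 0):
        raise ValueError("tissue activity must be >= 0")
    k_hi = 10.0  # s^-1, far above any physiological clearance
    ci_max = _uptake(k_hi, inp)
    if np.any(ci >= ci_max):
        raise ValueError(
            f"tissue activity exceeds the asymptotic maximum ({ci_max:g} uCi/g) "
            "for this arterial input"
        )
    out = np.zeros_like(ci)
    for i, val in enumerate(ci.ravel()):
        if val == 0.0:
            continue
        out.ravel()[i] = brentq(
            lambda k: _uptake(k, inp) - val, 1e-12, k_hi, xtol=1e-14, rtol=1e-14
        )
    f = out * lam * F_UNIT
    return float(f.ravel()[0]) if scalar else f


def align_downsample(autorad_map, src_points, dst_points, target_shape=(64, 64)):
    """Projective warp from control-point pairs, then block-mean
    down-sampling onto the target (MR) grid.

    ``src_points`` are (row, col) positions on the film, ``dst_points``
    the matching positions on the warped intermediate grid (an integer
    multiple of ``target_shape``); at least 4 non-degenerate pairs are
    required.  Mean intensity of constant images is preserved.
    """
    img = np.asarray(autorad_map, dtype=float)
    src = np.asarray(src_points, dtype=float)
    dst = np.asarray(dst_points, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[0] < 4:
        raise ValueError("need >= 4 matching control-point pairs")
    block = max(1, int(np.ceil(max(img.shape) / max(target_shape))))
    inter_shape = (target_shape[0] * block, target_shape[1] * block)
    tform = sktransform.ProjectiveTransform()
    # skimage transforms use (x, y) = (col, row)
    if not tform.estimate(src[:, ::-1], dst[:, ::-1]):
        raise ValueError("degenerate control points: projective estimate failed")
    if not np.all(np.isfinite(tform.params)) or abs(np.linalg.det(tform.params)) < 1e-12:
        raise ValueError("degenerate control points: singular transform")
    warped = sktransform.warp(
        img, tform.inverse, output_shape=inter_shape, order=1, mode="edge",
        preserve_range=True,
    )
    return warped.reshape(
        target_shape[0], block, target_shape[1], block
    ).mean(axis=(1, 3))


def positive_pixel_fraction(
    ihc,
    moderate_range=(185, 202),
    strong_max=10,
    analysis_mask=None,
) -> float:
    """Stained-area percentage by intensity thresholding.

    A pixel is positive when its intensity lies in the (inclusive)
    moderate range or strictly below ``strong_max``; the two classes are
    disjoint by construction and counted once.  Returns percent of the
    analysed area.
    """
    img = np.asarray(ihc, dtype=float)
    if analysis_mask is not None:
        sel = np.asarray(analysis_mask, dtype=bool)
        if sel.shape != img.shape:
            raise ValueError("analysis mask grid must match the image")
        vals = img[sel]
    else:
        vals = img.ravel()
    if vals.size == 0:
        raise ValueError("empty analysis region")
    lo, hi = sorted(moderate_range)
    moderate = (vals >= lo) & (vals <= hi)
    strong = vals < strong_max
    positive = moderate | strong
    return 100.0 * float(positive.sum()) / vals.size


def roi_stats(
    map_a,
    map_b,
    rois: dict,
    paired: bool = False,
) -> pd.DataFrame:
    """Per-ROI comparison of two maps.

    For each ROI mask: mean +- SD of both maps, t statistic and p value
    (paired or unpaired two-tailed), variance-ratio F statistic
    (var_a / var_b) with its two-tailed p, and Bonferroni-adjusted
    p values across ROIs.
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("maps must share a grid")
    rows = []
    for name, mask in rois.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != a.shape:
            raise ValueError(f"ROI {name!r} grid does not match the maps")
        xa = a[mask]
        xb = b[mask]
        xa = xa[np.isfinite(xa)]
        xb = xb[np.isfinite(xb)]
        if len(xa) < 2 or len(xb) < 2:
            raise ValueError(f"ROI {name!r} needs >= 2 observations per group")
        if paired:
            if len(xa) != len(xb):
                raise ValueError("paired test requires equal-length samples")
            t, p = stats.ttest_rel(xa, xb)
            if np.isnan(t):  # identical inputs: zero variance of differences
                t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(xa, xb)
            if np.isnan(t):
                t, p = 0.0, 1.0
        va = xa.var(ddof=1)
        vb = xb.var(ddof=1)
        if vb == 0:
            raise ValueError(f"ROI {name!r}: zero variance in F-test denominator")
        fstat = va / vb
        dfa, dfb = len(xa) - 1, len(xb) - 1
        cdf = stats.f.cdf(fstat, dfa, dfb)
        fp = 2.0 * min(cdf, 1.0 - cdf)
        rows.append(
            {
                "roi": name,
                "n_a": len(xa),
                "n_b": len(xb),
                "mean_a": xa.mean(),
                "sd_a": xa.std(ddof=1),
                "mean_b": xb.mean(),
                "sd_b": xb.std(ddof=1),
                "t": float(t),
                "p": float(p),
                "f": float(fstat),
                "f_p": float(min(fp, 1.0)),
            }
        )
    df = pd.DataFrame(rows)
    m = len(df)
    df["p_bonferroni"] = np.minimum(df["p"] * m, 1.0)
    df["f_p_bonferroni"] = np.minimum(df["f_p"] * m, 1.0)
    return df


def film_response(activity, r_max: float = 60000.0, a: float = 0.08, background: float = 500.0):
    """Synthetic saturating film response used by tests and fixtures:
    ``reading = r_max * (1 - exp(-a * activity)) + background``."""
    activity = np.asarray(activity, dtype=float)
    out = r_max * (1.0 - np.exp(-a * activity)) + background
    return float(out) if out.ndim == 0 else out
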