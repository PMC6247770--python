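"""Multiphase ASL analysis chain.

Per-voxel modified-Fermi phase fit -> circular smoothing -> supervoxel
clustering -> high-SNR cluster re-fit -> perfusion-weighted amplitude ->
CBF quantification.

The labelled condition reduces signal, so the response model is
``S(theta) = C - A * F(wrap(theta - theta0))`` with ``F`` the modified
Fermi response and ``A >= 0``.  All angle arithmetic is circular with the
wrapping convention (-180, 180].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from . import kinetic

#: the 8 labelling RF phase offsets, degrees, acquisition order
PHASE_ANGLES = np.arange(0.0, 360.0, 45.0)

GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0

__all__ = [
    "PHASE_ANGLES",
    "MultiphaseSeries",
    "FermiFit",
    "SupervoxelSegmentation",
    "PipelineConfig",
    "wrap_angle",
    "fermi_response",
    "fit_fermi_voxel",
    "fit_fermi_map",
    "smooth_phase_map",
    "supervoxel_cluster",
    "refit_supervoxels",
    "perfusion_weighted_map",
    "series_snr",
    "run_pipeline",
]


def _resolve_voxel_size(voxel_size, ndim: int) -> np.ndarray:
    """Per-axis voxel size, trimmed or broadcast to the map dimensionality."""
    vs = np.atleast_1d(np.asarray(voxel_size, dtype=float))
    if vs.size == 1:
        return np.full(ndim, vs[0])
    if vs.size < ndim:
        raise ValueError("voxel_size has fewer entries than map dimensions")
    return vs[:ndim]


def wrap_angle(theta):
    """Wrap degrees into (-180, 180]."""
    w = np.mod(np.asarray(theta, dtype=float) + 180.0, 360.0) - 180.0
    w = np.where(w == -180.0, 180.0, w)
    return float(w) if w.ndim == 0 else w


@dataclass
class MultiphaseSeries:
    """Voxel grid x 8 labelling phase offsets, acquisition order."""

    signal: np.ndarray  # (..., 8)
    phase_angles: np.ndarray = field(default_factory=lambda: PHASE_ANGLES.copy())

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.phase_angles = np.asarray(self.phase_angles, dtype=float)
        if self.phase_angles.shape != (8,):
            raise ValueError("exactly 8 labelling phases are expected")
        if self.signal.shape[-1] != 8:
            raise ValueError("signal last axis must hold the 8 phases")

    @property
    def grid_shape(self):
        return self.signal.shape[:-1]


@dataclass
class FermiFit:
    """Result of fitting one multiphase response."""

    amplitude: float
    theta0: float  # degrees in (-180, 180]; NaN when undefined
    offset: float
    residual: float
    alpha_f: float = 70.0
    beta_f: float = 19.0

    @property
    def defined(self) -> bool:
        return np.isfinite(self.theta0)


@dataclass
class SupervoxelSegmentation:
    """Integer label map; 0 outside the mask, clusters numbered from 1."""

    labels: np.ndarray
    k: int
    compactness: float

    @property
    def cluster_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


def fermi_response(dtheta, alpha_f: float = 70.0, beta_f: float = 19.0):
    """Modified Fermi response ``1 / (1 + exp((|dtheta| - alpha_f) / beta_f))``.

    Even in ``dtheta`` and non-increasing in ``|dtheta|``; equals 0.5 at
    ``|dtheta| = alpha_f``.
    """
    if beta_f <= 0:
        raise ValueError("beta_f must be > 0")
    d = np.abs(wrap_angle(dtheta))
    out = 1.0 / (1.0 + np.exp((d - alpha_f) / beta_f))
    return float(out) if np.ndim(out) == 0 else out


def _regress(signals: np.ndarray, fvals: np.ndarray):
    """Least-squares of ``S = C - A*F`` row-wise with ``A >= 0``.

    ``signals``: (n, 8); ``fvals``: (8,) or (n, 8).  Returns (A, C, rss).
    """
    if fvals.ndim == 1:
        fvals = np.broadcast_to(fvals, signals.shape)
    fbar = fvals.mean(axis=-1, keepdims=True)
    sbar = signals.mean(axis=-1, keepdims=True)
    df = fvals - fbar
    ds = signals - sbar
    var = np.sum(df * df, axis=-1)
    cov = np.sum(df * ds, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(var > 0, -cov / np.where(var > 0, var, 1.0), 0.0)
    a = np.clip(a, 0.0, None)
    c = sbar[..., 0] + a * fbar[..., 0]
    pred = c[..., None] - a[..., None] * fvals
    rss = np.sum((signals - pred) ** 2, axis=-1)
    return a, c, rss


def _rss_at(signals: np.ndarray, phases: np.ndarray, theta0: np.ndarray, alpha_f, beta_f):
    """Residual sum of squares for per-row theta0 values."""
    dtheta = wrap_angle(phases[None, :] - theta0[:, None])
    fvals = fermi_response(dtheta, alpha_f, beta_f)
    return _regress(signals, fvals)


def fit_fermi_map(
    signals: np.ndarray,
    phase_angles: np.ndarray = PHASE_ANGLES,
    alpha_f: float = 70.0,
    beta_f: float = 19.0,
    grid_step: float = 5.0,
    refine_iter: int = 60,
):
    """Vectorised Fermi fit of many 8-phase responses.

    ``signals``: (n, 8).  Coarse theta0 grid every ``grid_step`` degrees
    (scanned in order of increasing |theta0| so ties resolve toward the
    smallest magnitude), then golden-section refinement of the profiled
    residual within +-``grid_step``.  Returns (A, theta0, C, rss) arrays;
    constant rows get A = 0 and theta0 = NaN.
    """
    signals = np.asarray(signals, dtype=float)
    phases = np.asarray(phase_angles, dtype=float)
    n = signals.shape[0]
    if n == 0:
        z = np.zeros(0)
        return z, z.copy(), z.copy(), z.copy()

    candidates = wrap_angle(np.arange(-180.0 + grid_step, 180.0 + 1e-9, grid_step))
    order = np.argsort(np.abs(candidates), kind="stable")
    best_rss = np.full(n, np.inf)
    best_theta = np.zeros(n)
    for theta in candidates[order]:
        dtheta = wrap_angle(phases - theta)
        fvals = fermi_response(dtheta, alpha_f, beta_f)
        _, _, rss = _regress(signals, fvals)
        # relative tolerance keeps the tie-break scale-invariant
        better = rss < best_rss * (1.0 - 1e-12)
        best_rss = np.where(better, rss, best_rss)
        best_theta = np.where(better, theta, best_theta)

    # golden-section refinement on the profiled RSS
    lo = best_theta - grid_step
    hi = best_theta + grid_step
    x1 = hi - GOLDEN * (hi - lo)
    x2 = lo + GOLDEN * (hi - lo)
    _, _, f1 = _rss_at(signals, phases, x1, alpha_f, beta_f)
    _, _, f2 = _rss_at(signals, phases, x2, alpha_f, beta_f)
    for _ in range(refine_iter):
        take1 = f1 < f2
        hi = np.where(take1, x2, hi)
        lo = np.where(take1, lo, x1)
        x1_new = np.where(take1, hi - GOLDEN * (hi - lo), x2)
        x2_new = np.where(take1, x1, lo + GOLDEN * (hi - lo))
        x1, x2 = x1_new, x2_new
        _, _, f1_new = _rss_at(signals, phases, x1, alpha_f, beta_f)
        _, _, f2_new = _rss_at(signals, phases, x2, alpha_f, beta_f)
        f1, f2 = f1_new, f2_new
    theta0 = wrap_angle(0.5 * (lo + hi))
    a, c, rss = _rss_at(signals, phases, theta0, alpha_f, beta_f)
    # keep the coarse optimum when refinement did not improve (flat rows)
    worse = rss > best_rss * (1.0 + 1e-12)
    if np.any(worse):
        theta0 = np.where(worse, best_theta, theta0)
        a2, c2, rss2 = _rss_at(signals, phases, best_theta, alpha_f, beta_f)
        a = np.where(worse, a2, a)
        c = np.where(worse, c2, c)
        rss = np.where(worse, rss2, rss)

    flat = signals.std(axis=-1) == 0.0
    a = np.where(flat, 0.0, a)
    c = np.where(flat, signals.mean(axis=-1), c)
    theta0 = np.where(flat | (a == 0.0), np.nan, theta0)
    rss = np.where(flat, 0.0, rss)
    return a, theta0, c, rss


def fit_fermi_voxel(
    signal,
    phase_angles=PHASE_ANGLES,
    alpha_f: float = 70.0,
    beta_f: float = 19.0,
) -> FermiFit:
    """Fit ``S(theta) = C - A*F(wrap(theta - theta0))`` to one voxel.

    Constant signal yields A = 0 with theta0 flagged NaN; any NaN in the
    input raises (callers exclude such voxels).
    """
    signal = np.asarray(signal, dtype=float)
    if signal.shape != (8,):
        raise ValueError("signal must hold exactly 8 values")
    if not np.all(np.isfinite(signal)):
        raise ValueError("signal contains non-finite values")
    a, theta0, c, rss = fit_fermi_map(
        signal[None, :], phase_angles, alpha_f=alpha_f, beta_f=beta_f
    )
    return FermiFit(
        amplitude=float(a[0]),
        theta0=float(theta0[0]),
        offset=float(c[0]),
        residual=float(np.sqrt(rss[0])),
        alpha_f=alpha_f,
        beta_f=beta_f,
    )


def smooth_phase_map(phase_map, fwhm, mask, voxel_size=(1.0, 1.0, 1.0)):
    """Angle-aware Gaussian smoothing of a phase map (degrees).

    Phases are averaged as unit vectors; voxels with undefined phase (NaN)
    or outside the mask are excluded from the kernel.  ``fwhm`` is in the
    same units as ``voxel_size`` (mm); ``fwhm = 0`` is the identity.
    """
    if fwhm < 0:
        raise ValueError("fwhm must be >= 0")
    phase = np.asarray(phase_map, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if phase.shape != mask.shape:
        raise ValueError("phase_map and mask grids must match")
    out = np.full(phase.shape, np.nan)
    if fwhm == 0:
        out[mask] = phase[mask]
        return out
    voxel_size = _resolve_voxel_size(voxel_size, phase.ndim)
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size
    valid = mask & np.isfinite(phase)
    theta = np.radians(np.where(valid, phase, 0.0))
    w = valid.astype(float)
    su = ndimage.gaussian_filter(np.cos(theta) * w, sigma)
    sv = ndimage.gaussian_filter(np.sin(theta) * w, sigma)
    sw = ndimage.gaussian_filter(w, sigma)
    with np.errstate(invalid="ignore", divide="ignore"):
        sm = wrap_angle(np.degrees(np.arctan2(sv, su)))
    keep = valid & (sw > 1e-12)
    out[keep] = sm[keep]
    out[mask & ~valid] = np.nan
    return out


def _seed_points(coords: np.ndarray, k: int) -> np.ndarray:
    """Deterministic farthest-point seeds over the masked voxel positions.

    Starts from the voxel nearest the mask centroid, then greedily adds
    the voxel farthest from all chosen seeds (maximin coverage); ties
    resolve to the lowest index, so seeding is fully deterministic.
    """
    centroid = coords.mean(axis=0)
    first = int(np.argmin(np.sum((coords - centroid) ** 2, axis=1)))
    seeds = [first]
    mind = np.sum((coords - coords[first]) ** 2, axis=1)
    for _ in range(1, k):
        nxt = int(np.argmax(mind))
        seeds.append(nxt)
        mind = np.minimum(mind, np.sum((coords - coords[nxt]) ** 2, axis=1))
    return coords[seeds].astype(float)


def supervoxel_cluster(
    phase_map,
    mask,
    k: int,
    compactness: float = 0.1,
    voxel_size=(1.0, 1.0, 1.0),
    max_iter: int = 15,
) -> SupervoxelSegmentation:
    """SLIC-style clustering of a phase map into spatially compact regions.

    Feature space is (cos, sin of the phase, spatial position); the
    spatial term is weighted by ``compactness / S`` with ``S`` the mean
    seed spacing.  Deterministic: seeds are quantiles of the masked voxel
    list in lexicographic order.  Connectivity is enforced afterwards by
    splitting disconnected fragments and absorbing tiny ones into an
    adjacent cluster, so the final number of labels can differ slightly
    from ``k``.  Labels partition the mask exactly.
    """
    phase = np.asarray(phase_map, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if phase.shape != mask.shape:
        raise ValueError("phase_map and mask grids must match")
    n_masked = int(mask.sum())
    if n_masked == 0:
        raise ValueError("empty mask")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n_masked:
        raise ValueError("k exceeds the number of masked voxels")

    labels = np.zeros(phase.shape, dtype=np.int32)
    if k == 1:
        labels[mask] = 1
        return SupervoxelSegmentation(labels=labels, k=k, compactness=compactness)

    voxel_size = _resolve_voxel_size(voxel_size, phase.ndim)
    coords_vox = np.argwhere(mask)
    coords = coords_vox * voxel_size  # physical positions
    theta = np.radians(np.nan_to_num(phase[mask], nan=0.0))
    defined = np.isfinite(phase[mask])
    feat_uv = np.stack([np.cos(theta), np.sin(theta)], axis=1)
    feat_uv[~defined] = 0.0

    volume = float(n_masked * np.prod(voxel_size))
    spacing = (volume / k) ** (1.0 / phase.ndim)
    w_spatial = compactness / spacing

    seeds_xyz = _seed_points(coords, k)
    seed_uv = np.zeros((k, 2))
    # initialise seed phase features from the nearest masked voxel
    for i in range(k):
        j = int(np.argmin(np.sum((coords - seeds_xyz[i]) ** 2, axis=1)))
        seed_uv[i] = feat_uv[j]

    assign = np.zeros(n_masked, dtype=np.int32)
    for _ in range(max_iter):
        d_spatial = np.sum(
            (coords[:, None, :] - seeds_xyz[None, :, :]) ** 2, axis=2
        )
        d_phase = np.sum((feat_uv[:, None, :] - seed_uv[None, :, :]) ** 2, axis=2)
        new_assign = np.argmin(d_phase + (w_spatial**2) * d_spatial, axis=1).astype(
            np.int32
        )
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for i in range(k):
            sel = assign == i
            if not np.any(sel):
                continue
            seeds_xyz[i] = coords[sel].mean(axis=0)
            uv = feat_uv[sel][defined[sel]]
            if len(uv):
                m = uv.mean(axis=0)
                nrm = np.hypot(m[0], m[1])
                seed_uv[i] = m / nrm if nrm > 1e-12 else m

    labels[tuple(coords_vox.T)] = assign + 1

    # connectivity: split fragments, absorb tiny ones into a neighbour
    structure = ndimage.generate_binary_structure(phase.ndim, phase.ndim)
    final = np.zeros_like(labels)
    next_label = 1
    for lab in range(1, k + 1):
        comp, ncomp = ndimage.label(labels == lab, structure=structure)
        for c in range(1, ncomp + 1):
            final[comp == c] = next_label
            next_label += 1
    min_size = max(2, n_masked // (4 * k))
    changed = True
    while changed:
        changed = False
        ids, counts = np.unique(final[final > 0], return_counts=True)
        if len(ids) <= 1:
            break
        for lab, cnt in zip(ids, counts):
            if cnt >= min_size:
                continue
            region = final == lab
            dil = ndimage.binary_dilation(region, structure=structure)
            neigh = final[dil & ~region & mask]
            neigh = neigh[(neigh > 0) & (neigh != lab)]
            if len(neigh) == 0:
                continue
            vals, vcnt = np.unique(neigh, return_counts=True)
            final[region] = vals[np.argmax(vcnt)]
            changed = True
    # renumber compactly
    ids = np.unique(final[final > 0])
    remap = np.zeros(final.max() + 1, dtype=np.int32)
    remap[ids] = np.arange(1, len(ids) + 1)
    final = remap[final]
    return SupervoxelSegmentation(labels=final, k=k, compactness=compactness)


def refit_supervoxels(
    raw: MultiphaseSeries,
    seg: SupervoxelSegmentation,
    alpha_f: float = 70.0,
    beta_f: float = 19.0,
):
    """High-precision phase map from cluster-mean multiphase signals.

    The raw 8-phase signals of each cluster's voxels are averaged, that
    mean response is Fermi-fitted once, and the fitted phase is assigned
    to every member voxel.  Clusters whose mean fit is undefined get NaN.
    """
    signal = raw.signal
    if signal.shape[:-1] != seg.labels.shape:
        raise ValueError("series and segmentation grids must match")
    phase_map = np.full(seg.labels.shape, np.nan)
    ids = seg.cluster_ids
    if len(ids) == 0:
        return phase_map
    means = np.stack([signal[seg.labels == lab].mean(axis=0) for lab in ids])
    _, theta0, _, _ = fit_fermi_map(means, raw.phase_angles, alpha_f, beta_f)
    for lab, th in zip(ids, theta0):
        phase_map[seg.labels == lab] = th
    return phase_map


def _leave_one_out_phase(
    raw: MultiphaseSeries,
    seg: SupervoxelSegmentation,
    alpha_f: float = 70.0,
    beta_f: float = 19.0,
):
    """Per-voxel cluster phase with the voxel excluded from the mean.

    Decorrelates the phase estimate from each voxel's own noise before
    the amplitude refit (jackknife).  Singleton clusters fall back to the
    voxel's own fit.
    """
    labels = seg.labels
    phase = np.full(labels.shape, np.nan)
    sel = labels > 0
    if not np.any(sel):
        return phase
    sig = raw.signal[sel]
    labs = labels[sel]
    ids, inv, counts = np.unique(labs, return_inverse=True, return_counts=True)
    sums = np.zeros((len(ids), sig.shape[-1]))
    np.add.at(sums, inv, sig)
    n = counts[inv][:, None].astype(float)
    loo = np.where(n > 1, (sums[inv] - sig) / np.maximum(n - 1, 1), sig)
    _, theta0, _, _ = fit_fermi_map(loo, raw.phase_angles, alpha_f, beta_f)
    phase[sel] = theta0
    return phase


def perfusion_weighted_map(
    raw: MultiphaseSeries,
    phase_map,
    alpha_f: float = 70.0,
    beta_f: float = 19.0,
    allow_negative: bool = False,
):
    """Per-voxel amplitude with the labelling phase fixed.

    Re-fits only (A, C) by linear least squares at each voxel's assigned
    phase; by default ``dM = A >= 0``.  ``allow_negative=True`` keeps the
    signed estimate, which is unbiased under noise (the clamp rectifies
    noise and inflates low-SNR regional means); quantification uses the
    signed value internally.  Voxels with undefined phase become NaN.
    """
    phase = np.asarray(phase_map, dtype=float)
    if raw.signal.shape[:-1] != phase.shape:
        raise ValueError("series and phase map grids must match")
    out = np.full(phase.shape, np.nan)
    valid = np.isfinite(phase)
    if not np.any(valid):
        return out
    sig = raw.signal[valid]
    dtheta = wrap_angle(raw.phase_angles[None, :] - phase[valid][:, None])
    fvals = fermi_response(dtheta, alpha_f, beta_f)
    fbar = fvals.mean(axis=-1, keepdims=True)
    sbar = sig.mean(axis=-1, keepdims=True)
    df = fvals - fbar
    var = np.sum(df * df, axis=-1)
    cov = np.sum(df * (sig - sbar), axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(var > 0, -cov / np.where(var > 0, var, 1.0), 0.0)
    if not allow_negative:
        a = np.clip(a, 0.0, None)
    out[valid] = a
    return out


def series_snr(raw: MultiphaseSeries, signal_roi, noise_roi) -> float:
    """SNR = mean over the signal ROI / SD over the noise ROI."""
    signal_roi = np.asarray(signal_roi, dtype=bool)
    noise_roi = np.asarray(noise_roi, dtype=bool)
    if np.any(signal_roi & noise_roi):
        raise ValueError("signal and noise ROIs must be disjoint")
    if not signal_roi.any() or not noise_roi.any():
        raise ValueError("empty ROI")
    sd = float(raw.signal[noise_roi].std())
    if sd == 0:
        raise ValueError("zero noise standard deviation")
    return float(raw.signal[signal_roi].mean()) / sd


@dataclass
class PipelineConfig:
    """Tunables of the multiphase analysis chain."""

    alpha_f: float = 70.0
    beta_f: float = 19.0
    smooth_fwhm_mm: float | None = None  # default: 2 voxels (in-plane)
    n_supervoxels: int = 60
    compactness: float = 0.1
    voxel_size: tuple = (0.3125, 0.3125, 1.0)
    pld: float = 0.4
    kinetic: kinetic.KineticParams = field(default_factory=kinetic.KineticParams)


def run_pipeline(
    raw: MultiphaseSeries,
    m0,
    mask,
    config: PipelineConfig | None = None,
    bat_map=None,
):
    """Full multiphase quantification; returns a dict of all intermediates.

    ``bat_map`` is an optional voxelwise bolus-arrival map (e.g. from a
    multi-delay acquisition); without it the nominal ``config.kinetic``
    arrival time is assumed everywhere.  Keys of the result:
    ``phase_raw``, ``phase_smooth``, ``segmentation``, ``phase_hi``,
    ``delta_m``, ``m0_blood``, ``cbf``.  Deterministic for a fixed config.
    """
    if config is None:
        config = PipelineConfig()
    mask = np.asarray(mask, dtype=bool)
    m0 = np.asarray(m0, dtype=float)
    if raw.signal.shape[:-1] != mask.shape or m0.shape != mask.shape:
        raise ValueError("series, m0 and mask grids must match")
    if not mask.any():
        raise ValueError("empty mask")

    # 1. raw per-voxel phase map
    phase_raw = np.full(mask.shape, np.nan)
    sig = raw.signal[mask]
    a_raw, theta0, _, _ = fit_fermi_map(
        sig, raw.phase_angles, config.alpha_f, config.beta_f
    )
    phase_raw[mask] = theta0

    # 2. circular smoothing
    fwhm = config.smooth_fwhm_mm
    if fwhm is None:
        fwhm = 2.0 * float(np.min(config.voxel_size[: mask.ndim]))
    phase_smooth = smooth_phase_map(phase_raw, fwhm, mask, config.voxel_size)

    # 3. supervoxel clustering
    k = min(config.n_supervoxels, int(mask.sum()))
    seg = supervoxel_cluster(
        phase_smooth, mask, k, config.compactness, config.voxel_size
    )

    # 4. high-precision phase from cluster means
    phase_hi = refit_supervoxels(raw, seg, config.alpha_f, config.beta_f)

    # 5. perfusion-weighted amplitude.  The phase used for each voxel's
    # amplitude refit is re-estimated from its cluster mean with the voxel
    # itself left out: the cluster fit otherwise shares the voxel's own
    # noise and the refit amplitude overshoots badly at low SNR.  The
    # signed estimate feeds quantification (clamping would rectify
    # noise); the published dM map is clamped at 0.
    phase_loo = _leave_one_out_phase(raw, seg, config.alpha_f, config.beta_f)
    delta_m_signed = perfusion_weighted_map(
        raw, phase_loo, config.alpha_f, config.beta_f, allow_negative=True
    )
    delta_m = np.clip(delta_m_signed, 0.0, None)

    # 6. calibration and CBF inversion (odd extension for signed input)
    m0_blood = kinetic.calibrate_m0(m0, mask, config.kinetic.lam)
    cbf = np.full(mask.shape, np.nan)
    valid = mask & np.isfinite(delta_m_signed) & np.isfinite(m0_blood) & (m0_blood > 0)
    norm = delta_m_signed[valid] / m0_blood[valid]
    p1 = replace(config.kinetic, m0_blood=1.0)
    dt_vox = None
    if bat_map is not None:
        bat = np.asarray(bat_map, dtype=float)
        if bat.shape != mask.shape:
            raise ValueError("bat_map grid must match the mask")
        dt_vox = np.where(np.isfinite(bat[valid]), bat[valid], config.kinetic.delta_t)
    f_vals, _ = kinetic.invert_cbf(
        np.abs(norm), config.pld, p1, delta_t=dt_vox, out_of_range="extrapolate"
    )
    cbf[valid] = np.sign(norm) * f_vals

    return {
        "phase_raw": phase_raw,
        "phase_smooth": phase_smooth,
        "segmentation": seg,
        "phase_hi": phase_hi,
        "delta_m": delta_m,
        "delta_m_signed": delta_m_signed,
        "m0_blood": m0_blood,
        "cbf": cbf,
    }
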