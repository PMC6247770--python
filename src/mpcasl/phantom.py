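"""Digital mouse-brain phantom and ASL acquisition simulator.

Generates a labelled region map (cortex / striatum / corpus callosum /
ventricle, optional tumour core and rim) with ground-truth perfusion
parameters, a smooth spatial labelling-phase offset field, and simulates
multiphase and multi-delay ASL series through the same forward model used
by the analysis code (:mod:`mpcasl.kinetic`, :mod:`mpcasl.pipeline`).

All randomness flows from a single seed; regenerating with the same seed
is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import kinetic
from .pipeline import MultiphaseSeries, PHASE_ANGLES, fermi_response, wrap_angle

#: region codes of the label map
REGIONS = {
    "background": 0,
    "cortex": 1,
    "striatum": 2,
    "corpus_callosum": 3,
    "ventricle": 4,
    "tumour_rim": 5,
    "tumour_core": 6,
}

#: default regional CBF, mL/100 g/min
DEFAULT_F = {"cortex": 103.0, "striatum": 90.0, "corpus_callosum": 77.0, "ventricle": 0.0}
#: default regional bolus arrival time, s
DEFAULT_DELTA_T = {
    "cortex": 0.12,
    "striatum": 0.18,
    "corpus_callosum": 0.26,
    "ventricle": 0.30,
}
#: default regional baseline (M0-weighted) signal
DEFAULT_M0 = {"cortex": 100.0, "striatum": 95.0, "corpus_callosum": 90.0, "ventricle": 110.0}

__all__ = [
    "REGIONS",
    "DEFAULT_F",
    "DEFAULT_DELTA_T",
    "DEFAULT_M0",
    "DigitalPhantom",
    "RespirationConfig",
    "AcquisitionConfig",
    "make_mouse_phantom",
    "add_tumour",
    "simulate_multiphase",
    "simulate_multi_pld",
]


@dataclass
class DigitalPhantom:
    """Ground-truth maps on a common voxel grid."""

    region_map: np.ndarray  # int codes per REGIONS
    f: np.ndarray  # CBF map, mL/100 g/min
    delta_t: np.ndarray  # arrival time map, s
    t1_tissue: np.ndarray  # s
    m0: np.ndarray  # baseline signal
    phase_offset: np.ndarray  # degrees, smooth field
    voxel_size: tuple = (0.3125, 0.3125, 1.0)
    seed: int = 0

    @property
    def mask(self) -> np.ndarray:
        return self.region_map > 0

    def region_mask(self, name: str) -> np.ndarray:
        return self.region_map == REGIONS[name]

    def region_mean(self, name: str, values: np.ndarray | None = None) -> float:
        vals = self.f if values is None else values
        sel = self.region_mask(name)
        return float(np.nanmean(vals[sel]))


@dataclass
class RespirationConfig:
    """Respiration-locked multiplicative signal fluctuation."""

    amplitude: float = 0.05  # fractional, at the most inferior slice
    period_s: float = 1.0
    triggered: bool = True  # triggering suppresses the fluctuation


@dataclass
class AcquisitionConfig:
    """Simulated MP pCASL acquisition settings."""

    phases: np.ndarray = field(default_factory=lambda: PHASE_ANGLES.copy())
    pld: float = 0.4
    tau: float = 0.9
    target_snr: float | None = None  # default: 15.1 triggered / 6.5 untriggered
    noise_sigma: float | None = None  # overrides target_snr when set
    noise: str = "gaussian"  # or "rician"
    tr: float = 4.0
    respiration: RespirationConfig = field(default_factory=RespirationConfig)
    seed: int = 0

    def resolved_snr(self) -> float:
        if self.target_snr is not None:
            return self.target_snr
        return 15.1 if self.respiration.triggered else 6.5


def _ellipse(shape2d, centre, semi, grid=None):
    ny, nx = shape2d
    yy, xx = np.mgrid[0:ny, 0:nx]
    return ((yy - centre[0]) / semi[0]) ** 2 + ((xx - centre[1]) / semi[1]) ** 2 <= 1.0


def make_mouse_phantom(
    seed: int = 0,
    shape=(64, 64, 8),
    f_defaults: dict | None = None,
    delta_t_defaults: dict | None = None,
    m0_defaults: dict | None = None,
    t1_tissue: float = 1.9,
    phase_amplitude: float = 60.0,
    f_jitter_sd: float = 0.0,
    delta_t_jitter_sd: float = 0.03,
    voxel_size=(0.3125, 0.3125, 1.0),
) -> DigitalPhantom:
    """Geometric mouse-brain phantom: nested ellipsoids plus a callosal band.

    Regional CBF defaults to {cortex 103, striatum 90, corpus callosum 77}
    mL/100 g/min.  Arrival times combine a regional base, a small
    anterior->posterior gradient, and seeded jitter such that the large
    majority (>= 95 %) of brain voxels arrive within 0.4 s.  The phase
    offset field is a sum of three low-order in-plane cosine modes scaled
    to ``phase_amplitude`` degrees peak.
    """
    shape = tuple(shape)
    if len(shape) != 3 or shape[0] < 16 or shape[1] < 16 or shape[2] < 1:
        raise ValueError("shape must be at least 16 x 16 x 1")
    f_defaults = {**DEFAULT_F, **(f_defaults or {})}
    delta_t_defaults = {**DEFAULT_DELTA_T, **(delta_t_defaults or {})}
    m0_defaults = {**DEFAULT_M0, **(m0_defaults or {})}
    rng = np.random.default_rng(seed)
    ny, nx, nz = shape

    region = np.zeros(shape, dtype=np.int16)
    centre = (ny / 2.0 - 0.5, nx / 2.0 - 0.5)
    for z in range(nz):
        # slice profile: brain shrinks toward both ends of the stack
        rel = 0.0 if nz == 1 else abs(z - (nz - 1) / 2.0) / (nz / 2.0)
        scale = np.sqrt(max(1.0 - 0.5 * rel**2, 0.2))
        a = 0.42 * ny * scale
        b = 0.36 * nx * scale
        brain = _ellipse((ny, nx), centre, (a, b))
        inner = _ellipse((ny, nx), centre, (0.62 * a, 0.62 * b))
        cc_outer = _ellipse((ny, nx), centre, (0.72 * a, 0.72 * b))
        vent = _ellipse((ny, nx), centre, (max(0.12 * a, 1.2), max(0.12 * b, 1.2)))
        sl = np.zeros((ny, nx), dtype=np.int16)
        sl[brain] = REGIONS["cortex"]
        sl[cc_outer] = REGIONS["corpus_callosum"]
        sl[inner] = REGIONS["striatum"]
        sl[vent] = REGIONS["ventricle"]
        region[:, :, z] = sl

    f = np.zeros(shape)
    dt = np.zeros(shape)
    m0 = np.zeros(shape)
    t1 = np.full(shape, t1_tissue)
    grad = (
        np.zeros(nz) if nz == 1 else 0.06 * np.arange(nz) / max(nz - 1, 1)
    )  # anterior -> posterior arrival gradient, s
    for name in ("cortex", "striatum", "corpus_callosum", "ventricle"):
        sel = region == REGIONS[name]
        f[sel] = f_defaults[name]
        m0[sel] = m0_defaults[name]
        dt[sel] = delta_t_defaults[name]
    dt += grad[None, None, :]
    mask = region > 0
    if f_jitter_sd > 0:
        f[mask] += rng.normal(0.0, f_jitter_sd, size=int(mask.sum()))
        f = np.clip(f, 0.0, None)
    if delta_t_jitter_sd > 0:
        dt[mask] += rng.normal(0.0, delta_t_jitter_sd, size=int(mask.sum()))
    dt = np.clip(dt, 0.0, None)
    dt[~mask] = 0.0
    f[~mask] = 0.0
    m0[~mask] = 0.0

    phase = _phase_field(rng, (ny, nx), phase_amplitude)
    phase_offset = np.repeat(phase[:, :, None], nz, axis=2)

    return DigitalPhantom(
        region_map=region,
        f=f,
        delta_t=dt,
        t1_tissue=t1,
        m0=m0,
        phase_offset=phase_offset,
        voxel_size=tuple(voxel_size),
        seed=seed,
    )


def _phase_field(rng, shape2d, amplitude: float) -> np.ndarray:
    """Sum of 3 low-order 2-D cosine modes, scaled to ``amplitude`` peak."""
    ny, nx = shape2d
    yy, xx = np.mgrid[0:ny, 0:nx]
    field2d = np.zeros((ny, nx))
    for _ in range(3):
        ky, kx = rng.integers(0, 3, size=2)
        if ky == 0 and kx == 0:
            kx = 1
        amp = rng.uniform(0.5, 1.0)
        psi = rng.uniform(0.0, 2.0 * np.pi)
        field2d += amp * np.cos(2.0 * np.pi * (ky * yy / ny + kx * xx / nx) + psi)
    peak = np.abs(field2d).max()
    if peak > 0 and amplitude > 0:
        field2d *= amplitude / peak
    elif amplitude == 0:
        field2d[:] = 0.0
    return field2d


def add_tumour(
    phantom: DigitalPhantom,
    centre=None,
    radius_core: float = 4.0,
    radius_rim: float = 7.0,
    f_core: float = 69.0,
    f_rim: float = 83.0,
    f_core_sd: float = 14.0,
    f_rim_sd: float = 5.0,
    seed: int | None = None,
) -> DigitalPhantom:
    """Concentric core/rim lesion overriding the (left) striatum.

    Defaults emulate a hypoperfused core (69 mL/100 g/min) inside a rim
    (83 mL/100 g/min), with inflated voxelwise variance in the core to
    reproduce intra-lesion heterogeneity.  Radii are in-plane voxels;
    ``radius_core = 0`` gives a rim-only lesion.  Raises if the lesion
    would overlap the ventricle or leave the brain mask.
    """
    if radius_rim <= 0 or radius_core < 0 or radius_core > radius_rim:
        raise ValueError("need 0 <= radius_core <= radius_rim, radius_rim > 0")
    region = phantom.region_map.copy()
    ny, nx, nz = region.shape
    if centre is None:
        # deepest left-striatum voxel: maximises clearance from both the
        # ventricle and the brain edge so default lesions stay legal
        from scipy import ndimage

        sel = (region == REGIONS["striatum"])
        sel[:, nx // 2 :, :] = False
        if not sel.any():
            raise ValueError("no left striatum voxels to seed the tumour")
        forbidden = (region == REGIONS["ventricle"]) | (region == REGIONS["background"])
        clearance = ndimage.distance_transform_edt(~forbidden)
        clearance[~sel] = -1.0
        centre = np.unravel_index(int(np.argmax(clearance)), region.shape)
    centre = np.asarray(centre, dtype=float)
    yy, xx, zz = np.mgrid[0:ny, 0:nx, 0:nz]
    zscale = phantom.voxel_size[2] / phantom.voxel_size[0]
    r2 = (
        (yy - centre[0]) ** 2
        + (xx - centre[1]) ** 2
        + ((zz - centre[2]) * zscale) ** 2
    )
    rim = r2 <= radius_rim**2
    core = r2 <= radius_core**2 if radius_core > 0 else np.zeros_like(rim)
    if np.any(rim & (region == REGIONS["ventricle"])):
        raise ValueError("tumour overlaps the ventricle")
    if np.any(rim & (region == REGIONS["background"])):
        raise ValueError("tumour extends outside the brain mask")
    region[rim] = REGIONS["tumour_rim"]
    region[core] = REGIONS["tumour_core"]

    rng = np.random.default_rng(phantom.seed + 1 if seed is None else seed)
    f = phantom.f.copy()
    rim_only = rim & ~core
    f[rim_only] = f_rim + rng.normal(0.0, f_rim_sd, size=int(rim_only.sum()))
    f[core] = f_core + rng.normal(0.0, f_core_sd, size=int(core.sum()))
    f = np.clip(f, 0.0, None)
    return replace(phantom, region_map=region, f=f)


def _kinetic_params(phantom: DigitalPhantom, acq: AcquisitionConfig) -> kinetic.KineticParams:
    return kinetic.KineticParams(
        tau=acq.tau,
        t1_tissue=float(np.median(phantom.t1_tissue)),
        m0_blood=1.0,
    )


def _apply_noise(rng, signal, sigma, kind):
    if sigma <= 0:
        return signal
    if kind == "gaussian":
        return signal + rng.normal(0.0, sigma, size=signal.shape)
    if kind == "rician":
        re = signal + rng.normal(0.0, sigma, size=signal.shape)
        im = rng.normal(0.0, sigma, size=signal.shape)
        return np.hypot(re, im)
    raise ValueError(f"unknown noise model: {kind!r}")


def simulate_multiphase(phantom: DigitalPhantom, acq: AcquisitionConfig):
    """Simulate an 8-phase labelling series.

    Per voxel, ``S(theta) = C - A * F(wrap(theta - phase_offset))`` with
    ``A`` the kinetic forward signal at ``t = pld + tau`` (scaled by the
    voxel's baseline via the blood magnetisation) and ``C`` the baseline.
    Additive seeded noise; in untriggered mode a respiration-locked
    multiplicative fluctuation is concentrated in the inferior slices.

    Returns ``(MultiphaseSeries, truth)`` where ``truth`` carries every
    map needed to score the pipeline without reading generator internals.
    """
    p = _kinetic_params(phantom, acq)
    m0_blood = phantom.m0 / p.lam
    a_map = (
        kinetic.delta_m_map(acq.pld + acq.tau, phantom.f, phantom.delta_t, p) * m0_blood
    )
    c_map = phantom.m0
    dtheta = wrap_angle(
        np.asarray(acq.phases)[None, None, None, :] - phantom.phase_offset[..., None]
    )
    signal = c_map[..., None] - a_map[..., None] * fermi_response(dtheta)

    rng = np.random.default_rng(acq.seed)
    mask = phantom.mask
    if acq.noise_sigma is not None:
        sigma = acq.noise_sigma
    else:
        sigma = float(c_map[mask].mean()) / acq.resolved_snr()

    # the respiration phase is drawn unconditionally so that triggered and
    # untriggered series with the same seed share the same noise stream
    phase0 = rng.uniform(0.0, 2.0 * np.pi)
    resp = acq.respiration
    if not resp.triggered and resp.amplitude > 0:
        nz = signal.shape[2]
        depth = np.exp(-np.arange(nz) / max(nz / 4.0, 1.0))  # inferior = slice 0
        t_acq = np.arange(signal.shape[-1]) * acq.tr
        flutter = 1.0 + resp.amplitude * depth[None, None, :, None] * np.sin(
            2.0 * np.pi * t_acq[None, None, None, :] / resp.period_s + phase0
        )
        signal = signal * flutter

    signal = _apply_noise(rng, signal, sigma, acq.noise)
    series = MultiphaseSeries(signal=signal, phase_angles=np.asarray(acq.phases))
    truth = {
        "delta_m": a_map,
        "baseline": c_map,
        "f": phantom.f,
        "delta_t": phantom.delta_t,
        "phase_offset": phantom.phase_offset,
        "m0_blood": m0_blood,
        "mask": mask,
        "region_map": phantom.region_map,
        "noise_sigma": sigma,
        "kinetic_params": p,
    }
    return series, truth


def simulate_multi_pld(
    phantom: DigitalPhantom,
    schedule: kinetic.PLDSchedule,
    acq: AcquisitionConfig,
):
    """Simulate a multi-delay difference-signal series.

    Output shape is grid + (n_pld,): the forward kinetic signal at each
    postlabel delay with the voxelwise arrival time, plus seeded noise
    scaled so the peak brain signal over delays has the target SNR.

    Returns ``(signal, truth)``.
    """
    p = _kinetic_params(phantom, acq)
    m0_blood = phantom.m0 / p.lam
    stacks = [
        kinetic.delta_m_map(pld + acq.tau, phantom.f, phantom.delta_t, p) * m0_blood
        for pld in schedule.pld_list
    ]
    signal = np.stack(stacks, axis=-1)
    mask = phantom.mask
    if acq.noise_sigma is not None:
        sigma = acq.noise_sigma
    else:
        peak = float(signal[mask].max(initial=0.0))
        sigma = peak / acq.resolved_snr() if peak > 0 else 0.0
    rng = np.random.default_rng(acq.seed)
    noisy = _apply_noise(rng, signal, sigma, acq.noise)
    truth = {
        "delta_m": signal,
        "f": phantom.f,
        "delta_t": phantom.delta_t,
        "m0_blood": m0_blood,
        "mask": mask,
        "noise_sigma": sigma,
        "kinetic_params": p,
        "schedule": schedule,
    }
    return noisy, truth
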