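"""Seeded synthetic intravital-microscopy scenes with known ground truth.

The generator emulates the statistical structure of multichannel IVM
recordings of a superficial tumor during RF hyperthermia:

* a tumor region constitutively expressing a red fluorophore (``tumor``
  channel),
* a perfused vessel network carrying a circulating macromolecular tracer
  (``dextran`` / ``albumin`` channels),
* temperature-dependent extravasation of the tracer through the vessel
  wall — enhanced in the mild-hyperthermia band (39-41 degC), declining
  above it, and shut off entirely at the coagulation temperature
  (default 44 degC),
* photon (scaled-Poisson) and read (Gaussian) acquisition noise, and
* optional rigid sinusoidal translation emulating respiration jitter.

Tracer kinetics are a two-compartment model.  The intravascular
concentration obeys

    dC/dt = -(clearance + k(T)) * C

and the extravasated flux ``k(T) * C`` is deposited at the abluminal
(boundary) pixels of perfused vessels, then spread by isotropic
diffusion.  Total tracer (intravascular + extravascular + cleared) is
conserved to floating-point accuracy; extravasated tracer is never
resorbed, so tissue accumulation is monotone — matching the observation
that enhanced perfusion persists after the RF power is switched off.

Every public entry point takes an explicit seed or ``numpy`` Generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import line as draw_line
from skimage.morphology import disk

from .physics import TemperatureTrace
from .stack import DEFAULT_CHANNEL_ROLES, ImageStack


class TimeCoverageError(ValueError):
    """Raised when a temperature trace does not cover all frame times."""


@dataclass(frozen=True)
class SceneConfig:
    """Geometry and acquisition layout of a synthetic scene.

    The tumor is an axis-aligned ellipse; ``tumor_axes_frac`` are the
    semi-axes as fractions of the half frame dimensions.
    """

    frame_shape: tuple[int, int] = (512, 512)
    n_frames: int = 48
    frame_interval_s: float = 10.0
    pixel_size_um: float = 1.24
    channel_roles: tuple[str, ...] = DEFAULT_CHANNEL_ROLES
    tumor_center_frac: tuple[float, float] = (0.5, 0.5)
    tumor_axes_frac: tuple[float, float] = (0.78, 0.66)
    tumor_amplitude: float = 0.9
    tracer_background: float = 0.02
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.frame_shape) <= 0:
            raise ValueError("frame_shape must be positive")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")

    @property
    def frame_times(self) -> np.ndarray:
        return self.frame_interval_s * np.arange(self.n_frames)

    def tumor_mask(self) -> np.ndarray:
        """Ground-truth tumor region (boolean)."""
        rows, cols = self.frame_shape
        cy = self.tumor_center_frac[0] * rows
        cx = self.tumor_center_frac[1] * cols
        ry = self.tumor_axes_frac[0] * rows / 2.0
        rx = self.tumor_axes_frac[1] * cols / 2.0
        mask = np.zeros(self.frame_shape, dtype=bool)
        rr, cc = draw_ellipse(cy, cx, ry, rx, shape=self.frame_shape)
        mask[rr, cc] = True
        return mask


@dataclass(frozen=True)
class VesselSegment:
    """One vessel centerline (float pixel coords, (N, 2) row/col) with a
    tube radius in pixels."""

    points: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
            raise ValueError("segment needs >= 2 (row, col) points")
        if not self.radius > 0:
            raise ValueError("radius must be > 0")


@dataclass
class VesselNetwork:
    """Collection of vessel segments with per-segment perfusion flags."""

    segments: list[VesselSegment]
    perfused: list[bool]
    frame_shape: tuple[int, int]

    def rasterize(self, perfused_only: bool = False) -> np.ndarray:
        """Boolean vessel mask: centerlines dilated to their tube radius."""
        canvas = np.zeros(self.frame_shape, dtype=bool)
        by_radius: dict[int, np.ndarray] = {}
        for seg, perf in zip(self.segments, self.perfused):
            if perfused_only and not perf:
                continue
            r = max(1, int(round(seg.radius)))
            layer = by_radius.setdefault(r, np.zeros(self.frame_shape, dtype=bool))
            pts = np.clip(
                np.round(seg.points).astype(int),
                [0, 0],
                [self.frame_shape[0] - 1, self.frame_shape[1] - 1],
            )
            for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
                rr, cc = draw_line(r0, c0, r1, c1)
                layer[rr, cc] = True
        for r, layer in by_radius.items():
            canvas |= ndimage.binary_dilation(layer, structure=disk(r))
        return canvas


def _walk_vessel(
    cfg: SceneConfig, rng: np.random.Generator, tortuosity: float, step_px: float
) -> np.ndarray:
    """Random-walk centerline entering the tumor from its rim."""
    rows, cols = cfg.frame_shape
    cy = cfg.tumor_center_frac[0] * rows
    cx = cfg.tumor_center_frac[1] * cols
    ry = cfg.tumor_axes_frac[0] * rows / 2.0
    rx = cfg.tumor_axes_frac[1] * cols / 2.0
    theta = rng.uniform(0, 2 * math.pi)
    start = np.array([cy + ry * math.sin(theta), cx + rx * math.cos(theta)])
    # Head inward with a random skew so vessels cross, not just radiate.
    heading = math.atan2(cy - start[0], cx - start[1]) + rng.uniform(-0.6, 0.6)
    n_steps = int(2.2 * max(ry, rx) / step_px)
    pts = [start]
    for _ in range(n_steps):
        heading += tortuosity * rng.normal()
        nxt = pts[-1] + step_px * np.array([math.sin(heading), math.cos(heading)])
        nxt = np.clip(nxt, [1.0, 1.0], [rows - 2.0, cols - 2.0])
        pts.append(nxt)
    return np.asarray(pts)


def generate_vessel_network(
    cfg: SceneConfig,
    n_vessels: int = 8,
    tortuosity: float = 0.35,
    rng: np.random.Generator | int | None = None,
    radius_px: float = 2.0,
    step_px: float = 6.0,
    target_area_fraction: float | None = None,
    max_extra_vessels: int = 40,
) -> VesselNetwork:
    """Generate a seeded random vessel network threading the tumor.

    With ``target_area_fraction`` set, vessels are grown one at a time
    until the rasterized vessel area inside the tumor reaches that
    fraction of the tumor area; each vessel adds a small increment, so
    the overshoot stays within a few percent of the target.  Without it,
    exactly ``n_vessels`` vessels are drawn.  ``tortuosity = 0`` yields
    straight segments.
    """
    if n_vessels < 1:
        raise ValueError("n_vessels must be >= 1")
    rng = np.random.default_rng(rng)

    def new_segment() -> VesselSegment:
        return VesselSegment(points=_walk_vessel(cfg, rng, tortuosity, step_px),
                             radius=radius_px)

    net = VesselNetwork(segments=[], perfused=[], frame_shape=cfg.frame_shape)
    if target_area_fraction is None:
        for _ in range(n_vessels):
            net.segments.append(new_segment())
            net.perfused.append(True)
        return net
    tumor = cfg.tumor_mask()
    tumor_area = tumor.sum()
    for _ in range(max_extra_vessels):
        net.segments.append(new_segment())
        net.perfused.append(True)
        frac = (net.rasterize() & tumor).sum() / tumor_area
        if frac >= target_area_fraction:
            break
    return net


@dataclass(frozen=True)
class TracerKinetics:
    """Two-compartment extravasation parameters.

    ``permeability_base`` (k0, 1/s) is the transvascular leak rate at
    normothermia; in the mild-hyperthermia band ``enhancement_band``
    (degC) it is multiplied by ``enhancement_factor`` (alpha >= 1), above
    the band it declines linearly to zero at ``shutdown_temp_c`` (vessel
    coagulation).  ``diffusion_coeff`` (px^2/s) spreads extravasated
    tracer through the interstitium.
    """

    c_vasc0: float = 1.0
    clearance_rate: float = 2.0e-4
    permeability_base: float = 1.0e-4
    enhancement_factor: float = 10.0
    shutdown_temp_c: float = 44.0
    diffusion_coeff: float = 2.0
    enhancement_band: tuple[float, float] = (39.0, 41.0)

    def __post_init__(self) -> None:
        for name in ("c_vasc0", "clearance_rate", "permeability_base",
                     "diffusion_coeff"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.enhancement_factor < 1:
            raise ValueError("enhancement_factor must be >= 1")
        lo, hi = self.enhancement_band
        if not lo < hi < self.shutdown_temp_c:
            raise ValueError(
                "require enhancement_band.low < high < shutdown_temp_c"
            )


def permeability_at(kin: TracerKinetics, temp_c: float | np.ndarray) -> float | np.ndarray:
    """Vessel-wall permeability k(T) in 1/s.

    Piecewise in temperature: baseline k0 below the enhancement band,
    alpha*k0 inside it (a step up at the lower band edge), a linear
    decline from alpha*k0 down to zero between the upper band edge and
    the shutdown temperature, and exactly zero at or above shutdown.
    """
    t = np.asarray(temp_c, dtype=float)
    k0 = kin.permeability_base
    lo, hi = kin.enhancement_band
    peak = kin.enhancement_factor * k0
    decline = peak * (kin.shutdown_temp_c - t) / (kin.shutdown_temp_c - hi)
    out = np.where(
        t < lo, k0,
        np.where(t <= hi, peak, np.where(t < kin.shutdown_temp_c, decline, 0.0)),
    )
    return out if out.ndim else float(out)


@dataclass
class TracerScene:
    """Ground-truth generator state for one time-lapse.

    Extravascular fields hold per-pixel tracer amounts in the same
    intensity units as the intravascular concentration; the intravascular
    total is ``c_vasc * vessel_area``.
    """

    times: np.ndarray
    tumor_mask: np.ndarray
    vessel_mask: np.ndarray
    c_vasc: np.ndarray
    extravascular: np.ndarray
    cleared: np.ndarray
    permeability: np.ndarray
    c_vasc0: float

    @property
    def vessel_area(self) -> int:
        return int(self.vessel_mask.sum())

    def extravascular_total(self, frame: int = -1) -> float:
        """Total extravasated tracer at a frame (intensity * px)."""
        return float(self.extravascular[frame].sum())

    def extravascular_in(self, region: np.ndarray, frame: int = -1) -> float:
        """Extravasated tracer inside a boolean region at a frame.

        The natural region is the ground-truth extravascular tumor
        compartment (``tumor_mask & ~vessel_mask``): tracer that has
        diffused beyond the tumor is outside the quantity an imaging
        analysis of the tumor region reports.
        """
        return float(self.extravascular[frame][np.asarray(region, bool)].sum())

    def mass_balance_error(self) -> float:
        """Max relative deviation of (intravascular + extravascular +
        cleared) from the initial total, over all frames."""
        total0 = self.c_vasc0 * self.vessel_area
        totals = (
            self.c_vasc * self.vessel_area
            + self.extravascular.sum(axis=(1, 2))
            + self.cleared
        )
        return float(np.max(np.abs(totals - total0)) / total0)


def vessel_boundary(vessel_mask: np.ndarray) -> np.ndarray:
    """Abluminal shell: pixels adjacent to, but outside, the vessels."""
    return ndimage.binary_dilation(vessel_mask, structure=disk(1)) & ~vessel_mask


def simulate_tracer(
    tumor_mask: np.ndarray,
    network: VesselNetwork,
    kin: TracerKinetics,
    trace: TemperatureTrace,
    cfg: SceneConfig,
    substep_s: float = 1.0,
) -> TracerScene:
    """Integrate the two-compartment extravasation model over the scene.

    Per sub-step the intravascular pool decays by the exact exponential
    factor for the combined (clearance + permeability) rate; the
    extravasated share is deposited uniformly on the abluminal pixels of
    perfused vessels and then diffused (Gaussian kernel, reflecting
    boundaries, which conserves mass exactly).  Mass balance therefore
    holds to floating-point round-off by construction.
    """
    times = cfg.frame_times
    if not trace.covers(times):
        raise TimeCoverageError(
            f"temperature trace [{trace.times[0]}, {trace.times[-1]}] s does "
            f"not cover frame times up to {times[-1]} s"
        )
    vessel_mask = network.rasterize()
    deposit_mask = vessel_boundary(network.rasterize(perfused_only=True))
    dep_idx = np.nonzero(deposit_mask)
    n_dep = max(1, dep_idx[0].size)
    vessel_area = float(vessel_mask.sum())

    n_frames = cfg.n_frames
    extrav = np.zeros((n_frames,) + cfg.frame_shape)
    c_vasc = np.empty(n_frames)
    cleared = np.empty(n_frames)
    perm = np.empty(n_frames)

    c = kin.c_vasc0
    cleared_mass = 0.0
    field_now = np.zeros(cfg.frame_shape)
    c_vasc[0] = c
    cleared[0] = 0.0
    perm[0] = permeability_at(kin, float(trace.at(times[0])))

    for i in range(1, n_frames):
        t0, t1 = times[i - 1], times[i]
        n_sub = max(1, int(math.ceil((t1 - t0) / substep_s)))
        dt = (t1 - t0) / n_sub
        sigma = math.sqrt(2.0 * kin.diffusion_coeff * dt) if kin.diffusion_coeff > 0 else 0.0
        for s in range(n_sub):
            t_mid = t0 + (s + 0.5) * dt
            k = permeability_at(kin, float(trace.at(t_mid)))
            rate = kin.clearance_rate + k
            if rate > 0:
                transferred = c * (1.0 - math.exp(-rate * dt))
                c -= transferred
                extr_share = transferred * (k / rate)
                cleared_mass += (transferred - extr_share) * vessel_area
                if extr_share > 0:
                    field_now[dep_idx] += extr_share * vessel_area / n_dep
            if sigma > 0 and field_now.any():
                field_now = ndimage.gaussian_filter(field_now, sigma, mode="reflect")
        c_vasc[i] = c
        cleared[i] = cleared_mass
        extrav[i] = field_now
        perm[i] = permeability_at(kin, float(trace.at(t1)))

    return TracerScene(
        times=times,
        tumor_mask=tumor_mask,
        vessel_mask=vessel_mask,
        c_vasc=c_vasc,
        extravascular=extrav,
        cleared=cleared,
        permeability=perm,
        c_vasc0=kin.c_vasc0,
    )


@dataclass(frozen=True)
class AcquisitionNoise:
    """Acquisition noise and motion parameters.

    ``photon_scale`` is the intensity per detected photon (gain): photon
    noise is scaled-Poisson, so variance grows linearly with both signal
    and gain.  ``read_sigma`` is additive Gaussian read noise.  Jitter is
    a rigid sinusoidal frame translation of amplitude
    ``jitter_amplitude_px`` and period ``jitter_period_s``.
    """

    photon_scale: float = 1.0e-3
    read_sigma: float = 4.0e-3
    jitter_amplitude_px: float = 0.0
    jitter_period_s: float = 2.0

    def __post_init__(self) -> None:
        if min(self.photon_scale, self.read_sigma,
               self.jitter_amplitude_px, self.jitter_period_s) < 0:
            raise ValueError("noise parameters must be nonnegative")


NOISELESS = AcquisitionNoise(photon_scale=0.0, read_sigma=0.0,
                             jitter_amplitude_px=0.0)


def jitter_shifts(noise: AcquisitionNoise, times: np.ndarray) -> np.ndarray:
    """Deterministic (row, col) respiration shifts per frame, px."""
    times = np.asarray(times, dtype=float)
    if noise.jitter_amplitude_px == 0:
        return np.zeros((times.size, 2))
    phase = 2.0 * math.pi * times / noise.jitter_period_s
    return noise.jitter_amplitude_px * np.stack(
        [np.sin(phase), np.sin(phase + math.pi / 3.0)], axis=1
    )


def _tumor_texture(cfg: SceneConfig, tumor_mask: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    blur = ndimage.gaussian_filter(rng.normal(size=cfg.frame_shape), 6.0)
    blur /= max(np.abs(blur).max(), 1e-12)
    tex = cfg.tumor_amplitude * (1.0 + 0.35 * blur)
    return np.where(tumor_mask, np.clip(tex, 0.05, None), 0.0)


def render_timelapse(
    scene: TracerScene,
    noise: AcquisitionNoise,
    cfg: SceneConfig,
    rng: np.random.Generator | int | None = None,
) -> ImageStack:
    """Render a scene into a multichannel stack with noise and jitter.

    Channel content: the tumor channel is a static textured field on the
    tumor mask; each tracer channel is the diffuse background plus the
    intravascular concentration on the vessel mask plus the extravascular
    field.  With all noise and jitter parameters zero, tracer-channel
    pixel values equal the scene concentrations exactly.
    """
    if scene.times.size != cfg.n_frames:
        raise ValueError("scene frame count does not match config")
    rng = np.random.default_rng(rng)
    tumor_tex = _tumor_texture(cfg, scene.tumor_mask, rng)
    vessel = scene.vessel_mask
    shifts = jitter_shifts(noise, scene.times)
    n_ch = len(cfg.channel_roles)
    frames = np.empty((cfg.n_frames, n_ch, *cfg.frame_shape), dtype=np.float32)

    for i in range(cfg.n_frames):
        tracer = (cfg.tracer_background
                  + scene.c_vasc[i] * vessel
                  + scene.extravascular[i])
        for ci, role in enumerate(cfg.channel_roles):
            img = tumor_tex if role == "tumor" else tracer
            if shifts[i].any():
                img = ndimage.shift(img, shifts[i], order=1, mode="nearest")
            if noise.photon_scale > 0:
                img = rng.poisson(
                    np.clip(img, 0, None) / noise.photon_scale
                ) * noise.photon_scale
            if noise.read_sigma > 0:
                img = img + rng.normal(0.0, noise.read_sigma, size=img.shape)
            frames[i, ci] = np.clip(img, 0.0, None)
    return ImageStack(frames=frames, channel_roles=cfg.channel_roles,
                      timestamps_s=scene.times.copy())


# ---------------------------------------------------------------------------
# Study presets: RF-treated vs untreated-control imaging sessions.


def ramp_hold_trace(
    t_end_s: float,
    rf_on_s: float,
    rf_off_s: float,
    baseline_c: float = 37.0,
    plateau_c: float = 40.5,
    ramp_tau_s: float = 40.0,
    cool_tau_s: float = 60.0,
    dt_s: float = 1.0,
) -> TemperatureTrace:
    """Tumor-temperature profile for a set-point-limited RF exposure:
    baseline, exponential ramp toward a plateau just under the mild-
    hyperthermia ceiling while the power is on, exponential relaxation
    back to baseline after power-off."""
    times = np.arange(0.0, t_end_s + dt_s / 2, dt_s)
    temp = np.full_like(times, baseline_c)
    on = (times >= rf_on_s) & (times < rf_off_s)
    temp[on] = plateau_c - (plateau_c - baseline_c) * np.exp(
        -(times[on] - rf_on_s) / ramp_tau_s
    )
    t_off_val = plateau_c - (plateau_c - baseline_c) * math.exp(
        -(rf_off_s - rf_on_s) / ramp_tau_s
    )
    after = times >= rf_off_s
    temp[after] = baseline_c + (t_off_val - baseline_c) * np.exp(
        -(times[after] - rf_off_s) / cool_tau_s
    )
    return TemperatureTrace(times=times, temperature=temp,
                            probe_labels=("tumor",))


@dataclass(frozen=True)
class Scenario:
    """Bundle of everything needed to synthesise one imaging session."""

    name: str
    scene: SceneConfig
    kinetics: TracerKinetics
    noise: AcquisitionNoise
    temperature: TemperatureTrace
    rf_off_s: float | None = None
    n_vessels: int = 6
    tortuosity: float = 0.35
    vessel_area_fraction: float = 0.08
    vessel_radius_px: float = 1.0


#: Duration of the RF exposure window in the treated imaging preset, s.
TREATED_EXPOSURE_S = 270.0  # 4.5 min
#: Start of the RF window after the pre-exposure baseline, s.
TREATED_RF_ON_S = 30.0
#: Control sessions image an untreated tumor for 30 min.
CONTROL_DURATION_S = 1800.0


def treated_control_presets(
    frame_shape: tuple[int, int] = (256, 256),
) -> tuple[Scenario, Scenario]:
    """Default treated (RF, mild hyperthermia) and control (no RF)
    scenarios.

    The treated session ramps the tumor to just below 41 degC for a
    4.5-minute exposure and keeps imaging through the post-exposure
    cool-down; the control session images the same scene geometry at
    normothermia for 30 minutes with a near-zero baseline permeability
    (the impaired perfusion barrier of untreated tumors).  The kinetic
    constants are pinned so that the end-point accumulation contrast of
    the pair reproduces the magnitude of RF-enhanced tracer delivery the
    quantification module is meant to detect.
    """
    rf_off = TREATED_RF_ON_S + TREATED_EXPOSURE_S
    treated_scene = SceneConfig(
        frame_shape=frame_shape, n_frames=48, frame_interval_s=10.0
    )
    treated = Scenario(
        name="treated",
        scene=treated_scene,
        kinetics=TracerKinetics(permeability_base=1.25e-4),
        noise=AcquisitionNoise(),
        temperature=ramp_hold_trace(
            t_end_s=treated_scene.frame_times[-1] + 10.0,
            rf_on_s=TREATED_RF_ON_S,
            rf_off_s=rf_off,
        ),
        rf_off_s=rf_off,
    )
    control_scene = SceneConfig(
        frame_shape=frame_shape, n_frames=60, frame_interval_s=30.0
    )
    t = np.array([0.0, CONTROL_DURATION_S + 30.0])
    control = Scenario(
        name="control",
        scene=control_scene,
        kinetics=TracerKinetics(permeability_base=2.0e-6),
        noise=AcquisitionNoise(),
        temperature=TemperatureTrace(
            times=t, temperature=np.full_like(t, 37.0), probe_labels=("tumor",)
        ),
        rf_off_s=None,
    )
    return treated, control


def simulate_scenario(
    scenario: Scenario,
    seed: int,
    noise: AcquisitionNoise | None = None,
    substep_s: float = 1.0,
) -> tuple[VesselNetwork, TracerScene, ImageStack]:
    """Run one scenario end-to-end: vessels, kinetics, rendered stack.

    ``noise`` overrides the scenario's acquisition noise (e.g.
    :data:`NOISELESS` for ground-truth recovery checks).  Deterministic
    for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    net_rng, render_rng = rng.spawn(2)
    network = generate_vessel_network(
        scenario.scene,
        n_vessels=scenario.n_vessels,
        tortuosity=scenario.tortuosity,
        rng=net_rng,
        radius_px=scenario.vessel_radius_px,
        target_area_fraction=scenario.vessel_area_fraction,
    )
    scene = simulate_tracer(
        scenario.scene.tumor_mask(), network, scenario.kinetics,
        scenario.temperature, scenario.scene, substep_s=substep_s,
    )
    stack = render_timelapse(
        scene, noise if noise is not None else scenario.noise,
        scenario.scene, rng=render_rng,
    )
    return network, scene, stack
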