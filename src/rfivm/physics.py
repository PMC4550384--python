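"""Lumped physics of capacitively-delivered radiofrequency hyperthermia.

The module models the thermal side of an RF exposure rig operating at a
fixed ISM frequency (13.56 MHz by default): how a lossy dielectric sample
converts an applied electric field into heat, how the field between the
transmitting and receiving heads is reconstructed from a measured voltage
grid, and how tissue temperature evolves when a set-point controller
switches the power amplifier on and off.

Heating is described by the specific-absorption-rate relation

    HR = dT/dt = omega * eps0 * eps'' * |E|^2 / (2 * rho * c_p)   [K/s]

where ``eps''`` is the imaginary (loss) part of the complex relative
permittivity, ``E`` the field amplitude, ``rho`` the mass density and
``c_p`` the specific heat.  The variant without the angular-frequency
factor is also exposed (``include_omega=False``); see
:func:`heating_rate`.

Temperature dynamics are a single lumped compartment with Newtonian
cooling toward ambient:

    dT/dt = HR * P(t)/P_max - h * (T - T_ambient)

integrated with an explicit fixed-step (Euler) scheme.  This is not a
bioheat PDE; it reproduces the ramp/decay shape of probe traces, not
spatial temperature fields.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: Vacuum permittivity, F/m.
VACUUM_PERMITTIVITY = 8.854e-12

#: Default drive frequency of the RF amplifier, Hz.
DEFAULT_FREQUENCY_HZ = 13.56e6


class InvalidMaterialError(ValueError):
    """Raised for non-physical material parameters (rho or c_p <= 0)."""


class InvalidGridError(ValueError):
    """Raised for malformed voltage grids (bad spacing or size)."""


class InvalidScheduleError(ValueError):
    """Raised for empty or non-monotone power schedules."""


class NoOverlapError(ValueError):
    """Raised when two temperature traces share no time support."""


class ControllerStalledError(RuntimeError):
    """Raised when the set-point controller cannot complete its protocol.

    Typically the ambient temperature sits above the resume band, so the
    sample never cools enough to re-arm the next heating episode; detected
    by a step cap rather than analytically.
    """


@dataclass(frozen=True)
class ComplexPermittivity:
    """Complex relative permittivity eps* = eps' - i eps'' at a frequency.

    ``eps_real`` stores energy, ``eps_imag`` (the loss factor) converts it
    to heat.  Both are dimensionless relative values.
    """

    eps_real: float
    eps_imag: float
    frequency_hz: float = DEFAULT_FREQUENCY_HZ

    def __post_init__(self) -> None:
        if not self.eps_real > 0:
            raise ValueError(f"eps_real must be > 0, got {self.eps_real}")
        if self.eps_imag < 0:
            raise ValueError(f"eps_imag must be >= 0, got {self.eps_imag}")
        if not self.frequency_hz > 0:
            raise ValueError(f"frequency_hz must be > 0, got {self.frequency_hz}")

    @property
    def omega(self) -> float:
        """Angular frequency, rad/s."""
        return 2.0 * math.pi * self.frequency_hz


@dataclass(frozen=True)
class MaterialThermal:
    """Bulk thermal properties: density rho (kg/m^3), c_p (J/(kg K))."""

    density: float
    specific_heat: float

    def __post_init__(self) -> None:
        if not self.density > 0 or not self.specific_heat > 0:
            raise InvalidMaterialError(
                f"density and specific_heat must be > 0, got "
                f"rho={self.density}, c_p={self.specific_heat}"
            )


#: Permittivity/thermal values in the range reported for tumor tissue at
#: low-MHz frequencies; used as defaults by the simulators.
TUMOR_TISSUE = MaterialThermal(density=1000.0, specific_heat=4186.0)
TUMOR_PERMITTIVITY = ComplexPermittivity(eps_real=90.0, eps_imag=70.0)


@dataclass(frozen=True)
class VoltageGrid:
    """Voltages measured on a uniform 2-D grid between the TX and RX heads."""

    values: np.ndarray
    spacing: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if not self.spacing > 0:
            raise InvalidGridError(f"spacing must be > 0 m, got {self.spacing}")
        if values.ndim != 2 or min(values.shape) < 2:
            raise InvalidGridError(
                f"voltage grid must be at least 2x2, got shape {values.shape}"
            )

    @classmethod
    def from_csv(cls, path: str | Path) -> "VoltageGrid":
        """Read a grid written by :meth:`to_csv` (header carries spacing)."""
        path = Path(path)
        with path.open() as fh:
            header = fh.readline().strip()
        if not header.startswith("# spacing_m="):
            raise InvalidGridError(
                f"{path}: expected '# spacing_m=<value>' header, got {header!r}"
            )
        spacing = float(header.split("=", 1)[1])
        values = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(values=values, spacing=spacing)

    def to_csv(self, path: str | Path) -> None:
        np.savetxt(path, self.values, delimiter=",",
                   header=f"spacing_m={self.spacing}", comments="# ")


@dataclass(frozen=True)
class FieldGrid:
    """Electric field reconstructed on a voltage grid: per-axis components
    (V/m) and their Euclidean norm."""

    magnitude: np.ndarray
    components: tuple[np.ndarray, ...]


@dataclass(frozen=True)
class PowerSchedule:
    """Piecewise-constant, right-continuous applied power P(t).

    ``power[i]`` holds on ``[times[i], times[i+1])``; before ``times[0]``
    the power is zero, after ``times[-1]`` it is ``power[-1]``.
    """

    times: np.ndarray
    power: np.ndarray
    max_power: float = 200.0

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        power = np.asarray(self.power, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "power", power)
        if times.size == 0:
            raise InvalidScheduleError("power schedule is empty")
        if times.size != power.size:
            raise InvalidScheduleError("times and power must have equal length")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise InvalidScheduleError("schedule times must be strictly increasing")
        if np.any(power < 0) or np.any(power > self.max_power):
            raise InvalidScheduleError(
                f"power must lie within [0, {self.max_power}] W"
            )

    def power_at(self, t: float | np.ndarray) -> np.ndarray:
        """Evaluate P(t) (vectorised)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, self.power[np.clip(idx, 0, None)], 0.0)
        return out

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"time_s": self.times, "power_w": self.power}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path, max_power: float = 200.0) -> "PowerSchedule":
        df = pd.read_csv(path)
        return cls(times=df["time_s"].to_numpy(),
                   power=df["power_w"].to_numpy(), max_power=max_power)


@dataclass(frozen=True)
class TemperatureTrace:
    """Temperature time series for one or more probes.

    ``temperature`` has shape ``(n_times, n_probes)``; a 1-D array is
    promoted to a single probe.
    """

    times: np.ndarray
    temperature: np.ndarray
    probe_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        temp = np.asarray(self.temperature, dtype=float)
        if temp.ndim == 1:
            temp = temp[:, None]
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "temperature", temp)
        if temp.shape[0] != times.shape[0]:
            raise ValueError("temperature and times lengths differ")
        if not np.all(np.isfinite(temp)):
            raise ValueError("temperatures must be finite")
        if not self.probe_labels:
            labels = tuple(f"probe{i + 1}" for i in range(temp.shape[1]))
            object.__setattr__(self, "probe_labels", labels)
        elif len(self.probe_labels) != temp.shape[1]:
            raise ValueError("probe_labels length mismatch")

    @property
    def n_probes(self) -> int:
        return self.temperature.shape[1]

    def probe(self, which: int | str = 0) -> np.ndarray:
        """Temperature series of a single probe (by index or label)."""
        if isinstance(which, str):
            which = self.probe_labels.index(which)
        return self.temperature[:, which]

    def at(self, t: float | np.ndarray, which: int | str = 0) -> np.ndarray:
        """Linearly interpolate one probe's temperature at time(s) t."""
        return np.interp(np.asarray(t, dtype=float), self.times, self.probe(which))

    def covers(self, t: np.ndarray) -> bool:
        t = np.asarray(t, dtype=float)
        return bool(t.min() >= self.times[0] - 1e-9 and
                    t.max() <= self.times[-1] + 1e-9)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame({"time_s": self.times})
        for j, lab in enumerate(self.probe_labels):
            df[lab] = self.temperature[:, j]
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TemperatureTrace":
        df = pd.read_csv(path)
        labels = tuple(c for c in df.columns if c != "time_s")
        return cls(times=df["time_s"].to_numpy(),
                   temperature=df[list(labels)].to_numpy(),
                   probe_labels=labels)


@dataclass(frozen=True)
class ControllerConfig:
    """Set-point protocol for pulsed hyperthermia.

    The amplifier runs at ``on_power`` until the reference probe reaches
    the current set-point, is switched off until every probe has cooled
    back into ``resume_band``, then re-arms with the next (lower)
    set-point.  Defaults follow the three-step 45/43/41 degC protocol with
    a 29-31 degC resume window.
    """

    setpoints: tuple[float, ...] = (45.0, 43.0, 41.0)
    resume_band: tuple[float, float] = (29.0, 31.0)
    on_power: float = 90.0

    def __post_init__(self) -> None:
        sp = tuple(float(s) for s in self.setpoints)
        object.__setattr__(self, "setpoints", sp)
        if len(sp) == 0:
            raise ValueError("at least one setpoint required")
        if len(sp) > 1 and not all(a > b for a, b in zip(sp, sp[1:])):
            raise ValueError("setpoints must be strictly decreasing")
        lo, hi = self.resume_band
        if not lo < hi:
            raise ValueError("resume_band must satisfy low < high")
        if hi >= min(sp):
            raise ValueError("resume_band.high must lie below every setpoint")
        if self.on_power <= 0:
            raise ValueError("on_power must be > 0 W")


def heating_rate(
    perm: ComplexPermittivity,
    field_vm: float | np.ndarray,
    mat: MaterialThermal,
    include_omega: bool = True,
) -> float | np.ndarray:
    """Dielectric heating rate dT/dt (K/s) of a sample in a field.

    Parameters
    ----------
    perm
        Complex permittivity of the sample at the drive frequency.
    field_vm
        Electric-field amplitude(s), V/m (nonnegative).
    mat
        Density and specific heat of the sample.
    include_omega
        With ``True`` (default) the rate carries the angular-frequency
        factor, ``omega * eps0 * eps'' * E^2 / (2 rho c_p)``, which is the
        dimensionally consistent loss form.  With ``False`` the omega
        factor is dropped — the compact textbook shorthand in which
        ``eps''(omega)`` implicitly absorbs the frequency.  Both are exact
        to quadratic field scaling; they differ by the constant omega.
    """
    field = np.asarray(field_vm, dtype=float)
    if np.any(field < 0):
        raise ValueError("field_vm must be nonnegative")
    rate = (
        VACUUM_PERMITTIVITY * perm.eps_imag * field ** 2
        / (2.0 * mat.density * mat.specific_heat)
    )
    if include_omega:
        rate = perm.omega * rate
    return rate if rate.ndim else float(rate)


def efield_from_voltage(grid: VoltageGrid) -> FieldGrid:
    """Reconstruct E = -grad(V) from a uniform voltage grid.

    Central differences on interior nodes, one-sided differences on the
    boundary rows/columns.  The magnitude is the per-node Euclidean norm
    of the components.
    """
    grads = np.gradient(grid.values, grid.spacing)
    components = tuple(-g for g in grads)
    magnitude = np.sqrt(sum(c ** 2 for c in components))
    return FieldGrid(magnitude=magnitude, components=components)


def _heating_rates_per_probe(
    perm: ComplexPermittivity,
    mat: MaterialThermal,
    field_at_max_power: float | Sequence[float],
    include_omega: bool,
) -> np.ndarray:
    fields = np.atleast_1d(np.asarray(field_at_max_power, dtype=float))
    return np.atleast_1d(heating_rate(perm, fields, mat, include_omega=include_omega))


def simulate_temperature(
    schedule: PowerSchedule,
    perm: ComplexPermittivity = TUMOR_PERMITTIVITY,
    mat: MaterialThermal = TUMOR_TISSUE,
    field_at_max_power: float | Sequence[float] = 15e3,
    cooling_coeff: float = 0.0,
    ambient_c: float = 30.0,
    t0_c: float = 30.0,
    dt: float = 0.1,
    probe_labels: tuple[str, ...] = (),
) -> TemperatureTrace:
    """Integrate the lumped heating/cooling ODE over a power schedule.

    ``field_at_max_power`` is the field amplitude each probe sees at full
    amplifier power; instantaneous heating scales linearly with
    ``P(t)/max_power`` (power, not field, is the commanded quantity).
    A scalar simulates one probe; a sequence simulates one trace per
    probe, emulating field fall-off with distance from the TX head.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if cooling_coeff < 0:
        raise ValueError("cooling_coeff must be >= 0")
    hr = _heating_rates_per_probe(perm, mat, field_at_max_power, include_omega=True)
    t_start, t_end = float(schedule.times[0]), float(schedule.times[-1])
    n_steps = max(1, int(round((t_end - t_start) / dt)))
    times = t_start + dt * np.arange(n_steps + 1)
    temps = np.empty((n_steps + 1, hr.size))
    temps[0] = t0_c
    frac = schedule.power_at(times) / schedule.max_power
    for i in range(n_steps):
        dTdt = hr * frac[i] - cooling_coeff * (temps[i] - ambient_c)
        temps[i + 1] = temps[i] + dt * dTdt
    return TemperatureTrace(times=times, temperature=temps,
                            probe_labels=probe_labels)


def setpoint_controller(
    cfg: ControllerConfig,
    perm: ComplexPermittivity = TUMOR_PERMITTIVITY,
    mat: MaterialThermal = TUMOR_TISSUE,
    field_at_max_power: float | Sequence[float] = 15e3,
    max_power: float = 200.0,
    cooling_coeff: float = 0.005,
    ambient_c: float = 30.0,
    t0_c: float = 30.0,
    dt: float = 0.1,
    max_steps: int = 5_000_000,
    probe_labels: tuple[str, ...] = (),
) -> tuple[PowerSchedule, TemperatureTrace]:
    """Simulate the on/off set-point protocol and return (schedule, trace).

    Probe 0 is the reference: power switches off the moment its
    temperature reaches the active set-point.  Power resumes — with the
    next, lower set-point — once *all* probes have re-entered the resume
    band.  The run terminates when the last set-point has been reached.

    Raises
    ------
    ControllerStalledError
        If the protocol does not finish within ``max_steps`` integration
        steps (e.g. ambient above the resume band, or heating too weak to
        reach a set-point).
    """
    hr = _heating_rates_per_probe(perm, mat, field_at_max_power, include_omega=True)
    power_frac = cfg.on_power / max_power

    times = [0.0]
    temps = [np.full(hr.size, float(t0_c))]
    sched_times = [0.0]
    sched_power = [cfg.on_power]

    setpoint_idx = 0
    heating = True
    # Degenerate boundary: reference already at/above the first setpoint.
    while setpoint_idx < len(cfg.setpoints) and temps[0][0] >= cfg.setpoints[setpoint_idx]:
        setpoint_idx += 1
    if setpoint_idx > 0:
        heating = False
        sched_power[0] = 0.0
    done = setpoint_idx >= len(cfg.setpoints)

    step = 0
    while not done:
        step += 1
        if step > max_steps:
            raise ControllerStalledError(
                f"set-point protocol incomplete after {max_steps} steps; "
                f"check that ambient ({ambient_c} degC) lies below the "
                f"resume band {cfg.resume_band}"
            )
        T = temps[-1]
        drive = hr * power_frac if heating else 0.0
        T_next = T + dt * (drive - cooling_coeff * (T - ambient_c))
        t_next = times[-1] + dt
        times.append(t_next)
        temps.append(T_next)
        if heating:
            if T_next[0] >= cfg.setpoints[setpoint_idx]:
                setpoint_idx += 1
                heating = False
                sched_times.append(t_next)
                sched_power.append(0.0)
                if setpoint_idx >= len(cfg.setpoints):
                    done = True
        else:
            lo, hi = cfg.resume_band
            if np.all((T_next >= lo) & (T_next <= hi)):
                heating = True
                sched_times.append(t_next)
                sched_power.append(cfg.on_power)

    schedule = PowerSchedule(times=np.asarray(sched_times),
                             power=np.asarray(sched_power),
                             max_power=max_power)
    trace = TemperatureTrace(times=np.asarray(times),
                             temperature=np.vstack(temps),
                             probe_labels=probe_labels)
    return schedule, trace


@dataclass(frozen=True)
class TraceComparison:
    """Deviation statistics between two traces on their common support."""

    mean_abs_dev: float
    max_abs_dev: float
    n_samples: int


def compare_traces(a: TemperatureTrace, b: TemperatureTrace) -> TraceComparison:
    """Mean/max absolute deviation after aligning onto common times.

    Both traces are linearly interpolated onto the union of their sample
    times restricted to the overlapping interval; probes are paired by
    index (both traces must carry the same number of probes).  Symmetric
    in its arguments and identically zero for identical traces.  Used,
    e.g., to quantify probe-vs-IR-camera agreement.
    """
    if a.n_probes != b.n_probes:
        raise ValueError("traces must have the same number of probes")
    lo = max(a.times[0], b.times[0])
    hi = min(a.times[-1], b.times[-1])
    if lo > hi:
        raise NoOverlapError(
            f"no overlapping time support: [{a.times[0]}, {a.times[-1]}] vs "
            f"[{b.times[0]}, {b.times[-1]}]"
        )
    common = np.union1d(a.times, b.times)
    common = common[(common >= lo) & (common <= hi)]
    devs = []
    for j in range(a.n_probes):
        ya = np.interp(common, a.times, a.temperature[:, j])
        yb = np.interp(common, b.times, b.temperature[:, j])
        devs.append(np.abs(ya - yb))
    devs = np.concatenate(devs)
    return TraceComparison(mean_abs_dev=float(devs.mean()),
                           max_abs_dev=float(devs.max()),
                           n_samples=int(common.size))
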