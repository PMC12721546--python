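"""Discrete-time closed-loop simulators for the three bioreactor control loops.

* **Temperature** — a first-order-plus-dead-time (FOPDT) plant
  ``G(s) = K e^{-theta s} / (tau s + 1)`` driven by the average voltage on the
  band heater, under a three-mode controller: full line voltage until the
  temperature has risen 20 % of the commanded change, then PID, with the
  heater forced off whenever the setpoint is exceeded (PID re-engages below
  it).  The duty cycle of the AC relay sets the average voltage, so the
  controller output is expressed in volts and converted to a duty fraction.
* **pH** — band ("bang-band") drip titration of an unbuffered, well-mixed
  volume with strong acid/base: a fixed pulse of drops whenever the filtered
  pH leaves the commanded band, followed by a settling wait.  [H+] solves the
  strong-acid charge balance ``[H+] - Kw/[H+] = c`` with ``c`` the net strong
  acid concentration.
* **Stirrer speed** — a first-order DC-motor model under PID with a
  moving-average filter on the noisy tachometer signal.

All simulators use fixed steps, exact exponential discretization of the
first-order dynamics, and are deterministic given (configuration, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import ConfigError, NonConvergenceError

__all__ = [
    "FOPDTPlant",
    "PIDGains",
    "PIDState",
    "pid_step",
    "PIDController",
    "TimeSeries",
    "fopdt_response",
    "TempControlConfig",
    "TemperatureResult",
    "simulate_temperature",
    "PHPlant",
    "PHResult",
    "simulate_ph",
    "StirrerPlant",
    "StirrerResult",
    "simulate_stirrer",
    "moving_average",
]

KW = 1.0e-14  # water autoprotolysis constant at 25 degC


# ---------------------------------------------------------------------------
# generic pieces
# ---------------------------------------------------------------------------


@dataclass
class TimeSeries:
    """Fixed-step record of a controlled variable and its actuator signal."""

    t: np.ndarray
    value: np.ndarray
    actuator: np.ndarray
    mode: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        self.actuator = np.asarray(self.actuator, dtype=float)
        if not (len(self.t) == len(self.value) == len(self.actuator)):
            raise ConfigError("TimeSeries channels must have equal length")
        if self.mode is not None:
            self.mode = np.asarray(self.mode)
            if len(self.mode) != len(self.t):
                raise ConfigError("TimeSeries.mode length mismatch")
        if len(self.t) and self.t[0] != 0.0:
            raise ConfigError("TimeSeries.t must start at 0")

    def to_dataframe(self):
        import pandas as pd

        data = {"t_s": self.t, "value": self.value, "actuator": self.actuator}
        if self.mode is not None:
            data["mode"] = self.mode
        return pd.DataFrame(data)


@dataclass(frozen=True)
class FOPDTPlant:
    """First-order-plus-dead-time temperature plant.

    ``gain`` is in degC per volt of *average* applied voltage (the model was
    identified under duty-cycled line voltage), ``time_constant`` and
    ``dead_time`` in seconds, ``ambient`` in degC.
    """

    gain: float = 1.475
    time_constant: float = 990.0
    dead_time: float = 120.0
    ambient: float = 25.0

    def __post_init__(self) -> None:
        if not self.time_constant > 0.0:
            raise ConfigError("FOPDTPlant.time_constant must be > 0")
        if self.dead_time < 0.0:
            raise ConfigError("FOPDTPlant.dead_time must be >= 0")


@dataclass(frozen=True)
class PIDGains:
    """Proportional/integral/derivative constants (loop-specific units)."""

    kp: float
    ki: float = 0.0
    kd: float = 0.0

    def __post_init__(self) -> None:
        for name in ("kp", "ki", "kd"):
            if not math.isfinite(getattr(self, name)):
                raise ConfigError(f"PIDGains.{name} must be finite")


@dataclass(frozen=True)
class PIDState:
    """Integral and previous-error memory of a positional PID."""

    integral: float = 0.0
    prev_error: float | None = None


def pid_step(
    gains: PIDGains,
    error: float,
    state: PIDState,
    dt: float,
    u_min: float = -math.inf,
    u_max: float = math.inf,
) -> tuple[float, PIDState]:
    """One positional-PID update: ``u = kp e + ki int(e) + kd de/dt``.

    Trapezoidal integral, backward-difference derivative (zero on the first
    call).  Anti-windup by conditional integration: when the unsaturated
    output exceeds the ``[u_min, u_max]`` clamp, the integral is frozen for
    that step.  Returns the clamped output and the new state.
    """
    if not dt > 0.0:
        raise ConfigError(f"pid_step requires dt > 0, got {dt}")
    prev = error if state.prev_error is None else state.prev_error
    integral = state.integral + 0.5 * (error + prev) * dt
    derivative = (error - prev) / dt
    u = gains.kp * error + gains.ki * integral + gains.kd * derivative
    if u > u_max or u < u_min:
        # conditional integration: keep the old integral while saturated
        integral = state.integral
        u = min(max(gains.kp * error + gains.ki * integral + gains.kd * derivative, u_min), u_max)
    return u, PIDState(integral=integral, prev_error=error)


class PIDController:
    """Stateful positional PID with derivative-on-measurement.

    Computing the derivative from the measurement (rather than the error)
    avoids the derivative kick on setpoint changes; the sign is chosen so the
    behaviour matches the error derivative for a fixed setpoint.
    """

    def __init__(
        self,
        gains: PIDGains,
        u_min: float = -math.inf,
        u_max: float = math.inf,
        derivative_on_measurement: bool = True,
    ):
        self.gains = gains
        self.u_min = u_min
        self.u_max = u_max
        self.derivative_on_measurement = derivative_on_measurement
        self.reset()

    def reset(self) -> None:
        self.integral = 0.0
        self._prev_error: float | None = None
        self._prev_meas: float | None = None

    def observe(self, measurement: float) -> None:
        """Track the measurement without acting (keeps the derivative smooth)."""
        self._prev_meas = measurement

    def update(self, setpoint: float, measurement: float, dt: float) -> float:
        error = setpoint - measurement
        prev_error = error if self._prev_error is None else self._prev_error
        if self.derivative_on_measurement:
            prev_meas = measurement if self._prev_meas is None else self._prev_meas
            derivative = -(measurement - prev_meas) / dt
        else:
            derivative = (error - prev_error) / dt
        integral = self.integral + 0.5 * (error + prev_error) * dt
        u = self.gains.kp * error + self.gains.ki * integral + self.gains.kd * derivative
        if self.u_min <= u <= self.u_max:
            self.integral = integral
        else:
            u = self.gains.kp * error + self.gains.ki * self.integral + self.gains.kd * derivative
            u = min(max(u, self.u_min), self.u_max)
        self._prev_error = error
        self._prev_meas = measurement
        return u


def moving_average(series: Sequence[float], window: int) -> np.ndarray:
    """Trailing moving average; the first ``window - 1`` outputs average the
    partial available history, so output length equals input length."""
    if window < 1:
        raise ConfigError(f"moving_average window must be >= 1, got {window}")
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        return x.copy()
    csum = np.cumsum(x)
    out = np.empty_like(x)
    head = min(window, x.size)
    out[:head] = csum[:head] / np.arange(1, head + 1)
    if x.size > window:
        out[window:] = (csum[window:] - csum[:-window]) / window
    return out


class _TrailingMean:
    """Streaming counterpart of :func:`moving_average`."""

    def __init__(self, window: int):
        if window < 1:
            raise ConfigError("filter window must be >= 1")
        self.window = window
        self._buf: list[float] = []

    def update(self, value: float) -> float:
        self._buf.append(value)
        if len(self._buf) > self.window:
            self._buf.pop(0)
        return sum(self._buf) / len(self._buf)


# ---------------------------------------------------------------------------
# open-loop FOPDT response
# ---------------------------------------------------------------------------


def fopdt_response(
    plant: FOPDTPlant,
    u: float | Callable[[float], float] | Sequence[float],
    t_end: float,
    dt: float,
) -> TimeSeries:
    """Open-loop response of the FOPDT plant to a piecewise-constant input.

    ``u`` may be a constant (a step applied at t = 0), a callable ``u(t)`` in
    volts, or a per-step sequence.  The first-order lag is integrated with the
    exact exponential update, so a pure step reproduces
    ``dT = K u0 (1 - exp(-(t - theta)/tau))`` at the sample points to
    round-off when the dead time is a multiple of ``dt``.
    """
    if not dt > 0.0:
        raise ConfigError("dt must be > 0")
    if dt > plant.time_constant / 10.0:
        raise ConfigError(
            f"dt = {dt} too coarse for time constant {plant.time_constant} "
            "(need dt <= tau/10)"
        )
    n = int(round(t_end / dt))
    t = np.arange(n + 1) * dt
    if callable(u):
        u_arr = np.array([float(u(tk)) for tk in t])
    elif np.ndim(u) == 0:
        u_arr = np.full(n + 1, float(u))
    else:
        u_arr = np.asarray(u, dtype=float)
        if u_arr.size != n + 1:
            raise ConfigError(f"input sequence must have {n + 1} samples, got {u_arr.size}")
    delay = int(round(plant.dead_time / dt))
    phi = math.exp(-dt / plant.time_constant)
    delta = np.empty(n + 1)
    delta[0] = 0.0
    for k in range(n):
        u_eff = u_arr[k - delay] if k >= delay else 0.0
        delta[k + 1] = phi * delta[k] + plant.gain * (1.0 - phi) * u_eff
    return TimeSeries(t=t, value=plant.ambient + delta, actuator=u_arr)


# ---------------------------------------------------------------------------
# temperature loop
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TempControlConfig:
    """Three-mode temperature controller configuration.

    The PID output is interpreted in volts of average heater voltage and
    clamped to ``[0, v_line]``; the relay duty fraction is ``u / v_line``.
    Mode 1 applies full line voltage until the temperature has risen
    ``pid_activation_fraction`` of the commanded change; mode 3 forces the
    heater off whenever the setpoint is met or exceeded.
    """

    setpoint: float
    pid: PIDGains = PIDGains(3.3, 0.0033, 82.5)
    v_line: float = 120.0
    duty_period: float = 5.0
    pid_activation_fraction: float = 0.2
    tolerance_band: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.pid_activation_fraction < 1.0:
            raise ConfigError("pid_activation_fraction must lie in (0, 1)")
        if not self.v_line > 0.0:
            raise ConfigError("v_line must be > 0")
        if not self.duty_period > 0.0:
            raise ConfigError("duty_period must be > 0")


@dataclass
class TemperatureResult:
    """Closed-loop temperature simulation output and summary statistics."""

    series: TimeSeries
    setpoint: float
    overshoot: float
    steady_state_error: float
    stabilization_time: float | None

    def summary(self) -> dict:
        return {
            "setpoint_c": self.setpoint,
            "overshoot_c": self.overshoot,
            "steady_state_error_c": self.steady_state_error,
            "stabilization_time_s": self.stabilization_time,
            "final_c": float(self.series.value[-1]),
        }


def _stabilization_time(
    t: np.ndarray, value: np.ndarray, target: float, band: float
) -> float | None:
    """First time after which |value - target| stays strictly inside ``band``."""
    outside = np.abs(value - target) >= band
    if outside.any():
        last_out = int(np.nonzero(outside)[0][-1])
        if last_out == len(t) - 1:
            return None
        return float(t[last_out + 1])
    return float(t[0])


def simulate_temperature(
    plant: FOPDTPlant,
    cfg: TempControlConfig,
    t_end: float = 7200.0,
    dt: float = 1.0,
) -> TemperatureResult:
    """Closed-loop temperature simulation under the three-mode controller.

    The controller samples every ``cfg.duty_period`` seconds (the relay
    switching period) and the commanded average voltage is held between
    samples; the plant integrates at ``dt`` with the exact exponential update
    and a ``dead_time / dt``-step delay line.
    """
    if not dt > 0.0:
        raise ConfigError("dt must be > 0")
    if dt > plant.time_constant / 10.0:
        raise ConfigError("dt too coarse for the plant time constant (need dt <= tau/10)")
    n = int(round(t_end / dt))
    ctrl_every = max(1, int(round(cfg.duty_period / dt)))
    ctrl_dt = ctrl_every * dt
    delay = int(round(plant.dead_time / dt))
    phi = math.exp(-dt / plant.time_constant)

    t0 = plant.ambient
    threshold = t0 + cfg.pid_activation_fraction * (cfg.setpoint - t0)
    pid = PIDController(cfg.pid, u_min=0.0, u_max=cfg.v_line)
    pid_engaged = t0 >= threshold  # setpoint at/below ambient: skip mode 1

    t = np.arange(n + 1) * dt
    temp = np.empty(n + 1)
    volts = np.empty(n + 1)
    modes = np.empty(n + 1, dtype=object)
    delay_line = [0.0] * max(delay, 1)

    delta = 0.0
    v_cmd = 0.0
    mode = "full-power"
    for k in range(n + 1):
        temp_k = plant.ambient + delta
        if k % ctrl_every == 0:
            if not pid_engaged and temp_k >= threshold:
                pid_engaged = True
            if not pid_engaged:
                mode, v_cmd = "full-power", cfg.v_line
                pid.observe(temp_k)
            elif temp_k >= cfg.setpoint:
                mode, v_cmd = "off", 0.0
                pid.observe(temp_k)
            else:
                mode = "pid"
                v_cmd = pid.update(cfg.setpoint, temp_k, ctrl_dt)
        temp[k] = temp_k
        volts[k] = v_cmd
        modes[k] = mode
        if k < n:
            u_eff = delay_line[0] if delay > 0 else v_cmd
            if delay > 0:
                delay_line.pop(0)
                delay_line.append(v_cmd)
            delta = phi * delta + plant.gain * (1.0 - phi) * u_eff

    series = TimeSeries(t=t, value=temp, actuator=volts, mode=modes)
    tail = temp[int(0.95 * n):]
    return TemperatureResult(
        series=series,
        setpoint=cfg.setpoint,
        overshoot=max(0.0, float(temp.max() - cfg.setpoint)),
        steady_state_error=float(cfg.setpoint - tail.mean()),
        stabilization_time=_stabilization_time(t, temp, cfg.setpoint, cfg.tolerance_band),
    )


# ---------------------------------------------------------------------------
# pH loop
# ---------------------------------------------------------------------------


def ph_from_strong_acid_concentration(c: float) -> float:
    """pH of an unbuffered solution with net strong-acid concentration ``c``.

    Solves the charge balance ``[H+] - Kw/[H+] = c`` (c < 0 means excess
    strong base): ``[H+] = (c + sqrt(c^2 + 4 Kw)) / 2``.  The alkaline branch
    is evaluated through [OH-] to avoid cancellation for strongly negative c.
    """
    if c >= 0.0:
        h = 0.5 * (c + math.sqrt(c * c + 4.0 * KW))
    else:
        oh = 0.5 * (-c + math.sqrt(c * c + 4.0 * KW))
        h = KW / oh
    return -math.log10(h)


def strong_acid_concentration_from_ph(ph: float) -> float:
    """Inverse of :func:`ph_from_strong_acid_concentration`."""
    h = 10.0**-ph
    return h - KW / h


@dataclass(frozen=True)
class PHPlant:
    """Unbuffered, well-mixed titration plant with drip dosing.

    Concentrations in mol/L, volumes in litres.  ``band`` is the acceptable
    (low, high) pH range; a pulse of ``pulse_s * drop_rate`` drops is
    dispensed whenever the filtered reading leaves the band, followed by a
    ``settle_s`` mixing wait.
    """

    volume: float = 3.0
    acid_conc: float = 0.47
    base_conc: float = 0.5
    drop_volume: float = 5.0e-5
    initial_ph: float = 7.0
    band: tuple[float, float] = (4.5, 5.5)
    pulse_s: float = 3.0
    drop_rate: float = 1.0
    settle_s: float = 5.0
    noise_sd: float = 0.05
    filter_window: int = 5

    def __post_init__(self) -> None:
        if not 0.0 < self.initial_ph < 14.0:
            raise ConfigError("initial_ph must lie in (0, 14)")
        low, high = self.band
        if not low < high:
            raise ConfigError(f"band low must be < high, got {self.band}")
        for name in ("volume", "acid_conc", "base_conc", "drop_volume", "pulse_s", "drop_rate"):
            if not getattr(self, name) > 0.0:
                raise ConfigError(f"PHPlant.{name} must be > 0")
        if self.settle_s < 0.0 or self.noise_sd < 0.0:
            raise ConfigError("settle_s and noise_sd must be >= 0")


@dataclass
class PHResult:
    """Drip-titration simulation output with reagent bookkeeping."""

    series: TimeSeries
    band: tuple[float, float]
    final_ph: float
    stabilization_time: float | None
    drops_acid: int
    drops_base: int
    moles_acid: float
    moles_base: float

    def summary(self) -> dict:
        return {
            "band": list(self.band),
            "final_ph": self.final_ph,
            "stabilization_time_s": self.stabilization_time,
            "drops_acid": self.drops_acid,
            "drops_base": self.drops_base,
            "moles_acid": self.moles_acid,
            "moles_base": self.moles_base,
        }


def simulate_ph(
    plant: PHPlant,
    t_end: float = 600.0,
    dt: float = 0.5,
    seed: int | None = 0,
    max_pulses: int = 2000,
) -> PHResult:
    """Bang-band drip titration toward the commanded pH band.

    Event cycle: sense (noisy reading through a trailing moving average) ->
    if the filtered pH is above the band dispense acid drops for ``pulse_s``
    at ``drop_rate`` (below the band: base) -> wait ``settle_s`` -> repeat.
    The well-mixed, unbuffered chemistry makes each drop an instantaneous jump
    of the net strong-acid concentration.  Raises
    :class:`~biomag.errors.NonConvergenceError` if ``max_pulses`` pulses do
    not reach the band.
    """
    if not dt > 0.0:
        raise ConfigError("dt must be > 0")
    rng = np.random.default_rng(seed)
    filt = _TrailingMean(plant.filter_window)

    volume = plant.volume
    c0 = strong_acid_concentration_from_ph(plant.initial_ph)
    moles_net_acid = c0 * volume  # signed net strong-acid content, mol
    drops_acid = drops_base = 0
    pulses = 0

    n = int(round(t_end / dt))
    t = np.arange(n + 1) * dt
    ph_log = np.empty(n + 1)
    act_log = np.zeros(n + 1)
    mode_log = np.empty(n + 1, dtype=object)

    drop_times: list[float] = []  # pending drop instants for the active pulse
    drop_sign = 0  # -1 acid, +1 base
    busy_until = 0.0
    in_band_since: float | None = None

    for k in range(n + 1):
        now = t[k]
        # dispense any scheduled drops up to now
        dispensed = 0
        while drop_times and drop_times[0] <= now + 1e-9:
            drop_times.pop(0)
            dispensed += 1
            if drop_sign < 0:
                moles_net_acid += plant.drop_volume * plant.acid_conc
                drops_acid += 1
            else:
                moles_net_acid -= plant.drop_volume * plant.base_conc
                drops_base += 1
            volume += plant.drop_volume
        ph_true = ph_from_strong_acid_concentration(moles_net_acid / volume)
        reading = ph_true + (rng.normal(0.0, plant.noise_sd) if plant.noise_sd > 0 else 0.0)
        ph_filtered = filt.update(reading)

        mode = "idle"
        if drop_times or now < busy_until:
            mode = "acid" if drop_sign < 0 else "base"
        elif now >= busy_until:
            low, high = plant.band
            if ph_filtered > high or ph_filtered < low:
                if pulses >= max_pulses:
                    raise NonConvergenceError(
                        f"pH band {plant.band} not reached after {max_pulses} pulses"
                    )
                pulses += 1
                drop_sign = -1 if ph_filtered > high else +1
                n_drops = int(math.floor(plant.pulse_s * plant.drop_rate))
                drop_times = [now + j / plant.drop_rate for j in range(n_drops)]
                busy_until = now + plant.pulse_s + plant.settle_s
                mode = "acid" if drop_sign < 0 else "base"
                in_band_since = None

        if plant.band[0] < ph_true < plant.band[1]:
            if in_band_since is None:
                in_band_since = now
        else:
            in_band_since = None

        ph_log[k] = ph_true
        act_log[k] = dispensed * (-1 if drop_sign < 0 else +1) if dispensed else 0
        mode_log[k] = mode

    final_ph = float(ph_log[-1])
    low, high = plant.band
    if not low < final_ph < high:
        raise NonConvergenceError(
            f"pH {final_ph:.2f} still outside band {plant.band} at t_end = {t_end} s; "
            "extend t_end or check the reagent configuration"
        )
    series = TimeSeries(t=t, value=ph_log, actuator=act_log, mode=mode_log)
    return PHResult(
        series=series,
        band=plant.band,
        final_ph=final_ph,
        stabilization_time=in_band_since,
        drops_acid=drops_acid,
        drops_base=drops_base,
        moles_acid=drops_acid * plant.drop_volume * plant.acid_conc,
        moles_base=drops_base * plant.drop_volume * plant.base_conc,
    )


# ---------------------------------------------------------------------------
# stirrer loop
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StirrerPlant:
    """First-order DC-motor agitation plant under PID speed control.

    ``gain`` maps full drive (u = 1) to the no-load-ish top speed in RPM;
    ``time_constant`` is the mechanical time constant in seconds.  The rated
    operating range of the instrument is 25-100 RPM; setpoints outside it are
    allowed for diagnostics (e.g. 0 RPM).
    """

    gain: float = 130.0
    time_constant: float = 0.3
    setpoint: float = 50.0
    pid: PIDGains = PIDGains(0.18, 0.8, 0.0016)
    noise_sd: float = 2.0
    seed: int = 0
    filter_window: int = 5

    def __post_init__(self) -> None:
        if not self.time_constant > 0.0:
            raise ConfigError("StirrerPlant.time_constant must be > 0")
        if not self.gain > 0.0:
            raise ConfigError("StirrerPlant.gain must be > 0")
        if self.setpoint < 0.0:
            raise ConfigError("StirrerPlant.setpoint must be >= 0")
        if self.noise_sd < 0.0:
            raise ConfigError("StirrerPlant.noise_sd must be >= 0")


@dataclass
class StirrerResult:
    """Stirrer-speed simulation output and steady-state statistics."""

    series: TimeSeries
    setpoint: float
    steady_state_error: float
    band_occupancy: float  # fraction of the last quarter within +/- 10 RPM

    def summary(self) -> dict:
        return {
            "setpoint_rpm": self.setpoint,
            "steady_state_error_rpm": self.steady_state_error,
            "band_occupancy": self.band_occupancy,
            "final_rpm": float(self.series.value[-1]),
        }


def simulate_stirrer(
    plant: StirrerPlant,
    t_end: float = 20.0,
    dt: float = 0.01,
) -> StirrerResult:
    """Closed-loop stirrer-speed simulation.

    Motor: ``domega/dt = (gain * u - omega) / tau`` with drive ``u`` clamped
    to [0, 1]; the PID acts on the moving-average-filtered, noise-corrupted
    tachometer signal.  Deterministic for a fixed ``plant.seed``.
    """
    if not dt > 0.0:
        raise ConfigError("dt must be > 0")
    rng = np.random.default_rng(plant.seed)
    pid = PIDController(plant.pid, u_min=0.0, u_max=1.0)
    filt = _TrailingMean(plant.filter_window)
    phi = math.exp(-dt / plant.time_constant)

    n = int(round(t_end / dt))
    t = np.arange(n + 1) * dt
    omega_log = np.empty(n + 1)
    u_log = np.empty(n + 1)

    omega = 0.0
    for k in range(n + 1):
        noise = rng.normal(0.0, plant.noise_sd) if plant.noise_sd > 0 else 0.0
        filtered = filt.update(omega + noise)
        u = pid.update(plant.setpoint, filtered, dt)
        omega_log[k] = omega
        u_log[k] = u
        if k < n:
            omega = phi * omega + plant.gain * (1.0 - phi) * u

    tail = omega_log[int(0.75 * n):]
    series = TimeSeries(t=t, value=omega_log, actuator=u_log)
    return StirrerResult(
        series=series,
        setpoint=plant.setpoint,
        steady_state_error=float(plant.setpoint - tail.mean()),
        band_occupancy=float(np.mean(np.abs(tail - plant.setpoint) <= 10.0)),
    )
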