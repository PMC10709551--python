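"""Pulsatile inlet signals and the five basilar-infarct envelope transforms.

The healthy signal is a periodic, nonnegative cardiac-like trace: a
raised-cosine systolic pulse on a diastolic floor, normalized so its peak
equals the configured peak velocity, with a linear multiplicative warm-up
ramp from rest.  Three beats at the default period span 2.6 s.

A stroke scenario multiplies the basilar signal by a piecewise-linear,
non-increasing envelope g(t): sudden halt (1), linear decline to zero by
the end of the run (2), or linear restriction to a residual fraction of
50/30/10 % (3-5), all starting from a common onset time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError

#: Default cardiac period (s); three beats span 2.6 s.
DEFAULT_PERIOD = 2.6 / 3.0
#: Default warm-up ramp duration (s).
DEFAULT_WARMUP = 0.4


@dataclass(frozen=True)
class Waveform:
    """Transient mean/peak inlet velocity signal v(t) in m/s.

    ``shape(phi)`` maps phase phi in [0, 1) to [p_min, 1] with max 1; the
    signal is ``ramp(t) * v_max * shape(phase)`` where the warm-up ramp
    rises linearly from 0 to 1 over ``warmup`` seconds and beats are
    counted from the end of warm-up.
    """

    v_max: float
    period: float = DEFAULT_PERIOD
    warmup: float = DEFAULT_WARMUP
    p_min: float = 0.25
    phi_peak: float = 0.25
    pulse_width: float = 0.3

    def __post_init__(self):
        if self.period <= 0:
            raise InvalidParameterError("period must be positive")
        if self.v_max < 0:
            raise InvalidParameterError("peak velocity must be nonnegative")
        if not 0 <= self.p_min <= 1:
            raise InvalidParameterError("diastolic floor must lie in [0, 1]")

    def shape(self, phi):
        """Dimensionless periodic profile p(phi) in [p_min, 1]."""
        phi = np.asarray(phi, float) % 1.0
        d = phi - self.phi_peak
        d = np.where(d > 0.5, d - 1.0, np.where(d < -0.5, d + 1.0, d))
        pulse = np.where(np.abs(d) < self.pulse_width,
                         0.5 * (1.0 + np.cos(np.pi * d / self.pulse_width)),
                         0.0)
        return self.p_min + (1.0 - self.p_min) * pulse

    def ramp(self, t):
        if self.warmup <= 0:
            return np.ones_like(np.asarray(t, float))
        return np.clip(np.asarray(t, float) / self.warmup, 0.0, 1.0)

    def __call__(self, t):
        t = np.asarray(t, float)
        phi = (t - self.warmup) / self.period
        return self.ramp(t) * self.v_max * self.shape(phi)

    def sample(self, t):
        """Two-column (time s, velocity m/s) array."""
        t = np.asarray(t, float)
        return np.column_stack([t, self(t)])


def healthy_profile(v_max, period=DEFAULT_PERIOD, warmup=DEFAULT_WARMUP,
                    **shape_params):
    """Healthy pulsatile inlet signal (see :class:`Waveform`)."""
    return Waveform(v_max=v_max, period=period, warmup=warmup,
                    **shape_params)


@dataclass(frozen=True)
class SampledWaveform:
    """A waveform given by a sampled (time, velocity) trace, interpolated
    linearly; supports the same scenario transforms."""

    times: np.ndarray
    velocities: np.ndarray

    def __call__(self, t):
        return np.interp(np.asarray(t, float), self.times, self.velocities)

    @classmethod
    def read(cls, path):
        data = np.loadtxt(path)
        return cls(times=data[:, 0], velocities=data[:, 1])

    def write(self, path):
        np.savetxt(path, np.column_stack([self.times, self.velocities]),
                   header="time_s velocity_m_per_s")


@dataclass(frozen=True)
class StrokeScenario:
    """One basilar-infarct envelope: onset, ramp duration, residual.

    ``ramp`` is the duration of the linear decline; ``None`` means the
    decline extends to the end of the simulation (scenario 2).  ``residual``
    is the fraction of the healthy signal retained afterwards.
    """

    id: int
    onset: float
    ramp: float = None
    residual: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.residual <= 1.0:
            raise InvalidParameterError("residual fraction must be in [0, 1]")
        if self.ramp is not None and self.ramp <= 0:
            raise InvalidParameterError("ramp duration must be positive")


def scenario_defaults(period=DEFAULT_PERIOD, onset=None,
                      warmup=DEFAULT_WARMUP):
    """The five stroke scenarios, sharing one onset (default: start of the
    second beat after warm-up).

    1: sudden halt over a quarter heartbeat; 2: linear decline to zero at
    the simulation end; 3-5: quarter-beat decline to 50 %, 30 %, 10 % of
    the healthy flow, then constant.
    """
    if onset is None:
        onset = warmup + period
    quarter = period / 4.0
    return [
        StrokeScenario(id=1, onset=onset, ramp=quarter, residual=0.0),
        StrokeScenario(id=2, onset=onset, ramp=None, residual=0.0),
        StrokeScenario(id=3, onset=onset, ramp=quarter, residual=0.5),
        StrokeScenario(id=4, onset=onset, ramp=quarter, residual=0.3),
        StrokeScenario(id=5, onset=onset, ramp=quarter, residual=0.1),
    ]


def envelope(scenario, t, t_end=None):
    """Multiplier g(t) in [0, 1]: 1 before onset, linear decline over the
    ramp, then the residual fraction."""
    t = np.asarray(t, float)
    ramp = scenario.ramp
    if ramp is None:
        if t_end is None:
            raise InvalidParameterError(
                "open-ended scenario needs the simulation end time")
        if t_end <= scenario.onset:
            raise InvalidParameterError("t_end must exceed the onset")
        ramp = t_end - scenario.onset
    frac = np.clip((t - scenario.onset) / ramp, 0.0, 1.0)
    return 1.0 - (1.0 - scenario.residual) * frac


@dataclass(frozen=True)
class ScenarioWaveform:
    """A healthy waveform multiplied by a stroke envelope."""

    base: object
    scenario: StrokeScenario
    t_end: float = None

    def __call__(self, t):
        return envelope(self.scenario, t, self.t_end) * self.base(t)


def apply_scenario(waveform, scenario, t_end=None):
    """Modulate ``waveform`` by the scenario envelope: v'(t) = g(t) v(t)."""
    return ScenarioWaveform(base=waveform, scenario=scenario, t_end=t_end)
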