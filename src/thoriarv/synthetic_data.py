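"""Synthetic sled-test channels and landing-severity samples.

Capsule landings and launch aborts expose a seated crewmember to short,
smooth, unimodal acceleration pulses (tens of g over tens of milliseconds).
:func:`make_pulse` emulates such channels with analytic shapes — half-sine,
haversine, trapezoid, constant — whose peak and integral are known in
closed form, so the signal metrics computed on them can be checked against
exact values. Gaussian noise is available but off by default so oracle
tests stay exact.

:func:`sample_landings` draws landing-severity indices from a normal
distribution and classifies each draw into the nominal / off-nominal /
contingency design bands (mu + 1.5 sigma and mu + 2.5 sigma thresholds).

All generators are seed-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .signal_metrics import Channel, ChannelSet

__all__ = [
    "PulseSpec",
    "LandingScenarioSpec",
    "make_pulse",
    "make_channelset",
    "sample_landings",
    "NOMINAL_SIGMA",
    "OFF_NOMINAL_SIGMA",
]

#: Design band edges in sigma units above the mean landing severity.
NOMINAL_SIGMA = 1.5
OFF_NOMINAL_SIGMA = 2.5

_SHAPES = ("half-sine", "haversine", "trapezoid", "constant")


@dataclass(frozen=True)
class PulseSpec:
    """Description of one unimodal test pulse.

    amplitude is in the channel's physical units (g, rad/s, m/s, N);
    duration and onset in seconds; rate in Hz. ``noise_sd`` adds zero-mean
    Gaussian noise (default 0: exact closed forms). ``tail`` seconds of
    zeros follow the pulse so sliding-window metrics see the full pulse.
    """

    shape: str = "haversine"
    amplitude: float = 50.0
    duration: float = 0.050
    onset: float = 0.005
    rate: float = 10_000.0
    noise_sd: float = 0.0
    tail: float = 0.005
    seed: int = 0
    label: str = "pulse"
    units: str = "g"

    def __post_init__(self) -> None:
        if self.shape not in _SHAPES:
            raise ValueError(f"unknown pulse shape {self.shape!r}; choose from {_SHAPES}")
        if self.duration <= 0:
            raise ValueError("pulse duration must be positive")
        if self.rate * self.duration < 20:
            raise ValueError("sampling rate too low: need at least 20 samples per pulse")
        if self.onset < 0 or self.tail < 0:
            raise ValueError("onset and tail must be non-negative")


def _pulse_values(shape: str, amplitude: float, phase: np.ndarray) -> np.ndarray:
    """Analytic pulse evaluated at phase in [0, 1] (zero outside)."""
    inside = (phase >= 0.0) & (phase <= 1.0)
    out = np.zeros_like(phase)
    p = phase[inside]
    if shape == "half-sine":
        out[inside] = amplitude * np.sin(np.pi * p)
    elif shape == "haversine":
        out[inside] = amplitude * 0.5 * (1.0 - np.cos(2.0 * np.pi * p))
    elif shape == "trapezoid":
        # 25% rise, 50% plateau, 25% fall
        out[inside] = amplitude * np.clip(np.minimum(p / 0.25, (1.0 - p) / 0.25), 0.0, 1.0)
    elif shape == "constant":
        out[inside] = amplitude
    return out


def trapezoid_pulse_integral(amplitude: float, duration: float) -> float:
    """Closed-form time integral of the 25/50/25 trapezoid pulse."""
    return amplitude * duration * 0.75


def make_pulse(spec: PulseSpec) -> Channel:
    """Render a :class:`PulseSpec` onto a uniform time base."""
    total = spec.onset + spec.duration + spec.tail
    n = int(round(total * spec.rate)) + 1
    t = np.arange(n) / spec.rate
    phase = (t - spec.onset) / spec.duration
    v = _pulse_values(spec.shape, spec.amplitude, phase)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        v = v + rng.normal(0.0, spec.noise_sd, size=v.shape)
    return Channel(t, v, label=spec.label, units=spec.units)


def make_channelset(head_pulse: PulseSpec | None = None,
                    omega_pulses: dict[str, PulseSpec] | None = None,
                    force_pulses: dict[str, PulseSpec] | None = None,
                    out_dir: str | Path | None = None,
                    basename: str = "run") -> ChannelSet:
    """Assemble a synthetic multi-channel run.

    ``head_pulse`` becomes the resultant head acceleration channel
    (label HEAD_RES, g); ``omega_pulses`` maps OMEGA_X/Y/Z labels to
    angular-rate pulses (rad/s); ``force_pulses`` adds arbitrary force
    channels (N). With ``out_dir`` set, writes ``<basename>.csv`` plus a
    YAML units sidecar, round-trippable by :meth:`ChannelSet.from_csv`.
    """
    from dataclasses import replace

    cs = ChannelSet()
    if head_pulse is not None:
        cs.add(make_pulse(replace(head_pulse, label="HEAD_RES", units="g")))
    for label, spec in (omega_pulses or {}).items():
        cs.add(make_pulse(replace(spec, label=label, units="rad/s")))
    for label, spec in (force_pulses or {}).items():
        cs.add(make_pulse(replace(spec, label=label, units="N")))
    if not cs.channels:
        raise ValueError("channel set needs at least one pulse")
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        cs.to_csv(out_dir / f"{basename}.csv")
    return cs


@dataclass(frozen=True)
class LandingScenarioSpec:
    """Normal landing-severity distribution: ``n`` draws of a scalar
    severity index with mean ``mu`` and spread ``sigma``."""

    mu: float = 0.0
    sigma: float = 1.0
    n: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.n < 1:
            raise ValueError("need at least one draw")


def classify_severity(values: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    """Label severities: 'nominal' (<= mu + 1.5 sigma), 'off-nominal'
    (<= mu + 2.5 sigma), else 'contingency'."""
    v = np.asarray(values, dtype=float)
    labels = np.where(
        v <= mu + NOMINAL_SIGMA * sigma, "nominal",
        np.where(v <= mu + OFF_NOMINAL_SIGMA * sigma, "off-nominal", "contingency"),
    )
    return labels


def sample_landings(spec: LandingScenarioSpec) -> tuple[np.ndarray, np.ndarray]:
    """Draw severities and classify each into its design band.

    Returns ``(severities, labels)``; the empirical band fractions converge
    to the normal-CDF design-table values (93.3% nominal, 6.1% off-nominal,
    0.6% contingency) as n grows.
    """
    rng = np.random.default_rng(spec.seed)
    values = rng.normal(spec.mu, spec.sigma, size=spec.n)
    return values, classify_severity(values, spec.mu, spec.sigma)
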