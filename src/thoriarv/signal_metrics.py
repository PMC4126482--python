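"""Signal-level injury metrics from ATD time-history channels.

Implements HIC-15 (sliding-window head injury criterion on resultant linear
acceleration in g), BrIC (normalised combination of peak angular head
velocities) and distal-forearm-speed measures, plus the small channel
containers they operate on.

Conventions:

* every channel carries its own time base in seconds (strictly increasing,
  not necessarily uniform) and declares its unit;
* integration is trapezoidal on the native time base;
* HIC window endpoints are restricted to sample instants — no sub-sample
  interpolation — which makes the computation exactly reproducible by an
  all-pairs brute-force search;
* no frequency-class (CFC) filtering is applied by default; a pre-filter
  hook accepts any callable mapping values to values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import yaml
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "Channel",
    "ChannelSet",
    "HICResult",
    "hic15",
    "bric",
    "adfs",
    "adfs_mass_scale",
    "resultant",
    "BRIC_CRITICAL_RATE_RAD_S",
    "ADFS_REFERENCE_MASS_KG",
    "ADFS_MASS_SLOPE",
    "THOR_ARM_MASS_KG",
]

#: Critical angular rates (rad/s) about the X, Y, Z head axes.
BRIC_CRITICAL_RATE_RAD_S = (66.3, 53.8, 41.5)

#: Surrogate arm mass (kg) at which the ADFS risk curve was fitted.
ADFS_REFERENCE_MASS_KG = 2.67
#: ADFS shift per kg of surrogate arm mass (m/s per kg).
ADFS_MASS_SLOPE = 1.94
#: Mass of the THOR (Hybrid-III) 50th-percentile-male arm assembly.
THOR_ARM_MASS_KG = 4.27


@dataclass(frozen=True)
class Channel:
    """A single time-synchronous measurement channel.

    ``time`` is in seconds and strictly increasing; ``values`` holds the
    physical signal in ``units`` (g for linear acceleration, rad/s for
    angular velocity, m/s for speed, N for force).
    """

    time: np.ndarray
    values: np.ndarray
    label: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or v.ndim != 1 or t.size != v.size:
            raise ValueError("time and values must be 1-D arrays of equal length")
        if t.size < 2:
            raise ValueError("a channel needs at least two samples")
        if np.isnan(t).any() or np.isnan(v).any():
            raise ValueError("channel contains NaNs")
        if not np.all(np.diff(t) > 0):
            raise ValueError("time must be strictly increasing")

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    def resampled(self, time: np.ndarray) -> "Channel":
        """Linear interpolation of the channel onto a new time base."""
        return replace(self, time=np.asarray(time, float),
                       values=np.interp(time, self.time, self.values))


@dataclass
class ChannelSet:
    """A bundle of channels keyed by label, with unit metadata.

    Channels may sit on different time bases; :meth:`common_time` resamples
    everything onto the densest base before vector operations.
    """

    channels: dict[str, Channel] = field(default_factory=dict)

    def __getitem__(self, label: str) -> Channel:
        try:
            return self.channels[label]
        except KeyError:
            raise KeyError(f"no channel labelled {label!r}") from None

    def __contains__(self, label: str) -> bool:
        return label in self.channels

    def add(self, channel: Channel) -> None:
        if not channel.label:
            raise ValueError("channel must carry a label to join a set")
        self.channels[channel.label] = channel

    def common_time(self) -> np.ndarray:
        """Time base of the most densely sampled channel, spanning the
        intersection of all channels."""
        if not self.channels:
            raise ValueError("empty channel set")
        chans = list(self.channels.values())
        start = max(c.time[0] for c in chans)
        stop = min(c.time[-1] for c in chans)
        densest = max(chans, key=lambda c: c.time.size / max(c.duration, 1e-12))
        mask = (densest.time >= start) & (densest.time <= stop)
        return densest.time[mask]

    def aligned(self) -> "ChannelSet":
        """All channels resampled onto :meth:`common_time`."""
        base = self.common_time()
        rates = {c.label: c.time.size / max(c.duration, 1e-12)
                 for c in self.channels.values()}
        if len({round(r) for r in rates.values()}) > 1:
            warnings.warn("channels have mismatched sampling rates; resampling "
                          "onto the densest base", stacklevel=2)
        return ChannelSet({k: c.resampled(base) for k, c in self.channels.items()})

    # -- plain-text persistence (CSV + YAML units sidecar) ------------------

    def to_csv(self, csv_path: str | Path, sidecar_path: str | Path | None = None) -> None:
        """Write aligned channels as one time column plus one column per
        label, with a YAML sidecar declaring units."""
        import pandas as pd

        aligned = self.aligned()
        base = aligned.common_time()
        frame = pd.DataFrame({"time": base})
        units = {}
        for label, chan in aligned.channels.items():
            frame[label] = chan.values
            units[label] = chan.units
        csv_path = Path(csv_path)
        frame.to_csv(csv_path, index=False, float_format="%.9g")
        sidecar = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".yaml")
        sidecar.write_text(yaml.safe_dump({"time_units": "s", "units": units},
                                          sort_keys=True))

    @classmethod
    def from_csv(cls, csv_path: str | Path,
                 sidecar_path: str | Path | None = None) -> "ChannelSet":
        import pandas as pd

        csv_path = Path(csv_path)
        frame = pd.read_csv(csv_path)
        if "time" not in frame.columns:
            raise ValueError("channel CSV must contain a 'time' column (seconds)")
        sidecar = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".yaml")
        units: Mapping[str, str] = {}
        if sidecar.exists():
            units = yaml.safe_load(sidecar.read_text()).get("units", {})
        out = cls()
        t = frame["time"].to_numpy()
        for col in frame.columns:
            if col == "time":
                continue
            out.add(Channel(t, frame[col].to_numpy(), label=col,
                            units=units.get(col, "")))
        return out


@dataclass(frozen=True)
class HICResult:
    """HIC value with the maximising window [t1, t2] (seconds)."""

    hic: float
    t1: float
    t2: float

    def __float__(self) -> float:
        return self.hic


def hic15(accel: Channel, window_max: float = 0.015,
          prefilter: Callable[[np.ndarray], np.ndarray] | None = None) -> HICResult:
    """Head injury criterion over sliding windows of at most ``window_max``
    seconds (15 ms by default).

    ``accel`` must be the resultant (non-negative) head acceleration in g.
    The criterion is

        HIC = max over t1 < t2, t2 - t1 <= window_max of
              ((1/(t2-t1)) * integral of a dt)^2.5 * (t2 - t1)

    with the integral taken trapezoidally and window endpoints restricted to
    sample instants.
    """
    if window_max <= 0:
        raise ValueError("window_max must be positive")
    if accel.units and accel.units != "g":
        raise ValueError(f"HIC expects acceleration in g, got units {accel.units!r}")
    t = accel.time
    a = accel.values
    if prefilter is not None:
        a = np.asarray(prefilter(a), dtype=float)
    if (a < 0).any():
        raise ValueError("HIC expects a resultant (non-negative) acceleration trace")

    # cumulative trapezoid integral, I[k] = integral from t[0] to t[k]
    integral = np.concatenate(([0.0], cumulative_trapezoid(a, t)))
    n = t.size
    best = 0.0
    best_i, best_j = 0, 1
    for i in range(n - 1):
        # admissibility is judged on dt itself, not an offset comparison,
        # so boundary windows resolve identically to the all-pairs oracle
        j_hi = min(int(np.searchsorted(t, t[i] + window_max, side="right")) + 1, n)
        dt = t[i + 1:j_hi] - t[i]
        valid = dt <= window_max
        if not valid.any():
            continue  # no sample pair fits inside the window
        dt = dt[valid]
        avg = (integral[i + 1:j_hi][valid] - integral[i]) / dt
        vals = avg ** 2.5 * dt
        k = int(np.argmax(vals))
        if vals[k] > best:
            best = float(vals[k])
            best_i, best_j = i, i + 1 + int(np.flatnonzero(valid)[k])
    return HICResult(hic=best, t1=float(t[best_i]), t2=float(t[best_j]))


def bric(omega_x: Channel, omega_y: Channel, omega_z: Channel,
         critical: tuple[float, float, float] = BRIC_CRITICAL_RATE_RAD_S) -> float:
    """Brain rotational injury criterion from three angular-velocity
    channels (rad/s).

    Uses the maximum absolute angular velocity of each axis over its whole
    trace (axis maxima may occur at different times) normalised by the
    per-axis critical rate, combined in quadrature.
    """
    if len(critical) != 3 or any(c <= 0 for c in critical):
        raise ValueError("need three positive critical angular rates")
    total = 0.0
    for chan, crit in zip((omega_x, omega_y, omega_z), critical):
        if chan.units and chan.units not in ("rad/s", "rad s-1"):
            raise ValueError(f"BrIC expects rad/s channels, got {chan.units!r}")
        total += (float(np.max(np.abs(chan.values))) / crit) ** 2
    return float(np.sqrt(total))


def adfs(speed: Channel, mode: str = "peak",
         window: tuple[float, float] | None = None) -> float:
    """Distal forearm speed metric from a speed trace (m/s).

    ``mode='peak'`` returns the trace maximum; ``mode='windowed-average'``
    returns the time-average (trapezoidal) over ``window = (t0, t1)``,
    defaulting to the full trace.
    """
    if (speed.values < 0).any():
        raise ValueError("speed trace must be non-negative")
    if mode == "peak":
        return float(np.max(speed.values))
    if mode == "windowed-average":
        t0, t1 = window if window is not None else (speed.time[0], speed.time[-1])
        mask = (speed.time >= t0) & (speed.time <= t1)
        if mask.sum() < 2:
            raise ValueError("averaging window contains fewer than two samples")
        tt, vv = speed.time[mask], speed.values[mask]
        return float(np.trapezoid(vv, tt) / (tt[-1] - tt[0]))
    raise ValueError(f"unknown ADFS mode {mode!r}")


def adfs_mass_scale(adfs_measured: float, surrogate_mass_kg: float) -> float:
    """Shift a measured ADFS (m/s) from the reference 2.67 kg surrogate arm
    to a surrogate of ``surrogate_mass_kg`` (linear mass scaling)."""
    if surrogate_mass_kg <= 0:
        raise ValueError("surrogate mass must be positive")
    return adfs_measured + ADFS_MASS_SLOPE * (surrogate_mass_kg - ADFS_REFERENCE_MASS_KG)


def resultant(*channels: Channel, label: str = "resultant") -> Channel:
    """Pointwise Euclidean norm of 1-3 channels sharing a time base."""
    if not 1 <= len(channels) <= 3:
        raise ValueError("resultant takes one to three channels")
    base = channels[0].time
    for chan in channels[1:]:
        if chan.time.shape != base.shape or not np.allclose(chan.time, base):
            raise ValueError("channels must share a common time base")
    stacked = np.vstack([c.values for c in channels])
    return Channel(base, np.sqrt((stacked ** 2).sum(axis=0)), label=label,
                   units=channels[0].units)
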