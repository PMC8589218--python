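"""From per-stride kinetics to 101-point mass-normalized power waveforms.

The common processing chain applied to every source study: scalar joint
power as the dot product of the net joint moment and the joint angular
velocity, gait events from a vertical ground-reaction-force threshold
(10 N, 20 N or 50 N depending on the study), time normalization of each
stride (initial contact to the next initial contact of the same limb) onto
101 cycle points, normalization to body mass, and averaging across strides.

For the ankle only the 21-69% portion of the cycle enters the model: power
outside that window is close to zero and would bias the fit toward zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

#: vertical GRF event thresholds (N) used by the source studies
STUDY_THRESHOLDS = {"taylor": 10.0, "fukuchi": 50.0, "horst": 20.0, "schreiber": 20.0}

#: ankle model support, inclusive cycle-point bounds (percent of stride)
ANKLE_WINDOW = (21, 69)


class NoEventsError(ValueError):
    """No threshold crossing found in the vertical GRF."""


class NoToeOffError(ValueError):
    """Initial contact found but the force never falls below threshold."""


@dataclass(frozen=True)
class GaitEvents:
    """Sample indices of one stride's events.

    ``next_initial_contact`` is None for a trailing stance without a
    detected following contact; complete cycles always satisfy
    initial_contact < toe_off < next_initial_contact.
    """

    initial_contact: int
    toe_off: int
    next_initial_contact: int | None = None

    def __post_init__(self):
        if not self.initial_contact < self.toe_off:
            raise ValueError("initial contact must precede toe-off")
        if self.next_initial_contact is not None and not (
            self.toe_off < self.next_initial_contact
        ):
            raise ValueError("toe-off must precede the next initial contact")


@dataclass
class StrideCycle:
    """One joint's 101-point mass-normalized power waveform (W/kg)."""

    subject_id: str
    study_id: str
    joint: str
    points: np.ndarray
    side: str | None = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.shape != (101,):
            raise ValueError("a stride cycle has exactly 101 points")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("non-finite power values")


def compute_joint_power(moment: np.ndarray, angular_velocity: np.ndarray) -> np.ndarray:
    """Element-wise dot product of joint moment (N*m) and angular velocity
    (rad/s), giving scalar power in W."""
    m = np.atleast_2d(np.asarray(moment, dtype=float))
    w = np.atleast_2d(np.asarray(angular_velocity, dtype=float))
    if m.shape != w.shape:
        raise ValueError(f"shape mismatch: {m.shape} vs {w.shape}")
    return np.einsum("ij,ij->i", m, w)


def butterworth_lowpass(
    series: np.ndarray, cutoff_hz: float, sample_rate_hz: float, order: int = 4
) -> np.ndarray:
    """Zero-lag low-pass Butterworth filter.

    ``order`` is the effective order of the two-pass (forward-backward)
    filter and must be even: a Butterworth of order ``order // 2`` is
    designed and applied with filtfilt, matching the conventional
    "4th order, zero-lag" description.
    """
    if not 0 < cutoff_hz < sample_rate_hz / 2:
        raise ValueError("cutoff must lie strictly below the Nyquist frequency")
    if order % 2 or order < 2:
        raise ValueError("order must be even for zero-lag two-pass filtering")
    b, a = signal.butter(order // 2, cutoff_hz, fs=sample_rate_hz)
    return signal.filtfilt(b, a, np.asarray(series, dtype=float))


def detect_gait_events(vertical_grf: np.ndarray, threshold: float) -> list[GaitEvents]:
    """Threshold-crossing gait events from the vertical GRF.

    Initial contact: first sample where force rises from below threshold to
    at or above it (the closed lower bound makes tie handling
    deterministic).  Toe-off: first subsequent sample falling below
    threshold.  Raises NoEventsError when no contact is found and
    NoToeOffError when a contact never ends.
    """
    f = np.asarray(vertical_grf, dtype=float)
    if f.size < 2:
        raise ValueError("series too short")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    above = f >= threshold
    rises = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if above[0]:
        rises = np.concatenate([[0], rises])
    if rises.size == 0:
        raise NoEventsError("no events: force never reaches the threshold")
    events = []
    for i, ic in enumerate(rises):
        falls = np.flatnonzero(~above[ic:]) + ic
        if falls.size == 0:
            if not events:
                raise NoToeOffError("no toe-off: force never falls below threshold")
            break  # trailing partial contact: already the previous next-IC
        to = int(falls[0])
        nxt = int(rises[i + 1]) if i + 1 < rises.size else None
        events.append(GaitEvents(int(ic), to, nxt))
    return events


def time_normalize(series: np.ndarray, start_index: int, end_index: int) -> np.ndarray:
    """Linearly interpolate the segment [start, end] onto 101 equal points."""
    y = np.asarray(series, dtype=float)
    if end_index - start_index < 2:
        raise ValueError("segment too short to normalize")
    if not 0 <= start_index < end_index < y.size:
        raise ValueError("segment indices out of bounds")
    q = np.linspace(start_index, end_index, 101)
    return np.interp(q, np.arange(y.size), y)


def mass_normalize(power: np.ndarray, mass: float) -> np.ndarray:
    """Element-wise division by body mass (kg): W -> W/kg."""
    if mass <= 0:
        raise ValueError("mass must be positive")
    return np.asarray(power, dtype=float) / mass


def average_strides(cycles: list[StrideCycle]) -> StrideCycle:
    """Point-wise mean waveform across a subject's strides."""
    if not cycles:
        raise ValueError("no stride cycles to average")
    first = cycles[0]
    if any(c.joint != first.joint or c.subject_id != first.subject_id for c in cycles):
        raise ValueError("stride cycles mix subjects or joints")
    pts = np.mean([c.points for c in cycles], axis=0)
    return StrideCycle(first.subject_id, first.study_id, first.joint, pts, first.side)


def subset_ankle_cycle(
    cycle: StrideCycle, window: tuple[int, int] = ANKLE_WINDOW
) -> tuple[np.ndarray, np.ndarray]:
    """Restrict an ankle waveform to the modelled cycle window.

    Returns (cycle point indices, power values) for points 21..69 inclusive
    (49 points) by default.  Knee and hip waveforms use the full cycle and
    must not be routed through this restriction.
    """
    if cycle.joint != "ankle":
        raise ValueError("only ankle waveforms are windowed; knee and hip use all 101 points")
    lo, hi = window
    idx = np.arange(lo, hi + 1)
    return idx, cycle.points[idx]


def restrict_cycle_support(
    data: pd.DataFrame, window: tuple[int, int] = ANKLE_WINDOW
) -> pd.DataFrame:
    """Apply the ankle cycle window to a long-format dataset.

    Ankle rows outside [21, 69] are dropped; knee and hip rows are kept for
    the entire stride cycle (101 data points).
    """
    lo, hi = window
    keep = (data["joint"] != "ankle") | (
        (data["cycle"] >= lo) & (data["cycle"] <= hi)
    )
    return data.loc[keep].reset_index(drop=True)


def process_strides(
    strides,
    subject_id: str,
    study_id: str,
    joint: str,
    threshold: float = 10.0,
) -> StrideCycle:
    """Full pipeline for one subject/joint: power -> events -> 101-point
    normalization -> mass normalization -> stride average."""
    cycles = []
    for st in strides:
        power = compute_joint_power(st.moment, st.angular_velocity)
        events = detect_gait_events(st.vgrf, threshold)
        complete = [e for e in events if e.next_initial_contact is not None]
        if not complete:
            raise NoEventsError("no complete stride (two initial contacts) found")
        ev = complete[0]
        wave = time_normalize(power, ev.initial_contact, ev.next_initial_contact)
        cycles.append(
            StrideCycle(subject_id, study_id, joint, mass_normalize(wave, st.mass))
        )
    return average_strides(cycles)
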