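"""Group-level delocalization analysis along trajectories: aggregation of
raw pair predictions into group-group electron-sharing series, binding-event
detection (delocalization maxima / center-of-mass-distance minima), the
+-10 fs electronic/geometric event matching, and ranking of the dominant
pairwise contributions behind a contact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import find_peaks

from .chemsys import Molecule, pair_flat_index

__all__ = [
    "ATOMIC_MASSES",
    "GroupDefinition",
    "TrajectorySeries",
    "Event",
    "EventTable",
    "group_delocalization",
    "center_of_mass_distance",
    "bin_average",
    "detect_events",
    "match_events",
    "dominant_pair_contributions",
    "delta_series",
    "distance_series",
]

# standard atomic weights for the elements this artifact works with
ATOMIC_MASSES: Dict[int, float] = {
    1: 1.008, 2: 4.0026, 3: 6.94, 4: 9.0122, 5: 10.81, 6: 12.011,
    7: 14.007, 8: 15.999, 9: 18.998, 10: 20.180, 11: 22.990, 12: 24.305,
    13: 26.982, 14: 28.085, 15: 30.974, 16: 32.06, 17: 35.45, 18: 39.948,
}


def atomic_mass(Z: int) -> float:
    # crude fallback keeps heavy elements usable without a full table
    return ATOMIC_MASSES.get(int(Z), 2.0 * float(Z))


@dataclass(frozen=True)
class GroupDefinition:
    """A named set of atom indices, optionally with explicit masses."""

    name: str
    indices: Tuple[int, ...]
    masses: Optional[Tuple[float, ...]] = None

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.indices)
        if not idx:
            raise ValueError(f"group {self.name!r} is empty")
        if len(set(idx)) != len(idx):
            raise ValueError(f"group {self.name!r} has duplicate atom indices")
        if any(i < 0 for i in idx):
            raise ValueError(f"group {self.name!r} has negative atom indices")
        object.__setattr__(self, "indices", idx)
        if self.masses is not None:
            m = tuple(float(v) for v in self.masses)
            if len(m) != len(idx):
                raise ValueError(f"group {self.name!r}: one mass per atom required")
            object.__setattr__(self, "masses", m)


@dataclass
class TrajectorySeries:
    """A scalar observable sampled along a trajectory."""

    times: np.ndarray
    values: np.ndarray
    label: str = ""
    kind: str = "electronic"  # or "geometric"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.size != self.values.size:
            raise ValueError("times and values must have equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.kind not in ("electronic", "geometric"):
            raise ValueError(f"unknown series kind {self.kind!r}")


@dataclass(frozen=True)
class Event:
    time: float
    value: float
    kind: str
    status: str = "unmatched"  # both | electronic-only | geometric-only | unmatched


@dataclass
class EventTable:
    events: List[Event] = field(default_factory=list)
    match_fraction: Optional[float] = None

    def times(self) -> np.ndarray:
        return np.array([e.time for e in self.events])


def group_delocalization(
    delta_pairs: np.ndarray, M: int, g1: Sequence[int], g2: Sequence[int]
) -> float:
    """delta(G1, G2) = sum over inter-group pairs, each unordered pair once.

    ``delta_pairs`` is a canonical flat pair array for an M-atom system.
    """
    s1, s2 = set(g1), set(g2)
    if s1 & s2:
        raise ValueError(
            f"groups overlap on atoms {sorted(s1 & s2)}; inter-group "
            "delocalization is undefined for shared atoms"
        )
    delta_pairs = np.asarray(delta_pairs, dtype=float)
    total = 0.0
    for i in s1:
        for j in s2:
            total += float(delta_pairs[pair_flat_index(i, j, M)])
    return total


def center_of_mass_distance(
    frame: Molecule,
    g1: GroupDefinition,
    g2: GroupDefinition,
) -> float:
    """Distance between the mass-weighted centroids of two groups (angstrom)."""
    coms = []
    for g in (g1, g2):
        masses = (
            np.asarray(g.masses, float)
            if g.masses is not None
            else np.array([atomic_mass(frame.Z[i]) for i in g.indices])
        )
        pos = frame.R[list(g.indices)]
        coms.append(masses @ pos / masses.sum())
    return float(np.linalg.norm(coms[0] - coms[1]))


def bin_average(series: TrajectorySeries, bin_width_fs: float) -> TrajectorySeries:
    """Mean over non-overlapping consecutive time bins.

    Output times are bin midpoints; a trailing partial bin is kept.
    """
    if bin_width_fs <= 0:
        raise ValueError("bin width must be positive")
    t, v = series.times, series.values
    if t.size > 1:
        step = float(np.min(np.diff(t)))
        if bin_width_fs < step:
            raise ValueError(
                f"bin width {bin_width_fs} fs is smaller than the time step {step} fs"
            )
    t0 = t[0]
    idx = np.floor((t - t0) / bin_width_fs).astype(int)
    times_out = []
    values_out = []
    for b in np.unique(idx):
        mask = idx == b
        times_out.append(t0 + (b + 0.5) * bin_width_fs)
        values_out.append(float(np.mean(v[mask])))
    return TrajectorySeries(
        times=np.array(times_out),
        values=np.array(values_out),
        label=series.label,
        kind=series.kind,
    )


def detect_events(
    series: TrajectorySeries,
    kind: Optional[str] = None,
    min_prominence: Optional[float] = None,
    min_separation_fs: float = 50.0,
) -> EventTable:
    """Interior local extrema of the series as binding events.

    Electronic series: local maxima of the delocalization values; geometric
    series: local minima of the center-of-mass distance (maxima of the
    negated series). ``min_prominence`` defaults to 10% of the value range.
    Events closer than ``min_separation_fs`` are merged keeping the more
    prominent one.
    """
    kind = kind or series.kind
    if series.times.size < 3:
        raise ValueError("event detection needs a series of length >= 3")
    values = series.values if kind == "electronic" else -series.values
    vrange = float(values.max() - values.min())
    if min_prominence is None:
        min_prominence = 0.1 * vrange
    if vrange == 0.0:
        return EventTable(events=[])
    peaks, props = find_peaks(values, prominence=min_prominence)
    prominences = props["prominences"]
    # merge close events, keeping the more prominent (ties -> earlier)
    order = sorted(range(len(peaks)), key=lambda k: (-prominences[k], series.times[peaks[k]]))
    kept: List[int] = []
    for k in order:
        t_k = series.times[peaks[k]]
        if all(abs(t_k - series.times[peaks[m]]) >= min_separation_fs for m in kept):
            kept.append(k)
    kept.sort(key=lambda k: series.times[peaks[k]])
    events = [
        Event(
            time=float(series.times[peaks[k]]),
            value=float(series.values[peaks[k]]),
            kind=kind,
        )
        for k in kept
    ]
    return EventTable(events=events)


def match_events(
    electronic: EventTable, geometric: EventTable, tolerance_fs: float = 10.0
) -> EventTable:
    """Greedy nearest-time one-to-one matching within the tolerance.

    Matched pairs are labeled "both" (one merged entry at the electronic
    time); remainders become "electronic-only" / "geometric-only". The match
    fraction is matched pairs over total distinct events.
    """
    e_times = electronic.times()
    g_times = geometric.times()
    candidates = [
        (abs(te - tg), te, i, j)
        for i, te in enumerate(e_times)
        for j, tg in enumerate(g_times)
        if abs(te - tg) <= tolerance_fs
    ]
    candidates.sort(key=lambda c: (c[0], c[1]))
    used_e: set = set()
    used_g: set = set()
    pairs: List[Tuple[int, int]] = []
    for _, _, i, j in candidates:
        if i not in used_e and j not in used_g:
            used_e.add(i)
            used_g.add(j)
            pairs.append((i, j))
    events: List[Event] = []
    for i, j in pairs:
        ev = electronic.events[i]
        events.append(Event(time=ev.time, value=ev.value, kind="electronic", status="both"))
    for i, ev in enumerate(electronic.events):
        if i not in used_e:
            events.append(
                Event(time=ev.time, value=ev.value, kind="electronic", status="electronic-only")
            )
    for j, ev in enumerate(geometric.events):
        if j not in used_g:
            events.append(
                Event(time=ev.time, value=ev.value, kind="geometric", status="geometric-only")
            )
    events.sort(key=lambda e: e.time)
    n_total = len(electronic.events) + len(geometric.events) - len(pairs)
    fraction = len(pairs) / n_total if n_total else 1.0
    return EventTable(events=events, match_fraction=fraction)


def dominant_pair_contributions(
    delta_pairs: np.ndarray,
    M: int,
    g1: Sequence[int],
    g2: Sequence[int],
    k: int,
) -> Tuple[List[Tuple[Tuple[int, int], float]], bool]:
    """Top-k inter-group atom pairs ranked by their share of delta(G1, G2).

    Returns (ranked list of ((i, j), share), zero_total_flag). Shares over
    the full inter-group list sum to 1 when the total is positive; ties are
    broken lexicographically on (i, j).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    s1, s2 = set(g1), set(g2)
    if s1 & s2:
        raise ValueError(f"groups overlap on atoms {sorted(s1 & s2)}")
    delta_pairs = np.asarray(delta_pairs, dtype=float)
    contributions = []
    total = 0.0
    for i in s1:
        for j in s2:
            a, b = (i, j) if i < j else (j, i)
            val = float(delta_pairs[pair_flat_index(a, b, M)])
            contributions.append(((a, b), val))
            total += val
    if total <= 0.0:
        return [], True
    contributions.sort(key=lambda c: (-c[1], c[0]))
    ranked = [(pair, val / total) for pair, val in contributions[:k]]
    return ranked, False


# ---------------------------------------------------------------------------
# Series construction along trajectories
# ---------------------------------------------------------------------------

def delta_series(
    frames: Sequence[Molecule],
    per_frame_delta: Sequence[np.ndarray],
    g1: GroupDefinition,
    g2: GroupDefinition,
    dt_fs: float = 1.0,
    t0_fs: float = 0.0,
) -> TrajectorySeries:
    """Group-group delocalization over a trajectory (electronic series)."""
    values = [
        group_delocalization(d, frame.n_atoms, g1.indices, g2.indices)
        for frame, d in zip(frames, per_frame_delta)
    ]
    times = t0_fs + dt_fs * np.arange(len(values))
    return TrajectorySeries(
        times=times, values=np.array(values),
        label=f"delta({g1.name},{g2.name})", kind="electronic",
    )


def distance_series(
    frames: Sequence[Molecule],
    g1: GroupDefinition,
    g2: GroupDefinition,
    dt_fs: float = 1.0,
    t0_fs: float = 0.0,
) -> TrajectorySeries:
    """Center-of-mass distance over a trajectory (geometric series)."""
    values = [center_of_mass_distance(f, g1, g2) for f in frames]
    times = t0_fs + dt_fs * np.arange(len(values))
    return TrajectorySeries(
        times=times, values=np.array(values),
        label=f"|R|({g1.name},{g2.name})", kind="geometric",
    )
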