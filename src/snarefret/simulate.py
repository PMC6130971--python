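"""Synthetic smFRET data generator.

Stands in for the microscope: a continuous-time Markov chain over
conformational states with state-specific FRET efficiencies is rendered
into camera-integrated two-channel intensity traces with channel
cross-talk, Gaussian read noise, and irreversible single-exponential
photobleaching of each dye.  Stochastic two-site labeling produces the
realistic mixture of FRET-capable, donor-only, and invisible molecules
that a field of view contains, and every molecule's ground truth is kept
in a ledger so downstream stages can be validated end to end.

Frames spanning a state transition carry the time-weighted average
emission of the sub-intervals (camera integration model).  After
acceptor bleach the donor recovers the full total intensity; after donor
bleach both channels fall to zero-mean background noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .traceio import IntensityTrace, TraceSet


@dataclass
class StatePath:
    """Exact continuous-time state path: segment i occupies
    ``[entry_times[i], entry_times[i+1])`` (last segment runs to
    ``duration``)."""

    states: np.ndarray        # int, per segment
    entry_times: np.ndarray   # float s, first is 0.0
    duration: float

    @property
    def n_transitions(self) -> int:
        return len(self.states) - 1

    def state_at(self, t: float) -> int:
        idx = int(np.searchsorted(self.entry_times, t, side="right")) - 1
        return int(self.states[idx])

    def segments(self) -> list[tuple[float, float, int]]:
        """(t_start, t_end, state) triples covering [0, duration)."""
        ends = np.append(self.entry_times[1:], self.duration)
        return [(float(t0), float(t1), int(s))
                for t0, t1, s in zip(self.entry_times, ends, self.states)]

    def occupancy(self, n_states: int, until: float | None = None) -> np.ndarray:
        """Fraction of time spent in each state over [0, until)."""
        until = self.duration if until is None else min(until, self.duration)
        occ = np.zeros(n_states)
        for t0, t1, s in self.segments():
            if t0 >= until:
                break
            occ[s] += min(t1, until) - t0
        return occ / until if until > 0 else occ


@dataclass
class MoleculeTruth:
    """Ground-truth ledger entry for one simulated molecule."""

    molecule_id: str
    field_id: str
    label_class: str               # fret | donor_only | acceptor_only | dark
    path: StatePath | None         # None unless FRET-capable
    donor_bleach_time: float       # s; inf if never
    acceptor_bleach_time: float    # s; inf if never (inf for donor_only)
    n_donors: int
    n_acceptors: int

    @property
    def visible(self) -> bool:
        """Detectable under donor excitation."""
        return self.n_donors > 0

    @property
    def observed_end(self) -> float:
        """End of the usable FRET observation window (s)."""
        if self.path is None:
            return 0.0
        return min(self.donor_bleach_time, self.acceptor_bleach_time,
                   self.path.duration)

    @property
    def n_observed_transitions(self) -> int:
        """True conformational transitions before any bleach."""
        if self.path is None:
            return 0
        end = self.observed_end
        return int(np.sum((self.path.entry_times[1:] < end)))

    @property
    def n_completed_excursions(self) -> int:
        """Excursions below the top state that return to it before the
        observation window ends.

        Only these are observable as transitions: a down-step that never
        returns to high FRET before bleach is, by construction of the
        assay, indistinguishable from acceptor photobleaching.
        """
        if self.path is None:
            return 0
        top = int(self.path.states.max(initial=0))
        end = self.observed_end
        # every entry into the top state is a visible up-step closing an
        # excursion; entries after the window don't count
        return int(np.sum((self.path.states[1:] == top)
                          & (self.path.entry_times[1:] < end)))

    def true_interior_dwells(self) -> list[tuple[int, float]]:
        """(state, duration) of true dwells fully inside the observation
        window, first and last dropped — the ground-truth counterpart of
        the section-II dwell extraction.

        Because only dwells that complete before bleach are observable,
        their durations are length-biased relative to the raw exponential
        holding times; comparisons must use these, not 1/k.
        """
        if self.path is None:
            return []
        end = self.observed_end
        out = []
        for t0, t1, s in self.path.segments():
            if t1 <= end:
                out.append((s, t1 - t0))
            else:
                break
        return out[1:-1]

    def expected_classification(self, min_frames: int, frame_rate: float) -> str:
        """Classification a perfect analyzer would assign.

        Donor-only and dual-donor molecules show no colocalized acceptor
        signal; FRET molecules whose usable window is shorter than the
        configured minimum are too short to analyze; a molecule counts as
        transitioning only if at least one excursion completes (returns
        to high FRET) inside the observation window.
        """
        if self.label_class != "fret":
            return "excluded"
        if self.observed_end * frame_rate < min_frames:
            return "excluded"
        return ("with_transitions" if self.n_completed_excursions > 0
                else "without_transitions")


@dataclass
class FieldSimulation:
    """One simulated field of view: visible traces plus full ledger."""

    field_id: str
    traces: list[IntensityTrace]
    ledger: list[MoleculeTruth]

    def ledger_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.ledger:
            rows.append({
                "molecule_id": m.molecule_id,
                "field_id": m.field_id,
                "label_class": m.label_class,
                "n_donors": m.n_donors,
                "n_acceptors": m.n_acceptors,
                "donor_bleach_time": m.donor_bleach_time,
                "acceptor_bleach_time": m.acceptor_bleach_time,
                "n_transitions": (m.path.n_transitions if m.path else 0),
                "n_observed_transitions": m.n_observed_transitions,
                "observed_end": m.observed_end,
            })
        return pd.DataFrame(rows)


def _molecule_rng(seed: int, field_index: int, molecule_index: int) -> np.random.Generator:
    # counter-based substream: reproducible per molecule regardless of order
    ss = np.random.SeedSequence([int(seed), int(field_index), int(molecule_index)])
    return np.random.default_rng(ss)


def simulate_state_path(config: SimulationConfig,
                        rng: np.random.Generator,
                        initial_state: int | None = None,
                        duration: float | None = None) -> StatePath:
    """Draw an exact continuous-time Markov path over [0, trace_length].

    Holding times are exponential with the configured exit rates; jump
    targets follow the off-diagonal rates.  An absorbing state (zero exit
    rate) ends the path with a single terminal segment.  Molecules start
    in the highest-FRET (assembled) state unless ``initial_state`` given.
    """
    q = config.q_matrix()
    duration = config.trace_length if duration is None else duration
    state = (config.n_states - 1) if initial_state is None else int(initial_state)
    t = 0.0
    states = [state]
    entries = [0.0]
    while True:
        exit_rate = -q[state, state]
        if exit_rate <= 0:
            break
        t += rng.exponential(1.0 / exit_rate)
        if t >= duration:
            break
        probs = q[state].copy()
        probs[state] = 0.0
        probs /= exit_rate
        state = int(rng.choice(config.n_states, p=probs))
        states.append(state)
        entries.append(t)
    return StatePath(np.array(states, dtype=int), np.array(entries), duration)


def _frame_average(segments: Sequence[tuple[float, float, float, float]],
                   n_frames: int, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Time-average piecewise-constant (donor, acceptor) emission rates
    over the camera frames.  ``segments`` are (t0, t1, donor, acceptor)."""
    donor = np.zeros(n_frames)
    acceptor = np.zeros(n_frames)
    for t0, t1, d, a in segments:
        if t1 <= t0:
            continue
        first = int(t0 / dt)
        last = min(int(np.ceil(t1 / dt)), n_frames)
        for i in range(first, last):
            lo = max(t0, i * dt)
            hi = min(t1, (i + 1) * dt)
            if hi > lo:
                w = (hi - lo) / dt
                donor[i] += d * w
                acceptor[i] += a * w
    return donor, acceptor


def render_intensities(path: StatePath, config: SimulationConfig,
                       rng: np.random.Generator,
                       molecule_id: str = "mol0", field_id: str = "field0",
                       donor_bleach_time: float | None = None,
                       acceptor_bleach_time: float | None = None,
                       ) -> tuple[IntensityTrace, float, float]:
    """Render a state path into a noisy two-channel intensity trace.

    Bleach times are drawn from the configured exponential rates unless
    supplied.  Returns the trace and the (donor, acceptor) bleach times
    actually used.
    """
    if donor_bleach_time is None:
        donor_bleach_time = (rng.exponential(1.0 / config.donor_bleach_rate)
                             if config.donor_bleach_rate > 0 else np.inf)
    if acceptor_bleach_time is None:
        acceptor_bleach_time = (rng.exponential(1.0 / config.acceptor_bleach_rate)
                                if config.acceptor_bleach_rate > 0 else np.inf)

    total = config.total_intensity
    fret = np.asarray(config.state_fret)
    pieces: list[tuple[float, float, float, float]] = []
    ab, db = acceptor_bleach_time, donor_bleach_time
    for t0, t1, s in path.segments():
        # split each conformational segment at the bleach events
        cuts = sorted({t0, t1, *(c for c in (ab, db) if t0 < c < t1)})
        for lo, hi in zip(cuts, cuts[1:]):
            if lo >= db:
                d_rate, a_rate = 0.0, 0.0
            elif lo >= ab:
                d_rate, a_rate = total, 0.0
            else:
                a_rate = total * fret[s]
                d_rate = total - a_rate
            pieces.append((lo, hi, d_rate, a_rate))

    dt = 1.0 / config.frame_rate
    donor_true, acceptor_true = _frame_average(pieces, config.n_frames, dt)

    m = config.leakage.matrix()
    donor_obs = m[0, 0] * donor_true + m[0, 1] * acceptor_true
    acceptor_obs = m[1, 0] * donor_true + m[1, 1] * acceptor_true
    if config.noise_sigma > 0:
        donor_obs = donor_obs + rng.normal(0.0, config.noise_sigma, config.n_frames)
        acceptor_obs = acceptor_obs + rng.normal(0.0, config.noise_sigma, config.n_frames)

    trace = IntensityTrace(molecule_id, field_id, config.frame_rate,
                           donor_obs, acceptor_obs)
    return trace, donor_bleach_time, acceptor_bleach_time


def _render_donor_only(config: SimulationConfig, rng: np.random.Generator,
                       n_donors: int, molecule_id: str, field_id: str,
                       ) -> tuple[IntensityTrace, float]:
    """Trace for a molecule carrying only donor dye(s): constant donor
    emission, stepwise loss as each donor bleaches, leakage into the
    acceptor channel."""
    total = config.total_intensity
    bleaches = sorted(
        rng.exponential(1.0 / config.donor_bleach_rate)
        if config.donor_bleach_rate > 0 else np.inf
        for _ in range(n_donors)
    )
    pieces = []
    t0 = 0.0
    level = float(n_donors)
    for b in bleaches:
        b = min(b, config.trace_length)
        if b > t0:
            pieces.append((t0, b, total * level, 0.0))
        t0 = b
        level -= 1.0
    if t0 < config.trace_length:
        pieces.append((t0, config.trace_length, max(level, 0.0) * total, 0.0))

    dt = 1.0 / config.frame_rate
    donor_true, acceptor_true = _frame_average(pieces, config.n_frames, dt)
    m = config.leakage.matrix()
    donor_obs = m[0, 0] * donor_true + m[0, 1] * acceptor_true
    acceptor_obs = m[1, 0] * donor_true + m[1, 1] * acceptor_true
    if config.noise_sigma > 0:
        donor_obs = donor_obs + rng.normal(0.0, config.noise_sigma, config.n_frames)
        acceptor_obs = acceptor_obs + rng.normal(0.0, config.noise_sigma, config.n_frames)
    trace = IntensityTrace(molecule_id, field_id, config.frame_rate,
                           donor_obs, acceptor_obs)
    return trace, float(bleaches[-1])


def _draw_labels(config: SimulationConfig, rng: np.random.Generator) -> tuple[int, int]:
    """Stochastic labeling of the two dye sites → (n_donors, n_acceptors)."""
    n_d = n_a = 0
    for _ in range(2):
        if rng.random() < config.label_efficiency:
            if rng.random() < config.donor_prob:
                n_d += 1
            else:
                n_a += 1
    return n_d, n_a


def simulate_field(config: SimulationConfig, field_index: int = 0) -> FieldSimulation:
    """Simulate one field of view: traces for every donor-visible molecule
    plus a ground-truth ledger row for every molecule (visible or not).

    Each molecule uses a counter-based RNG substream keyed on
    (seed, field, molecule), so individual molecules are reproducible
    independently of simulation order.
    """
    field_id = f"field{field_index}"
    traces: list[IntensityTrace] = []
    ledger: list[MoleculeTruth] = []
    for j in range(config.n_molecules_per_field):
        rng = _molecule_rng(config.seed, field_index, j)
        mid = f"f{field_index}m{j:04d}"
        n_d, n_a = _draw_labels(config, rng)
        if n_d >= 1 and n_a >= 1:
            path = simulate_state_path(config, rng)
            trace, db, ab = render_intensities(
                path, config, rng, molecule_id=mid, field_id=field_id)
            traces.append(trace)
            ledger.append(MoleculeTruth(mid, field_id, "fret", path, db, ab, n_d, n_a))
        elif n_d >= 1:
            trace, db = _render_donor_only(config, rng, n_d, mid, field_id)
            ledger.append(MoleculeTruth(mid, field_id, "donor_only", None,
                                        db, np.inf, n_d, 0))
            traces.append(trace)
        elif n_a >= 1:
            ledger.append(MoleculeTruth(mid, field_id, "acceptor_only", None,
                                        np.inf, np.inf, 0, n_a))
        else:
            ledger.append(MoleculeTruth(mid, field_id, "dark", None,
                                        np.inf, np.inf, 0, 0))
    return FieldSimulation(field_id, traces, ledger)


def simulate_dataset(config: SimulationConfig) -> tuple[TraceSet, list[FieldSimulation]]:
    """Simulate all configured fields and pool the visible traces."""
    fields = [simulate_field(config, i) for i in range(config.n_fields)]
    traces = [t for f in fields for t in f.traces]
    ts = TraceSet(traces, metadata={
        "frame_rate": config.frame_rate,
        "condition": "simulated",
        "leakage_l_da": config.leakage.l_da,
        "leakage_l_ad": config.leakage.l_ad,
    })
    return ts, fields


def write_ledger(fields: Sequence[FieldSimulation], path: str | Path) -> None:
    """Ground-truth ledger as one CSV row per molecule."""
    df = pd.concat([f.ledger_frame() for f in fields], ignore_index=True)
    df.to_csv(path, index=False, float_format="%.10g")
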