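"""Stochastic single-filament simulator (synthetic-data generator).

Each filament barbed end is a continuous-time Markov chain over the four
occupancy states {B, BC, BF, BFC} whose transition rates follow from a
:class:`~bfckinetics.model_core.RateSet` and the instantaneous solution
composition.  A microfluidics experiment is a :class:`FlowProtocol`: an
ordered list of piecewise-constant solution conditions (profilin–actin,
formin, CP), each applied for a fixed duration, with solution exchange
treated as instantaneous.  Because exponential waiting times are
memoryless, the chain is simulated segment by segment with freshly drawn
waiting times after every boundary, which is an exact realization.

Two anchoring geometries are supported, mirroring the two single-filament
assays the generator emulates:

* ``seed_anchored`` — the filament grows from an immobilized
  spectrin–actin seed; the barbed end is free (distal) and every state
  change shows up only as a change in elongation regime.
* ``formin_anchored`` — the filament is held by a surface-bound formin;
  any transition that removes formin from the barbed end (BF → B or
  BFC → BC) releases the filament into the flow, which is recorded as a
  detachment and terminates the observation of that filament.

Elongation is modelled as deterministic drift: a state- and
condition-dependent velocity in subunits/s integrated between
transitions.  Capped states (BC, BFC) do not grow.  Per-monomer
stochasticity is ignored because every inferred quantity depends only on
the switching times between velocity regimes.

:func:`observe` degrades a ground-truth trace the way a camera does —
finite frame rate, additive length noise, velocity classification over a
short smoothing window, a minimum detectable event duration — and emits
the per-filament switching-event rows (the ``SwitchEventTable``) that the
inference module consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .model_core import BarbedEndState, RateSet, _require_nonnegative

__all__ = [
    "SolutionCondition",
    "FlowProtocol",
    "FilamentTrace",
    "SEED_ANCHORED",
    "FORMIN_ANCHORED",
    "EVENT_COLUMNS",
    "V_FREE_DEFAULT",
    "V_FORMIN_MDIA1",
    "propensities",
    "elongation_velocity",
    "simulate_filament",
    "simulate_population",
    "observe",
    "observe_population",
    "traces_to_frame",
]

SEED_ANCHORED = "seed_anchored"
FORMIN_ANCHORED = "formin_anchored"

#: columns of the switching-event table, the simulator/inference interface
EVENT_COLUMNS = ("filament_id", "condition_label", "event_type", "time_s", "censored")

#: free barbed-end elongation velocity at 1 µM profilin-actin, subunits/s.
#: Not directly constrained by the fitted kinetics (it only affects how
#: growth regimes are classified), so it is a configurable default.
V_FREE_DEFAULT = 10.0

#: mDia1-driven processive elongation velocity at 1 µM actin / 4 µM
#: profilin, subunits/s (measured value for the FH1-FH2-DAD fragment).
V_FORMIN_MDIA1 = 44.2


@dataclass(frozen=True)
class SolutionCondition:
    """Composition of one microfluidics flow, concentrations in µM.

    ``actin`` is the polymerization-competent profilin–actin concentration
    (the elongation substrate); ``profilin`` is free profilin beyond that.
    ``labelled`` records whether the actin is fluorescent — it does not
    influence the kinetics here, only bookkeeping of what a real
    experiment could visualize.
    """

    actin: float = 0.0
    profilin: float = 0.0
    formin: float = 0.0
    cp: float = 0.0
    labelled: bool = True
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("actin", "profilin", "formin", "cp"):
            _require_nonnegative(name, getattr(self, name))


@dataclass(frozen=True)
class FlowProtocol:
    """Ordered piecewise-constant flow segments plus the anchoring geometry."""

    segments: tuple[tuple[float, SolutionCondition], ...]
    anchor_mode: str = SEED_ANCHORED

    def __post_init__(self) -> None:
        segs = tuple((float(d), c) for d, c in self.segments)
        if len(segs) == 0:
            raise ValueError("a protocol needs at least one segment")
        for d, cond in segs:
            if not (math.isfinite(d) and d > 0):
                raise ValueError(f"segment durations must be positive, got {d}")
            if not isinstance(cond, SolutionCondition):
                raise TypeError("each segment must carry a SolutionCondition")
        if self.anchor_mode not in (SEED_ANCHORED, FORMIN_ANCHORED):
            raise ValueError(f"unknown anchor_mode {self.anchor_mode!r}")
        object.__setattr__(self, "segments", segs)

    @property
    def total_duration(self) -> float:
        return float(sum(d for d, _ in self.segments))

    def boundaries(self) -> np.ndarray:
        """Cumulative segment end times, seconds."""
        return np.cumsum([d for d, _ in self.segments])

    def segment_label(self, index: int) -> str:
        label = self.segments[index][1].label
        return label if label else f"segment{index}"

    def segment_starts(self) -> np.ndarray:
        return np.concatenate([[0.0], self.boundaries()[:-1]])


def propensities(
    state: BarbedEndState,
    cond: SolutionCondition,
    rates: RateSet,
    bfc_decay_requires_actin: bool = True,
) -> list[tuple[BarbedEndState, float]]:
    """Outgoing transition channels ``(target_state, rate s⁻¹)`` for one state.

    Channels with zero rate (absent binding partner) are omitted.  By
    default the ternary complex is kinetically locked while no
    profilin–actin is present: displacement of CP by formin requires
    actin, and transient-exposure titrations behave as if the freshly
    formed complex survives the exposure intact, so both resolution
    channels (BFC → BF and BFC → BC) are gated on ``actin > 0``.  Set
    ``bfc_decay_requires_actin=False`` for the ungated scheme in which
    the complex decays at the same branch rates in any solution.
    """
    S = BarbedEndState
    if state is S.B:
        channels = [(S.BF, rates.k_plus_F * cond.formin), (S.BC, rates.k_plus_C * cond.cp)]
    elif state is S.BF:
        channels = [(S.BFC, rates.k_prime_plus_C * cond.cp), (S.B, rates.k_minus_F)]
    elif state is S.BC:
        channels = [(S.BFC, rates.k_prime_plus_F * cond.formin), (S.B, rates.k_minus_C)]
    elif state is S.BFC:
        if bfc_decay_requires_actin and cond.actin <= 0:
            channels = []
        else:
            channels = [(S.BF, rates.k_prime_minus_C), (S.BC, rates.k_prime_minus_F)]
    else:  # pragma: no cover - enum is closed
        raise ValueError(f"unknown barbed-end state {state!r}")
    return [(target, r) for target, r in channels if r > 0]


def elongation_velocity(
    state: BarbedEndState,
    cond: SolutionCondition,
    rates: RateSet,
    v_free: float = V_FREE_DEFAULT,
    v_formin: Optional[float] = None,
) -> float:
    """Barbed-end elongation velocity in subunits/s.

    Capped states do not grow.  Free ends elongate at ``v_free`` per µM of
    profilin-actin; formin-bound ends at ``v_formin`` per µM (default:
    the measured mDia1 value, or twice the free-end velocity for FMNL2,
    whose processive acceleration is about two-fold).
    """
    if state.is_capped:
        return 0.0
    scale = cond.actin  # linear in substrate, referenced to 1 µM
    if state is BarbedEndState.B:
        return v_free * scale
    if v_formin is None:
        if "FMNL" in rates.formin_name.upper():
            v_formin = 2.0 * v_free
        else:
            v_formin = V_FORMIN_MDIA1
    return v_formin * scale


@dataclass
class FilamentTrace:
    """Ground-truth piecewise state path of one simulated filament.

    ``times``/``lengths`` are the breakpoints of the piecewise-linear
    length trajectory (subunits); breakpoints occur at every state
    transition and at every segment boundary.  ``transitions`` holds
    ``(time, from_state, to_state)`` in increasing time order.  For
    formin-anchored filaments, ``detached_at`` is the time at which the
    formin released the barbed end (the filament is lost in the flow and
    observation stops).
    """

    filament_id: int
    initial_state: BarbedEndState
    transitions: list[tuple[float, BarbedEndState, BarbedEndState]]
    times: np.ndarray
    lengths: np.ndarray
    observed_until: float
    anchor_mode: str = SEED_ANCHORED
    detached_at: Optional[float] = None
    rng_seed: Optional[tuple] = None

    def __post_init__(self) -> None:
        ts = [t for t, _, _ in self.transitions]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("transition times must be strictly increasing")
        if np.any(np.diff(self.lengths) < -1e-9):
            raise ValueError("filament length must be non-decreasing")

    @property
    def final_state(self) -> BarbedEndState:
        return self.transitions[-1][2] if self.transitions else self.initial_state

    def state_at(self, t: float) -> BarbedEndState:
        state = self.initial_state
        for tt, _, to in self.transitions:
            if tt <= t:
                state = to
            else:
                break
        return state

    def length_at(self, t: Union[float, np.ndarray]) -> Union[float, np.ndarray]:
        """Length (subunits) at time ``t``; exact piecewise-linear interpolation."""
        return np.interp(t, self.times, self.lengths)

    def ever_visited(self, state: BarbedEndState) -> bool:
        return self.initial_state is state or any(to is state for _, _, to in self.transitions)

    def ternary_formation_order(self) -> Optional[str]:
        """Bookkeeping tag: how the ternary complex was first assembled.

        ``"via_BF_then_C"`` if the first entry into BFC came from BF,
        ``"via_BC_then_F"`` if it came from BC, ``None`` if the ternary
        state was never formed during the trace (a filament *started* in
        BFC has no recorded order).  Purely provenance — propensities
        never depend on it.
        """
        for _, frm, to in self.transitions:
            if to is BarbedEndState.BFC:
                return "via_BF_then_C" if frm is BarbedEndState.BF else "via_BC_then_F"
        return None

    def to_frame(self) -> pd.DataFrame:
        """Length-vs-time breakpoints as a tidy frame (kymograph-style export)."""
        return pd.DataFrame(
            {
                "filament_id": self.filament_id,
                "time_s": self.times,
                "length_subunits": self.lengths,
            }
        )


def _seed_sequence(master_seed, index: Optional[int] = None) -> np.random.SeedSequence:
    entropy = list(master_seed) if isinstance(master_seed, (tuple, list)) else [int(master_seed)]
    key = () if index is None else (int(index),)
    return np.random.SeedSequence(entropy=entropy, spawn_key=key)


def simulate_filament(
    protocol: FlowProtocol,
    rates: RateSet,
    initial_state: BarbedEndState = BarbedEndState.B,
    rng_seed=0,
    filament_id: int = 0,
    bfc_decay_requires_actin: bool = True,
    v_free: float = V_FREE_DEFAULT,
    v_formin: Optional[float] = None,
) -> FilamentTrace:
    """Exact stochastic realization of one filament under a flow protocol.

    Waiting times are drawn from the exponential distribution of the total
    outgoing rate in the current (state, condition); the branch is chosen
    proportionally to the channel rates (Gillespie direct method).  State
    is carried across segment boundaries and the clock redrawn there,
    which is exact for memoryless waiting times.  In ``formin_anchored``
    mode, any transition that removes formin from the barbed end detaches
    the filament and ends its observation.
    """
    rng = np.random.default_rng(
        rng_seed if isinstance(rng_seed, np.random.SeedSequence) else _seed_sequence(rng_seed)
    )
    seed_tag = rng_seed if isinstance(rng_seed, tuple) else (rng_seed,) if isinstance(rng_seed, int) else None

    state = initial_state
    t = 0.0
    length = 0.0
    bp_t = [0.0]
    bp_len = [0.0]
    transitions: list[tuple[float, BarbedEndState, BarbedEndState]] = []
    detached_at: Optional[float] = None
    seg_start = 0.0

    for _, (duration, cond) in enumerate(protocol.segments):
        seg_end = seg_start + duration
        while True:
            channels = propensities(state, cond, rates, bfc_decay_requires_actin)
            total = sum(r for _, r in channels)
            velocity = elongation_velocity(state, cond, rates, v_free, v_formin)
            wait = rng.exponential(1.0 / total) if total > 0 else math.inf
            if t + wait >= seg_end:
                length += velocity * (seg_end - t)
                t = seg_end
                bp_t.append(t)
                bp_len.append(length)
                break
            t += wait
            length += velocity * wait
            u = rng.random() * total
            acc = 0.0
            new_state = channels[-1][0]
            for target, r in channels:
                acc += r
                if u < acc:
                    new_state = target
                    break
            transitions.append((t, state, new_state))
            bp_t.append(t)
            bp_len.append(length)
            if (
                protocol.anchor_mode == FORMIN_ANCHORED
                and state.has_formin
                and not new_state.has_formin
            ):
                detached_at = t
                return FilamentTrace(
                    filament_id=filament_id,
                    initial_state=initial_state,
                    transitions=transitions,
                    times=np.asarray(bp_t),
                    lengths=np.asarray(bp_len),
                    observed_until=t,
                    anchor_mode=protocol.anchor_mode,
                    detached_at=detached_at,
                    rng_seed=seed_tag,
                )
            state = new_state
        seg_start = seg_end

    return FilamentTrace(
        filament_id=filament_id,
        initial_state=initial_state,
        transitions=transitions,
        times=np.asarray(bp_t),
        lengths=np.asarray(bp_len),
        observed_until=protocol.total_duration,
        anchor_mode=protocol.anchor_mode,
        detached_at=None,
        rng_seed=seed_tag,
    )


def simulate_population(
    n: int,
    protocol: FlowProtocol,
    rates: RateSet,
    initial_state: BarbedEndState = BarbedEndState.B,
    master_seed=0,
    **kwargs,
) -> list[FilamentTrace]:
    """Simulate ``n`` independent filaments with per-filament child seeds.

    Child streams are derived from ``master_seed`` by counter
    (``SeedSequence(master_seed, spawn_key=(i,))`` feeding a PCG64
    generator), so a population is reproducible from the master seed
    alone and any single filament can be regenerated in isolation.
    """
    if not isinstance(n, (int, np.integer)) or n < 1:
        raise ValueError(f"population size must be a positive integer, got {n!r}")
    traces = []
    for i in range(int(n)):
        ss = _seed_sequence(master_seed, i)
        trace = simulate_filament(
            protocol,
            rates,
            initial_state=initial_state,
            rng_seed=ss,
            filament_id=i,
            **kwargs,
        )
        trace.rng_seed = (master_seed, i) if isinstance(master_seed, int) else tuple(master_seed) + (i,)
        traces.append(trace)
    return traces


_PAUSED, _SLOW, _FAST = 0, 1, 2
_EVENT_NAME = {_PAUSED: "arrest", _SLOW: "resume_slow", _FAST: "resume_fast"}


def observe(
    trace: FilamentTrace,
    protocol: FlowProtocol,
    rates: RateSet,
    frame_interval: float = 1.0 / 3.0,
    length_noise_sd: float = 1.0,
    min_pause: float = 2.0,
    velocity_window: float = 3.0,
    rng: Optional[np.random.Generator] = None,
    v_free: float = V_FREE_DEFAULT,
    v_formin: Optional[float] = None,
) -> list[dict]:
    """Camera-limited event detection on one trace → switching-event rows.

    The length trajectory is sampled every ``frame_interval`` seconds with
    additive Gaussian noise (``length_noise_sd`` subunits), converted to a
    velocity estimate over a forward ``velocity_window``, and classified
    per frame into paused / slow / fast using thresholds halfway between
    the expected regime velocities of the segment's condition.  Runs of a
    regime shorter than ``min_pause`` seconds are below the detection
    limit and merged into the preceding regime.  One row is emitted per
    detected regime change (``arrest``, ``resume_slow``, ``resume_fast``),
    one ``detach`` row if the filament was released, and one censored row
    per flow segment in which the filament was observed but showed no
    event (carrying the end of that segment's observation window as its
    time).  Times are reported relative to the start of the flow segment
    the event falls in.  In the noiseless, fine-frame, zero-window limit
    the detected times converge to the true transition times.
    """
    if frame_interval <= 0:
        raise ValueError("frame_interval must be positive")
    if rng is None:
        rng = np.random.default_rng(0)

    end = trace.observed_until
    n_frames = int(math.floor(end / frame_interval + 1e-9)) + 1
    tf = np.arange(n_frames) * frame_interval
    lengths = np.asarray(trace.length_at(tf), dtype=float)
    if length_noise_sd > 0:
        lengths = lengths + rng.normal(0.0, length_noise_sd, size=lengths.shape)

    boundaries = protocol.boundaries()
    seg_starts = protocol.segment_starts()
    seg_idx = np.minimum(
        np.searchsorted(boundaries, tf, side="right"), len(boundaries) - 1
    )

    # expected regime velocities per segment -> classification thresholds
    thr_pause = np.empty(len(protocol.segments))
    thr_fast = np.empty(len(protocol.segments))
    for s, (_, cond) in enumerate(protocol.segments):
        v_slow = elongation_velocity(BarbedEndState.B, cond, rates, v_free, v_formin)
        v_fast = elongation_velocity(BarbedEndState.BF, cond, rates, v_free, v_formin)
        if v_fast <= 0:
            # no elongation substrate: nothing grows, nothing is classifiable
            thr_pause[s] = math.inf
            thr_fast[s] = math.inf
        else:
            thr_pause[s] = 0.5 * v_slow if v_slow > 0 else 0.25 * v_fast
            thr_fast[s] = 0.5 * (v_slow + v_fast)

    if n_frames < 2:
        regimes = np.zeros(1, dtype=int)
    else:
        w = max(1, int(round(velocity_window / frame_interval)))
        j_hi = np.minimum(np.arange(n_frames) + w, n_frames - 1)
        span = tf[j_hi] - tf
        span[span == 0] = frame_interval
        vel = (lengths[j_hi] - lengths) / span
        # last frame has no forward span; inherit its neighbour's estimate
        if n_frames >= 2:
            vel[-1] = vel[-2]
        tp = thr_pause[seg_idx]
        tfst = thr_fast[seg_idx]
        regimes = np.where(vel < tp, _PAUSED, np.where(vel >= tfst, _FAST, _SLOW))

    # run-length encode, dropping runs below the detection limit
    runs: list[list] = []  # [start_frame, regime]
    for j in range(len(regimes)):
        if not runs or regimes[j] != runs[-1][1]:
            runs.append([j, int(regimes[j])])
    min_frames = max(1, int(round(min_pause / frame_interval)))
    kept: list[list] = []
    for idx, (start, regime) in enumerate(runs):
        run_end = runs[idx + 1][0] if idx + 1 < len(runs) else len(regimes)
        n_run = run_end - start
        is_last = idx == len(runs) - 1
        if kept and n_run < min_frames and not is_last:
            continue  # below detection limit: absorbed into the previous regime
        if kept and kept[-1][1] == regime:
            continue
        kept.append([start, regime])

    rows: list[dict] = []
    for start, regime in kept[1:]:
        t_event = tf[start]
        s = int(seg_idx[start])
        rows.append(
            {
                "filament_id": trace.filament_id,
                "condition_label": protocol.segment_label(s),
                "event_type": _EVENT_NAME[regime],
                "time_s": float(t_event - seg_starts[s]),
                "censored": False,
            }
        )

    if trace.detached_at is not None:
        s = int(np.minimum(np.searchsorted(boundaries, trace.detached_at, side="right"), len(boundaries) - 1))
        rows.append(
            {
                "filament_id": trace.filament_id,
                "condition_label": protocol.segment_label(s),
                "event_type": "detach",
                "time_s": float(trace.detached_at - seg_starts[s]),
                "censored": False,
            }
        )

    # one censored row per event-free segment the filament was observed in
    seen = {r["condition_label"] for r in rows}
    for s in range(len(protocol.segments)):
        seg_start = seg_starts[s]
        if seg_start >= end:
            break
        label = protocol.segment_label(s)
        if label in seen:
            continue
        seg_stop = min(boundaries[s], end)
        rows.append(
            {
                "filament_id": trace.filament_id,
                "condition_label": label,
                "event_type": "none",
                "time_s": float(seg_stop - seg_start),
                "censored": True,
            }
        )
    return rows


def observe_population(
    traces: Iterable[FilamentTrace],
    protocol: FlowProtocol,
    rates: RateSet,
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Apply :func:`observe` to a population; returns the switching-event table.

    Columns: ``filament_id, condition_label, event_type, time_s, censored``
    (times in seconds since the start of the segment the event falls in).
    """
    rng = np.random.default_rng(_seed_sequence(seed))
    rows: list[dict] = []
    for trace in traces:
        rows.extend(observe(trace, protocol, rates, rng=rng, **kwargs))
    if not rows:
        return pd.DataFrame(columns=list(EVENT_COLUMNS))
    # rows are already chronological within each filament; keep that order
    return pd.DataFrame(rows, columns=list(EVENT_COLUMNS))


def traces_to_frame(traces: Sequence[FilamentTrace]) -> pd.DataFrame:
    """Concatenate length-vs-time breakpoints of many traces (CSV export)."""
    if not traces:
        return pd.DataFrame(columns=["filament_id", "time_s", "length_subunits"])
    return pd.concat([t.to_frame() for t in traces], ignore_index=True)
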