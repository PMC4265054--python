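"""Discrete-time simulation of a cell population around the cell cycle.

The cycle is a circular array of 1-minute slots (default 77: G1 21, S 14,
G2 14, M 21, M.G1 7) holding the relative number of cells at each point;
each time step advances every slot's mass by one slot, wrapping at the end
of the cycle (no proliferation term — the state is a relative density, and
an unsynchronised uniform density is then a fixed point).

A stress such as heat shock erects a transient barrier at the START
checkpoint (between slots 14 and 15, 1-based): while cells recover
(default 25 min) no mass crosses, so the slot in front of START piles up
and the slots beyond it empty out.  After recovery the pile is released,
either as a single synchronised block (``cohort``, default) or one
steady-state slot-mass per minute (``drain``).

Derived observables: the 1N (pre-replication) fraction (slots 1..28),
7-minute coarse-grained occupancies, and predicted expression-magnitude
transients obtained by treating expression changes as proportional to the
per-bin fold change in cell numbers, thresholded at 1.7-fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PopulationModel",
    "PopulationState",
    "SimulationTrace",
    "init_steady_state",
    "step",
    "simulate",
    "one_n_fraction",
    "coarse_grain",
    "expression_magnitude",
]

DEFAULT_PHASE_LENGTHS = {"G1": 21, "S": 14, "G2": 14, "M": 21, "M.G1": 7}

_MAG_EPS = 1e-6  # floor before fold-ratio computation on empty bins


@dataclass
class PopulationModel:
    """Slot-model parameters.  Slot indices are 1-based in all interfaces."""

    phase_lengths_min: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_PHASE_LENGTHS)
    )
    barrier_after_slot: int = 14
    recovery_min: int = 25
    one_n_last_slot: int = 28
    coarse_bin_min: int = 7
    fold_threshold: float = 1.7
    release_mode: str = "cohort"

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.phase_lengths_min.values()):
            raise ValueError("phase lengths must be positive")
        if not 1 <= self.barrier_after_slot < self.n_slots:
            raise ValueError("barrier_after_slot out of range")
        if not 1 <= self.one_n_last_slot <= self.n_slots:
            raise ValueError("one_n_last_slot out of range")
        if self.n_slots % self.coarse_bin_min != 0:
            raise ValueError("coarse_bin_min must divide the cycle length")
        if self.release_mode not in ("cohort", "drain"):
            raise ValueError("release_mode must be 'cohort' or 'drain'")
        if self.recovery_min < 1:
            raise ValueError("recovery_min must be >= 1")

    @property
    def n_slots(self) -> int:
        return int(sum(self.phase_lengths_min.values()))

    @property
    def n_coarse_bins(self) -> int:
        return self.n_slots // self.coarse_bin_min


@dataclass
class PopulationState:
    """Per-slot relative cell numbers at one instant (sums to 1)."""

    time_min: int
    density: np.ndarray
    barrier_active: bool = False

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=float)
        if (self.density < 0).any():
            raise ValueError("negative density")
        if abs(self.density.sum() - 1.0) > 1e-9:
            raise ValueError("density does not sum to 1")


def init_steady_state(model: PopulationModel) -> PopulationState:
    """Uniform density over the circular array (unsynchronised population)."""
    n = model.n_slots
    return PopulationState(time_min=0, density=np.full(n, 1.0 / n))


def step(
    state: PopulationState,
    model: PopulationModel,
    barrier_active: bool | None = None,
    drain_release: bool = False,
) -> PopulationState:
    """Advance one minute: every slot's mass moves to the next slot (wrapping).

    With the barrier up, mass bound from slot ``barrier_after_slot`` to the
    next slot stays put and accumulates there instead.  With
    ``drain_release``, at most one steady-state slot-mass (1/n_slots)
    crosses per minute while the rest of the pile waits.
    """
    if barrier_active is None:
        barrier_active = state.barrier_active
    d = state.density
    n = model.n_slots
    b = model.barrier_after_slot - 1  # 0-based index of the slot before the barrier
    new = np.roll(d, 1)
    if barrier_active:
        # blocked: slot b keeps its mass (plus inflow); slot b+1 gets nothing
        new[(b + 1) % n] = 0.0
        new[b] = d[b] + d[b - 1] if b > 0 else d[b] + d[n - 1]
    elif drain_release:
        quota = 1.0 / n
        crossing = min(d[b], quota)
        held = d[b] - crossing
        new[(b + 1) % n] = crossing
        new[b] = held + (d[b - 1] if b > 0 else d[n - 1])
    out = PopulationState(
        time_min=state.time_min + 1, density=new, barrier_active=barrier_active
    )
    return out


def one_n_fraction(state: PopulationState, model: PopulationModel) -> float:
    """Fraction of cells with 1N DNA content (slots 1..one_n_last_slot)."""
    return float(state.density[: model.one_n_last_slot].sum())


def coarse_grain(state: PopulationState, model: PopulationModel) -> np.ndarray:
    """Average consecutive groups of ``coarse_bin_min`` slots (for display
    and for the magnitude model)."""
    n_bins = model.n_coarse_bins
    return state.density.reshape(n_bins, model.coarse_bin_min).mean(axis=1)


@dataclass
class SimulationTrace:
    """Minute-by-minute record of a simulation run."""

    times_min: np.ndarray
    densities: np.ndarray          # (steps+1, n_slots)
    one_n_fractions: np.ndarray
    coarse_densities: np.ndarray   # (steps+1, n_slots / coarse_bin_min)
    magnitude_up: np.ndarray
    magnitude_down: np.ndarray
    model: PopulationModel = field(repr=False, default=None)

    def state_at(self, t: int) -> PopulationState:
        i = int(np.searchsorted(self.times_min, t))
        if i >= self.times_min.size or self.times_min[i] != t:
            raise KeyError(f"time {t} not in trace")
        return PopulationState(time_min=t, density=self.densities[i])


def simulate(
    model: PopulationModel, t_end_min: int, shock_at_min: int = 0
) -> SimulationTrace:
    """Run the slot model for ``t_end_min`` minutes with a shock at
    ``shock_at_min`` (use a negative value for a no-shock run).

    The barrier blocks the START transition for the ``recovery_min`` steps
    following the shock; afterwards the accumulated cells pass according to
    the model's release mode.
    """
    if t_end_min < 1:
        raise ValueError("t_end_min must be >= 1")
    if shock_at_min >= 0 and t_end_min < shock_at_min:
        raise ValueError("t_end_min is before the shock")
    state = init_steady_state(model)
    densities = [state.density.copy()]
    for t in range(t_end_min):
        if shock_at_min >= 0:
            barrier = shock_at_min <= t < shock_at_min + model.recovery_min
            draining = (
                model.release_mode == "drain" and t >= shock_at_min + model.recovery_min
            )
        else:
            barrier = False
            draining = False
        state = step(state, model, barrier_active=barrier, drain_release=draining)
        densities.append(state.density.copy())
    densities = np.asarray(densities)
    times = np.arange(t_end_min + 1)
    one_n = densities[:, : model.one_n_last_slot].sum(axis=1)
    coarse = densities.reshape(
        densities.shape[0], model.n_coarse_bins, model.coarse_bin_min
    ).mean(axis=2)
    trace = SimulationTrace(
        times_min=times,
        densities=densities,
        one_n_fractions=one_n,
        coarse_densities=coarse,
        magnitude_up=np.zeros(times.size),
        magnitude_down=np.zeros(times.size),
        model=model,
    )
    up, down = expression_magnitude(trace, model)
    trace.magnitude_up, trace.magnitude_down = up, down
    return trace


def expression_magnitude(
    trace: SimulationTrace, model: PopulationModel
) -> tuple[np.ndarray, np.ndarray]:
    """Predicted average expression-change magnitudes from occupancy shifts.

    Expression change of phase-specific genes is taken proportional to the
    fold change of cell numbers in each coarse bin relative to the pre-shock
    steady state (t = 0); only bins beyond the ``fold_threshold`` (1.7 by
    default) contribute.  Each series is normalised to its own maximum
    absolute value — the output is a shape, the proportionality constant
    being unidentified without matched expression data.
    """
    if trace.times_min[0] != 0:
        raise ValueError("trace must include the t = 0 pre-shock state")
    ref = trace.coarse_densities[0]
    up = np.zeros(trace.times_min.size)
    down = np.zeros(trace.times_min.size)
    log_thr = np.log2(model.fold_threshold)
    for i in range(trace.times_min.size):
        fold = np.maximum(trace.coarse_densities[i], _MAG_EPS) / ref
        lf = np.log2(fold)
        rising = lf > log_thr
        falling = lf < -log_thr
        if rising.any():
            up[i] = lf[rising].mean()
        if falling.any():
            down[i] = lf[falling].mean()
    if np.abs(up).max() > 0:
        up = up / np.abs(up).max()
    if np.abs(down).max() > 0:
        down = down / np.abs(down).max()
    return up, down
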