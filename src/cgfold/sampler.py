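"""Metropolis Monte Carlo engine.

Supports fixed-temperature folding/unfolding, simulated annealing with a
geometric temperature schedule, replica-exchange Monte Carlo (REMC) with
conformation swaps between neighboring temperatures, frozen residues, and
multi-run orchestration.  All randomness flows from one seeded generator, so
(seed, config, inputs) fully determine every output.

The move set is symmetric (each proposal and its exact inverse are equally
likely), so the standard Metropolis acceptance rule samples the Boltzmann
distribution at the configured temperature factor.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np

logger = logging.getLogger("cgfold")

from .cg_model_io import (
    CGConformation,
    Trajectory,
    TrajectoryFrame,
    make_header,
)
from .energy import EnergyContext, EnergyModel
from .restraints import RestraintSet

MOVE_KINDS = ("jitter", "shift", "pivot")


@dataclass
class SimulationConfig:
    """Run parameters; temperatures are unitless factors in energy units."""

    n_steps: int = 10_000
    frame_every: int = 100          # record every N attempted steps
    temperature: float = 1.0        # fixed-T modes
    t_start: float | None = None    # annealing
    t_end: float | None = None
    n_replicas: int = 1
    replica_temperatures: list[float] | None = None
    swap_every: int = 100           # REMC swap-attempt interval, steps
    n_runs: int = 1
    seed: int = 0
    mode: str = "fold"              # fold | anneal | unfold | remc
    move_weights: tuple[float, float, float] = (0.3, 0.2, 0.5)
    jitter_sigma: float = 0.3       # A
    shift_sigma: float = 0.6        # A
    pivot_sigma: float = 0.5        # rad
    record_initial: bool = True

    def __post_init__(self) -> None:
        if self.n_steps <= 0:
            raise ValueError("n_steps must be > 0")
        if self.frame_every < 1:
            raise ValueError("frame_every must be >= 1")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.mode == "anneal":
            if self.t_start is None or self.t_end is None:
                raise ValueError("annealing needs t_start and t_end")
            if not self.t_start >= self.t_end > 0:
                raise ValueError("need t_start >= t_end > 0")
        if self.replica_temperatures is not None:
            ladder = self.replica_temperatures
            if any(t <= 0 for t in ladder):
                raise ValueError("temperatures must be > 0")
            if any(b <= a for a, b in zip(ladder, ladder[1:])):
                raise ValueError("replica ladder must be strictly increasing")

    def ladder(self) -> list[float]:
        """Replica temperature ladder (default: geometric from 1.0 to 2.0)."""
        if self.replica_temperatures is not None:
            return list(self.replica_temperatures)
        n = self.n_replicas
        if n == 1:
            return [self.temperature]
        return [1.0 * (2.0 ** (k / (n - 1))) for k in range(n)]

    def to_dict(self) -> dict:
        return asdict(self)


def metropolis_accept(delta_E: float, T: float, u: float) -> bool:
    """Standard Metropolis rule: accept iff ΔE <= 0 or u < exp(-ΔE / T)."""
    if T <= 0:
        raise ValueError("temperature must be > 0")
    if delta_E <= 0:
        return True
    return u < math.exp(-delta_E / T)


@dataclass
class MoveProposal:
    kind: str
    residue_range: tuple[int, int]      # inclusive range of affected residues
    bead: int | None = None             # jitter only
    delta: np.ndarray | None = None     # jitter / shift displacement
    pivot_residue: int | None = None
    axis: np.ndarray | None = None      # pivot rotation axis (unit)
    angle: float | None = None          # pivot rotation angle, rad

    def inverse(self) -> "MoveProposal":
        inv = MoveProposal(self.kind, self.residue_range, self.bead,
                           None if self.delta is None else -self.delta,
                           self.pivot_residue, self.axis,
                           None if self.angle is None else -self.angle)
        return inv


def _rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    x, y, z = float(axis[0]), float(axis[1]), float(axis[2])
    n = math.sqrt(x * x + y * y + z * z)
    x, y, z = x / n, y / n, z / n
    c, s = math.cos(angle), math.sin(angle)
    t = 1.0 - c
    return np.array([
        [c + x * x * t, x * y * t - z * s, x * z * t + y * s],
        [y * x * t + z * s, c + y * y * t, y * z * t - x * s],
        [z * x * t - y * s, z * y * t + x * s, c + z * z * t],
    ])


def apply_move(coords: np.ndarray, proposal: MoveProposal) -> np.ndarray:
    """Apply a proposal to (n, 5, 3) coordinates, returning a new array."""
    out = coords.copy()
    lo, hi = proposal.residue_range
    if proposal.kind == "jitter":
        out[lo, proposal.bead] += proposal.delta
    elif proposal.kind == "shift":
        out[lo:hi + 1] += proposal.delta
    elif proposal.kind == "pivot":
        R = _rotation(proposal.axis, proposal.angle)
        center = coords[proposal.pivot_residue, 1]   # the pivot's C4' bead
        seg = out[lo:hi + 1].reshape(-1, 3)
        out[lo:hi + 1] = ((seg - center) @ R.T + center).reshape(-1, 5, 3)
    else:
        raise ValueError(f"unknown move kind {proposal.kind!r}")
    return out


def propose_move(
    coords: np.ndarray,
    frozen_mask: np.ndarray,
    chain_of: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, MoveProposal]:
    """Draw a symmetric move; frozen residues are never touched."""
    n = coords.shape[0]
    unfrozen = np.nonzero(~frozen_mask)[0]
    if unfrozen.size == 0:
        raise ValueError("all residues are frozen; nothing to move")
    w = config.move_weights
    tot = w[0] + w[1] + w[2]
    c1, c2 = w[0] / tot, (w[0] + w[1]) / tot
    for _attempt in range(20):
        u = rng.random()
        kind = "jitter" if u < c1 else ("shift" if u < c2 else "pivot")
        if kind == "jitter":
            r = int(unfrozen[rng.integers(unfrozen.size)])
            bead = int(rng.integers(5))
            delta = rng.normal(0.0, config.jitter_sigma, 3)
            prop = MoveProposal("jitter", (r, r), bead=bead, delta=delta)
            return apply_move(coords, prop), prop
        if kind == "shift":
            r = int(unfrozen[rng.integers(unfrozen.size)])
            delta = rng.normal(0.0, config.shift_sigma, 3)
            prop = MoveProposal("shift", (r, r), delta=delta)
            return apply_move(coords, prop), prop
        # pivot: rotate the chain tail on one side of a pivot residue,
        # truncated before any frozen residue
        r = int(unfrozen[rng.integers(unfrozen.size)])
        direction = 1 if rng.random() < 0.5 else -1
        axis = rng.normal(0.0, 1.0, 3)
        axis /= np.linalg.norm(axis)
        angle = float(rng.normal(0.0, config.pivot_sigma))
        lo = hi = None
        if direction == 1:
            stop = r
            while stop + 1 < n and chain_of[stop + 1] == chain_of[r] \
                    and not frozen_mask[stop + 1]:
                stop += 1
            if stop > r:
                lo, hi = r + 1, stop
        else:
            stop = r
            while stop - 1 >= 0 and chain_of[stop - 1] == chain_of[r] \
                    and not frozen_mask[stop - 1]:
                stop -= 1
            if stop < r:
                lo, hi = stop, r - 1
        if lo is None:
            continue  # no rotatable tail on that side; redraw
        prop = MoveProposal("pivot", (lo, hi), pivot_residue=r,
                            axis=axis, angle=angle)
        return apply_move(coords, prop), prop
    # fall back to a guaranteed-valid move
    r = int(unfrozen[rng.integers(unfrozen.size)])
    delta = rng.normal(0.0, config.shift_sigma, 3)
    prop = MoveProposal("shift", (r, r), delta=delta)
    return apply_move(coords, prop), prop


# ---------------------------------------------------------------------------
# drivers
# ---------------------------------------------------------------------------

def _make_context(start: CGConformation, model, restraints):
    if hasattr(model, "evaluate"):
        return model
    return EnergyContext(start.sequences, model or EnergyModel(),
                         restraints or RestraintSet())


def _chain_of(conf: CGConformation) -> np.ndarray:
    ids = {c: k for k, c in enumerate(conf.chain_ids)}
    return np.array([ids[r.chain_id] for r in conf.residues])


def _frozen(start: CGConformation, restraints: RestraintSet | None) -> np.ndarray:
    if restraints is not None and restraints.frozen_mask is not None:
        return np.asarray(restraints.frozen_mask, dtype=bool)
    return start.frozen_mask.copy()


def _temperature_schedule(config: SimulationConfig):
    if config.mode == "anneal":
        t0, t1, n = config.t_start, config.t_end, config.n_steps
        if t0 == t1:
            return lambda step: t0
        ratio = t1 / t0
        return lambda step: t0 * ratio ** (step / n)
    return lambda step: config.temperature


def _frame(step, replica, T, total, terms, coords) -> TrajectoryFrame:
    if logger.isEnabledFor(logging.DEBUG):
        logger.debug(
            "step %d replica %d T %.4g E %.6g | %s", step, replica, T, total,
            " ".join(f"{k}={v:.4g}" for k, v in terms.items()),
        )
    return TrajectoryFrame(step, replica, T, total, dict(terms),
                           coords.ravel().copy())


def run_mc(
    start: CGConformation,
    model: EnergyModel | object | None,
    restraints: RestraintSet | None,
    config: SimulationConfig,
) -> Trajectory:
    """Single-replica Metropolis run (folding, unfolding or annealing).

    A frame is recorded every ``frame_every`` attempted steps — the current
    state is written whether or not the last proposal was accepted.
    """
    ctx = _make_context(start, model, restraints)
    rng = np.random.default_rng(config.seed)
    frozen = _frozen(start, restraints)
    chain_of = _chain_of(start)
    coords = start.coords()
    total, terms = ctx.evaluate(coords)
    sched = _temperature_schedule(config)
    frames: list[TrajectoryFrame] = []
    if config.record_initial:
        frames.append(_frame(0, 0, sched(0), total, terms, coords))
    for step in range(1, config.n_steps + 1):
        T = sched(step)
        new_coords, _prop = propose_move(coords, frozen, chain_of, config, rng)
        new_total, new_terms = ctx.evaluate(new_coords)
        if not math.isfinite(new_total):
            raise RuntimeError(f"non-finite energy at step {step}")
        if metropolis_accept(new_total - total, T, float(rng.random())):
            coords, total, terms = new_coords, new_total, new_terms
        if step % config.frame_every == 0:
            frames.append(_frame(step, 0, T, total, terms, coords))
    header = make_header(
        list(start.sequences.values()), start.chain_ids,
        list(terms.keys()), 1, config.seed,
        mode=config.mode, n_steps=config.n_steps,
        frame_every=config.frame_every,
        temperature=config.temperature,
        t_start=config.t_start, t_end=config.t_end,
    )
    return Trajectory(header, frames)


def anneal(
    start: CGConformation,
    model,
    restraints: RestraintSet | None,
    config: SimulationConfig,
) -> Trajectory:
    """Simulated annealing: geometric temperature profile t_start → t_end."""
    if config.mode != "anneal":
        config = SimulationConfig(**{**config.to_dict(), "mode": "anneal"})
    return run_mc(start, model, restraints, config)


def run_remc(
    start: CGConformation,
    model,
    restraints: RestraintSet | None,
    config: SimulationConfig,
) -> list[Trajectory]:
    """Replica-exchange Monte Carlo.

    Every ``swap_every`` steps neighboring replicas attempt to exchange
    *conformations* (temperatures stay put) with acceptance
    min(1, exp((1/T_i - 1/T_j) (E_i - E_j))).  Returns one trajectory per
    replica, each carrying its replica id.
    """
    ladder = config.ladder()
    if len(ladder) < 2:
        raise ValueError("REMC needs at least 2 replicas")
    ctx = _make_context(start, model, restraints)
    rng = np.random.default_rng(config.seed)
    frozen = _frozen(start, restraints)
    chain_of = _chain_of(start)
    n_rep = len(ladder)
    coords = [start.coords() for _ in range(n_rep)]
    totals, terms = [], []
    for c in coords:
        e, t = ctx.evaluate(c)
        totals.append(e)
        terms.append(t)
    frames: list[list[TrajectoryFrame]] = [[] for _ in range(n_rep)]
    if config.record_initial:
        for r in range(n_rep):
            frames[r].append(_frame(0, r, ladder[r], totals[r], terms[r], coords[r]))
    parity = 0
    swap_attempts = swap_accepted = 0
    for step in range(1, config.n_steps + 1):
        for r in range(n_rep):
            new_c, _ = propose_move(coords[r], frozen, chain_of, config, rng)
            new_e, new_t = ctx.evaluate(new_c)
            if not math.isfinite(new_e):
                raise RuntimeError(f"non-finite energy at step {step}, replica {r}")
            if metropolis_accept(new_e - totals[r], ladder[r], float(rng.random())):
                coords[r], totals[r], terms[r] = new_c, new_e, new_t
        if step % config.swap_every == 0:
            for a in range(parity, n_rep - 1, 2):
                b = a + 1
                arg = (1.0 / ladder[a] - 1.0 / ladder[b]) * (totals[a] - totals[b])
                swap_attempts += 1
                if arg >= 0 or rng.random() < math.exp(arg):
                    swap_accepted += 1
                    coords[a], coords[b] = coords[b], coords[a]
                    totals[a], totals[b] = totals[b], totals[a]
                    terms[a], terms[b] = terms[b], terms[a]
            parity = 1 - parity
        if step % config.frame_every == 0:
            for r in range(n_rep):
                frames[r].append(
                    _frame(step, r, ladder[r], totals[r], terms[r], coords[r])
                )
    out = []
    for r in range(n_rep):
        header = make_header(
            list(start.sequences.values()), start.chain_ids,
            list(terms[r].keys()), n_rep, config.seed,
            mode="remc", n_steps=config.n_steps,
            frame_every=config.frame_every, replica=r,
            ladder=" ".join(f"{t:g}" for t in ladder),
            swap_every=config.swap_every,
            swap_attempts=swap_attempts, swap_accepted=swap_accepted,
        )
        out.append(Trajectory(header, frames[r]))
    return out


def remc_swap_probability(E_i: float, E_j: float, T_i: float, T_j: float) -> float:
    """Closed-form swap acceptance for one attempted exchange."""
    arg = (1.0 / T_i - 1.0 / T_j) * (E_i - E_j)
    return 1.0 if arg >= 0 else math.exp(arg)


def run_repeats(
    start: CGConformation,
    model,
    restraints: RestraintSet | None,
    config: SimulationConfig,
) -> list[Trajectory]:
    """Independent repeats with seeds ``seed + run_index``."""
    out = []
    for k in range(config.n_runs):
        cfg = SimulationConfig(**{**config.to_dict(), "seed": config.seed + k,
                                  "n_runs": 1})
        if cfg.mode == "remc":
            out.extend(run_remc(start, model, restraints, cfg))
        else:
            out.append(run_mc(start, model, restraints, cfg))
    return out
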