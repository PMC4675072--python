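"""Trajectory simulation and outcome selection (the "double-dipping" operator).

Discrete chains are iterated by categorical draws from the current row;
continuous chains by the standard exponential-sojourn / proportional-jump
scheme (the exact stochastic simulation algorithm on a fixed rate matrix).
Trajectories that hit the step cap before absorbing are marked *censored*,
never silently truncated: discarding them IS an outcome selection, so
:func:`select_by_outcome` drops them loudly, with a logged count.

Reproducibility: an ensemble is seeded once; every trajectory gets its own
deterministic child stream (``SeedSequence.spawn``), so results do not
depend on simulation order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .chains import ChainSpec

__all__ = [
    "Trajectory",
    "Ensemble",
    "simulate_discrete",
    "simulate_continuous",
    "sample_ensemble",
    "select_by_outcome",
    "write_ensemble_tsv",
    "read_ensemble_tsv",
]

logger = logging.getLogger("condchain")


@dataclass(frozen=True)
class Trajectory:
    """One realized path.

    ``sojourns`` is ``None`` in discrete time; in continuous time it holds
    one duration per visited state, with 0.0 for the final state (an
    absorbed state is never left; a censored final visit has no completed
    sojourn).  ``outcome`` is the final state label if absorbed, ``None``
    if censored by the step cap.
    """

    states: tuple[str, ...]
    sojourns: tuple[float, ...] | None
    outcome: str | None

    @property
    def is_censored(self) -> bool:
        return self.outcome is None

    def __len__(self) -> int:
        return len(self.states)


@dataclass(frozen=True)
class Ensemble:
    """A collection of independent trajectories from one chain."""

    trajectories: tuple[Trajectory, ...]
    spec: ChainSpec
    chain_fingerprint: str
    seed: int | None
    start_rule: str

    def __len__(self) -> int:
        return len(self.trajectories)

    @property
    def n_censored(self) -> int:
        return sum(1 for t in self.trajectories if t.is_censored)

    def outcome_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for t in self.trajectories:
            key = t.outcome if t.outcome is not None else "<censored>"
            out[key] = out.get(key, 0) + 1
        return out


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def default_max_steps(spec: ChainSpec) -> int:
    # diffusive absorption-time scale: quadratic in the state count
    return 50 * spec.n_states**2


def _cum_rows(spec: ChainSpec) -> np.ndarray:
    """Row-wise cumulative kernel; discrete rows rescaled so the last
    entry is exactly 1.0 (uniform draws can then never index past it)."""
    cum = np.cumsum(spec.kernel, axis=1)
    if spec.is_discrete:
        last = cum[:, -1:].copy()
        last[last == 0.0] = 1.0
        cum = cum / last
    return cum


def _sim_discrete_idx(
    cum: np.ndarray, amask: np.ndarray, start: int, rng: np.random.Generator,
    max_steps: int,
) -> list[int]:
    path = [start]
    i = start
    buf = rng.random(64)
    ptr = 0
    for _ in range(max_steps):
        if amask[i]:
            break
        if ptr == buf.size:
            buf = rng.random(256)
            ptr = 0
        i = int(np.searchsorted(cum[i], buf[ptr], side="right"))
        ptr += 1
        path.append(i)
    return path


def simulate_discrete(
    spec: ChainSpec, start: str, seed, max_steps: int | None = None
) -> Trajectory:
    """Simulate one discrete-time trajectory from ``start``.

    ``seed`` may be an int or a ``numpy.random.Generator``.  The walk stops
    at an absorbing state or after ``max_steps`` jumps (censored).
    """
    if not spec.is_discrete:
        raise ValueError("simulate_discrete requires a discrete-time chain")
    if start not in spec.index:
        raise ValueError(f"start state {start!r} is not in the chain")
    if max_steps is None:
        max_steps = default_max_steps(spec)
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    rng = _rng(seed)
    cum = _cum_rows(spec)
    amask = spec.absorbing_mask
    path = _sim_discrete_idx(cum, amask, spec.index[start], rng, max_steps)
    labels = tuple(spec.state_labels[i] for i in path)
    outcome = labels[-1] if amask[path[-1]] else None
    return Trajectory(labels, None, outcome)


def _sim_continuous_idx(
    cum: np.ndarray,
    exit_rates: np.ndarray,
    amask: np.ndarray,
    start: int,
    rng: np.random.Generator,
    max_events: int,
) -> tuple[list[int], list[float]]:
    path = [start]
    sojourns: list[float] = []
    i = start
    for _ in range(max_events):
        if amask[i] or exit_rates[i] == 0.0:
            break
        sojourns.append(rng.exponential(1.0 / exit_rates[i]))
        i = int(np.searchsorted(cum[i], rng.random() * exit_rates[i], side="right"))
        path.append(i)
    sojourns.append(0.0)
    return path, sojourns


def simulate_continuous(
    spec: ChainSpec, start: str, seed, max_events: int | None = None
) -> Trajectory:
    """Simulate one continuous-time trajectory from ``start``.

    Each visit to a transient state draws an exponential sojourn with the
    state's total exit rate, then jumps proportionally to the outgoing
    rates.  Starting at an absorbing state returns the trivial one-state
    trajectory.
    """
    if spec.is_discrete:
        raise ValueError("simulate_continuous requires a continuous-time chain")
    if start not in spec.index:
        raise ValueError(f"start state {start!r} is not in the chain")
    if max_events is None:
        max_events = default_max_steps(spec)
    rng = _rng(seed)
    cum = _cum_rows(spec)
    amask = spec.absorbing_mask
    exit_rates = cum[:, -1]
    path, soj = _sim_continuous_idx(
        cum, exit_rates, amask, spec.index[start], rng, max_events
    )
    labels = tuple(spec.state_labels[i] for i in path)
    last = path[-1]
    outcome = labels[-1] if (amask[last] or exit_rates[last] == 0.0) else None
    return Trajectory(labels, tuple(soj), outcome)


def sample_ensemble(
    spec: ChainSpec,
    n_traj: int,
    seed: int,
    start_rule: str = "uniform",
    max_steps: int | None = None,
) -> Ensemble:
    """Draw ``n_traj`` independent trajectories.

    ``start_rule`` is either ``"uniform"`` (uniform over transient states —
    the ensemble convention for the walk demos) or a state label for a
    fixed start.  Censored trajectories are retained and their count
    logged.
    """
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    if max_steps is None:
        max_steps = default_max_steps(spec)
    trans = [l for l in spec.state_labels if l not in spec.absorbing]
    if start_rule == "uniform":
        if not trans:
            raise ValueError("chain has no transient states to start from")
        starts_pool = np.array([spec.index[l] for l in trans])
    else:
        if start_rule not in spec.index:
            raise ValueError(f"start state {start_rule!r} is not in the chain")
        starts_pool = np.array([spec.index[start_rule]])

    root = np.random.SeedSequence(seed)
    children = root.spawn(n_traj + 1)
    start_rng = np.random.default_rng(children[0])
    starts = starts_pool[start_rng.integers(0, starts_pool.size, size=n_traj)]

    cum = _cum_rows(spec)
    amask = spec.absorbing_mask
    labels = spec.state_labels
    trajs: list[Trajectory] = []
    if spec.is_discrete:
        for t in range(n_traj):
            rng = np.random.default_rng(children[t + 1])
            path = _sim_discrete_idx(cum, amask, int(starts[t]), rng, max_steps)
            lab = tuple(labels[i] for i in path)
            outcome = lab[-1] if amask[path[-1]] else None
            trajs.append(Trajectory(lab, None, outcome))
    else:
        exit_rates = cum[:, -1]
        for t in range(n_traj):
            rng = np.random.default_rng(children[t + 1])
            path, soj = _sim_continuous_idx(
                cum, exit_rates, amask, int(starts[t]), rng, max_steps
            )
            lab = tuple(labels[i] for i in path)
            last = path[-1]
            absorbed = amask[last] or exit_rates[last] == 0.0
            trajs.append(Trajectory(lab, tuple(soj), lab[-1] if absorbed else None))

    ens = Ensemble(
        tuple(trajs), spec, spec.fingerprint(), seed, str(start_rule)
    )
    if ens.n_censored:
        logger.info(
            "ensemble: %d of %d trajectories censored at the %d-step cap",
            ens.n_censored,
            n_traj,
            max_steps,
        )
    return ens


def select_by_outcome(ens: Ensemble, target) -> Ensemble:
    """Keep exactly the trajectories whose outcome is in ``target``.

    This is the selection operator whose bias the h-transform describes.
    Censored trajectories are always dropped — itself a selection, so the
    drop count is logged loudly.  An empty result is valid (warned).
    """
    tset = frozenset({target}) if isinstance(target, str) else frozenset(target)
    kept = tuple(
        t for t in ens.trajectories if t.outcome is not None and t.outcome in tset
    )
    n_cens = ens.n_censored
    if n_cens:
        logger.warning(
            "select_by_outcome: dropping %d censored trajectories — this is "
            "itself an outcome selection",
            n_cens,
        )
    if not kept:
        logger.warning("select_by_outcome: empty selection for target %s", sorted(tset))
    return replace(
        ens,
        trajectories=kept,
        start_rule=f"{ens.start_rule}; selected on {sorted(tset)}",
    )


# ---------------------------------------------------------------------------
# TSV interchange: one row per visited state


def write_ensemble_tsv(ens: Ensemble, path) -> None:
    """Write trajectories as TSV with columns traj_id, step, state, sojourn."""
    rows = []
    for tid, traj in enumerate(ens.trajectories):
        soj = traj.sojourns
        for step, state in enumerate(traj.states):
            rows.append(
                (tid, step, state, "" if soj is None else repr(soj[step]))
            )
    df = pd.DataFrame(rows, columns=["traj_id", "step", "state", "sojourn"])
    df.to_csv(path, sep="\t", index=False)


def read_ensemble_tsv(path, spec: ChainSpec) -> Ensemble:
    """Read a trajectory TSV back into an :class:`Ensemble`.

    The chain spec is required to classify outcomes: a trajectory is
    absorbed iff its final state is absorbing in ``spec``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"state": str}, float_precision="round_trip")
    for col in ("traj_id", "step", "state"):
        if col not in df.columns:
            raise ValueError(f"trajectory TSV missing column {col!r}")
    has_sojourn = "sojourn" in df.columns and df["sojourn"].notna().any()
    trajs = []
    for tid, grp in df.groupby("traj_id", sort=True):
        grp = grp.sort_values("step")
        states = tuple(grp["state"].tolist())
        for s in states:
            if s not in spec.index:
                raise ValueError(f"trajectory state {s!r} is not in the chain")
        soj = tuple(float(x) for x in grp["sojourn"]) if has_sojourn else None
        outcome = states[-1] if states[-1] in spec.absorbing else None
        trajs.append(Trajectory(states, soj, outcome))
    return Ensemble(tuple(trajs), spec, spec.fingerprint(), None, "loaded")
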