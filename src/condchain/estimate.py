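"""Empirical transition laws from trajectory ensembles, and bias reports.

The estimators are the count ratios a practitioner would write down from a
time series: in discrete time the jump probability ``N_{i->j} / N_i``
(transitions out of ``i`` observed to land in ``j``, over observed visits
of ``i`` with a successor); in continuous time the occupation-time
maximum-likelihood rate ``N_{i->j} / T_i``.  Applied to an
outcome-selected ensemble these converge not to the physical law but to
its h-transform — which is exactly what :func:`compare` quantifies.

Unvisited states are reported as missing, never as zero: zero would
fabricate certainty about a law that was never observed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chains import ChainSpec
from .doob import ConditionedChain
from .simulate import Ensemble

__all__ = [
    "TransitionCounts",
    "BiasReport",
    "count_transitions",
    "empirical_jump_probabilities",
    "empirical_rates",
    "compare",
]

logger = logging.getLogger("condchain")


@dataclass(frozen=True)
class TransitionCounts:
    """Observed transition tallies from one ensemble.

    ``visit_counts[i]`` is the row sum of ``pair_counts`` — the number of
    visits to ``i`` with an observed successor.  The final visit of every
    trajectory (absorbed or censored) contributes no outgoing count; in
    continuous mode it likewise contributes no occupation time, so rates
    pair completed sojourns with observed exits.
    """

    spec: ChainSpec
    pair_counts: np.ndarray  # (n, n) integer tallies
    visit_counts: np.ndarray  # (n,) = pair_counts.sum(axis=1)
    state_time: np.ndarray | None  # (n,) total occupation time (continuous)
    n_traj: int


def count_transitions(ens: Ensemble) -> TransitionCounts:
    """Tally every observed consecutive transition across an ensemble.

    Raises if a trajectory contains a transition the chain's kernel
    forbids (probability/rate zero) — an ensemble/chain mismatch.
    """
    if len(ens) == 0:
        raise ValueError("ensemble is empty")
    spec = ens.spec
    n = spec.n_states
    idx = {lab: i for i, lab in enumerate(spec.state_labels)}
    pair = np.zeros((n, n), dtype=np.int64)
    state_time = None if spec.is_discrete else np.zeros(n)
    for traj in ens.trajectories:
        if len(traj) < 2:
            continue
        ids = np.fromiter((idx[s] for s in traj.states), dtype=np.int64)
        np.add.at(pair, (ids[:-1], ids[1:]), 1)
        if state_time is not None:
            soj = np.asarray(traj.sojourns)
            np.add.at(state_time, ids[:-1], soj[:-1])
    bad = np.argwhere((pair > 0) & (spec.kernel == 0.0))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"observed transition {spec.state_labels[i]!r} -> "
            f"{spec.state_labels[j]!r} has zero kernel weight: "
            "ensemble does not match this chain"
        )
    return TransitionCounts(spec, pair, pair.sum(axis=1), state_time, len(ens))


def _estimates_frame(
    counts: TransitionCounts, denom: np.ndarray, se_fn
) -> pd.DataFrame:
    spec = counts.spec
    labels = spec.state_labels
    amask = spec.absorbing_mask
    unobserved = [
        labels[i]
        for i in range(spec.n_states)
        if not amask[i] and denom[i] == 0.0
    ]
    if unobserved:
        logger.info(
            "%d transient state(s) unobserved (no estimate, not zero): %s",
            len(unobserved),
            unobserved,
        )
    rows = []
    for i in range(spec.n_states):
        if amask[i] or denom[i] == 0.0:
            continue
        for j in range(spec.n_states):
            if counts.pair_counts[i, j] == 0 and spec.kernel[i, j] == 0.0:
                continue
            est, se = se_fn(counts.pair_counts[i, j], denom[i])
            rows.append(
                {
                    "from_state": labels[i],
                    "to_state": labels[j],
                    "n_num": int(counts.pair_counts[i, j]),
                    "n_den": float(denom[i]),
                    "estimate": est,
                    "se": se,
                }
            )
    df = pd.DataFrame(
        rows, columns=["from_state", "to_state", "n_num", "n_den", "estimate", "se"]
    )
    df.attrs["unobserved_states"] = unobserved
    df.attrs["time_mode"] = spec.time_mode
    return df


def empirical_jump_probabilities(counts: TransitionCounts) -> pd.DataFrame:
    """Per-pair jump-probability estimates ``N_{i->j} / N_i`` with binomial SE.

    One row per (from, to) pair with either observed transitions or
    positive kernel weight, for every state visited at least once.
    """
    if not counts.spec.is_discrete:
        raise ValueError("jump probabilities require discrete-mode counts")

    def binom(k, n):
        p = k / n
        return p, float(np.sqrt(p * (1.0 - p) / n))

    return _estimates_frame(counts, counts.visit_counts.astype(float), binom)


def empirical_rates(counts: TransitionCounts) -> pd.DataFrame:
    """Per-pair rate estimates ``N_{i->j} / T_i`` with Poisson SE."""
    if counts.spec.is_discrete:
        raise ValueError("rate estimation requires continuous-mode counts")

    def poisson(k, t):
        return k / t, float(np.sqrt(k) / t)

    return _estimates_frame(counts, counts.state_time, poisson)


@dataclass(frozen=True)
class BiasReport:
    """Side-by-side empirical vs predicted (vs true) transition laws.

    ``table`` has one row per compared pair with the empirical estimate,
    its standard error, the prediction, the true (unconditioned) value
    where supplied, and the z-score of empirical against prediction.
    """

    table: pd.DataFrame
    max_abs_deviation: float
    max_abs_z: float
    n_skipped: int

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _kernel_lookup(predicted) -> tuple[dict[tuple[str, str], float], set[str]]:
    if isinstance(predicted, ConditionedChain):
        spec = predicted.spec
    elif isinstance(predicted, ChainSpec):
        spec = predicted
    else:
        raise TypeError("predicted must be a ConditionedChain or ChainSpec")
    table = {}
    for i, frm in enumerate(spec.state_labels):
        if frm in spec.absorbing:
            continue
        for j, to in enumerate(spec.state_labels):
            table[(frm, to)] = float(spec.kernel[i, j])
    return table, set(spec.state_labels)


def compare(
    estimates: pd.DataFrame,
    predicted,
    true_spec: ChainSpec | None = None,
) -> BiasReport:
    """Score empirical estimates against a predicted transition law.

    ``predicted`` is a :class:`ConditionedChain` (h-transform theory) or a
    plain :class:`ChainSpec` (e.g. the physical chain, to exhibit the
    bias).  Pairs whose source state lies outside the predicted state
    space are skipped with a logged count; no overlap at all is an error.
    The z-score is ``(estimate - predicted) / se``; with a degenerate
    ``se = 0`` it is 0 on exact agreement and infinite otherwise.
    """
    lookup, states = _kernel_lookup(predicted)
    true_lookup = None
    if true_spec is not None:
        true_lookup, _ = _kernel_lookup(true_spec)
    rows = []
    skipped = 0
    for rec in estimates.to_dict("records"):
        key = (rec["from_state"], rec["to_state"])
        if rec["from_state"] not in states or key not in lookup:
            skipped += 1
            continue
        pred = lookup[key]
        diff = rec["estimate"] - pred
        if rec["se"] > 0:
            z = diff / rec["se"]
        else:
            z = 0.0 if abs(diff) < 1e-12 else float(np.inf)
        rec = dict(rec)
        rec["predicted"] = pred
        rec["true_value"] = (
            true_lookup.get(key, np.nan) if true_lookup is not None else np.nan
        )
        rec["z"] = z
        rows.append(rec)
    if not rows:
        raise ValueError(
            "no overlap between estimated pairs and the predicted state space"
        )
    if skipped:
        logger.info("compare: skipped %d pair(s) outside the predicted support", skipped)
    table = pd.DataFrame(
        rows,
        columns=[
            "from_state",
            "to_state",
            "n_num",
            "n_den",
            "estimate",
            "se",
            "predicted",
            "true_value",
            "z",
        ],
    )
    return BiasReport(
        table=table,
        max_abs_deviation=float((table["estimate"] - table["predicted"]).abs().max()),
        max_abs_z=float(table["z"].abs().max()),
        n_skipped=skipped,
    )
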