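"""Absorption probabilities — the harmonic ``h`` function of the transform.

For a chain with absorbing set ``A`` and a target ``k`` (a state or a set
of states inside ``A``), the profile ``pi_i`` is the probability that the
process started in ``i`` is eventually absorbed in the target.  It is the
unique solution of the harmonic system

    discrete:    pi_i = sum_j q_ij pi_j          (transient i)
    continuous:  sum_{j != i} omega_ij (pi_j - pi_i) = 0

with boundary values 1 on the target and 0 on every other absorbing state.
The solver uses a dense direct linear solve (LAPACK), which is exact to
float precision at the desk scales this package targets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .chains import ChainSpec, _reaches_absorbing

__all__ = [
    "AbsorptionProfile",
    "absorption_probabilities",
    "check_harmonicity",
]

logger = logging.getLogger("condchain")

MAX_DENSE_STATES = 2000
HARMONIC_TOL = 1e-9
CLIP_TOL = 1e-12


@dataclass(frozen=True)
class AbsorptionProfile:
    """Per-state probability of eventual absorption in ``target``."""

    target: frozenset[str]
    values: np.ndarray  # indexed like spec.state_labels
    chain_fingerprint: str

    def __getitem__(self, i: int) -> float:
        return float(self.values[i])


def _as_target_set(target) -> frozenset[str]:
    if isinstance(target, str):
        return frozenset({target})
    return frozenset(target)


def absorption_probabilities(spec: ChainSpec, target) -> AbsorptionProfile:
    """Solve the harmonic linear system for the target absorption profile.

    Parameters
    ----------
    spec
        A validated chain whose absorbing set is non-empty.
    target
        A state label or iterable of labels, all inside ``spec.absorbing``.

    Raises
    ------
    ValueError
        If the target is not a subset of the absorbing set, a transient
        state cannot reach the absorbing set, or the chain exceeds the
        dense-solver size limit.
    """
    tset = _as_target_set(target)
    if not spec.absorbing:
        raise ValueError(
            "chain has no absorbing states; conditioning workflows require "
            "a non-empty absorbing set"
        )
    if not tset:
        raise ValueError("target set is empty")
    if not tset <= spec.absorbing:
        raise ValueError(
            f"target {sorted(tset - spec.absorbing)} is not absorbing"
        )
    n = spec.n_states
    if n > MAX_DENSE_STATES:
        raise ValueError(
            f"chain has {n} states; the dense solver supports at most "
            f"{MAX_DENSE_STATES}"
        )
    reach = _reaches_absorbing(spec)
    amask = spec.absorbing_mask
    stranded = np.flatnonzero(~reach & ~amask)
    if stranded.size:
        raise ValueError(
            f"transient state {spec.state_labels[stranded[0]]!r} has no path "
            "to the absorbing set"
        )

    idx = spec.index
    tmask = np.zeros(n, dtype=bool)
    for lab in tset:
        tmask[idx[lab]] = True
    trans = np.flatnonzero(~amask)

    values = np.zeros(n)
    values[tmask] = 1.0
    if trans.size:
        if spec.is_discrete:
            # (I - Q_TT) x = Q_T,target 1
            Q = spec.kernel
            A = np.eye(trans.size) - Q[np.ix_(trans, trans)]
            b = Q[np.ix_(trans, np.flatnonzero(tmask))].sum(axis=1)
        else:
            # (diag(a) - W_TT) x = W_T,target 1
            W = spec.kernel
            a = spec.exit_rates()
            A = np.diag(a[trans]) - W[np.ix_(trans, trans)]
            b = W[np.ix_(trans, np.flatnonzero(tmask))].sum(axis=1)
        x = np.linalg.solve(A, b)
        # float dust near the bounds is clipped; anything larger is a bug
        if np.any(x < -CLIP_TOL) or np.any(x > 1 + CLIP_TOL):
            worst = x[np.argmax(np.maximum(-x, x - 1))]
            raise RuntimeError(
                f"absorption solver produced probability {worst!r} outside "
                "[0,1] beyond clip tolerance"
            )
        values[trans] = np.clip(x, 0.0, 1.0)

    return AbsorptionProfile(tset, values, spec.fingerprint())


def check_harmonicity(spec: ChainSpec, profile: AbsorptionProfile) -> float:
    """Max absolute harmonicity residual of ``profile`` over transient states.

    Also checks the boundary conditions (1 on target, 0 on other absorbing
    states); boundary violations count toward the residual.  Raises if the
    profile was computed from a different chain.
    """
    if profile.chain_fingerprint != spec.fingerprint():
        raise ValueError("profile fingerprint does not match this chain")
    pi = np.asarray(profile.values, dtype=float)
    amask = spec.absorbing_mask
    idx = spec.index
    resid = 0.0
    for lab in spec.absorbing:
        want = 1.0 if lab in profile.target else 0.0
        resid = max(resid, abs(pi[idx[lab]] - want))
    trans = np.flatnonzero(~amask)
    if trans.size:
        if spec.is_discrete:
            r = spec.kernel[trans] @ pi - pi[trans]
        else:
            a = spec.exit_rates()
            r = spec.kernel[trans] @ pi - a[trans] * pi[trans]
        resid = max(resid, float(np.max(np.abs(r))))
    return resid
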