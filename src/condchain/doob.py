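"""The Doob h-transform: exact laws of outcome-conditioned chains.

Selecting trajectories on their final outcome ("double-dipping") is
equivalent to running a different Markov chain whose transition law is the
h-transform of the original one,

    discrete:    qhat_ij  = q_ij  * pi_j / pi_i
    continuous:  what_ij  = omega_ij * pi_j / pi_i

where ``pi`` is the absorption probability of the selected outcome as a
function of the current state.  Both directions are implemented: applying
the transform (predicting the biased law an outcome-selected ensemble will
exhibit) and inverting it (de-biasing an estimated law back to the
physical chain).  First-passage conditioning — keep only realizations that
reach a goal before returning to their source — is reduced to the same
transform on an auxiliary chain in which the return event is absorbing.

Two structural facts are preserved exactly and checked, never forced:
conditioned discrete rows sum to 1 because ``pi`` is harmonic, and
conditioned exit rates equal the original exit rates (the sojourn-time law
is invariant under conditioning).  A residual beyond tolerance indicates a
defective ``pi`` and raises.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import breadth_first_order

from .absorption import AbsorptionProfile, absorption_probabilities, _as_target_set
from .chains import ChainSpec

__all__ = [
    "ConditionedChain",
    "condition_discrete",
    "condition_continuous",
    "first_passage_aux_chain",
    "first_passage_condition",
    "debias",
]

logger = logging.getLogger("condchain")

CHECK_TOL = 1e-9


@dataclass(frozen=True)
class ConditionedChain:
    """An outcome-conditioned chain together with its provenance.

    ``spec`` is a fully valid :class:`ChainSpec` of the conditioned process
    (same time mode as the base chain) restricted to the support — the
    states from which the selected outcome has positive probability.
    Non-target absorbing states and zero-probability transients are outside
    the support: no selected trajectory ever visits them.

    ``profile`` holds the absorption probabilities of the *base* chain,
    indexed by ``profile_labels`` (the base chain's state order).
    """

    base_fingerprint: str
    target: frozenset[str]
    spec: ChainSpec
    support: tuple[str, ...]
    profile: AbsorptionProfile
    profile_labels: tuple[str, ...]

    @property
    def support_profile(self) -> np.ndarray:
        """Absorption probabilities restricted to (and ordered like) the support."""
        by_label = dict(zip(self.profile_labels, self.profile.values))
        return np.array([by_label[l] for l in self.support])


def _conditioned_kernel(
    spec: ChainSpec, profile: AbsorptionProfile, target: frozenset[str]
) -> tuple[ChainSpec, tuple[str, ...]]:
    """Shared discrete/continuous transform on the positive-pi support."""
    pi = profile.values
    pos = pi > 0.0
    dropped = [
        l
        for l, keep in zip(spec.state_labels, pos)
        if not keep and l not in spec.absorbing
    ]
    if dropped:
        logger.info(
            "dropping %d zero-probability state(s) from the conditioned "
            "support: %s",
            len(dropped),
            dropped,
        )
    support_idx = np.flatnonzero(pos)
    if support_idx.size == 0 or not any(
        spec.state_labels[i] in target for i in support_idx
    ):
        raise ValueError("conditioned support is empty")
    support = tuple(spec.state_labels[i] for i in support_idx)

    sub = spec.kernel[np.ix_(support_idx, support_idx)]
    pi_s = pi[support_idx]
    hat = sub * pi_s[None, :] / pi_s[:, None]

    amask = spec.absorbing_mask[support_idx]
    if spec.is_discrete:
        for k in np.flatnonzero(amask):
            hat[k, :] = 0.0
            hat[k, k] = 1.0
        rows = hat[~amask].sum(axis=1)
        worst = float(np.max(np.abs(rows - 1.0))) if rows.size else 0.0
        if worst > CHECK_TOL:
            raise RuntimeError(
                f"conditioned rows fail to normalize (residual {worst:.3g}); "
                "the absorption profile violates harmonicity"
            )
    else:
        for k in np.flatnonzero(amask):
            hat[k, :] = 0.0
        exit_orig = spec.kernel[support_idx].sum(axis=1)
        exit_hat = hat.sum(axis=1)
        scale = np.maximum(1.0, exit_orig[~amask])
        worst = (
            float(
                np.max(np.abs(exit_hat[~amask] - exit_orig[~amask]) / scale)
            )
            if (~amask).any()
            else 0.0
        )
        if worst > CHECK_TOL:
            raise RuntimeError(
                f"conditioned exit rates drift from the originals "
                f"(relative residual {worst:.3g}); the absorption profile "
                "violates harmonicity"
            )
    cond_spec = ChainSpec(
        support, spec.time_mode, hat, frozenset(l for l in support if l in target)
    )
    return cond_spec, support


def _condition(spec: ChainSpec, target) -> ConditionedChain:
    tset = _as_target_set(target)
    profile = absorption_probabilities(spec, tset)
    cond_spec, support = _conditioned_kernel(spec, profile, tset)
    return ConditionedChain(
        base_fingerprint=spec.fingerprint(),
        target=tset,
        spec=cond_spec,
        support=support,
        profile=profile,
        profile_labels=spec.state_labels,
    )


def condition_discrete(spec: ChainSpec, target) -> ConditionedChain:
    """Condition a discrete-time chain on absorption in ``target``.

    Conditioning on the entire absorbing set is the identity transform
    (``pi`` is 1 everywhere); conditioning on a strict subset produces the
    biased law that an outcome-selected trajectory ensemble exhibits.
    """
    if not spec.is_discrete:
        raise ValueError("condition_discrete requires a discrete-time chain")
    return _condition(spec, target)


def condition_continuous(spec: ChainSpec, target) -> ConditionedChain:
    """Condition a continuous-time chain on absorption in ``target``.

    The transformed rates reshape where the process jumps but conserve
    every state's total exit rate, so sojourn-time statistics carry no
    signature of the conditioning.
    """
    if spec.is_discrete:
        raise ValueError("condition_continuous requires a continuous-time chain")
    return _condition(spec, target)


def first_passage_aux_chain(spec: ChainSpec, source: str, goal: str) -> ChainSpec:
    """Auxiliary chain in which a return to ``source`` and an arrival at
    ``goal`` are both absorbing events.

    ``source`` keeps its outgoing rates (the process must leave it once);
    every transition *into* ``source`` is redirected to an absorbing
    return sink labelled ``"<source>*return"``; ``goal`` loses its
    outgoing rates.  Simulating this chain from ``source`` and selecting
    on outcome ``goal`` is exactly rejection sampling of first-passage
    realizations.
    """
    if spec.is_discrete:
        raise ValueError("first-passage conditioning requires a continuous-time chain")
    if source == goal:
        raise ValueError("source and goal must differ")
    idx = spec.index
    if source not in idx or goal not in idx:
        raise ValueError("source and goal must be states of the chain")
    if source in spec.absorbing:
        raise ValueError(f"source {source!r} is absorbing; it cannot be left")

    sink = f"{source}*return"
    while sink in idx:
        sink += "'"
    n = spec.n_states
    labels = spec.state_labels + (sink,)
    kern = np.zeros((n + 1, n + 1))
    kern[:n, :n] = spec.kernel
    s, g = idx[source], idx[goal]
    # redirect every arrival at the source to the absorbing return sink
    kern[:n, n] = kern[:n, s]
    kern[:n, s] = 0.0
    kern[g, :] = 0.0  # goal absorbs
    absorbing = set(spec.absorbing) | {goal, sink}
    aux = ChainSpec(labels, "continuous", kern, frozenset(absorbing))

    # goal must be reachable from source in the auxiliary chain
    adj = csr_matrix((aux.kernel > 0).astype(np.int8))
    order = breadth_first_order(adj, s, return_predecessors=False)
    if g not in set(np.atleast_1d(order).tolist()):
        raise ValueError(
            f"goal {goal!r} is unreachable from {source!r} without returning"
        )
    return aux


def first_passage_condition(
    spec: ChainSpec, source: str, goal: str
) -> ConditionedChain:
    """Condition on reaching ``goal`` before returning to ``source``.

    Reduces first-passage selection to the plain h-transform on the
    auxiliary chain of :func:`first_passage_aux_chain`; the reported
    rates are those of the conditioned auxiliary chain.
    """
    aux = first_passage_aux_chain(spec, source, goal)
    return condition_continuous(aux, goal)


def debias(conditioned: ConditionedChain, profile: AbsorptionProfile) -> ChainSpec:
    """Invert the h-transform: recover the physical kernel on the support.

    ``profile`` must be the absorption profile used to build
    ``conditioned`` (fingerprints are checked).  The inverse is exact:
    ``q_ij = qhat_ij * pi_i / pi_j`` entrywise (rates likewise).  The
    result is restricted to the support, so transient rows may sum to less
    than 1 — mass into states outside the support (other outcomes) is not
    recoverable from outcome-selected data alone.
    """
    if profile.chain_fingerprint != conditioned.base_fingerprint:
        raise ValueError(
            "profile fingerprint does not match the conditioned chain's base"
        )
    pi_by_label = dict(zip(conditioned.profile_labels, profile.values))
    support = conditioned.support
    pi_s = np.array([pi_by_label[l] for l in support])
    if np.any(pi_s <= 0):
        raise ValueError("support contains a zero-probability state")
    hat = conditioned.spec.kernel
    kern = hat * pi_s[:, None] / pi_s[None, :]
    amask = conditioned.spec.absorbing_mask
    if conditioned.spec.is_discrete:
        for k in np.flatnonzero(amask):
            kern[k, :] = 0.0
            kern[k, k] = 1.0
    else:
        for k in np.flatnonzero(amask):
            kern[k, :] = 0.0
    return ChainSpec(
        support,
        conditioned.spec.time_mode,
        kern,
        conditioned.spec.absorbing,
    )
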