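"""Seeded random-chain generators for property suites.

These generate "generic" valid chains — no structure beyond the invariants
— so that identities which hold by algebra (row normalization of the
conditioned chain, exit-rate conservation, mixture recomposition) can be
asserted far from the hand-built examples.  Every generator is a pure
function of its seed.
"""

from __future__ import annotations

import numpy as np

from .chains import ChainSpec

__all__ = ["random_discrete_chain", "random_ctmc"]


def random_discrete_chain(
    seed: int,
    n_transient: int = 4,
    n_absorbing: int = 2,
    density: float = 0.8,
) -> ChainSpec:
    """A random discrete chain with every transient state able to absorb.

    Transient rows are Dirichlet-ish draws over a random sparsity pattern;
    each transient state gets at least one positive entry toward some
    other state, and one transient state is guaranteed a direct edge into
    the absorbing set so absorption is reachable.
    """
    rng = np.random.default_rng(seed)
    n = n_transient + n_absorbing
    labels = tuple(f"s{i}" for i in range(n_transient)) + tuple(
        f"a{k}" for k in range(n_absorbing)
    )
    kern = np.zeros((n, n))
    for i in range(n_transient):
        mask = rng.random(n) < density
        mask[i] = False
        if not mask.any():
            mask[(i + 1) % n] = True
        w = rng.random(n) * mask
        # guarantee a path to absorption: every transient state points at
        # either a later transient state or an absorber
        w[n_transient + rng.integers(n_absorbing)] += 0.2
        kern[i] = w / w.sum()
    for k in range(n_absorbing):
        kern[n_transient + k, n_transient + k] = 1.0
    return ChainSpec(labels, "discrete", kern, frozenset(labels[n_transient:]))


def random_ctmc(
    seed: int,
    n_transient: int | None = None,
    n_absorbing: int = 2,
    rate_scale: float = 2.0,
) -> ChainSpec:
    """A random CTMC with 5-20 states by default and reachable absorption."""
    rng = np.random.default_rng(seed)
    if n_transient is None:
        n_transient = int(rng.integers(3, 19))
    n = n_transient + n_absorbing
    labels = tuple(f"s{i}" for i in range(n_transient)) + tuple(
        f"a{k}" for k in range(n_absorbing)
    )
    kern = np.zeros((n, n))
    for i in range(n_transient):
        mask = rng.random(n) < 0.6
        mask[i] = False
        w = rng.exponential(rate_scale, size=n) * mask
        w[n_transient + rng.integers(n_absorbing)] += rate_scale * rng.random() + 0.05
        kern[i] = w
    kern[n_transient:, :] = 0.0
    np.fill_diagonal(kern, 0.0)
    return ChainSpec(labels, "continuous", kern, frozenset(labels[n_transient:]))
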