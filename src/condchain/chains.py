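"""Chain specifications: labeled state spaces with absorbing boundaries.

A :class:`ChainSpec` holds either a one-step row-stochastic matrix
(``time_mode="discrete"``) or a matrix of nonnegative off-diagonal
transition rates with zero diagonal (``time_mode="continuous"``), together
with the declared absorbing set.  All downstream machinery — absorption
probabilities, the h-transform of outcome conditioning, trajectory
simulation and estimation — consumes this one type.

States are identified by label externally and by 0-based ordinal
internally; every matrix is indexed in the order of ``state_labels``.
Continuous kernels never store the diagonal: the exit rate
``a_i = sum_j omega_ij`` is always derived.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import breadth_first_order

__all__ = [
    "ChainSpec",
    "StateIndexMap",
    "ChainSpecError",
    "validate_chain",
    "make_drunkard_walk",
    "make_atb_chain",
    "read_chain_spec",
    "write_chain_spec",
]

logger = logging.getLogger("condchain")

ROW_SUM_TOL = 1e-9


class ChainSpecError(ValueError):
    """Raised for malformed chain-spec files or invalid chain parameters."""


@dataclass(frozen=True)
class StateIndexMap:
    """Bijective label -> 0-based ordinal mapping in ``state_labels`` order."""

    labels: tuple[str, ...]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "_index", {lab: i for i, lab in enumerate(self.labels)}
        )
        if len(self._index) != len(self.labels):
            raise ChainSpecError("state labels must be unique")

    def __getitem__(self, label: str) -> int:
        return self._index[label]

    def __contains__(self, label: str) -> bool:
        return label in self._index

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True, eq=False)
class ChainSpec:
    """A finite Markov chain in discrete or continuous time.

    Parameters
    ----------
    state_labels
        Ordered unique text labels; fixes the matrix indexing.
    time_mode
        ``"discrete"`` (``kernel`` is row-stochastic, absorbing rows are
        identity) or ``"continuous"`` (``kernel`` holds off-diagonal rates,
        zero diagonal, absorbing rows all zero).
    kernel
        Square ``(n, n)`` array in ``state_labels`` order.
    absorbing
        Subset of labels declared absorbing.  May be empty (e.g. a
        reversible chain used only as input to first-passage conditioning).
    """

    state_labels: tuple[str, ...]
    time_mode: str
    kernel: np.ndarray
    absorbing: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "state_labels", tuple(self.state_labels))
        object.__setattr__(self, "absorbing", frozenset(self.absorbing))
        kern = np.asarray(self.kernel, dtype=float)
        kern = kern.copy()
        kern.setflags(write=False)
        object.__setattr__(self, "kernel", kern)

    # -- derived views -------------------------------------------------

    @property
    def n_states(self) -> int:
        return len(self.state_labels)

    @property
    def index(self) -> StateIndexMap:
        return StateIndexMap(self.state_labels)

    @property
    def is_discrete(self) -> bool:
        return self.time_mode == "discrete"

    @property
    def absorbing_mask(self) -> np.ndarray:
        idx = self.index
        mask = np.zeros(self.n_states, dtype=bool)
        for lab in self.absorbing:
            mask[idx[lab]] = True
        return mask

    @property
    def transient_labels(self) -> tuple[str, ...]:
        return tuple(l for l in self.state_labels if l not in self.absorbing)

    def exit_rates(self) -> np.ndarray:
        """Total exit rate ``a_i = sum_j omega_ij`` (continuous chains)."""
        if self.is_discrete:
            raise ValueError("exit rates are defined for continuous chains only")
        return self.kernel.sum(axis=1)

    def generator(self) -> np.ndarray:
        """Infinitesimal generator with the derived negative diagonal."""
        if self.is_discrete:
            raise ValueError("generator is defined for continuous chains only")
        gen = self.kernel.copy()
        np.fill_diagonal(gen, -self.exit_rates())
        return gen

    def fingerprint(self) -> str:
        """Stable content hash used to tie derived objects to their chain."""
        payload = {
            "states": list(self.state_labels),
            "time_mode": self.time_mode,
            "absorbing": sorted(self.absorbing),
            "kernel": [repr(float(v)) for v in np.ravel(self.kernel)],
        }
        blob = json.dumps(payload, separators=(",", ":")).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# validation


def _reaches_absorbing(spec: ChainSpec) -> np.ndarray:
    """Boolean per-state flag: can this state reach the absorbing set?"""
    mask = spec.absorbing_mask
    if not mask.any():
        return np.zeros(spec.n_states, dtype=bool)
    # BFS on the reversed adjacency graph from the absorbing states.
    adj = csr_matrix((spec.kernel > 0).T.astype(np.int8))
    reach = mask.copy()
    for a in np.flatnonzero(mask):
        order = breadth_first_order(adj, a, return_predecessors=False)
        reach[order] = True
    return reach


def validate_chain(spec: ChainSpec) -> list[str]:
    """Check every structural invariant; return human-readable violations.

    Validation never raises: an empty list means the spec is valid.
    """
    issues: list[str] = []
    n = spec.n_states
    if len(set(spec.state_labels)) != n:
        issues.append("state labels are not unique")
        return issues
    if spec.time_mode not in ("discrete", "continuous"):
        issues.append(f"unknown time_mode {spec.time_mode!r}")
        return issues
    if spec.kernel.shape != (n, n):
        issues.append(
            f"kernel shape {spec.kernel.shape} does not match {n} states"
        )
        return issues
    unknown = sorted(set(spec.absorbing) - set(spec.state_labels))
    if unknown:
        issues.append(f"absorbing labels not in state space: {unknown}")
        return issues

    idx = spec.index
    if spec.is_discrete:
        if np.any(spec.kernel < 0) or np.any(spec.kernel > 1):
            bad = np.argwhere((spec.kernel < 0) | (spec.kernel > 1))[0]
            issues.append(
                "probability out of [0,1] at "
                f"({spec.state_labels[bad[0]]} -> {spec.state_labels[bad[1]]})"
            )
        sums = spec.kernel.sum(axis=1)
        for i, s in enumerate(sums):
            if abs(s - 1.0) > ROW_SUM_TOL:
                issues.append(
                    f"row {spec.state_labels[i]!r} sums to {s!r}, not 1"
                )
        for lab in sorted(spec.absorbing):
            i = idx[lab]
            if abs(spec.kernel[i, i] - 1.0) > ROW_SUM_TOL:
                issues.append(
                    f"absorbing state {lab!r} must have self-probability 1"
                )
    else:
        off = spec.kernel.copy()
        np.fill_diagonal(off, 0.0)
        if np.any(off < 0):
            bad = np.argwhere(off < 0)[0]
            issues.append(
                "negative rate at "
                f"({spec.state_labels[bad[0]]} -> {spec.state_labels[bad[1]]})"
            )
        diag = np.diagonal(spec.kernel)
        if np.any(diag != 0):
            i = int(np.flatnonzero(diag)[0])
            issues.append(
                f"continuous kernel diagonal must be zero "
                f"(state {spec.state_labels[i]!r}); the exit rate is derived"
            )
        for lab in sorted(spec.absorbing):
            i = idx[lab]
            if np.any(spec.kernel[i] != 0):
                issues.append(
                    f"absorbing state {lab!r} must have zero outgoing rates"
                )

    # Reachability matters only once an absorbing set is declared: chains
    # without one (e.g. reversible inputs to first-passage conditioning)
    # are valid but unusable for conditioning workflows.
    if spec.absorbing and not issues:
        reach = _reaches_absorbing(spec)
        for i in np.flatnonzero(~reach):
            issues.append(
                f"transient state {spec.state_labels[i]!r} cannot reach the "
                "absorbing set"
            )
    return issues


def _require_valid(spec: ChainSpec, context: str) -> ChainSpec:
    issues = validate_chain(spec)
    if issues:
        raise ChainSpecError(f"{context}: " + "; ".join(issues))
    return spec


# ---------------------------------------------------------------------------
# constructors


def make_drunkard_walk(n_intermediate: int, p_right: float) -> ChainSpec:
    """Symmetric-boundary random walk: home at 0, bar at ``n_intermediate+1``.

    Transient positions ``1..n`` step right with probability ``p_right``
    and left with ``1 - p_right``; both boundary states absorb.
    """
    if n_intermediate < 1:
        raise ChainSpecError("n_intermediate must be >= 1")
    if not (0.0 < p_right < 1.0):
        raise ChainSpecError("p_right must lie strictly in (0, 1)")
    n = n_intermediate + 2
    labels = tuple(str(i) for i in range(n))
    kern = np.zeros((n, n))
    kern[0, 0] = 1.0
    kern[n - 1, n - 1] = 1.0
    for i in range(1, n - 1):
        kern[i, i + 1] = p_right
        kern[i, i - 1] = 1.0 - p_right
    spec = ChainSpec(labels, "discrete", kern, frozenset({labels[0], labels[-1]}))
    return _require_valid(spec, "make_drunkard_walk")


def make_atb_chain(rates: Mapping[str, float]) -> ChainSpec:
    """Three-state reversible chain A <-> T <-> B in continuous time.

    ``rates`` must supply the four positive rates ``w_at``, ``w_ta``,
    ``w_tb``, ``w_bt``.  The chain has no absorbing states; it is the
    canonical input to first-passage conditioning.
    """
    required = ("w_at", "w_ta", "w_tb", "w_bt")
    missing = [k for k in required if k not in rates]
    if missing:
        raise ChainSpecError(f"missing rates: {missing}")
    for k in required:
        if not rates[k] > 0:
            raise ChainSpecError(
                f"rate {k} must be positive (all four rates nonzero), got {rates[k]}"
            )
    labels = ("A", "T", "B")
    kern = np.zeros((3, 3))
    kern[0, 1] = rates["w_at"]
    kern[1, 0] = rates["w_ta"]
    kern[1, 2] = rates["w_tb"]
    kern[2, 1] = rates["w_bt"]
    spec = ChainSpec(labels, "continuous", kern, frozenset())
    return _require_valid(spec, "make_atb_chain")


# ---------------------------------------------------------------------------
# serialization (JSON dialect: states / time_mode / absorbing / transitions)


def write_chain_spec(spec: ChainSpec, path) -> None:
    """Serialize to the JSON chain-spec dialect (sparse transition list)."""
    transitions = []
    for i, frm in enumerate(spec.state_labels):
        for j, to in enumerate(spec.state_labels):
            v = spec.kernel[i, j]
            if v != 0.0:
                transitions.append({"from": frm, "to": to, "value": float(v)})
    doc = {
        "states": list(spec.state_labels),
        "time_mode": spec.time_mode,
        "absorbing": sorted(spec.absorbing),
        "transitions": transitions,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def read_chain_spec(path) -> ChainSpec:
    """Parse a chain-spec JSON file; validate; renormalize float dust.

    Discrete rows whose sum deviates from 1 by no more than ``1e-9`` are
    renormalized exactly (and the renormalization is logged); larger
    deviations are validation errors.
    """
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ChainSpecError(f"not valid JSON: {exc}") from exc
    for key in ("states", "time_mode", "absorbing", "transitions"):
        if key not in doc:
            raise ChainSpecError(f"missing field {key!r}")
    labels = doc["states"]
    if not isinstance(labels, list) or not all(isinstance(s, str) for s in labels):
        raise ChainSpecError("field 'states' must be an array of strings")
    if len(set(labels)) != len(labels):
        raise ChainSpecError("field 'states' contains duplicate labels")
    if doc["time_mode"] not in ("discrete", "continuous"):
        raise ChainSpecError(
            f"field 'time_mode' must be 'discrete' or 'continuous', "
            f"got {doc['time_mode']!r}"
        )
    label_set = set(labels)
    for lab in doc["absorbing"]:
        if lab not in label_set:
            raise ChainSpecError(f"field 'absorbing' names unknown state {lab!r}")
    n = len(labels)
    idx = {lab: i for i, lab in enumerate(labels)}
    kern = np.zeros((n, n))
    for t in doc["transitions"]:
        for key in ("from", "to", "value"):
            if key not in t:
                raise ChainSpecError(f"transition entry missing field {key!r}")
        if t["from"] not in label_set:
            raise ChainSpecError(
                f"field 'transitions' names unknown state {t['from']!r}"
            )
        if t["to"] not in label_set:
            raise ChainSpecError(
                f"field 'transitions' names unknown state {t['to']!r}"
            )
        kern[idx[t["from"]], idx[t["to"]]] = float(t["value"])

    if doc["time_mode"] == "discrete":
        sums = kern.sum(axis=1)
        for i in range(n):
            if sums[i] != 1.0 and abs(sums[i] - 1.0) <= ROW_SUM_TOL and sums[i] > 0:
                kern[i] /= sums[i]
                logger.info(
                    "renormalized row %r (sum deviated by %.3g)",
                    labels[i],
                    sums[i] - 1.0,
                )
    spec = ChainSpec(tuple(labels), doc["time_mode"], kern, frozenset(doc["absorbing"]))
    return _require_valid(spec, f"chain spec {path}")
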