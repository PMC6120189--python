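"""Six-state gating scheme for the homomeric rho1 GABA-A receptor.

The kinetic model is a linear activation chain with two desensitized
branches::

            k1[A]      f1        beta
        R  <----->  AR <----> AF <----> AO
            k_-1      f_-1      alpha
                               |          |
                       dAF_on  |  dAF_off |  dAO_on / dAO_off
                               v          v
                              AFD        AOD

``R`` is the resting, agonist-free receptor; ``AR`` is agonist-bound shut;
``AF`` is agonist-bound and preactivated (flipped) but still shut; ``AO`` is
the open, conducting state.  ``AFD`` and ``AOD`` are non-conducting
desensitized states entered from the preactivated and open states
respectively.  Agonist binding is a single bimolecular step, so the only
concentration-dependent rate is ``k1 * [A]``.

Macroscopic current is represented by the open-state occupancy ``p_open``;
no conductance, driving force or channel count is modelled, because every
downstream summary statistic is normalized.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.linalg import null_space

STATE_LABELS: tuple[str, ...] = ("R", "AR", "AF", "AO", "AFD", "AOD")
CONDUCTING_STATE = "AO"
OPEN_INDEX = STATE_LABELS.index(CONDUCTING_STATE)

#: Names of the ten rate constants, in canonical order.  ``k1`` is second
#: order (per molar per second); all others are first order (per second).
RATE_NAMES: tuple[str, ...] = (
    "k1",
    "k_minus1",
    "f1",
    "f_minus1",
    "beta",
    "alpha",
    "dAF_on",
    "dAF_off",
    "dAO_on",
    "dAO_off",
)

# Directed transitions (from-state, to-state, rate-name).  The R -> AR rate
# is multiplied by the agonist concentration when building the generator.
_TRANSITIONS: tuple[tuple[str, str, str], ...] = (
    ("R", "AR", "k1"),
    ("AR", "R", "k_minus1"),
    ("AR", "AF", "f1"),
    ("AF", "AR", "f_minus1"),
    ("AF", "AO", "beta"),
    ("AO", "AF", "alpha"),
    ("AF", "AFD", "dAF_on"),
    ("AFD", "AF", "dAF_off"),
    ("AO", "AOD", "dAO_on"),
    ("AOD", "AO", "dAO_off"),
)


class SchemeError(ValueError):
    """Invalid gating-scheme parameters or usage."""


@dataclass(frozen=True)
class GatingScheme:
    """Rate constants of the six-state scheme.

    Parameters
    ----------
    k1 : float
        Agonist association rate, M^-1 s^-1 (R -> AR occurs at ``k1*[A]``).
    k_minus1 : float
        Agonist dissociation (deactivation) rate, s^-1 (AR -> R).
    f1, f_minus1 : float
        Forward/backward preactivation ("flip") rates, s^-1 (AR <-> AF).
    beta, alpha : float
        Channel opening/closing rates, s^-1 (AF <-> AO).
    dAF_on, dAF_off : float
        Desensitization entry/exit rates from the preactivated state, s^-1.
    dAO_on, dAO_off : float
        Desensitization entry/exit rates from the open state, s^-1.
    """

    k1: float
    k_minus1: float
    f1: float
    f_minus1: float
    beta: float
    alpha: float
    dAF_on: float
    dAF_off: float
    dAO_on: float
    dAO_off: float

    state_labels: tuple[str, ...] = field(default=STATE_LABELS, init=False, repr=False)
    conducting_state: str = field(default=CONDUCTING_STATE, init=False, repr=False)

    def __post_init__(self) -> None:
        for name in RATE_NAMES:
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise SchemeError(f"rate {name!r} must be finite and >= 0, got {value!r}")
        if self.k1 <= 0:
            raise SchemeError(f"k1 must be > 0, got {self.k1!r}")

    def rates(self) -> dict[str, float]:
        """Rate constants as an ordered name -> value mapping."""
        return {name: float(getattr(self, name)) for name in RATE_NAMES}

    def with_rates(self, **updates: float) -> "GatingScheme":
        unknown = set(updates) - set(RATE_NAMES)
        if unknown:
            raise SchemeError(f"unknown rate name(s): {sorted(unknown)}")
        return replace(self, **updates)

    def digest(self) -> str:
        """Short stable hash of the parameter vector, used in trace metadata."""
        payload = json.dumps(self.rates(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass(frozen=True)
class MutantRule:
    """Multiplicative perturbation of named rate constants.

    Rates absent from ``factors`` are unchanged.  Used to derive mutant
    receptor schemes from a single wild-type rate set.
    """

    name: str
    factors: Mapping[str, float]

    def __post_init__(self) -> None:
        for rate, factor in self.factors.items():
            if rate not in RATE_NAMES:
                raise SchemeError(f"rule {self.name!r}: unknown rate name {rate!r}")
            if not np.isfinite(factor) or factor < 0:
                raise SchemeError(
                    f"rule {self.name!r}: multiplier for {rate!r} must be >= 0"
                )
        object.__setattr__(self, "factors", dict(self.factors))


def apply_mutation(scheme: GatingScheme, rule: MutantRule) -> GatingScheme:
    """Return a new scheme with each rate named in ``rule`` multiplied by its factor."""
    updates = {rate: getattr(scheme, rate) * factor for rate, factor in rule.factors.items()}
    return scheme.with_rates(**updates) if updates else scheme


def predefined_mutant_rules() -> dict[str, MutantRule]:
    """The fixed wild-type -> mutant rules for the rho1 TMD tryptophan mutants.

    * ``WT`` — identity.
    * ``W329A`` — entry into both desensitized states eliminated
      (``dAF_on = dAO_on = 0``) and unbinding ``k_minus1`` increased 10-fold.
    * ``W280Q`` — unbinding ``k_minus1`` decreased 10-fold and entry into the
      open-state desensitized state ``dAO_on`` reduced by 30%.
    """
    return {
        "WT": MutantRule("WT", {}),
        "W329A": MutantRule("W329A", {"dAF_on": 0.0, "dAO_on": 0.0, "k_minus1": 10.0}),
        "W280Q": MutantRule("W280Q", {"k_minus1": 0.1, "dAO_on": 0.7}),
    }


def build_generator(scheme: GatingScheme, conc: float) -> np.ndarray:
    """Q-matrix of the scheme at agonist concentration ``conc`` (molar).

    Entry ``Q[i, j]`` (i != j) is the transition rate from state i to state j
    in s^-1; diagonal entries make every row sum to zero.  Only the ten
    directed transitions of the scheme are nonzero.
    """
    if not np.isfinite(conc) or conc < 0:
        raise SchemeError(f"agonist concentration must be >= 0, got {conc!r}")
    idx = {label: i for i, label in enumerate(STATE_LABELS)}
    q = np.zeros((6, 6))
    for src, dst, rate_name in _TRANSITIONS:
        rate = getattr(scheme, rate_name)
        if rate_name == "k1":
            rate = rate * conc
        q[idx[src], idx[dst]] = rate
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def _reachable_states(q: np.ndarray, start: int = 0) -> np.ndarray:
    """Indices reachable from ``start`` following strictly positive rates."""
    n = q.shape[0]
    seen = np.zeros(n, dtype=bool)
    stack = [start]
    seen[start] = True
    while stack:
        i = stack.pop()
        for j in range(n):
            if i != j and q[i, j] > 0 and not seen[j]:
                seen[j] = True
                stack.append(j)
    return np.flatnonzero(seen)


def steady_state(scheme: GatingScheme, conc: float) -> np.ndarray:
    """Stationary occupancy vector at fixed agonist concentration.

    The stationary distribution is computed on the set of states reachable
    from the resting state R; unreachable states (e.g. all bound states at
    zero agonist) receive occupancy 0.  Raises if the stationary distribution
    on the reachable set is not unique.
    """
    q = build_generator(scheme, conc)
    reach = _reachable_states(q)
    sub = q[np.ix_(reach, reach)]
    # rows of a generator sum to 0 only on the closed reachable set
    np.fill_diagonal(sub, 0.0)
    np.fill_diagonal(sub, -sub.sum(axis=1))
    ns = null_space(sub.T, rcond=1e-10)
    if ns.shape[1] != 1:
        raise SchemeError(
            "stationary distribution on the reachable state set is not unique "
            f"(null space dimension {ns.shape[1]})"
        )
    pi_sub = ns[:, 0].real
    pi_sub = pi_sub / pi_sub.sum()
    if np.any(pi_sub < -1e-9):
        raise SchemeError("null-space vector is not a probability distribution")
    pi = np.zeros(6)
    pi[reach] = np.clip(pi_sub, 0.0, None)
    return pi / pi.sum()
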