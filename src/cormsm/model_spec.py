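"""Model specification: state spaces, transition structure and random-effect links.

A correlated multistate model couples two (or more) reversible continuous-time
Markov processes observed as panel data through a shared subject-level frailty
``U`` with a gamma distribution of mean 1 and variance ``theta``.  The frailty
enters each transition intensity multiplicatively through a link function
``g_rs(u)`` whose form is one of a small set of named variants:

``none``
    no random effect, ``g = 1`` everywhere;
``simple``
    ``g = u`` on every transition of both processes (fast movers move fast in
    both directions);
``inverse``
    ``g = u`` on deterioration transitions and ``g = 1/u`` on improvement
    transitions (fast-worsening subjects improve slowly);
``power_inverse``
    as ``inverse`` for process 1, and ``u**alpha`` / ``u**-alpha`` for
    process 2, with a free exponent ``alpha``;
``separate``
    as ``inverse`` but each process carries its own independent frailty.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "VARIANTS",
    "StateSpace",
    "ProcessParams",
    "RELink",
    "REDistribution",
    "ModelSpec",
    "re_multiplier",
    "count_free_parameters",
]

VARIANTS = ("none", "simple", "inverse", "power_inverse", "separate")

Transition = tuple[int, int]


def _as_pairs(pairs: Iterable[Sequence[int]]) -> tuple[Transition, ...]:
    return tuple(sorted((int(r), int(s)) for r, s in pairs))


@dataclass(frozen=True)
class StateSpace:
    """A finite state space with an explicit set of permitted transitions.

    States are 1-based integers (matching the clinical severity labels used
    in reporting).  Each allowed transition is classified as *deterioration*
    (worsening) or *improvement*; the classification is part of the model
    specification, not inferred from the labels, so non-birth-death
    structures remain expressible.
    """

    n_states: int
    allowed: tuple[Transition, ...]
    deterioration: tuple[Transition, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "allowed", _as_pairs(self.allowed))
        object.__setattr__(self, "deterioration", _as_pairs(self.deterioration))
        if self.n_states < 2:
            raise ValueError("a state space needs at least two states")
        for r, s in self.allowed:
            if r == s or not (1 <= r <= self.n_states and 1 <= s <= self.n_states):
                raise ValueError(f"invalid transition ({r}, {s}) for K={self.n_states}")
        if len(set(self.allowed)) != len(self.allowed):
            raise ValueError("duplicate transitions in allowed set")
        extra = set(self.deterioration) - set(self.allowed)
        if extra:
            raise ValueError(f"deterioration transitions not in allowed set: {sorted(extra)}")

    @property
    def improvement(self) -> tuple[Transition, ...]:
        det = set(self.deterioration)
        return tuple(t for t in self.allowed if t not in det)

    def is_deterioration(self, transition: Transition) -> bool:
        t = (int(transition[0]), int(transition[1]))
        if t not in self.allowed:
            raise ValueError(f"transition {t} is not permitted")
        return t in set(self.deterioration)

    @classmethod
    def birth_death(cls, n_states: int = 3) -> "StateSpace":
        """Adjacent-move (birth-death) structure: r <-> r+1 only.

        Moves to a higher-numbered (more severe) state are deterioration.
        """
        allowed = [(r, r + 1) for r in range(1, n_states)] + [
            (r + 1, r) for r in range(1, n_states)
        ]
        det = [(r, r + 1) for r in range(1, n_states)]
        return cls(n_states=n_states, allowed=tuple(allowed), deterioration=tuple(det))

    def to_dict(self) -> dict:
        return {
            "n_states": self.n_states,
            "allowed": [list(t) for t in self.allowed],
            "deterioration": [list(t) for t in self.deterioration],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "StateSpace":
        return cls(
            n_states=int(d["n_states"]),
            allowed=_as_pairs(d["allowed"]),
            deterioration=_as_pairs(d["deterioration"]),
        )


@dataclass
class ProcessParams:
    """Baseline transition intensities and covariate effects for one process.

    ``baseline[(r, s)]`` is the intensity (per year) of the r -> s transition
    for a reference subject; ``coveffects[(r, s)]`` is the vector of
    log-intensity ratios for the covariates acting on that transition.
    """

    baseline: dict[Transition, float]
    coveffects: dict[Transition, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.baseline = {(int(r), int(s)): float(v) for (r, s), v in self.baseline.items()}
        for t, v in self.baseline.items():
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"baseline intensity for {t} must be finite and >= 0, got {v}")
        self.coveffects = {
            (int(r), int(s)): np.asarray(v, dtype=float)
            for (r, s), v in self.coveffects.items()
        }
        lens = {v.size for v in self.coveffects.values()}
        if len(lens) > 1:
            raise ValueError("covariate-effect vectors must all have the same length")

    @property
    def n_covariates(self) -> int:
        for v in self.coveffects.values():
            return int(v.size)
        return 0

    def vector(self, order: Sequence[Transition]) -> np.ndarray:
        return np.array([self.baseline[t] for t in order], dtype=float)


@dataclass
class RELink:
    """Random-effect link: the named variant plus the power exponent alpha."""

    variant: str = "inverse"
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown RE link variant {self.variant!r}; choose from {VARIANTS}")
        self.alpha = float(self.alpha)


@dataclass
class REDistribution:
    """Gamma frailty distribution with mean 1 and variance ``theta``.

    The shape and rate are both ``1/theta``.  For the ``separate`` variant,
    ``theta`` is the variance of the process-1 frailty and ``theta2`` that of
    the independent process-2 frailty.
    """

    theta: float = 0.5
    theta2: float | None = None

    def __post_init__(self) -> None:
        self.theta = float(self.theta)
        if self.theta <= 0:
            raise ValueError("theta must be > 0")
        if self.theta2 is not None:
            self.theta2 = float(self.theta2)
            if self.theta2 <= 0:
                raise ValueError("theta2 must be > 0")

    def theta_for(self, process_index: int) -> float:
        if process_index == 2 and self.theta2 is not None:
            return self.theta2
        return self.theta

    def density(self, u, process_index: int = 1):
        """Gamma(1/theta, 1/theta) pdf, mean exactly 1 and variance theta."""
        from scipy import stats

        a = 1.0 / self.theta_for(process_index)
        return stats.gamma.pdf(u, a, scale=1.0 / a)

    def quantile(self, q, process_index: int = 1):
        from scipy import stats

        a = 1.0 / self.theta_for(process_index)
        return stats.gamma.ppf(q, a, scale=1.0 / a)

    def sample(self, n: int, rng: np.random.Generator, process_index: int = 1) -> np.ndarray:
        a = 1.0 / self.theta_for(process_index)
        return rng.gamma(shape=a, scale=1.0 / a, size=n)


def re_multiplier(
    link: RELink,
    process_index: int,
    transition: Transition,
    u: float,
    statespace: StateSpace | None = None,
):
    """Multiplier g_rs(u) applied to the baseline intensity of ``transition``.

    ``process_index`` is 1-based.  If ``statespace`` is omitted, a birth-death
    classification is assumed (r < s means deterioration).  Works elementwise
    on array-valued ``u``.
    """
    u = np.asarray(u, dtype=float)
    if np.any(u <= 0):
        raise ValueError("frailty u must be > 0")
    if process_index not in (1, 2):
        raise ValueError("process_index must be 1 or 2")
    if statespace is not None:
        det = statespace.is_deterioration(transition)
    else:
        det = transition[0] < transition[1]

    v = link.variant
    if v == "none":
        out = np.ones_like(u)
    elif v == "simple":
        out = u.copy()
    elif v in ("inverse", "separate"):
        out = u if det else 1.0 / u
    elif v == "power_inverse":
        expo = 1.0 if process_index == 1 else link.alpha
        out = u**expo if det else u**-expo
    else:  # pragma: no cover - guarded in RELink
        raise ValueError(f"unknown variant {v!r}")
    return out if out.ndim else float(out)


@dataclass
class ModelSpec:
    """Full definition of one correlated multistate model.

    One :class:`StateSpace` per process, the random-effect link and frailty
    distribution, and the covariate design: covariate names plus, per
    process, the set of transitions the covariates act on (empty by
    default).
    """

    statespaces: tuple[StateSpace, ...]
    link: RELink = field(default_factory=RELink)
    covariates: tuple[str, ...] = ()
    cov_transitions: tuple[tuple[Transition, ...], ...] | None = None
    process_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.statespaces = tuple(self.statespaces)
        if not self.statespaces:
            raise ValueError("at least one process is required")
        if self.cov_transitions is None:
            self.cov_transitions = tuple(() for _ in self.statespaces)
        self.cov_transitions = tuple(_as_pairs(ts) for ts in self.cov_transitions)
        if len(self.cov_transitions) != len(self.statespaces):
            raise ValueError("cov_transitions must have one entry per process")
        if self.process_names is None:
            self.process_names = tuple(f"p{j + 1}" for j in range(len(self.statespaces)))
        self.process_names = tuple(self.process_names)
        if len(self.process_names) != len(self.statespaces):
            raise ValueError("process_names must have one entry per process")

    @property
    def n_processes(self) -> int:
        return len(self.statespaces)

    @property
    def n_variance_params(self) -> int:
        if self.link.variant == "none":
            return 0
        if self.link.variant == "separate":
            return 2
        return 1

    @classmethod
    def birth_death(
        cls,
        variant: str = "inverse",
        n_states: int = 3,
        n_processes: int = 2,
        process_names: Sequence[str] | None = None,
    ) -> "ModelSpec":
        ss = StateSpace.birth_death(n_states)
        return cls(
            statespaces=tuple(ss for _ in range(n_processes)),
            link=RELink(variant=variant),
            process_names=tuple(process_names) if process_names else None,
        )

    def to_dict(self) -> dict:
        return {
            "statespaces": [s.to_dict() for s in self.statespaces],
            "link": {"variant": self.link.variant, "alpha": self.link.alpha},
            "covariates": list(self.covariates),
            "cov_transitions": [[list(t) for t in ts] for ts in self.cov_transitions],
            "process_names": list(self.process_names),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelSpec":
        return cls(
            statespaces=tuple(StateSpace.from_dict(s) for s in d["statespaces"]),
            link=RELink(**d.get("link", {})),
            covariates=tuple(d.get("covariates", ())),
            cov_transitions=tuple(
                _as_pairs(ts) for ts in d.get("cov_transitions", [])
            )
            or None,
            process_names=tuple(d["process_names"]) if d.get("process_names") else None,
        )


def count_free_parameters(spec: ModelSpec) -> int:
    """Number of free parameters: intensities + covariate effects + variance
    parameters + the power exponent if the link is ``power_inverse``."""
    k = sum(len(ss.allowed) for ss in spec.statespaces)
    k += sum(len(ts) for ts in spec.cov_transitions) * len(spec.covariates)
    k += spec.n_variance_params
    if spec.link.variant == "power_inverse":
        k += 1
    return k
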