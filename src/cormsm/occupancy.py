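"""Expected state-occupancy times over a fixed horizon.

The expected time in state r over [0, h], starting from state r1, is the
time integral of the transition probability,

    E[time in r] = int_0^h P[r1 -> r](t) dt,

computed exactly from the matrix exponential of the augmented block matrix
[[Q, I], [0, 0]] (whose top-right block is int_0^h expm(Q t) dt).  Frailty
averaging wraps a one-dimensional adaptive quadrature over u around the
exact time integral.  Joint states of two conditionally independent
processes are handled on the Kronecker-sum generator Q1 (+) Q2, for which
expm((Q1 (+) Q2) t) = expm(Q1 t) (x) expm(Q2 t); its occupancy vector is the
joint-state table, so no two-dimensional time-by-frailty product rule is
needed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import quad_vec

from .intensity import (
    build_generator,
    integrated_transition_probabilities,
    kronecker_sum,
)
from .model_spec import ProcessParams, RELink, REDistribution, StateSpace
from .likelihood import QuadratureOptions

__all__ = [
    "OccupancyTable",
    "occupancy_conditional",
    "occupancy_marginal",
    "occupancy_joint",
    "occupancy_mc",
    "occupancy_table",
    "joint_occupancy_table",
]

_U_TOL = 1e-8  # absolute tolerance of the frailty quadrature


def _check_no_covariates(params: ProcessParams) -> None:
    if params.coveffects and any(v.size for v in params.coveffects.values()):
        raise ValueError(
            "occupancy with dynamic covariates is not defined; supply a model "
            "without covariate effects (or fold a fixed covariate value into "
            "the baseline intensities first)"
        )


def occupancy_conditional(
    params: ProcessParams,
    link: RELink,
    u: float,
    start: int,
    horizon: float,
    process_index: int = 1,
    statespace: StateSpace | None = None,
) -> np.ndarray:
    """Expected years in each state over [0, horizon] at a fixed frailty."""
    _check_no_covariates(params)
    if statespace is None:
        statespace = StateSpace.birth_death(max(max(t) for t in params.baseline))
    if not 1 <= start <= statespace.n_states:
        raise ValueError(f"start state {start} outside 1..{statespace.n_states}")
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    Q = build_generator(params, link, process_index, u, None, statespace)
    return integrated_transition_probabilities(Q, horizon)[start - 1]


def _frailty_average(fn, redist: REDistribution, process_index: int = 1):
    """int fn(u) f(u; theta) du by adaptive quadrature on v = exp(-u)."""
    u_lo, u_hi = redist.quantile([1e-12, 1 - 1e-12], process_index)
    v_lo, v_hi = float(np.exp(-u_hi)), float(min(np.exp(-u_lo), 1.0))

    def integrand(v):
        u = -np.log(v)
        return fn(u) * redist.density(u, process_index) / v

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        val, _ = quad_vec(integrand, v_lo, v_hi, epsabs=_U_TOL, epsrel=1e-7)
    return val


def occupancy_marginal(
    params: ProcessParams,
    redist: REDistribution,
    link: RELink,
    start: int,
    horizon: float,
    process_index: int = 1,
    statespace: StateSpace | None = None,
) -> np.ndarray:
    """Population-averaged occupancy: the conditional vector integrated over
    the gamma frailty distribution."""
    if link.variant == "none":
        return occupancy_conditional(params, link, 1.0, start, horizon,
                                     process_index, statespace)
    return _frailty_average(
        lambda u: occupancy_conditional(params, link, u, start, horizon,
                                        process_index, statespace),
        redist, process_index,
    )


def occupancy_joint(
    params_p1: ProcessParams,
    params_p2: ProcessParams,
    redist: REDistribution | None,
    link: RELink,
    joint_start: tuple[int, int],
    horizon: float,
    mode: str = "re_averaged",
    statespaces: tuple[StateSpace, StateSpace] | None = None,
) -> np.ndarray:
    """Expected years in each joint state (r, s), row-major over K1 x K2.

    ``marginal_model`` integrates the product of the two unconditional
    transition probabilities (no frailty); ``re_averaged`` shares one frailty
    between the processes inside the integral; ``conditional_u`` accepts the
    frailty through ``mode=('conditional_u', u)``.
    """
    for p in (params_p1, params_p2):
        _check_no_covariates(p)
    if statespaces is None:
        statespaces = (
            StateSpace.birth_death(max(max(t) for t in params_p1.baseline)),
            StateSpace.birth_death(max(max(t) for t in params_p2.baseline)),
        )
    K1, K2 = statespaces[0].n_states, statespaces[1].n_states
    r1, s1 = joint_start
    if not (1 <= r1 <= K1 and 1 <= s1 <= K2):
        raise ValueError(f"joint start {joint_start} outside the state spaces")
    row = (r1 - 1) * K2 + (s1 - 1)

    def joint_row(u: float) -> np.ndarray:
        Q1 = build_generator(params_p1, link, 1, u, None, statespaces[0])
        Q2 = build_generator(params_p2, link, 2, u, None, statespaces[1])
        QJ = kronecker_sum(Q1, Q2)
        return integrated_transition_probabilities(QJ, horizon)[row]

    if isinstance(mode, tuple) and mode[0] == "conditional_u":
        return joint_row(float(mode[1]))
    if mode == "conditional_u":
        return joint_row(1.0)
    if mode == "marginal_model" or link.variant == "none":
        return joint_row(1.0)  # g(1) = 1 for every link variant
    if mode != "re_averaged":
        raise ValueError(f"unknown joint occupancy mode {mode!r}")
    if redist is None:
        raise ValueError("re_averaged mode needs a frailty distribution")
    return _frailty_average(joint_row, redist)


def occupancy_mc(
    params: ProcessParams,
    redist: REDistribution,
    link: RELink,
    start: int,
    horizon: float,
    n_draws: int,
    seed: int,
    process_index: int = 1,
    statespace: StateSpace | None = None,
) -> np.ndarray:
    """Monte Carlo frailty average: sample u from the gamma distribution,
    evaluate the conditional occupancy at each draw, average."""
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    us = redist.sample(n_draws, rng, process_index)
    acc = np.zeros_like(
        occupancy_conditional(params, link, 1.0, start, horizon, process_index, statespace)
    )
    for u in us:
        acc += occupancy_conditional(params, link, float(u), start, horizon,
                                     process_index, statespace)
    return acc / n_draws


@dataclass
class OccupancyTable:
    """Occupancy vectors for every starting state, as a labelled table."""

    horizon: float
    mode: str
    values: pd.DataFrame

    def to_csv(self, path) -> None:
        self.values.to_csv(path)


def occupancy_table(
    params: ProcessParams,
    link: RELink,
    horizon: float,
    mode: str = "conditional_u",
    u: float = 1.0,
    redist: REDistribution | None = None,
    process_index: int = 1,
    statespace: StateSpace | None = None,
    label: str = "state",
) -> OccupancyTable:
    """Single-process occupancy for all starting states (one row each)."""
    if statespace is None:
        statespace = StateSpace.birth_death(max(max(t) for t in params.baseline))
    K = statespace.n_states
    rows = []
    for start in range(1, K + 1):
        if mode == "conditional_u":
            v = occupancy_conditional(params, link, u, start, horizon,
                                      process_index, statespace)
        elif mode in ("re_averaged", "marginal_model"):
            if mode == "marginal_model":
                v = occupancy_conditional(params, RELink("none"), 1.0, start, horizon,
                                          process_index, statespace)
            else:
                v = occupancy_marginal(params, redist, link, start, horizon,
                                       process_index, statespace)
        else:
            raise ValueError(f"unknown occupancy mode {mode!r}")
        rows.append(v)
    idx = [f"{label} {r}" for r in range(1, K + 1)]
    cols = [f"{label} {r}" for r in range(1, K + 1)]
    return OccupancyTable(
        horizon=horizon, mode=mode,
        values=pd.DataFrame(np.vstack(rows), index=idx, columns=cols),
    )


def joint_occupancy_table(
    params_p1: ProcessParams,
    params_p2: ProcessParams,
    link: RELink,
    horizon: float,
    mode: str = "re_averaged",
    redist: REDistribution | None = None,
    statespaces: tuple[StateSpace, StateSpace] | None = None,
) -> OccupancyTable:
    """Joint-state occupancy for all K1*K2 starting pairs."""
    if statespaces is None:
        statespaces = (
            StateSpace.birth_death(max(max(t) for t in params_p1.baseline)),
            StateSpace.birth_death(max(max(t) for t in params_p2.baseline)),
        )
    K1, K2 = statespaces[0].n_states, statespaces[1].n_states
    labels = [f"({r}, {s})" for r in range(1, K1 + 1) for s in range(1, K2 + 1)]
    rows = []
    for r in range(1, K1 + 1):
        for s in range(1, K2 + 1):
            rows.append(
                occupancy_joint(params_p1, params_p2, redist, link, (r, s),
                                horizon, mode, statespaces)
            )
    return OccupancyTable(
        horizon=horizon, mode=mode,
        values=pd.DataFrame(np.vstack(rows), index=labels, columns=labels),
    )
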