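"""Generator matrices and interval transition probabilities.

The generator (intensity) matrix Q of a continuous-time Markov chain has
nonnegative off-diagonal entries for permitted transitions and zero row sums;
over an interval of length ``dt`` the transition-probability matrix is the
matrix exponential ``P(dt) = expm(Q * dt)``.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm

from .model_spec import ProcessParams, RELink, StateSpace, re_multiplier

__all__ = [
    "build_generator",
    "transition_matrix",
    "transition_matrices",
    "integrated_transition_probabilities",
    "kronecker_sum",
]


def build_generator(
    params: ProcessParams,
    link: RELink,
    process_index: int,
    u: float = 1.0,
    covariates: np.ndarray | None = None,
    statespace: StateSpace | None = None,
) -> np.ndarray:
    """Subject-specific generator Q with entries g_rs(u) * q_rs * exp(beta_rs'z).

    Covariates act log-linearly on the intensities of the transitions they
    are declared for; transitions without declared effects are unaffected.
    """
    if statespace is None:
        k = max(max(t) for t in params.baseline)
        statespace = StateSpace.birth_death(k)
    if u <= 0:
        raise ValueError("frailty u must be > 0")
    K = statespace.n_states
    Q = np.zeros((K, K))
    for (r, s) in statespace.allowed:
        rate = params.baseline.get((r, s), 0.0)
        rate *= re_multiplier(link, process_index, (r, s), u, statespace)
        beta = params.coveffects.get((r, s))
        if beta is not None and beta.size:
            if covariates is None:
                raise ValueError(
                    f"transition ({r},{s}) has covariate effects but no covariate "
                    "vector was supplied"
                )
            z = np.asarray(covariates, dtype=float)
            if z.size != beta.size:
                raise ValueError("covariate vector length does not match the design")
            rate *= float(np.exp(beta @ z))
        Q[r - 1, s - 1] = rate
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def transition_matrix(Q: np.ndarray, dt: float) -> np.ndarray:
    """P(dt) = expm(Q * dt), clipped into [0, 1] against roundoff."""
    if dt < 0:
        raise ValueError("dt must be >= 0")
    Q = np.asarray(Q, dtype=float)
    if not np.all(np.isfinite(Q)):
        raise ValueError("generator contains non-finite entries")
    if dt == 0:
        return np.eye(Q.shape[0])
    P = expm(Q * dt)
    return np.clip(P, 0.0, 1.0)


def transition_matrices(Q: np.ndarray, dts: np.ndarray) -> np.ndarray:
    """P(dt) for many interval lengths at once.

    Uses a single eigendecomposition of Q and vectorised scaling when Q is
    diagonalisable with a well-conditioned eigenvector matrix (the generic
    case for small reversible generators, whose spectrum is real), and falls
    back to per-interval scaling-and-squaring otherwise.  Returns an array of
    shape ``(len(dts), K, K)``.
    """
    Q = np.asarray(Q, dtype=float)
    dts = np.asarray(dts, dtype=float)
    if np.any(dts < 0):
        raise ValueError("dt must be >= 0")
    K = Q.shape[0]
    out = None
    try:
        w, V = np.linalg.eig(Q)
        cond = np.linalg.cond(V)
        if np.isfinite(cond) and cond < 1e8:
            Vinv = np.linalg.inv(V)
            # P(dt) = V diag(exp(w dt)) Vinv
            E = np.exp(np.multiply.outer(dts, w))  # (n, K)
            out = np.einsum("ij,nj,jk->nik", V, E, Vinv).real
    except np.linalg.LinAlgError:
        out = None
    if out is None:
        out = np.stack([expm(Q * dt) for dt in dts])
    else:
        # validate the eigen path; fall back if it lost accuracy
        err = np.abs(out.sum(axis=2) - 1.0).max() if len(dts) else 0.0
        if not np.isfinite(err) or err > 1e-8:
            out = np.stack([expm(Q * dt) for dt in dts])
    return np.clip(out, 0.0, 1.0)


def integrated_transition_probabilities(Q: np.ndarray, horizon: float) -> np.ndarray:
    """Exact time integral of the transition matrix: int_0^h expm(Q t) dt.

    Computed from the matrix exponential of the augmented block matrix
    [[Q, I], [0, 0]]; its top-right K-by-K block is the integral.  Entry
    (r, s) is the expected time spent in state s over [0, h] starting from
    state r.
    """
    Q = np.asarray(Q, dtype=float)
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    K = Q.shape[0]
    A = np.zeros((2 * K, 2 * K))
    A[:K, :K] = Q
    A[:K, K:] = np.eye(K)
    E = expm(A * horizon)
    return np.clip(E[:K, K:], 0.0, horizon)


def kronecker_sum(Q1: np.ndarray, Q2: np.ndarray) -> np.ndarray:
    """Generator of two independent chains run jointly: Q1 (+) Q2.

    Satisfies expm((Q1 (+) Q2) t) = expm(Q1 t) (x) expm(Q2 t), so joint-state
    probabilities of conditionally independent processes are matrix
    exponentials of the Kronecker sum.  Joint state (r, s) maps to row-major
    index (r-1) * K2 + (s-1).
    """
    K1 = Q1.shape[0]
    K2 = Q2.shape[0]
    return np.kron(Q1, np.eye(K2)) + np.kron(np.eye(K1), Q2)
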