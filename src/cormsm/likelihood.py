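"""Panel-data likelihood with a shared gamma frailty.

For subject *i* observed at visit times ``t_1 < ... < t_n`` the conditional
likelihood given the frailty ``u`` is the product over processes and visit
intervals of interval transition probabilities

    L_i(u) = prod_j prod_k P_j[ x_j(t_k) -> x_j(t_{k+1}) ; t_{k+1} - t_k | u ],

and the marginal contribution integrates the frailty out against the
gamma(1/theta, 1/theta) density.  The integral has no closed form for
reversible panel models, so it is evaluated numerically after the
substitution ``v = exp(-u)`` which maps (0, inf) onto (0, 1].  Underflow over
long series is controlled by scaling the integrand with the maximum
conditional log-likelihood over a coarse frailty grid before exponentiating.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import sparse
from scipy.integrate import quad
from scipy.special import roots_legendre

from .intensity import build_generator, transition_matrices
from .model_spec import ModelSpec, ProcessParams, REDistribution

__all__ = [
    "Subject",
    "PanelData",
    "QuadratureOptions",
    "QuadratureError",
    "subject_conditional_loglik",
    "subject_integrated_loglik",
    "total_loglik",
    "PanelLikelihood",
]

logger = logging.getLogger(__name__)

_PROB_FLOOR = 1e-300


class QuadratureError(RuntimeError):
    """Raised when the frailty integral cannot be evaluated reliably."""


@dataclass
class Subject:
    """One subject's visit times, observed states per process, covariates.

    ``states`` holds one integer array per process; 0 marks a missing state
    at that visit.  ``covariates`` is an optional (n_visits, n_covariates)
    array, constant over each observation interval at its left-endpoint
    value.
    """

    id: str
    times: np.ndarray
    states: tuple[np.ndarray, ...]
    covariates: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or self.times.size < 1:
            raise ValueError(f"subject {self.id}: at least one visit required")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"subject {self.id}: visit times must be strictly increasing")
        self.states = tuple(np.asarray(s, dtype=int) for s in self.states)
        for s in self.states:
            if s.shape != self.times.shape:
                raise ValueError(f"subject {self.id}: state/time length mismatch")
            if np.any(s < 0):
                raise ValueError(f"subject {self.id}: states must be >= 0 (0 = missing)")
        if self.covariates is not None:
            self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
            if self.covariates.shape[0] != self.times.size:
                raise ValueError(f"subject {self.id}: covariate rows must match visits")

    @property
    def n_visits(self) -> int:
        return self.times.size

    def intervals(self, process_index: int) -> list[tuple[float, int, int, int]]:
        """Observation intervals (dt, from_state, to_state, left_visit_index)
        for one 1-based process, bridging over visits with a missing state."""
        s = self.states[process_index - 1]
        obs = np.flatnonzero(s > 0)
        out = []
        for a, b in zip(obs[:-1], obs[1:]):
            out.append((float(self.times[b] - self.times[a]), int(s[a]), int(s[b]), int(a)))
        return out


@dataclass
class PanelData:
    """A cohort of subjects plus column metadata."""

    subjects: list[Subject]
    covariate_names: tuple[str, ...] = ()
    state_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.subjects:
            raise ValueError("panel must contain at least one subject")
        ids = [s.id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate subject ids in panel")
        n_proc = len(self.subjects[0].states)
        if any(len(s.states) != n_proc for s in self.subjects):
            raise ValueError("all subjects must have the same number of processes")
        if not self.state_names:
            self.state_names = tuple(f"state{j + 1}" for j in range(n_proc))

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_processes(self) -> int:
        return len(self.subjects[0].states)


@dataclass
class QuadratureOptions:
    """How the frailty integral is evaluated.

    ``adaptive`` uses an adaptive rule on v in (0, 1] (restricted to the
    gamma distribution's [tail_prob, 1 - tail_prob] quantile range, whose
    excluded mass is negligible); ``fixed`` uses Gauss-Legendre with
    ``n_nodes`` points on (0, 1].
    """

    method: str = "adaptive"
    n_nodes: int = 96
    atol: float = 1e-9
    rtol: float = 1e-7
    tail_prob: float = 1e-12

    def __post_init__(self) -> None:
        if self.method not in ("adaptive", "fixed"):
            raise ValueError("quadrature method must be 'adaptive' or 'fixed'")


def _gl_nodes_01(n: int) -> tuple[np.ndarray, np.ndarray]:
    x, w = roots_legendre(n)
    return 0.5 * (x + 1.0), 0.5 * w


def subject_conditional_loglik(
    subject: Subject,
    spec: ModelSpec,
    params: Sequence[ProcessParams],
    u: float,
    u2: float | None = None,
) -> float:
    """log L_i(u): sum over processes and intervals of log transition
    probabilities given the frailty.  ``u2`` supplies the second process's
    frailty for the ``separate`` variant (defaults to ``u``)."""
    total = 0.0
    for j in range(spec.n_processes):
        uj = u2 if (j == 1 and u2 is not None) else u
        total += _process_conditional_loglik(subject, spec, params[j], j + 1, uj)
    if not np.isfinite(total):
        raise ValueError(f"subject {subject.id}: non-finite conditional log-likelihood")
    return total


def _process_conditional_loglik(
    subject: Subject, spec: ModelSpec, params: ProcessParams, process_index: int, u: float
) -> float:
    ss = spec.statespaces[process_index - 1]
    cache: dict[tuple, np.ndarray] = {}
    total = 0.0
    for dt, r, s, left in subject.intervals(process_index):
        if params.coveffects and subject.covariates is not None:
            cov = subject.covariates[left]
            key = (dt, tuple(cov))
        else:
            cov = subject.covariates[left] if subject.covariates is not None else None
            key = (dt, None)
        P = cache.get(key)
        if P is None:
            Q = build_generator(params, spec.link, process_index, u, cov, ss)
            P = transition_matrices(Q, np.array([dt]))[0]
            cache[key] = P
        total += np.log(max(P[r - 1, s - 1], _PROB_FLOOR))
    return total


def _log_frailty_integral(
    loglik_at_u: Callable[[float], float],
    redist: REDistribution,
    quad_opts: QuadratureOptions,
    process_index: int = 1,
    moment: int = 0,
    scale: float | None = None,
) -> float:
    """log of int_0^inf u^moment exp(loglik_at_u(u)) f(u; theta) du.

    ``scale`` is the log scaling constant; if omitted it is taken as the
    maximum of ``loglik_at_u`` over a coarse grid of gamma quantiles.
    """
    if scale is None:
        grid = redist.quantile(np.linspace(0.001, 0.999, 25), process_index)
        grid = np.append(grid, 1.0)
        scale = max(loglik_at_u(float(g)) for g in grid)

    def integrand(v: float) -> float:
        u = -np.log(v)
        val = np.exp(loglik_at_u(u) - scale) * redist.density(u, process_index) / v
        if moment:
            val *= u**moment
        return val

    if quad_opts.method == "fixed":
        v, w = _gl_nodes_01(quad_opts.n_nodes)
        total = float(np.sum(w * np.array([integrand(vk) for vk in v])))
        err = np.nan
    else:
        u_lo, u_hi = redist.quantile([quad_opts.tail_prob, 1 - quad_opts.tail_prob],
                                     process_index)
        v_lo = float(np.exp(-u_hi))
        v_hi = float(min(np.exp(-u_lo), 1.0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            total, err = quad(
                integrand, v_lo, v_hi,
                epsabs=quad_opts.atol, epsrel=quad_opts.rtol, limit=200,
            )
        if total > 0 and err > max(quad_opts.atol, 100 * quad_opts.rtol * total):
            raise QuadratureError(
                f"frailty integral did not converge: value {total:.3e}, "
                f"error estimate {err:.3e}"
            )
    if not np.isfinite(total) or total <= 0:
        raise QuadratureError(
            f"frailty integral evaluated to {total!r} (scaled by exp({scale:.3f}))"
        )
    return scale + float(np.log(total))


def subject_integrated_loglik(
    subject: Subject,
    spec: ModelSpec,
    params: Sequence[ProcessParams],
    redist: REDistribution | None,
    quad_opts: QuadratureOptions | None = None,
) -> float:
    """Marginal log-likelihood contribution of one subject.

    Integrates the shared frailty out by quadrature; for ``separate`` the two
    processes integrate independently and the terms add; for ``none`` this is
    the conditional log-likelihood at u = 1.
    """
    quad_opts = quad_opts or QuadratureOptions()
    variant = spec.link.variant
    if variant == "none":
        return subject_conditional_loglik(subject, spec, params, 1.0)
    if redist is None:
        raise ValueError("a frailty distribution is required unless the link is 'none'")
    observed = [bool(subject.intervals(j + 1)) for j in range(spec.n_processes)]
    if not any(observed):
        return 0.0  # empty product; the frailty density integrates to 1
    if variant == "separate":
        total = 0.0
        for j in range(spec.n_processes):
            if not observed[j]:
                continue
            pidx = j + 1
            total += _log_frailty_integral(
                lambda u, _j=j: _process_conditional_loglik(subject, spec, params[_j], _j + 1, u),
                redist, quad_opts, process_index=pidx,
            )
        return total
    return _log_frailty_integral(
        lambda u: subject_conditional_loglik(subject, spec, params, u),
        redist, quad_opts,
    )


def total_loglik(
    panel: PanelData,
    spec: ModelSpec,
    params: Sequence[ProcessParams],
    redist: REDistribution | None,
    quad_opts: QuadratureOptions | None = None,
) -> float:
    """Cohort log-likelihood: ordered sum of per-subject marginal terms."""
    total = 0.0
    for subj in panel.subjects:
        try:
            total += subject_integrated_loglik(subj, spec, params, redist, quad_opts)
        except Exception as exc:
            raise type(exc)(f"subject {subj.id}: {exc}") from exc
    return total


class PanelLikelihood:
    """Vectorised cohort likelihood sharing frailty nodes across subjects.

    Precomputes, per process, the unique (interval length, covariate value)
    pairs and each subject's transition counts over them; a likelihood
    evaluation then needs one transition-matrix batch per frailty node per
    process, regardless of cohort size.  Used by the fitting routines, where
    the deterministic fixed-node rule makes the objective smooth in the
    parameters; agrees with the per-subject adaptive path to quadrature
    accuracy.
    """

    def __init__(self, panel: PanelData, spec: ModelSpec, n_nodes: int = 96):
        self.panel = panel
        self.spec = spec
        self.n_nodes = int(n_nodes)
        self._v, self._w = _gl_nodes_01(self.n_nodes)
        self._u = -np.log(self._v)
        self._build_index()
        n_single = sum(1 for s in panel.subjects if s.n_visits < 2)
        if n_single:
            logger.warning(
                "%d subject(s) have a single visit and contribute 0 to the likelihood",
                n_single,
            )

    def _build_index(self) -> None:
        N = self.panel.n_subjects
        self._proc: list[dict] = []
        for j in range(self.spec.n_processes):
            keys: dict[tuple, int] = {}
            sub_idx: list[int] = []
            key_idx: list[int] = []
            fr: list[int] = []
            to: list[int] = []
            for i, subj in enumerate(self.panel.subjects):
                for dt, r, s, left in subj.intervals(j + 1):
                    cov = (
                        tuple(subj.covariates[left])
                        if subj.covariates is not None
                        else None
                    )
                    k = keys.setdefault((dt, cov), len(keys))
                    sub_idx.append(i)
                    key_idx.append(k)
                    fr.append(r - 1)
                    to.append(s - 1)
            n_rec = len(sub_idx)
            S = sparse.csr_matrix(
                (np.ones(n_rec), (np.asarray(sub_idx, int), np.arange(n_rec))),
                shape=(N, n_rec),
            )
            self._proc.append(
                {
                    "keys": list(keys),
                    "key_idx": np.asarray(key_idx, int),
                    "fr": np.asarray(fr, int),
                    "to": np.asarray(to, int),
                    "S": S,
                }
            )

    def conditional_matrix(
        self, params: Sequence[ProcessParams], process_index: int, us: np.ndarray
    ) -> np.ndarray:
        """log-likelihood of every subject at every frailty value, one process.

        Returns an (n_subjects, len(us)) array.
        """
        info = self._proc[process_index - 1]
        ss = self.spec.statespaces[process_index - 1]
        pj = params[process_index - 1]
        keys = info["keys"]
        dts = np.array([k[0] for k in keys])
        covs = [k[1] for k in keys]
        n_us = len(us)
        # group keys by covariate value: one generator per (u, cov)
        by_cov: dict = {}
        for idx, c in enumerate(covs):
            by_cov.setdefault(c, []).append(idx)
        logP_entries = np.empty((info["key_idx"].size, n_us))
        for m, u in enumerate(us):
            Pk = np.empty((len(keys), ss.n_states, ss.n_states))
            for c, idxs in by_cov.items():
                Q = build_generator(
                    pj, self.spec.link, process_index, float(u),
                    np.array(c) if c is not None else None, ss,
                )
                Pk[idxs] = transition_matrices(Q, dts[idxs])
            vals = np.log(np.maximum(Pk[info["key_idx"], info["fr"], info["to"]], _PROB_FLOOR))
            logP_entries[:, m] = vals
        return np.asarray(info["S"] @ logP_entries)

    def total_loglik(
        self,
        params: Sequence[ProcessParams],
        redist: REDistribution | None,
    ) -> float:
        """Cohort marginal log-likelihood at the panel's fixed frailty nodes."""
        variant = self.spec.link.variant
        if variant == "none":
            ll = sum(
                self.conditional_matrix(params, j + 1, np.array([1.0]))[:, 0]
                for j in range(self.spec.n_processes)
            )
            return float(np.sum(ll))
        if redist is None:
            raise ValueError("a frailty distribution is required unless the link is 'none'")
        if variant == "separate":
            total = 0.0
            for j in range(self.spec.n_processes):
                llmat = self.conditional_matrix(params, j + 1, self._u)
                total += self._integrate(llmat, redist, j + 1)
            return total
        llmat = sum(
            self.conditional_matrix(params, j + 1, self._u)
            for j in range(self.spec.n_processes)
        )
        return self._integrate(llmat, redist, 1)

    def _integrate(self, llmat: np.ndarray, redist: REDistribution, pidx: int) -> float:
        wts = self._w * redist.density(self._u, pidx) / self._v
        c = llmat.max(axis=1, keepdims=True)
        with np.errstate(over="ignore"):
            vals = np.exp(llmat - c) @ wts
        vals = np.maximum(vals, _PROB_FLOOR)
        return float(np.sum(c[:, 0] + np.log(vals)))
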