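"""Maximum-likelihood fitting, Wald intervals, AIC and likelihood-ratio tests.

Parameters are optimised on a working scale — log for transition intensities
and the frailty variance (which must stay positive), identity for the power
exponent alpha and covariate effects — by BFGS, with a central-difference
numeric Hessian at the optimum supplying the asymptotic covariance.
Confidence intervals for log-scale parameters are exponentiated, so they are
asymmetric about the estimate on the natural scale.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .likelihood import PanelData, PanelLikelihood, QuadratureOptions
from .model_spec import (
    ModelSpec,
    ProcessParams,
    REDistribution,
    count_free_parameters,
)

__all__ = [
    "ParamLayout",
    "FittedModel",
    "fit_mle",
    "wald_confint",
    "aic",
    "lr_test",
    "crude_init",
]

logger = logging.getLogger(__name__)


@dataclass
class ParamLayout:
    """Mapping between the flat working-scale vector and model objects.

    ``kinds`` labels each entry: ``rate`` and ``variance`` live on the log
    scale; ``linear`` entries (alpha, covariate effects) are untransformed.
    """

    spec: ModelSpec
    names: list[str] = field(init=False)
    kinds: list[str] = field(init=False)

    def __post_init__(self) -> None:
        names: list[str] = []
        kinds: list[str] = []
        for j, ss in enumerate(self.spec.statespaces):
            pname = self.spec.process_names[j]
            for (r, s) in ss.allowed:
                names.append(f"{pname}.q{r}{s}")
                kinds.append("rate")
        for j, trans in enumerate(self.spec.cov_transitions):
            pname = self.spec.process_names[j]
            for (r, s) in trans:
                for cov in self.spec.covariates:
                    names.append(f"{pname}.q{r}{s}.{cov}")
                    kinds.append("linear")
        variant = self.spec.link.variant
        if variant == "separate":
            names += ["theta1", "theta2"]
            kinds += ["variance", "variance"]
        elif variant != "none":
            names.append("theta")
            kinds.append("variance")
        if variant == "power_inverse":
            names.append("alpha")
            kinds.append("linear")
        self.names = names
        self.kinds = kinds

    @property
    def n_params(self) -> int:
        return len(self.names)

    def pack(
        self,
        params: Sequence[ProcessParams],
        redist: REDistribution | None,
        alpha: float | None = None,
    ) -> np.ndarray:
        x: list[float] = []
        for j, ss in enumerate(self.spec.statespaces):
            for t in ss.allowed:
                x.append(np.log(max(params[j].baseline[t], 1e-12)))
        for j, trans in enumerate(self.spec.cov_transitions):
            for t in trans:
                beta = params[j].coveffects.get(t, np.zeros(len(self.spec.covariates)))
                x.extend(np.asarray(beta, float))
        variant = self.spec.link.variant
        if variant == "separate":
            x.append(np.log(redist.theta))
            x.append(np.log(redist.theta2 if redist.theta2 is not None else redist.theta))
        elif variant != "none":
            x.append(np.log(redist.theta))
        if variant == "power_inverse":
            x.append(self.spec.link.alpha if alpha is None else alpha)
        return np.asarray(x, dtype=float)

    def unpack(self, x: np.ndarray) -> tuple[list[ProcessParams], REDistribution | None]:
        """Build parameter objects from the working vector.

        Also sets ``spec.link.alpha`` for the power-inverse variant so the
        link the likelihood sees carries the current exponent.
        """
        x = np.asarray(x, dtype=float)
        pos = 0
        params: list[ProcessParams] = []
        baselines = []
        for ss in self.spec.statespaces:
            n = len(ss.allowed)
            baselines.append(dict(zip(ss.allowed, np.exp(x[pos:pos + n]))))
            pos += n
        coveffs: list[dict] = []
        ncov = len(self.spec.covariates)
        for trans in self.spec.cov_transitions:
            d = {}
            for t in trans:
                d[t] = x[pos:pos + ncov].copy()
                pos += ncov
            coveffs.append(d)
        for b, c in zip(baselines, coveffs):
            params.append(ProcessParams(baseline=b, coveffects=c))
        variant = self.spec.link.variant
        redist = None
        if variant == "separate":
            redist = REDistribution(theta=np.exp(x[pos]), theta2=np.exp(x[pos + 1]))
            pos += 2
        elif variant != "none":
            redist = REDistribution(theta=np.exp(x[pos]))
            pos += 1
        if variant == "power_inverse":
            self.spec.link.alpha = float(x[pos])
            pos += 1
        return params, redist


@dataclass
class FittedModel:
    """A fitted correlated multistate model.

    Working-scale estimates and covariance, plus the log-likelihood, AIC and
    convergence metadata.  ``params``/``redist`` expose the natural-scale
    parameter objects.
    """

    spec: ModelSpec
    layout: ParamLayout
    x: np.ndarray
    cov: np.ndarray | None
    loglik: float
    k: int
    n_subjects: int
    converged: bool = True
    grad_norm: float = np.nan
    message: str = ""
    quad: QuadratureOptions | None = None

    @property
    def aic(self) -> float:
        return aic(self.loglik, self.k)

    @property
    def params(self) -> list[ProcessParams]:
        p, _ = self.layout.unpack(self.x)
        return p

    @property
    def redist(self) -> REDistribution | None:
        _, r = self.layout.unpack(self.x)
        return r

    @property
    def estimates(self) -> pd.Series:
        """Natural-scale point estimates."""
        vals = [
            np.exp(v) if k in ("rate", "variance") else v
            for v, k in zip(self.x, self.layout.kinds)
        ]
        return pd.Series(vals, index=self.layout.names, name="estimate")

    @classmethod
    def from_params(
        cls,
        spec: ModelSpec,
        params: Sequence[ProcessParams],
        redist: REDistribution | None = None,
        loglik: float = np.nan,
        n_subjects: int = 0,
    ) -> "FittedModel":
        """Wrap known parameter values (e.g. published estimates) so that
        downstream computations (occupancy, empirical Bayes) can run without
        refitting."""
        layout = ParamLayout(spec)
        x = layout.pack(list(params), redist)
        return cls(
            spec=spec, layout=layout, x=x, cov=None, loglik=loglik,
            k=count_free_parameters(spec), n_subjects=n_subjects,
        )

    def to_dict(self) -> dict:
        d = {
            "model": self.spec.to_dict(),
            "loglik": self.loglik,
            "aic": self.aic,
            "k": self.k,
            "n_subjects": self.n_subjects,
            "converged": bool(self.converged),
            "grad_norm": None if np.isnan(self.grad_norm) else float(self.grad_norm),
            "message": self.message,
            "estimates": {n: float(v) for n, v in self.estimates.items()},
            "working": {
                "x": self.x.tolist(),
                "names": self.layout.names,
                "kinds": self.layout.kinds,
                "cov": self.cov.tolist() if self.cov is not None else None,
            },
        }
        if self.quad is not None:
            d["quadrature"] = {
                "method": self.quad.method, "n_nodes": self.quad.n_nodes,
                "atol": self.quad.atol, "rtol": self.quad.rtol,
            }
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def crude_init(panel: PanelData, spec: ModelSpec) -> list[ProcessParams]:
    """Starting intensities: observed transition counts divided by person-time
    at risk in the origin state, floored at 0.01 per year."""
    out = []
    for j, ss in enumerate(spec.statespaces):
        counts = {t: 0.0 for t in ss.allowed}
        persontime = np.zeros(ss.n_states)
        for subj in panel.subjects:
            for dt, r, s, _ in subj.intervals(j + 1):
                persontime[r - 1] += dt
                if (r, s) in counts:
                    counts[(r, s)] += 1.0
        baseline = {}
        for (r, s), c in counts.items():
            pt = max(persontime[r - 1], 1e-9)
            baseline[(r, s)] = max(c / pt, 0.01)
        out.append(ProcessParams(baseline=baseline))
    return out


def _numeric_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian with per-coordinate relative steps."""
    n = x.size
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = h[i]
        H[i, i] = (f(x + ei) + f(x - ei) - 2.0 * f0) / h[i] ** 2
        for j in range(i + 1, n):
            ej = np.zeros(n)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def fit_mle(
    panel: PanelData,
    spec: ModelSpec,
    init: np.ndarray | Sequence[ProcessParams] | None = None,
    quad_opts: QuadratureOptions | None = None,
    gtol: float = 1e-5,
    maxiter: int = 500,
    compute_hessian: bool = True,
    hessian_rel_step: float = 1e-4,
) -> FittedModel:
    """Fit by BFGS on the working scale.

    ``init`` may be a working-scale vector or per-process parameter objects;
    by default, crude occurrence/exposure rates with theta = 0.5 and
    alpha = 1.  Deterministic given the panel, the start values and the
    quadrature options.
    """
    n_ok = sum(1 for s in panel.subjects if s.n_visits >= 2)
    if n_ok < 2:
        raise ValueError("fitting needs at least 2 subjects with at least 2 visits")
    quad_opts = quad_opts or QuadratureOptions(method="fixed", n_nodes=96)
    layout = ParamLayout(spec)
    if init is None:
        start_params = crude_init(panel, spec)
        x0 = layout.pack(start_params, REDistribution(theta=0.5, theta2=0.5), alpha=1.0)
    elif isinstance(init, (list, tuple)) and init and isinstance(init[0], ProcessParams):
        x0 = layout.pack(list(init), REDistribution(theta=0.5, theta2=0.5), alpha=1.0)
    else:
        x0 = np.asarray(init, dtype=float)
        if x0.size != layout.n_params:
            raise ValueError(
                f"init has {x0.size} entries; the model has {layout.n_params} parameters"
            )

    pl = PanelLikelihood(panel, spec, n_nodes=quad_opts.n_nodes)
    logger.info(
        "fitting %s model: %d parameters, %d subjects, %d-node quadrature",
        spec.link.variant, layout.n_params, panel.n_subjects, quad_opts.n_nodes,
    )

    def negll(x: np.ndarray) -> float:
        try:
            params, redist = layout.unpack(x)
            val = -pl.total_loglik(params, redist)
        except (ValueError, FloatingPointError, OverflowError):
            return 1e10
        if not np.isfinite(val):
            return 1e10
        return val

    res = optimize.minimize(
        negll, x0, method="BFGS", options={"gtol": gtol, "maxiter": maxiter}
    )
    grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.nan
    converged = bool(res.success) or grad_norm < 1e-3
    if not converged:
        logger.warning("optimizer did not converge: %s (|grad| = %.3g)", res.message, grad_norm)

    cov = None
    if compute_hessian:
        H = _numeric_hessian(negll, res.x, rel_step=hessian_rel_step)
        try:
            cov = np.linalg.inv(H)
            cov = 0.5 * (cov + cov.T)
            if np.any(np.diag(cov) < 0):
                logger.warning("Hessian not positive definite; intervals unreliable")
        except np.linalg.LinAlgError:
            logger.warning("singular Hessian; confidence intervals unavailable")
            cov = None

    fit = FittedModel(
        spec=spec, layout=layout, x=res.x, cov=cov,
        loglik=float(-res.fun), k=count_free_parameters(spec),
        n_subjects=panel.n_subjects, converged=converged,
        grad_norm=grad_norm, message=str(res.message), quad=quad_opts,
    )
    return fit


def wald_confint(fit: FittedModel, level: float = 0.95) -> pd.DataFrame:
    """Natural-scale Wald intervals.

    Log-scale parameters (intensities, theta) get exp(estimate +- z se) —
    asymmetric about the point estimate; linear parameters (alpha, covariate
    effects) get symmetric intervals.
    """
    if fit.cov is None:
        raise ValueError("no covariance matrix available (singular or absent Hessian)")
    z = stats.norm.ppf(0.5 * (1 + level))
    se = np.sqrt(np.diag(fit.cov))
    rows = []
    for est_w, s, kind in zip(fit.x, se, fit.layout.kinds):
        lo, hi = est_w - z * s, est_w + z * s
        if kind in ("rate", "variance"):
            rows.append((np.exp(est_w), np.exp(lo), np.exp(hi)))
        else:
            rows.append((est_w, lo, hi))
    return pd.DataFrame(rows, columns=["estimate", "lower", "upper"], index=fit.layout.names)


def aic(loglik: float, k: int) -> float:
    """Akaike information criterion, 2k - 2 loglik."""
    if k < 0:
        raise ValueError("k must be >= 0")
    return 2.0 * k - 2.0 * loglik


def lr_test(fit_nested: FittedModel, fit_full: FittedModel) -> tuple[float, int, float]:
    """Likelihood-ratio test of a nested model against a fuller one.

    Returns (chi-square statistic, degrees of freedom, p-value).
    """
    stat = 2.0 * (fit_full.loglik - fit_nested.loglik)
    df = fit_full.k - fit_nested.k
    if df < 0:
        raise ValueError("the 'full' model has fewer parameters than the nested one")
    if stat < -1e-6:
        raise ValueError(
            f"negative LR statistic ({stat:.3g}): the fuller model fit worse; "
            "check convergence of both fits"
        )
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, df)) if df > 0 else (1.0 if stat == 0 else 0.0)
    return float(stat), int(df), p
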