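"""Empirical Bayes (posterior mean) estimates of subject frailties.

Given fitted parameters, the posterior mean of subject *i*'s frailty is the
ratio of two frailty integrals,

    uhat_i = int u f(u; theta) L_i(u) du / int f(u; theta) L_i(u) du,

evaluated with the same quadrature engine as the likelihood and a shared
scaling constant so the ratio is underflow-safe.  Subjects with no observed
transitions carry no information and their posterior mean is the prior mean,
exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fit import FittedModel
from .likelihood import (
    PanelData,
    QuadratureOptions,
    Subject,
    _log_frailty_integral,
    _process_conditional_loglik,
    subject_conditional_loglik,
)

__all__ = ["EBTable", "empirical_bayes", "eb_summary"]


@dataclass
class EBTable:
    """Per-subject posterior-mean frailties plus cohort summary statistics."""

    table: pd.DataFrame
    summary: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _posterior_mean(loglik_at_u, redist, quad_opts, process_index) -> float:
    grid = redist.quantile(np.linspace(0.001, 0.999, 25), process_index)
    grid = np.append(grid, 1.0)
    scale = max(loglik_at_u(float(g)) for g in grid)
    log_num = _log_frailty_integral(
        loglik_at_u, redist, quad_opts, process_index, moment=1, scale=scale
    )
    log_den = _log_frailty_integral(
        loglik_at_u, redist, quad_opts, process_index, moment=0, scale=scale
    )
    return float(np.exp(log_num - log_den))


def empirical_bayes(
    subject: Subject,
    fit: FittedModel,
    quad_opts: QuadratureOptions | None = None,
) -> float | tuple[float, float]:
    """Posterior-mean frailty for one subject.

    For the ``separate`` variant returns one value per process.
    """
    spec = fit.spec
    if spec.link.variant == "none":
        raise ValueError("the no-random-effect model has no frailties to estimate")
    quad_opts = quad_opts or QuadratureOptions()
    params = fit.params
    redist = fit.redist
    observed = [bool(subject.intervals(j + 1)) for j in range(spec.n_processes)]
    if spec.link.variant == "separate":
        # a process with no observed transitions keeps the prior mean, exactly 1
        return tuple(
            _posterior_mean(
                lambda u, _j=j: _process_conditional_loglik(subject, spec, params[_j], _j + 1, u),
                redist, quad_opts, j + 1,
            )
            if observed[j]
            else 1.0
            for j in range(spec.n_processes)
        )
    if not any(observed):
        return 1.0  # posterior equals the mean-1 gamma prior
    return _posterior_mean(
        lambda u: subject_conditional_loglik(subject, spec, params, u),
        redist, quad_opts, 1,
    )


def eb_summary(
    panel: PanelData,
    fit: FittedModel,
    quad_opts: QuadratureOptions | None = None,
) -> EBTable:
    """Posterior-mean frailties for every subject plus mean/median/SD/min/max."""
    separate = fit.spec.link.variant == "separate"
    rows = []
    for subj in panel.subjects:
        try:
            val = empirical_bayes(subj, fit, quad_opts)
        except Exception as exc:
            raise type(exc)(f"subject {subj.id}: {exc}") from exc
        rows.append((subj.id,) + (tuple(val) if separate else (val,)))
    cols = ["id"] + (["uhat_p1", "uhat_p2"] if separate else ["uhat"])
    table = pd.DataFrame(rows, columns=cols)
    stats_rows = {}
    for c in cols[1:]:
        v = table[c].to_numpy()
        stats_rows[c] = {
            "mean": float(np.mean(v)),
            "median": float(np.median(v)),
            "sd": float(np.std(v, ddof=1)) if v.size > 1 else 0.0,
            "min": float(np.min(v)),
            "max": float(np.max(v)),
        }
    summary = pd.DataFrame(stats_rows).T[["mean", "median", "sd", "min", "max"]]
    return EBTable(table=table, summary=summary)
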