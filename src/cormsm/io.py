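"""Panel CSV reading/writing and YAML model configuration.

The panel format is long: one row per visit with a subject id column, a
time column (decimal years, strictly increasing within subject), one state
column per process (integers 1..K, blank = missing) and optional covariate
columns.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .likelihood import PanelData, Subject
from .model_spec import ModelSpec, ProcessParams, REDistribution, StateSpace, RELink

__all__ = [
    "PanelFormatError",
    "read_panel",
    "write_panel",
    "panel_to_frame",
    "load_config",
    "model_from_config",
    "model_to_config",
]


class PanelFormatError(ValueError):
    """A panel file violates the format contract; the message names rows."""


def read_panel(
    path,
    id_col: str = "id",
    time_col: str = "time",
    state_cols: Sequence[str] | None = None,
    covariate_cols: Sequence[str] = (),
    n_states: int = 3,
) -> PanelData:
    """Read and validate a long-format panel CSV.

    If ``state_cols`` is omitted, every column other than id, time and the
    declared covariates is treated as a state column (in file order).
    """
    df = pd.read_csv(path)
    for col in (id_col, time_col):
        if col not in df.columns:
            raise PanelFormatError(f"required column {col!r} missing")
    if state_cols is None:
        reserved = {id_col, time_col, *covariate_cols}
        state_cols = [c for c in df.columns if c not in reserved]
    if not state_cols:
        raise PanelFormatError("no state columns found")
    for col in list(state_cols) + list(covariate_cols):
        if col not in df.columns:
            raise PanelFormatError(f"column {col!r} missing")

    subjects = []
    for sid, grp in df.groupby(id_col, sort=False):
        rows = grp.index.to_numpy() + 2  # 1-based file rows incl. header
        times = grp[time_col].to_numpy(dtype=float)
        diffs = np.diff(times)
        if np.any(diffs <= 0):
            k = int(np.flatnonzero(diffs <= 0)[0])
            kind = "duplicate" if diffs[k] == 0 else "non-increasing"
            raise PanelFormatError(
                f"subject {sid}: {kind} visit time {times[k + 1]} at file row "
                f"{rows[k + 1]}"
            )
        states = []
        for col in state_cols:
            raw = grp[col].to_numpy()
            s = np.zeros(len(raw), dtype=int)
            for i, v in enumerate(raw):
                if pd.isna(v) or (isinstance(v, str) and not v.strip()):
                    continue
                iv = int(v)
                if not 1 <= iv <= n_states:
                    raise PanelFormatError(
                        f"subject {sid}: state {iv} in column {col!r} outside "
                        f"1..{n_states} at file row {rows[i]}"
                    )
                s[i] = iv
            states.append(s)
        cov = (
            grp[list(covariate_cols)].to_numpy(dtype=float)
            if covariate_cols
            else None
        )
        subjects.append(Subject(id=str(sid), times=times, states=tuple(states),
                                covariates=cov))
    if not subjects:
        raise PanelFormatError("panel file contains no subjects")
    return PanelData(subjects=subjects, covariate_names=tuple(covariate_cols),
                     state_names=tuple(state_cols))


def panel_to_frame(
    panel: PanelData, id_col: str = "id", time_col: str = "time"
) -> pd.DataFrame:
    rows = []
    for subj in panel.subjects:
        for k in range(subj.n_visits):
            row = {id_col: subj.id, time_col: subj.times[k]}
            for j, name in enumerate(panel.state_names):
                v = subj.states[j][k]
                row[name] = int(v) if v > 0 else pd.NA
            for c, name in enumerate(panel.covariate_names):
                row[name] = subj.covariates[k, c]
            rows.append(row)
    return pd.DataFrame(rows)


def write_panel(panel: PanelData, path, id_col: str = "id", time_col: str = "time") -> None:
    """Write a panel CSV that round-trips through :func:`read_panel`."""
    df = panel_to_frame(panel, id_col, time_col)
    for name in panel.state_names:
        df[name] = df[name].astype("Int64")
    df.to_csv(path, index=False)


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _parse_transition(key: str) -> tuple[int, int]:
    if "->" in key:
        r, s = key.split("->")
    else:
        r, s = key[0], key[-1]
    return int(r), int(s)


def model_from_config(cfg: Mapping):
    """Build (spec, params, redist) from a config dictionary.

    Expected layout::

        model:
          variant: inverse
          n_states: 3
          process_names: [eGFR, PU]
          intensities:
            eGFR: {"1->2": 0.053, "2->1": 0.496, "2->3": 0.073, "3->2": 0.453}
            PU:   {"1->2": 0.468, "2->1": 0.653, "2->3": 0.127, "3->2": 2.111}
          theta: 0.549
          alpha: 1.0
    """
    m = cfg["model"] if "model" in cfg else cfg
    n_states = int(m.get("n_states", 3))
    intens = m["intensities"]
    names = m.get("process_names") or list(intens)
    spec = ModelSpec(
        statespaces=tuple(StateSpace.birth_death(n_states) for _ in names),
        link=RELink(variant=m.get("variant", "inverse"), alpha=m.get("alpha", 1.0)),
        process_names=tuple(names),
    )
    params = [
        ProcessParams(baseline={_parse_transition(k): float(v)
                                for k, v in intens[name].items()})
        for name in names
    ]
    redist = None
    if spec.link.variant != "none":
        redist = REDistribution(theta=float(m.get("theta", 0.5)),
                                theta2=m.get("theta2"))
    return spec, params, redist


def model_to_config(spec: ModelSpec, params, redist: REDistribution | None) -> dict:
    intens = {}
    for j, name in enumerate(spec.process_names):
        intens[name] = {
            f"{r}->{s}": float(v) for (r, s), v in params[j].baseline.items()
        }
    m = {
        "variant": spec.link.variant,
        "n_states": spec.statespaces[0].n_states,
        "process_names": list(spec.process_names),
        "intensities": intens,
    }
    if redist is not None:
        m["theta"] = redist.theta
        if redist.theta2 is not None:
            m["theta2"] = redist.theta2
    if spec.link.variant == "power_inverse":
        m["alpha"] = spec.link.alpha
    return {"model": m}
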