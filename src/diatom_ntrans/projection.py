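"""Presence thresholds and temperature-increment scenario projection.

Predicted presence probabilities are binarized at the threshold that
maximizes sensitivity + specificity (the Youden-optimal cut) computed
on the model's own predictions at the sampled stations; occurrence
frequency under each warming increment is then the percentage of
stations at which the clade is predicted present after adding the
increment to the temperature column only, holding every other variable
at its observed value.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .brt import BRTModel

DEFAULT_INCREMENTS = (0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0)


def maxss_threshold(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Probability cut maximizing sensitivity + specificity.

    Candidates are the midpoints of consecutive distinct predicted
    values plus one candidate below the minimum (everything present)
    and the maximum itself (nothing present, under the strict
    ``predicted > threshold`` rule).  Ties break toward the smallest
    threshold.  If every prediction is identical no cut is informative
    (sens + spec = 1 everywhere); the low extreme is returned with a
    warning.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if set(np.unique(observed)) - {0.0, 1.0}:
        raise ValueError("observed must be binary 0/1")
    n_pos = observed.sum()
    n_neg = len(observed) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to set a threshold")
    u = np.unique(predicted)
    candidates = np.concatenate([[u[0] - 1.0], (u[:-1] + u[1:]) / 2.0, [u[-1]]])
    if len(u) == 1:
        warnings.warn("uninformative predictions: all values identical; "
                      "returning the low extreme threshold")
    best_t, best_ss = None, -np.inf
    for t in candidates:
        pred_pos = predicted > t
        sens = (pred_pos & (observed == 1)).sum() / n_pos
        spec = (~pred_pos & (observed == 0)).sum() / n_neg
        ss = sens + spec
        if ss > best_ss + 1e-12:        # strict: first (smallest) t wins ties
            best_ss, best_t = ss, float(t)
    return best_t


@dataclasses.dataclass
class ScenarioProjection:
    """Occurrence frequencies (% of stations present) per increment."""

    frequencies: pd.Series          # increment -> % present
    threshold: float
    presence: pd.DataFrame          # station/site x increment binary


def warming_projection(
    model: BRTModel,
    env: pd.DataFrame,
    threshold: float,
    increments: tuple[float, ...] = DEFAULT_INCREMENTS,
    temperature_col: str = "temperature",
) -> ScenarioProjection:
    """Project clade occurrence under uniform warming increments.

    For each increment d the temperature column alone is raised by d,
    the model predicts the presence probability at every station, and
    the probability is binarized at the clade's threshold (strict
    ``p > threshold``).  Temperatures beyond the training range are not
    clipped: tree ensembles plateau at their outermost splits, which is
    the intended extrapolation behavior.
    """
    if temperature_col not in env.columns:
        raise ValueError(f"env has no {temperature_col!r} column")
    feats = model.feature_names
    X = env[feats].copy()
    pres = {}
    for d in increments:
        Xd = X.copy()
        if temperature_col in feats:
            Xd[temperature_col] = Xd[temperature_col] + d
        p = model.predict(Xd)
        pres[d] = (p > threshold).astype(int)
    presence = pd.DataFrame(pres, index=env.index)
    presence.columns.name = "increment"
    freq = presence.mean(axis=0) * 100.0
    return ScenarioProjection(freq.rename("pct_present"), threshold, presence)


def project_clades(
    models: dict[str, BRTModel],
    observed_presence: pd.DataFrame,
    env: pd.DataFrame,
    increments: tuple[float, ...] = DEFAULT_INCREMENTS,
) -> tuple[pd.DataFrame, pd.Series]:
    """Threshold + project every clade; returns (clade x increment
    frequency table, per-clade thresholds)."""
    rows, thr = {}, {}
    for clade, model in models.items():
        obs = observed_presence.loc[clade].reindex(env.index).to_numpy()
        pred = model.predict(env[model.feature_names])
        t = maxss_threshold(obs, pred)
        proj = warming_projection(model, env, t, increments)
        rows[clade] = proj.frequencies
        thr[clade] = t
    table = pd.DataFrame(rows).T
    table.index.name = "clade"
    return table, pd.Series(thr, name="threshold").rename_axis("clade")
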