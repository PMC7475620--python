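"""Time-dependent discrimination of dynamic predictions.

For a landmark s and window t, cases are subjects who die in (s, s+t],
controls are subjects still at risk beyond s+t, and subjects censored
inside the window are excluded from both groups (simple landmark
estimator; an inverse-probability-of-censoring-weighted variant is
available behind a flag for sensitivity analysis).  AUC(s, t) is the
Mann-Whitney concordance of the dynamic risks between cases and controls,
ties counting 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data import JointDataset


@dataclass(frozen=True)
class AUCResult:
    landmark: float
    window: float
    auc: float  # NaN when undefined (no cases or no controls)
    n_cases: int
    n_controls: int
    n_excluded: int
    model_tag: str = ""

    @property
    def defined(self) -> bool:
        return not np.isnan(self.auc)


class CaseControlSplit(NamedTuple):
    cases: np.ndarray
    controls: np.ndarray
    excluded: np.ndarray


def cases_controls(dataset: JointDataset, s: float, t: float) -> CaseControlSplit:
    """Partition subjects at risk at s into window cases / controls / excluded.

    cases: event in (s, s+t]; controls: follow-up beyond s+t (event or
    censored later); excluded: censored inside the window.  Subjects with
    T <= s never enter.
    """
    if s < 0 or t <= 0:
        raise ValueError("require s >= 0 and t > 0")
    sub = dataset.subjects
    T = sub["event_time"].to_numpy(dtype=float)
    delta = sub["event"].to_numpy()
    ids = sub["subject_id"].to_numpy()
    in_window = (T > s) & (T <= s + t)
    return CaseControlSplit(
        cases=ids[in_window & (delta == 1)],
        controls=ids[T > s + t],
        excluded=ids[in_window & (delta == 0)],
    )


def _risk_map(predictions: pd.DataFrame | dict, s: float | None) -> dict:
    if isinstance(predictions, dict):
        return predictions
    df = predictions
    if s is not None and "s" in df.columns:
        df = df[np.isclose(df["s"], s)]
    return dict(zip(df["subject_id"], df["risk"]))


def auc_st(
    predictions,
    cases: Sequence,
    controls: Sequence,
    s: float | None = None,
    t: float = np.nan,
    n_excluded: int = 0,
    model_tag: str = "",
    weights: dict | None = None,
) -> AUCResult:
    """Mann-Whitney AUC of risks: P(risk_case > risk_control) + P(tie)/2.

    ``predictions`` is a dict subject_id -> risk or a tidy prediction table
    (optionally filtered to landmark ``s``).  With ``weights`` (subject_id
    -> weight) the concordance is weight-averaged over case/control pairs
    (used by the IPCW variant).  Undefined (NaN) when either group is empty.
    """
    risks = _risk_map(predictions, s)
    case_r = np.array([risks[c] for c in cases], dtype=float)
    ctrl_r = np.array([risks[c] for c in controls], dtype=float)
    if len(case_r) == 0 or len(ctrl_r) == 0:
        return AUCResult(s if s is not None else np.nan, t, np.nan, len(case_r), len(ctrl_r), n_excluded, model_tag)
    if weights is None:
        # tie-averaged ranks give exactly the pairwise concordance with 1/2 ties
        allr = np.concatenate([case_r, ctrl_r])
        ranks = rankdata(allr)
        u = ranks[: len(case_r)].sum() - len(case_r) * (len(case_r) + 1) / 2
        auc = u / (len(case_r) * len(ctrl_r))
    else:
        wc = np.array([weights.get(c, 1.0) for c in cases], dtype=float)
        wk = np.array([weights.get(c, 1.0) for c in controls], dtype=float)
        gt = (case_r[:, None] > ctrl_r[None, :]).astype(float)
        eq = (case_r[:, None] == ctrl_r[None, :]).astype(float)
        W = wc[:, None] * wk[None, :]
        auc = float((W * (gt + 0.5 * eq)).sum() / W.sum())
    return AUCResult(
        landmark=s if s is not None else np.nan,
        window=t,
        auc=float(auc),
        n_cases=len(case_r),
        n_controls=len(ctrl_r),
        n_excluded=n_excluded,
        model_tag=model_tag,
    )


def roc_curve(predictions, cases: Sequence, controls: Sequence, s: float | None = None):
    """ROC points from thresholding risks, ordered by increasing FPR.

    Returns a DataFrame (threshold, fpr, tpr) including the (0,0) and (1,1)
    endpoints; the trapezoidal area under the curve equals :func:`auc_st`
    exactly (ties produce diagonal segments).
    """
    risks = _risk_map(predictions, s)
    case_r = np.array([risks[c] for c in cases], dtype=float)
    ctrl_r = np.array([risks[c] for c in controls], dtype=float)
    if len(case_r) == 0 or len(ctrl_r) == 0:
        raise ValueError("ROC requires at least one case and one control")
    thresholds = np.unique(np.concatenate([case_r, ctrl_r]))[::-1]
    rows = [{"threshold": np.inf, "fpr": 0.0, "tpr": 0.0}]
    for thr in thresholds:
        rows.append(
            {
                "threshold": thr,
                "fpr": float((ctrl_r >= thr).mean()),
                "tpr": float((case_r >= thr).mean()),
            }
        )
    return pd.DataFrame(rows)


def trapezoid_auc(roc: pd.DataFrame) -> float:
    return float(np.trapezoid(roc["tpr"], roc["fpr"]))


def average_auc(results: Sequence[AUCResult]) -> float:
    """Unweighted mean AUC over landmarks where the AUC is defined."""
    vals = [r.auc for r in results if r.defined]
    if not vals:
        raise ValueError("no defined AUC results to average")
    return float(np.mean(vals))


def censoring_weights(dataset: JointDataset, s: float, t: float) -> dict:
    """IPCW weights from the Kaplan-Meier curve of the censoring distribution.

    Cases are weighted by 1/G(T_i-), controls by 1/G(s+t), with G the KM
    estimator of P(censoring time > u) among subjects at risk.
    """
    from lifelines import KaplanMeierFitter

    sub = dataset.subjects
    km = KaplanMeierFitter()
    km.fit(sub["event_time"], event_observed=1 - sub["event"])
    split = cases_controls(dataset, s, t)
    weights = {}
    for cid in split.cases:
        Ti = float(sub.loc[sub["subject_id"] == cid, "event_time"].iloc[0])
        g = float(km.predict(max(Ti - 1e-9, 0.0)))
        weights[cid] = 1.0 / max(g, 1e-8)
    g_ctrl = float(km.predict(s + t))
    for cid in split.controls:
        weights[cid] = 1.0 / max(g_ctrl, 1e-8)
    return weights


class ModelComparison(NamedTuple):
    table: pd.DataFrame
    average: dict
    series: dict  # plot-ready: landmarks + per-model AUC lists


def compare_models(
    dataset: JointDataset,
    predictions_by_model: dict[str, pd.DataFrame],
    landmarks,
    window: float,
    ipcw: bool = False,
) -> ModelComparison:
    """Per-landmark AUC for each model on identical case/control sets.

    ``predictions_by_model`` maps a model tag to its tidy prediction table
    (as produced by :func:`trajsurv.predict.batch_dynamic_predictions`).
    Returns the long comparison table, the per-model average AUC, and
    plot-ready series including the per-landmark difference.
    """
    tags = list(predictions_by_model)
    rows = []
    results: dict[str, list[AUCResult]] = {tag: [] for tag in tags}
    for s in np.asarray(landmarks, dtype=float):
        split = cases_controls(dataset, s, window)
        weights = censoring_weights(dataset, s, window) if ipcw else None
        for tag in tags:
            r = auc_st(
                predictions_by_model[tag],
                split.cases,
                split.controls,
                s=s,
                t=window,
                n_excluded=len(split.excluded),
                model_tag=tag,
                weights=weights,
            )
            results[tag].append(r)
            rows.append(
                {
                    "model": tag,
                    "s": s,
                    "t": window,
                    "auc": r.auc,
                    "n_cases": r.n_cases,
                    "n_controls": r.n_controls,
                    "n_excluded": r.n_excluded,
                }
            )
    table = pd.DataFrame(rows)
    average = {tag: average_auc(results[tag]) for tag in tags}
    series = {"landmarks": list(np.asarray(landmarks, dtype=float))}
    for tag in tags:
        series[tag] = [r.auc for r in results[tag]]
    if len(tags) == 2:
        series["difference"] = [
            a - b for a, b in zip(series[tags[0]], series[tags[1]])
        ]
    return ModelComparison(table=table, average=average, series=series)
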