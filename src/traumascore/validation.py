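"""Discrimination analysis for death-prediction scores.

Empirical ROC curves, AUC with DeLong (1988) standard errors and confidence
intervals, paired DeLong comparison of correlated AUCs, Youden-index optimal
cutoffs with full confusion metrics, and the analytic identities linking
accuracy/PPV/NPV to sensitivity, specificity and prevalence.

Orientation: severity scores such as NISS rank *up* with death risk, while
RTS and the TRISS survival probabilities rank *down*; every routine takes an
orientation so both kinds are handled without pre-negating inputs. The AUC
is the concordance probability — the chance a randomly chosen death case is
ranked more severe than a randomly chosen survivor, ties counted one half.

DeLong variances come from per-case placement values computed with midranks
(the O(n log n) formulation), so large cohorts are cheap; a brute-force
pair-count oracle covers the same quantities in the test-suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Orientation",
    "ROCCurve",
    "AUCResult",
    "PairedComparison",
    "CutoffReport",
    "SCORE_ORIENTATIONS",
    "roc_points",
    "auc_concordance",
    "auc_with_ci",
    "delong_paired_test",
    "youden_optimal_cutoff",
    "cutoff_metrics",
    "metrics_from_rates",
    "pairwise_auc_table",
]


HIGHER = "higher_predicts_event"
LOWER = "lower_predicts_event"

#: Orientation of each score in the panel: NISS rises with severity, RTS and
#: both survival probabilities fall (Table-4 style "NISS > c", "RTS < c").
SCORE_ORIENTATIONS = {
    "niss": HIGHER,
    "rts": LOWER,
    "ps_mtos": LOWER,
    "ps_ntrd": LOWER,
}

_ORIENTATION_ALIASES = {
    HIGHER: HIGHER,
    LOWER: LOWER,
    "higher": HIGHER,
    "lower": LOWER,
}


class Orientation:
    """Namespace for the two score orientations."""

    HIGHER_PREDICTS_EVENT = HIGHER
    LOWER_PREDICTS_EVENT = LOWER


def _check_orientation(orientation: str) -> str:
    try:
        return _ORIENTATION_ALIASES[orientation]
    except KeyError:
        raise ValueError(
            f"orientation must be one of {sorted(set(_ORIENTATION_ALIASES))}, "
            f"got {orientation!r}"
        ) from None


def _check_inputs(values, events, orientation: str):
    values = np.asarray(values, dtype=float)
    events = np.asarray(events, dtype=bool)
    if values.ndim != 1 or events.ndim != 1 or len(values) != len(events):
        raise ValueError("values and events must be 1-d sequences of equal length")
    if not events.any():
        raise ValueError("degenerate labels: no event (death) cases present")
    if events.all():
        raise ValueError("degenerate labels: no non-event (survivor) cases present")
    oriented = values if _check_orientation(orientation) == HIGHER else -values
    return oriented, events


@dataclass(frozen=True)
class ROCCurve:
    """Empirical ROC curve over the distinct observed score values.

    ``thresholds`` are on the original score scale, ordered from the most
    severe end of the scale inward; ``tpr``/``fpr`` are the sensitivity and
    1-specificity of classifying "event" strictly beyond each threshold.
    Endpoints (0, 0) and (1, 1) are always present.
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    orientation: str

    def auc_trapezoid(self) -> float:
        """Area under the curve by the trapezoidal rule."""
        return float(np.trapezoid(self.tpr, self.fpr))


@dataclass(frozen=True)
class AUCResult:
    """AUC with DeLong standard error and normal-approximation CI."""

    auc: float
    se: float
    ci_low: float
    ci_high: float
    level: float = 0.95


@dataclass(frozen=True)
class PairedComparison:
    """DeLong paired comparison of two correlated AUCs."""

    score_a: str
    score_b: str
    auc_a: float
    auc_b: float
    delta_auc: float
    z: float
    p: float


@dataclass(frozen=True)
class CutoffReport:
    """An operating point: cutoff, direction and its confusion metrics.

    The classification rule is strict: ``value > cutoff`` predicts death for
    higher-oriented scores, ``value < cutoff`` for lower-oriented ones.
    PPV/NPV are NaN when the corresponding margin is empty.
    """

    cutoff: float
    orientation: str
    sensitivity: float
    specificity: float
    accuracy: float
    ppv: float
    npv: float
    youden_j: float

    @property
    def direction(self) -> str:
        return ">" if self.orientation == HIGHER else "<"


# ---------------------------------------------------------------------------
# placements (the DeLong structural components)
# ---------------------------------------------------------------------------

def _placements(oriented: np.ndarray, events: np.ndarray):
    """Midrank placement values.

    Returns ``(auc, v_event, v_control)`` where ``v_event[i]`` is the
    fraction of controls ranked below event i (ties half) and
    ``v_control[j]`` the fraction of events ranked above control j.
    """
    x = oriented[events]
    y = oriented[~events]
    n, m = len(x), len(y)
    r_all = stats.rankdata(np.concatenate([x, y]))
    r_x = stats.rankdata(x)
    r_y = stats.rankdata(y)
    v_event = (r_all[:n] - r_x) / m
    v_control = 1.0 - (r_all[n:] - r_y) / n
    auc = float(v_event.mean())
    return auc, v_event, v_control


def roc_points(values, events, orientation: str) -> ROCCurve:
    """Empirical ROC curve; tied score values share one threshold."""
    oriented, events = _check_inputs(values, events, orientation)
    orientation = _check_orientation(orientation)
    order = np.argsort(-oriented, kind="mergesort")
    sorted_scores = oriented[order]
    sorted_events = events[order]
    # indices of the last element of each tie-group
    last_of_group = np.nonzero(np.diff(sorted_scores))[0]
    idx = np.r_[last_of_group, len(oriented) - 1]
    tp = np.cumsum(sorted_events)[idx]
    fp = np.cumsum(~sorted_events)[idx]
    n_event = events.sum()
    n_control = len(events) - n_event
    tpr = np.r_[0.0, tp / n_event]
    fpr = np.r_[0.0, fp / n_control]
    thresholds = np.r_[np.inf, sorted_scores[idx]]
    if orientation == LOWER:
        thresholds = -thresholds
    return ROCCurve(thresholds=thresholds, tpr=tpr, fpr=fpr, orientation=orientation)


def auc_concordance(values, events, orientation: str) -> float:
    """Concordance AUC: P(random event outranks random control), ties 1/2."""
    oriented, events = _check_inputs(values, events, orientation)
    auc, _, _ = _placements(oriented, events)
    return auc


def auc_with_ci(values, events, orientation: str, level: float = 0.95) -> AUCResult:
    """AUC with DeLong standard error and a normal-approximation CI
    truncated to [0, 1]."""
    oriented, events = _check_inputs(values, events, orientation)
    if events.sum() < 2 or (~events).sum() < 2:
        raise ValueError("need at least two events and two non-events for a CI")
    auc, v_event, v_control = _placements(oriented, events)
    var = v_event.var(ddof=1) / len(v_event) + v_control.var(ddof=1) / len(v_control)
    se = float(np.sqrt(max(var, 0.0)))
    zcrit = stats.norm.ppf(0.5 + level / 2)
    return AUCResult(
        auc=auc,
        se=se,
        ci_low=float(max(0.0, auc - zcrit * se)),
        ci_high=float(min(1.0, auc + zcrit * se)),
        level=level,
    )


def delong_paired_test(
    values_a,
    values_b,
    events,
    orientation_a: str,
    orientation_b: str,
    labels: tuple[str, str] = ("a", "b"),
) -> PairedComparison:
    """DeLong test for a difference between two correlated AUCs.

    Both score vectors must be measured on the same patients against the
    same outcome. The variance of the AUC difference uses the paired
    placement covariance; if it vanishes with equal AUCs (e.g. identical
    scores) the comparison degenerates to z = 0, p = 1.
    """
    oriented_a, events_arr = _check_inputs(values_a, events, orientation_a)
    oriented_b, events_b = _check_inputs(values_b, events, orientation_b)
    if len(oriented_a) != len(oriented_b):
        raise ValueError("paired scores must cover the same patients")
    auc_a, ve_a, vc_a = _placements(oriented_a, events_arr)
    auc_b, ve_b, vc_b = _placements(oriented_b, events_b)
    n, m = len(ve_a), len(vc_a)
    var_a = ve_a.var(ddof=1) / n + vc_a.var(ddof=1) / m
    var_b = ve_b.var(ddof=1) / n + vc_b.var(ddof=1) / m
    cov = (
        np.cov(ve_a, ve_b, ddof=1)[0, 1] / n
        + np.cov(vc_a, vc_b, ddof=1)[0, 1] / m
    )
    var_diff = var_a + var_b - 2.0 * cov
    delta = auc_a - auc_b
    if var_diff <= 0 or np.isclose(var_diff, 0.0):
        if np.isclose(delta, 0.0):
            z, p = 0.0, 1.0
        else:  # exactly separable difference; report an effectively-zero p
            z = np.inf * np.sign(delta)
            p = 0.0
    else:
        z = float(delta / np.sqrt(var_diff))
        p = float(2.0 * stats.norm.sf(abs(z)))
    return PairedComparison(
        score_a=labels[0],
        score_b=labels[1],
        auc_a=auc_a,
        auc_b=auc_b,
        delta_auc=float(delta),
        z=float(z),
        p=float(p),
    )


# ---------------------------------------------------------------------------
# cutoffs
# ---------------------------------------------------------------------------

def _confusion_report(
    tp: float, fp: float, tn: float, fn: float, cutoff: float, orientation: str
) -> CutoffReport:
    n = tp + fp + tn + fn
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    if tp + fp == 0:
        warnings.warn("no predicted positives: PPV undefined", stacklevel=3)
        ppv = float("nan")
    else:
        ppv = tp / (tp + fp)
    if tn + fn == 0:
        warnings.warn("no predicted negatives: NPV undefined", stacklevel=3)
        npv = float("nan")
    else:
        npv = tn / (tn + fn)
    return CutoffReport(
        cutoff=float(cutoff),
        orientation=orientation,
        sensitivity=float(sens),
        specificity=float(spec),
        accuracy=float((tp + tn) / n),
        ppv=float(ppv),
        npv=float(npv),
        youden_j=float(sens + spec - 1.0),
    )


def cutoff_metrics(values, events, cutoff: float, orientation: str) -> CutoffReport:
    """Confusion metrics at a fixed cutoff (strict inequality)."""
    orientation = _check_orientation(orientation)
    values = np.asarray(values, dtype=float)
    events = np.asarray(events, dtype=bool)
    if orientation == HIGHER:
        predicted = values > cutoff
    else:
        predicted = values < cutoff
    tp = int(np.sum(predicted & events))
    fp = int(np.sum(predicted & ~events))
    fn = int(np.sum(~predicted & events))
    tn = int(np.sum(~predicted & ~events))
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("degenerate labels: need at least one event and one non-event")
    return _confusion_report(tp, fp, tn, fn, cutoff, orientation)


def youden_optimal_cutoff(values, events, orientation: str) -> CutoffReport:
    """Cutoff maximising the Youden index J = sensitivity + specificity - 1.

    Every achievable confusion table is scanned: candidates are the distinct
    observed values (strict ``>`` in oriented space) plus the all-positive
    extreme. Ties in J break toward higher specificity (fewer false
    positives). The reported cutoff is an observed score value, so the
    operating point reads naturally as e.g. "NISS > 24".
    """
    from .estimators import YoudenCutoffClassifier

    clf = YoudenCutoffClassifier(orientation=orientation)
    clf.fit(np.asarray(values, dtype=float), np.asarray(events, dtype=bool))
    return clf.report_


def metrics_from_rates(
    sensitivity: float, specificity: float, prevalence: float
) -> tuple[float, float, float]:
    """Accuracy, PPV and NPV implied by sensitivity, specificity and
    prevalence (the standard post-test probability identities)."""
    for name, value in (
        ("sensitivity", sensitivity),
        ("specificity", specificity),
        ("prevalence", prevalence),
    ):
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {value}")
    accuracy = sensitivity * prevalence + specificity * (1.0 - prevalence)
    ppv_den = sensitivity * prevalence + (1.0 - specificity) * (1.0 - prevalence)
    npv_den = specificity * (1.0 - prevalence) + (1.0 - sensitivity) * prevalence
    if ppv_den == 0:
        warnings.warn("zero positive-classification rate: PPV undefined", stacklevel=2)
        ppv = float("nan")
    else:
        ppv = sensitivity * prevalence / ppv_den
    if npv_den == 0:
        warnings.warn("zero negative-classification rate: NPV undefined", stacklevel=2)
        npv = float("nan")
    else:
        npv = specificity * (1.0 - prevalence) / npv_den
    return float(accuracy), float(ppv), float(npv)


# ---------------------------------------------------------------------------
# the Table-3 analogue
# ---------------------------------------------------------------------------

def pairwise_auc_table(
    panels: pd.DataFrame | Sequence, events: Iterable[bool]
) -> tuple[dict[str, AUCResult], pd.DataFrame, list[PairedComparison]]:
    """AUCs and all pairwise DeLong comparisons for the four-score panel.

    Parameters
    ----------
    panels
        DataFrame with columns ``niss, rts, ps_mtos, ps_ntrd`` (a sequence
        of :class:`~traumascore.scores.ScorePanel` is also accepted).
    events
        In-hospital death indicators.

    Returns
    -------
    aucs
        ``{score_name: AUCResult}`` in panel order.
    p_matrix
        Symmetric 4x4 DataFrame of two-sided p-values, NaN diagonal.
    comparisons
        The six :class:`PairedComparison` objects (upper triangle).
    """
    if not isinstance(panels, pd.DataFrame):
        panels = pd.DataFrame(
            {
                "niss": [p.niss for p in panels],
                "rts": [p.rts for p in panels],
                "ps_mtos": [p.ps_mtos for p in panels],
                "ps_ntrd": [p.ps_ntrd for p in panels],
            }
        )
    events = np.asarray(list(events), dtype=bool)
    names = list(SCORE_ORIENTATIONS)
    aucs = {
        name: auc_with_ci(panels[name].to_numpy(), events, SCORE_ORIENTATIONS[name])
        for name in names
    }
    p_matrix = pd.DataFrame(np.nan, index=names, columns=names)
    comparisons = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            comp = delong_paired_test(
                panels[a].to_numpy(),
                panels[b].to_numpy(),
                events,
                SCORE_ORIENTATIONS[a],
                SCORE_ORIENTATIONS[b],
                labels=(a, b),
            )
            comparisons.append(comp)
            p_matrix.loc[a, b] = comp.p
            p_matrix.loc[b, a] = comp.p
    return aucs, p_matrix, comparisons
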