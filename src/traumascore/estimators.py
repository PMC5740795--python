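"""scikit-learn-compatible estimators.

`TraumaScoreTransformer` turns a registry-shaped DataFrame into the score
panel columns so the panel can sit inside an sklearn `Pipeline`;
`YoudenCutoffClassifier` is a one-feature threshold classifier whose `fit`
selects the Youden-optimal operating point of a severity score against the
death outcome.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin

from . import validation as _v
from .registry import AISInjury, Mechanism, PatientRecord, Physiology, Sex
from .scores import score_panel

__all__ = ["TraumaScoreTransformer", "YoudenCutoffClassifier"]

PANEL_COLUMNS = (
    "iss",
    "niss",
    "rts",
    "ps_mtos",
    "ps_ntrd",
    "age_index",
    "coefficient_set_used",
)


def _record_from_row(row: pd.Series) -> PatientRecord:
    injuries = []
    cell = str(row.get("injuries", "") or "")
    for token in cell.split(";"):
        token = token.strip()
        if token:
            region, sev = token.split(":")
            injuries.append(AISInjury(region.strip(), int(sev)))
    return PatientRecord(
        patient_id=str(row.get("patient_id", "")),
        age=int(row["age"]),
        sex=Sex(str(row["sex"])) if "sex" in row else Sex.MALE,
        mechanism=Mechanism(str(row["mechanism"])),
        injuries=tuple(injuries),
        physiology=Physiology(
            respiratory_rate=int(row["rr"]),
            systolic_bp=int(row["sbp"]),
            gcs=int(row["gcs"]),
        ),
        died=bool(int(row["died"])) if "died" in row else False,
    )


class TraumaScoreTransformer(TransformerMixin, BaseEstimator):
    """Compute the trauma score panel for every row of a registry table.

    A stateless transformer: ``fit`` only validates the input schema.
    ``transform`` returns the panel columns (ISS, NISS, RTS, the two TRISS
    survival probabilities, the age index and the MTOS coefficient set
    used), optionally appended to the input.

    Parameters
    ----------
    append : bool, default False
        If True, return the input DataFrame with the panel columns added;
        otherwise return the panel columns alone.
    """

    REQUIRED = ("age", "mechanism", "rr", "sbp", "gcs", "injuries")

    def __init__(self, append: bool = False):
        self.append = append

    def _validate(self, X: pd.DataFrame) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            raise TypeError("TraumaScoreTransformer expects a registry DataFrame")
        missing = [c for c in self.REQUIRED if c not in X.columns]
        if missing:
            raise ValueError(f"missing required registry column(s): {missing}")
        return X

    def fit(self, X: pd.DataFrame, y=None) -> "TraumaScoreTransformer":
        self._validate(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = self._validate(X)
        rows = []
        for _, row in X.iterrows():
            panel = score_panel(_record_from_row(row))
            rows.append(
                {
                    "iss": panel.iss,
                    "niss": panel.niss,
                    "rts": panel.rts,
                    "ps_mtos": panel.ps_mtos,
                    "ps_ntrd": panel.ps_ntrd,
                    "age_index": panel.age_index,
                    "coefficient_set_used": panel.coefficient_set,
                }
            )
        panel_frame = pd.DataFrame(rows, columns=PANEL_COLUMNS, index=X.index)
        if self.append:
            return pd.concat([X, panel_frame], axis=1)
        return panel_frame

    def get_feature_names_out(self, input_features=None):
        return np.asarray(PANEL_COLUMNS, dtype=object)


class YoudenCutoffClassifier(ClassifierMixin, BaseEstimator):
    """Single-score threshold classifier at the Youden-optimal cutoff.

    ``fit`` scans every achievable confusion table of the score against the
    binary outcome — candidate cutoffs are the distinct observed values
    (strict inequality) plus the all-positive extreme — and keeps the cutoff
    maximising J = sensitivity + specificity - 1, breaking ties toward
    higher specificity. ``predict`` then classifies ``value > cutoff_``
    (orientation "higher") or ``value < cutoff_`` ("lower") as an event.

    Parameters
    ----------
    orientation : {"higher", "lower"}, default "higher"
        Whether larger score values indicate the event (NISS-like) or
        smaller ones do (RTS- and survival-probability-like).

    Attributes
    ----------
    cutoff_ : float
        The selected operating point, an observed score value.
    sensitivity_, specificity_, accuracy_, ppv_, npv_, youden_j_ : float
        Confusion metrics at ``cutoff_``.
    report_ : CutoffReport
        The full operating-point report.
    classes_ : ndarray
        Always ``[False, True]``.
    """

    def __init__(self, orientation: str = "higher"):
        self.orientation = orientation

    def fit(self, X, y) -> "YoudenCutoffClassifier":
        values = np.asarray(X, dtype=float)
        if values.ndim == 2 and values.shape[1] == 1:
            values = values[:, 0]
        oriented, events = _v._check_inputs(values, y, self.orientation)
        orientation = _v._check_orientation(self.orientation)

        order = np.argsort(-oriented, kind="mergesort")
        s = oriented[order]
        e = events[order]
        n_event = int(e.sum())
        n_control = len(e) - n_event
        # cumulative TP/FP when the cutoff sits just below each tie group
        last = np.r_[np.nonzero(np.diff(s))[0], len(s) - 1]
        tp = np.cumsum(e)[last].astype(float)
        fp = np.cumsum(~e)[last].astype(float)
        # candidate "all positive" (cutoff below every value) is the final
        # entry of tp/fp already; prepend the "none positive" extreme
        tp = np.r_[0.0, tp]
        fp = np.r_[0.0, fp]
        sens = tp / n_event
        spec = 1.0 - fp / n_control
        j = sens + spec - 1.0
        best_j = j.max()
        # ties toward higher specificity = fewer predicted positives; the
        # candidate list is ordered from none-positive downward, so take the
        # first maximiser
        k = int(np.argmax(j >= best_j - 1e-12))

        group_values = s[last]  # distinct oriented values, descending
        if k < len(group_values):
            # strict ">": the cutoff is the first excluded tie group, an
            # observed value (k = 0 puts it at the top: nothing positive)
            cutoff_oriented = group_values[k]
        else:
            # all positive: any cutoff below the least observed value
            cutoff_oriented = group_values[-1] - 1.0
        tp_k, fp_k = tp[k], fp[k]
        fn_k, tn_k = n_event - tp_k, n_control - fp_k
        cutoff = cutoff_oriented if orientation == _v.HIGHER else -cutoff_oriented
        self.report_ = _v._confusion_report(
            tp_k, fp_k, tn_k, fn_k, cutoff, orientation
        )
        self.cutoff_ = self.report_.cutoff
        self.sensitivity_ = self.report_.sensitivity
        self.specificity_ = self.report_.specificity
        self.accuracy_ = self.report_.accuracy
        self.ppv_ = self.report_.ppv
        self.npv_ = self.report_.npv
        self.youden_j_ = self.report_.youden_j
        self.classes_ = np.array([False, True])
        self.n_features_in_ = 1
        return self

    def predict(self, X) -> np.ndarray:
        values = np.asarray(X, dtype=float)
        if values.ndim == 2 and values.shape[1] == 1:
            values = values[:, 0]
        if _v._check_orientation(self.orientation) == _v.HIGHER:
            return values > self.cutoff_
        return values < self.cutoff_
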