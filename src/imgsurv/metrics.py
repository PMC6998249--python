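"""Prognostic performance metrics: concordance index and IPCW-based IPA.

The concordance index is the fraction of comparable pairs ordered correctly
by the model, where a pair (i, j) is comparable when subject i's failure was
observed and subject j is known to have outlived it. The index of prediction
accuracy (IPA) is ``1 - BS_model / BS_null`` with BS the inverse-probability-
of-censoring-weighted (IPCW) Brier score at an evaluation horizon and the
null model the Kaplan-Meier estimate used as every subject's prediction;
100% is a perfect model, 0% matches the null, and negative values flag a
model that is worse than ignoring the covariates altogether.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .survival import SurvivalRecord, kaplan_meier, km_evaluator, survival_at

__all__ = [
    "RiskPrediction",
    "concordance_index",
    "ipcw_brier",
    "ipa",
    "evaluation_report",
    "HORIZON_18_MONTHS_DAYS",
]

#: 18 months expressed in days (365.25 * 1.5, rounded) — the evaluation
#: horizon used for pancreatic-cancer prognosis.
HORIZON_18_MONTHS_DAYS = 548.0


@dataclass(frozen=True)
class RiskPrediction:
    """A model's output for one subject.

    ``score`` is oriented so that larger means longer predicted survival.
    ``horizon_survival`` is the predicted probability of surviving past the
    evaluation horizon, required for Brier/IPA but not for concordance.
    """

    subject_id: str
    score: float
    horizon_survival: float | None = None

    def __post_init__(self) -> None:
        if self.horizon_survival is not None and not (
            0.0 <= self.horizon_survival <= 1.0
        ):
            raise ValueError(
                f"subject {self.subject_id!r}: horizon survival must be in [0, 1]"
            )


def _align(
    predictions: Sequence[RiskPrediction], records: Sequence[SurvivalRecord]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    by_id = {p.subject_id: p for p in predictions}
    missing = [r.subject_id for r in records if r.subject_id not in by_id]
    if missing:
        raise ValueError(f"no prediction for subjects: {missing[:5]}")
    if len(by_id) != len(predictions):
        raise ValueError("duplicate subject_id in predictions")
    scores = np.array([by_id[r.subject_id].score for r in records], dtype=float)
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=int)
    return scores, times, events, [r.subject_id for r in records]


def concordance_index(
    predictions: Sequence[RiskPrediction],
    records: Sequence[SurvivalRecord],
    tie_rule: Literal["strict", "half"] = "strict",
) -> float:
    """Concordance over the order graph of comparable pairs.

    Pairs (i, j) with ``T_i`` uncensored and ``T_j > T_i`` are comparable;
    the pair is concordant when ``score_i < score_j`` (subject i, who failed
    first, was predicted the shorter survival). Tied scores earn no credit
    under ``tie_rule="strict"`` (the literal order-graph indicator) and half
    credit under ``"half"`` (Harrell's convention).
    """
    scores, times, events, _ = _align(predictions, records)
    comparable = (events[:, None] == 1) & (times[None, :] > times[:, None])
    n_pairs = int(comparable.sum())
    if n_pairs == 0:
        raise ValueError("no comparable (uncensored, longer-lived) pairs")
    concordant = comparable & (scores[:, None] < scores[None, :])
    credit = float(concordant.sum())
    if tie_rule == "half":
        tied = comparable & (scores[:, None] == scores[None, :])
        credit += 0.5 * float(tied.sum())
    elif tie_rule != "strict":
        raise ValueError(f"unknown tie_rule {tie_rule!r}")
    return credit / n_pairs


def ipcw_brier(
    predictions: Sequence[RiskPrediction],
    records: Sequence[SurvivalRecord],
    t_star: float,
) -> float:
    """IPCW Brier score of predicted horizon survival at ``t_star``.

    ``BS(t*) = (1/n) sum_i [ S_i(t*)^2 1{T_i <= t*, event} / G(T_i-)
                            + (1 - S_i(t*))^2 1{T_i > t*} / G(t*) ]``

    with ``G`` the Kaplan-Meier estimator of the censoring distribution
    (records with event flags inverted). Subjects censored before ``t_star``
    carry zero weight. Under independent censoring this is a consistent
    estimate of the mean squared error between the survival indicator
    ``1{T > t*}`` and the prediction.
    """
    by_id = {p.subject_id: p for p in predictions}
    records = list(records)
    surv_hat = np.empty(len(records))
    for i, rec in enumerate(records):
        p = by_id.get(rec.subject_id)
        if p is None or p.horizon_survival is None:
            raise ValueError(
                f"subject {rec.subject_id!r}: missing horizon survival prediction"
            )
        surv_hat[i] = p.horizon_survival
    censor_km = km_evaluator(
        [SurvivalRecord(r.subject_id, r.time, 1 - r.event) for r in records]
    )
    g_star = censor_km(t_star)
    total = 0.0
    for i, rec in enumerate(records):
        if rec.time <= t_star and rec.event == 1:
            g = censor_km(rec.time, left_limit=True)
            if g <= 0:
                raise ValueError(
                    f"censoring survival is 0 at T- for subject {rec.subject_id!r}"
                )
            total += surv_hat[i] ** 2 / g
        elif rec.time > t_star:
            if g_star <= 0:
                raise ValueError(
                    f"censoring survival is 0 at t*={t_star} "
                    f"(needed for subject {rec.subject_id!r})"
                )
            total += (1.0 - surv_hat[i]) ** 2 / g_star
        # censored at or before t_star: weight 0
    return total / len(records)


def ipa(
    predictions: Sequence[RiskPrediction],
    records: Sequence[SurvivalRecord],
    t_star: float,
    null_records: Sequence[SurvivalRecord] | None = None,
) -> float:
    """Index of prediction accuracy, in percent.

    ``IPA = (1 - BS_model(t*) / BS_null(t*)) * 100`` where the null model
    predicts the Kaplan-Meier survival at ``t_star`` (estimated from
    ``null_records``, defaulting to ``records`` themselves) for every
    subject. 100 is perfect, 0 matches the null, negative is harmful.
    """
    records = list(records)
    km = kaplan_meier(list(null_records) if null_records is not None else records)
    t_eval = min(t_star, float(km.grid.boundaries[-1]))
    s_null = survival_at(km, t_eval)
    null_preds = [
        RiskPrediction(r.subject_id, score=s_null, horizon_survival=s_null)
        for r in records
    ]
    bs_null = ipcw_brier(null_preds, records, t_star)
    if bs_null == 0:
        raise ValueError("degenerate sample: null-model Brier score is 0")
    bs_model = ipcw_brier(predictions, records, t_star)
    return (1.0 - bs_model / bs_null) * 100.0


def evaluation_report(
    predictions: Sequence[RiskPrediction],
    records: Sequence[SurvivalRecord],
    t_star: float = HORIZON_18_MONTHS_DAYS,
    tie_rule: Literal["strict", "half"] = "strict",
) -> dict:
    """Bundle CI, Brier, null Brier and IPA into one JSON-serializable dict."""
    records = list(records)
    scores, times, events, _ = _align(list(predictions), records)
    n_pairs = int(((events[:, None] == 1) & (times[None, :] > times[:, None])).sum())
    km = kaplan_meier(records)
    s_null = survival_at(km, min(t_star, float(km.grid.boundaries[-1])))
    null_preds = [
        RiskPrediction(r.subject_id, score=s_null, horizon_survival=s_null)
        for r in records
    ]
    return {
        "ci": concordance_index(predictions, records, tie_rule=tie_rule),
        "brier": ipcw_brier(predictions, records, t_star),
        "brier_null": ipcw_brier(null_preds, records, t_star),
        "ipa_percent": ipa(predictions, records, t_star),
        "n_pairs": n_pairs,
        "horizon_days": t_star,
    }


def read_predictions_csv(path) -> list[RiskPrediction]:
    """Read a `subject_id,score,surv_at_horizon` CSV."""
    df = pd.read_csv(path)
    preds = []
    for row in df.itertuples(index=False):
        horizon = getattr(row, "surv_at_horizon", None)
        if horizon is not None and pd.isna(horizon):
            horizon = None
        preds.append(
            RiskPrediction(
                str(row.subject_id),
                float(row.score),
                None if horizon is None else float(horizon),
            )
        )
    return preds


def write_predictions_csv(predictions: Iterable[RiskPrediction], path) -> None:
    pd.DataFrame(
        [(p.subject_id, p.score, p.horizon_survival) for p in predictions],
        columns=["subject_id", "score", "surv_at_horizon"],
    ).to_csv(path, index=False)
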