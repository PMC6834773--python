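"""The prediction-quality metric battery.

Regression metrics on the confidence score (MAE_c, MSE_c, signed ME_c,
Pearson PCC_c, Spearman SCC_c), correlation metrics on the expression-change
direction (PCC_d, SCC_d against -1/0/1 truth), and the primary ranking
metrics for regulatory-vs-neutral binary classification:

* AUCROC — equal to the Mann-Whitney U statistic divided by n_pos * n_neg,
  with ties counted 0.5 (computed from average ranks);
* AUPRC — average precision (step interpolation), with tied scores processed
  as one block.  Trapezoidal PR interpolation is deliberately not used.

Correlations of constant vectors are reported as NaN ("missing"), never 0.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import EvalReport
from .layouts import SplitLayout
from .models import PredictionSet, binary_scores

LOW_SUPPORT_POSITIVES = 20


class MetricError(ValueError):
    pass


def _check_lengths(a: np.ndarray, b: np.ndarray) -> None:
    if len(a) != len(b):
        raise MetricError(f"length mismatch: {len(a)} vs {len(b)}")
    if len(a) == 0:
        raise MetricError("empty input")


def _corr(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    return float(stats.spearmanr(x, y).statistic)


def regression_metrics(predicted_confidence: Sequence[float],
                       true_confidence: Sequence[float]) -> dict[str, float]:
    p = np.asarray(predicted_confidence, dtype=float)
    t = np.asarray(true_confidence, dtype=float)
    _check_lengths(p, t)
    err = p - t
    return {
        "MAE_c": float(np.mean(np.abs(err))),
        "MSE_c": float(np.mean(err ** 2)),
        "ME_c": float(np.mean(err)),
        "PCC_c": _corr(p, t, "pearson"),
        "SCC_c": _corr(p, t, "spearman"),
    }


def direction_metrics(predicted_direction_score: Sequence[float],
                      true_direction: Sequence[int]) -> dict[str, float]:
    p = np.asarray(predicted_direction_score, dtype=float)
    t = np.asarray(true_direction, dtype=float)
    _check_lengths(p, t)
    return {
        "PCC_d": _corr(p, t, "pearson"),
        "SCC_d": _corr(p, t, "spearman"),
    }


def binarize(true_direction: Sequence[int]) -> np.ndarray:
    """Regulatory-vs-neutral labels: |direction| (the +-1 classes combined
    against the 0 class)."""
    t = np.asarray(true_direction, dtype=int)
    if not np.isin(t, (-1, 0, 1)).all():
        raise MetricError("direction values must be in {-1, 0, 1}")
    return np.abs(t)


def auc_roc(scores: Sequence[float], binary_labels: Sequence[int]) -> float:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(binary_labels, dtype=int)
    _check_lengths(s, y)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        missing = "positive" if n_pos == 0 else "negative"
        raise MetricError(f"AUCROC undefined: no {missing} examples")
    ranks = stats.rankdata(s)  # average ranks handle ties as 0.5
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def au_prc(scores: Sequence[float], binary_labels: Sequence[int]) -> float:
    """Average precision with tied scores grouped into one block."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(binary_labels, dtype=int)
    _check_lengths(s, y)
    n_pos = int(y.sum())
    if n_pos == 0:
        raise MetricError("AUPRC undefined: no positive examples")
    order = np.argsort(-s, kind="mergesort")
    s_sorted, y_sorted = s[order], y[order]
    # block boundaries where the score changes
    boundaries = np.nonzero(np.diff(s_sorted))[0] + 1
    block_ends = np.append(boundaries, len(s_sorted))
    cum_tp = np.cumsum(y_sorted)
    ap = 0.0
    prev_tp = 0
    for end in block_ends:
        tp = int(cum_tp[end - 1])
        if tp > prev_tp:
            precision = tp / end
            ap += (tp - prev_tp) * precision
        prev_tp = tp
    return float(ap / n_pos)


# ---------------------------------------------------------------------------
# dataset-level evaluation


def _metric_battery(pred_conf, true_conf, pred_dir_score, true_dir) -> tuple[dict, list[str]]:
    flags: list[str] = []
    metrics = regression_metrics(pred_conf, true_conf)
    if pred_dir_score is not None:
        metrics.update(direction_metrics(pred_dir_score, true_dir))
    else:
        metrics.update({"PCC_d": float("nan"), "SCC_d": float("nan")})
    labels = binarize(true_dir)
    try:
        metrics["AUCROC"] = auc_roc(pred_conf, labels)
        metrics["AUPRC"] = au_prc(pred_conf, labels)
    except MetricError:
        metrics["AUCROC"] = float("nan")
        metrics["AUPRC"] = float("nan")
        flags.append("single_class")
    if int(labels.sum()) < LOW_SUPPORT_POSITIVES:
        flags.append("low_support")
    return metrics, flags


def evaluate(
    prediction_set: PredictionSet,
    dataset,
    layout: SplitLayout,
    direction_predictions: PredictionSet | None = None,
) -> list[EvalReport]:
    """One report per reporter over its validation SNVs, plus a pooled one.

    ``prediction_set`` must cover every SNV of the dataset (predictions on
    training rows are ignored).  Reporters with an empty validation set are
    omitted.  Reporters whose validation set contains a single class get NaN
    ranking metrics and a ``single_class`` flag rather than fabricated values.
    """
    index = {sid: i for i, sid in enumerate(prediction_set.snv_index)}
    val_ids = [sid for sid, lab in zip(layout.snv_ids, layout.labels) if lab == 1]
    missing = [sid for sid in val_ids if sid not in index]
    if missing:
        raise MetricError(
            f"{len(missing)} validation SNVs lack predictions, e.g. {missing[0]}"
        )
    conf = binary_scores(prediction_set)
    dir_score = None
    if direction_predictions is not None:
        dir_index = {sid: i for i, sid in enumerate(direction_predictions.snv_index)}
        dir_score = (direction_predictions.predicted_direction_score, dir_index)

    by_rep: dict[str, list] = {}
    snv_by_id = {s.snv_id: s for s in dataset.snvs}
    for sid in val_ids:
        by_rep.setdefault(snv_by_id[sid].reporter_id, []).append(sid)

    reports: list[EvalReport] = []
    pooled_ids: list[str] = []
    for rep in dataset.reporters:
        ids = by_rep.get(rep.reporter_id, [])
        if not ids:
            continue
        pooled_ids.extend(ids)
        reports.append(_scope_report(rep.reporter_id, ids, snv_by_id, index,
                                     conf, dir_score))
    reports.append(_scope_report("pooled", pooled_ids, snv_by_id, index,
                                 conf, dir_score))
    return reports


def _scope_report(scope, ids, snv_by_id, index, conf, dir_score) -> EvalReport:
    rows = [index[sid] for sid in ids]
    true_conf = np.array([snv_by_id[sid].confidence for sid in ids])
    true_dir = np.array([snv_by_id[sid].direction for sid in ids])
    pred_conf = conf[rows]
    pred_dir = None
    if dir_score is not None:
        scores, dir_index = dir_score
        pred_dir = np.array([scores[dir_index[sid]] for sid in ids])
    metrics, flags = _metric_battery(pred_conf, true_conf, pred_dir, true_dir)
    return EvalReport(
        scope=scope,
        metrics=metrics,
        n=len(ids),
        n_positive=int(np.abs(true_dir).sum()),
        flags=tuple(flags),
    )


def reports_to_frame(reports: Sequence[EvalReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        for metric, value in r.metrics.items():
            rows.append((r.scope, metric, value, r.n, r.n_positive,
                         ",".join(r.flags)))
    return pd.DataFrame(
        rows, columns=["scope", "metric", "value", "n", "n_positive", "flags"]
    )


def reports_to_json(reports: Sequence[EvalReport], path: str | Path) -> None:
    payload = [
        {
            "scope": r.scope,
            "metrics": {k: (None if not np.isfinite(v) else v)
                        for k, v in r.metrics.items()},
            "n": r.n,
            "n_positive": r.n_positive,
            "flags": list(r.flags),
        }
        for r in reports
    ]
    Path(path).write_text(json.dumps(payload, indent=2))
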