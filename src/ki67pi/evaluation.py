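"""Classification metrics, PI error metrics, and tabular reports.

Fragment classification is scored with accuracy, precision, recall and F1
from the confusion counts; ranking quality with AUROC.  PI estimates are
scored against the count-based ground truth with MAE and RMSE,

    MAE  = (1/N) sum |y_i - x_i|
    RMSE = sqrt((1/N) sum (y_i - x_i)^2),

a percentile-bootstrap 95% confidence interval for the MAE (lower bound
clipped at 0, since the MAE cannot be negative), and the count of *invalid*
estimations — slides missed by more than 0.2 absolute, the reliability
criterion under which an automated read would be clinically misleading.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from ki67pi.io_annotations import GroundTruthPI
from ki67pi.segmentation import PIEstimate

#: Absolute PI error beyond which an estimate counts as invalid.
INVALID_THRESHOLD = 0.2


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @classmethod
    def from_labels(cls, pred: np.ndarray, truth: np.ndarray) -> "ConfusionCounts":
        pred = np.asarray(pred).ravel().astype(bool)
        truth = np.asarray(truth).ravel().astype(bool)
        if pred.shape != truth.shape:
            raise ValueError(f"length mismatch: {pred.shape[0]} vs {truth.shape[0]}")
        return cls(
            tp=int((pred & truth).sum()),
            tn=int((~pred & ~truth).sum()),
            fp=int((pred & ~truth).sum()),
            fn=int((~pred & truth).sum()),
        )


@dataclass(frozen=True)
class ClassificationMetrics:
    """Accuracy/precision/recall/F1; ``None`` marks an undefined ratio.

    A zero denominator (e.g. precision with no positive predictions) yields
    ``None`` rather than 0 — averaging a silent 0 into a summary table would
    bias it.
    """

    accuracy: float | None
    precision: float | None
    recall: float | None
    f1: float | None
    counts: ConfusionCounts


def classification_metrics(pred, truth) -> ClassificationMetrics:
    """Confusion-count metrics for binary fragment labels.

    Accepts arrays or anything with a ``labels`` attribute (FragmentLabels,
    PredictionMap).
    """
    pred = getattr(pred, "labels", pred)
    truth = getattr(truth, "labels", truth)
    c = ConfusionCounts.from_labels(np.asarray(pred), np.asarray(truth))
    n = c.tp + c.tn + c.fp + c.fn

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    accuracy = ratio(c.tp + c.tn, n)
    precision = ratio(c.tp, c.tp + c.fp)
    recall = ratio(c.tp, c.tp + c.fn)
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return ClassificationMetrics(
        accuracy=accuracy, precision=precision, recall=recall, f1=f1, counts=c
    )


def roc_auc(scores, truth) -> float:
    """Area under the ROC curve of fragment scores against binary truth.

    Equals the Mann-Whitney statistic: the probability that a random
    positive fragment outscores a random negative one, ties counted half.
    """
    scores = np.asarray(getattr(scores, "scores", scores), dtype=float).ravel()
    truth = np.asarray(getattr(truth, "labels", truth)).ravel()
    if scores.shape != truth.shape:
        raise ValueError("scores and truth lengths differ")
    if np.unique(truth).size < 2:
        raise ValueError("AUROC undefined: truth contains a single class")
    return float(roc_auc_score(truth, scores))


@dataclass
class PIErrorReport:
    """Aggregate PI error metrics over a slide set."""

    slide_ids: list[str]
    errors: np.ndarray  # per-slide |estimate - truth|
    mae: float
    rmse: float
    ci_low: float
    ci_high: float
    n_invalid: int

    @property
    def n_slides(self) -> int:
        return len(self.slide_ids)


def _as_pi(value) -> float:
    if isinstance(value, PIEstimate):
        return value.pi
    if isinstance(value, GroundTruthPI):
        return value.pi
    return float(value)


def pi_errors(
    estimates: Mapping[str, "PIEstimate | float"],
    truths: Mapping[str, "GroundTruthPI | float"],
    n_bootstrap: int = 10_000,
    seed: int = 0,
    invalid_threshold: float = INVALID_THRESHOLD,
) -> PIErrorReport:
    """MAE, RMSE, bootstrap 95% CI of the MAE, and invalid-estimate count.

    ``estimates`` and ``truths`` are keyed by slide id and must cover the
    same slides.  The CI is a seeded percentile bootstrap over slides with
    the lower bound clipped at 0; invalid estimates are those with absolute
    error strictly greater than ``invalid_threshold``.
    """
    if set(estimates) != set(truths):
        missing = set(estimates) ^ set(truths)
        raise ValueError(f"estimate/truth slide sets differ on: {sorted(missing)}")
    if not estimates:
        raise ValueError("no slides to evaluate")
    slide_ids = sorted(estimates)
    est = np.array([_as_pi(estimates[s]) for s in slide_ids])
    tru = np.array([_as_pi(truths[s]) for s in slide_ids])
    errors = np.abs(est - tru)
    mae = float(errors.mean())
    rmse = float(np.sqrt(np.mean(errors**2)))

    rng = np.random.default_rng(seed)
    resamples = rng.integers(0, errors.size, size=(n_bootstrap, errors.size))
    boot_maes = errors[resamples].mean(axis=1)
    ci_low = max(0.0, float(np.percentile(boot_maes, 2.5)))
    ci_high = float(np.percentile(boot_maes, 97.5))

    return PIErrorReport(
        slide_ids=slide_ids,
        errors=errors,
        mae=mae,
        rmse=rmse,
        ci_low=ci_low,
        ci_high=ci_high,
        n_invalid=int((errors > invalid_threshold).sum()),
    )


def build_report(rows: Sequence[Mapping]) -> pd.DataFrame:
    """Flat table of per-method results, one row per (subset, method, ...).

    Each row may mix keys from a :class:`PIErrorReport` and/or
    :class:`ClassificationMetrics` plus grouping keys such as ``subset``,
    ``model``, ``window`` and ``biased``; rows are kept as given, sorted by
    whichever grouping keys are present.
    """
    columns = [
        "subset", "model", "window", "biased",
        "accuracy", "precision", "recall", "f1",
        "mae", "ci_low", "ci_high", "rmse", "n_invalid", "n_slides",
    ]
    records = []
    for row in rows:
        rec = {}
        for key in columns:
            if key in row:
                rec[key] = row[key]
            elif hasattr(row.get("report"), key):
                rec[key] = getattr(row["report"], key)
        records.append(rec)
    df = pd.DataFrame.from_records(records)
    df = df.reindex(columns=[c for c in columns if c in df.columns])
    sort_keys = [c for c in ("subset", "model", "window", "biased") if c in df.columns]
    if sort_keys and len(df):
        df = df.sort_values(sort_keys, kind="stable").reset_index(drop=True)
    return df


def report_to_markdown(df: pd.DataFrame) -> str:
    return df.to_markdown(index=False)
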