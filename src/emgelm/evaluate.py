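"""Metrics, repetition-based splitting and experiment orchestration.

Two complementary accuracy metrics are used throughout.  Overall accuracy is
the plain fraction of correctly labeled windows; because rest dominates
cue-driven sEMG recordings it is biased upward by the (easy) rest class.
Weighted accuracy is the unweighted mean of per-class recalls over the
classes present in the test set, removing that bias.  For the reliable
classifier variants, abstained windows are excluded from both metrics and
reported separately as the non-reliable-data rate.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .classify import (
    ABSTAIN,
    ElmModel,
    predict,
    reliable_predict,
    train_elm,
    train_relm,
)
from .features import FeatureTable, WindowSpec, segment_and_extract
from .preprocess import AvtConfig, GlrConfig, avt_filter, glr_relabel
from .synthetic import EmgRecording

logger = logging.getLogger("emgelm")

VARIANTS = ("elm", "relm", "r-elm", "r-relm")

#: Soft sanity band (percent) for reliable-variant discard rates.
DISCARD_SANITY_BAND = (2.0, 25.0)

REPORT_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class SplitPlan:
    """Which repetition ids train and which test."""

    train_repetitions: frozenset
    test_repetitions: frozenset
    description: str = ""

    def __post_init__(self) -> None:
        train = frozenset(self.train_repetitions)
        test = frozenset(self.test_repetitions)
        object.__setattr__(self, "train_repetitions", train)
        object.__setattr__(self, "test_repetitions", test)
        if not train or not test:
            raise ValueError("both repetition sets must be non-empty")
        if train & test:
            raise ValueError(f"overlapping repetition sets: {sorted(train & test)}")

    @classmethod
    def default_for(cls, repetition_ids) -> "SplitPlan":
        """{1,3,4,6}/{2,5} for 6-repetition assays, else first ~66% to train."""
        reps = sorted(set(int(r) for r in np.unique(repetition_ids)))
        if reps == [1, 2, 3, 4, 5, 6]:
            return cls(frozenset({1, 3, 4, 6}), frozenset({2, 5}),
                       "repetitions 1,3,4,6 train / 2,5 test")
        k = max(1, min(len(reps) - 1, int(np.ceil(len(reps) * 2 / 3))))
        return cls(frozenset(reps[:k]), frozenset(reps[k:]),
                   f"first {k} of {len(reps)} repetitions train")


@dataclass
class EvaluationReport:
    """Accuracy summary for one classifier variant on one test block."""

    variant: str
    overall_accuracy: float
    weighted_accuracy: float
    per_class_recall: dict
    confusion: np.ndarray
    class_ids: np.ndarray
    split_descriptor: str = ""
    discard_rate: float | None = None
    n_test: int = 0

    def to_dict(self) -> dict:
        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "variant": self.variant,
            "overall_accuracy": self.overall_accuracy,
            "weighted_accuracy": self.weighted_accuracy,
            "per_class_recall": {int(k): v for k, v in self.per_class_recall.items()},
            "confusion": self.confusion.tolist(),
            "class_ids": [int(c) for c in self.class_ids],
            "split_descriptor": self.split_descriptor,
            "discard_rate": self.discard_rate,
            "n_test": self.n_test,
        }


def _select(true_labels, predicted_labels, abstain_policy):
    y, p = np.asarray(true_labels), np.asarray(predicted_labels)
    if y.shape != p.shape:
        raise ValueError("label streams differ in length")
    if abstain_policy == "exclude":
        keep = p != ABSTAIN
        return y[keep], p[keep]
    if abstain_policy == "count_as_error":
        return y, p
    raise ValueError(f"unknown abstain_policy {abstain_policy!r}")


def overall_accuracy(true_labels, predicted_labels, abstain_policy="exclude") -> float:
    """Correct / total x 100 over the population chosen by ``abstain_policy``."""
    y, p = _select(true_labels, predicted_labels, abstain_policy)
    if y.size == 0:
        raise ValueError("no samples to evaluate (everything abstained?)")
    return float(np.mean(y == p) * 100.0)


def weighted_accuracy(true_labels, predicted_labels, class_ids=None,
                      abstain_policy="exclude") -> float:
    """Unweighted mean of per-class recalls, in percent.

    Classes with no test sample (after abstention handling) are excluded
    from the mean with a logged notice.
    """
    y, p = _select(true_labels, predicted_labels, abstain_policy)
    if class_ids is None:
        class_ids = np.unique(np.asarray(true_labels))
    recalls = []
    skipped = []
    for c in class_ids:
        n_c = np.sum(y == c)
        if n_c == 0:
            skipped.append(int(c))
            continue
        recalls.append(np.sum((y == c) & (p == c)) / n_c)
    if skipped:
        logger.info("weighted_accuracy: classes %s have no test samples; excluded",
                    skipped)
    if not recalls:
        raise ValueError("no class has any test sample")
    return float(np.mean(recalls) * 100.0)


def per_class_recall(true_labels, predicted_labels, class_ids,
                     abstain_policy="exclude") -> dict:
    y, p = _select(true_labels, predicted_labels, abstain_policy)
    out = {}
    for c in class_ids:
        n_c = np.sum(y == c)
        if n_c:
            out[int(c)] = float(np.sum((y == c) & (p == c)) / n_c * 100.0)
    return out


def confusion_matrix(true_labels, predicted_labels, class_ids,
                     abstain_policy="exclude") -> np.ndarray:
    """C x C count matrix, rows = true class, columns = predicted class."""
    y, p = _select(true_labels, predicted_labels, abstain_policy)
    class_ids = np.asarray(class_ids)
    idx = {int(c): i for i, c in enumerate(class_ids)}
    cm = np.zeros((class_ids.size, class_ids.size), dtype=np.int64)
    for yt, yp in zip(y, p):
        cm[idx[int(yt)], idx[int(yp)]] += 1
    return cm


def split_by_repetition(table: FeatureTable, plan: SplitPlan):
    """Route windows into train/test tables by their repetition id."""
    if table.repetitions is None:
        raise ValueError("feature table carries no repetition ids")
    present = set(int(r) for r in np.unique(table.repetitions))
    missing = sorted((plan.train_repetitions | plan.test_repetitions) - present)
    if missing:
        raise ValueError(f"repetition ids {missing} absent from the data")
    reps = table.repetitions
    train_mask = np.isin(reps, list(plan.train_repetitions))
    test_mask = np.isin(reps, list(plan.test_repetitions))
    return table.subset(train_mask), table.subset(test_mask)


def _report(variant, test_y, pred, class_ids, split_desc, discard_rate=None):
    return EvaluationReport(
        variant=variant,
        overall_accuracy=overall_accuracy(test_y, pred),
        weighted_accuracy=weighted_accuracy(test_y, pred, class_ids),
        per_class_recall=per_class_recall(test_y, pred, class_ids),
        confusion=confusion_matrix(test_y, pred, class_ids),
        class_ids=np.asarray(class_ids),
        split_descriptor=split_desc,
        discard_rate=discard_rate,
        n_test=int(np.asarray(test_y).size),
    )


def run_experiment(
    recording: EmgRecording,
    *,
    window: WindowSpec | None = None,
    avt: AvtConfig | None = None,
    relabel: bool = True,
    glr: GlrConfig | None = None,
    label_source: str | None = None,
    split: SplitPlan | None = None,
    L: int = 200,
    C_reg: float = 1.0,
    seed: int = 0,
    filter_signal: bool = True,
) -> dict:
    """Run the full pipeline and evaluate all four classifier variants.

    Stages: AVT filter -> (optional) GLR relabel -> windowed features ->
    repetition split -> ELM / RELM training -> plain and reliable prediction
    -> metrics.  Returns ``{variant: EvaluationReport}`` with variants
    ``elm``, ``relm``, ``r-elm``, ``r-relm``; ``discard_rate`` is present
    only for the two reliable variants.  Fully seeded and deterministic.
    ``label_source`` defaults to ``refined`` when relabeling, else ``stim``.
    """
    window = window or WindowSpec()
    avt = avt or AvtConfig()
    glr = glr or GlrConfig()

    try:
        filtered = avt_filter(recording.signal, recording.sample_rate_hz, avt) \
            if filter_signal else np.abs(recording.signal)
    except Exception as exc:
        raise RuntimeError(f"stage 'filter' failed: {exc}") from exc

    work = EmgRecording(
        signal=filtered,
        sample_rate_hz=recording.sample_rate_hz,
        stim_labels=recording.stim_labels,
        true_labels=recording.true_labels,
        repetition_ids=recording.repetition_ids,
        refined_labels=recording.refined_labels,
    )
    if relabel:
        try:
            work.refined_labels = glr_relabel(
                recording.signal, recording.stim_labels,
                recording.sample_rate_hz, glr)
        except Exception as exc:
            raise RuntimeError(f"stage 'relabel' failed: {exc}") from exc
    if label_source is None:
        label_source = "refined" if relabel else "stim"

    try:
        table = segment_and_extract(work, window, label_source)
    except Exception as exc:
        raise RuntimeError(f"stage 'features' failed: {exc}") from exc

    plan = split or SplitPlan.default_for(work.repetition_ids)
    try:
        train_tbl, test_tbl = split_by_repetition(table, plan)
    except Exception as exc:
        raise RuntimeError(f"stage 'split' failed: {exc}") from exc

    class_ids = np.unique(table.y)
    reports = {}
    for variant in ("elm", "relm"):
        try:
            if variant == "elm":
                model = train_elm(train_tbl, L, seed=seed)
            else:
                model = train_relm(train_tbl, L, C_reg=C_reg, seed=seed)
        except Exception as exc:
            raise RuntimeError(f"stage 'train:{variant}' failed: {exc}") from exc
        _, pred = predict(model, test_tbl)
        reports[variant] = _report(variant, test_tbl.y, pred, class_ids,
                                   plan.description)
        r_pred, profile = reliable_predict(model, test_tbl)
        discard_pct = profile.discard_rate * 100.0
        lo, hi = DISCARD_SANITY_BAND
        if not (lo <= discard_pct <= hi):
            warnings.warn(
                f"r-{variant}: discard rate {discard_pct:.1f}% outside the "
                f"{lo}-{hi}% sanity band")
        reports[f"r-{variant}"] = _report(
            f"r-{variant}", test_tbl.y, r_pred, class_ids, plan.description,
            discard_rate=discard_pct)
    return reports


def window_length_metrics(
    recording: EmgRecording,
    spec: WindowSpec,
    *,
    variant: str = "relm",
    L: int = 200,
    C_reg: float = 1.0,
    seed: int = 0,
    label_source: str = "stim",
    split: SplitPlan | None = None,
) -> dict:
    """The six window-length study metrics for one segmentation length.

    The recording is used as-is (filter and relabel beforehand if desired);
    only segmentation, training and evaluation are redone, which is what a
    window-length sweep varies.  Returns training accuracy, overall and
    weighted test accuracy, their reliable counterparts and the
    non-reliable-data rate, all in percent.  Pair with
    :func:`~emgelm.features.sweep_window_lengths` via ``functools.partial``.
    """
    table = segment_and_extract(recording, spec, label_source)
    plan = split or SplitPlan.default_for(recording.repetition_ids)
    train_tbl, test_tbl = split_by_repetition(table, plan)
    if variant == "elm":
        model = train_elm(train_tbl, L, seed=seed)
    elif variant == "relm":
        model = train_relm(train_tbl, L, C_reg=C_reg, seed=seed)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    _, pred = predict(model, test_tbl)
    r_pred, profile = reliable_predict(model, test_tbl)
    return {
        "training_accuracy": training_accuracy(train_tbl, model),
        "overall": overall_accuracy(test_tbl.y, pred),
        "weighted": weighted_accuracy(test_tbl.y, pred),
        "reliable_overall": overall_accuracy(test_tbl.y, r_pred),
        "non_reliable_rate": profile.discard_rate * 100.0,
        "reliable_weighted": weighted_accuracy(test_tbl.y, r_pred),
    }


def training_accuracy(train_tbl: FeatureTable, model: ElmModel) -> float:
    """Overall accuracy of a model on its own training windows, percent."""
    _, pred = predict(model, train_tbl)
    return overall_accuracy(train_tbl.y, pred)


def report_to_json(reports: dict, path=None) -> str:
    """Serialize a ``{variant: EvaluationReport}`` mapping to JSON."""
    payload = {k: v.to_dict() for k, v in reports.items()}
    text = json.dumps(payload, indent=2)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def format_report_table(reports: dict) -> str:
    """Aligned text table, one row per variant."""
    lines = [f"{'variant':<8} {'overall%':>9} {'weighted%':>10} {'discard%':>9} {'n_test':>7}"]
    for name, rep in reports.items():
        disc = f"{rep.discard_rate:9.2f}" if rep.discard_rate is not None else "        -"
        lines.append(
            f"{name:<8} {rep.overall_accuracy:9.2f} {rep.weighted_accuracy:10.2f} "
            f"{disc} {rep.n_test:7d}")
    return "\n".join(lines)
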