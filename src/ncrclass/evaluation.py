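"""Scoring and benchmark harmonization.

Per-class and macro precision/recall/F1 and the multi-category Matthews
correlation coefficient are computed from a confusion matrix with a frozen
class order.  Correctness-overlap (Venn) region counts compare the correct-id
sets of several models over one shared test universe.  Harmonization maps
heterogeneous benchmark label schemes onto a common one (with DROP rules, a
maximum input length, and a similarity filter against a reference training
set) before scoring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .datasets import NcRNARecord, sequence_identity

__all__ = [
    "ConfusionMatrix",
    "EvaluationReport",
    "HarmonizationRules",
    "HarmonizedRecord",
    "confusion",
    "scores",
    "multiclass_mcc",
    "overlap_sets",
    "harmonize",
]

#: row-normalized cells below this value are omitted when rendering
RENDER_THRESHOLD = 0.005


@dataclass
class ConfusionMatrix:
    """K x K counts; rows are true labels, columns predicted labels."""

    counts: np.ndarray
    classes: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError("counts shape does not match the class order")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_normalized(self) -> np.ndarray:
        rows = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            norm = np.where(rows > 0, self.counts / rows, 0.0)
        return norm

    def render(self, omit_below: float = RENDER_THRESHOLD) -> str:
        """Row-normalized text rendering; small cells print blank."""
        norm = self.row_normalized()
        width = max(len(c) for c in self.classes) + 2
        lines = [" " * width + "".join(f"{c:>{width}}" for c in self.classes)]
        for i, cls in enumerate(self.classes):
            cells = [
                f"{v:>{width}.3f}" if v >= omit_below else " " * width
                for v in norm[i]
            ]
            lines.append(f"{cls:>{width}}" + "".join(cells))
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("true\\pred\t" + "\t".join(self.classes) + "\n")
            for cls, row in zip(self.classes, self.counts):
                fh.write(cls + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


@dataclass
class EvaluationReport:
    per_class: dict[str, dict[str, float]]
    macro_precision: float
    macro_recall: float
    macro_f1: float
    mcc: float
    confusion: ConfusionMatrix
    correct_ids: set[str] = field(default_factory=set)

    def to_json(self, path) -> None:
        payload = {
            "per_class": self.per_class,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "mcc": self.mcc,
            "classes": self.confusion.classes,
            "confusion": self.confusion.counts.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def confusion(
    true_labels, predicted_labels, class_order: list[str]
) -> ConfusionMatrix:
    """Count (true, predicted) pairs against a frozen class order."""
    true_labels, predicted_labels = list(true_labels), list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label lists differ in length")
    index = {c: i for i, c in enumerate(class_order)}
    counts = np.zeros((len(class_order), len(class_order)), dtype=np.int64)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index:
            raise ValueError(f"unknown true label {t!r}")
        if p not in index:
            raise ValueError(f"unknown predicted label {p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, classes=list(class_order))


def multiclass_mcc(counts: np.ndarray) -> float:
    """Multi-category Matthews correlation coefficient from a K x K matrix.

    Reduces to the classical binary MCC for K = 2.  A zero denominator
    (a degenerate marginal) yields 0 by convention.
    """
    C = np.asarray(counts, dtype=float)
    s = C.sum()
    c = np.trace(C)
    t = C.sum(axis=1)  # true-class totals
    p = C.sum(axis=0)  # predicted-class totals
    cov = c * s - t @ p
    denom = np.sqrt(s * s - p @ p) * np.sqrt(s * s - t @ t)
    return float(cov / denom) if denom > 0 else 0.0


def scores(cm: ConfusionMatrix) -> EvaluationReport:
    """Per-class and macro precision/recall/F1 plus multiclass MCC.

    Classes absent from both the true and the predicted labels are excluded
    from the macro averages; the F1 of a class with zero precision and zero
    recall is 0.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    C = cm.counts.astype(float)
    diag = np.diag(C)
    colsum = C.sum(axis=0)
    rowsum = C.sum(axis=1)
    per_class: dict[str, dict[str, float]] = {}
    macro_p, macro_r, macro_f = [], [], []
    for i, cls in enumerate(cm.classes):
        if rowsum[i] == 0 and colsum[i] == 0:
            continue  # class never occurs: excluded from macro means
        prec = diag[i] / colsum[i] if colsum[i] > 0 else 0.0
        rec = diag[i] / rowsum[i] if rowsum[i] > 0 else 0.0
        f1 = 2 * prec * rec / (prec + rec) if (prec + rec) > 0 else 0.0
        per_class[cls] = {"precision": prec, "recall": rec, "f1": f1}
        macro_p.append(prec)
        macro_r.append(rec)
        macro_f.append(f1)
    return EvaluationReport(
        per_class=per_class,
        macro_precision=float(np.mean(macro_p)),
        macro_recall=float(np.mean(macro_r)),
        macro_f1=float(np.mean(macro_f)),
        mcc=multiclass_mcc(cm.counts),
        confusion=cm,
    )


def overlap_sets(
    correct_sets: dict[str, set], universe: set
) -> dict[frozenset, int]:
    """Venn region counts for the correct-id sets of several models.

    Returns one count per non-empty model combination (ids correct under
    exactly that combination) plus the ``frozenset()`` region of ids no model
    got right; region counts sum to the universe size.
    """
    names = sorted(correct_sets)
    for name in names:
        extra = correct_sets[name] - universe
        if extra:
            raise ValueError(
                f"ids outside the universe in {name}: {sorted(extra)[:5]}"
            )
    regions = {
        frozenset(combo): 0
        for r in range(1, len(names) + 1)
        for combo in combinations(names, r)
    }
    regions[frozenset()] = 0
    for uid in universe:
        membership = frozenset(n for n in names if uid in correct_sets[n])
        regions[membership] += 1
    return regions


DROP = "DROP"


@dataclass(frozen=True)
class HarmonizationRules:
    """Label mapping and eligibility rules for cross-tool benchmarking."""

    label_map: dict
    max_length: int = 750
    exclude_mature_mirna: bool = False
    similarity_threshold: float = 0.90

    def __post_init__(self) -> None:
        if self.max_length <= 0:
            raise ValueError("max_length must be positive")

    def map_label(self, label: str) -> str:
        if label not in self.label_map:
            raise ValueError(f"unmapped label {label!r}")
        return self.label_map[label]


@dataclass
class HarmonizedRecord:
    id: str
    true_label: str
    predicted_label: str
    correct: bool


def harmonize(
    records: list[NcRNARecord],
    predictions: dict[str, str],
    rules: HarmonizationRules,
    reference: list[NcRNARecord] | None = None,
) -> list[HarmonizedRecord]:
    """Filter and score benchmark records under a common label scheme.

    Records whose true label maps to DROP, that exceed ``max_length``, that
    are mature-length miRNAs when excluded, or that exceed the similarity
    threshold against the reference training set are dropped.  Surviving
    records score as correct when the mapped prediction equals the mapped
    true label; predictions mapping to DROP are incorrect.  The operation is
    idempotent: its output records re-harmonize to themselves.
    """
    out = []
    for rec in records:
        mapped_true = rules.map_label(rec.label)
        if mapped_true == DROP:
            continue
        if rec.length > rules.max_length:
            continue
        if (
            rules.exclude_mature_mirna
            and mapped_true == "miRNA"
            and rec.length <= 30
        ):
            continue
        if reference is not None and any(
            sequence_identity(rec.sequence, ref.sequence)
            > rules.similarity_threshold
            for ref in reference
        ):
            continue
        pred = predictions.get(rec.id)
        if pred is None:
            raise ValueError(f"no prediction for record {rec.id}")
        mapped_pred = rules.map_label(pred)
        out.append(
            HarmonizedRecord(
                id=rec.id,
                true_label=mapped_true,
                predicted_label=mapped_pred,
                correct=(mapped_pred == mapped_true and mapped_pred != DROP),
            )
        )
    return out
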