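"""Dataset construction: labeled FASTA I/O, filtering, redundancy reduction,
balanced splitting and the fine-grained (10-class) relabeling scheme.

The six general classes are lncRNA, miRNA, rRNA, snRNA, snoRNA and tRNA.
The fine-grained scheme splits snoRNA into C/D-box, H/ACA-box and scaRNA,
miRNA into mature (15-30 nt) and precursor (39-6306 nt), and rRNA into short
(5S, 5.8S) and long (23S, 25S, 28S, SSU) subunits.

Redundancy reduction mirrors the CD-HIT-EST recipe: greedy longest-first
clustering at 90% identity with a word length of 7, identity defined as the
maximal number of aligned matches divided by the length of the shorter
sequence.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner

__all__ = [
    "GENERAL_CLASSES",
    "FINE_GRAINED_CLASSES",
    "MIN_LENGTH",
    "MAX_LENGTH",
    "NcRNARecord",
    "DatasetSplit",
    "read_labeled_fasta",
    "write_fasta",
    "write_labels",
    "length_filter",
    "assign_mirna_length_class",
    "sequence_identity",
    "cluster_reduce",
    "make_split",
    "relabel_fine_grained",
    "coarsen_labels",
]

GENERAL_CLASSES = ["lncRNA", "miRNA", "rRNA", "snRNA", "snoRNA", "tRNA"]
FINE_GRAINED_CLASSES = [
    "CD-box snoRNA",
    "HACA-box snoRNA",
    "lncRNA",
    "long rRNA",
    "mature miRNA",
    "precursor miRNA",
    "scaRNA",
    "short rRNA",
    "snRNA",
    "tRNA",
]

MIN_LENGTH = 15
MAX_LENGTH = 11_922

_SHORT_RRNA = {"5S", "5.8S"}
_LONG_RRNA = {"23S", "25S", "28S", "SSU"}
_SNORNA_SUBTYPES = {
    "C/D-Box": "CD-box snoRNA",
    "H/ACA-Box": "HACA-box snoRNA",
    "scaRNA": "scaRNA",
}
_FINE_TO_GENERAL = {
    "CD-box snoRNA": "snoRNA",
    "HACA-box snoRNA": "snoRNA",
    "scaRNA": "snoRNA",
    "mature miRNA": "miRNA",
    "precursor miRNA": "miRNA",
    "short rRNA": "rRNA",
    "long rRNA": "rRNA",
}


@dataclass
class NcRNARecord:
    """One labeled RNA sequence (uppercase IUPAC; DNA 'T' preserved)."""

    id: str
    sequence: str
    label: str
    subtype: str | None = None

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class DatasetSplit:
    train: list[NcRNARecord] = field(default_factory=list)
    validation: list[NcRNARecord] = field(default_factory=list)
    test: list[NcRNARecord] = field(default_factory=list)

    def class_counts(self, partition: str) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rec in getattr(self, partition):
            counts[rec.label] = counts.get(rec.label, 0) + 1
        return counts

    def write_manifest(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("id\tpartition\n")
            for part in ("train", "validation", "test"):
                for rec in getattr(self, part):
                    fh.write(f"{rec.id}\t{part}\n")


def read_labeled_fasta(fasta_path, labels_path) -> list[NcRNARecord]:
    """Read sequences from FASTA and (label, subtype) from a sidecar TSV.

    The TSV has columns id, label and optionally subtype (header optional).
    Every FASTA id must have a label; duplicate ids are an error.
    """
    labels: dict[str, tuple[str, str | None]] = {}
    with open(labels_path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0] in ("id", ""):
                continue
            subtype = row[2] if len(row) > 2 and row[2] else None
            labels[row[0]] = (row[1], subtype)
    records, seen = [], set()
    for entry in SeqIO.parse(str(fasta_path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"duplicate id in FASTA: {entry.id}")
        seen.add(entry.id)
        if entry.id not in labels:
            missing = [
                e.id
                for e in SeqIO.parse(str(fasta_path), "fasta")
                if e.id not in labels
            ]
            raise ValueError(f"missing labels for ids: {', '.join(missing)}")
        label, subtype = labels[entry.id]
        records.append(
            NcRNARecord(
                id=entry.id,
                sequence=str(entry.seq).upper(),
                label=label,
                subtype=subtype,
            )
        )
    return records


def write_fasta(records: list[NcRNARecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def write_labels(records: list[NcRNARecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tlabel\tsubtype\n")
        for rec in records:
            fh.write(f"{rec.id}\t{rec.label}\t{rec.subtype or ''}\n")


def length_filter(
    records: list[NcRNARecord],
    min_length: int = MIN_LENGTH,
    max_length: int = MAX_LENGTH,
) -> list[NcRNARecord]:
    """Keep records with min_length <= length <= max_length (both inclusive)."""
    return [r for r in records if min_length <= r.length <= max_length]


def assign_mirna_length_class(length: int) -> str:
    """miRNA length rule: <=30 nt mature, >=40 nt precursor, 31-39 excluded."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if length <= 30:
        return "mature"
    if length >= 40:
        return "precursor"
    return "excluded"


_aligner = PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1.0
_aligner.mismatch_score = 0.0
_aligner.open_gap_score = 0.0
_aligner.extend_gap_score = 0.0


def sequence_identity(a: str, b: str) -> float:
    """Fraction of identical aligned positions over the shorter length.

    The aligner maximizes the match count (match 1, mismatch/gap 0), so the
    score equals the best achievable number of identities.
    """
    if not a or not b:
        return 0.0
    matches = _aligner.score(a.upper(), b.upper())
    return matches / min(len(a), len(b))


def _words(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def cluster_reduce(
    records: list[NcRNARecord],
    identity: float = 0.90,
    word_length: int = 7,
) -> list[NcRNARecord]:
    """Greedy longest-first redundancy reduction at an identity threshold.

    Records are visited longest-first (id as tie-break); each joins the first
    existing cluster whose representative exceeds the identity threshold
    (after a shared-word prefilter), otherwise it founds a new cluster.
    Representatives are returned in their visiting order.
    """
    if not records:
        raise ValueError("no records to cluster")
    ordered = sorted(records, key=lambda r: (-r.length, r.id))
    reps: list[NcRNARecord] = []
    rep_words: list[set[str]] = []
    for rec in ordered:
        w = _words(rec.sequence.upper(), word_length)
        placed = False
        for rep, rw in zip(reps, rep_words):
            if w and rw and not (w & rw):
                continue  # no shared word: identity cannot reach the threshold
            if sequence_identity(rec.sequence, rep.sequence) > identity:
                placed = True
                break
        if not placed:
            reps.append(rec)
            rep_words.append(w)
    return reps


def _balanced_draw(
    groups: dict[str, list[NcRNARecord]], n: int, rng: np.random.Generator
) -> tuple[list[NcRNARecord], dict[str, list[NcRNARecord]]]:
    """Draw n records spread equally over subtype groups (sorted order gets
    the remainder); returns (drawn, leftover groups)."""
    keys = sorted(groups)
    quota = {k: n // len(keys) for k in keys}
    for k in keys[: n % len(keys)]:
        quota[k] += 1
    # groups too small to fill their quota hand the surplus to the others
    short = sum(max(0, quota[k] - len(groups[k])) for k in keys)
    for k in keys:
        quota[k] = min(quota[k], len(groups[k]))
    while short > 0:
        progressed = False
        for k in keys:
            if short == 0:
                break
            if quota[k] < len(groups[k]):
                quota[k] += 1
                short -= 1
                progressed = True
        if not progressed:
            break
    drawn, leftover = [], {}
    for k in keys:
        pool = groups[k]
        idx = rng.permutation(len(pool))
        take = set(idx[: quota[k]].tolist())
        drawn.extend(pool[i] for i in sorted(take))
        leftover[k] = [pool[i] for i in range(len(pool)) if i not in take]
    return drawn, leftover


def make_split(
    records: list[NcRNARecord],
    per_class_total: int | None = None,
    test_per_class: int = 1000,
    seed: int = 0,
) -> DatasetSplit:
    """Per-class split: fixed-size test set, then 90/10 train/validation.

    Classes with fewer than ``per_class_total`` records contribute everything
    they have (with a warning); fewer than ``test_per_class`` records in a
    class is an error.  Where subtypes exist the draws are subtype-balanced
    with deterministic remainder handling.
    """
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[NcRNARecord]] = {}
    for rec in records:
        by_class.setdefault(rec.label, []).append(rec)
    split = DatasetSplit()
    for label in sorted(by_class):
        pool = sorted(by_class[label], key=lambda r: r.id)
        if per_class_total is not None:
            if len(pool) < per_class_total:
                warnings.warn(
                    f"class {label}: only {len(pool)} records available "
                    f"(requested {per_class_total})",
                    stacklevel=2,
                )
            else:
                groups = {}
                for rec in pool:
                    groups.setdefault(rec.subtype or "", []).append(rec)
                pool, _ = _balanced_draw(groups, per_class_total, rng)
        if len(pool) < test_per_class:
            raise ValueError(
                f"class {label}: {len(pool)} records < test size {test_per_class}"
            )
        groups = {}
        for rec in pool:
            groups.setdefault(rec.subtype or "", []).append(rec)
        test, remaining = _balanced_draw(groups, test_per_class, rng)
        rest = [r for grp in remaining.values() for r in grp]
        rest.sort(key=lambda r: r.id)
        n_val = len(rest) // 10
        groups = {}
        for rec in rest:
            groups.setdefault(rec.subtype or "", []).append(rec)
        val, train_groups = _balanced_draw(groups, n_val, rng)
        train = [r for grp in train_groups.values() for r in grp]
        train.sort(key=lambda r: r.id)
        split.test.extend(test)
        split.validation.extend(val)
        split.train.extend(train)
    return split


def relabel_fine_grained(records: list[NcRNARecord]) -> list[NcRNARecord]:
    """Expand 6-class labels to the 10-class scheme.

    snoRNA and rRNA need a known subtype; miRNA is split by length
    (15-30 mature, >=40 precursor); lncRNA, snRNA and tRNA pass through.
    """
    out = []
    for rec in records:
        if rec.label == "snoRNA":
            if rec.subtype not in _SNORNA_SUBTYPES:
                raise ValueError(
                    f"record {rec.id}: unknown snoRNA subtype {rec.subtype!r}"
                )
            label = _SNORNA_SUBTYPES[rec.subtype]
        elif rec.label == "rRNA":
            if rec.subtype in _SHORT_RRNA:
                label = "short rRNA"
            elif rec.subtype in _LONG_RRNA:
                label = "long rRNA"
            else:
                raise ValueError(
                    f"record {rec.id}: unknown rRNA subtype {rec.subtype!r}"
                )
        elif rec.label == "miRNA":
            cls = assign_mirna_length_class(rec.length)
            if cls == "excluded":
                raise ValueError(
                    f"record {rec.id}: miRNA length {rec.length} falls in the "
                    "excluded 31-39 nt gap"
                )
            label = f"{cls} miRNA"
        elif rec.label in ("lncRNA", "snRNA", "tRNA"):
            label = rec.label
        else:
            raise ValueError(f"record {rec.id}: unknown label {rec.label!r}")
        out.append(
            NcRNARecord(
                id=rec.id, sequence=rec.sequence, label=label, subtype=rec.subtype
            )
        )
    return out


def coarsen_labels(records: list[NcRNARecord]) -> list[NcRNARecord]:
    """Map fine-grained labels back to their parent general class."""
    return [
        NcRNARecord(
            id=r.id,
            sequence=r.sequence,
            label=_FINE_TO_GENERAL.get(r.label, r.label),
            subtype=r.subtype,
        )
        for r in records
    ]
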