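"""Confusion matrices, macro scores, multiclass MCC, overlaps, harmonization."""

import numpy as np
import pytest
from sklearn.metrics import matthews_corrcoef, precision_recall_fscore_support

from ncrclass.datasets import NcRNARecord
from ncrclass.evaluation import (
    ConfusionMatrix,
    HarmonizationRules,
    confusion,
    harmonize,
    multiclass_mcc,
    overlap_sets,
    scores,
)


def _labels_from_matrix(counts):
    """Expand a confusion matrix back into (true, predicted) label vectors."""
    true, pred = [], []
    for i, row in enumerate(counts):
        for j, n in enumerate(row):
            true += [i] * int(n)
            pred += [j] * int(n)
    return np.asarray(true), np.asarray(pred)


def test_confusion_examples():
    classes = ["a", "b", "c"]
    perfect = confusion(
        ["a"] * 10 + ["b"] * 10 + ["c"] * 10,
        ["a"] * 10 + ["b"] * 10 + ["c"] * 10,
        classes,
    )
    assert np.array_equal(perfect.counts, 10 * np.eye(3, dtype=int))
    all_a = confusion(["a", "b", "c"], ["a", "a", "a"], classes)
    assert all_a.counts[:, 0].tolist() == [1, 1, 1]
    assert not all_a.counts[:, 1:].any()
    with pytest.raises(ValueError, match="unknown"):
        confusion(["a"], ["z"], classes)


def test_row_normalized_diagonal_equals_recall():
    cm = confusion(
        ["a"] * 8 + ["b"] * 4, ["a"] * 6 + ["b"] * 2 + ["b"] * 3 + ["a"],
        ["a", "b"],
    )
    rep = scores(cm)
    norm = cm.row_normalized()
    for i, cls in enumerate(cm.classes):
        assert norm[i, i] == pytest.approx(rep.per_class[cls]["recall"])


def test_render_omits_small_cells():
    cm = ConfusionMatrix(np.array([[999, 1], [0, 1000]]), ["a", "b"])
    text = cm.render()
    assert "0.001" not in text and "0.999" in text


def test_scores_identity_and_anticorrelated():
    ident = ConfusionMatrix(np.eye(4, dtype=int) * 5, list("abcd"))
    rep = scores(ident)
    assert rep.macro_f1 == rep.macro_precision == rep.macro_recall == 1.0
    assert rep.mcc == pytest.approx(1.0)
    swapped = ConfusionMatrix(np.array([[0, 10], [10, 0]]), ["a", "b"])
    assert scores(swapped).mcc == pytest.approx(-1.0)


def test_scores_match_sklearn_oracle(rng):
    """Per-class and macro scores plus MCC agree with sklearn to 1e-10."""
    for _ in range(100):
        k = int(rng.integers(2, 11))
        counts = rng.integers(0, 20, size=(k, k))
        counts[np.arange(k), np.arange(k)] += 1  # no fully absent class
        cm = ConfusionMatrix(counts, [str(i) for i in range(k)])
        rep = scores(cm)
        true, pred = _labels_from_matrix(counts)
        p, r, f, _ = precision_recall_fscore_support(
            true, pred, labels=range(k), zero_division=0
        )
        for i in range(k):
            pc = rep.per_class[str(i)]
            assert abs(pc["precision"] - p[i]) < 1e-10
            assert abs(pc["recall"] - r[i]) < 1e-10
            assert abs(pc["f1"] - f[i]) < 1e-10
        assert abs(rep.macro_f1 - f.mean()) < 1e-10
        assert abs(rep.mcc - matthews_corrcoef(true, pred)) < 1e-10


def test_binary_mcc_equals_classical_formula(rng):
    for _ in range(50):
        tp, fn, fp, tn = rng.integers(1, 50, size=4)
        counts = np.array([[tp, fn], [fp, tn]])
        classical = (tp * tn - fp * fn) / np.sqrt(
            float((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        )
        assert abs(multiclass_mcc(counts) - classical) < 1e-10


def test_scores_permutation_invariance(rng):
    counts = rng.integers(0, 15, size=(4, 4)) + np.eye(4, dtype=int)
    classes = list("abcd")
    rep = scores(ConfusionMatrix(counts, classes))
    perm = [2, 0, 3, 1]
    rep_p = scores(
        ConfusionMatrix(counts[np.ix_(perm, perm)], [classes[i] for i in perm])
    )
    for i, cls in enumerate(classes):
        assert rep.per_class[cls] == rep_p.per_class[cls]
    assert rep.mcc == pytest.approx(rep_p.mcc, abs=1e-12)
    assert rep.macro_f1 == pytest.approx(rep_p.macro_f1, abs=1e-12)


def test_scores_excludes_absent_classes():
    counts = np.array([[5, 0, 0], [0, 5, 0], [0, 0, 0]])
    rep = scores(ConfusionMatrix(counts, ["a", "b", "ghost"]))
    assert "ghost" not in rep.per_class
    assert rep.macro_f1 == 1.0
    with pytest.raises(ValueError, match="empty"):
        scores(ConfusionMatrix(np.zeros((2, 2), dtype=int), ["a", "b"]))


def test_micro_accuracy_identities(rng):
    counts = rng.integers(0, 10, size=(3, 3)) + np.eye(3, dtype=int)
    cm = ConfusionMatrix(counts, list("abc"))
    assert np.trace(cm.counts) / cm.total == pytest.approx(
        float(np.trace(counts)) / counts.sum()
    )


def test_overlap_sets_examples():
    universe = {"a", "b", "c", "d", "e"}
    twin = {"m1": set("abcde"), "m2": set("abcde")}
    regions = overlap_sets(twin, universe)
    assert regions[frozenset(["m1", "m2"])] == 5
    assert regions[frozenset(["m1"])] == regions[frozenset(["m2"])] == 0
    disjoint = overlap_sets({"m1": {"a"}, "m2": {"b"}}, {"a", "b", "c"})
    assert disjoint[frozenset(["m1"])] == 1
    assert disjoint[frozenset(["m2"])] == 1
    assert disjoint[frozenset()] == 1
    with pytest.raises(ValueError, match="outside"):
        overlap_sets({"m": {"zzz"}}, {"a"})


def test_overlap_sets_match_enumeration(rng):
    universe = {f"id{i}" for i in range(20)}
    ids = sorted(universe)
    sets = {
        f"m{j}": {ids[i] for i in rng.choice(20, size=8, replace=False)}
        for j in range(4)
    }
    regions = overlap_sets(sets, universe)
    assert sum(regions.values()) == 20
    for uid in universe:  # brute-force per-id membership
        member = frozenset(n for n, s in sets.items() if uid in s)
        assert regions[member] >= 1


_RULES = HarmonizationRules(
    label_map={
        "CD-Box": "snoRNA", "HACA-Box": "snoRNA", "scaRNA": "snoRNA",
        "5S rRNA": "rRNA", "5.8S rRNA": "rRNA", "tRNA": "tRNA",
        "miRNA": "miRNA", "Ribozyme": "DROP", "Intron gpI": "DROP",
        "Intron gpII": "DROP", "Riboswitch": "DROP", "IRES": "DROP",
        "Leader": "DROP",
        # mapped targets map to themselves so harmonization is idempotent
        "snoRNA": "snoRNA", "rRNA": "rRNA",
    },
    max_length=750,
)


def _bench_record(i, label, length):
    return NcRNARecord(id=f"b{i}", sequence="ACGU" * (length // 4), label=label)


def test_harmonize_label_merging_and_drops():
    records = [
        _bench_record(0, "CD-Box", 100),
        _bench_record(1, "tRNA", 80),
        _bench_record(2, "Ribozyme", 100),
        _bench_record(3, "5S rRNA", 120),
        _bench_record(4, "miRNA", 800),  # over the length cap
    ]
    predictions = {
        "b0": "HACA-Box",   # same merged class -> correct
        "b1": "Riboswitch",  # label absent from the other model -> incorrect
        "b3": "5.8S rRNA",
    }
    out = harmonize(records, predictions, _RULES)
    assert [h.id for h in out] == ["b0", "b1", "b3"]
    by_id = {h.id: h for h in out}
    assert by_id["b0"].correct and by_id["b0"].true_label == "snoRNA"
    assert not by_id["b1"].correct
    assert by_id["b3"].correct  # both subtypes merge to rRNA
    with pytest.raises(ValueError, match="unmapped"):
        harmonize([_bench_record(9, "mystery", 50)], {"b9": "tRNA"}, _RULES)


def test_harmonize_similarity_filter_and_idempotence():
    reference = [_bench_record(100, "tRNA", 80)]
    records = [
        _bench_record(0, "tRNA", 80),  # identical to the reference -> dropped
        NcRNARecord(id="b1", sequence="GAUUACA" * 12, label="tRNA"),
    ]
    predictions = {"b0": "tRNA", "b1": "tRNA"}
    out = harmonize(records, predictions, _RULES, reference=reference)
    assert [h.id for h in out] == ["b1"]
    # idempotence: harmonizing the already-harmonized labels changes nothing
    again = harmonize(
        [NcRNARecord(id=h.id, sequence="GAUUACA" * 12, label=h.true_label)
         for h in out],
        {h.id: h.predicted_label for h in out},
        _RULES,
    )
    assert [(h.true_label, h.predicted_label, h.correct) for h in again] == [
        (h.true_label, h.predicted_label, h.correct) for h in out
    ]
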