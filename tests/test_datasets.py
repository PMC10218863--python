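"""FASTA/label I/O, filters, clustering and balanced splits."""

import numpy as np
import pytest

from ncrclass.datasets import (
    NcRNARecord,
    assign_mirna_length_class,
    cluster_reduce,
    coarsen_labels,
    length_filter,
    make_split,
    read_labeled_fasta,
    relabel_fine_grained,
    sequence_identity,
)
from conftest import random_rna


def _rec(i, seq, label="tRNA", subtype=None):
    return NcRNARecord(id=f"r{i}", sequence=seq, label=label, subtype=subtype)


def test_read_labeled_fasta_roundtrip(labeled_fasta):
    records = [
        _rec(0, "ACGU", "miRNA"),
        _rec(1, "acgu", "tRNA"),
        _rec(2, "ACGGU", "rRNA", "5S"),
    ]
    fasta, labels = labeled_fasta(records)
    loaded = read_labeled_fasta(fasta, labels)
    assert [r.id for r in loaded] == ["r0", "r1", "r2"]
    assert loaded[1].sequence == "ACGU"  # lowercase normalized
    assert loaded[2].subtype == "5S"


def test_read_labeled_fasta_errors(tmp_path, labeled_fasta):
    fasta, labels = labeled_fasta([_rec(0, "ACGU")])
    with open(fasta, "a") as fh:
        fh.write(">r0\nACGU\n")
    with pytest.raises(ValueError, match="duplicate"):
        read_labeled_fasta(fasta, labels)
    fasta2 = tmp_path / "extra.fasta"
    fasta2.write_text(">r0\nACGU\n>orphan\nACGU\n")
    with pytest.raises(ValueError, match="orphan"):
        read_labeled_fasta(fasta2, labels)


def test_length_filter_boundaries():
    recs = [_rec(i, "A" * n) for i, n in enumerate([10, 15, 11_922, 12_000])]
    kept = length_filter(recs)
    assert [r.length for r in kept] == [15, 11_922]
    assert length_filter([]) == []
    assert length_filter(recs, 1, 20_000) == recs  # identity when all in range


@pytest.mark.parametrize(
    "length,expected",
    [(22, "mature"), (30, "mature"), (31, "excluded"), (35, "excluded"),
     (39, "excluded"), (40, "precursor"), (100, "precursor")],
)
def test_assign_mirna_length_class(length, expected):
    assert assign_mirna_length_class(length) == expected


def test_sequence_identity_oracle_cases(rng):
    assert sequence_identity("ACGU", "ACGU") == 1.0
    assert sequence_identity("AAAACCCCGGGG", "UUUUAGCAUCGA") < 0.9
    seq = random_rna(rng, 100)
    mutated = seq[:50] + ("A" if seq[50] != "A" else "C") + seq[51:]
    assert sequence_identity(seq, mutated) == pytest.approx(0.99)


def test_cluster_reduce_cases(rng):
    seq = random_rna(rng, 100)
    mutated = seq[:50] + ("A" if seq[50] != "A" else "C") + seq[51:]
    # identical pair collapses; 99%-identical pair collapses
    assert len(cluster_reduce([_rec(0, seq), _rec(1, seq)])) == 1
    assert len(cluster_reduce([_rec(0, seq), _rec(1, mutated)])) == 1
    # dissimilar short pair stays apart
    reps = cluster_reduce([_rec(0, "AAAACCCCGGGG"), _rec(1, "UUUUAGCAUCGA")])
    assert len(reps) == 2
    with pytest.raises(ValueError):
        cluster_reduce([])


def test_cluster_reduce_longest_first_representative(rng):
    core = random_rna(rng, 80)
    longer = core + random_rna(rng, 5)
    reps = cluster_reduce([_rec(0, core), _rec(1, longer)])
    assert [r.id for r in reps] == ["r1"]  # longest founds the cluster


def test_make_split_arithmetic_and_determinism():
    records = [
        _rec(f"{c}{i}", "A" * 20, label=c)
        for c in ("x", "y")
        for i in range(10_000)
    ]
    split = make_split(records, test_per_class=1000, seed=4)
    for c in ("x", "y"):
        assert split.class_counts("test")[c] == 1000
        assert split.class_counts("validation")[c] == 900
        assert split.class_counts("train")[c] == 8100
    ids = (
        {r.id for r in split.train}
        | {r.id for r in split.validation}
        | {r.id for r in split.test}
    )
    assert len(ids) == 20_000  # partition: disjoint and complete
    split2 = make_split(records, test_per_class=1000, seed=4)
    assert [r.id for r in split2.test] == [r.id for r in split.test]
    assert [r.id for r in split2.train] == [r.id for r in split.train]


def test_make_split_fine_grained_counts():
    records = [_rec(f"a{i}", "A" * 20, label="snRNA") for i in range(5000)]
    split = make_split(records, test_per_class=500, seed=0)
    assert split.class_counts("test")["snRNA"] == 500
    assert split.class_counts("validation")["snRNA"] == 450
    assert split.class_counts("train")["snRNA"] == 4050


def test_make_split_subtype_balance():
    records = [
        _rec(f"s{i}", "A" * 20, label="snoRNA",
             subtype=["C/D-Box", "H/ACA-Box"][i % 2])
        for i in range(100)
    ]
    split = make_split(records, test_per_class=10, seed=1)
    subtypes = [r.subtype for r in split.test]
    assert subtypes.count("C/D-Box") == subtypes.count("H/ACA-Box") == 5


def test_make_split_errors_and_warning():
    records = [_rec(i, "A" * 20) for i in range(5)]
    with pytest.raises(ValueError, match="test size"):
        make_split(records, test_per_class=10)
    with pytest.warns(UserWarning, match="available"):
        make_split(records, per_class_total=50, test_per_class=2, seed=0)


@pytest.mark.parametrize(
    "label,subtype,length,expected",
    [
        ("rRNA", "5S", 120, "short rRNA"),
        ("rRNA", "28S", 4000, "long rRNA"),
        ("snoRNA", "C/D-Box", 90, "CD-box snoRNA"),
        ("snoRNA", "scaRNA", 200, "scaRNA"),
        ("miRNA", None, 22, "mature miRNA"),
        ("miRNA", None, 80, "precursor miRNA"),
        ("tRNA", None, 75, "tRNA"),
    ],
)
def test_relabel_fine_grained(label, subtype, length, expected):
    rec = NcRNARecord(id="q", sequence="A" * length, label=label, subtype=subtype)
    assert relabel_fine_grained([rec])[0].label == expected


def test_relabel_fine_grained_errors():
    with pytest.raises(ValueError, match="subtype"):
        relabel_fine_grained([_rec(0, "A" * 90, label="snoRNA")])
    with pytest.raises(ValueError, match="excluded"):
        relabel_fine_grained([_rec(0, "A" * 35, label="miRNA")])


def test_relabel_then_coarsen_is_identity():
    records = [
        _rec(0, "A" * 22, "miRNA"),
        _rec(1, "A" * 80, "miRNA"),
        _rec(2, "A" * 120, "rRNA", "5S"),
        _rec(3, "A" * 90, "snoRNA", "H/ACA-Box"),
        _rec(4, "A" * 75, "tRNA"),
        _rec(5, "A" * 300, "lncRNA"),
    ]
    roundtrip = coarsen_labels(relabel_fine_grained(records))
    assert [r.label for r in roundtrip] == [r.label for r in records]
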