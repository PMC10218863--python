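import numpy as np
import pytest

from ncrclass.datasets import NcRNARecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.asarray(list("ACGU"))[rng.integers(0, 4, size=length)])


@pytest.fixture
def labeled_fasta(tmp_path):
    """Write records to FASTA + label TSV; returns (fasta_path, labels_path)."""

    def _write(records: list[NcRNARecord], fasta_name="seqs.fasta"):
        fasta = tmp_path / fasta_name
        labels = tmp_path / (fasta_name + ".labels.tsv")
        with open(fasta, "w") as fh:
            for rec in records:
                fh.write(f">{rec.id}\n{rec.sequence}\n")
        with open(labels, "w") as fh:
            fh.write("id\tlabel\tsubtype\n")
            for rec in records:
                fh.write(f"{rec.id}\t{rec.label}\t{rec.subtype or ''}\n")
        return fasta, labels

    return _write
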