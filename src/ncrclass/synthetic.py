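"""Synthetic labeled ncRNA generator.

Emulates the class heterogeneity the classifiers exploit — class-specific
length distributions, conserved sequence motifs (IUPAC patterns) and
stem-loop structure content — so the full pipeline can train and evaluate
without any database download.  Background nucleotides are i.i.d. uniform
over A/C/G/U; motifs overwrite the background at their (possibly
position-biased) insertion points; hairpin and cloverleaf templates copy
arm sequences as reverse complements with a per-base mismatch rate.

The generated data is deliberately simpler than real ncRNA: no covariance
models, no phylogenetic structure, no database noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .datasets import NcRNARecord, write_fasta, write_labels

__all__ = [
    "Motif",
    "ClassProfile",
    "SyntheticDataset",
    "default_profiles",
    "structure_dominated_profiles",
    "desk_scale",
    "simulate",
]

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "U": "U", "T": "U",
    "R": "AG", "Y": "CU", "S": "GC", "W": "AU", "K": "GU", "M": "AC",
    "B": "CGU", "D": "AGU", "H": "ACU", "V": "ACG", "N": "ACGU",
}
_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
_NUCS = np.array(list("ACGU"))


@dataclass(frozen=True)
class Motif:
    """IUPAC pattern inserted with a probability at a positional preference.

    ``position`` is the preferred fractional offset along the sequence
    (0 = 5' end, 1 = 3' end); None places the motif uniformly at random.
    """

    pattern: str
    probability: float = 1.0
    position: float | None = None


@dataclass(frozen=True)
class ClassProfile:
    label: str
    length_range: tuple[int, int]
    subtype: str | None = None
    motifs: tuple[Motif, ...] = ()
    structure_template: str = "none"  # none | hairpin | multi_stem
    stem_mismatch_rate: float = 0.05

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if lo < 15:
            raise ValueError("minimum synthetic length is 15 nt")
        if hi > 11_922:
            raise ValueError("maximum synthetic length is 11,922 nt")
        if lo > hi:
            raise ValueError("empty length range")
        if self.structure_template not in ("none", "hairpin", "multi_stem"):
            raise ValueError(
                f"unknown structure template {self.structure_template!r}"
            )


@dataclass
class SyntheticDataset:
    records: list[NcRNARecord] = field(default_factory=list)
    provenance: list[dict] = field(default_factory=list)

    def write(self, fasta_path, labels_path) -> None:
        write_fasta(self.records, fasta_path)
        write_labels(self.records, labels_path)


# fixed conserved blocks standing in for rRNA expansion-segment conservation
_RRNA_BLOCKS = (
    Motif("GCCUGGCGGCCGUAG", 1.0, 0.08),
    Motif("CUAACGGAUUCAGGU", 1.0, 0.50),
    Motif("GGUAGAGCGCUGCCU", 1.0, 0.88),
)


def default_profiles(
    fine_grained: bool = False, max_length: int | None = None
) -> list[ClassProfile]:
    """Profiles for the six general classes (or the ten fine-grained ones).

    The six-class list holds seven profiles: the miRNA class is an equal
    mixture of a mature-like (20-24 nt) and a precursor-like (60-120 nt,
    hairpin) profile, mirroring its bimodal length composition.
    ``max_length`` caps all length ranges for desk-scale runs.
    """
    mature = ClassProfile(
        label="miRNA", subtype="mature", length_range=(20, 24),
        motifs=(Motif("UGAGGUAGR", 1.0, 0.0),),
    )
    precursor = ClassProfile(
        label="miRNA", subtype="precursor", length_range=(60, 120),
        structure_template="hairpin",
    )
    trna = ClassProfile(
        label="tRNA", length_range=(70, 90), structure_template="multi_stem",
        motifs=(Motif("GUUCRAUU", 1.0, 0.72), Motif("CCA", 1.0, 1.0)),
    )
    snorna = ClassProfile(
        label="snoRNA", subtype="C/D-Box", length_range=(70, 250),
        motifs=(Motif("RUGAUGA", 1.0, 0.05), Motif("CUGA", 1.0, 0.95)),
    )
    snrna = ClassProfile(
        label="snRNA", length_range=(100, 300),
        motifs=(Motif("AAUUUUUGG", 1.0, 0.60),),
    )
    lncrna = ClassProfile(label="lncRNA", length_range=(200, 4000))
    rrna = ClassProfile(
        label="rRNA", subtype="SSU", length_range=(1400, 3000),
        motifs=_RRNA_BLOCKS,
    )
    if not fine_grained:
        profiles = [mature, precursor, trna, snorna, snrna, lncrna, rrna]
    else:
        profiles = [
            replace(mature, label="mature miRNA"),
            replace(precursor, label="precursor miRNA"),
            trna,
            replace(snorna, label="CD-box snoRNA"),
            ClassProfile(
                label="HACA-box snoRNA", subtype="H/ACA-Box",
                length_range=(100, 250),
                motifs=(Motif("ANANNA", 1.0, 0.45), Motif("ACA", 1.0, 0.97)),
            ),
            ClassProfile(
                label="scaRNA", subtype="scaRNA", length_range=(150, 250),
                motifs=(
                    Motif("RUGAUGA", 1.0, 0.05),
                    Motif("CUGA", 1.0, 0.55),
                    Motif("ACA", 1.0, 0.97),
                ),
            ),
            snrna,
            lncrna,
            ClassProfile(
                label="short rRNA", subtype="5S", length_range=(110, 160),
                motifs=(Motif("GCCUGGCGGCCGUAG", 1.0, 0.10),),
            ),
            replace(rrna, label="long rRNA", subtype="28S"),
        ]
    if max_length is not None:
        capped = []
        for p in profiles:
            lo, hi = p.length_range
            hi = min(hi, max_length)
            if lo > hi:  # long classes: keep a band near the cap
                lo = max(15, int(0.8 * hi))
            capped.append(replace(p, length_range=(lo, hi)))
        profiles = capped
    return profiles


def structure_dominated_profiles(
    max_length: int | None = None,
) -> list[ClassProfile]:
    """Six-class profiles with sequence motifs stripped from the classes whose
    identity is structural (precursor miRNA hairpin, tRNA cloverleaf)."""
    out = []
    for p in default_profiles(max_length=max_length):
        if p.structure_template in ("hairpin", "multi_stem"):
            p = replace(p, motifs=())
        out.append(p)
    return out


def desk_scale(profiles: list[ClassProfile], pad_to: int = 500) -> list[ClassProfile]:
    """Cap profile lengths so every sequence fits a reduced padded length."""
    capped = []
    for p in profiles:
        lo, hi = p.length_range
        hi = min(hi, pad_to)
        if lo > hi:
            lo = max(15, int(0.8 * hi))
        capped.append(replace(p, length_range=(lo, hi)))
    return capped


def _random_seq(rng: np.random.Generator, n: int) -> list[str]:
    return list(_NUCS[rng.integers(0, 4, size=n)])


def _revcomp(seq: list[str]) -> list[str]:
    return [_COMPLEMENT[c] for c in reversed(seq)]


def _mismatch(seq: list[str], rate: float, rng: np.random.Generator) -> list[str]:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = str(rng.choice([c for c in "ACGU" if c != out[i]]))
    return out


def hairpin_with_arms(
    length: int, rate: float, rng: np.random.Generator
) -> tuple[list[str], int, int]:
    """Hairpin sequence plus its (arm_length, loop_length) layout.

    The 3' arm is the reverse complement of the 5' arm with a per-base
    mismatch probability of ``rate``.
    """
    loop = int(rng.integers(4, 9))
    arm = max(1, (length - loop) // 2)
    left = _random_seq(rng, arm)
    right = _mismatch(_revcomp(left), rate, rng)
    tail = _random_seq(rng, length - 2 * arm - loop)
    return left + _random_seq(rng, loop) + right + tail, arm, loop


def _hairpin(length: int, rate: float, rng: np.random.Generator) -> list[str]:
    return hairpin_with_arms(length, rate, rng)[0]


def _cloverleaf(length: int, rate: float, rng: np.random.Generator) -> list[str]:
    """Acceptor stem plus three designed stem-loop arms, tRNA-style."""
    acc = _random_seq(rng, 7)
    arms: list[list[str]] = []
    for _ in range(3):
        stem = _random_seq(rng, int(rng.integers(4, 6)))
        loop = _random_seq(rng, int(rng.integers(7, 9)))
        arms.append(stem + loop + _mismatch(_revcomp(stem), rate, rng))
    core = len(acc) * 2 + sum(len(a) for a in arms)
    spare = max(0, length - core)
    linkers = [int(spare // 4)] * 4
    linkers[3] += spare - sum(linkers)
    seq = list(acc)
    for arm, link in zip(arms, linkers[:3]):
        seq += _random_seq(rng, link) + arm
    seq += _mismatch(_revcomp(acc), rate, rng) + _random_seq(rng, linkers[3])
    return seq[:length] if len(seq) > length else seq + _random_seq(
        rng, length - len(seq)
    )


def _instantiate_motif(pattern: str, rng: np.random.Generator) -> list[str]:
    out = []
    for c in pattern.upper():
        choices = _IUPAC.get(c)
        if choices is None:
            raise ValueError(f"invalid IUPAC code {c!r} in motif {pattern!r}")
        out.append(choices if len(choices) == 1 else str(rng.choice(list(choices))))
    return out


def _generate_one(
    profile: ClassProfile, rng: np.random.Generator
) -> str:
    lo, hi = profile.length_range
    length = int(rng.integers(lo, hi + 1))
    if profile.structure_template == "hairpin":
        seq = _hairpin(length, profile.stem_mismatch_rate, rng)
    elif profile.structure_template == "multi_stem":
        seq = _cloverleaf(length, profile.stem_mismatch_rate, rng)
    else:
        seq = _random_seq(rng, length)
    for motif in profile.motifs:
        if rng.random() >= motif.probability:
            continue
        inst = _instantiate_motif(motif.pattern, rng)
        if len(inst) > length:
            continue
        span = length - len(inst)
        if motif.position is None:
            start = int(rng.integers(0, span + 1))
        else:
            start = int(round(motif.position * span))
        seq[start : start + len(inst)] = inst
    return "".join(seq)


def _slug(profile: ClassProfile) -> str:
    base = profile.label if profile.subtype is None else (
        f"{profile.label}-{profile.subtype}"
    )
    return base.replace(" ", "_").replace("/", "")


def simulate(
    profiles: list[ClassProfile], n_per_class: int, seed: int
) -> SyntheticDataset:
    """Generate ``n_per_class`` records per class label, deterministically.

    When several profiles share a label (the bimodal miRNA class) the class
    budget is split equally across them, remainder to the earlier profiles.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    label_profiles: dict[str, list[ClassProfile]] = {}
    for p in profiles:
        label_profiles.setdefault(p.label, []).append(p)
    dataset = SyntheticDataset()
    for profile in profiles:
        siblings = label_profiles[profile.label]
        share = n_per_class // len(siblings)
        if siblings.index(profile) < n_per_class % len(siblings):
            share += 1
        slug = _slug(profile)
        for i in range(share):
            seq = _generate_one(profile, rng)
            rid = f"syn_{slug}_{i:05d}"
            dataset.records.append(
                NcRNARecord(
                    id=rid,
                    sequence=seq,
                    label=profile.label,
                    subtype=profile.subtype,
                )
            )
            dataset.provenance.append(
                {"id": rid, "profile": slug, "seed": seed}
            )
    return dataset
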