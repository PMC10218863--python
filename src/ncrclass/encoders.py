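"""Model-ready encodings of RNA sequences and structures.

Three representations feed the classifiers:

* ordinal sequence encoding — each IUPAC letter maps to a fixed integer,
  right-padded with 0 ('_') to a fixed length (production default 12,000 nt);
* combined nucleotide-substructure encoding — each (nucleotide, F/T/S/M/H/I
  state) pair maps to one of 24 symbols, with 'N' for any ambiguous
  nucleotide and '_' padding, 26 tokens in total;
* hashed weighted graph features — per structure representative, a graph
  with backbone and base-pair edges is decomposed into pairs of small rooted
  neighborhood subgraphs; each (neighborhood, neighborhood, distance) feature
  hashes into a fixed 2^15 = 32,768-dimensional weight vector accumulated
  over all representatives.

All encodings are deterministic across runs and platforms: the graph hash is
CRC-32 on canonical feature strings combined with an FNV-style integer mix.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import sparse

from .folding import ShrepSet, annotate_structure, pair_table

__all__ = [
    "SequenceVocabulary",
    "StructSeqVocabulary",
    "EncodedInput",
    "GraphEncoderConfig",
    "GraphFeatureVector",
    "SEQUENCE_VOCAB",
    "STRUCTSEQ_VOCAB",
    "PAD_LENGTH",
    "encode_sequence",
    "decode_sequence",
    "encode_struct_sequence",
    "decode_struct_sequence",
    "encode_graph",
    "graph_feature_matrix",
]

PAD_LENGTH = 12_000

_IUPAC_ORDER = "ACGTURYSWKMBDHVN"  # 16 letters; '_' (padding) is code 0
_NUCS = "ACGU"
_STATES = "FTSMHI"
# 24 printable display characters for the combined alphabet, starting at 'Q'
# so that (A, F) -> 'Q'; the run skips into lowercase to avoid '_' and 'N'.
_COMBINED_CHARS = "QRSTUVWXYZabcdefghijklmn"


@dataclass(frozen=True)
class SequenceVocabulary:
    """17-token ordinal vocabulary: padding '_' plus the 16 IUPAC letters."""

    tokens: tuple[str, ...] = tuple("_" + _IUPAC_ORDER)

    @property
    def code(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.tokens)}

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass(frozen=True)
class StructSeqVocabulary:
    """26-token combined vocabulary: '_', 24 (nucleotide, state) pairs, 'N'.

    Pairs are laid out row-major over nucleotides (A,C,G,U) x states
    (F,T,S,M,H,I); the display character of (A,F) is 'Q'.
    """

    tokens: tuple[str, ...] = tuple("_" + _COMBINED_CHARS + "N")

    @property
    def code(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.tokens)}

    def pair_code(self, nucleotide: str, state: str) -> int:
        """Integer code of a (nucleotide, substructure-state) pair."""
        nuc = nucleotide.upper().replace("T", "U")
        if nuc not in _NUCS:
            return self.code["N"]
        if state not in _STATES:
            raise ValueError(f"unknown substructure state {state!r}")
        return 1 + _NUCS.index(nuc) * len(_STATES) + _STATES.index(state)

    def pair_char(self, nucleotide: str, state: str) -> str:
        return self.tokens[self.pair_code(nucleotide, state)]

    def __len__(self) -> int:
        return len(self.tokens)


SEQUENCE_VOCAB = SequenceVocabulary()
STRUCTSEQ_VOCAB = StructSeqVocabulary()


@dataclass
class EncodedInput:
    """Padded integer vector for one sequence (sequence or structure channel)."""

    values: np.ndarray
    channel: str  # "sequence" | "structure"

    def __post_init__(self) -> None:
        if self.channel not in ("sequence", "structure"):
            raise ValueError(f"unknown channel {self.channel!r}")
        self.values = np.asarray(self.values, dtype=np.int64)


def encode_sequence(
    sequence: str,
    vocab: SequenceVocabulary = SEQUENCE_VOCAB,
    pad_to: int = PAD_LENGTH,
) -> EncodedInput:
    """Ordinal-encode a sequence and right-pad with 0 to ``pad_to``."""
    if len(sequence) > pad_to:
        raise ValueError(
            f"sequence exceeds maximum length ({len(sequence)} > {pad_to})"
        )
    code = vocab.code
    values = np.zeros(pad_to, dtype=np.int64)
    for i, c in enumerate(sequence.upper()):
        try:
            values[i] = code[c]
        except KeyError:
            raise ValueError(f"non-IUPAC character {c!r} at position {i}") from None
    return EncodedInput(values=values, channel="sequence")


def decode_sequence(
    encoded: EncodedInput, vocab: SequenceVocabulary = SEQUENCE_VOCAB
) -> str:
    """Invert :func:`encode_sequence` (padding stripped)."""
    out = []
    for v in encoded.values:
        if v == 0:
            break
        out.append(vocab.tokens[int(v)])
    return "".join(out)


def encode_struct_sequence(
    sequence: str,
    annotation: str,
    vocab: StructSeqVocabulary = STRUCTSEQ_VOCAB,
    pad_to: int = PAD_LENGTH,
) -> EncodedInput:
    """Encode (nucleotide, substructure-state) pairs; ambiguous bases -> 'N'."""
    if len(sequence) != len(annotation):
        raise ValueError(
            f"sequence length {len(sequence)} != annotation length {len(annotation)}"
        )
    if len(sequence) > pad_to:
        raise ValueError(
            f"sequence exceeds maximum length ({len(sequence)} > {pad_to})"
        )
    values = np.zeros(pad_to, dtype=np.int64)
    for i, (c, s) in enumerate(zip(sequence.upper(), annotation)):
        values[i] = vocab.pair_code(c, s)
    return EncodedInput(values=values, channel="structure")


def decode_struct_sequence(
    encoded: EncodedInput, vocab: StructSeqVocabulary = STRUCTSEQ_VOCAB
) -> tuple[str, str]:
    """Recover the (sequence, annotation) pair; 'N' positions decode as ('N','F')."""
    nucs, states = [], []
    for v in encoded.values:
        v = int(v)
        if v == 0:
            break
        if vocab.tokens[v] == "N":
            nucs.append("N")
            states.append("F")
        else:
            k = v - 1
            nucs.append(_NUCS[k // len(_STATES)])
            states.append(_STATES[k % len(_STATES)])
    return "".join(nucs), "".join(states)


# ---------------------------------------------------------------------------
# graph features
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GraphEncoderConfig:
    """Neighborhood-subgraph-pair feature parameters.

    ``max_radius`` bounds the BFS radius of each rooted neighborhood,
    ``max_distance`` the graph distance between the two roots; features hash
    into ``2**hash_bits`` buckets.
    """

    max_radius: int = 1
    max_distance: int = 4
    hash_bits: int = 15

    @property
    def dim(self) -> int:
        return 1 << self.hash_bits


@dataclass
class GraphFeatureVector:
    """Sparse nonnegative weight vector of hashed graph features."""

    dim: int
    entries: dict[int, float] = field(default_factory=dict)

    def to_array(self) -> np.ndarray:
        arr = np.zeros(self.dim)
        for k, v in self.entries.items():
            arr[k] = v
        return arr

    def to_sparse(self) -> sparse.csr_matrix:
        if not self.entries:
            return sparse.csr_matrix((1, self.dim))
        idx = np.fromiter(self.entries.keys(), dtype=np.int64)
        val = np.fromiter(self.entries.values(), dtype=np.float64)
        return sparse.csr_matrix(
            (val, (np.zeros_like(idx), idx)), shape=(1, self.dim)
        )

    @property
    def total_weight(self) -> float:
        return float(sum(self.entries.values()))


def _structure_graph(sub: str, db: str) -> tuple[list[str], list[list[int]]]:
    """Vertex labels and adjacency of the backbone + base-pair graph."""
    ann = annotate_structure(sub, db)
    labels = []
    for c, s in zip(sub.upper(), ann):
        nuc = c.replace("T", "U")
        if nuc not in _NUCS:
            nuc = "N"
        labels.append(nuc + s)
    n = len(sub)
    adj: list[list[int]] = [[] for _ in range(n)]
    for i in range(n - 1):
        adj[i].append(i + 1)
        adj[i + 1].append(i)
    for i, j in enumerate(pair_table(db)):
        if j > i:
            adj[i].append(j)
            adj[j].append(i)
    return labels, adj


def neighborhood_signature(
    labels: list[str], adj: list[list[int]], root: int, radius: int
) -> str:
    """Canonical string of the radius-bounded neighborhood rooted at a vertex.

    BFS layers up to ``radius``; each layer contributes its sorted label
    multiset.  Exact up to radius 1 (the default); beyond that the layered
    form is a deterministic approximation of graph canonicalization.
    """
    seen = {root}
    layer = [root]
    parts = [f"{radius}:{labels[root]}"]
    for _ in range(radius):
        nxt = []
        for u in layer:
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    nxt.append(v)
        parts.append("|".join(sorted(labels[v] for v in nxt)))
        layer = nxt
    return ";".join(parts)


@njit(cache=True)
def _accumulate_pairs(indptr, indices, node_hashes, max_distance, weights):
    """BFS from each root; hash (h_u, h_v, d) for unordered pairs u <= v."""
    n = node_hashes.shape[0]
    mask = np.int64(weights.shape[0] - 1)
    dist = np.full(n, -1, dtype=np.int64)
    queue = np.empty(n, dtype=np.int64)
    for u in range(n):
        for t in range(n):
            dist[t] = -1
        dist[u] = 0
        queue[0] = u
        head, tail = 0, 1
        while head < tail:
            x = queue[head]
            head += 1
            if dist[x] >= max_distance:
                continue
            for p in range(indptr[x], indptr[x + 1]):
                y = indices[p]
                if dist[y] < 0:
                    dist[y] = dist[x] + 1
                    queue[tail] = y
                    tail += 1
        for v in range(u, n):
            d = dist[v]
            if d < 0:
                continue
            a = node_hashes[u]
            b = node_hashes[v]
            lo = a if a < b else b
            hi = b if a < b else a
            h = np.uint64(2166136261)
            for val in (lo, hi, np.uint64(d)):
                h = (h ^ np.uint64(val)) * np.uint64(16777619)
                h = h & np.uint64(0xFFFFFFFF)
            weights[np.int64(h) & mask] += 1.0


def encode_graph(
    sequence: str,
    shreps: ShrepSet,
    config: GraphEncoderConfig | None = None,
) -> GraphFeatureVector:
    """Accumulate hashed neighborhood-subgraph-pair features over all shreps."""
    config = config or GraphEncoderConfig()
    weights = np.zeros(config.dim)
    if not sequence:
        if shreps.windows:
            raise ValueError("shreps do not match the (empty) sequence")
        return GraphFeatureVector(dim=config.dim)
    for off, structs in shreps.windows:
        for db in structs:
            sub = sequence[off : off + len(db)]
            if len(sub) != len(db):
                raise ValueError(
                    f"shrep window at offset {off} exceeds the sequence"
                )
            labels, adj = _structure_graph(sub, db)
            n = len(labels)
            for radius in range(config.max_radius + 1):
                hashes = np.empty(n, dtype=np.uint64)
                for u in range(n):
                    sig = neighborhood_signature(labels, adj, u, radius)
                    hashes[u] = zlib.crc32(sig.encode())
                indptr = np.zeros(n + 1, dtype=np.int64)
                for u in range(n):
                    indptr[u + 1] = indptr[u] + len(adj[u])
                indices = np.empty(indptr[-1], dtype=np.int64)
                pos = 0
                for u in range(n):
                    for v in adj[u]:
                        indices[pos] = v
                        pos += 1
                _accumulate_pairs(
                    indptr, indices, hashes, config.max_distance, weights
                )
    nz = np.nonzero(weights)[0]
    return GraphFeatureVector(
        dim=config.dim, entries={int(i): float(weights[i]) for i in nz}
    )


def graph_feature_matrix(vectors: list[GraphFeatureVector]) -> sparse.csr_matrix:
    """Stack feature vectors into one CSR matrix (rows = sequences)."""
    if not vectors:
        raise ValueError("no vectors to stack")
    return sparse.vstack([v.to_sparse() for v in vectors]).tocsr()
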