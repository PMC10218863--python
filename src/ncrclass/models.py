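"""Declarative model architectures for ncRNA classification.

Four architectures are built as declarative specs and realized as networks:

* ``grenc`` — a fully connected net on the 32,768-dimensional hashed graph
  vector: dense(10, ReLU) -> softmax output;
* ``seqenc`` — embedding(17, 4) over the ordinal-encoded sequence, four
  convolutional blocks (two 64-kernel conv layers each, kernel sizes
  3/7/11/17, max-pool sizes 4/4/2/2), dropout 0.5, flatten, dense(10, ReLU),
  softmax output;
* ``strenc`` — same shape as seqenc with embedding(26, 4) over the combined
  nucleotide-substructure tokens and kernel size 7 in every block;
* ``merged`` (MncR) — seqenc and grenc branches in parallel, their 10-wide
  penultimate layers concatenated to width 20 and fed directly into one
  softmax output layer, trained from scratch without reusing solo weights.

Specs are countable (:func:`count_parameters`) and serializable; realization
returns a network from :mod:`ncrclass.nn` whose own parameter count must
agree with the declarative count.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn

__all__ = [
    "ConvBlockSpec",
    "ModelSpec",
    "build_grenc",
    "build_seqenc",
    "build_strenc",
    "build_mncr",
    "count_parameters",
    "pooled_length",
    "realize",
    "MODEL_NAMES",
]

MODEL_NAMES = ("GrEnc", "SeqEnc", "StrEnc", "MncR")

GRAPH_DIM = 32_768
MERGE_WIDTH = 20
DENSE_WIDTH = 10
EMBED_DIM = 4


@dataclass(frozen=True)
class ConvBlockSpec:
    """One convolutional block: ``n_conv`` ReLU conv layers then a max pool."""

    kernel_size: int
    pool_size: int
    n_conv: int = 2
    kernels: int = 64

    def __post_init__(self) -> None:
        if self.kernel_size < 1 or self.pool_size < 1:
            raise ValueError("kernel_size and pool_size must be >= 1")


@dataclass
class ModelSpec:
    name: str
    input_dims: int  # padded sequence length, or graph vector dim for GrEnc
    embedding: tuple[int, int] | None = None  # (vocab_size, embed_dim)
    blocks: list[ConvBlockSpec] = field(default_factory=list)
    dropout: float = 0.5
    dense_width: int = DENSE_WIDTH
    n_classes: int = 6
    merge_width: int | None = None
    branches: tuple["ModelSpec", "ModelSpec"] | None = None  # (seq, graph)
    input_norm: str | None = None  # "l2" rescales each input row (no params)

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.branches is not None:
            d["branches"] = [b.to_dict() for b in self.branches]
        return d


def build_grenc(input_dim: int = GRAPH_DIM, n_classes: int = 6) -> ModelSpec:
    """Fully connected net on the hashed graph feature vector."""
    if input_dim <= 0:
        raise ValueError("input_dim must be positive")
    return ModelSpec(
        name="GrEnc", input_dims=input_dim, n_classes=n_classes, input_norm="l2"
    )


def build_seqenc(
    vocab: int = 17,
    pad_to: int = 12_000,
    n_classes: int = 6,
    kernels: int = 64,
    kernel_sizes: tuple[int, ...] = (3, 7, 11, 17),
    pool_sizes: tuple[int, ...] = (4, 4, 2, 2),
) -> ModelSpec:
    """Sequence-channel CNN; kernel size grows with depth (3/7/11/17)."""
    blocks = [
        ConvBlockSpec(kernel_size=k, pool_size=p, kernels=kernels)
        for k, p in zip(kernel_sizes, pool_sizes)
    ]
    return ModelSpec(
        name="SeqEnc",
        input_dims=pad_to,
        embedding=(vocab, EMBED_DIM),
        blocks=blocks,
        n_classes=n_classes,
    )


def build_strenc(
    vocab: int = 26,
    pad_to: int = 12_000,
    n_classes: int = 6,
    kernels: int = 64,
    n_blocks: int = 4,
    pool_sizes: tuple[int, ...] = (4, 4, 2, 2),
) -> ModelSpec:
    """Structure-channel CNN: like seqenc but kernel size 7 in every block."""
    blocks = [
        ConvBlockSpec(kernel_size=7, pool_size=p, kernels=kernels)
        for p in pool_sizes[:n_blocks]
    ]
    return ModelSpec(
        name="StrEnc",
        input_dims=pad_to,
        embedding=(vocab, EMBED_DIM),
        blocks=blocks,
        n_classes=n_classes,
    )


def build_mncr(
    seq_spec: ModelSpec, graph_spec: ModelSpec, n_classes: int = 6
) -> ModelSpec:
    """Late-integration model from a sequence branch and a graph branch.

    Both branch specs must end in a ``dense_width``-10 penultimate layer;
    their outputs concatenate to a 20-wide layer followed directly by the
    softmax output.  No weights are shared with or taken from the solo models.
    """
    for spec in (seq_spec, graph_spec):
        if spec.dense_width != DENSE_WIDTH:
            raise ValueError(
                f"branch {spec.name} lacks a {DENSE_WIDTH}-node penultimate layer"
            )
    return ModelSpec(
        name="MncR",
        input_dims=seq_spec.input_dims,
        n_classes=n_classes,
        merge_width=2 * DENSE_WIDTH,
        branches=(seq_spec, graph_spec),
    )


def pooled_length(input_length: int, blocks: list[ConvBlockSpec]) -> int:
    """Temporal length after all pooling (floor division per block)."""
    length = input_length
    for b in blocks:
        length //= b.pool_size
    return length


def _branch_parameters(spec: ModelSpec) -> int:
    """Parameters of a spec's feature branch, i.e. everything but the head."""
    total = 0
    if spec.embedding is not None:
        v, d = spec.embedding
        total += v * d
        ch = d
    else:
        ch = None
    for b in spec.blocks:
        for i in range(b.n_conv):
            cin = ch if i == 0 else b.kernels
            total += b.kernel_size * cin * b.kernels + b.kernels
        ch = b.kernels
    if spec.blocks:
        flat = pooled_length(spec.input_dims, spec.blocks) * spec.blocks[-1].kernels
    else:
        flat = spec.input_dims
    total += flat * spec.dense_width + spec.dense_width
    return total


def count_parameters(spec: ModelSpec) -> int:
    """Trainable parameter count of the realized model (pure arithmetic)."""
    if spec.branches is not None:
        seq_spec, graph_spec = spec.branches
        head = spec.merge_width * spec.n_classes + spec.n_classes
        return (
            _branch_parameters(seq_spec) + _branch_parameters(graph_spec) + head
        )
    return (
        _branch_parameters(spec)
        + spec.dense_width * spec.n_classes
        + spec.n_classes
    )


def _realize_branch(spec: ModelSpec, rng: np.random.Generator) -> nn.Sequential:
    layers: list[nn.Layer] = []
    if spec.input_norm == "l2" and spec.embedding is None:
        layers.append(nn.L2Normalize())
    if spec.embedding is not None:
        v, d = spec.embedding
        layers.append(nn.Embedding(v, d, rng))
        ch = d
    else:
        ch = None
    for b in spec.blocks:
        for i in range(b.n_conv):
            cin = ch if i == 0 else b.kernels
            layers.append(nn.Conv1D(cin, b.kernels, b.kernel_size, rng))
        layers.append(nn.MaxPool1D(b.pool_size))
        ch = b.kernels
    if spec.blocks:
        layers.append(nn.Dropout(spec.dropout))
        layers.append(nn.Flatten())
        flat = pooled_length(spec.input_dims, spec.blocks) * spec.blocks[-1].kernels
    else:
        flat = spec.input_dims
    layers.append(nn.Dense(flat, spec.dense_width, rng, activation="relu"))
    return nn.Sequential(layers)


def realize(spec: ModelSpec, seed: int | np.random.Generator = 0):
    """Instantiate a spec as a trainable network with seeded initialization."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if spec.branches is not None:
        seq_spec, graph_spec = spec.branches
        seq_branch = _realize_branch(seq_spec, rng)
        graph_branch = _realize_branch(graph_spec, rng)
        head = nn.Dense(spec.merge_width, spec.n_classes, rng)
        return nn.MergedNetwork(seq_branch, graph_branch, head)
    branch = _realize_branch(spec, rng)
    branch.layers.append(nn.Dense(spec.dense_width, spec.n_classes, rng))
    return branch
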