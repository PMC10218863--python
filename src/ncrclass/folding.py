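"""RNA secondary-structure prediction and substructure annotation.

Provides a self-contained base-pair-maximization folding engine (Nussinov-style
dynamic programming over Watson-Crick + GU pairs with a minimum hairpin size),
sliding-window generation of suboptimal structure representatives ("shreps"),
and per-position annotation of a dot-bracket structure with the six
substructure states F/T/S/M/H/I (5'-end, 3'-end, stem, multi-loop, hairpin
loop, internal loop).

The builtin engine guarantees only the dot-bracket contract downstream encoders
rely on (balanced, pseudoknot-free, deterministic); it is not a thermodynamic
model.  An adapter to an external MFE folder (RNAfold) is available through
``engine="external_mfe"``.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "FoldingConfig",
    "ShrepSet",
    "fold_mfe",
    "compute_shift",
    "windowed_shreps",
    "annotate_structure",
    "pair_table",
    "write_vienna",
    "write_shreps_tsv",
]

#: canonical pairs: Watson-Crick plus the GU wobble, T treated as U
_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}

STRUCTURE_STATES = "FTSMHI"


@dataclass(frozen=True)
class FoldingConfig:
    """Parameters of the windowed folding step.

    ``window_size``/``shift_fraction``/``n_shreps`` mirror the fasta2shrep
    parameters wins=150, shift=25(%), M=3.
    """

    window_size: int = 150
    shift_fraction: float = 0.25
    n_shreps: int = 3
    min_hairpin: int = 3
    engine: str = "builtin_nussinov"

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if not (0.0 < self.shift_fraction <= 1.0):
            raise ValueError("shift_fraction must be in (0, 1]")
        if self.n_shreps < 1:
            raise ValueError("n_shreps must be >= 1")
        if self.min_hairpin < 0:
            raise ValueError("min_hairpin must be >= 0")
        if self.engine not in ("builtin_nussinov", "external_mfe"):
            raise ValueError(f"unknown folding engine: {self.engine!r}")


@dataclass
class ShrepSet:
    """Windowed structure representatives for one sequence.

    ``windows`` is an ordered list of ``(offset, [dot_bracket, ...])`` with
    strictly increasing 0-based offsets; every structure spans
    ``window_size`` nucleotides (or the whole sequence when shorter).
    """

    windows: list[tuple[int, list[str]]] = field(default_factory=list)

    def n_structures(self) -> int:
        return sum(len(structs) for _, structs in self.windows)


def pair_table(db: str) -> list[int]:
    """Partner index per position (-1 for unpaired); rejects unbalanced input."""
    stack: list[int] = []
    pt = [-1] * len(db)
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            pt[i], pt[j] = j, i
        elif c != ".":
            raise ValueError(f"invalid dot-bracket character {c!r} at position {i}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return pt


def _pairable_matrix(seq: str) -> np.ndarray:
    """Boolean n x n matrix of allowed pairs; ambiguity codes never pair."""
    s = seq.upper().replace("T", "U")
    n = len(s)
    can = np.zeros((n, n), dtype=np.bool_)
    for i in range(n):
        for j in range(i + 1, n):
            if (s[i], s[j]) in _PAIRS:
                can[i, j] = True
                can[j, i] = True
    return can


@njit(cache=True)
def _nussinov_fill(can_pair, min_hairpin):  # pragma: no cover - jitted
    n = can_pair.shape[0]
    dp = np.zeros((n, n), dtype=np.int32)
    for span in range(min_hairpin + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i + 1, j]
            for k in range(i + min_hairpin + 1, j + 1):
                if can_pair[i, k]:
                    v = 1
                    if k - 1 >= i + 1:
                        v += dp[i + 1, k - 1]
                    if k + 1 <= j:
                        v += dp[k + 1, j]
                    if v > best:
                        best = v
            dp[i, j] = best
    return dp


def _traceback(dp: np.ndarray, can: np.ndarray, min_hairpin: int) -> list[tuple[int, int]]:
    """Deterministic traceback: leave i unpaired on ties, else smallest partner."""
    n = dp.shape[0]
    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)] if n else []
    while stack:
        i, j = stack.pop()
        if j - i <= min_hairpin:
            continue
        if dp[i, j] == dp[i + 1, j]:
            stack.append((i + 1, j))
            continue
        for k in range(i + min_hairpin + 1, j + 1):
            if not can[i, k]:
                continue
            v = 1
            if k - 1 >= i + 1:
                v += dp[i + 1, k - 1]
            if k + 1 <= j:
                v += dp[k + 1, j]
            if v == dp[i, j]:
                pairs.append((i, k))
                if k - 1 > i:
                    stack.append((i + 1, k - 1))
                if k + 1 <= j:
                    stack.append((k + 1, j))
                break
    return sorted(pairs)


def _pairs_to_db(pairs: list[tuple[int, int]], n: int) -> str:
    db = ["."] * n
    for i, j in pairs:
        db[i] = "("
        db[j] = ")"
    return "".join(db)


def _fold_nussinov(seq: str, min_hairpin: int, can: np.ndarray | None = None) -> str:
    if not seq:
        return ""
    if can is None:
        can = _pairable_matrix(seq)
    dp = _nussinov_fill(can, min_hairpin)
    return _pairs_to_db(_traceback(dp, can, min_hairpin), len(seq))


def _fold_external(seq: str) -> str:
    exe = shutil.which("RNAfold")
    if exe is None:
        raise RuntimeError("external_mfe engine requested but RNAfold is not on PATH")
    out = subprocess.run(
        [exe, "--noPS"], input=seq + "\n", capture_output=True, text=True, check=True
    ).stdout.splitlines()
    return out[1].split()[0]


def fold_mfe(sequence: str, config: FoldingConfig | None = None) -> str:
    """Predict one dot-bracket structure for ``sequence``.

    With the builtin engine the result maximizes the number of nested
    Watson-Crick/GU pairs subject to ``min_hairpin`` unpaired positions inside
    every hairpin; the traceback is deterministic.  Empty input yields an
    empty structure.
    """
    config = config or FoldingConfig()
    if not sequence:
        return ""
    if config.engine == "external_mfe":
        return _fold_external(sequence)
    return _fold_nussinov(sequence, config.min_hairpin)


def compute_shift(window_size: int, shift_fraction: float) -> int:
    """Window shift in nucleotides: floor(window_size * fraction), at least 1."""
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    return max(1, int(window_size * shift_fraction))


def _window_offsets(length: int, window_size: int, shift: int) -> list[int]:
    if length <= window_size:
        return [0]
    offsets = []
    off = 0
    while off + window_size < length:
        offsets.append(off)
        off += shift
    last = length - window_size
    if offsets[-1] != last:
        offsets.append(last)
    return offsets


def _suboptimal_structures(seq: str, min_hairpin: int, n_shreps: int) -> list[str]:
    """Optimal structure plus up to n_shreps-1 distinct near-optimal ones.

    Each suboptimal candidate re-runs the DP with one pair of the optimal
    structure forbidden, in 5'-to-3' order of those pairs.
    """
    can = _pairable_matrix(seq)
    dp = _nussinov_fill(can, min_hairpin)
    best_pairs = _traceback(dp, can, min_hairpin)
    structures = [_pairs_to_db(best_pairs, len(seq))]
    for i, j in best_pairs:
        if len(structures) >= n_shreps:
            break
        can2 = can.copy()
        can2[i, j] = False
        can2[j, i] = False
        alt = _fold_nussinov(seq, min_hairpin, can2)
        if alt not in structures:
            structures.append(alt)
    return structures


def windowed_shreps(sequence: str, config: FoldingConfig | None = None) -> ShrepSet:
    """Fold overlapping windows and return structure representatives per window.

    Windows start at 0, s, 2s, ... (s = :func:`compute_shift`); when the
    arithmetic progression would overshoot, the final window is anchored at
    ``length - window_size`` so every window keeps the full window size.
    """
    if not sequence:
        raise ValueError("empty input")
    config = config or FoldingConfig()
    shift = compute_shift(config.window_size, config.shift_fraction)
    offsets = _window_offsets(len(sequence), config.window_size, shift)
    windows = []
    for off in offsets:
        sub = sequence[off : off + config.window_size]
        if config.engine == "external_mfe":
            structs = [_fold_external(sub)]
        else:
            structs = _suboptimal_structures(sub, config.min_hairpin, config.n_shreps)
        windows.append((off, structs))
    return ShrepSet(windows=windows)


def annotate_structure(sequence: str, db: str) -> str:
    """Annotate each position with a substructure state.

    S: paired.  H: unpaired in a hairpin loop (enclosing pair closes no inner
    stem).  I: unpaired in an internal loop or bulge (exactly one inner stem).
    M: unpaired in a multi-loop (>= 2 inner stems) or in an external segment
    between two top-level stems.  F / T: external unpaired positions before
    the first / after the last paired position.  A fully unpaired structure
    annotates as all F.
    """
    if len(sequence) != len(db):
        raise ValueError(
            f"sequence length {len(sequence)} != structure length {len(db)}"
        )
    n = len(db)
    if n == 0:
        return ""
    pt = pair_table(db)
    paired = [i for i in range(n) if pt[i] >= 0]
    if not paired:
        return "F" * n

    # direct child-stem count for each opening position
    children: dict[int, int] = {}
    for i in range(n):
        if pt[i] > i:
            cnt = 0
            k = i + 1
            while k < pt[i]:
                if pt[k] > k:
                    cnt += 1
                    k = pt[k] + 1
                else:
                    k += 1
            children[i] = cnt

    first, last = paired[0], paired[-1]
    states = []
    enclosing: list[int] = []  # stack of opening positions
    for i in range(n):
        if pt[i] >= 0:
            states.append("S")
            if pt[i] > i:
                enclosing.append(i)
            else:
                enclosing.pop()
        elif not enclosing:
            if i < first:
                states.append("F")
            elif i > last:
                states.append("T")
            else:
                states.append("M")
        else:
            c = children[enclosing[-1]]
            states.append("H" if c == 0 else ("I" if c == 1 else "M"))
    return "".join(states)


def write_vienna(path, entries: list[tuple[str, str, str]]) -> None:
    """Write (id, sequence, structure) triples in Vienna style."""
    with open(path, "w") as fh:
        for rid, seq, db in entries:
            fh.write(f">{rid}\n{seq}\n{db}\n")


def write_shreps_tsv(path, shreps_by_id: dict[str, ShrepSet]) -> None:
    with open(path, "w") as fh:
        fh.write("id\toffset\tstructure\n")
        for rid, shreps in shreps_by_id.items():
            for off, structs in shreps.windows:
                for db in structs:
                    fh.write(f"{rid}\t{off}\t{db}\n")
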