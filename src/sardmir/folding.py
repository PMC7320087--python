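"""RNA secondary structure prediction for precursor candidates.

The folder is a deterministic dynamic-programming minimizer over a simple
additive pair-energy model (G:C -3, A:U -2, G:U -1 kcal/mol, hairpin loops
of at least 3 unpaired nt, no pseudoknots).  It is intentionally *not* a
nearest-neighbor thermodynamic engine: the pipeline only needs a stable,
reproducible notion of "folds into a hairpin", and the published absolute
MFE values are carried as data rather than recomputed.  A pluggable folder
protocol lets users substitute a thermodynamic engine with the same
contract.

``brute_force_fold`` enumerates every non-crossing pairing on short
sequences and serves as the independent testing oracle for the DP.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Protocol

import numpy as np

from .errors import AnatomyError, DomainError
from .sequence import can_pair, normalize_to_rna

#: Pair energies (kcal/mol) of the simple additive model.
PAIR_ENERGY = {
    ("G", "C"): -3.0,
    ("C", "G"): -3.0,
    ("A", "U"): -2.0,
    ("U", "A"): -2.0,
    ("G", "U"): -1.0,
    ("U", "G"): -1.0,
}

#: Minimum number of unpaired nt in a hairpin loop.
MIN_LOOP = 3

_INT_ENERGY = {k: int(v) for k, v in PAIR_ENERGY.items()}


@dataclass(frozen=True)
class SecondaryStructure:
    """A sequence with its dot-bracket structure and folding energy.

    Invariants enforced on construction: brackets balanced and non-crossing,
    every pair Watson-Crick or G:U, every hairpin loop at least
    :data:`MIN_LOOP` unpaired nt, energy non-positive and zero iff unpaired.
    """

    seq: str
    dot_bracket: str
    energy: float

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.dot_bracket):
            raise DomainError("sequence and dot-bracket lengths differ")
        if set(self.dot_bracket) - set("(.)"):
            raise DomainError("dot-bracket may only contain '(', '.', ')'")
        pairs = _pairs_from_dotbracket(self.dot_bracket)
        for i, j in pairs:
            if not can_pair(self.seq[i], self.seq[j]):
                raise DomainError(
                    f"positions {i + 1}/{j + 1} ({self.seq[i]}:{self.seq[j]}) "
                    "cannot pair"
                )
            if j - i - 1 < MIN_LOOP and _is_hairpin_closing(pairs, i, j):
                raise DomainError(
                    f"hairpin loop closed by {i + 1}:{j + 1} spans "
                    f"{j - i - 1} nt (< {MIN_LOOP})"
                )
        if self.energy > 0:
            raise DomainError("folding energy must be <= 0")
        if (self.energy == 0) != (not pairs):
            raise DomainError("energy is 0 iff the structure has no pairs")

    @property
    def pairs(self) -> list[tuple[int, int]]:
        """Base pairs as 0-based (i, j) tuples, i < j, sorted by i."""
        return _pairs_from_dotbracket(self.dot_bracket)

    def pair_table(self) -> dict[int, int]:
        """Symmetric 0-based position -> partner map for paired positions."""
        table: dict[int, int] = {}
        for i, j in self.pairs:
            table[i] = j
            table[j] = i
        return table


def _pairs_from_dotbracket(db: str) -> list[tuple[int, int]]:
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise DomainError(f"unbalanced ')' at position {i + 1}")
            pairs.append((stack.pop(), i))
    if stack:
        raise DomainError(f"unbalanced '(' at position {stack[-1] + 1}")
    return sorted(pairs)


def _is_hairpin_closing(pairs: list[tuple[int, int]], i: int, j: int) -> bool:
    """True if (i, j) closes a hairpin loop (no pair strictly inside)."""
    return not any(i < a and b < j for a, b in pairs)


def structure_energy(seq: str, pairs: list[tuple[int, int]]) -> float:
    """Additive energy of a pairing under :data:`PAIR_ENERGY`."""
    return float(sum(PAIR_ENERGY[(seq[i], seq[j])] for i, j in pairs))


class Folder(Protocol):
    """Anything that maps an RNA string to a :class:`SecondaryStructure`.

    The shipped DP folder satisfies this; an external thermodynamic engine
    (e.g. a ViennaRNA wrapper) can be dropped into the pipeline in its
    place as long as it honours determinism and the structure invariants.
    """

    def __call__(self, seq: str) -> SecondaryStructure: ...


def fold(seq: str, *, min_len: int = 10) -> SecondaryStructure:
    """Minimum-energy non-crossing structure under the additive pair model.

    Deterministic: among equal-energy optima the traceback pairs the
    5'-most pairable position first, choosing its outermost admissible
    partner (favouring one enclosing stem over equal-energy branched
    layouts).  Sequences shorter than ``min_len`` raise
    :class:`DomainError` (the brute-force oracle relaxes this guard).
    """
    seq = normalize_to_rna(seq)
    if len(seq) < min_len:
        raise DomainError(f"fold needs >= {min_len} nt, got {len(seq)}")
    return _fold_any(seq)


def _fold_any(seq: str) -> SecondaryStructure:
    n = len(seq)
    # integer energy matrix of the i..j subproblem; exact comparisons.
    pair_e = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        a = seq[i]
        for j in range(i + MIN_LOOP + 1, n):
            pair_e[i, j] = _INT_ENERGY.get((a, seq[j]), 1)  # 1 == forbidden
    allowed = pair_e < 0

    BIG = np.int64(1) << 40
    # W padded by one row/col so W[i, j] with j < i reads as 0.
    W = np.zeros((n + 2, n + 2), dtype=np.int64)

    # E(i, j) = min( E(i+1, j),  min_k pair(i,k) + E(i+1,k-1) + E(k+1,j) )
    for span in range(MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = W[i + 1, j]
            ks = np.arange(i + MIN_LOOP + 1, j + 1)
            ok = allowed[i, ks]
            if ok.any():
                ksv = ks[ok]
                cand = pair_e[i, ksv] + W[i + 1, ksv - 1] + W[ksv + 1, j]
                m = cand.min()
                if m < best:
                    best = m
            W[i, j] = best

    # greedy deterministic traceback
    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        while i < j:
            target = W[i, j]
            if target == 0:
                break
            paired = False
            if target != W[i + 1, j]:
                # ties: prefer the outermost partner, which favours one
                # long enclosing stem over equal-energy branched layouts
                for k in range(j, i + MIN_LOOP, -1):
                    if (
                        allowed[i, k]
                        and pair_e[i, k] + W[i + 1, k - 1] + W[k + 1, j]
                        == target
                    ):
                        pairs.append((i, k))
                        stack.append((k + 1, j))
                        i, j = i + 1, k - 1
                        paired = True
                        break
            if not paired:
                i += 1
    db = ["."] * n
    for i, j in pairs:
        db[i], db[j] = "(", ")"
    energy = structure_energy(seq, pairs)
    assert energy == float(W[0, n - 1]) if n > 1 else True
    return SecondaryStructure(seq, "".join(db), energy)


BRUTE_FORCE_MAX = 14


def _enumerate_pairings(
    seq: str, i: int, j: int, memo: dict
) -> list[list[tuple[int, int]]]:
    """All non-crossing pairings of seq[i..j] honouring the loop minimum."""
    if (i, j) in memo:
        return memo[(i, j)]
    if j - i < MIN_LOOP + 1:
        return [[]]
    out: list[list[tuple[int, int]]] = []
    # position i unpaired
    out.extend(_enumerate_pairings(seq, i + 1, j, memo))
    # position i paired with k
    for k in range(i + MIN_LOOP + 1, j + 1):
        if can_pair(seq[i], seq[k]):
            for inner in _enumerate_pairings(seq, i + 1, k - 1, memo):
                for outer in _enumerate_pairings(seq, k + 1, j, memo):
                    out.append([(i, k)] + inner + outer)
    memo[(i, j)] = out
    return out


def brute_force_fold(seq: str) -> SecondaryStructure:
    """Exhaustive-enumeration optimum; testing oracle for :func:`fold`.

    Refuses sequences longer than :data:`BRUTE_FORCE_MAX` nt.  Ties are
    broken by the lexicographically smallest dot-bracket ('(' < ')' < '.'),
    which prefers structures pairing the 5'-most positions first.
    """
    seq = normalize_to_rna(seq)
    if len(seq) > BRUTE_FORCE_MAX:
        raise DomainError(
            f"brute-force folding is limited to {BRUTE_FORCE_MAX} nt"
        )
    n = len(seq)
    best: tuple[float, str] | None = None
    for pairing in _enumerate_pairings(seq, 0, n - 1, {}):
        db = ["."] * n
        for i, j in pairing:
            db[i], db[j] = "(", ")"
        key = (structure_energy(seq, pairing), "".join(db))
        if best is None or key < best:
            best = key
    assert best is not None
    return SecondaryStructure(seq, best[1], best[0])


@dataclass(frozen=True)
class HairpinAnatomy:
    """Decomposition of a structure into hairpin elements.

    ``loops`` holds every hairpin loop as a 0-based inclusive (start, end)
    range of unpaired positions; ``five_arm`` / ``three_arm`` /
    ``terminal_loop`` are only set for single-hairpin structures and span
    the closing stem from its outermost enclosing pair to the loop.
    """

    n_hairpin_loops: int
    loops: tuple[tuple[int, int], ...]
    paired_partner: dict[int, int] = field(repr=False)
    length: int = 0
    five_arm: tuple[int, int] | None = None
    three_arm: tuple[int, int] | None = None
    terminal_loop: tuple[int, int] | None = None


def parse_hairpin(ss: SecondaryStructure) -> HairpinAnatomy:
    """Identify hairpin loops and, for single-hairpin structures, the arms.

    A hairpin loop is a maximal unpaired run directly closed by a pair.
    Structures with zero pairs raise :class:`AnatomyError`.
    """
    pairs = ss.pairs
    if not pairs:
        raise AnatomyError("no stem: structure has no base pairs")
    partner = ss.pair_table()
    loops = tuple(
        (i + 1, j - 1) for i, j in pairs if _is_hairpin_closing(pairs, i, j)
    )
    five = three = terminal = None
    if len(loops) == 1:
        lo, hi = loops[0]
        outer_i, outer_j = hairpin_element_span(ss, (lo - 1, hi + 1))
        five = (outer_i, lo - 1)
        three = (hi + 1, outer_j)
        terminal = loops[0]
    return HairpinAnatomy(
        n_hairpin_loops=len(loops),
        loops=loops,
        paired_partner=partner,
        length=len(ss.seq),
        five_arm=five,
        three_arm=three,
        terminal_loop=terminal,
    )


def hairpin_element_span(
    ss: SecondaryStructure, closing: tuple[int, int]
) -> tuple[int, int]:
    """Outermost pair whose subtree contains only the given hairpin loop.

    Walk outward from the loop-closing pair through enclosing pairs while
    no second hairpin loop enters the subtree.
    """
    pairs = ss.pairs
    loop_closers = [
        (i, j) for i, j in pairs if _is_hairpin_closing(pairs, i, j)
    ]
    i, j = closing
    enclosing = sorted(
        ((a, b) for a, b in pairs if a <= i and j <= b),
        key=lambda p: p[0],
        reverse=True,
    )  # innermost first
    span = closing
    for a, b in enclosing:
        inside = [
            (x, y) for x, y in loop_closers if a <= x and y <= b
        ]
        if len(inside) > 1:
            break
        span = (a, b)
    return span


# ---------------------------------------------------------------------------
# Vienna-style dot-bracket file IO

_ENERGY_RE = re.compile(r"\(\s*(-?\d+(?:\.\d+)?)\s*\)\s*$")


def write_dotbracket(
    records: list[tuple[str, SecondaryStructure]], path
) -> None:
    """Write ``>id / seq / structure ( energy )`` records."""
    with open(path, "w") as fh:
        for rid, ss in records:
            fh.write(f">{rid}\n{ss.seq}\n{ss.dot_bracket} ({ss.energy:7.2f})\n")


def read_dotbracket(path) -> Iterator[tuple[str, SecondaryStructure]]:
    """Inverse of :func:`write_dotbracket`."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    for k in range(0, len(lines), 3):
        rid = lines[k].lstrip(">")
        seq = lines[k + 1]
        struct_line = lines[k + 2]
        m = _ENERGY_RE.search(struct_line)
        if not m:
            raise DomainError(f"record {rid}: missing '( energy )' suffix")
        yield rid, SecondaryStructure(
            seq, struct_line[: m.start()].strip(), float(m.group(1))
        )
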