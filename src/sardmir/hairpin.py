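"""Stem-loop filtering of precursor candidates.

Implements the four published screening rules for a candidate pre-miRNA:

1. the precursor folds into a stem-loop with the mature sequence on one arm;
2. the mature sequence does not overlap the terminal loop;
3. the mature has fewer than nine mismatches with the opposite-arm (star)
   sequence — i.e. at most 8;
4. the structure shows low MFE and high MFEI; the MFEI floor defaults to
   0.70, the smallest value in the published catalog and above the cited
   mRNA band (0.62-0.66).

MFEI = (|MFE| / precursor length x 100) / GC%.  Report-form MFEI values are
truncated (not rounded) to two decimals, matching the published table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import AnatomyError, CoordinateError, DomainError
from .folding import (
    HairpinAnatomy,
    SecondaryStructure,
    hairpin_element_span,
    parse_hairpin,
)

ARM_FIVE = "five_prime"
ARM_THREE = "three_prime"


def truncate2(x: float) -> float:
    """Truncate to two decimals (1.3361 -> 1.33; never rounds up)."""
    return math.floor(x * 100 + 1e-9) / 100


def compute_gc(seq: str) -> float:
    """G+C percentage of a sequence, full precision."""
    if not seq:
        raise DomainError("GC content of an empty sequence is undefined")
    return 100.0 * sum(c in "GC" for c in seq) / len(seq)


def compute_mfei(
    mfe: float, length: int, gc: float, *, report: bool = False
) -> float:
    """Minimum folding free energy index.

    ``(|mfe| / length x 100) / gc``; with ``report=True`` the value is
    truncated to two decimals as in the published table.
    """
    if length <= 0:
        raise DomainError("precursor length must be positive")
    if gc <= 0:
        raise DomainError("GC percentage must be positive")
    if mfe > 0:
        raise DomainError("MFE must be <= 0")
    value = (abs(mfe) / length * 100.0) / gc
    return truncate2(value) if report else value


@dataclass(frozen=True)
class FilterThresholds:
    """Tunable screening thresholds (defaults follow the published rules)."""

    max_star_mismatches: int = 8
    min_mfei: float = 0.70
    min_loop: int = 3

    def __post_init__(self) -> None:
        if (
            self.max_star_mismatches < 0
            or self.min_mfei < 0
            or self.min_loop < 0
        ):
            raise DomainError("thresholds must be non-negative")


def _check_range(structure_len: int, mature_range: tuple[int, int]) -> None:
    s, e = mature_range
    if not (0 <= s <= e < structure_len):
        raise CoordinateError(
            f"mature range {mature_range} outside structure of length "
            f"{structure_len}"
        )


def mature_arm_check(
    anatomy: HairpinAnatomy, mature_range: tuple[int, int]
) -> tuple[bool, str | None]:
    """Is the mature (0-based inclusive range) wholly on a single arm?

    Passes iff every mature position lies within exactly one arm and none
    falls in the terminal loop; returns the arm label used for the
    catalog's Location column.  Requires a single-hairpin anatomy.
    """
    if anatomy.five_arm is None or anatomy.three_arm is None:
        raise AnatomyError("arm check requires a single-hairpin anatomy")
    _check_range(anatomy.length, mature_range)
    s, e = mature_range
    f0, f1 = anatomy.five_arm
    t0, t1 = anatomy.three_arm
    if f0 <= s and e <= f1:
        return True, ARM_FIVE
    if t0 <= s and e <= t1:
        return True, ARM_THREE
    return False, None


def count_star_mismatches(
    structure: SecondaryStructure, mature_range: tuple[int, int]
) -> int:
    """Mature positions not paired to the opposite arm.

    A "mismatch" with the star sequence is any mature position lacking a
    partner outside the mature itself (covers true mismatches and bulges).
    The caller must have established via :func:`mature_arm_check` that the
    mature avoids the terminal loop; a mature position inside a hairpin
    loop raises :class:`DomainError`.
    """
    _check_range(len(structure.seq), mature_range)
    s, e = mature_range
    anatomy = parse_hairpin(structure)
    for lo, hi in anatomy.loops:
        if s <= hi and lo <= e:
            raise DomainError(
                "mature overlaps a hairpin loop; run mature_arm_check first"
            )
    partner = structure.pair_table()
    count = 0
    for pos in range(s, e + 1):
        p = partner.get(pos)
        if p is None or s <= p <= e:
            count += 1
    return count


def trim_to_hairpin(
    window_seq: str,
    structure: SecondaryStructure,
    mature_range: tuple[int, int],
) -> tuple[str, tuple[int, int]]:
    """Minimal subsequence spanning the hairpin around mature and star.

    Returns the subsequence under the outermost base pair that encloses
    both the mature and its star region while still containing a single
    hairpin loop, together with its 0-based inclusive coordinates in the
    window.  Raises :class:`AnatomyError` when no base pair encloses the
    mature/star region.
    """
    _check_range(len(structure.seq), mature_range)
    s, e = mature_range
    partner = structure.pair_table()
    positions = set(range(s, e + 1))
    star = {partner[p] for p in range(s, e + 1) if p in partner}
    region = positions | star
    lo, hi = min(region), max(region)
    enclosing = [
        (a, b) for a, b in structure.pairs if a <= lo and hi <= b
    ]
    if not enclosing:
        raise AnatomyError(
            "no base pair encloses the mature and its star region"
        )
    innermost = max(enclosing, key=lambda p: p[0])
    a, b = hairpin_element_span(structure, innermost)
    return window_seq[a : b + 1], (a, b)


@dataclass
class PrecursorCandidate:
    """A folded precursor window with its filter verdict.

    ``mature_range`` is 0-based inclusive within ``structure.seq``.  The
    trimmed fields and GC/MFE/MFEI are filled by the pipeline on the
    trimmed precursor; ``classify_candidate`` fills verdict and reasons.
    """

    structure: SecondaryStructure
    mature_range: tuple[int, int]
    name: str = ""
    trimmed_seq: str = ""
    trimmed_range: tuple[int, int] | None = None
    gc_percent: float = float("nan")
    mfe: float = float("nan")
    mfei: float = float("nan")
    arm: str | None = None
    star_mismatches: int | None = None
    verdict: str = "unclassified"
    rejection_reasons: list[str] = field(default_factory=list)


REASON_MULTI_LOOP = "not a single stem-loop (multiple hairpin loops)"
REASON_NO_STEM = "no stem-loop structure"
REASON_ARM = "mature not contained within one arm / overlaps terminal loop"
REASON_STAR = "more than the allowed star mismatches"
REASON_MFEI = "MFEI below threshold"


def classify_candidate(
    cand: PrecursorCandidate,
    thresholds: FilterThresholds = FilterThresholds(),
) -> PrecursorCandidate:
    """Apply the four screening rules; fill verdict and every violated rule.

    Expects ``cand.structure`` to be the folded (trimmed) precursor and
    ``cand.mfei`` computed on it.  Monotone in the thresholds: relaxing
    any threshold never rejects a previously accepted candidate.
    """
    reasons: list[str] = []
    try:
        anatomy = parse_hairpin(cand.structure)
    except AnatomyError:
        anatomy = None
        reasons.append(REASON_NO_STEM)
    if anatomy is not None:
        if anatomy.n_hairpin_loops != 1:
            reasons.append(REASON_MULTI_LOOP)
        else:
            ok, arm = mature_arm_check(anatomy, cand.mature_range)
            if not ok:
                reasons.append(REASON_ARM)
            else:
                cand.arm = arm
                mism = count_star_mismatches(
                    cand.structure, cand.mature_range
                )
                cand.star_mismatches = mism
                if mism > thresholds.max_star_mismatches:
                    reasons.append(REASON_STAR)
    if not math.isnan(cand.mfei) and cand.mfei < thresholds.min_mfei:
        reasons.append(REASON_MFEI)
    cand.rejection_reasons = reasons
    cand.verdict = "accepted" if not reasons else "rejected"
    return cand
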