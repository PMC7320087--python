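"""Rule-based miRNA target-site prediction.

Candidate transcripts are pre-screened by local alignment of the mature's
reverse complement (at least 75% of the mature aligned and at least 75%
identity over the aligned columns, both configurable), then each candidate
site is globally aligned against the mature and screened by the three seed
rules:

1. no mismatches at mature positions 2-8 (the seed region);
2. at most one G:U wobble in the seed;
3. at most four gap columns whose miRNA-side coordinate falls in 9-21.

Positions are counted from the miRNA 5' end.  No hybridization free energy
is computed; the screen is purely rule-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from Bio import Align

from .errors import DomainError
from .sequence import normalize_to_rna, reverse_complement

# duplex pairing states, per mature position (5'->3')
WC = "WC"
GU = "GU"
MM = "MM"
GAP_M = "GAP_M"  # mature position aligned to a gap (deletion in the site)
# GAP_T: site nucleotide aligned to a gap in the mature, recorded as an
# insertion between mature positions.

#: Needleman-Wunsch scoring of the duplex alignment.
SCORE_WC = 2
SCORE_GU = 1
SCORE_MM = -1
SCORE_GAP = -2

SEED = (2, 8)  # inclusive, 1-based mature coordinates
GAP_REGION = (9, 21)


@dataclass(frozen=True)
class CandidateSite:
    """A pre-screen hit on a transcript (1-based inclusive coordinates)."""

    transcript_id: str
    start: int
    end: int
    site_seq: str
    coverage_percent: float
    identity_percent: float


@dataclass(frozen=True)
class DuplexAlignment:
    """Per-position pairing states of a miRNA-target duplex.

    ``states[k]`` is the state of mature position ``k+1`` (from the miRNA
    5' end); ``insertions`` maps a mature position ``p`` to the number of
    unpaired site nucleotides inserted between ``p`` and ``p+1`` (GAP_T
    columns; position 0 means before the first mature position).
    """

    mirna_id: str
    transcript_id: str
    site_start: int
    site_end: int
    states: tuple[str, ...]
    insertions: dict[int, int] = field(default_factory=dict)
    coverage_percent: float = 100.0
    identity_percent: float = 100.0

    @property
    def length(self) -> int:
        return len(self.states)


@dataclass(frozen=True)
class SeedRuleVerdict:
    """Outcome of the three duplex rules with the violated ones listed."""

    passed: bool
    seed_mismatches: int
    seed_gu: int
    gaps_9_21: int
    reasons: tuple[str, ...]


def _prescreen_aligner() -> Align.PairwiseAligner:
    # megablast-flavoured local scoring for the coverage/identity screen
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    return aligner


def prescreen_targets(
    mature: str,
    transcripts: Mapping[str, str],
    min_coverage: float = 75.0,
    min_identity: float = 75.0,
) -> list[CandidateSite]:
    """Complementarity pre-screen of a mature against whole transcripts.

    Locally aligns the mature's reverse complement in overlapping chunks of
    each transcript; a site is kept when at least ``min_coverage`` percent
    of the mature aligns and at least ``min_identity`` percent of the
    aligned columns match.  Overlapping chunk hits are deduplicated,
    keeping the best-scoring site.
    """
    mature = normalize_to_rna(mature)
    if not transcripts:
        warnings.warn("empty transcript set; nothing to pre-screen")
        return []
    probe = reverse_complement(mature)
    L = len(mature)
    aligner = _prescreen_aligner()
    raw: dict[str, list[CandidateSite]] = {}
    chunk, step = 4 * L, 2 * L
    for tid, seq in transcripts.items():
        seq = normalize_to_rna(seq)
        for off in range(0, max(1, len(seq) - L + 1), step):
            piece = seq[off : off + chunk]
            if len(piece) < L * min_coverage / 100:
                continue
            alignments = aligner.align(piece, probe)
            if alignments.score <= 0:
                continue
            aln = alignments[0]
            cov, ident, t0, t1 = _local_stats(aln, L)
            if cov >= min_coverage and ident >= min_identity:
                # extend the local span so the site covers the whole mature
                start = max(1, off + t0 + 1)
                end = min(len(seq), off + t1)
                raw.setdefault(tid, []).append(
                    CandidateSite(
                        tid, start, end, seq[start - 1 : end], cov, ident
                    )
                )
    # keep the best site among mutually overlapping chunk hits
    out: list[CandidateSite] = []
    for tid, cands in raw.items():
        cands.sort(
            key=lambda s: (-s.identity_percent, -s.coverage_percent, s.start)
        )
        chosen: list[CandidateSite] = []
        for s in cands:
            if all(s.end < c.start or s.start > c.end for c in chosen):
                chosen.append(s)
        out.extend(chosen)
    return sorted(out, key=lambda s: (s.transcript_id, s.start))


def _local_stats(aln, probe_len: int) -> tuple[float, float, int, int]:
    """Coverage/identity of a local alignment plus the extended target span.

    The returned (t0, t1) span is widened by the unaligned probe flanks so
    the excised site faces the entire mature during duplex alignment.
    """
    t, q = aln.aligned  # blocks on target (transcript chunk) and query
    aligned_cols = sum(b - a for a, b in q)
    matches = 0
    for (ta, tb), (qa, qb) in zip(t, q):
        for k in range(tb - ta):
            if aln.target[ta + k] == aln.query[qa + k]:
                matches += 1
    coverage = 100.0 * aligned_cols / probe_len
    identity = 100.0 * matches / aligned_cols if aligned_cols else 0.0
    t0 = int(t[0][0]) - int(q[0][0])
    t1 = int(t[-1][1]) + (probe_len - int(q[-1][1]))
    return coverage, identity, max(0, t0), t1


def align_duplex(
    mature: str,
    site: str,
    *,
    mirna_id: str = "",
    transcript_id: str = "",
    site_start: int = 1,
) -> DuplexAlignment:
    """Global complementarity alignment of a mature against a site.

    The site (given 5'->3' as on the transcript) is reverse-complemented
    and aligned to the mature under WC=+2, G:U=+1, mismatch=-1, gap=-2.
    Ties are broken deterministically (pairing preferred over gaps,
    site-side gaps over mature-side gaps).
    """
    mature = normalize_to_rna(mature)
    if not mature or not site:
        raise DomainError("mature and site must be non-empty")
    rc_site = reverse_complement(normalize_to_rna(site))
    n, m = len(mature), len(rc_site)

    def col_score(a: str, b: str) -> int:
        if a == b:
            return SCORE_WC
        # after reverse complement, a G:U wobble shows up as G~A or U~C
        if (a, b) in (("G", "A"), ("U", "C")):
            return SCORE_GU
        return SCORE_MM

    # Needleman-Wunsch, linear gaps
    NEG = -(10**9)
    score = [[NEG] * (m + 1) for _ in range(n + 1)]
    move = [[""] * (m + 1) for _ in range(n + 1)]
    score[0][0] = 0
    for i in range(1, n + 1):
        score[i][0] = i * SCORE_GAP
        move[i][0] = "U"
    for j in range(1, m + 1):
        score[0][j] = j * SCORE_GAP
        move[0][j] = "L"
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = score[i - 1][j - 1] + col_score(mature[i - 1], rc_site[j - 1])
            up = score[i - 1][j] + SCORE_GAP  # mature vs gap (GAP_M)
            left = score[i][j - 1] + SCORE_GAP  # site nt vs gap (GAP_T)
            best = max(diag, left, up)
            score[i][j] = best
            move[i][j] = "D" if best == diag else ("L" if best == left else "U")

    states: list[str] = []
    insertions: dict[int, int] = {}
    i, j = n, m
    rev_cols: list[tuple[str, int]] = []  # (kind, mature_pos)
    while i > 0 or j > 0:
        mv = move[i][j]
        if mv == "D":
            a, b = mature[i - 1], rc_site[j - 1]
            kind = WC if a == b else (GU if col_score(a, b) == SCORE_GU else MM)
            rev_cols.append((kind, i))
            i, j = i - 1, j - 1
        elif mv == "U":
            rev_cols.append((GAP_M, i))
            i -= 1
        else:
            rev_cols.append(("GAP_T", i))
            j -= 1
    for kind, pos in reversed(rev_cols):
        if kind == "GAP_T":
            insertions[pos] = insertions.get(pos, 0) + 1
        else:
            states.append(kind)
    assert len(states) == n
    aligned = sum(s != GAP_M for s in states)
    ident = sum(s == WC for s in states)
    return DuplexAlignment(
        mirna_id=mirna_id,
        transcript_id=transcript_id,
        site_start=site_start,
        site_end=site_start + len(site) - 1,
        states=tuple(states),
        insertions=insertions,
        coverage_percent=100.0 * aligned / n,
        identity_percent=100.0 * ident / aligned if aligned else 0.0,
    )


def apply_seed_rules(aln: DuplexAlignment) -> SeedRuleVerdict:
    """Screen a duplex by the three published rules.

    Seed mismatches count MM and gap columns at mature positions 2-8;
    ``gaps_9_21`` counts both mature-side and site-side gap columns whose
    miRNA coordinate falls in 9-21 (an insertion between positions p and
    p+1 is attributed to p).
    """
    if aln.length < SEED[1]:
        raise DomainError(
            f"alignment spans {aln.length} mature positions; "
            f"seed rules need at least {SEED[1]}"
        )
    lo, hi = SEED
    seed_states = aln.states[lo - 1 : hi]
    seed_mm = sum(s in (MM, GAP_M) for s in seed_states)
    seed_mm += sum(
        c for p, c in aln.insertions.items() if lo <= p < hi
    )
    seed_gu = sum(s == GU for s in seed_states)
    g0, g1 = GAP_REGION
    gaps = sum(
        s == GAP_M for s in aln.states[g0 - 1 : min(g1, aln.length)]
    )
    gaps += sum(c for p, c in aln.insertions.items() if g0 <= p <= g1)
    reasons = []
    if seed_mm > 0:
        reasons.append("seed mismatch")
    if seed_gu > 1:
        reasons.append("more than one G:U pair in seed")
    if gaps > 4:
        reasons.append("more than four gaps in positions 9-21")
    return SeedRuleVerdict(
        passed=not reasons,
        seed_mismatches=seed_mm,
        seed_gu=seed_gu,
        gaps_9_21=gaps,
        reasons=tuple(reasons),
    )


def scan_targets(
    matures: Mapping[str, str],
    transcripts: Mapping[str, str],
    min_coverage: float = 75.0,
    min_identity: float = 75.0,
) -> pd.DataFrame:
    """Full target scan: pre-screen then seed rules for every mature.

    Returns one row per (miRNA, transcript, site) triple passing both
    stages; a miRNA may target many transcripts and vice versa.  The frame
    is empty (with the full schema) when nothing passes.
    """
    rows = []
    for mid, mature in matures.items():
        for site in prescreen_targets(
            mature, transcripts, min_coverage, min_identity
        ):
            aln = align_duplex(
                mature,
                site.site_seq,
                mirna_id=mid,
                transcript_id=site.transcript_id,
                site_start=site.start,
            )
            verdict = apply_seed_rules(aln)
            if verdict.passed:
                rows.append(
                    {
                        "mirna_id": mid,
                        "transcript_id": site.transcript_id,
                        "site_start": site.start,
                        "site_end": site.end,
                        "coverage_percent": round(site.coverage_percent, 1),
                        "identity_percent": round(site.identity_percent, 1),
                        "seed_mismatches": verdict.seed_mismatches,
                        "seed_gu": verdict.seed_gu,
                        "gaps_9_21": verdict.gaps_9_21,
                    }
                )
    columns = [
        "mirna_id",
        "transcript_id",
        "site_start",
        "site_end",
        "coverage_percent",
        "identity_percent",
        "seed_mismatches",
        "seed_gu",
        "gaps_9_21",
    ]
    df = pd.DataFrame(rows, columns=columns)
    return df.sort_values(
        ["mirna_id", "transcript_id", "site_start"]
    ).reset_index(drop=True)
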