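"""Exact-match mapping of reference mature miRNAs onto a genome.

The conserved-miRNA discovery strategy maps known mature sequences (e.g.
zebrafish ``dre-`` and cod ``gmo-`` sets) onto the target genome, keeping
only perfect matches on either strand, excises a window of +/-200 nt around
each hit as the candidate precursor, and discards windows that look
protein-coding (a long open reading frame in any of the six frames).

Coordinates are 1-based inclusive on the forward strand (GenBank
convention); minus-strand hits report the reverse-complement locus.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

from .errors import CoordinateError, DomainError
from .sequence import normalize_to_rna, reverse_complement

STOP_CODONS = ("UAA", "UAG", "UGA")


@dataclass(frozen=True)
class ReferenceMature:
    """A reference mature miRNA (18-26 nt, pure RNA)."""

    ref_id: str
    species_prefix: str
    seq: str

    def __post_init__(self) -> None:
        if not 18 <= len(self.seq) <= 26:
            raise DomainError(
                f"{self.ref_id}: mature length {len(self.seq)} outside 18-26"
            )
        if set(self.seq) - set("ACGU"):
            raise DomainError(f"{self.ref_id}: sequence is not pure RNA")


@dataclass(frozen=True, order=True)
class GenomeHit:
    """An exact match of a reference mature on the genome.

    ``start``/``end`` are 1-based inclusive forward-strand coordinates;
    ``matched_seq`` reads 5'->3' on the hit strand (equals the reference).
    """

    contig: str
    start: int
    end: int
    strand: str
    ref_id: str
    matched_seq: str


@dataclass(frozen=True)
class PrecursorWindow:
    """The genomic window excised around a hit, 5'->3' on the hit strand."""

    hit: GenomeHit
    window_seq: str
    mature_offset: int
    flank_up: int
    flank_down: int

    def __post_init__(self) -> None:
        got = self.window_seq[
            self.mature_offset : self.mature_offset + len(self.hit.matched_seq)
        ]
        if got != self.hit.matched_seq:
            raise CoordinateError(
                f"window does not contain the mature at offset "
                f"{self.mature_offset}"
            )

    @property
    def mature_range(self) -> tuple[int, int]:
        """0-based inclusive range of the mature within the window."""
        return (
            self.mature_offset,
            self.mature_offset + len(self.hit.matched_seq) - 1,
        )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (possibly gzipped) FASTA into {id: RNA-normalized sequence}."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        records = {rec.id: normalize_to_rna(str(rec.seq)) for rec in SeqIO.parse(fh, "fasta")}
    return records


def load_reference_matures(path: str | Path) -> list[ReferenceMature]:
    """Load a miRBase-style mature FASTA (ids like ``dre-miR-1``)."""
    return [
        ReferenceMature(ref_id=rid, species_prefix=rid.split("-", 1)[0], seq=seq)
        for rid, seq in read_fasta(path).items()
    ]


def _find_all(haystack: str, needle: str) -> Iterable[int]:
    start = 0
    while True:
        idx = haystack.find(needle, start)
        if idx < 0:
            return
        yield idx
        start = idx + 1


def find_exact_matches(
    refs: Iterable[ReferenceMature], genome: Mapping[str, str]
) -> list[GenomeHit]:
    """Every exact occurrence of every reference on either genome strand.

    ``N`` in the genome never matches.  Output sorted by
    (contig, start, ref_id).
    """
    refs = list(refs)
    if not refs:
        raise DomainError("reference mature set is empty")
    hits: list[GenomeHit] = []
    for contig, seq in genome.items():
        for ref in refs:
            L = len(ref.seq)
            for idx in _find_all(seq, ref.seq):
                hits.append(
                    GenomeHit(contig, idx + 1, idx + L, "+", ref.ref_id, ref.seq)
                )
            # minus strand: forward genome contains revcomp(reference)
            for idx in _find_all(seq, reverse_complement(ref.seq)):
                hits.append(
                    GenomeHit(contig, idx + 1, idx + L, "-", ref.ref_id, ref.seq)
                )
    hits.sort(key=lambda h: (h.contig, h.start, h.ref_id, h.strand))
    return hits


def dedupe_hits(hits: Iterable[GenomeHit]) -> tuple[list[GenomeHit], int]:
    """Collapse hits identical in (contig, start, end, strand).

    Keeps the lexicographically smallest ref_id per locus; returns the
    deduplicated, sorted list and the number of collapsed duplicates.
    """
    by_locus: dict[tuple, GenomeHit] = {}
    n_in = 0
    for h in hits:
        n_in += 1
        key = (h.contig, h.start, h.end, h.strand)
        cur = by_locus.get(key)
        if cur is None or h.ref_id < cur.ref_id:
            by_locus[key] = h
    out = sorted(by_locus.values(), key=lambda h: (h.contig, h.start, h.ref_id))
    return out, n_in - len(out)


def extract_precursor_window(
    genome: Mapping[str, str], hit: GenomeHit, flank: int = 200
) -> PrecursorWindow:
    """Excise hit +/- ``flank`` nt, 5'->3' on the hit strand.

    Flanks are truncated at contig boundaries and the obtained lengths
    recorded.  ``flank_up`` is 5' of the mature on its own strand.
    """
    if hit.contig not in genome:
        raise CoordinateError(f"unknown contig {hit.contig!r}")
    contig = genome[hit.contig]
    n = len(contig)
    if not (1 <= hit.start <= hit.end <= n):
        raise CoordinateError(
            f"hit {hit.start}-{hit.end} outside contig of length {n}"
        )
    left = min(flank, hit.start - 1)
    right = min(flank, n - hit.end)
    fwd = contig[hit.start - 1 - left : hit.end + right]
    if hit.strand == "+":
        return PrecursorWindow(hit, fwd, left, left, right)
    return PrecursorWindow(hit, reverse_complement(fwd), right, right, left)


def _orfs_in_frame(seq: str) -> Iterable[tuple[int, int]]:
    """(start, length_nt) of AUG..stop ORFs, stop included, one frame."""
    n = len(seq)
    for i in range(0, n - 2, 3):
        if seq[i : i + 3] == "AUG":
            for j in range(i + 3, n - 2, 3):
                if seq[j : j + 3] in STOP_CODONS:
                    yield i, j + 3 - i
                    break


def find_orfs(seq: str) -> list[tuple[int, int, int]]:
    """All AUG..stop ORFs in the 6 frames of ``seq``.

    Returns (frame, start, length_nt) with frames 0-2 forward and 3-5 on
    the reverse complement; start is 0-based within the scanned strand.
    """
    out = []
    rc = reverse_complement(seq)
    for strand_idx, s in enumerate((seq, rc)):
        for off in range(3):
            for start, length in _orfs_in_frame(s[off:]):
                out.append((strand_idx * 3 + off, start + off, length))
    return out


def exclude_protein_coding(
    windows: Iterable[PrecursorWindow],
    min_orf: int = 300,
    *,
    require_mature_overlap: bool = False,
) -> tuple[list[PrecursorWindow], list[dict]]:
    """Drop windows containing an ORF of at least ``min_orf`` nt.

    Scans all six frames for AUG..stop open reading frames (stop codon
    included in the length).  Returns retained windows and a rejection log
    with the offending frame and coordinates.

    With ``require_mature_overlap`` only ORFs overlapping the mature hit
    region count: in a ~400-nt window, chance ORFs of 300+ nt arise in
    random flanking sequence at a non-negligible rate, and an ORF confined
    to a distal flank says nothing about the hairpin locus itself.
    """
    kept: list[PrecursorWindow] = []
    log: list[dict] = []
    for w in windows:
        n = len(w.window_seq)
        ms, me = w.mature_range

        def _touches_mature(frame: int, start: int, length: int) -> bool:
            if frame < 3:
                lo, hi = start, start + length - 1
            else:  # reverse-strand ORF: map back to window coordinates
                lo, hi = n - (start + length), n - start - 1
            return lo <= me and ms <= hi

        offending = [
            (frame, start, length)
            for frame, start, length in find_orfs(w.window_seq)
            if length >= min_orf
            and (not require_mature_overlap or _touches_mature(frame, start, length))
        ]
        if offending:
            frame, start, length = offending[0]
            log.append(
                {
                    "contig": w.hit.contig,
                    "hit_start": w.hit.start,
                    "ref_id": w.hit.ref_id,
                    "frame": frame,
                    "orf_start": start,
                    "orf_length": length,
                }
            )
        else:
            kept.append(w)
    return kept, log
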