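"""End-to-end orchestration: discovery, target scan, expression contrast.

``run_discovery`` chains the full precursor-discovery stage: exact-match
mapping of reference matures, precursor-window excision, protein-coding
exclusion, folding, trimming to the minimal hairpin, and rule-based
classification, producing a catalog-style table plus a dot-bracket sidecar
and per-stage counts.  ``run_targets`` and ``run_expression`` wrap the
target scan and the comparative-Ct contrast.

Trimming is iterative: the window is folded, cut down to the hairpin
element around the mature and its star, refolded, and cut again until the
segment is stable (a few rounds at most).  This mirrors how ~400-nt
windows shrink to the 53-116 nt precursors of the published catalog.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .errors import AnatomyError, DomainError
from .folding import Folder, fold, write_dotbracket
from .hairpin import (
    FilterThresholds,
    PrecursorCandidate,
    classify_candidate,
    compute_gc,
    compute_mfei,
    trim_to_hairpin,
)
from .homology import (
    dedupe_hits,
    exclude_protein_coding,
    extract_precursor_window,
    find_exact_matches,
    read_fasta,
)
from .qpcr import contrast_to_frame, read_ct_table, tissue_contrast
from .targets import scan_targets

MAX_TRIM_ROUNDS = 5


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the pipeline, serialized into every report header."""

    flank: int = 200
    min_orf: int = 300
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    min_coverage: float = 75.0
    min_identity: float = 75.0
    reference_gene: str = "U6"
    test_tissue: str = "brain"
    calibrator_tissue: str = "liver"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.flank < 0 or self.min_orf < 0:
            raise DomainError("flank and min_orf must be non-negative")
        if not (0 <= self.min_coverage <= 100 and 0 <= self.min_identity <= 100):
            raise DomainError("coverage/identity minima must be percentages")

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        data = yaml.safe_load(text) or {}
        if "thresholds" in data and isinstance(data["thresholds"], dict):
            data["thresholds"] = FilterThresholds(**data["thresholds"])
        return cls(**data)


def _as_contigs(genome) -> Mapping[str, str]:
    if isinstance(genome, (str, Path)):
        return read_fasta(genome)
    return genome


CATALOG_COLUMNS = [
    "name",
    "length_mature",
    "query",
    "mature_seq",
    "arm",
    "length_precursor",
    "gc_percent",
    "mfe",
    "mfei",
    "verdict",
    "reasons",
    "contig",
    "genome_start",
    "genome_end",
    "strand",
    "star_mismatches",
]


def run_discovery(
    genome,
    refs,
    config: PipelineConfig = PipelineConfig(),
    out_dir: str | Path | None = None,
    folder: Folder = fold,
):
    """Discover precursor candidates for a reference mature set.

    ``genome`` is a FASTA path or a {contig: seq} mapping; ``refs`` a list
    of :class:`~sardmir.homology.ReferenceMature`.  Returns
    ``(catalog_frame, structures, log)`` where ``structures`` maps
    candidate names to trimmed :class:`SecondaryStructure` objects and
    ``log`` carries per-stage counts.  Deterministic for fixed inputs and
    config; when ``out_dir`` is given writes ``catalog.tsv``,
    ``structures.dbn`` and ``run_log.yaml``.
    """
    contigs = _as_contigs(genome)
    log: dict = {"config": asdict(config), "version": __version__}
    if contigs:
        hits = find_exact_matches(refs, contigs)
    else:
        hits = []
    hits, n_dupes = dedupe_hits(hits)
    log["hits"] = len(hits)
    log["duplicate_hits_collapsed"] = n_dupes
    windows = [
        extract_precursor_window(contigs, h, config.flank) for h in hits
    ]
    log["windows"] = len(windows)
    windows, orf_log = exclude_protein_coding(
        windows, config.min_orf, require_mature_overlap=True
    )
    log["orf_rejected"] = len(orf_log)
    rows = []
    structures = {}
    counts = {"accepted": 0, "rejected": 0}
    for idx, w in enumerate(windows, start=1):
        name = f"cand-{idx}-{w.hit.ref_id}"
        cand = classify_window(w.window_seq, w.mature_range, folder,
                               config.thresholds, name)
        counts[cand.verdict] += 1
        if cand.verdict == "accepted":
            structures[name] = cand.structure
        rows.append(
            {
                "name": name,
                "length_mature": len(w.hit.matched_seq),
                "query": w.hit.ref_id,
                "mature_seq": w.hit.matched_seq,
                "arm": cand.arm or "",
                "length_precursor": len(cand.trimmed_seq) or None,
                "gc_percent": round(cand.gc_percent, 2),
                "mfe": round(cand.mfe, 2),
                "mfei": cand.mfei,
                "verdict": cand.verdict,
                "reasons": "; ".join(cand.rejection_reasons),
                "contig": w.hit.contig,
                "genome_start": w.hit.start,
                "genome_end": w.hit.end,
                "strand": w.hit.strand,
                "star_mismatches": cand.star_mismatches,
            }
        )
    log["folded"] = len(windows)
    log.update(counts)
    frame = pd.DataFrame(rows, columns=CATALOG_COLUMNS)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        frame.to_csv(out_dir / "catalog.tsv", sep="\t", index=False)
        write_dotbracket(sorted(structures.items()), out_dir / "structures.dbn")
        (out_dir / "run_log.yaml").write_text(yaml.safe_dump(log, sort_keys=True))
    return frame, structures, log


def classify_window(
    window_seq: str,
    mature_range: tuple[int, int],
    folder: Folder = fold,
    thresholds: FilterThresholds = FilterThresholds(),
    name: str = "",
) -> PrecursorCandidate:
    """Classify a hit by folding a ladder of windows anchored on the mature.

    A genuine precursor hairpin is local: the star lies within a loop's
    reach of the mature, and published precursors top out near 120 nt.  In
    a 400-nt window the energy minimizer can entangle the mature with
    distant flank sequence, so candidates are evaluated on a deterministic
    ladder of anchored sub-windows first — star downstream, star upstream,
    then symmetric slices — and the full window last.  The first accepted
    candidate wins; a hairpin that violates the rules is rejected at every
    scale.  The verdict of the largest window is reported when nothing is
    accepted.
    """
    L = mature_range[1] - mature_range[0] + 1
    pads = [
        (4, L + 12),
        (L + 12, 4),
        (4, L + 28),
        (L + 28, 4),
        (10, L + 48),
        (L + 48, 10),
        (60, 60),
        (120, 120),
    ]
    for pad_left, pad_right in pads:
        a = max(0, mature_range[0] - pad_left)
        b = min(len(window_seq), mature_range[1] + 1 + pad_right)
        if (a, b) == (0, len(window_seq)):
            continue  # identical to the full-window attempt below
        sliced = window_seq[a:b]
        srange = (mature_range[0] - a, mature_range[1] - a)
        cand = _trim_rounds(sliced, srange, folder, thresholds, name)
        if cand.verdict == "accepted":
            return cand
    return _trim_rounds(window_seq, mature_range, folder, thresholds, name)


def _trim_rounds(
    window_seq: str,
    mature_range: tuple[int, int],
    folder: Folder,
    thresholds: FilterThresholds,
    name: str,
) -> PrecursorCandidate:
    """Fold a window and iterate trim/refold until the segment is stable.

    The primary cut is the enclosing-pair rule of
    :func:`~sardmir.hairpin.trim_to_hairpin`.  When that stalls on a
    multi-hairpin segment (a spurious long-range pair can wrap the mature
    around an unrelated hairpin), the segment is instead cut to the
    hairpin element covering most of the mature, extended to include the
    whole mature, and refolded.
    """
    seq = window_seq
    rng = mature_range
    structure = folder(seq)
    for _ in range(MAX_TRIM_ROUNDS):
        try:
            trimmed, (a, b) = trim_to_hairpin(seq, structure, rng)
        except AnatomyError:
            cand = PrecursorCandidate(structure, rng, name=name)
            cand.trimmed_seq = seq
            return classify_candidate(cand, thresholds)
        if trimmed == seq:
            fallback = _element_trim(structure, rng)
            if fallback is None:
                break
            a, b = fallback
            trimmed = seq[a : b + 1]
            if trimmed == seq:
                break
        seq = trimmed
        rng = (rng[0] - a, rng[1] - a)
        structure = folder(seq)
    cand = PrecursorCandidate(structure, rng, name=name)
    cand.trimmed_seq = seq
    cand.trimmed_range = (0, len(seq) - 1)
    cand.gc_percent = compute_gc(seq)
    cand.mfe = structure.energy
    if structure.energy < 0:
        cand.mfei = compute_mfei(
            structure.energy, len(seq), cand.gc_percent, report=True
        )
    return classify_candidate(cand, thresholds)


def _element_trim(structure, mature_range) -> tuple[int, int] | None:
    """Span of the hairpin element holding most of the mature, or None.

    Only used on multi-hairpin segments; returns the element span extended
    to cover the whole mature so no mature nucleotide is cut away.
    """
    from .folding import hairpin_element_span, parse_hairpin

    try:
        anatomy = parse_hairpin(structure)
    except AnatomyError:
        return None
    if anatomy.n_hairpin_loops < 2:
        return None
    s, e = mature_range
    best = None
    for lo, hi in anatomy.loops:
        a, b = hairpin_element_span(structure, (lo - 1, hi + 1))
        overlap = max(0, min(e, b) - max(s, a) + 1)
        if best is None or overlap > best[0]:
            best = (overlap, a, b)
    if best is None or best[0] == 0:
        return None
    _, a, b = best
    return min(a, s), max(b, e)


def run_targets(
    matures: Mapping[str, str],
    transcripts,
    config: PipelineConfig = PipelineConfig(),
    out_path: str | Path | None = None,
) -> pd.DataFrame:
    """Scan transcripts for rule-compliant target sites of the matures."""
    tx = _as_contigs(transcripts)
    frame = scan_targets(
        matures, tx, config.min_coverage, config.min_identity
    )
    if out_path is not None:
        with open(out_path, "w") as fh:
            fh.write(f"# sardmir {__version__} target scan\n")
            frame.to_csv(fh, sep="\t", index=False)
    return frame


def run_expression(
    ct_table,
    config: PipelineConfig = PipelineConfig(),
    out_path: str | Path | None = None,
) -> pd.DataFrame:
    """Comparative-Ct contrast of the configured test vs calibrator tissue."""
    if isinstance(ct_table, (str, Path)):
        ct_table = read_ct_table(ct_table)
    results = tissue_contrast(
        ct_table,
        test=config.test_tissue,
        calibrator=config.calibrator_tissue,
        reference_gene=config.reference_gene,
    )
    frame = contrast_to_frame(results)
    if out_path is not None:
        frame.to_csv(out_path, sep="\t", index=False)
    return frame


__all__ = [
    "PipelineConfig",
    "classify_window",
    "run_discovery",
    "run_targets",
    "run_expression",
    "CATALOG_COLUMNS",
]
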