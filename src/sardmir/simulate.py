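"""Synthetic inputs with known ground truth for every pipeline stage.

Generators for (a) genomes carrying implanted hairpin precursors at known
coordinates, (b) transcripts carrying implanted complementary target sites
(rule-compliant or violating exactly one named rule), and (c) Ct tables
built backwards from known true fold changes with Gaussian replicate noise.
All generators are seed-deterministic: the same seed yields byte-identical
output.

The genomic background is i.i.d. uniform with configurable GC, which is
adequate because the discovery pipeline matches exactly and filters by
rule; implanted hairpins are constructed (and verified) with the package's
own folding model so positives are detectable by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, PlacementError
from .sequence import reverse_complement

BASES = np.array(list("ACGU"))


@dataclass(frozen=True)
class ImplantedPrecursor:
    contig: str
    start: int  # 1-based start of the precursor on the forward strand
    strand: str
    mature_seq: str
    mature_start: int  # 1-based forward-strand start of the mature
    star_mismatches: int
    precursor_seq: str
    arm: str


@dataclass(frozen=True)
class ImplantedSite:
    transcript: str
    start: int  # 1-based
    mature_id: str
    rule_compliant: bool
    kind: str


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside each synthetic dataset."""

    seed: int
    implanted_precursors: list[ImplantedPrecursor] = field(default_factory=list)
    implanted_sites: list[ImplantedSite] = field(default_factory=list)
    true_folds: dict[str, float] = field(default_factory=dict)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def random_rna(rng, length: int, gc: float = 0.5) -> str:
    """Uniform i.i.d. RNA with expected GC fraction ``gc``."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(BASES, size=length, p=p))


# nucleotides that can pair with neither Watson-Crick nor wobble rules
_NON_PAIRING = {"A": "CG", "C": "AU", "G": "AG", "U": "CU"}

# screening geometry matching the discovery pipeline defaults
_ORF_SCREEN_MIN = 300
_ORF_SCREEN_FLANK = 200


def _chance_orf_over_implant(contig: list, span: tuple[int, int]) -> bool:
    """Would a 6-frame ORF screen of the excised window hit this implant?"""
    from .homology import find_orfs

    lo = max(0, span[0] - _ORF_SCREEN_FLANK)
    hi = min(len(contig), span[1] + _ORF_SCREEN_FLANK)
    window = "".join(contig[lo:hi])
    n = len(window)
    i_lo, i_hi = span[0] - lo, span[1] - lo - 1
    for frame, start, length in find_orfs(window):
        if length < _ORF_SCREEN_MIN:
            continue
        if frame < 3:
            a, b = start, start + length - 1
        else:
            a, b = n - (start + length), n - start - 1
        if a <= i_hi and i_lo <= b:
            return True
    return False


def make_hairpin(
    mature: str,
    loop_len: int = 8,
    n_star_mismatches: int = 0,
    seed=0,
    arm: str = "five_prime",
) -> str:
    """Build ``mature + loop + star`` (or star first for a 3'-arm mature).

    The star is the reverse complement of the mature with
    ``n_star_mismatches`` positions mutated so they can pair neither
    Watson-Crick nor G:U with their mature partner.  The loop is random
    over {A, C} so it cannot pair with itself.  The construction is
    verified with the package's own folding model: up to a few loop draws
    are tried until the precursor refolds into a single hairpin with the
    mature on one arm (verification is skipped for heavily mismatched
    stars, which legitimately fail to form a clean stem).
    """
    if loop_len < 3:
        raise DomainError("hairpin loop must span at least 3 nt")
    if not 0 <= n_star_mismatches <= len(mature):
        raise DomainError("star mismatch count outside [0, mature length]")
    if arm not in ("five_prime", "three_prime"):
        raise DomainError(f"unknown arm {arm!r}")
    rng = _rng(seed)
    verify = n_star_mismatches <= len(mature) // 3
    candidate = ""
    for _ in range(40):
        star = list(reverse_complement(mature))
        # star position (L-1-k) faces mature position k
        positions = rng.choice(
            len(mature), size=n_star_mismatches, replace=False
        )
        for k in sorted(int(p) for p in positions):
            choices = _NON_PAIRING[mature[k]]
            star[len(mature) - 1 - k] = choices[int(rng.integers(len(choices)))]
        loop = "".join(rng.choice(np.array(list("AC")), size=loop_len))
        if arm == "five_prime":
            candidate = mature + loop + "".join(star)
            mrange = (0, len(mature) - 1)
        else:
            candidate = "".join(star) + loop + mature
            mrange = (len(candidate) - len(mature), len(candidate) - 1)
        if not verify or _folds_to_single_hairpin(candidate, mrange):
            return candidate
    return candidate


def _folds_to_single_hairpin(seq: str, mature_range) -> bool:
    from .folding import fold, parse_hairpin
    from .hairpin import mature_arm_check

    anatomy = parse_hairpin(fold(seq))
    if anatomy.n_hairpin_loops != 1:
        return False
    ok, _ = mature_arm_check(anatomy, mature_range)
    return ok


def make_genome(
    n_contigs: int,
    contig_len: int,
    implants: list[tuple[str, str]],
    seed=0,
    gc: float = 0.5,
    arm: str = "five_prime",
    loop_len: int = 8,
    n_star_mismatches: int = 0,
) -> tuple[dict[str, str], SyntheticTruth]:
    """Random genome with hairpin precursors implanted at known loci.

    ``implants`` is a list of (mature_id, mature_seq); each becomes a
    hairpin built by :func:`make_hairpin` and placed at a random
    non-overlapping position and strand.  Raises :class:`PlacementError`
    when the implants cannot fit without overlap.
    """
    rng = _rng(seed)
    truth = SyntheticTruth(seed=seed if isinstance(seed, int) else -1)
    contigs = {
        f"contig{i + 1}": list(random_rna(rng, contig_len, gc))
        for i in range(n_contigs)
    }
    names = list(contigs)
    occupied: dict[str, list[tuple[int, int]]] = {n: [] for n in names}
    for mid, mature in implants:
        hp = make_hairpin(
            mature,
            loop_len=loop_len,
            n_star_mismatches=n_star_mismatches,
            seed=rng,
            arm=arm,
        )
        placed = False
        for _ in range(200):
            contig = names[int(rng.integers(n_contigs))]
            if contig_len <= len(hp):
                break
            pos = int(rng.integers(contig_len - len(hp)))  # 0-based
            span = (pos, pos + len(hp))
            if any(a < span[1] and pos < b for a, b in occupied[contig]):
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            ins = hp if strand == "+" else reverse_complement(hp)
            original = contigs[contig][span[0] : span[1]]
            contigs[contig][span[0] : span[1]] = list(ins)
            if _chance_orf_over_implant(contigs[contig], span):
                # a stop-free stretch of background happens to read as a
                # long ORF across this locus; a protein-coding screen would
                # discard it, so re-draw the placement
                contigs[contig][span[0] : span[1]] = original
                continue
            occupied[contig].append(span)
            if arm == "five_prime":
                off = 0  # mature is 5' on the hairpin strand
            else:
                off = len(hp) - len(mature)
            if strand == "+":
                mstart = pos + off + 1
            else:
                mstart = pos + len(hp) - off - len(mature) + 1
            truth.implanted_precursors.append(
                ImplantedPrecursor(
                    contig=contig,
                    start=pos + 1,
                    strand=strand,
                    mature_seq=mature,
                    mature_start=mstart,
                    star_mismatches=n_star_mismatches,
                    precursor_seq=hp,
                    arm=arm,
                )
            )
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place implant {mid!r} without overlap"
            )
    return {n: "".join(s) for n, s in contigs.items()}, truth


SITE_KINDS = (
    "perfect",  # exact reverse complement: compliant
    "seed_gu1",  # one G:U wobble in the seed: compliant
    "gaps4",  # four gaps in positions 9-21: compliant
    "seed_mismatch",  # violates rule 1
    "seed_gu2",  # violates rule 2
    "gaps5",  # violates rule 3
)

_COMPLIANT = {"perfect": True, "seed_gu1": True, "gaps4": True,
              "seed_mismatch": False, "seed_gu2": False, "gaps5": False}

# transcript-side wobble partner: mature G pairs site U, mature U pairs G
_WOBBLE_SITE = {"G": "U", "U": "G"}
_MISMATCH_SITE = {"A": "C", "C": "A", "G": "G", "U": "U"}


def make_target_site(mature: str, kind: str, rng=None) -> str:
    """A transcript-side site of the requested compliance ``kind``.

    The site reads 5'->3' on the transcript; site position ``L-1-k``
    faces mature position ``k`` (antiparallel duplex).  Non-compliant
    kinds violate exactly one rule.
    """
    if kind not in SITE_KINDS:
        raise DomainError(f"unknown site kind {kind!r}")
    rng = _rng(rng if rng is not None else 0)
    L = len(mature)
    site = list(reverse_complement(mature))

    def face(k: int) -> int:  # site index facing mature position k (0-based)
        return L - 1 - k

    def seed_wobble_pos() -> int:
        cands = [k for k in range(1, 8) if mature[k] in "GU"]
        if not cands:
            raise DomainError(
                "mature has no G/U in the seed; cannot build a wobble site"
            )
        return cands[int(rng.integers(len(cands)))]

    if kind == "perfect":
        pass
    elif kind == "seed_gu1":
        k = seed_wobble_pos()
        site[face(k)] = _WOBBLE_SITE[mature[k]]
    elif kind == "seed_gu2":
        cands = [k for k in range(1, 8) if mature[k] in "GU"]
        if len(cands) < 2:
            raise DomainError("mature needs two G/U seed positions")
        for k in (cands[0], cands[-1]):
            site[face(k)] = _WOBBLE_SITE[mature[k]]
    elif kind == "seed_mismatch":
        k = 4  # mature position 5, mid-seed
        site[face(k)] = _MISMATCH_SITE[mature[k]]
    elif kind in ("gaps4", "gaps5"):
        return _gap_site(mature, 4 if kind == "gaps4" else 5)
    return "".join(site)


def _gap_site(mature: str, n_gaps: int) -> str:
    """Delete ``n_gaps`` site nucleotides facing mature positions 9-21.

    Gap placement under alignment ties can drift along repeated
    nucleotides, so candidate position sets are verified against the
    package's own duplex aligner until one yields exactly the requested
    gap count in 9-21 with a clean seed.
    """
    from itertools import combinations

    from .targets import align_duplex, apply_seed_rules

    L = len(mature)
    region = [k for k in range(9, min(21, L - 1))]  # 0-based 10..21 (1-based)
    base = list(reverse_complement(mature))
    for positions in combinations(region, n_gaps):
        site = list(base)
        for k in sorted(positions, reverse=True):
            del site[L - 1 - k]
        candidate = "".join(site)
        v = apply_seed_rules(align_duplex(mature, candidate))
        if (
            v.gaps_9_21 == n_gaps
            and v.seed_mismatches == 0
            and v.seed_gu == 0
        ):
            return candidate
    raise DomainError(
        f"could not construct a {n_gaps}-gap site for this mature"
    )


def make_transcripts(
    n: int,
    length: int,
    sites: list[tuple[str, str, str]],
    seed=0,
    gc: float = 0.5,
) -> tuple[dict[str, str], SyntheticTruth]:
    """Random transcripts with implanted target sites.

    ``sites`` is a list of (mature_id, mature_seq, kind); each site is
    placed at a random position of a random transcript (non-overlapping).
    """
    rng = _rng(seed)
    truth = SyntheticTruth(seed=seed if isinstance(seed, int) else -1)
    transcripts = {
        f"tx{i + 1}": list(random_rna(rng, length, gc)) for i in range(n)
    }
    names = list(transcripts)
    occupied: dict[str, list[tuple[int, int]]] = {t: [] for t in names}
    for mid, mature, kind in sites:
        site = make_target_site(mature, kind, rng)
        placed = False
        for _ in range(200):
            tx = names[int(rng.integers(n))]
            if length <= len(site):
                break
            pos = int(rng.integers(length - len(site)))
            span = (pos, pos + len(site))
            if any(a < span[1] and pos < b for a, b in occupied[tx]):
                continue
            transcripts[tx][span[0] : span[1]] = list(site)
            occupied[tx].append(span)
            truth.implanted_sites.append(
                ImplantedSite(
                    transcript=tx,
                    start=pos + 1,
                    mature_id=mid,
                    rule_compliant=_COMPLIANT[kind],
                    kind=kind,
                )
            )
            placed = True
            break
        if not placed:
            raise PlacementError(f"could not place site for {mid!r}")
    return {t: "".join(s) for t, s in transcripts.items()}, truth


def make_ct_table(
    true_folds: dict[str, float],
    base_ct: float = 32.0,
    ref_ct: float = 18.0,
    noise_sd: float = 0.2,
    n_replicates: int = 3,
    seed=0,
    test: str = "brain",
    calibrator: str = "liver",
    reference_gene: str = "U6",
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Ct table built backwards from known fold changes.

    The calibrator tissue carries every gene at ``base_ct`` and the
    reference gene at ``ref_ct`` in both tissues; in the test tissue each
    gene's Ct is shifted by ``-log2(true fold)``.  Gaussian noise of SD
    ``noise_sd`` is added independently to each target-gene replicate
    well while the reference gene is emitted at its nominal Ct, so
    ``noise_sd`` is exactly the per-replicate standard deviation of the
    normalized dCt (the quantity replicate scatter acts on in the
    comparative-Ct model).
    """
    if noise_sd < 0:
        raise DomainError("noise SD must be non-negative")
    if n_replicates < 1:
        raise DomainError("at least one replicate is required")
    rng = _rng(seed)
    truth = SyntheticTruth(
        seed=seed if isinstance(seed, int) else -1,
        true_folds=dict(true_folds),
    )
    rows = []
    for tissue in (calibrator, test):
        for gene in [reference_gene, *true_folds]:
            if gene == reference_gene:
                center = ref_ct
            elif tissue == calibrator:
                center = base_ct
            else:
                center = base_ct - math.log2(true_folds[gene])
            noisy = noise_sd > 0 and gene != reference_gene
            for rep in range(1, n_replicates + 1):
                ct = center + (rng.normal(0.0, noise_sd) if noisy else 0.0)
                rows.append(
                    {"tissue": tissue, "gene": gene, "replicate": rep, "ct": ct}
                )
    return pd.DataFrame(rows, columns=["tissue", "gene", "replicate", "ct"]), truth


def write_fasta(records: dict[str, str], path) -> None:
    """Write sequences as wrapped FASTA."""
    with open(path, "w") as fh:
        for rid, seq in records.items():
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
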