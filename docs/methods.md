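# Methods

This note documents the models and procedures implemented in `sardmir`,
the parameter choices that matter, what the synthetic-data generators do
and do not emulate, and the package's known limitations.

## The catalog fixture and its statistics

The package ships a 101-row transcription of the published sardine miRNA
catalog (`sardmir/data/table1_catalog.tsv`): name, mature length, query
miRNA, mature sequence, arm, precursor length (LP), GC%, MFE and MFEI.
Dashes and minus signs are normalized to ASCII. One printed cell is
internally inconsistent — `spi-miR-142a-3p` lists a mature length of 23
over a printed 22-nt sequence — and the fixture stores 22 so that the
record invariant (length equals sequence length) holds; no summary
statistic is affected.

`summarize_catalog` reproduces the published summary conventions:
precursor mean rounded to an integer, arm percentages to one decimal,
GC/MFE/MFEI aggregates to two decimals, and the U-start percentage to the
nearest integer. Two observations about the published figures:

* **MFEI is truncated, not rounded.** Recomputing
  MFEI = (|MFE|/LP × 100)/GC% and *truncating* to two decimals reproduces
  all 101 printed cells (e.g. 33.40/59×100/42.37 = 1.3361 → 1.33, where
  rounding would print 1.34). Rounding contradicts several cells;
  truncation contradicts none.
* **The U-start figure is a count.** 59 of the 101 mature sequences begin
  with U, i.e. 58.4%, which rounds to 58 — the published "59%" reports the
  raw count as a percentage. The package reports the computed value.

## Homology search

Reference matures (18–26 nt, RNA alphabet) are matched exactly against
both strands of the genome; `N` never matches. Coordinates are 1-based
inclusive on the forward strand (GenBank convention); minus-strand hits
report the reverse-complement locus. Windows of hit ±200 nt (truncated at
contig edges) are excised 5′→3′ on the hit strand. Mismatch-tolerant
matching is deliberately out of scope: the workflow this package
implements kept only exact matches.

Protein-coding exclusion scans all six frames for AUG…stop open reading
frames of ≥300 nt (stop included; the threshold is the common
smallest-protein heuristic and is configurable). The *operation* rejects
any window containing such an ORF; the *pipeline* additionally requires
the ORF to overlap the mature locus, because ~400 nt of background
sequence contains a chance ≥300-nt ORF in some frame at a 1–2% rate, and
an ORF confined to a distal flank carries no evidence about the hairpin
locus itself.

## Folding model

The folder is a deterministic dynamic-programming minimizer over an
additive pair-energy model: G:C −3, A:U −2, G:U −1 kcal/mol, hairpin
loops ≥3 unpaired nt, no pseudoknots, no loop or stacking terms. Ties
are resolved by pairing the 5′-most pairable position first and choosing
its outermost admissible partner, which prefers a single enclosing stem
over equal-energy branched layouts; the result is fully deterministic.
`brute_force_fold` exhaustively enumerates all valid pairings of ≤14-nt
sequences under the same score and serves as the testing oracle (the DP
matches it on 1,000 random 10–14-mers).

**Consequence, stated openly:** this is not a nearest-neighbor
thermodynamic engine, and absolute energies are not comparable to mfold
or ViennaRNA values. The published catalog's MFE values are therefore
treated as data (the fixture) and never recomputed; every MFE-dependent
statistic uses the printed values. The pipeline accepts any callable with
the folder contract (`seq -> SecondaryStructure`), so a thermodynamic
engine can be substituted without touching pipeline logic.

## Hairpin screen

A candidate is accepted iff (1) the trimmed segment folds into a single
stem-loop, (2) the mature lies wholly on one arm and off the terminal
loop, (3) at most 8 mature positions lack a partner on the star side
("fewer than nine mismatches"; an unpaired or bulged mature position
counts as a mismatch — the criteria do not distinguish), and (4) MFEI of
the trimmed precursor is at least 0.70. The 0.70 floor is the smallest
MFEI in the published catalog and sits above the cited mRNA band
(0.62–0.66); it is configurable. GC% and MFEI are computed on the trimmed
precursor, matching the catalog's LP-based values.

**Trimming.** Published precursors are 53–116 nt while windows are ~400
nt, so trimming is integral. The primary rule cuts to the outermost base
pair that encloses the mature and its star partners while the enclosed
subtree still contains a single hairpin loop, then refolds and repeats to
a fixpoint (≤5 rounds). Two pragmatic refinements make this robust under
the simple energy model, which on long windows can entangle the mature
with distant flank sequence at equal energy:

* classification evaluates a deterministic ladder of mature-anchored
  sub-windows (tight asymmetric slices first — star downstream, star
  upstream — then symmetric 60/120-nt pads, then the full window),
  accepting the first candidate that passes; a hairpin that violates the
  rules is rejected at every scale, so the ladder cannot manufacture
  positives out of rule-violating loci;
* when the enclosing-pair cut stalls on a multi-hairpin segment (a
  spurious long-range pair can wrap the mature around an unrelated
  hairpin), the segment is cut to the hairpin element covering most of
  the mature, extended to include the whole mature, and refolded.

## Target prediction

The pre-screen locally aligns the mature's reverse complement against
each transcript (megablast-flavoured scores: match +2, mismatch −3, gap
open −5, extend −2, via Biopython's `PairwiseAligner`) in overlapping
chunks, keeping sites with ≥75% of the mature aligned and ≥75% identity
over aligned columns (both configurable; identity is measured over the
aligned region). Whole transcripts are scanned, not just 3′ UTRs.

Each candidate site is then globally aligned to the mature under WC +2,
G:U +1, mismatch −1, gap −2 (deterministic tie-breaking), yielding
per-position duplex states from the miRNA 5′ end. The seed rules are:
no mismatch or gap at positions 2–8; at most one G:U wobble at positions
2–8; at most four gap columns with miRNA-side coordinate 9–21 (an
insertion between positions p and p+1 is attributed to p). No
hybridization free energy is computed — the screen is exactly the
rule set, which is all the filtering specifies.

## Comparative-Ct quantification

Technical replicates are averaged on the Ct scale; then
ΔCt = Ct_gene − Ct_U6 within each tissue, ΔΔCt = ΔCt_test − ΔCt_cal
(calibrator: liver), and fold = 2^−ΔΔCt with amplification efficiency
fixed at 2. Swapping test and calibrator inverts the fold exactly, and
self-calibration returns 1 for any input.

## Synthetic data

All generators take a seed and are byte-deterministic; each emits a truth
table sufficient to compute sensitivity/precision of the corresponding
stage without external data.

* `make_hairpin` builds mature + loop + star (star first for a 3′-arm
  mature), with the requested number of star positions mutated to bases
  that can pair neither Watson–Crick nor wobble. The loop is drawn over
  {A, C} so it cannot self-pair. Constructions are verified with the
  package's own folder (re-drawing mutation positions and loop up to 40
  times) so that positives are detectable by construction — a stated
  circularity that is acceptable for correctness testing and removable by
  plugging in an external folder. Verification is skipped for heavily
  mismatched stars (> length/3), which legitimately fail to form a clean
  stem.
* `make_genome` places the hairpins at non-overlapping uniform-random
  loci and strands in i.i.d. uniform background (configurable GC).
  Placements where a six-frame ≥300-nt chance ORF crosses the implant are
  re-drawn, for the same reason the pipeline's ORF screen requires mature
  overlap. A perfect implant yields two exact hits (mature and star arm),
  so a discovery run typically reports two accepted candidates per
  implant.
* `make_transcripts` implants target sites that are perfect complements
  or controlled variants: one seed wobble (compliant), four gaps at 9–21
  (compliant), a seed mismatch, two seed wobbles, or five gaps (each
  violating exactly one rule). Gap-site constructions are verified
  against the package's own duplex aligner, since gap placement can
  drift along repeated nucleotides under alignment ties.
* `make_ct_table` builds Ct values backwards from known fold changes:
  liver at a fixed baseline (default 32 cycles; U6 at 18), brain shifted
  by −log2(fold), Gaussian noise per replicate. `noise_sd`
  parameterizes the per-replicate SD of the normalized ΔCt: noise is
  injected into the target-gene wells with the reference emitted at its
  nominal Ct. (With independent SD-σ noise on all four well groups and
  n=3 replicates, Var(ΔΔCt) = 4σ²/3 and the median fold error at σ=0.2
  would be ≈10.8%; under the ΔCt reading it is 2σ²/3 ≈ 7.6%, which is
  the regime the recovery checks operate in.) Default noise SD 0.2 and
  three technical replicates mirror a well-run qPCR experiment.

What the generators do **not** emulate: repeat structure, isochores or
realistic base composition; sequencing reads; biological replication or
pipetting structure in the qPCR error model; imperfect homology between
the reference mature and the target genome (the pipeline's matching is
exact, so synthetic matures are implanted verbatim). Passing recovery
tests therefore demonstrates the correctness of the algorithms, not the
sensitivity of exact-match homology search on diverged real genomes.

## Problem sizes

The shipped checks use desk-scale inputs: 10-kb synthetic genomes with 5
implants, 6 × 1.5-kb transcripts with 8 sites, 500 simulated qPCR
experiments, 1,000 oracle folds at 10–14 nt. All are regenerated at run
time from seeds; nothing is precomputed.

## Known limitations

* The pair-energy folding model over-pairs random RNA relative to
  thermodynamic engines, so MFEI values computed on synthetic hairpins
  (≈1.7–2.3) are higher than thermodynamic MFEIs and the 0.70 floor is
  not discriminative on synthetic data; discrimination there rests on the
  structural rules. On real data, substitute a thermodynamic folder.
* Recovery of implanted hairpins is complete at zero star mismatches; at
  4+ mismatches the toy energy model increasingly entangles loose stems
  with flanking sequence and recovery degrades (~80% at 4, lower at 8).
  This is a property of the folding model, not of the rule screen.
* Exact matching cannot find miRNAs whose mature sequence differs by even
  one base from every reference; that is inherent to the workflow's
  design, not a defect of this implementation.
* The 101-miRNA sardine catalog itself is not recomputed: that would
  require the sardine whole-genome assembly and mfold; the catalog is
  packaged data, and the pipeline is validated on synthetic genomes.
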