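"""GC/MFEI arithmetic and the four-rule precursor screen."""

import dataclasses

import pytest

from sardmir.errors import AnatomyError, CoordinateError, DomainError
from sardmir.folding import fold, parse_hairpin
from sardmir.hairpin import (
    REASON_MFEI,
    REASON_MULTI_LOOP,
    REASON_STAR,
    FilterThresholds,
    PrecursorCandidate,
    classify_candidate,
    compute_gc,
    compute_mfei,
    count_star_mismatches,
    mature_arm_check,
    trim_to_hairpin,
)
from sardmir.sequence import reverse_complement
from sardmir.simulate import make_hairpin


@pytest.mark.parametrize(
    "seq,expected", [("GCGC", 100.0), ("AUAU", 0.0), ("GAUC", 50.0)]
)
def test_compute_gc(seq, expected):
    assert compute_gc(seq) == expected


def test_compute_gc_empty_rejected():
    with pytest.raises(DomainError):
        compute_gc("")


class TestMfei:
    @pytest.mark.parametrize(
        "mfe,length,gc,expected",
        [
            (-24.00, 64, 29.69, 1.26),  # catalog row spi-miR-1
            (-16.10, 60, 38.33, 0.70),  # catalog row spi-miR-734-3p
            (-10.0, 100, 50.0, 0.20),
        ],
    )
    def test_report_form(self, mfe, length, gc, expected):
        assert compute_mfei(mfe, length, gc, report=True) == expected

    def test_full_precision_vs_report(self):
        raw = compute_mfei(-33.40, 59, 42.37)
        assert raw == pytest.approx(1.3361, abs=1e-4)
        assert compute_mfei(-33.40, 59, 42.37, report=True) == 1.33

    @pytest.mark.parametrize("kw", [dict(gc=0.0), dict(length=0)])
    def test_degenerate_inputs_rejected(self, kw):
        base = dict(mfe=-10.0, length=60, gc=50.0)
        base.update(kw)
        with pytest.raises(DomainError):
            compute_mfei(base["mfe"], base["length"], base["gc"])


MATURE = "UGGAAUGUAAAGAAGUAUGUAU"  # 22 nt


def _hairpin_candidate(n_star_mismatches=0, arm="five_prime", loop_len=8):
    hp = make_hairpin(MATURE, loop_len=loop_len,
                      n_star_mismatches=n_star_mismatches, seed=5, arm=arm)
    if arm == "five_prime":
        rng = (0, len(MATURE) - 1)
    else:
        rng = (len(hp) - len(MATURE), len(hp) - 1)
    return fold(hp), rng


class TestArmCheck:
    def test_mature_on_five_arm(self):
        ss, rng = _hairpin_candidate(arm="five_prime")
        ok, arm = mature_arm_check(parse_hairpin(ss), rng)
        assert ok and arm == "five_prime"

    def test_mature_on_three_arm(self):
        ss, rng = _hairpin_candidate(arm="three_prime")
        ok, arm = mature_arm_check(parse_hairpin(ss), rng)
        assert ok and arm == "three_prime"

    def test_overlapping_terminal_loop_fails(self):
        ss, rng = _hairpin_candidate(arm="five_prime")
        a = parse_hairpin(ss)
        # extend the mature range one base into the terminal loop
        bad = (rng[0], a.terminal_loop[0])
        ok, arm = mature_arm_check(a, bad)
        assert not ok and arm is None

    def test_spanning_both_arms_fails(self):
        ss, _ = _hairpin_candidate()
        a = parse_hairpin(ss)
        ok, _ = mature_arm_check(a, (0, len(ss.seq) - 1))
        assert not ok

    def test_out_of_range_is_coordinate_error(self):
        ss, _ = _hairpin_candidate()
        with pytest.raises(CoordinateError):
            mature_arm_check(parse_hairpin(ss), (0, len(ss.seq)))


def _sparse_stem(n_unpaired, loop_len=4):
    """Hand-built hairpin: mature + loop + full star, with ``n_unpaired``
    interior mature positions left unpaired (symmetric internal loops).

    Deterministic and independent of the folding engine, so the mismatch
    counter is tested against a structure whose pairing is known exactly.
    """
    from sardmir.folding import SecondaryStructure, structure_energy

    L = len(MATURE)
    star = reverse_complement(MATURE)
    seq = MATURE + "A" * loop_len + star
    # keep the outermost and loop-closing pairs; unpair interior positions
    unpaired = set(range(2, 2 + n_unpaired))
    pairs = [
        (k, len(seq) - 1 - k) for k in range(L) if k not in unpaired
    ]
    db = ["."] * len(seq)
    for i, j in pairs:
        db[i], db[j] = "(", ")"
    ss = SecondaryStructure(seq, "".join(db), structure_energy(seq, pairs))
    return ss, (0, L - 1)


class TestStarMismatches:
    def test_perfect_stem_has_zero(self):
        ss, rng = _hairpin_candidate(0)
        assert count_star_mismatches(ss, rng) == 0

    @pytest.mark.parametrize("n", [3, 9])
    def test_unpaired_mature_positions_counted(self, n):
        ss, rng = _sparse_stem(n)
        assert count_star_mismatches(ss, rng) == n

    def test_count_agrees_with_partner_map(self):
        ss, rng = _hairpin_candidate(3)
        partner = ss.pair_table()
        manual = sum(
            1
            for pos in range(rng[0], rng[1] + 1)
            if pos not in partner or rng[0] <= partner[pos] <= rng[1]
        )
        assert count_star_mismatches(ss, rng) == manual

    def test_mature_in_loop_rejected(self):
        ss, _ = _hairpin_candidate()
        loop = parse_hairpin(ss).terminal_loop
        with pytest.raises(DomainError):
            count_star_mismatches(ss, loop)


class TestTrim:
    def test_trims_flanked_hairpin_to_stem(self):
        hp = make_hairpin(MATURE, loop_len=8, n_star_mismatches=0, seed=5)
        window = "ACAACA" + hp + "ACAACAAC"
        ss = fold(window)
        rng = (6, 6 + len(MATURE) - 1)
        trimmed, (a, b) = trim_to_hairpin(window, ss, rng)
        assert trimmed == window[a : b + 1]
        assert len(MATURE) <= len(trimmed) <= len(window)
        # the full refine procedure (iterated trim with element fallback)
        # must settle on a single hairpin carrying the mature on one arm
        from sardmir.pipeline import classify_window

        cand = classify_window(window, rng)
        assert cand.verdict == "accepted"
        anatomy = parse_hairpin(cand.structure)
        assert anatomy.n_hairpin_loops == 1
        assert cand.arm == "five_prime"

    def test_already_minimal_is_identity(self):
        ss, rng = _hairpin_candidate()
        trimmed, (a, b) = trim_to_hairpin(ss.seq, ss, rng)
        assert (a, b) == (0, len(ss.seq) - 1)
        assert trimmed == ss.seq

    def test_no_enclosing_stem_is_anatomy_error(self):
        seq = "GGGGAAAACCCCAAAAAAAAAA"
        ss = fold(seq)  # trailing As unpaired
        with pytest.raises(AnatomyError):
            trim_to_hairpin(seq, ss, (14, 21))


def _candidate(n_star_mismatches=0, mfei=1.0):
    if n_star_mismatches:
        ss, rng = _sparse_stem(n_star_mismatches)
    else:
        ss, rng = _hairpin_candidate(0)
    cand = PrecursorCandidate(ss, rng, trimmed_seq=ss.seq)
    cand.gc_percent = compute_gc(ss.seq)
    cand.mfe = ss.energy
    cand.mfei = mfei
    return cand


class TestClassify:
    def test_compliant_candidate_accepted(self):
        cand = classify_candidate(_candidate(0))
        assert cand.verdict == "accepted"
        assert cand.rejection_reasons == []
        assert cand.arm == "five_prime"

    def test_low_mfei_rejected_with_reason(self):
        cand = classify_candidate(_candidate(0, mfei=0.65))
        assert cand.verdict == "rejected"
        assert cand.rejection_reasons == [REASON_MFEI]

    def test_nine_star_mismatches_rejected(self):
        cand = classify_candidate(_candidate(9))
        assert cand.verdict == "rejected"
        assert REASON_STAR in cand.rejection_reasons

    def test_multiple_violations_all_listed(self):
        cand = classify_candidate(_candidate(9, mfei=0.5))
        assert set(cand.rejection_reasons) >= {REASON_STAR, REASON_MFEI}

    def test_multi_hairpin_rejected(self):
        seq = "GGGGAAAACCCCGGGGAAAACCCC"
        ss = fold(seq)
        cand = PrecursorCandidate(ss, (0, 3), trimmed_seq=seq, mfei=1.0)
        cand = classify_candidate(cand)
        assert REASON_MULTI_LOOP in cand.rejection_reasons

    def test_monotone_in_thresholds(self):
        """Relaxing any threshold never flips accepted -> rejected."""
        strict = FilterThresholds()
        relaxed = [
            dataclasses.replace(strict, max_star_mismatches=22),
            dataclasses.replace(strict, min_mfei=0.0),
        ]
        for n in (0, 3, 9):
            for mfei in (0.5, 0.9):
                base = classify_candidate(_candidate(n, mfei=mfei), strict)
                if base.verdict == "accepted":
                    for th in relaxed:
                        again = classify_candidate(_candidate(n, mfei=mfei), th)
                        assert again.verdict == "accepted"


def test_catalog_mfei_column_consistent_with_formula(catalog):
    """compute_mfei on (MFE, LP, GC) reproduces the printed column."""
    agree = sum(
        compute_mfei(r.mfe, r.length_precursor, r.gc_percent, report=True)
        == pytest.approx(r.mfei)
        for r in catalog
    )
    assert agree >= 90
    for r in catalog:
        recomputed = compute_mfei(
            r.mfe, r.length_precursor, r.gc_percent, report=True
        )
        assert abs(recomputed - r.mfei) <= 0.02


def test_thresholds_reject_negative_values():
    with pytest.raises(DomainError):
        FilterThresholds(min_mfei=-1.0)
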