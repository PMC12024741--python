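import math
import re

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from endoqc import (
    AlignmentRecord,
    compute_damage_profile,
    dispersion,
    reconstruct_pairwise,
    simulate_records,
    summarize_damage,
)
from endoqc.damage import DamageProfile, MdCigarError, reverse_complement
from tests.conftest import make_config


def _rec(seq, cigar, md, reverse=False, rid="r1", mapq=37):
    return AlignmentRecord(
        read_id=rid, sequence=seq, is_mapped=True, is_reverse=reverse,
        mapq=mapq, cigar=cigar, md=md, ref_name="ref", ref_start=0,
    )


class TestReconstructPairwise:
    def test_perfect_match(self):
        pw = reconstruct_pairwise(_rec("ACGTACGTAC", "10M", "10"))
        assert len(pw.pairs) == 10
        assert all(rb == fb for rb, fb in pw.pairs)

    def test_single_mismatch_forward(self):
        # MD 3C4 on ACGTACGT: molecule position 4 read T over ref C
        pw = reconstruct_pairwise(_rec("ACGTACGT", "8M", "3C4"))
        assert pw.pairs[3] == ("T", "C")
        assert sum(rb != fb for rb, fb in pw.pairs) == 1

    def test_single_mismatch_reverse_strand(self):
        # same stored record on the reverse strand: the mismatch sits at
        # molecule position 5 from the 5' end with complemented bases
        pw = reconstruct_pairwise(_rec("ACGTACGT", "8M", "3C4", reverse=True))
        assert pw.pairs == [
            (rb.translate(str.maketrans("ACGT", "TGCA")), fb.translate(str.maketrans("ACGT", "TGCA")))
            for rb, fb in reversed(reconstruct_pairwise(_rec("ACGTACGT", "8M", "3C4")).pairs)
        ]
        assert pw.pairs[4] == ("A", "G")

    def test_insertion_and_softclip_excluded(self):
        # 2S3M2I3M: soft clip + insertion contribute no columns
        pw = reconstruct_pairwise(_rec("TTACGGGCAT", "2S3M2I3M", "6"))
        assert len(pw.pairs) == 6
        assert pw.n_clipped == 2 and pw.n_inserted == 2
        assert [rb for rb, _ in pw.pairs] == list("ACGCAT")

    def test_deletion_consumes_md_carets(self):
        pw = reconstruct_pairwise(_rec("ACGTAC", "3M2D3M", "3^GG3"))
        assert len(pw.pairs) == 6
        assert pw.n_deleted == 2

    def test_md_cigar_inconsistency_names_read(self):
        with pytest.raises(MdCigarError, match="r1"):
            reconstruct_pairwise(_rec("ACGTACGT", "8M", "3C10"))
        with pytest.raises(MdCigarError, match="r1"):
            reconstruct_pairwise(_rec("ACGTACGT", "8M", "2"))

    def test_no_md_no_reference_error(self):
        with pytest.raises(Exception, match="neither MD"):
            reconstruct_pairwise(_rec("ACGT", "4M", None))

    def test_reference_route_equals_md_route(self, reference_seq, reference):
        cfg = make_config(seed=13, n_reads=300, endo=1.0, d0_5p=0.2, d0_3p=0.2,
                          seq_error=0.01)
        records, _, _ = simulate_records(cfg, reference_seq)
        for rec in records:
            via_md = reconstruct_pairwise(rec, None)
            via_ref = reconstruct_pairwise(rec, reference)
            assert via_md.pairs == via_ref.pairs

    def test_unmapped_rejected(self):
        rec = AlignmentRecord(read_id="u", sequence="ACGT", is_mapped=False)
        with pytest.raises(Exception, match="mapped primary"):
            reconstruct_pairwise(rec)


class TestComputeDamageProfile:
    def test_no_damage_no_error_all_zero(self, reference_seq):
        cfg = make_config(seed=2, n_reads=2000, endo=1.0)
        records, _, _ = simulate_records(cfg, reference_seq)
        for end in ("five_prime", "three_prime"):
            profile = compute_damage_profile(records, end=end)
            assert all(d == 0 for d in profile.damage_count)

    def test_hand_built_three_prime_g_to_a(self):
        # three reads; reference ends ...G at the 3' terminal base; one read
        # carries G->A there.  Hand count: rate[1] = 1/3.
        recs = [
            _rec("ACGTG", "5M", "5", rid="a"),        # ref G at 3' pos 1, intact
            _rec("ACGTA", "5M", "4G0", rid="b"),      # ref G read A: damaged
            _rec("TTTTG", "5M", "5", rid="c"),        # intact
        ]
        profile = compute_damage_profile(recs, end="three_prime", window=3)
        assert profile.ref_base_count[0] == 3
        assert profile.damage_count[0] == 1
        assert profile.rates[0] == pytest.approx(1 / 3)

    def test_simulated_rate_recovery(self, reference_seq):
        cfg = make_config(seed=17, n_reads=20000, endo=1.0, d0_3p=0.30, decay=0.5)
        records, _, _ = simulate_records(cfg, reference_seq)
        profile = compute_damage_profile(records, end="three_prime")
        for i, expected in ((0, 0.30), (1, 0.15)):
            n = profile.ref_base_count[i]
            se = math.sqrt(expected * (1 - expected) / n)
            assert abs(profile.rates[i] - expected) <= 3 * se

    def test_five_prime_c_to_t_recovery(self, reference_seq):
        cfg = make_config(seed=18, n_reads=20000, endo=1.0, d0_5p=0.25, decay=0.6)
        records, _, _ = simulate_records(cfg, reference_seq)
        profile = compute_damage_profile(records, end="five_prime")
        for i, expected in ((0, 0.25), (1, 0.15)):
            n = profile.ref_base_count[i]
            se = math.sqrt(expected * (1 - expected) / n)
            assert abs(profile.rates[i] - expected) <= 3 * se

    def test_monotone_decay_recovered(self, reference_seq):
        cfg = make_config(seed=19, n_reads=50000, endo=1.0, d0_3p=0.3, decay=0.5)
        records, _, _ = simulate_records(cfg, reference_seq)
        profile = compute_damage_profile(records, end="three_prime")
        rates = profile.rates
        rho, p = spearmanr(range(1, len(rates) + 1), rates)
        assert rho < 0 and p < 0.01

    def test_short_reads_not_double_counted(self):
        # a 6-bp read with window 25: only 3 bases belong to each end
        rec = _rec("GGGGGG", "6M", "6")
        p5 = compute_damage_profile([rec], end="five_prime", substitution="GA", window=25)
        p3 = compute_damage_profile([rec], end="three_prime", substitution="GA", window=25)
        assert sum(p5.ref_base_count) + sum(p3.ref_base_count) == 6
        assert sum(p5.ref_base_count) == 3  # tie at the midpoint goes 5'

    def test_strand_symmetry(self, reference_seq):
        cfg = make_config(seed=23, n_reads=2000, endo=1.0, d0_5p=0.2, d0_3p=0.2)
        records, _, _ = simulate_records(cfg, reference_seq)
        flipped = [_flip_record(r) for r in records]
        for end in ("five_prime", "three_prime"):
            a = compute_damage_profile(records, end=end)
            b = compute_damage_profile(flipped, end=end)
            assert a.ref_base_count == b.ref_base_count
            assert a.damage_count == b.damage_count

    def test_position_rate_unaffected_by_sourceless_reads(self):
        recs = [_rec("ACGTA", "5M", "4G0", rid="b"), _rec("ACGTG", "5M", "5", rid="a")]
        base = compute_damage_profile(recs, end="three_prime", window=3)
        # terminal T: no G source base at 3' position 1
        extra = recs + [_rec("AAATT", "5M", "5", rid="t")]
        more = compute_damage_profile(extra, end="three_prime", window=3)
        assert more.rates[0] == base.rates[0]

    def test_no_usable_records_error(self):
        rec = AlignmentRecord(read_id="u", sequence="ACGT", is_mapped=False)
        with pytest.raises(ValueError, match="no usable"):
            compute_damage_profile([rec], end="three_prime")

    def test_mapq_filter(self):
        recs = [_rec("ACGTG", "5M", "5", mapq=0), _rec("ACGTG", "5M", "5", mapq=37, rid="r2")]
        p_all = compute_damage_profile(recs, end="three_prime", window=3)
        p_hi = compute_damage_profile(recs, end="three_prime", window=3, mapq_min=1)
        assert sum(p_all.ref_base_count) == 2 * sum(p_hi.ref_base_count)


def _flip_record(rec: AlignmentRecord) -> AlignmentRecord:
    """Represent the same molecule as if aligned to the opposite reference
    strand: reverse-complement SEQ, flip the strand flag, and mirror the MD
    tag (all-M alignments only)."""
    tokens = re.findall(r"\d+|\^[A-Z]+|[A-Z]", rec.md)
    comp = str.maketrans("ACGT", "TGCA")
    flipped_md = "".join(
        t if t.isdigit() else t.translate(comp) for t in reversed(tokens)
    )
    return AlignmentRecord(
        read_id=rec.read_id,
        sequence=reverse_complement(rec.sequence),
        is_mapped=True,
        is_reverse=not rec.is_reverse,
        mapq=rec.mapq,
        cigar=rec.cigar,
        md=flipped_md,
        ref_name=rec.ref_name,
        ref_start=rec.ref_start,
    )


class TestSummarizeDamage:
    def _profile(self, rates, counts=None):
        counts = counts or [1000] * len(rates)
        return DamageProfile(
            end="three_prime",
            substitution="GA",
            window=len(rates),
            ref_base_count=counts,
            damage_count=[int(round(r * c)) for r, c in zip(rates, counts)],
        )

    def test_spec_example(self):
        profile = self._profile([0.30, 0.20] + [0.05] * 8)
        s = summarize_damage(profile)
        assert s.n_db == 2
        assert s.r_dm == pytest.approx(0.30)
        assert s.window_mean == pytest.approx(0.09)

    def test_constant_rates_give_zero_n_db(self):
        s = summarize_damage(self._profile([0.1] * 10))
        assert s.n_db == 0
        assert s.r_dm == pytest.approx(0.1)

    def test_undefined_position_breaks_run(self):
        profile = self._profile([0.5, 0.0, 0.5, 0.0], counts=[100, 0, 100, 100])
        # position 2 undefined: run stops after position 1
        s = summarize_damage(profile)
        assert s.n_db == 1

    def test_all_undefined_error(self):
        with pytest.raises(ValueError, match="undefined"):
            summarize_damage(self._profile([0.0, 0.0], counts=[0, 0]))

    def test_random_profiles_match_brute_force(self, rng):
        for _ in range(1000):
            window = 25
            counts = rng.integers(0, 50, window).tolist()
            rates = [rng.random() if c > 0 else 0.0 for c in counts]
            profile = DamageProfile(
                end="three_prime", substitution="GA", window=window,
                ref_base_count=counts,
                damage_count=[int(r * c) for r, c in zip(rates, counts)],
            )
            defined = [d / c for c, d in zip(counts, profile.damage_count) if c > 0]
            if not defined:
                continue
            mean = sum(defined) / len(defined)
            # brute-force scan oracle, position by position
            expected = 0
            for c, d in zip(counts, profile.damage_count):
                if c > 0 and d / c > mean:
                    expected += 1
                else:
                    break
            s = summarize_damage(profile)
            assert s.n_db == expected
            assert s.r_dm == pytest.approx(max(defined))

    @given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=25))
    @settings(max_examples=200, deadline=None)
    def test_n_db_bounds_and_r_dm_max(self, rates):
        profile = DamageProfile(
            end="three_prime", substitution="GA", window=len(rates),
            ref_base_count=[10000] * len(rates),
            damage_count=[int(r * 10000) for r in rates],
        )
        s = summarize_damage(profile)
        assert 0 <= s.n_db <= len(rates)
        assert s.r_dm == max(profile.rates)
        if s.r_dm > s.window_mean:
            assert s.r_dm >= s.window_mean


class TestDispersion:
    def test_constant_values(self):
        d = dispersion([5, 5, 5, 5])
        assert d.cv == 0.0

    def test_hand_arithmetic(self):
        d = dispersion([2, 4, 6])
        assert d.mean == pytest.approx(4.0)
        assert d.sd == pytest.approx(2.0)
        assert d.cv == pytest.approx(0.5)

    def test_zero_mean_flagged(self):
        assert dispersion([-1, 1]).cv is None

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            dispersion([1.0])
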