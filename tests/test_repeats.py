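import numpy as np
import pytest

from mitoresolve.io_core import complement, revcomp
from mitoresolve.repeats import (
    canonical_rotation,
    find_dispersed_repeats,
    find_ssrs,
    find_tandem_repeats,
    ssr_base_share,
    SSRRecord,
)
from mitoresolve.synthetic import random_dna

from .oracles import bruteforce_dispersed


def _bg(seed, n, gc=0.45):
    seq = random_dna(np.random.default_rng(seed), n, gc)
    # keep the scaffold free of qualifying runs so planted features are alone
    while find_ssrs(seq) or find_tandem_repeats(seq):
        seq = random_dna(np.random.default_rng(seed + 1000), n, gc)
        seed += 1000
    return seq


class TestSSR:
    def test_planted_monomer_run(self):
        bg = _bg(0, 4000)
        seq = bg[:1000] + "T" * 12 + "A" + bg[1000:]
        (rec,) = find_ssrs(seq)
        assert (rec.motif, rec.unit_len, rec.copies) == ("T", 1, 12)
        assert rec.start == 1001 and rec.end == 1012

    def test_dimer_reported_once_with_canonical_motif(self):
        bg = _bg(1, 3000)
        seq = bg[:800] + "TA" * 7 + "GG" + bg[800:]
        recs = [r for r in find_ssrs(seq) if r.unit_len == 2]
        assert len(recs) == 1
        assert recs[0].motif == "AT"  # smallest rotation of TA

    def test_degenerate_unit_reported_at_smallest_period(self):
        # AAAAAA... qualifies as A x 12, AA x 6 and AAA x 4; only the
        # smallest (primitive) unit is reported
        seq = "CGT" + "A" * 12 + "TGC"
        recs = find_ssrs(seq, thresholds={1: 6, 2: 3, 3: 2})
        assert [(r.motif, r.unit_len, r.copies) for r in recs] == [("A", 1, 12)]

    def test_threshold_filters(self):
        seq = _bg(4, 1000) + "CAG" * 4 + "T" + _bg(5, 1000)
        assert find_ssrs(seq, thresholds={3: 5}) == []
        found = find_ssrs(seq, thresholds={3: 4})
        assert len(found) == 1 and found[0].copies == 4

    def test_origin_wrapping_run_found_once(self):
        bg = _bg(6, 2000)
        seq = "T" * 5 + bg + "T" * 7  # circular T x 12 across the origin
        recs = find_ssrs(seq, circular=True)
        assert len(recs) == 1
        (rec,) = recs
        assert rec.motif == "T" and rec.copies == 12
        assert rec.start == len(seq) - 7 + 1 and rec.end > len(seq)

    def test_base_share_percentages(self):
        recs = [
            SSRRecord("T", 1, 10, 1 + 20 * i, 10 + 20 * i) for i in range(25)
        ] + [
            SSRRecord("A", 1, 10, 1001 + 20 * i, 1010 + 20 * i) for i in range(21)
        ]
        share = ssr_base_share(recs, unit_len=1)
        assert share["T"] == 54.35
        assert share["A"] == 45.65


class TestTandem:
    UNIT15 = "GATCCTAGGTCAATG"

    def test_perfect_three_copy_array(self):
        bg = _bg(7, 5000)
        seq = bg[:2000] + self.UNIT15 * 3 + bg[2000:]
        recs = find_tandem_repeats(seq)
        assert len(recs) == 1
        (r,) = recs
        assert r.period == 15 and r.percent_match == 100.0
        assert (r.start, r.end) == (2001, 2045)
        assert r.consensus == self.UNIT15

    def test_one_substitution_keeps_locus_above_threshold(self):
        bg = _bg(8, 5000)
        unit = self.UNIT15
        middle = unit[:7] + ("A" if unit[7] != "A" else "C") + unit[8:]
        seq = bg[:2000] + unit + middle + unit + bg[2000:]
        recs = find_tandem_repeats(seq)
        assert len(recs) == 1
        (r,) = recs
        # one substitution breaks two of the 30 lag-period comparisons
        assert 75.0 < r.percent_match < 100.0
        assert abs(r.percent_match - 100 * 28 / 30) < 0.1

    def test_random_sequence_yields_nothing(self):
        hits = 0
        for seed in range(5):
            seq = random_dna(np.random.default_rng(3000 + seed), 10_000, 0.45)
            hits += bool(find_tandem_repeats(seq))
        assert hits == 0

    def test_min_period_respected(self):
        seq = _bg(9, 2000) + "ACGTA" * 10 + _bg(10, 2000)
        recs = find_tandem_repeats(seq, min_period=7)
        assert all(r.period >= 7 for r in recs)


class TestDispersed:
    def test_planted_forward_pair(self):
        bg = _bg(11, 4000)
        block = random_dna(np.random.default_rng(99), 40, 0.45)
        # distinct flank bases pin the maximal pair exactly to the block
        seq = (
            bg[:999] + "A" + block + "C" + bg[1001:2499] + "T" + block + "G"
            + bg[2501:]
        )
        recs = [r for r in find_dispersed_repeats(seq) if r.category == "forward"]
        assert len(recs) == 1
        (r,) = recs
        assert r.length == 40 and r.identity == 1.0
        assert (r.pos1, r.pos2) == (1001, 2541)

    def test_planted_palindromic_pair(self):
        bg = _bg(12, 4000)
        block = random_dna(np.random.default_rng(98), 40, 0.45)
        seq = bg[:1000] + block + bg[1000:2500] + revcomp(block) + bg[2500:]
        recs = [r for r in find_dispersed_repeats(seq) if r.category == "palindromic"]
        assert len(recs) == 1 and recs[0].length == 40

    def test_planted_reverse_and_complement_pairs(self):
        bg = _bg(13, 4000)
        block = random_dna(np.random.default_rng(97), 35, 0.45)
        seq = (
            bg[:800] + block + bg[800:1600] + block[::-1] + bg[1600:2400]
            + complement(block) + bg[2400:]
        )
        cats = {r.category for r in find_dispersed_repeats(seq)}
        assert "reverse" in cats and "complement" in cats

    def test_overlapping_self_matches_are_excluded(self):
        # a long homopolymer is SSR territory, not a dispersed pair
        seq = _bg(14, 1000) + "A" * 50 + _bg(15, 1000)
        recs = find_dispersed_repeats(seq)
        assert all("A" * 30 not in _slice(seq, r) for r in recs)

    def test_maximality_cannot_extend_any_pair(self):
        bg = _bg(16, 2000)
        block = random_dna(np.random.default_rng(96), 45, 0.45)
        seq = bg[:500] + block + bg[500:1200] + block + bg[1200:]
        for r in find_dispersed_repeats(seq):
            if r.category != "forward":
                continue
            a0, a1 = r.interval1
            b0, b1 = r.interval2
            if a0 > 0 and b0 > 0:
                assert seq[a0 - 1] != seq[b0 - 1]
            if a1 < len(seq) and b1 < len(seq):
                assert seq[a1] != seq[b1]

    def test_matches_bruteforce_oracle_on_constructed_sequence(self):
        bg = _bg(17, 1200)
        rng = np.random.default_rng(95)
        f = random_dna(rng, 34, 0.45)
        p = random_dna(rng, 31, 0.45)
        seq = (
            bg[:200] + f + bg[200:500] + f + bg[500:800] + p
            + bg[800:1000] + revcomp(p) + bg[1000:]
        )
        found = {
            (r.category, r.pos1 - 1, r.pos2 - 1, r.length)
            for r in find_dispersed_repeats(seq, min_len=30)
        }
        assert found == bruteforce_dispersed(seq, min_len=30)

    def test_revcomp_symmetry_of_category_sets(self):
        bg = _bg(18, 3000)
        rng = np.random.default_rng(94)
        f = random_dna(rng, 40, 0.45)
        p = random_dna(rng, 40, 0.45)
        seq = (
            bg[:600] + f + bg[600:1300] + f + bg[1300:2000] + p
            + bg[2000:2600] + revcomp(p) + bg[2600:]
        )
        n = len(seq)
        fwd = find_dispersed_repeats(seq)
        rev = find_dispersed_repeats(revcomp(seq))

        def transform(r):
            # map an interval pair through the genome-wide reverse complement
            a = (n - (r.pos2 - 1 + r.length), r.length)
            b = (n - (r.pos1 - 1 + r.length), r.length)
            (p1, _), (p2, _) = sorted([a, b])
            return (r.category, p1 + 1, p2 + 1, r.length)

        assert {transform(r) for r in fwd} == {
            (r.category, r.pos1, r.pos2, r.length) for r in rev
        }

    def test_min_len_floor(self):
        with pytest.raises(ValueError):
            find_dispersed_repeats("ACGT" * 100, min_len=4)


def _slice(seq, r):
    a0, a1 = r.interval1
    return seq[a0:a1]
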