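import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirkit.fold import pair_energy
from mirkit.targets import (
    RuleConfig,
    align_duplex,
    duplex_energy,
    energy_ratio,
    perfect_energy,
    predict_targets,
    rna_complement,
    score_rules,
    score_site,
)


def perfect_site(mirna):
    """Transcript subsequence that pairs the miRNA perfectly."""
    return rna_complement(mirna)[::-1]


MIRNA = "UGACAGAAGAGAGUGAGCACA"


def mutate_site(mirna, positions, base=None):
    """Force a mismatch opposite the given 1-based miRNA positions."""
    site = list(perfect_site(mirna))
    L = len(mirna)
    for p in positions:
        idx = L - p  # site position opposite miRNA position p
        cur = site[idx]
        mir = mirna[p - 1]
        for candidate in "ACGU":
            pair = (mir, candidate)
            if (
                pair not in {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
                and pair not in {("G", "U"), ("U", "G")}
            ):
                site[idx] = candidate
                break
    return "".join(site)


class TestAlignDuplex:
    def test_perfect_complement_all_wc(self):
        aln = align_duplex(MIRNA, perfect_site(MIRNA))
        assert set(aln.states) == {"W"}
        assert aln.total_weight == 0.0

    def test_single_gu_wobble(self):
        # G at miRNA position 4 opposite U instead of C
        site = list(perfect_site(MIRNA))
        assert MIRNA[3] == "C"  # position 4 is C; pick a G position instead
        gpos = MIRNA.index("G") + 1
        site[len(MIRNA) - gpos] = "U"
        aln = align_duplex(MIRNA, "".join(site))
        assert aln.states[gpos - 1] == "G"
        assert aln.total_weight == 0.5

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            align_duplex("ACGU", "ACG")

    @settings(max_examples=50, deadline=None)
    @given(st.text(alphabet="ACGU", min_size=21, max_size=21),
           st.text(alphabet="ACGU", min_size=21, max_size=21))
    def test_states_match_per_position_oracle(self, mirna, site):
        aln = align_duplex(mirna, site)
        L = 21
        for i in range(L):
            pair = (mirna[i], site[L - 1 - i])
            if pair in {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}:
                assert aln.states[i] == "W"
            elif pair in {("G", "U"), ("U", "G")}:
                assert aln.states[i] == "G"
            else:
                assert aln.states[i] == "M"


class TestScoreRules:
    def test_perfect_duplex_passes_all(self):
        aln = align_duplex(MIRNA, perfect_site(MIRNA))
        assert all(score_rules(aln).values())

    def test_single_wobble_counts_half(self):
        site = list(perfect_site(MIRNA))
        gpos = [i for i, c in enumerate(MIRNA, 1) if c == "G"][2]  # position 5 area
        site[len(MIRNA) - gpos] = "U"
        aln = align_duplex(MIRNA, "".join(site))
        assert aln.total_weight == 0.5
        assert all(score_rules(aln).values())

    def test_mismatch_at_position_10_fails_r4(self):
        aln = align_duplex(MIRNA, mutate_site(MIRNA, [10]))
        verdicts = score_rules(aln)
        assert not verdicts["R4"]

    def test_wobble_at_position_10_fails_r4_strict(self):
        site = list(perfect_site(MIRNA))
        # find a G or U at positions 10/11 to wobble
        p = 10 if MIRNA[9] in "GU" else 11
        assert MIRNA[p - 1] in "GU"
        site[len(MIRNA) - p] = "U" if MIRNA[p - 1] == "G" else "G"
        aln = align_duplex(MIRNA, "".join(site))
        assert aln.states[p - 1] == "G"
        assert not score_rules(aln)["R4"]
        relaxed = RuleConfig(gu_counts_in_adjacency=False)
        assert score_rules(aln, relaxed)["R4"]

    def test_three_adjacent_mismatches_fail_r2(self):
        aln = align_duplex(MIRNA, mutate_site(MIRNA, [15, 16, 17]))
        assert not score_rules(aln)["R2"]

    def test_two_adjacent_outside_seed_pass_r2_r3(self):
        aln = align_duplex(MIRNA, mutate_site(MIRNA, [15, 16]))
        verdicts = score_rules(aln)
        assert verdicts["R2"] and verdicts["R3"]

    def test_two_adjacent_inside_seed_fail_r3(self):
        aln = align_duplex(MIRNA, mutate_site(MIRNA, [5, 6]))
        assert not score_rules(aln)["R3"]

    def test_five_scattered_mismatches_fail_r1(self):
        aln = align_duplex(MIRNA, mutate_site(MIRNA, [1, 13, 15, 17, 19]))
        assert aln.total_weight == 5.0
        assert not score_rules(aln)["R1"]

    def test_seed_weight_fails_r5(self):
        aln = align_duplex(MIRNA, mutate_site(MIRNA, [2, 4, 6]))
        assert not score_rules(aln)["R5"]


class TestEnergyRatio:
    def test_perfect_duplex_100(self):
        aln = align_duplex(MIRNA, perfect_site(MIRNA))
        assert energy_ratio(aln) == pytest.approx(100.0)

    def test_gc_20mer_single_mismatch_95(self):
        mirna = "GC" * 10
        aln = align_duplex(mirna, mutate_site(mirna, [15]))
        assert perfect_energy(mirna) == -60.0
        assert duplex_energy(aln) == -57.0
        assert energy_ratio(aln) == pytest.approx(95.0)

    def test_ratio_bounds(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            mirna = "".join(rng.choice(list("ACGU"), 21))
            site = "".join(rng.choice(list("ACGU"), 21))
            aln = align_duplex(mirna, site)
            ratio = energy_ratio(aln)
            assert ratio is None or 0.0 <= ratio <= 100.0

    def test_below_60_fails_r6(self):
        mirna = "GC" * 10  # perfect -60; each mismatch costs 3 (5%)
        site = mutate_site(mirna, [13, 14, 15, 16, 17, 18, 19, 20, 12])
        s = score_site("m", mirna, "t", site[::-1][::-1], 0)
        # ratio = (60 - 9*3)/60 = 55%
        assert s.energy_ratio == pytest.approx(55.0)
        assert not s.rule_verdicts["R6"]


class TestPredictTargets:
    def test_planted_reverse_complement_found(self):
        mirna = MIRNA
        site_dna = perfect_site(mirna).replace("U", "T")
        transcript = "A" * 50 + site_dna + "A" * 50
        sites = predict_targets({"m": mirna}, {"t": transcript})
        assert any(s.start == 51 and s.passed for s in sites)

    def test_random_pairs_essentially_never_pass(self):
        rng = np.random.default_rng(11)
        hits = 0
        for _ in range(200):
            mirna = "".join(rng.choice(list("ACGU"), 21))
            transcript = "".join(rng.choice(list("ACGT"), 500))
            hits += len(predict_targets({"m": mirna}, {"t": transcript}))
        assert hits == 0

    def test_planted_sites_all_recalled(self, small_study):
        cfg, bundle, truth, _ = small_study
        mirnas = {mid: truth.matures[mid] for mid in truth.true_mirnas}
        sites = predict_targets(mirnas, bundle.transcripts)
        found = {(s.mirna_id, s.transcript_id, s.start - 1) for s in sites}
        for planted in truth.true_targets:
            assert planted in found

    def test_equivalence_with_exhaustive_re_derivation(self):
        # independent oracle: re-derive all six rules from scratch per offset
        rng = np.random.default_rng(5)
        mirna = "".join(rng.choice(list("ACGU"), 21))
        transcript = "".join(rng.choice(list("ACGT"), 400))
        # plant a near-perfect site to exercise passing paths
        planted = perfect_site(mirna).replace("U", "T")
        transcript = transcript[:100] + planted + transcript[100 + len(planted):]

        def oracle(mirna, transcript):
            t = transcript.replace("T", "U")
            L = len(mirna)
            wc = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
            gu = {("G", "U"), ("U", "G")}
            passing = set()
            for off in range(len(t) - L + 1):
                site = t[off : off + L]
                states = []
                for i in range(L):
                    p = (mirna[i], site[L - 1 - i])
                    states.append("W" if p in wc else ("G" if p in gu else "M"))
                w = [0.0 if s == "W" else (0.5 if s == "G" else 1.0) for s in states]
                bad = [s != "W" for s in states]
                if sum(w) > 4:
                    continue
                runs = max(
                    (len(run) for run in "".join("x" if b else "." for b in bad).split(".")),
                    default=0,
                )
                if runs >= 3:
                    continue
                if any(bad[i] and bad[i + 1] for i in range(1, 11)):
                    continue
                if bad[9] or bad[10]:
                    continue
                if sum(w[:12]) > 2.5:
                    continue
                e_duplex = sum(
                    pair_energy(mirna[i], site[L - 1 - i])
                    for i in range(L)
                    if states[i] != "M"
                )
                e_perfect = sum(
                    pair_energy(c, p) for c, p in zip(mirna, rna_complement(mirna))
                )
                if e_perfect == 0 or e_duplex / e_perfect * 100 < 60:
                    continue
                passing.add(off)
            return passing

        sites = predict_targets({"m": mirna}, {"t": transcript})
        assert {s.start - 1 for s in sites} == oracle(mirna, transcript)

    def test_added_mismatch_monotone(self):
        base = mutate_site(MIRNA, [15])
        more = mutate_site(MIRNA, [15, 17])
        w0 = align_duplex(MIRNA, base).total_weight
        w1 = align_duplex(MIRNA, more).total_weight
        assert w1 >= w0
        v0 = score_rules(align_duplex(MIRNA, base))
        v1 = score_rules(align_duplex(MIRNA, more))
        for rule in v0:
            if not v0[rule]:
                assert not v1[rule]
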