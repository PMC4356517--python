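"""Junction caller: microhomology, crossover location, classification."""

import itertools

import numpy as np
import pytest

import alurecomb as ar
from alurecomb.caller import COMPLEX
from conftest import make_pair


def brute_force_microhomology(seq: str, left: int, right: int, max_shift: int = 30):
    """Independent oracle: enumerate all shifted placements producing the same
    product; return (ambiguity, leftmost placement)."""
    product = seq[:left] + seq[right:]
    placements = []
    for l in range(max(0, left - max_shift), min(left + max_shift, right) + 1):
        r = l + (right - left)
        if r <= len(seq) and seq[:l] + seq[r:] == product:
            placements.append((l, r))
    lo = min(placements)
    hi = max(placements)
    return hi[0] - lo[0], lo[0], lo[1]


class TestMeasureMicrohomology:
    def test_blunt_junction_has_zero_microhomology(self):
        seq = "AAAACCCCGGGGTTTT"
        mh, left, right = ar.measure_microhomology(seq, 4, 8)
        # flanks 'AAAA' | 'GGGGTTTT': no shared bases across the junction
        assert (mh, left, right) == (0, 4, 8)

    def test_shared_gatc_flank_gives_microhomology_4_leftmost(self):
        seq = "AAGATCTTTTGATCAA"
        mh, left, right = ar.measure_microhomology(seq, 6, 14)
        assert mh == 4
        assert seq[left : left + mh] == "GATC"
        assert seq[:left] + seq[right:] == seq[:6] + seq[14:]
        assert (left, right) == (2, 10)

    def test_equivalent_placements_normalize_identically(self):
        seq = "AAGATCTTTTGATCAA"
        calls = {ar.measure_microhomology(seq, 2 + o, 10 + o) for o in range(5)}
        assert calls == {(4, 2, 10)}

    def test_agrees_with_brute_force_oracle_on_random_junctions(self):
        rng = np.random.default_rng(7)
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        for _ in range(300):
            left = int(rng.integers(50, 900))
            right = int(rng.integers(left + 1, 1950))
            assert ar.measure_microhomology(seq, left, right) == brute_force_microhomology(
                seq, left, right
            )


def oracle_locate(vec):
    """Independent oracle: brute-force consistency with every monotone vector."""
    n = len(vec)
    if n == 0:
        return 0
    if sum(g == 0 for g in vec) / n > 0.10:
        return ar.UNRESOLVED
    if all(g == 0 for g in vec):
        return ar.UNRESOLVED
    consistent = []
    for i in range(n + 1):
        monotone = [1] * i + [2] * (n - i)
        if all(g == 0 or g == m for g, m in zip(vec, monotone)):
            consistent.append(i)
    if not consistent:
        return COMPLEX
    # junction reported immediately left of the first observed parent-2 allele
    return max(consistent)


class TestLocateCrossover:
    @pytest.mark.parametrize(
        "vec,expected",
        [
            ((1, 1, 2, 2, 2), 2),
            ((2, 2, 2), 0),
            ((1, 1, 1), 3),
            ((1, 2, 1, 2), COMPLEX),
            ((2, 1), COMPLEX),
            ((), 0),
        ],
    )
    def test_conventions(self, vec, expected):
        assert ar.locate_crossover(vec) == expected

    def test_exhaustive_agreement_with_consistency_oracle_up_to_length_6(self):
        for n in range(1, 7):
            for vec in itertools.product((0, 1, 2), repeat=n):
                assert ar.locate_crossover(vec) == oracle_locate(vec), vec

    def test_missing_tolerance_on_long_vectors(self):
        vec = (1,) * 10 + (0,) + (2,) * 9  # 5% missing: resolvable
        assert ar.locate_crossover(vec) == 11
        vec = (1,) * 6 + (0, 0, 0) + (2,) * 11  # 15% missing: unresolved
        assert ar.locate_crossover(vec) == ar.UNRESOLVED


class TestCallJunction:
    def test_single_crossover_round_trip(self, pair5, cassette5, imap5):
        for idx in range(pair5.n_sites + 1):
            event = ar.simulate_recombination_product(cassette5, pair5, idx)
            call = ar.call_junction(event.product_sequence, cassette5, pair5, imap5)
            assert call.event_class == ar.RECOMB_SINGLE_CROSSOVER
            assert call.crossover_interval == idx
            assert call.segment_index == imap5.segment_of_interval(idx)

    def test_unmodified_cassette_is_unresolved(self, pair5, cassette5):
        call = ar.call_junction(cassette5.sequence, cassette5, pair5)
        assert call.event_class == ar.UNRESOLVED

    def test_truncated_flank_is_unresolved(self, pair5, cassette5):
        event = ar.simulate_recombination_product(cassette5, pair5, 3)
        call = ar.call_junction(event.product_sequence[25:], cassette5, pair5)
        assert call.event_class == ar.UNRESOLVED

    def test_nhej_breakpoints_and_microhomology_round_trip(self, pair5, cassette5, imap5):
        rng = np.random.default_rng(8)
        tested = 0
        while tested < 40:
            left = int(rng.integers(1250, 2350))
            right = int(rng.integers(2620, 2890))
            event = ar.simulate_nhej_deletion(cassette5, left, right)
            if not event.detectable:
                continue
            call = ar.call_junction(event.product_sequence, cassette5, pair5, imap5)
            if call.event_class != ar.NHEJ_DELETION:
                continue  # in-register junction, operationally a recombinant
            assert call.deletion_size == event.deletion_size
            assert call.left_breakpoint == event.left_breakpoint
            assert call.right_breakpoint == event.right_breakpoint
            assert call.microhomology_len == event.microhomology_len
            assert call.breakpoint_ambiguity == call.microhomology_len
            tested += 1

    def test_complex_chimera_round_trip(self, pair5, cassette5, imap5):
        alleles = (1, 2, 2, 1, 1) + (2,) * 10
        event = ar.simulate_complex_chimera(cassette5, pair5, alleles)
        call = ar.call_junction(event.product_sequence, cassette5, pair5, imap5)
        assert call.event_class == ar.RECOMB_COMPLEX_CHIMERA
        assert call.patch_alleles == alleles
        assert call.segment_index is None

    def test_spacer_only_deletion_keeps_both_alus_and_is_nhej(self, pair5, cassette5, imap5):
        a1, a2 = cassette5["alu1"], cassette5["alu2"]
        event = ar.simulate_nhej_deletion(cassette5, a1.end + 3, a2.start - 100)
        call = ar.call_junction(event.product_sequence, cassette5, pair5, imap5)
        assert call.event_class == ar.NHEJ_DELETION
        assert call.topology == "no_Alu"

    def test_gapped_pair_single_crossover_recovery(self, consensus):
        gapped = ar.AluSequence("gap", consensus.bases[:120] + consensus.bases[125:])
        pair = ar.align_pair(consensus, gapped)
        assert not pair.is_ungapped
        cassette = ar.build_cassette(pair, seed=404)
        for idx in range(pair.n_sites + 1):
            event = ar.simulate_recombination_product(cassette, pair, idx)
            call = ar.call_junction(event.product_sequence, cassette, pair)
            assert call.event_class == ar.RECOMB_SINGLE_CROSSOVER
            assert call.crossover_interval == idx


class TestNhejTopology:
    def test_left_in_alu1_right_in_alu2_is_both(self, pair5, cassette5):
        call = ar.JunctionCall(
            event_class=ar.NHEJ_DELETION, left_breakpoint=1300, right_breakpoint=2700,
            breakpoint_ambiguity=0,
        )
        assert ar.classify_nhej_topology(call, cassette5) == "both_Alus"

    def test_left_in_filler_right_in_alu2_is_one(self, pair5, cassette5):
        call = ar.JunctionCall(
            event_class=ar.NHEJ_DELETION, left_breakpoint=1600, right_breakpoint=2700,
            breakpoint_ambiguity=0,
        )
        assert ar.classify_nhej_topology(call, cassette5) == "one_Alu"

    def test_topology_requires_an_nhej_call(self, cassette5):
        call = ar.JunctionCall(event_class=ar.RECOMB_SINGLE_CROSSOVER)
        with pytest.raises(ValueError):
            ar.classify_nhej_topology(call, cassette5)

    def test_uniform_breakpoints_match_geometric_expectation(self, pair5, cassette5, imap5):
        rng = np.random.default_rng(44)
        a1, a2 = cassette5["alu1"], cassette5["alu2"]
        lo_l, hi_l = cassette5["promoter"].end, cassette5["sceI_site"].start
        lo_r, hi_r = cassette5["sceI_site"].end, cassette5["puroR"].start
        n, in_alu1 = 0, 0
        while n < 600:
            left = int(rng.integers(lo_l, hi_l + 1))
            right = int(rng.integers(lo_r, hi_r + 1))
            event = ar.simulate_nhej_deletion(cassette5, left, right)
            if not event.detectable:
                continue
            call = ar.call_junction(event.product_sequence, cassette5, pair5, imap5)
            if call.event_class != ar.NHEJ_DELETION:
                continue
            n += 1
            in_alu1 += a1.start <= call.left_breakpoint < a1.end
        # left breakpoints landing in alu1, among detectable draws: compare to
        # the geometric expectation computed by enumerating the accepted region
        accepted = []
        for left in range(lo_l, hi_l + 1):
            lo_size, hi_size = cassette5.detectable_deletion_window
            lo_ok = max(lo_r, left + lo_size, cassette5["sceI_site"].end)
            hi_ok = min(hi_r, left + hi_size)
            if left <= cassette5["polyA"].start and lo_ok <= hi_ok:
                accepted.append((left, hi_ok - lo_ok + 1))
        total = sum(w for _, w in accepted)
        p_alu1 = sum(w for l, w in accepted if a1.start <= l < a1.end) / total
        sd = (n * p_alu1 * (1 - p_alu1)) ** 0.5
        assert abs(in_alu1 - n * p_alu1) <= 3.5 * sd
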