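"""Read-to-amplicon assignment, trimming and fragment construction."""

import numpy as np
import pytest

from poolcross.assign import (
    REJECT_CONFLICT,
    REJECT_LENGTH,
    REJECT_NO_FORWARD,
    ReadPair,
    assign_pairs,
    match_primer,
    process_read_pair,
)
from conftest import random_seq


def brute_force_match(read_seq, variants, max_error_rate):
    """Independent oracle: try every variant by direct string comparison."""
    best = None  # (mismatches, -len, panel_index, variant)
    for idx, v in enumerate(variants):
        m = v.het_base + v.gene_seq
        if len(read_seq) < len(m):
            continue
        mism = sum(1 for a, b in zip(read_seq[: len(m)], m) if a != b)
        if mism > int(max_error_rate * len(m)):
            continue
        key = (mism, -len(m), idx)
        if best is None or key < best[0]:
            best = (key, v)
    return best[1] if best else None


def make_read(prefix, rng, length=150):
    return prefix + random_seq(rng, length - len(prefix))


class TestMatchPrimer:
    def test_het_variant_wins_and_trims_21(self, panel, rng):
        read = make_read("ACCACTCATCCATTCGGAAATGG", rng)
        m = match_primer(read, panel.variants("forward"), 0.1)
        assert m.amplicon_id == "1"
        assert m.variant.is_het
        assert m.trim_length == 21

    def test_plain_variant_trims_20(self, panel, rng):
        read = make_read("CCACTCATCCATTCGGAAATGG", rng)
        m = match_primer(read, panel.variants("forward"), 0.1)
        assert m.amplicon_id == "1"
        assert not m.variant.is_het
        assert m.trim_length == 20

    def test_garbage_no_match(self, panel):
        assert match_primer("G" * 150, panel["1"].forward, 0.1) is None

    def test_mismatch_budget_is_floor_of_rate_times_length(self, panel, rng):
        """2 substitutions in a 20-nt match: allowed at rate 0.1 (floor 2),
        rejected at rate 0.05 (floor 1)."""
        gene = panel["1"].plain("forward").gene_seq
        mutated = "GG" + gene[2:]  # 2 mismatches
        assert mutated != gene
        read = make_read(mutated, rng)
        variants = panel["1"].forward
        plain_only = [v for v in variants if not v.is_het]
        assert match_primer(read, plain_only, 0.1) is not None
        assert match_primer(read, plain_only, 0.05) is None

    def test_invalid_error_rate(self, panel):
        with pytest.raises(ValueError):
            match_primer("ACGT" * 40, panel.variants("forward"), 0.6)

    def test_oracle_equivalence_random_reads(self, panel, rng):
        """Exact agreement with the brute-force oracle on 1,000 random reads
        spanning clean, mutated and unmatchable prefixes."""
        variants = panel.variants("forward")
        reads = []
        plain_seqs = [panel[a].plain("forward").gene_seq for a in panel.amplicon_ids]
        for i in range(1000):
            kind = i % 4
            if kind == 0:
                reads.append(random_seq(rng, 150))
            else:
                gene = plain_seqs[rng.integers(0, len(plain_seqs))]
                prefix = ("A" if kind == 2 else "") + gene
                n_mut = int(rng.integers(0, 4))
                chars = list(prefix)
                for _ in range(n_mut):
                    p = int(rng.integers(0, len(chars)))
                    chars[p] = "ACGT"[rng.integers(0, 4)]
                reads.append(make_read("".join(chars), rng))
        for rate in (0.0, 0.1):
            for read in reads:
                got = match_primer(read, variants, rate)
                expected = brute_force_match(read, variants, rate)
                if expected is None:
                    assert got is None
                else:
                    assert got is not None
                    assert (got.variant.amplicon_id, got.variant.het_base) == (
                        expected.amplicon_id,
                        expected.het_base,
                    )


def valid_pair(panel, rng, amplicon_id="1", het1=False, het2=False, read_id="r"):
    amp = panel[amplicon_id]
    # amplicon 10 of the reference panel has no heterogeneity variants
    f = next((v for v in amp.forward if v.is_het == het1), amp.plain("forward"))
    r = next((v for v in amp.reverse if v.is_het == het2), amp.plain("reverse"))
    return ReadPair(
        read_id,
        make_read(f.match_seq, rng),
        make_read(r.match_seq, rng),
    )


class TestProcessReadPair:
    def test_kept_lengths_equalized_across_variants(self, panel, rng):
        """Het-forward + plain-reverse both keep 129 bases; the fragment is
        their 258-nt concatenation."""
        pair = valid_pair(panel, rng, het1=True, het2=False)
        frag, reason = process_read_pair(pair, panel, 0.1, "lib")
        assert reason is None
        assert len(frag.haplotype) == 258
        # plain read keeps read_length - plain_len = 130 then loses its last base
        trimmed_plain = pair.seq2[20:-1]
        assert frag.haplotype.endswith(trimmed_plain)
        # het read drops het base + primer, keeping 129 directly
        assert frag.haplotype.startswith(pair.seq1[21:])

    def test_variant_choice_does_not_change_haplotype(self, panel, rng):
        """The same template yields the same haplotype through het and plain
        primers (the motivation for the +1 trim)."""
        insert = random_seq(rng, 135)
        amp = panel["1"]
        frags = set()
        for het1 in (False, True):
            for het2 in (False, True):
                f = next(v for v in amp.forward if v.is_het == het1)
                r = next(v for v in amp.reverse if v.is_het == het2)
                s1 = (f.match_seq + insert)[:150]
                s2 = (r.match_seq + insert)[:150]
                frag, reason = process_read_pair(ReadPair("r", s1, s2), panel, 0.1)
                assert reason is None
                frags.add(frag.haplotype)
        assert len(frags) == 1

    def test_amplicon_conflict(self, panel, rng):
        p1 = valid_pair(panel, rng, "1")
        p3 = valid_pair(panel, rng, "3")
        pair = ReadPair("r", p1.seq1, p3.seq2)
        frag, reason = process_read_pair(pair, panel, 0.1)
        assert frag is None and reason == REJECT_CONFLICT

    def test_short_read_rejected_by_length_filter(self, panel, rng):
        pair = valid_pair(panel, rng)
        short = ReadPair("r", pair.seq1[:140], pair.seq2)
        frag, reason = process_read_pair(short, panel, 0.1)
        assert frag is None and reason == REJECT_LENGTH


class TestAssignPairs:
    def test_hand_built_fixture_counts(self, panel, rng):
        """4 valid amplicon-1 pairs, 1 cross-amplicon conflict, 1 unmatched."""
        pairs = [valid_pair(panel, rng, "1", i % 2 == 0, i % 2 == 1, f"v{i}") for i in range(4)]
        p1, p3 = valid_pair(panel, rng, "1"), valid_pair(panel, rng, "3")
        pairs.append(ReadPair("conflict", p1.seq1, p3.seq2))
        pairs.append(ReadPair("junk", "G" * 150, "G" * 150))
        frags, stats = assign_pairs(pairs, panel, "lib")
        assert len(frags) == 4
        assert stats.assigned == {"1": 4}
        assert stats.rejected == {REJECT_CONFLICT: 1, REJECT_NO_FORWARD: 1}
        assert stats.total_pairs == 6

    def test_conservation_and_constant_fragment_length(self, panel, rng):
        pairs = []
        for i in range(200):
            amp = panel.amplicon_ids[rng.integers(0, 12)]
            if i % 5 == 0:
                pairs.append(ReadPair(f"r{i}", random_seq(rng, 150), random_seq(rng, 150)))
            else:
                pairs.append(
                    valid_pair(panel, rng, amp, bool(rng.integers(2)), bool(rng.integers(2)), f"r{i}")
                )
        frags, stats = assign_pairs(pairs, panel, "lib")
        assert stats.n_assigned + stats.n_rejected == stats.total_pairs == 200
        by_amp = {}
        for f in frags:
            by_amp.setdefault(f.amplicon_id, set()).add(len(f.haplotype))
        for amp, lengths in by_amp.items():
            assert lengths == {panel.fragment_length(amp)}

    def test_mate_order_permutation_invariance(self, panel, rng):
        pairs = [
            valid_pair(panel, rng, panel.amplicon_ids[i % 12], read_id=f"r{i}")
            for i in range(50)
        ]
        frags1, _ = assign_pairs(pairs, panel, "lib")
        perm = [pairs[i] for i in np.random.default_rng(0).permutation(50)]
        frags2, _ = assign_pairs(perm, panel, "lib")
        assert sorted(f.haplotype for f in frags1) == sorted(f.haplotype for f in frags2)

    def test_empty_input(self, panel):
        frags, stats = assign_pairs([], panel, "lib")
        assert frags == [] and stats.total_pairs == 0
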