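"""The pooled-progeny sequencing simulator and its bias model."""

import math
from collections import Counter

import numpy as np
import pytest

from poolcross.assign import ReadPair, assign_pairs
from poolcross.filtering import apply_frequency_filters, count_haplotypes
from poolcross.panel import ROLE_PARENTAL_LEAF, ROLE_SEED_POOL, parse_sample_sheet
from poolcross.simulate import (
    LibrarySpec,
    SimulationConfig,
    build_genotypes,
    default_design,
    reverse_complement,
    simulate_experiment,
    simulate_reads,
    simulate_seed_pool,
    true_fragment,
)


@pytest.fixture()
def small_panel(panel):
    return panel.subset(["1", "3"])


def genotypes_for(config, panel, lines=("M",), seed=7):
    return build_genotypes(config, panel, list(lines), np.random.default_rng(seed))


class TestSeedPool:
    def test_fully_selfed_pool_is_all_maternal(self, small_panel):
        cfg = SimulationConfig(n_seeds=200)
        g = genotypes_for(cfg, small_panel)
        alleles, realized = simulate_seed_pool(
            cfg, g, "M", "1", t=0.0, rng=np.random.default_rng(0)
        )
        assert set(alleles) == set(g.maternal_inserts("M", "1"))
        assert sum(alleles.values()) == 400
        assert realized == 0.0

    def test_full_sharing_makes_outcrossing_invisible(self, small_panel):
        """t=1, q=1: every paternal allele equals the maternal haplotype."""
        cfg = SimulationConfig(n_seeds=200, q=1.0)
        g = genotypes_for(cfg, small_panel)
        alleles, realized = simulate_seed_pool(
            cfg, g, "M", "1", t=1.0, rng=np.random.default_rng(0)
        )
        assert set(alleles) == set(g.maternal_inserts("M", "1"))
        assert realized == 0.0

    def test_binomial_expectation_at_large_n(self, small_panel):
        """t=0.4, q=0: non-parental allele fraction ~ t/2 = 0.20 within 3
        binomial standard errors at 10,000 seeds."""
        cfg = SimulationConfig(n_seeds=10_000)
        g = genotypes_for(cfg, small_panel)
        _, realized = simulate_seed_pool(
            cfg, g, "M", "1", t=0.4, rng=np.random.default_rng(0)
        )
        se = math.sqrt(0.2 * 0.8 / 20_000)
        assert abs(realized - 0.2) < 3 * se

    def test_allele_total_is_twice_seed_count(self, small_panel):
        cfg = SimulationConfig(n_seeds=137)
        g = genotypes_for(cfg, small_panel)
        alleles, _ = simulate_seed_pool(
            cfg, g, "M", "1", t=0.5, rng=np.random.default_rng(1)
        )
        assert sum(alleles.values()) == 2 * 137


class TestReads:
    def test_error_free_reads_recover_exact_fragments(self, small_panel):
        """With e=0 and a single maternal allele, every assigned fragment
        equals the true trimmed haplotype and f = 0."""
        cfg = SimulationConfig(reads_per_amplicon=200)
        g = genotypes_for(cfg, small_panel)
        maternal = g.maternal_inserts("M", "1")[0]
        reads = simulate_reads(
            {maternal: 10}, cfg, small_panel, "1", np.random.default_rng(0)
        )
        pairs = [ReadPair(f"r{i}", s1, s2) for i, (s1, s2) in enumerate(reads)]
        frags, stats = assign_pairs(pairs, small_panel, "lib")
        assert stats.n_assigned == 200
        expected = true_fragment(maternal, small_panel, "1")
        assert {f.haplotype for f in frags} == {expected}

    def test_errors_create_minor_haplotypes_but_truth_dominates(self, small_panel):
        cfg = SimulationConfig(reads_per_amplicon=5000, error_rate=0.01)
        g = genotypes_for(cfg, small_panel)
        maternal = g.maternal_inserts("M", "1")[0]
        reads = simulate_reads(
            {maternal: 10}, cfg, small_panel, "1", np.random.default_rng(0)
        )
        pairs = [ReadPair(f"r{i}", s1, s2) for i, (s1, s2) in enumerate(reads)]
        frags, _ = assign_pairs(pairs, small_panel, "lib")
        counts = Counter(f.haplotype for f in frags)
        assert len(counts) > 1
        top, _ = counts.most_common(1)[0]
        assert top == true_fragment(maternal, small_panel, "1")

    def test_read_structure_and_lengths(self, small_panel):
        cfg = SimulationConfig(reads_per_amplicon=50)
        g = genotypes_for(cfg, small_panel)
        maternal = g.maternal_inserts("M", "1")[0]
        reads = simulate_reads(
            {maternal: 1}, cfg, small_panel, "1", np.random.default_rng(0)
        )
        fwd_plain = small_panel["1"].plain("forward").gene_seq
        rc = reverse_complement(maternal)
        seen_het = seen_plain = False
        for s1, s2 in reads:
            assert len(s1) == len(s2) == 150
            if s1.startswith("A" + fwd_plain):
                seen_het = True
            else:
                assert s1.startswith(fwd_plain)
                seen_plain = True
            assert rc[:50] in s2
        assert seen_het and seen_plain  # both primer variants used

    def test_insert_too_short_rejected(self, small_panel):
        cfg = SimulationConfig(insert_length=100)
        g = genotypes_for(cfg, small_panel)
        with pytest.raises(ValueError, match="too short"):
            simulate_reads(
                {g.maternal_inserts("M", "1")[0]: 1},
                cfg,
                small_panel,
                "1",
                np.random.default_rng(0),
            )

    def test_jackpot_injection_creates_private_haplotype(self, small_panel):
        """A jackpot-enabled cell contains exactly one extra haplotype in the
        1-5% band when reads are error-free."""
        cfg = SimulationConfig(
            rng_seed=3,
            amplicon_ids=["1", "3"],
            reads_per_amplicon=2000,
            jackpot_prob=1.0,
            libraries=[
                LibrarySpec("pool1", ROLE_SEED_POOL, "M", "open", "1", 0.0),
                LibrarySpec("leaf", ROLE_PARENTAL_LEAF, "M"),
            ],
        )
        import tempfile

        with tempfile.TemporaryDirectory() as d:
            sheet, truth = simulate_experiment(cfg, d, panel=small_panel)
            assert ("pool1", "1") in truth.jackpots
            from poolcross.assign import assign_library

            lib = sheet["pool1"]
            frags, _ = assign_library(
                f"{d}/{lib.fastq1}", f"{d}/{lib.fastq2}", small_panel, "pool1"
            )
            counts = count_haplotypes(frags)
            freqs = counts.frequencies("pool1", "1")
            jackpot_frag = true_fragment(truth.jackpots[("pool1", "1")], small_panel, "1")
            assert jackpot_frag in freqs
            assert 0.005 < freqs[jackpot_frag] < 0.06  # nominal 1-5% +/- noise
            assert len(freqs) == 2  # maternal + jackpot only


class TestExperiment:
    def test_default_design_yields_14_libraries(self, tmp_path, eight_amplicons):
        cfg = SimulationConfig(
            rng_seed=0, amplicon_ids=eight_amplicons[:2], reads_per_amplicon=50
        )
        sheet, truth = simulate_experiment(cfg, tmp_path)
        assert len(sheet.libraries) == 14
        assert len(sheet.seed_pools) == 12
        assert len(sheet.leaf_libraries) == 2
        assert (tmp_path / "sample_sheet.tsv").exists()
        assert (tmp_path / "truth.tsv").exists()
        again = parse_sample_sheet(tmp_path / "sample_sheet.tsv")
        assert len(again.libraries) == 14

    def test_same_seed_byte_identical(self, tmp_path, eight_amplicons):
        cfg = SimulationConfig(
            rng_seed=5, amplicon_ids=eight_amplicons[:2], reads_per_amplicon=30,
            error_rate=0.01, jackpot_prob=0.5,
        )
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_experiment(cfg, d1)
        simulate_experiment(cfg, d2)
        for f in sorted(p.name for p in d1.iterdir()):
            assert (d1 / f).read_bytes() == (d2 / f).read_bytes()

    def test_different_seed_differs(self, tmp_path, eight_amplicons):
        c1 = SimulationConfig(rng_seed=1, amplicon_ids=eight_amplicons[:1], reads_per_amplicon=30)
        c2 = SimulationConfig(rng_seed=2, amplicon_ids=eight_amplicons[:1], reads_per_amplicon=30)
        simulate_experiment(c1, tmp_path / "a")
        simulate_experiment(c2, tmp_path / "b")
        name = "CNL1_G_bird_1_R1.fastq"
        assert (tmp_path / "a" / name).read_bytes() != (tmp_path / "b" / name).read_bytes()

    def test_config_json_round_trip(self, tmp_path):
        cfg = SimulationConfig(rng_seed=9, q=0.25, libraries=default_design(t_open=0.4))
        path = tmp_path / "config.json"
        cfg.to_json(path)
        again = SimulationConfig.from_json(path)
        assert again == cfg

    def test_probability_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(error_rate=1.5).validate()
        with pytest.raises(ValueError):
            SimulationConfig(
                libraries=[LibrarySpec("x", ROLE_SEED_POOL, "M", t=1.2)]
            ).validate()


class TestFilterEfficacyOnSimulations:
    def test_jackpots_removed_errors_removed_donors_retained(self, panel):
        """On an error-free two-pool run with jackpots everywhere, every
        injected artifact survives the 1% rule yet is removed by the
        single-sample rule, while donor haplotypes shared by the pools are
        retained."""
        import tempfile

        amps = ["1", "3", "4"]
        cfg = SimulationConfig(
            rng_seed=11,
            amplicon_ids=amps,
            reads_per_amplicon=2000,
            jackpot_prob=1.0,
            jackpot_freq_range=(0.02, 0.05),
            libraries=[
                LibrarySpec("pool1", ROLE_SEED_POOL, "M", "open", "1", 0.3),
                LibrarySpec("pool2", ROLE_SEED_POOL, "M", "open", "2", 0.3),
                LibrarySpec("leaf", ROLE_PARENTAL_LEAF, "M"),
            ],
        )
        sub = panel.subset(amps)
        with tempfile.TemporaryDirectory() as d:
            sheet, truth = simulate_experiment(cfg, d, panel=sub)
            from poolcross.assign import assign_library

            frags = []
            for lib in sheet.libraries:
                fs, _ = assign_library(
                    f"{d}/{lib.fastq1}", f"{d}/{lib.fastq2}", sub, lib.library_id
                )
                frags.extend(fs)
            raw = count_haplotypes(frags)
            filtered = apply_frequency_filters(raw)
            for (lib, amp), insert in truth.jackpots.items():
                jf = true_fragment(insert, sub, amp)
                assert jf in raw.cell(lib, amp)  # injected and sequenced
                assert raw.cell(lib, amp)[jf] / raw.raw_totals[(lib, amp)] >= 0.01
                assert jf not in filtered.cell(lib, amp)  # single-sample rule
            for amp in amps:
                for donor in truth.genotypes.donors[amp]:
                    df = true_fragment(donor, sub, amp)
                    for pool in ("pool1", "pool2"):
                        assert df in filtered.cell(pool, amp)
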