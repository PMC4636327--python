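"""Simulator ground truth: reference synthesis, in-silico PCR, error model,
dilution series."""

import numpy as np
import pytest

from tissamp16s import mocksim, protocol
from tissamp16s._seq import reverse_complement
from tissamp16s.readprep import JoinConfig, join_pairs_batch

import oracles


class TestSynthReferenceSet:
    def test_even_fourteen_strain_design_with_dropout(self):
        spec, tax = mocksim.synth_reference_set(14, seed=1, primer_dropout=[13])
        assert len(spec.strains) == 14
        assert all(s.copies == mocksim.DEFAULT_EVEN_COPIES for s in spec.strains)
        amplifiable = mocksim.in_silico_pcr(spec)
        assert len(amplifiable) == 13
        assert "Strain14" not in {s.name for s, _ in amplifiable}

    def test_two_strains_share_family_not_genus(self):
        spec, tax = mocksim.synth_reference_set(2, seed=2)
        a, b = spec.strains
        assert a.lineage[4] == b.lineage[4]  # same family
        assert a.lineage[5] != b.lineage[5]  # different genus

    def test_pairwise_divergence_within_declared_bands(self):
        spec, _ = mocksim.synth_reference_set(8, seed=3)
        strains = spec.strains
        for i in range(len(strains)):
            for j in range(i + 1, len(strains)):
                a, b = strains[i], strains[j]
                diffs = oracles.hamming_loop(a.sequence, b.sequence)
                frac = diffs / len(a.sequence)
                if a.lineage[4] == b.lineage[4]:  # genus siblings
                    assert 0.02 < frac < 0.12
                else:  # different families
                    assert 0.08 < frac < 0.40

    def test_amplicon_carries_real_primer_sites(self):
        spec, _ = mocksim.synth_reference_set(2, seed=4)
        for s in spec.strains:
            assert s.sequence.startswith(protocol.FORWARD_16S_PRIMER)
            assert s.sequence.endswith(protocol.reverse_site_on_plus_strand())
            assert len(s.sequence) == protocol.REGION_LENGTH

    def test_training_sequences_disjoint_from_strain_sequences(self):
        spec, tax = mocksim.synth_reference_set(4, seed=5)
        strain_seqs = {s.sequence for s in spec.strains}
        assert all(seq not in strain_seqs for _, seq, _ in tax.records)


class TestInSilicoPCR:
    def test_exact_sites_amplify(self):
        spec, _ = mocksim.synth_reference_set(3, seed=6)
        hits = mocksim.in_silico_pcr(spec)
        assert len(hits) == 3
        for strain, (a, b) in hits:
            assert (a, b) == (0, protocol.REGION_LENGTH)

    def test_three_mismatches_in_forward_site_dropped(self):
        spec, _ = mocksim.synth_reference_set(3, seed=7, primer_dropout=[1])
        hits = mocksim.in_silico_pcr(spec)
        assert {s.name for s, _ in hits} == {"Strain01", "Strain03"}

    def test_dropout_fixture_equals_declared_set(self):
        spec, _ = mocksim.synth_reference_set(10, seed=8, primer_dropout=[0, 4])
        hits = {s.name for s, _ in mocksim.in_silico_pcr(spec)}
        assert hits == {f"Strain{i+1:02d}" for i in range(10) if i not in (0, 4)}


class TestSimulateRun:
    def test_zero_depth_empty(self):
        spec, _ = mocksim.synth_reference_set(2, seed=9)
        run = mocksim.simulate_run(spec, mocksim.SeqRunConfig(depth=0))
        assert run.pairs == [] and run.truth.reads == []

    def test_error_free_reads_roundtrip_through_joining(self):
        spec, _ = mocksim.synth_reference_set(2, seed=10)
        cfg = mocksim.SeqRunConfig(
            depth=50, substitution_rate=0, indel_rate=0, seed=11
        )
        run = mocksim.simulate_run(spec, cfg)
        joined, rejected = join_pairs_batch(run.pairs, JoinConfig.preset("v2"))
        assert not rejected
        amplicons = {s.sequence for s in spec.strains}
        assert all(j.sequence in amplicons for j in joined)

    def test_substitution_rate_within_binomial_error(self):
        spec, _ = mocksim.synth_reference_set(2, seed=12)
        depth = 10_000
        cfg = mocksim.SeqRunConfig(depth=depth, indel_rate=0, seed=13)
        run = mocksim.simulate_run(spec, cfg)
        by_name = {s.name: s.sequence for s in spec.strains}
        total_bases = 0
        total_subs = 0
        for pair, (rid, tname, chim) in zip(run.pairs, run.truth.reads):
            t = by_name[tname]
            total_bases += len(t)
            total_subs += oracles.hamming_loop(pair.r1_seq, t[:250])
            total_subs += oracles.hamming_loop(
                pair.r2_seq, reverse_complement(t)[:250]
            )
            total_bases -= 467 - 500  # overlap double-counted: 33 bases
        # observed rate over all sequenced bases vs nominal 0.001
        rate = total_subs / (depth * 500)
        se = np.sqrt(0.001 * 0.999 / (depth * 500))
        assert abs(rate - 0.001) < 3 * se

    def test_ground_truth_ledger_complete(self):
        spec, _ = mocksim.synth_reference_set(3, seed=14)
        cfg = mocksim.SeqRunConfig(depth=500, chimera_rate=0.02, seed=15)
        run = mocksim.simulate_run(spec, cfg)
        assert len(run.truth.reads) == 500
        names = {s.name for s in spec.strains}
        for rid, tname, chim in run.truth.reads:
            if chim:
                assert tname.startswith("chimera:")
            else:
                assert tname in names
        assert sum(1 for *_, c in run.truth.reads if c) == 10

    def test_seeded_runs_identical(self):
        spec, _ = mocksim.synth_reference_set(2, seed=16)
        cfg = mocksim.SeqRunConfig(depth=100, seed=17)
        r1 = mocksim.simulate_run(spec, cfg)
        r2 = mocksim.simulate_run(spec, cfg)
        assert [(p.r1_seq, p.r2_seq) for p in r1.pairs] == [
            (p.r1_seq, p.r2_seq) for p in r2.pairs
        ]

    def test_even_design_read_shares_near_uniform(self):
        spec, _ = mocksim.synth_reference_set(5, seed=18)
        depth = 20_000
        run = mocksim.simulate_run(spec, mocksim.SeqRunConfig(depth=depth, seed=19))
        from collections import Counter

        shares = Counter(t for _, t, _ in run.truth.reads)
        for name, n in shares.items():
            p = n / depth
            se = np.sqrt(0.2 * 0.8 / depth)
            assert abs(p - 0.2) < 4 * se

    def test_no_pool_raises(self):
        spec, _ = mocksim.synth_reference_set(2, seed=20, primer_dropout=[0, 1])
        with pytest.raises(ValueError):
            mocksim.simulate_run(spec, mocksim.SeqRunConfig(depth=10))

    def test_fastq_write_roundtrip(self, tmp_path):
        spec, _ = mocksim.synth_reference_set(2, seed=21)
        cfg = mocksim.SeqRunConfig(depth=20, seed=22, index_seq="AACCGG")
        run = mocksim.simulate_run(spec, cfg)
        mocksim.write_run_fastq(run, tmp_path / "r1.fastq", tmp_path / "r2.fastq")
        from tissamp16s.readprep import read_fastq_pairs

        pairs = list(read_fastq_pairs(tmp_path / "r1.fastq", tmp_path / "r2.fastq"))
        assert len(pairs) == 20
        assert pairs[0].r1_seq == run.pairs[0].r1_seq
        assert pairs[0].index_seq == "AACCGG"


class TestDilutionSeries:
    def test_background_share_matches_copy_ratio(self):
        spec, _ = mocksim.synth_reference_set(4, seed=23)
        bg, _ = mocksim.synth_background(3, seed=24, copies=500)
        depth = 4000
        cfg = mocksim.SeqRunConfig(depth=depth, background=bg, seed=25)
        runs = mocksim.dilution_series(spec, cfg, copies_grid=[100, 100_000])
        bg_names = {s.name for s in bg}
        for sid, copies, run in runs:
            n_bg = sum(1 for _, t, _ in run.truth.reads if t in bg_names)
            if copies == 0:
                assert n_bg == depth  # negative control is pure background
                continue
            total_copies = 4 * copies + 3 * 500
            expect = 3 * 500 / total_copies
            se = np.sqrt(expect * (1 - expect) / depth)
            assert abs(n_bg / depth - expect) < 4 * se

    def test_high_copy_point_dominated_by_strains(self):
        spec, _ = mocksim.synth_reference_set(4, seed=26)
        bg, _ = mocksim.synth_background(3, seed=27, copies=500)
        cfg = mocksim.SeqRunConfig(depth=1000, background=bg, seed=28)
        runs = mocksim.dilution_series(spec, cfg, copies_grid=[10_000_000])
        _, _, run = runs[0]
        bg_names = {s.name for s in bg}
        n_bg = sum(1 for _, t, _ in run.truth.reads if t in bg_names)
        assert n_bg < 10

    def test_distinct_sample_ids_and_indexes(self):
        spec, _ = mocksim.synth_reference_set(3, seed=29)
        bg, _ = mocksim.synth_background(2, seed=33)
        cfg = mocksim.SeqRunConfig(depth=10, background=bg, seed=30)
        runs = mocksim.dilution_series(
            spec, cfg, copies_grid=[10, 1000], n_negative_controls=2
        )
        sids = [sid for sid, _, _ in runs]
        idxs = [run.pairs[0].index_seq for _, _, run in runs]
        assert len(set(sids)) == 4 and len(set(idxs)) == 4


class TestStaggered:
    def test_staggered_copies_span_range(self):
        copies = mocksim.staggered_copies(14)
        assert copies[0] == 1000 and copies[-1] == 1_000_000
        assert all(b > a for a, b in zip(copies, copies[1:]))

    def test_expected_abundance_proportional_to_copies(self):
        spec, _ = mocksim.synth_reference_set(5, seed=31)
        copies = mocksim.staggered_copies(5)
        spec = spec.with_copies({s.name: c for s, c in zip(spec.strains, copies)})
        run = mocksim.simulate_run(spec, mocksim.SeqRunConfig(depth=100, seed=32))
        total = sum(copies)
        for s, c in zip(spec.strains, copies):
            assert run.truth.expected_abundance[s.name] == pytest.approx(c / total)
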