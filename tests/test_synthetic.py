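"""Synthetic generator: determinism, planted architecture, dropout model."""

import numpy as np
import pytest

from censcan.classify import diagnostic_residue_states, measure_loop1_extension
from censcan.references import CANONICAL_H3, DEFAULT_REFERENCE
from censcan.seqcore import align_global, translate_six_frames
from censcan.synthetic import (
    SpeciesScenario,
    back_translate,
    divergent_copy,
    fungal_cenh3_backbone,
    generate_assembly,
    host_cenh3_backbone,
    make_cenh3_like,
    make_degraded_h3_like,
    shred_reads,
)


class TestBackTranslate:
    def test_roundtrip_through_translation(self, rng):
        protein = "MKWVKRALDEQHIS"
        nt = back_translate(protein, rng)
        assert len(nt) == 3 * len(protein)
        assert translate_six_frames(nt)[1] == protein


class TestDivergentCopy:
    def test_rate_zero_is_identity(self, rng):
        assert divergent_copy(CANONICAL_H3, 0.0, rng) == CANONICAL_H3

    def test_observed_divergence_tracks_model(self, rng):
        """p_observed ~ (19/20)(1 - exp(-20 r / 19)) within binomial noise."""
        protein = "A" * 2000
        for rate in (0.1, 0.5, 1.0):
            copy = divergent_copy(protein, rate, rng)
            p_obs = sum(a != b for a, b in zip(protein, copy)) / len(protein)
            p_exp = (19 / 20) * (1 - np.exp(-20 * rate / 19))
            sd = np.sqrt(p_exp * (1 - p_exp) / len(protein))
            assert abs(p_obs - p_exp) < 4 * sd


class TestMakeCenH3Like:
    def test_deterministic(self):
        assert make_cenh3_like(CANONICAL_H3, 2, seed=7) == make_cenh3_like(
            CANONICAL_H3, 2, seed=7
        )
        assert make_cenh3_like(CANONICAL_H3, 2, seed=7) != make_cenh3_like(
            CANONICAL_H3, 2, seed=8
        )

    def test_loop1_insertion_size_recovered_by_alignment(self):
        for n in (1, 2, 4):
            cen = make_cenh3_like(CANONICAL_H3, n, seed=3)
            aln = align_global(cen, CANONICAL_H3, "cand", "H3")
            assert measure_loop1_extension(aln) == n

    def test_diagnostic_positions_substituted(self, reference):
        cen = make_cenh3_like(CANONICAL_H3, 2, seed=11)
        aln = align_global(cen, CANONICAL_H3, "cand", "H3")
        states = diagnostic_residue_states(aln, reference)
        assert all(s == "substituted" for s in states.values())

    def test_tail_is_divergent(self):
        cen = make_cenh3_like(CANONICAL_H3, 2, seed=5)
        end = DEFAULT_REFERENCE.ntail_end
        tail_id = sum(
            a == b for a, b in zip(cen[:end], CANONICAL_H3[:end])
        ) / end
        assert tail_id < 0.5

    def test_rejects_empty_insertion(self):
        with pytest.raises(ValueError):
            make_cenh3_like(CANONICAL_H3, 0, seed=1)

    def test_backbones_are_shared_derived_state(self):
        """Two CenH3s built on the same backbone share fold substitutions."""
        # equal insertion sizes so positions stay comparable without aligning
        a = make_cenh3_like(host_cenh3_backbone(), 2, seed=1)
        b = make_cenh3_like(host_cenh3_backbone(), 2, seed=2)
        c = make_cenh3_like(fungal_cenh3_backbone(), 2, seed=3)
        ref = DEFAULT_REFERENCE

        def fold_identity(x, y):
            lo, hi = ref.fold_start - 1, min(len(x), len(y), ref.fold_end)
            return sum(p == q for p, q in zip(x[lo:hi], y[lo:hi])) / (hi - lo)

        # same-backbone pair more similar than cross-backbone pair
        assert fold_identity(a, b) > fold_identity(a, c)


class TestDegradedH3:
    def test_keeps_canonical_diagnostic_residues(self, reference):
        deg = make_degraded_h3_like(seed=4)
        aln = align_global(deg, CANONICAL_H3, "cand", "H3")
        states = diagnostic_residue_states(aln, reference)
        assert all(s == "canonical" for s in states.values())

    def test_fold_is_substantially_diverged(self):
        deg = make_degraded_h3_like(seed=4)
        ref = DEFAULT_REFERENCE
        lo, hi = ref.fold_start - 1, ref.fold_end
        ident = sum(a == b for a, b in zip(deg[lo:hi], CANONICAL_H3[lo:hi]))
        assert ident / (hi - lo) < 0.9


class TestGenerateAssembly:
    def test_deterministic(self):
        scn = SpeciesScenario(species_id="d", n_benchmark_genes=8, seed=9)
        a1, a2 = generate_assembly(scn), generate_assembly(scn)
        assert [(t.id, t.seq) for t in a1.transcripts] == [
            (t.id, t.seq) for t in a2.transcripts
        ]

    def test_truth_table_matches_emitted_transcripts(self):
        scn = SpeciesScenario(species_id="t", n_benchmark_genes=12, seed=2)
        asm = generate_assembly(scn)
        emitted_ids = {t.locus_id for t in asm.transcripts}
        for gene, entry in asm.truth.items():
            assert (gene in emitted_ids) == entry.emitted

    def test_no_dropout_emits_everything(self):
        scn = SpeciesScenario(species_id="full", n_benchmark_genes=10,
                              dropout_prob=0.0, seed=3)
        asm = generate_assembly(scn)
        assert all(e.emitted for e in asm.truth.values())
        assert asm.truth["CenH3"].emitted

    def test_cenh3_absent_scenario_has_no_cenh3_transcript(self):
        scn = SpeciesScenario(species_id="no", n_benchmark_genes=5,
                              cenh3_present=False, seed=3)
        asm = generate_assembly(scn)
        assert "CenH3" not in asm.truth or not asm.truth["CenH3"].emitted
        assert not any(t.locus_id == "CenH3" for t in asm.transcripts)

    def test_contaminant_flagged_in_truth(self):
        scn = SpeciesScenario(species_id="c", n_benchmark_genes=5,
                              cenh3_present=False, contaminant_present=True,
                              seed=3)
        asm = generate_assembly(scn)
        contaminants = [g for g, e in asm.truth.items() if e.contaminant]
        assert len(contaminants) == 1
        assert asm.truth[contaminants[0]].emitted

    def test_dropout_fraction_is_binomial_around_mean(self):
        """Per-gene dropout varies with expression but averages dropout_prob."""
        p = 0.3
        n = 400
        scn = SpeciesScenario(species_id="b", n_benchmark_genes=n,
                              dropout_prob=p, seed=6)
        asm = generate_assembly(scn)
        benchmark = [e for g, e in asm.truth.items() if g.startswith("gene")]
        frac_dropped = sum(not e.emitted for e in benchmark) / len(benchmark)
        sd = np.sqrt(p * (1 - p) / n)
        assert abs(frac_dropped - p) < 4 * sd

    def test_low_expression_genes_drop_more(self):
        scn = SpeciesScenario(species_id="le", n_benchmark_genes=600,
                              dropout_prob=0.3, seed=8)
        asm = generate_assembly(scn)
        bench = [(e.count, e.emitted) for g, e in asm.truth.items()
                 if g.startswith("gene")]
        bench.sort()
        lo = bench[: len(bench) // 3]
        hi = bench[-len(bench) // 3:]
        drop_lo = sum(not e for _, e in lo) / len(lo)
        drop_hi = sum(not e for _, e in hi) / len(hi)
        assert drop_lo > drop_hi


class TestShredReads:
    def test_reads_are_exact_substrings(self, small_assembly):
        reads = shred_reads(small_assembly, read_length=100, seed=1,
                            max_reads_per_transcript=3)
        by_id = {t.id: t.seq for t in small_assembly.transcripts}
        for rid, seq in reads:
            src = rid.rsplit("_read", 1)[0]
            assert len(seq) == 100
            assert seq in by_id[src]

    def test_read_counts_follow_truth_counts(self, small_assembly):
        reads = shred_reads(small_assembly, read_length=100, seed=1)
        n_by_tx = {}
        for rid, _ in reads:
            src = rid.rsplit("_read", 1)[0]
            n_by_tx[src] = n_by_tx.get(src, 0) + 1
        for t in small_assembly.transcripts:
            expected = small_assembly.counts[t.id]
            if len(t.seq) >= 100 and expected > 0:
                assert n_by_tx.get(t.id, 0) == expected
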