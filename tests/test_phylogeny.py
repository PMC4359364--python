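"""Phylogenetic attribution: domain extraction, NJ trees, placement."""

import numpy as np
import pytest

from censcan.phylogeny import (
    align_domains,
    build_tree,
    default_panel,
    extract_fold_domain,
    place_candidate,
    poisson_distances,
)
from censcan.references import CANONICAL_H3
from censcan.synthetic import (
    divergent_copy,
    host_cenh3_backbone,
    make_cenh3_like,
    random_protein,
)


class TestFoldExtraction:
    def test_h3_domain_lengths(self, reference):
        full = extract_fold_domain(CANONICAL_H3, reference)
        no_loop1 = extract_fold_domain(CANONICAL_H3, reference,
                                       exclude_loop1=True)
        lo, hi = reference.loop1_window
        assert len(full) == reference.fold_end - reference.fold_start + 1
        assert len(no_loop1) == len(full) - (hi - lo + 1)

    def test_loop1_insertion_does_not_leak_into_domain(self, reference):
        """Loop1-excluded domains of CenH3s with different insertion sizes
        have equal length: the variable loop never enters the matrix."""
        a = extract_fold_domain(
            make_cenh3_like(host_cenh3_backbone(), 2, seed=1),
            reference, exclude_loop1=True,
        )
        b = extract_fold_domain(
            make_cenh3_like(host_cenh3_backbone(), 5, seed=2),
            reference, exclude_loop1=True,
        )
        assert abs(len(a) - len(b)) <= 1  # alignment wobble only

    def test_unalignable_protein_rejected(self, rng, reference):
        with pytest.raises(ValueError):
            extract_fold_domain("MKW", reference)


class TestDistancesAndTrees:
    def test_poisson_distance_known_values(self):
        # encode two 10-residue sequences differing at 2 sites: p = 0.2
        from censcan.phylogeny import _encode_alignment

        names, mat = _encode_alignment(
            {"a": "AAAAAAAAAA", "b": "AAAAAAAARR"}
        )
        d = poisson_distances(mat)
        assert d[0, 1] == pytest.approx(-np.log(1 - 0.2))
        assert d[0, 0] == 0.0

    def test_identical_sequences_have_zero_distance(self):
        from censcan.phylogeny import _encode_alignment

        names, mat = _encode_alignment({"a": "MKWVK", "b": "MKWVK"})
        assert poisson_distances(mat)[0, 1] == 0.0

    def test_nj_recovers_planted_quartet(self, rng):
        root = random_protein(120, rng)
        left = divergent_copy(root, 0.3, rng)
        right = divergent_copy(root, 0.3, rng)
        seqs = {
            "a": divergent_copy(left, 0.05, rng),
            "b": divergent_copy(left, 0.05, rng),
            "c": divergent_copy(right, 0.05, rng),
            "d": divergent_copy(right, 0.05, rng),
        }
        aligned = align_domains(seqs)
        result = build_tree(aligned, n_bootstrap=100, seed=0)
        support = result.supports.get(frozenset({"a", "b"})) or result.supports.get(
            frozenset({"c", "d"})
        )
        assert support is not None and support >= 95

    def test_duplicate_leaves_form_zero_length_cherry(self, rng):
        base = random_protein(100, rng)
        stem = divergent_copy(base, 0.3, rng)  # positive internal edge
        seqs = {
            "dup1": stem,
            "dup2": stem,
            "far1": divergent_copy(base, 0.5, rng),
            "far2": divergent_copy(base, 0.8, rng),
        }
        result = build_tree(align_domains(seqs), n_bootstrap=50, seed=1)
        # the canonical recorded side is the one without the min-name leaf
        assert frozenset({"far1", "far2"}) in result.supports

    def test_bootstrap_deterministic_given_seed(self, rng):
        seqs = {f"s{i}": divergent_copy(random_protein(80, rng), 0.0, rng)
                for i in range(1)}
        base = random_protein(90, rng)
        seqs = {
            "a": divergent_copy(base, 0.1, rng),
            "b": divergent_copy(base, 0.1, rng),
            "c": divergent_copy(base, 0.6, rng),
            "d": divergent_copy(base, 0.6, rng),
        }
        aligned = align_domains(seqs)
        r1 = build_tree(aligned, n_bootstrap=50, seed=3)
        r2 = build_tree(aligned, n_bootstrap=50, seed=3)
        assert r1.supports == r2.supports


class TestPlacement:
    def test_panel_member_places_in_its_own_clade(self):
        panel = default_panel()
        name, seq = sorted(panel.contaminant_refs.items())[0]
        verdict = place_candidate(seq, "candidate_x", panel=panel,
                                  n_bootstrap=100, seed=0)
        assert verdict.verdict == "contaminant"
        assert verdict.support >= 70

    def test_divergent_contaminant_copy_attributed(self, rng):
        panel = default_panel()
        donor = sorted(panel.contaminant_refs.values())[0]
        candidate = divergent_copy(donor, 0.5, rng)
        verdict = place_candidate(candidate, "contam_like", panel=panel,
                                  n_bootstrap=100, seed=0)
        assert verdict.verdict == "contaminant"
        assert verdict.support >= 70

    def test_host_style_candidate_never_called_contaminant(self):
        panel = default_panel()
        candidate = make_cenh3_like(host_cenh3_backbone(), 3, seed=77)
        verdict = place_candidate(candidate, "host_like", panel=panel,
                                  n_bootstrap=100, seed=0)
        assert verdict.verdict in {"host", "unresolved"}

    def test_order_invariance_of_alignment(self, rng):
        base = random_protein(100, rng)
        seqs = {f"n{i}": divergent_copy(base, 0.2, rng) for i in range(5)}
        a1 = align_domains(seqs)
        a2 = align_domains(dict(reversed(list(seqs.items()))))
        assert a1 == a2
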