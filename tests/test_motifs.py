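"""Profile (PSSM) scanning: hand-computed oracle, planted motifs, nulls."""

import math

import numpy as np
import pytest

from censcan.motifs import (
    PROFILE_ALPHABET,
    build_profile,
    call_cenpc_architecture,
    read_profile,
    scan_profile,
    write_profile,
    MotifHit,
)
from censcan.phylogeny import PlacementVerdict
from censcan.references import load_cenpc_motif_seed, load_cupin_seed
from censcan.synthetic import divergent_copy, random_protein


class TestBuildProfile:
    def test_hand_computed_log_odds(self):
        """3 sequences, all 'A' in column 0: score must equal
        log2(((3 + 0.5/20) / (3 + 0.5)) / (1/20))."""
        seed = {"s1": "AAAAA", "s2": "AAAAA", "s3": "AAAAA"}
        profile = build_profile(seed, pseudocount=0.5)
        expected = math.log2(((3 + 0.5 / 20) / 3.5) / (1 / 20))
        a_idx = PROFILE_ALPHABET.index("A")
        assert profile.matrix[0, a_idx] == pytest.approx(expected)
        # any other residue gets the pure-pseudocount score
        r_idx = PROFILE_ALPHABET.index("R")
        expected_r = math.log2(((0.5 / 20) / 3.5) / (1 / 20))
        assert profile.matrix[0, r_idx] == pytest.approx(expected_r)

    def test_consensus_is_column_argmax(self):
        seed = {"s1": "ARNDC", "s2": "ARNDC", "s3": "ARNWC"}
        assert build_profile(seed).consensus == "ARNDC"

    def test_rejects_ragged_or_tiny_input(self):
        with pytest.raises(ValueError):
            build_profile({"a": "AAAAA", "b": "AAAA", "c": "AAAAA"})
        with pytest.raises(ValueError):
            build_profile({"a": "AAAA", "b": "AAAA", "c": "AAAA"})
        with pytest.raises(ValueError):
            build_profile({"a": "AAAAA", "b": "AAAAA"})

    def test_rejects_all_gap_column(self):
        with pytest.raises(ValueError):
            build_profile({"a": "AA-AA", "b": "AA-AA", "c": "AA-AA"})


class TestScanProfile:
    def test_planted_motif_found_at_offset(self, rng):
        seed_aln = load_cenpc_motif_seed()
        profile = build_profile(seed_aln, name="cenpc_motif")
        consensus = profile.consensus
        host = random_protein(300, rng)
        planted = host[:137] + consensus + host[137 + len(consensus):]
        hit = scan_profile(profile, planted, "planted", n_null=199, seed=0)
        assert hit.offset == 137
        assert hit.pvalue == 1 / 200

    def test_diverged_motif_instance_still_significant(self, rng):
        profile = build_profile(load_cenpc_motif_seed(), name="cenpc_motif")
        instance = divergent_copy(profile.consensus, 0.2, rng)
        host = random_protein(250, rng)
        hit = scan_profile(profile, host[:100] + instance + host[100:],
                           "div", n_null=199, seed=0)
        assert hit.pvalue <= 0.01

    def test_null_pvalues_not_anticonservative(self, rng):
        """On random proteins the p-value must be stochastically >= uniform."""
        profile = build_profile(load_cenpc_motif_seed())
        pvals = [
            scan_profile(profile, random_protein(200, rng), f"null{i}",
                         n_null=99, seed=i).pvalue
            for i in range(40)
        ]
        # expect ~2 of 40 below 0.05 under uniformity; 6+ would be suspect
        assert sum(p <= 0.05 for p in pvals) <= 6

    def test_protein_shorter_than_profile_rejected(self):
        profile = build_profile(load_cupin_seed())
        with pytest.raises(ValueError):
            scan_profile(profile, "MKWVK")


class TestArchitectureCalls:
    def _hit(self, p):
        return MotifHit("x", "m", 0, 10.0, p)

    def test_four_way_labels(self):
        sig, ns = self._hit(1e-4), self._hit(0.4)
        assert call_cenpc_architecture(sig, sig) == "motif+cupin"
        assert call_cenpc_architecture(sig, ns) == "motif-only"
        assert call_cenpc_architecture(ns, sig) == "cupin-only"
        assert call_cenpc_architecture(ns, ns) == "none"
        assert call_cenpc_architecture(None, None) == "none"

    def test_cupin_requires_clade_attribution(self):
        sig = self._hit(1e-4)
        host = PlacementVerdict("c", "host", 90.0)
        other = PlacementVerdict("c", "contaminant", 90.0)
        assert call_cenpc_architecture(None, sig, host) == "cupin-only"
        assert call_cenpc_architecture(None, sig, other) == "none"


class TestSerialization:
    def test_roundtrip(self, tmp_path):
        profile = build_profile(load_cenpc_motif_seed(), name="cenpc_motif")
        path = tmp_path / "profile.txt"
        write_profile(profile, path)
        back = read_profile(path)
        assert back.name == profile.name
        assert np.allclose(back.matrix, profile.matrix, atol=1e-6)
        assert np.allclose(back.background, profile.background)
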