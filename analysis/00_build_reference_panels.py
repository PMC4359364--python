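"""Build the bundled synthetic reference panels.

Constructs, with fixed seeds, every labeled sequence set the pipeline needs
and writes them into the package data directory (``src/censcan/data``):

* an animal-style (host) CenH3 panel — four CenH3s sharing the host fold
  backbone, each with its own loop1 insertion, diagnostic substitutions and
  randomized N-terminal tail;
* a fungal-style (contaminant) CenH3 panel built the same way on the deeply
  diverged fungal backbone; its first member doubles as the contaminant
  donor used by the synthetic species generator;
* seed alignments for the CenpC motif (width 24) and the CenpC-type cupin
  domain (width 100): a fixed random consensus with 15% per-column noise in
  six seed sequences;
* a non-CenpC cupin panel (plus a distant cupin outgroup) for the cupin
  clade test.

All sequences are synthetic stand-ins with the diagnostic architecture of
the real families; filenames carry the ``synthetic_`` prefix.  Rerunning
this script reproduces the files byte-for-byte.
"""

from pathlib import Path

import numpy as np

from censcan.references import DEFAULT_REFERENCE
from censcan.seqcore import write_fasta
from censcan.synthetic import (
    AMINO_ACIDS,
    divergent_copy,
    fungal_cenh3_backbone,
    host_cenh3_backbone,
    make_cenh3_like,
)

DATA_DIR = Path(__file__).resolve().parents[1] / "src" / "censcan" / "data"


def build_cenh3_panels() -> None:
    host = {
        f"syn_host_cenh3_{i + 1:02d}": make_cenh3_like(
            host_cenh3_backbone(), n_insert, seed=1000 + i, reference=DEFAULT_REFERENCE
        )
        for i, n_insert in enumerate([2, 3, 3, 4])
    }
    write_fasta(host, DATA_DIR / "synthetic_cenh3_host_panel.fasta")

    contaminant = {
        f"syn_fungal_cenh3_{i + 1:02d}": make_cenh3_like(
            fungal_cenh3_backbone(), n_insert, seed=2000 + i,
            reference=DEFAULT_REFERENCE,
        )
        for i, n_insert in enumerate([4, 4, 3, 5])
    }
    write_fasta(contaminant, DATA_DIR / "synthetic_cenh3_contaminant_panel.fasta")


def _noisy_seed_alignment(consensus: str, n_seqs: int, noise: float,
                          rng: np.random.Generator) -> dict:
    out = {}
    for i in range(n_seqs):
        chars = list(consensus)
        for j, c in enumerate(chars):
            if rng.random() < noise:
                choices = [a for a in AMINO_ACIDS if a != c]
                chars[j] = choices[rng.integers(len(choices))]
        out[f"seed_{i + 1:02d}"] = "".join(chars)
    return out


def build_motif_seeds() -> None:
    rng = np.random.default_rng(424242)
    motif_consensus = "".join(rng.choice(list(AMINO_ACIDS), size=24))
    motif_seed = _noisy_seed_alignment(motif_consensus, 6, 0.15, rng)
    write_fasta(
        {f"cenpc_motif_{k}": v for k, v in motif_seed.items()},
        DATA_DIR / "synthetic_cenpc_motif_seed.fasta",
    )

    # The two cupin families descend from a common fold root, each through
    # its own derived ancestor (a positive stem edge), so each family is a
    # genuine clade the placement test can recover.
    cupin_root = "".join(rng.choice(list(AMINO_ACIDS), size=100))
    cenpc_ancestor = divergent_copy(cupin_root, 0.4, rng)
    cupin_seed = _noisy_seed_alignment(cenpc_ancestor, 6, 0.15, rng)
    write_fasta(
        {f"cenpc_cupin_{k}": v for k, v in cupin_seed.items()},
        DATA_DIR / "synthetic_cupin_seed.fasta",
    )

    # non-CenpC cupins: same fold family, deeply diverged from the CenpC type
    other_ancestor = divergent_copy(cupin_root, 0.4, rng)
    other = {
        f"syn_noncenpc_cupin_{i + 1:02d}": divergent_copy(other_ancestor, 0.1, rng)
        for i in range(3)
    }
    other["syn_cupin_outgroup"] = divergent_copy(cupin_root, 0.9, rng)
    write_fasta(other, DATA_DIR / "synthetic_noncenpc_cupin_panel.fasta")


def main() -> None:
    DATA_DIR.mkdir(parents=True, exist_ok=True)
    build_cenh3_panels()
    build_motif_seeds()
    for path in sorted(DATA_DIR.glob("synthetic_*.fasta")):
        n = sum(1 for line in open(path) if line.startswith(">"))
        print(f"wrote {path.name}: {n} sequences")


if __name__ == "__main__":
    main()
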