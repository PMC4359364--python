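"""Phylogenetic host-vs-contaminant attribution of CenH3-like candidates.

Reads candidate proteins written by ``02_classify_histones.py``, places
each against the bundled host and contaminant CenH3 reference panels, and
writes one verdict table.
"""

import argparse
from pathlib import Path

from censcan.phylogeny import default_panel, place_candidate, write_verdicts_tsv
from censcan.seqcore import read_fasta


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--indir", type=Path,
                        default=Path("results/classification"))
    parser.add_argument("--out", type=Path,
                        default=Path("results/contamination_verdicts.tsv"))
    parser.add_argument("--bootstrap", type=int, default=100)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()
    args.out.parent.mkdir(parents=True, exist_ok=True)

    panel = default_panel()
    verdicts = []
    for fasta in sorted(args.indir.glob("*.candidates.fasta")):
        species = fasta.name.replace(".candidates.fasta", "")
        for name, protein in read_fasta(fasta).items():
            verdict = place_candidate(
                protein, f"{species}:{name}", panel=panel,
                n_bootstrap=args.bootstrap, seed=args.seed,
            )
            verdicts.append(verdict)
            print(f"{verdict.candidate_id}: {verdict.verdict} "
                  f"(support {verdict.support:.0f})")
    write_verdicts_tsv(verdicts, args.out)


if __name__ == "__main__":
    main()
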