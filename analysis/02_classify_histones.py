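"""Classify H3-family candidates in every simulated assembly.

Reads the assemblies written by ``01_simulate_cohort.py``, runs the
translated homology search plus the five-way variant classifier, and
writes one calls table per species and a FASTA of candidate proteins for
the downstream contamination attribution step.
"""

import argparse
from pathlib import Path

from censcan.classify import classify_assembly, write_calls_tsv
from censcan.references import default_query_set
from censcan.seqcore import transcripts_from_fasta, write_fasta


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--indir", type=Path, default=Path("results/simulated"))
    parser.add_argument("--outdir", type=Path,
                        default=Path("results/classification"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    queries = default_query_set()
    for fasta in sorted(args.indir.glob("*.fasta")):
        if fasta.name.endswith(".benchmark.fasta"):
            continue
        species = fasta.stem
        transcripts = transcripts_from_fasta(fasta)
        pairs = classify_assembly(transcripts, queries=queries)
        write_calls_tsv([call for _, call in pairs],
                        args.outdir / f"{species}.calls.tsv")
        candidates = {
            cand.id: cand.protein for cand, call in pairs
            if call.label in ("CenH3", "H3-like")
        }
        if candidates:
            write_fasta(candidates, args.outdir / f"{species}.candidates.fasta")
        labels = ", ".join(
            f"{cand.source_id}={call.label}" for cand, call in pairs
        )
        print(f"{species}: {labels or 'no candidates'}")


if __name__ == "__main__":
    main()
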