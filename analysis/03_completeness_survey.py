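"""Benchmark-gene completeness of every simulated assembly.

For each species, measures the fraction of its benchmark protein
complement recoverable from the assembly by translated homology search
and writes one combined coverage table.
"""

import argparse
from pathlib import Path

from censcan.completeness import coverage_fraction, write_coverage_tsv
from censcan.seqcore import read_fasta, transcripts_from_fasta


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--indir", type=Path, default=Path("results/simulated"))
    parser.add_argument("--out", type=Path,
                        default=Path("results/completeness.tsv"))
    args = parser.parse_args()
    args.out.parent.mkdir(parents=True, exist_ok=True)

    reports = []
    for benchmark_fasta in sorted(args.indir.glob("*.benchmark.fasta")):
        species = benchmark_fasta.name.replace(".benchmark.fasta", "")
        benchmark = read_fasta(benchmark_fasta)
        transcripts = transcripts_from_fasta(args.indir / f"{species}.fasta")
        report = coverage_fraction(benchmark, transcripts, mode="fast",
                                   assembly_id=species, benchmark_id="benchmark")
        reports.append(report)
        print(f"{species}: {report.n_recovered}/{report.n_benchmark} "
              f"({report.fraction:.2f})")
    write_coverage_tsv(reports, args.out)


if __name__ == "__main__":
    main()
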