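"""Length-normalized abundance and rank percentiles per species.

Counts come from the simulation ground truth (one mapped-read count per
transcript).  Writes one abundance table per species and a summary of the
histone transcripts' rank percentiles.
"""

import argparse
import csv
from pathlib import Path

from censcan.abundance import abundance_table, percentile_rank, write_abundance_tsv
from censcan.seqcore import transcripts_from_fasta

HISTONES = ("H3.1", "H3_3.1", "CenH3.1")


def truth_counts(path: Path) -> dict:
    counts = {}
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            if row["emitted"] == "1":
                counts[f"{row['gene_id']}.1"] = int(row["count"])
    return counts


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--indir", type=Path, default=Path("results/simulated"))
    parser.add_argument("--outdir", type=Path, default=Path("results/abundance"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    summary_rows = []
    for truth in sorted(args.indir.glob("*.truth.tsv")):
        species = truth.name.replace(".truth.tsv", "")
        transcripts = transcripts_from_fasta(args.indir / f"{species}.fasta")
        table = abundance_table(transcripts, truth_counts(truth))
        write_abundance_tsv(table, args.outdir / f"{species}.abundance.tsv")
        row = {"species": species}
        for tx in HISTONES:
            try:
                row[tx] = f"{percentile_rank(table, tx):.1f}"
            except KeyError:
                row[tx] = "NA"
        summary_rows.append(row)
        print(f"{species}: " + " ".join(f"{t}={row[t]}" for t in HISTONES))

    with open(args.outdir / "histone_percentiles.tsv", "w") as fh:
        fh.write("species\t" + "\t".join(HISTONES) + "\n")
        for row in summary_rows:
            fh.write(row["species"] + "\t"
                     + "\t".join(row[t] for t in HISTONES) + "\n")


if __name__ == "__main__":
    main()
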