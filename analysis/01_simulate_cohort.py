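"""Simulate the synthetic survey cohort.

Writes, per species: the transcript assembly (FASTA), the ground-truth
table, and the benchmark protein complement used by the completeness
survey.  Scenario design: two deeply sequenced positive controls, species
with and without CenH3 across a range of dropout rates, one contaminated
species, and one species with a degraded H3-like paralog.
"""

import argparse
from pathlib import Path

from censcan.seqcore import write_fasta
from censcan.synthetic import (
    SpeciesScenario,
    generate_assembly,
    write_assembly_fasta,
    write_truth_tsv,
)


def cohort_scenarios(seed: int):
    scenarios = [
        SpeciesScenario(species_id="control_a", n_benchmark_genes=60,
                        seed=seed * 100 + 1),
        SpeciesScenario(species_id="control_b", n_benchmark_genes=60,
                        seed=seed * 100 + 2),
        SpeciesScenario(species_id="cenh3_present", n_benchmark_genes=60,
                        seed=seed * 100 + 3),
        SpeciesScenario(species_id="cenh3_present_dropout20",
                        n_benchmark_genes=60, dropout_prob=0.2,
                        seed=seed * 100 + 4),
        SpeciesScenario(species_id="cenh3_absent", n_benchmark_genes=60,
                        cenh3_present=False, seed=seed * 100 + 5),
        SpeciesScenario(species_id="cenh3_absent_dropout20",
                        n_benchmark_genes=60, cenh3_present=False,
                        dropout_prob=0.2, seed=seed * 100 + 6),
        SpeciesScenario(species_id="poor_assembly", n_benchmark_genes=60,
                        cenh3_present=False, dropout_prob=0.85,
                        seed=seed * 100 + 7),
        SpeciesScenario(species_id="contaminated", n_benchmark_genes=60,
                        cenh3_present=False, contaminant_present=True,
                        seed=seed * 100 + 8),
        SpeciesScenario(species_id="degraded_paralog", n_benchmark_genes=60,
                        degraded_h3_present=True, seed=seed * 100 + 9),
    ]
    return scenarios


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", type=Path,
                        default=Path("results/simulated"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    for scenario in cohort_scenarios(args.seed):
        assembly = generate_assembly(scenario)
        base = args.outdir / scenario.species_id
        write_assembly_fasta(assembly, base.with_suffix(".fasta"))
        write_truth_tsv(assembly, base.with_suffix(".truth.tsv"))
        write_fasta(assembly.benchmark_proteins,
                    base.with_suffix(".benchmark.fasta"))
        print(f"{scenario.species_id}: {len(assembly.transcripts)} transcripts")


if __name__ == "__main__":
    main()
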