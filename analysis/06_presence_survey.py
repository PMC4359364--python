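"""End-to-end presence/absence survey over the simulated cohort.

Re-generates the cohort scenarios deterministically, runs the full
pipeline (classification, completeness gate, contamination attribution)
and writes the presence matrix plus per-species call details.
"""

import argparse
import importlib.util
from pathlib import Path

from censcan.pipeline import PipelineConfig, run_survey
from censcan.synthetic import generate_assembly

_spec = importlib.util.spec_from_file_location(
    "simulate_cohort", Path(__file__).parent / "01_simulate_cohort.py"
)
_sim = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_sim)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", type=Path, default=Path("results/survey"))
    args = parser.parse_args()

    assemblies = [
        generate_assembly(s) for s in _sim.cohort_scenarios(args.seed)
    ]
    config = PipelineConfig(
        positive_control_ids=["control_a", "control_b"], seed=args.seed
    )
    result = run_survey(assemblies, config)
    result.write(args.outdir)
    print(result.matrix.to_string())
    for species in sorted(result.calls):
        call = result.calls[species]
        if call.notes:
            print(f"{species}: {call.notes}")


if __name__ == "__main__":
    main()
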