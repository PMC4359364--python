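# censcan

Infer presence or absence of the centromeric histone **CenH3** (and its
kinetochore partner **CenpC**) from transcriptome assemblies.

Most eukaryotes mark their centromeres with a specialized histone H3 variant,
CenH3 (also called CENP-A). Reports that a lineage has *lost* CenH3 are
extraordinary claims resting on negative evidence, and negative evidence from
transcriptome data fails in three mundane ways before it says anything about
biology:

1. **the assembly is incomplete** — the gene is there but was not sequenced
   deeply enough or not assembled;
2. **the search is too strict** — a true CenH3 is present but so divergent
   the homology search or classifier misses it;
3. **the positive is not the host's** — a convincing CenH3 transcript
   belongs to a contaminating organism in the library.

`censcan` is a pipeline that makes absence calls only after controlling for
all three, and reports `inconclusive` when the data cannot support either
verdict.

## Pipeline

| Stage | Module | What it does |
|---|---|---|
| Translated search | `censcan.seqcore` | Six-frame translation, Smith–Waterman (BLOSUM62, affine gaps) with calibrated E-values; exact k-mer prefilter for bulk searches |
| Variant classification | `censcan.classify` | Five-way call (`H3`, `H3.3`, `CenH3`, `H3-like`, `non-histone`) from diagnostic features: extended loop1, non-canonical residues at three diagnostic fold positions, unalignable N-terminal tail |
| Completeness gate | `censcan.completeness` | Fraction of a benchmark protein set recoverable from the assembly, compared against positive-control species |
| Abundance control | `censcan.abundance` | Length-normalized abundance rank percentiles (is the gene class well expressed in comparable libraries?) |
| Contamination attribution | `censcan.phylogeny` | Histone-fold placement against host-type and contaminant-type CenH3 panels (mafft + NJ + bootstrap) |
| Read-level rescue | `censcan.pipeline` | Searches unassembled reads for gene-specific fragments before accepting an absence |
| CenpC architecture | `censcan.motifs` | PSSM scans for the CenpC motif and cupin domain, with a clade test for cupin specificity |
| Synthetic truth | `censcan.synthetic` | Deterministic generator of assemblies with known ground truth, used by every benchmark in this repository |

A call of **present** requires a candidate that passes feature-based
classification *and* is not attributed to a contaminant lineage. A call of
**absent** requires the completeness gate to pass and, when reads are
supplied, no gene-specific read fragments. Everything else is
**inconclusive**.

## Quick start

Simulate a small species and classify its histones:

```
$ censcan simulate --species-id demo --n-genes 20 --seed 7 --outdir demo
$ censcan classify demo/demo.fasta
candidate_id	label	loop1_extension	state@68	state@84	state@118	fold_identity	ntail_identity	notes
CenH3.1|frame+1	CenH3	2	substituted	substituted	substituted	68.0	14.3
H3.1|frame+1	H3	0	canonical	canonical	canonical	100.0	100.0
H3_3.1|frame+1	H3.3	0	canonical	canonical	canonical	95.9	98.4
```

Run a miniature end-to-end survey (first species acts as positive control):

```
$ censcan survey --n-species 4 --seed 3 --outdir demo_survey
           CenH3
species
sp00     present
sp01      absent
sp02     present
sp03      absent
```

As a library:

```python
from censcan.synthetic import SpeciesScenario, generate_assembly
from censcan.pipeline import PipelineConfig, run_survey

assemblies = [
    generate_assembly(SpeciesScenario(species_id=f"sp{i}", seed=i,
                                      cenh3_present=(i != 2)))
    for i in range(4)
]
config = PipelineConfig(positive_control_ids=["sp0"])
result = run_survey(assemblies, config)
print(result.matrix)
#            CenH3
# species
# sp0      present
# sp1      present
# sp2       absent
# sp3      present
```

## Tests

```
python -m pytest -q tests/
```

Unit tests are oracle-based where possible (an independent brute-force
aligner, hand-computed profile scores, sort oracles for percentiles);
`tests/test_acceptance.py` runs the end-to-end properties at reduced scale.

## Data

Everything under `src/censcan/data/` is a synthetic stand-in generated by
`analysis/00_build_reference_panels.py` (filenames carry the `synthetic_`
prefix): reference CenH3 panels for two lineages, seed alignments for the
CenpC motif and cupin profiles, and a non-CenpC cupin panel. No real
biological sequence data is redistributed except the canonical H3 protein
sequence, which is universal.

## Limitations

- The synthetic generator models substitutions, insertions, expression and
  dropout, but not alternative splicing, sequencing error, or assembly
  chimerism; see `docs/methods.md` for the full list of modeling choices.
- Contamination attribution needs reference CenH3 panels bracketing the
  plausible source lineages; with the bundled synthetic panels it
  demonstrates the machinery, and real surveys must supply real panels.
- Verdicts on real data should treat `inconclusive` as exactly that — an
  instruction to sequence deeper, not a soft "absent".
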