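# Methods

This document describes the model behind each pipeline stage, the default
parameters and the reasons for them, and the known limits of the synthetic
data generator. Module names refer to `src/censcan/`.

## 1. Problem statement and decision logic

Given a transcriptome assembly (and optionally unassembled reads), decide
whether the host organism expresses CenH3, the centromeric histone H3
variant. The output is one of:

- **present** — at least one transcript encodes a protein that passes the
  feature-based CenH3 classification *and* is not attributed by
  phylogenetic placement to a contaminant lineage;
- **absent** — no such transcript exists, the assembly passes the
  completeness gate relative to positive-control species, and (when reads
  are provided) no gene-specific read fragments are found;
- **inconclusive** — anything else, in particular any assembly that fails
  the completeness gate.

The asymmetry is deliberate: a single validated positive establishes
presence, while absence is accepted only after assembly quality,
search sensitivity, and contamination have each been controlled.

## 2. Sequence core (`seqcore`)

- **Translation.** All six reading frames via Biopython's standard codon
  table; ambiguous codons translate to `X`.
- **Alignment.** Smith–Waterman with BLOSUM62 and affine gaps: gap open 11,
  gap extend 1 (the first gap residue costs 12). Scores against `X` are
  zeroed so low-quality translations neither help nor hurt. A
  numba-compiled kernel computes scores; it is verified in the tests
  against `Bio.Align.PairwiseAligner` and against an independent
  pure-Python Gotoh implementation, including exhaustive agreement on all
  short sequence pairs.
- **E-values.** Karlin–Altschul form `E = K·m·n·exp(−λS)` with parameters
  `K = 0.13919`, `λ = 0.32035`, calibrated once by maximum-likelihood fit
  of the Gumbel tail on scores of random protein pairs under exactly this
  scoring system, then frozen. Tests assert that searches of pure-noise
  assemblies produce approximately the expected number of `E < 1` hits.
- **Search modes.** `sensitive` aligns the query against every frame;
  `fast` first requires a shared exact 5-mer (a k-mer index over the
  translated frames) before aligning. The two modes are asserted to agree
  on every benchmark used here; `fast` exists only to keep large surveys
  inside practical runtimes.
- **Significance thresholds.** `1e-10` for assembly searches (full-length
  transcripts, long alignments, essentially no false positives tolerated)
  and `1e-5` for read searches (short translated fragments cannot reach
  extreme significance; the threshold still keeps the per-library false
  discovery count well below one in the null tests).

## 3. Histone variant classification (`classify`)

A candidate protein is globally aligned (Needleman–Wunsch, same scoring)
to the canonical 135-residue H3. Features, all in mature-H3 numbering:

- **loop1 extension** — net insertion inside the loop1 window
  (columns 80–88). Because global alignment localizes an insertion only to
  within a few columns, the gap flank may fall up to `loop1_slack = 6`
  columns outside the window and still count. The slack cannot create
  false positives among the negatives used here: canonical H3, H3.3 and
  the degraded paralog are all insertion-free and align gaplessly.
- **diagnostic positions** — residues at 68 (Q in H3), 84 (F), 118 (T).
  Each is reported as `canonical`, `substituted`, or `unaligned`.
- **N-tail divergence** — percent identity of the region preceding the
  histone fold (fold spans 63–135); CenH3 tails are effectively
  unalignable (< 50 % identity).
- **H3.3 signature** — positions 31 S, 87 A, 89 I, 90 G.

Label logic: full-length, near-identical fold → `H3` or `H3.3` (by the
signature); loop1 insertion **and** ≥ 2 substituted diagnostics **and**
divergent N-tail → `CenH3`; alignable fold that fits none of these →
`H3-like`; no significant fold alignment → `non-histone`. An in-frame
stop before the fold end marks the call `putatively nonfunctional`.
Requiring two of the three diagnostics (plus the loop and the tail) keeps
single-site drift in ordinary H3 paralogs from producing CenH3 calls; the
truth-table benchmark in `scripts/acceptance.py` measures both recall and
H3/CenH3 confusion under this rule.

## 4. Completeness gate (`completeness`)

Recovery fraction of a benchmark protein set: a benchmark protein counts
as recovered if any transcript ≥ 250 nt (inclusive) has a translated hit
at `E < 1e-10`. Per transcript, only the longest isoform per gene is kept
(ties broken lexicographically by identifier). A test assembly passes the
gate if its fraction is at least `0.7 ×` the *minimum* fraction across the
positive-control species. Using the minimum control rather than the mean
makes the gate a floor — "at least as complete as the worst assembly in
which the gene family is reliably found, up to a 30 % margin". Failing the
gate forces `inconclusive` regardless of the search outcome.

## 5. Abundance ranking (`abundance`)

Counts are length-normalized (counts per kilobase; RPKM when a library
size is supplied) over transcripts ≥ 200 nt, and converted to rank
percentiles `100 · mean-rank / N` (mean rank over ties, via
`scipy.stats.rankdata`). The percentile of H3/H3.3/CenH3 in control
libraries indicates how highly expressed the class is where it is known
to exist, which calibrates how surprising a dropout-driven absence would
be. Percentile computation is tested against independent sort oracles and
is invariant under monotone rescaling of counts.

## 6. Contamination attribution (`phylogeny`)

- Candidates and panel references are trimmed to the histone fold, aligned
  with `mafft --auto`, distances corrected with the Poisson model
  `d = −ln(1 − p)`, trees built by neighbor-joining (scikit-bio), with
  nonparametric bootstrap over alignment columns (default 100 replicates).
- **Placement verdict.** The lineage is fixed by the smallest informative
  clade containing the candidate and only references of one panel
  (host-type or contaminant-type, no outgroup). The reported support is
  the *maximum* bootstrap support over the chain of enclosing clades that
  remain pure for that lineage — support for *membership* in the lineage,
  not for the exact attachment point, which is the question the pipeline
  actually asks. Support below `70` yields `unresolved`.
- A `present`-eligible candidate placed with the contaminant panel is
  removed from the host's evidence and recorded in the call's
  contamination notes; a species whose only CenH3 signal is contaminant
  can therefore still be called `absent`. Candidates classified `H3-like`
  whose best assembly hit was a CenH3 panel query are also routed to
  placement, so contamination evidence is collected even when the
  contaminant's features are too diverged for a confident CenH3 label.

## 7. Read-level rescue (`pipeline.read_level_search`)

Before an absence is accepted for a read-backed library, reads are
searched (six-frame, `E < 1e-5`) with the host and contaminant CenH3
panels as queries and H3/H3.3 as competing background; a read supports
CenH3 only if its best hit is a CenH3 query. Reads shorter than 90 nt
raise `InsufficientReadLengthError` rather than silently returning a
negative, because a 30-residue translated fragment cannot reach the
significance threshold.

## 8. CenpC architecture (`motifs`)

Log-odds position-specific scoring matrices are built from the bundled
seed alignments for the CenpC motif and the cupin domain (pseudocount
0.5, background = seed composition). A scan reports the best-scoring
window and a permutation p-value from shuffled copies of the target, with
the standard floor `(exceed + 1)/(n_null + 1)`; the architecture
threshold `p ≤ 1e-3` therefore requires `n_null ≥ 999`. A protein is
called CenpC-architecture when both profiles hit at `p ≤ 1e-3` in the
motif→cupin order **and** the cupin window places inside the CenpC-type
cupin clade (same placement machinery as §6) — cupins are a large
superfamily, so a cupin hit alone is not evidence of CenpC.

## 9. Synthetic data generator (`synthetic`)

All benchmarks rest on assemblies with known ground truth.

- **Divergence model.** `divergent_copy(seq, r)` applies Poisson(r)
  substitutions per site under a 20-letter Jukes–Cantor-style model; the
  expected observed difference is `p = (19/20)(1 − exp(−20r/19))`, which
  the tests verify within binomial error.
- **CenH3 construction.** Start from a lineage backbone (host backbone at
  0.20 from canonical H3, fold only, diagnostic sites held fixed; the
  contaminant-lineage backbone at 0.40), insert 1–4 residues at the loop1
  midpoint, substitute the three diagnostics, replace the N-tail with a
  random tail. A **degraded paralog** keeps canonical diagnostics but
  erodes the fold below 90 % identity — a hard negative for the
  classifier.
- **Assemblies.** Benchmark genes, the three histones, optional
  contaminant CenH3, log-normal expression, Bernoulli dropout with
  probability increasing for low-expression transcripts, back-translation
  to nucleotide with random codon choice, random strand. `shred_reads`
  cuts emitted transcripts into fixed-length substrings.
- **Determinism and stream separation.** Every generator draws from
  `numpy.random.default_rng([domain, seed])` where `domain` is a constant
  unique to that generator. Without the domain, two different generators
  given the same integer seed replay the same PCG64 stream and can emit
  correlated — in one observed case verbatim-identical — sequence
  fragments across supposedly independent datasets.
- **Known simplifications.** No alternative splicing or UTR structure, no
  sequencing error or assembly chimerism, site-independent substitutions
  with uniform amino-acid replacement, a single contaminant source per
  library. These make the benchmarks cleaner than real data; the
  completeness gate and read-rescue thresholds should be re-examined on
  real libraries before biological conclusions are drawn.

## 10. Default parameters (summary)

| Parameter | Default | Rationale |
|---|---|---|
| Assembly search E-value | 1e-10 | long alignments; near-zero false positives |
| Read search E-value | 1e-5 | short fragments cannot reach 1e-10; null tests stay clean |
| Coverage min transcript length | 250 nt (inclusive) | shorter contigs rarely yield significant protein hits |
| Rank min transcript length | 200 nt | stabilizes length normalization |
| Min read length | 90 nt | 30 aa is the floor for significant fragments |
| Completeness gate ratio | 0.7 × min(control) | floor relative to worst reliable control |
| Bootstrap support threshold | 70 | conventional NJ bootstrap cut-off |
| Bootstrap replicates | 100 | support resolution of 1 %; runtime-bounded |
| loop1 slack | 6 columns | alignment localization error of an insertion |
| Diagnostics required for CenH3 | 2 of 3 | tolerates single-site noise, blocks paralog drift |
| Gap open / extend | 11 / 1 | BLOSUM62 standard |
| E-value K, λ | 0.13919, 0.32035 | one-time Gumbel fit under this exact scoring, then frozen |
| Motif/cupin p-value | ≤ 1e-3, n_null = 999 | permutation floor 1/(n_null+1) must reach the threshold |

## 11. Verification strategy

Unit tests prefer independent oracles over re-computation: a pure-Python
Gotoh aligner (exhaustive on short pairs), Biopython's aligner at realistic
lengths, sort-based percentile oracles, binomial-interval checks on the
divergence model and dropout, and null-model hit-count checks for the
E-value calibration. End-to-end properties — classifier truth table,
survey accuracy with zero false absents, contamination recall, CenpC
architecture accuracy — run at reduced scale in
`tests/test_acceptance.py` and at full scale in `scripts/acceptance.py`,
which writes a machine-readable JSON report.
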