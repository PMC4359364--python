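"""Synthetic species generator with ground truth.

Every downstream stage is exercised against assemblies generated here, where
the truth (which genes were emitted, what each histone variant is, which
transcript is a contaminant) is known by construction:

* a *benchmark complement* of random proteins back-translated with uniform
  codon choice — completeness statistics depend only on detectability, not on
  biological realism;
* a histone repertoire: canonical H3 and H3.3 (always expressed), optionally
  a CenH3 built by the documented construction (randomized N-terminal tail,
  loop1 insertion, substitution of the three diagnostic residues, mild extra
  fold divergence), optionally an H3-like degraded variant (fold heavily
  eroded, no CenH3 features — the pattern of pseudo-H3 genes that confound
  naive searches);
* optionally a contaminant CenH3 derived from a bundled fungal-style donor by
  i.i.d. substitutions at a given substitutions-per-site divergence —
  emulating cross-kingdom contamination of mRNA-Seq libraries;
* log-normal expression levels, with per-gene dropout biased against
  low-expression genes while averaging exactly ``dropout_prob``.

All output is byte-deterministic given the scenario (including its seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .references import H3_3, DEFAULT_REFERENCE, H3Reference
from .seqcore import TranscriptRecord

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

# residue -> list of codons, standard code
_CODONS: Dict[str, List[str]] = {}
for codon, aa in standard_dna_table.forward_table.items():
    _CODONS.setdefault(aa, []).append(codon)
for aa in _CODONS:
    _CODONS[aa].sort()


def random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def back_translate(protein: str, rng: np.random.Generator) -> str:
    """Nucleotide CDS with uniform codon choice per residue."""
    return "".join(
        _CODONS[aa][rng.integers(len(_CODONS[aa]))] for aa in protein
    )


def _substitute(residue: str, rng: np.random.Generator) -> str:
    choices = [a for a in AMINO_ACIDS if a != residue]
    return choices[rng.integers(len(choices))]


def divergent_copy(protein: str, rate: float, rng: np.random.Generator) -> str:
    """Apply i.i.d. substitutions at ``rate`` expected substitutions per site.

    The per-site probability of observing a changed residue follows the
    one-parameter Poisson substitution model on a 20-letter alphabet:
    ``p = (19/20) * (1 - exp(-20*rate/19))``.
    """
    if rate < 0:
        raise ValueError("divergence rate must be >= 0")
    p_diff = (19.0 / 20.0) * (1.0 - np.exp(-20.0 * rate / 19.0))
    out = list(protein)
    for i, aa in enumerate(out):
        if rng.random() < p_diff:
            out[i] = _substitute(aa, rng)
    return "".join(out)


# --------------------------------------------------------------------------
# histone constructions
# --------------------------------------------------------------------------

# Fixed seeds of the two ancestral CenH3 fold backbones.  All host-lineage
# CenH3s (reference panel and per-species generated ones) share derived fold
# substitutions from the "animal" backbone, and contaminant-lineage CenH3s
# share the much more diverged "fungal-style" backbone — real CenH3 folds are
# homologous within kingdoms, and that shared history is exactly the signal
# phylogenetic contamination attribution reads.
_HOST_BACKBONE_SEED = 20140915
_FUNGAL_BACKBONE_SEED = 19960117

# Every seeded generator function draws from its own stream domain
# (``default_rng([domain, seed])``).  Without this, two different functions
# called with the same integer seed replay identical random draws, so e.g.
# a fixture built with seed N would share literal subsequences with an
# unrelated species generated with scenario seed N.
_STREAM_BACKBONE = 1
_STREAM_CENH3 = 2
_STREAM_DEGRADED = 3
_STREAM_ASSEMBLY = 4
_STREAM_READS = 5


def _diverged_backbone(
    rate: float, seed: int, reference: H3Reference
) -> str:
    """Canonical H3 with fold-only divergence; diagnostic sites untouched."""
    rng = np.random.default_rng([_STREAM_BACKBONE, seed])
    p_diff = (19.0 / 20.0) * (1.0 - np.exp(-20.0 * rate / 19.0))
    out = list(reference.sequence)
    for p in range(reference.fold_start, reference.fold_end + 1):
        if p in reference.diagnostic_positions:
            continue
        if rng.random() < p_diff:
            out[p - 1] = _substitute(out[p - 1], rng)
    return "".join(out)


def host_cenh3_backbone(reference: H3Reference = DEFAULT_REFERENCE) -> str:
    """Shared animal-CenH3-style fold backbone (moderate divergence from H3)."""
    return _diverged_backbone(0.20, _HOST_BACKBONE_SEED, reference)


def fungal_cenh3_backbone(reference: H3Reference = DEFAULT_REFERENCE) -> str:
    """Shared fungal-style fold backbone (deep divergence from H3)."""
    return _diverged_backbone(0.40, _FUNGAL_BACKBONE_SEED, reference)


def make_cenh3_like(
    h3: str,
    n_loop1_insert: int,
    seed: int,
    reference: H3Reference = DEFAULT_REFERENCE,
    extra_fold_sub_rate: float = 0.1,
) -> str:
    """Build a CenH3-style variant from an H3 backbone.

    The construction realizes the diagnostic architecture of centromeric H3
    variants: a randomized N-terminal tail (the tail of true CenH3s is so
    divergent it is not even alignable), ``n_loop1_insert`` residues inserted
    inside the loop1 window, non-canonical residues at the three diagnostic
    fold positions, and mild extra divergence elsewhere in the fold (capped
    so identity to the backbone outside the edited sites stays >= 70%).

    ``h3`` must have the reference's length/coordinates (canonical H3 or a
    same-length diverged backbone such as the bundled contaminant donor).
    """
    if n_loop1_insert < 1:
        raise ValueError("n_loop1_insert must be >= 1")
    if len(h3) != len(reference.sequence):
        raise ValueError("backbone must match reference coordinates")
    rng = np.random.default_rng([_STREAM_CENH3, seed])
    out = list(h3)

    # randomized N-terminal tail
    for i in range(reference.ntail_end):
        out[i] = AMINO_ACIDS[rng.integers(20)]

    # non-canonical residues at the diagnostic positions
    for pos, canonical in reference.diagnostic_positions.items():
        out[pos - 1] = _substitute(canonical, rng)

    # mild extra fold divergence, capped to keep >=70% identity off the edits
    fold_positions = [
        p
        for p in range(reference.fold_start, reference.fold_end + 1)
        if p not in reference.diagnostic_positions
    ]
    flagged = [p for p in fold_positions if rng.random() < extra_fold_sub_rate]
    cap = int(0.3 * len(fold_positions))
    for p in flagged[:cap]:
        out[p - 1] = _substitute(out[p - 1], rng)

    # loop1 insertion at the middle of the window
    lo, hi = reference.loop1_window
    insert_after = (lo + hi) // 2
    insert = "".join(AMINO_ACIDS[rng.integers(20)] for _ in range(n_loop1_insert))
    return "".join(out[:insert_after]) + insert + "".join(out[insert_after:])


def make_degraded_h3_like(
    seed: int,
    reference: H3Reference = DEFAULT_REFERENCE,
    fold_sub_rate: float = 0.35,
) -> str:
    """An H3-derived variant whose fold has eroded without CenH3 features.

    Many canonical fold residues are substituted, but the loop1 region is not
    extended and the diagnostic residues stay canonical — the signature of a
    divergent H3 paralog rather than a centromeric variant.
    """
    rng = np.random.default_rng([_STREAM_DEGRADED, seed])
    out = list(reference.sequence)
    protected = set(reference.diagnostic_positions) | set(reference.h3_3_positions)
    for p in range(reference.fold_start, reference.fold_end + 1):
        if p in protected:
            continue
        if rng.random() < fold_sub_rate:
            out[p - 1] = _substitute(out[p - 1], rng)
    return "".join(out)


# --------------------------------------------------------------------------
# scenario and assembly
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SpeciesScenario:
    """Parameters of one synthetic species."""

    species_id: str
    n_benchmark_genes: int = 100
    dropout_prob: float = 0.0
    cenh3_present: bool = True
    contaminant_present: bool = False
    contaminant_divergence: float = 0.5
    degraded_h3_present: bool = False
    expression_logmean: float = 3.0
    expression_logsd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ValueError("dropout_prob must be in [0, 1]")
        if self.n_benchmark_genes < 1:
            raise ValueError("n_benchmark_genes must be >= 1")
        if self.contaminant_divergence < 0:
            raise ValueError("contaminant_divergence must be >= 0")
        if self.expression_logsd < 0:
            raise ValueError("expression_logsd must be >= 0")


@dataclass
class TruthEntry:
    emitted: bool
    label: str  # benchmark | H3 | H3.3 | CenH3 | H3-like
    contaminant: bool = False
    count: int = 0


@dataclass
class SyntheticAssembly:
    species_id: str
    scenario: SpeciesScenario
    transcripts: List[TranscriptRecord]
    proteins: Dict[str, str]  # gene_id -> true protein (emitted or not)
    truth: Dict[str, TruthEntry]  # gene_id -> truth
    counts: Dict[str, int]  # transcript_id -> read count

    @property
    def benchmark_proteins(self) -> Dict[str, str]:
        return {
            g: p
            for g, p in self.proteins.items()
            if self.truth[g].label == "benchmark"
        }


def _dropout_probs(
    abundances: np.ndarray, dropout_prob: float
) -> np.ndarray:
    """Per-gene dropout averaging ``dropout_prob``, higher at low expression."""
    n = len(abundances)
    order = np.argsort(np.argsort(abundances))  # ascending ranks, 0-based
    frac = (order + 0.5) / n
    coupling = min(dropout_prob, 1.0 - dropout_prob)
    return dropout_prob + coupling * (0.5 - frac) * 2.0 * 0.8


def generate_assembly(
    scenario: SpeciesScenario,
    reference: H3Reference = DEFAULT_REFERENCE,
) -> SyntheticAssembly:
    """Generate one species: transcripts, truth table and expression counts."""
    rng = np.random.default_rng([_STREAM_ASSEMBLY, scenario.seed])
    proteins: Dict[str, str] = {}
    truth: Dict[str, TruthEntry] = {}
    transcripts: List[TranscriptRecord] = []
    counts: Dict[str, int] = {}

    # benchmark complement
    gene_ids = [f"gene{i + 1:04d}" for i in range(scenario.n_benchmark_genes)]
    lengths = rng.integers(100, 601, size=scenario.n_benchmark_genes)
    for gid, length in zip(gene_ids, lengths):
        proteins[gid] = random_protein(int(length), rng)

    abundances = rng.lognormal(
        scenario.expression_logmean,
        scenario.expression_logsd,
        size=scenario.n_benchmark_genes,
    )
    drop_p = _dropout_probs(abundances, scenario.dropout_prob)
    emitted_mask = rng.random(scenario.n_benchmark_genes) >= drop_p

    def _emit(gid: str, protein: str, label: str, abundance: float,
              contaminant: bool = False) -> None:
        cds = back_translate(protein, rng)
        tid = f"{gid}.1"
        transcripts.append(TranscriptRecord(id=tid, seq=cds))
        count = int(rng.poisson(abundance))
        counts[tid] = count
        truth[gid] = TruthEntry(
            emitted=True, label=label, contaminant=contaminant, count=count
        )

    for gid, abundance, emitted in zip(gene_ids, abundances, emitted_mask):
        if emitted:
            _emit(gid, proteins[gid], "benchmark", abundance)
        else:
            truth[gid] = TruthEntry(emitted=False, label="benchmark")

    # histone repertoire: H3 and H3.3 always expressed
    histone_abundance = float(
        rng.lognormal(scenario.expression_logmean + 1.0, scenario.expression_logsd)
    )
    proteins["H3"] = reference.sequence
    _emit("H3", reference.sequence, "H3", histone_abundance)
    proteins["H3_3"] = H3_3
    _emit("H3_3", H3_3, "H3.3", histone_abundance)

    cenh3_seed = int(rng.integers(2**31 - 1))
    n_insert = int(rng.integers(2, 5))
    cenh3 = make_cenh3_like(
        host_cenh3_backbone(reference), n_insert, cenh3_seed, reference
    )
    cenh3_abundance = float(
        rng.lognormal(scenario.expression_logmean, scenario.expression_logsd)
    )
    cenh3_survives = rng.random() >= scenario.dropout_prob
    proteins["CenH3"] = cenh3
    if scenario.cenh3_present and cenh3_survives:
        _emit("CenH3", cenh3, "CenH3", cenh3_abundance)
    else:
        truth["CenH3"] = TruthEntry(emitted=False, label="CenH3")

    if scenario.degraded_h3_present:
        degraded = make_degraded_h3_like(int(rng.integers(2**31 - 1)), reference)
        proteins["H3like"] = degraded
        _emit("H3like", degraded, "H3-like", histone_abundance / 4.0)

    if scenario.contaminant_present:
        from .references import contaminant_donor

        _, donor = contaminant_donor()
        contaminant = divergent_copy(donor, scenario.contaminant_divergence, rng)
        proteins["CenH3_contaminant"] = contaminant
        _emit(
            "CenH3_contaminant",
            contaminant,
            "CenH3",
            cenh3_abundance / 2.0,
            contaminant=True,
        )

    return SyntheticAssembly(
        species_id=scenario.species_id,
        scenario=scenario,
        transcripts=transcripts,
        proteins=proteins,
        truth=truth,
        counts=counts,
    )


def shred_reads(
    assembly: SyntheticAssembly,
    read_length: int = 100,
    seed: int = 0,
    max_reads_per_transcript: Optional[int] = None,
) -> List[Tuple[str, str]]:
    """Fixed-length forward-strand reads, one per truth count by default."""
    rng = np.random.default_rng([_STREAM_READS, seed])
    reads: List[Tuple[str, str]] = []
    for record in assembly.transcripts:
        if record.length < read_length:
            continue
        n = assembly.counts.get(record.id, 0)
        if max_reads_per_transcript is not None:
            n = min(n, max_reads_per_transcript)
        starts = rng.integers(0, record.length - read_length + 1, size=n)
        for k, start in enumerate(starts):
            reads.append(
                (f"{record.id}_read{k}", record.seq[start : start + read_length])
            )
    return reads


# --------------------------------------------------------------------------
# output
# --------------------------------------------------------------------------


def write_truth_tsv(assembly: SyntheticAssembly, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\temitted\tclass\tcontaminant\tcount\n")
        for gid in assembly.truth:
            t = assembly.truth[gid]
            fh.write(
                f"{gid}\t{int(t.emitted)}\t{t.label}\t{int(t.contaminant)}\t{t.count}\n"
            )


def write_assembly_fasta(assembly: SyntheticAssembly, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for record in assembly.transcripts:
            fh.write(f">{record.id}\n")
            for i in range(0, record.length, width):
                fh.write(record.seq[i : i + width] + "\n")


__all__ = [
    "AMINO_ACIDS",
    "random_protein",
    "back_translate",
    "divergent_copy",
    "make_cenh3_like",
    "make_degraded_h3_like",
    "SpeciesScenario",
    "TruthEntry",
    "SyntheticAssembly",
    "generate_assembly",
    "shred_reads",
    "write_truth_tsv",
    "write_assembly_fasta",
]
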