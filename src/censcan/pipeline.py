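"""Integrated per-species presence/absence caller.

The pipeline combines every control into one verdict per gene per species:

``present``
    at least one candidate classified as the gene survives contamination
    attribution (i.e. is not placed in the contaminant clade);
``absent``
    no such candidate, *and* the assembly passes the completeness gate
    (benchmark-proteome recovery comparable to positive-control assemblies),
    *and* either no reads are available or a read-level translated search
    finds no gene-specific read fragments;
``inconclusive``
    anything else — in particular, an incomplete assembly can never support
    an absence call.

The expression-percentile of the gene in positive-control species is
attached as evidence (a well-expressed control gene strengthens an absence
call) but never flips a verdict: real surveys tolerate the occasional
low-percentile control.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import yaml

from . import abundance as abundance_mod
from .classify import (
    ClassifierThresholds,
    HistoneCall,
    classify_assembly,
)
from .completeness import CoverageReport, coverage_fraction, filter_transcripts
from .phylogeny import PlacementVerdict, ReferencePanel, default_panel, place_candidate
from .references import DEFAULT_REFERENCE, H3Reference, default_query_set
from .seqcore import TranscriptRecord, evalue_of, local_score, translate_six_frames
from .synthetic import SyntheticAssembly


class InsufficientReadLengthError(ValueError):
    """Reads are too short for translated search to reach significance."""


@dataclass
class PipelineConfig:
    sig_threshold: float = 1e-10
    read_search_threshold: float = 1e-5
    min_len_coverage: int = 250
    min_len_rank: int = 200
    min_read_length: int = 90
    support_threshold: float = 70.0
    n_bootstrap: int = 100
    completeness_gate_ratio: float = 0.7
    classifier: ClassifierThresholds = field(default_factory=ClassifierThresholds)
    positive_control_ids: List[str] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sig_threshold", "read_search_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        classifier = data.pop("classifier", None)
        config = cls(**data)
        if classifier:
            config.classifier = ClassifierThresholds(**classifier)
        return config


@dataclass
class ReadSearchResult:
    n_reads: int
    n_h3_attributable: int
    n_gene_specific: int
    gene_specific_read_ids: List[str] = field(default_factory=list)


@dataclass
class PresenceCall:
    species_id: str
    gene: str
    status: str  # present | absent | inconclusive
    candidates: List[HistoneCall] = field(default_factory=list)
    contamination: List[PlacementVerdict] = field(default_factory=list)
    coverage: Optional[CoverageReport] = None
    gate_passed: Optional[bool] = None
    control_percentiles: Dict[str, float] = field(default_factory=dict)
    read_search: Optional[ReadSearchResult] = None
    notes: str = ""


# --------------------------------------------------------------------------
# read-level search
# --------------------------------------------------------------------------


def read_level_search(
    reads: Sequence[Tuple[str, str]],
    gene_queries: Dict[str, str],
    background_queries: Dict[str, str],
    threshold: float = 1e-5,
    min_read_length: int = 90,
) -> ReadSearchResult:
    """Translated search of raw reads for gene-specific protein fragments.

    Each read's six frames are scored against the gene-of-interest queries
    (e.g. known CenH3s) and against background homologs (H3/H3.3); a read
    counts as gene-specific only if its best gene-query alignment is
    significant *and* strictly beats its best background score, so conserved
    fold fragments shared with H3 are attributed conservatively to H3.

    Raises :class:`InsufficientReadLengthError` when the read set is too
    short for translated significance — an explicit refusal, not a negative.
    """
    reads = list(reads)
    if not reads:
        return ReadSearchResult(0, 0, 0)
    usable = [(rid, seq) for rid, seq in reads if len(seq) >= min_read_length]
    if not usable:
        raise InsufficientReadLengthError(
            f"all reads shorter than {min_read_length} nt; translated read "
            "search would be blind, refusing to report a negative"
        )
    db_len = sum(len(seq) for _, seq in usable)
    n_h3 = 0
    specific_ids: List[str] = []
    for rid, seq in usable:
        frames = translate_six_frames(seq)
        best_gene, best_gene_len = 0.0, 1
        best_bg = 0.0
        for frame_protein in frames.values():
            if not frame_protein:
                continue
            for q in gene_queries.values():
                s = local_score(q, frame_protein)
                if s > best_gene:
                    best_gene, best_gene_len = s, len(q)
            for q in background_queries.values():
                best_bg = max(best_bg, local_score(q, frame_protein))
        gene_sig = (
            best_gene > 0
            and evalue_of(best_gene, best_gene_len, db_len) < threshold
        )
        if gene_sig and best_gene > best_bg:
            specific_ids.append(rid)
        elif best_bg > 0 and evalue_of(best_bg, 135, db_len) < threshold:
            n_h3 += 1
    return ReadSearchResult(
        n_reads=len(usable),
        n_h3_attributable=n_h3,
        n_gene_specific=len(specific_ids),
        gene_specific_read_ids=specific_ids,
    )


# --------------------------------------------------------------------------
# per-species presence call
# --------------------------------------------------------------------------


def call_presence(
    species_id: str,
    transcripts: Sequence[TranscriptRecord],
    gene: str = "CenH3",
    config: Optional[PipelineConfig] = None,
    reference: H3Reference = DEFAULT_REFERENCE,
    panel: Optional[ReferencePanel] = None,
    coverage: Optional[CoverageReport] = None,
    control_fractions: Optional[Sequence[float]] = None,
    control_percentiles: Optional[Dict[str, float]] = None,
    reads: Optional[Sequence[Tuple[str, str]]] = None,
) -> PresenceCall:
    """Integrate classification, contamination, completeness and read search.

    ``coverage`` and ``control_fractions`` are normally precomputed by
    :func:`run_survey`; without control fractions the completeness gate
    cannot run and a no-candidate species is forced inconclusive.
    """
    config = config or PipelineConfig()
    if panel is None:
        panel = default_panel()
    notes: List[str] = []

    pairs = classify_assembly(
        transcripts,
        reference,
        config.classifier,
        queries=default_query_set(),
        sig_threshold=config.sig_threshold,
    )
    calls = [call for _, call in pairs]
    gene_pairs = [(c, call) for c, call in pairs if call.label == gene]

    # Candidates sent to phylogenetic attribution: everything classified as
    # the gene, plus H3-like candidates whose best homology is to a known
    # CenH3 rather than to H3/H3.3 — heavily diverged contaminants can fail
    # the feature-based classification yet still demand attribution.
    cenh3_query_names = set(panel.host_refs) | set(panel.contaminant_refs)
    placement_pairs = list(gene_pairs)
    if gene == "CenH3":
        for cand, call in pairs:
            if (
                call.label == "H3-like"
                and cand.best_hit is not None
                and cand.best_hit.query_id in cenh3_query_names
            ):
                placement_pairs.append((cand, call))

    verdicts: List[PlacementVerdict] = []
    survivors = []
    contaminant_ids = set()
    if gene == "CenH3":
        for cand, call in placement_pairs:
            verdict = place_candidate(
                cand.protein,
                call.candidate_id,
                panel=panel,
                reference=reference,
                n_bootstrap=config.n_bootstrap,
                seed=config.seed,
                support_threshold=config.support_threshold,
            )
            verdicts.append(verdict)
            if verdict.verdict == "contaminant":
                contaminant_ids.add(call.candidate_id)
        survivors = [
            (c, call)
            for c, call in gene_pairs
            if call.candidate_id not in contaminant_ids
        ]
    else:
        survivors = list(gene_pairs)

    if survivors:
        status = "present"
        gate_passed = None
    else:
        if contaminant_ids:
            notes.append(
                "CenH3-like candidates attributed to contamination: "
                + ", ".join(sorted(contaminant_ids))
            )
        if control_fractions:
            if coverage is None:
                raise ValueError("completeness gate needs a coverage report")
            gate_passed = coverage.fraction >= (
                config.completeness_gate_ratio * min(control_fractions)
            )
        else:
            gate_passed = None
            notes.append("no positive controls: completeness gate cannot run")

        read_ok = True
        read_result = None
        if reads is not None:
            try:
                gene_queries = {
                    k: v
                    for k, v in default_query_set().items()
                    if k not in ("H3_canonical", "H3.3")
                }
                background = {
                    k: v
                    for k, v in default_query_set().items()
                    if k in ("H3_canonical", "H3.3")
                }
                read_result = read_level_search(
                    reads,
                    gene_queries,
                    background,
                    threshold=config.read_search_threshold,
                    min_read_length=config.min_read_length,
                )
                read_ok = read_result.n_gene_specific == 0
            except InsufficientReadLengthError as err:
                notes.append(str(err))
                read_result = None

        if gate_passed and read_ok:
            status = "absent"
        else:
            status = "inconclusive"
            if gate_passed is False:
                notes.append("completeness gate failed")
            elif not read_ok:
                notes.append("gene-specific read fragments found")

    call = PresenceCall(
        species_id=species_id,
        gene=gene,
        status=status,
        candidates=calls,
        contamination=verdicts,
        coverage=coverage,
        gate_passed=gate_passed if not survivors else None,
        control_percentiles=dict(control_percentiles or {}),
        notes="; ".join(notes),
    )
    if not survivors and reads is not None:
        call.read_search = read_result
    return call


# --------------------------------------------------------------------------
# survey over many species
# --------------------------------------------------------------------------


@dataclass
class SurveyResult:
    calls: Dict[str, PresenceCall]
    matrix: pd.DataFrame
    coverage: Dict[str, CoverageReport]
    control_percentiles: Dict[str, float]

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.matrix.to_csv(outdir / "presence_matrix.tsv", sep="\t")
        from .completeness import write_coverage_tsv

        write_coverage_tsv(list(self.coverage.values()), outdir / "coverage.tsv")
        with open(outdir / "calls.tsv", "w") as fh:
            fh.write("species\tgene\tstatus\tgate_passed\tnotes\n")
            for sid in sorted(self.calls):
                c = self.calls[sid]
                fh.write(
                    f"{sid}\t{c.gene}\t{c.status}\t{c.gate_passed}\t{c.notes}\n"
                )


def _cenh3_percentile(assembly: SyntheticAssembly, min_rank_len: int) -> Optional[float]:
    table = abundance_mod.abundance_table(
        assembly.transcripts, assembly.counts, min_rank_len=min_rank_len
    )
    tid = "CenH3.1"
    if tid in table.index:
        return abundance_mod.percentile_rank(table, tid)
    return None


def run_survey(
    assemblies: Sequence[SyntheticAssembly],
    config: Optional[PipelineConfig] = None,
    gene: str = "CenH3",
    reference: H3Reference = DEFAULT_REFERENCE,
    panel: Optional[ReferencePanel] = None,
    benchmark: Optional[Dict[str, str]] = None,
    reads_by_species: Optional[Dict[str, Sequence[Tuple[str, str]]]] = None,
) -> SurveyResult:
    """Presence/absence matrix over many species with all controls attached.

    Completeness uses ``benchmark`` when given, otherwise each synthetic
    assembly's own benchmark complement (whose recovery directly measures
    that assembly's dropout).  Positive-control species are named in
    ``config.positive_control_ids``.
    """
    config = config or PipelineConfig()
    if panel is None:
        panel = default_panel()

    coverage: Dict[str, CoverageReport] = {}
    for assembly in assemblies:
        bench = benchmark if benchmark is not None else assembly.benchmark_proteins
        filtered = filter_transcripts(
            assembly.transcripts, min_len=config.min_len_coverage
        )
        coverage[assembly.species_id] = coverage_fraction(
            bench,
            filtered,
            sig_threshold=config.sig_threshold,
            assembly_id=assembly.species_id,
            min_len=config.min_len_coverage,
            mode="fast",
        )

    control_fractions = [
        coverage[sid].fraction
        for sid in config.positive_control_ids
        if sid in coverage
    ]
    control_percentiles: Dict[str, float] = {}
    by_id = {a.species_id: a for a in assemblies}
    for sid in config.positive_control_ids:
        if sid in by_id:
            pct = _cenh3_percentile(by_id[sid], config.min_len_rank)
            if pct is not None:
                control_percentiles[sid] = pct

    calls: Dict[str, PresenceCall] = {}
    for assembly in assemblies:
        reads = None
        if reads_by_species is not None:
            reads = reads_by_species.get(assembly.species_id)
        calls[assembly.species_id] = call_presence(
            assembly.species_id,
            assembly.transcripts,
            gene=gene,
            config=config,
            reference=reference,
            panel=panel,
            coverage=coverage[assembly.species_id],
            control_fractions=control_fractions,
            control_percentiles=control_percentiles,
            reads=reads,
        )

    matrix = pd.DataFrame(
        {gene: {sid: calls[sid].status for sid in sorted(calls)}}
    )
    matrix.index.name = "species"
    return SurveyResult(
        calls=calls,
        matrix=matrix,
        coverage=coverage,
        control_percentiles=control_percentiles,
    )


__all__ = [
    "InsufficientReadLengthError",
    "PipelineConfig",
    "ReadSearchResult",
    "PresenceCall",
    "read_level_search",
    "call_presence",
    "SurveyResult",
    "run_survey",
]
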