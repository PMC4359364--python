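"""Transcriptome completeness: benchmark-proteome recovery fractions.

An absence call is only as good as the assembly it is made from.  The control
implemented here asks what fraction of a benchmark protein set can be
recovered from the assembly by translated homology search: assemblies that
recover a fraction comparable to positive-control assemblies are considered
complete enough to support absence calls.

Transcripts are first filtered to a non-redundant set (minimum length,
longest isoform per locus), then each benchmark protein is searched against
the filtered transcripts; a protein counts as recovered when it has at least
one significant hit, with at most one alignment counted per
(protein, transcript) pair.  Raw significant-alignment counts are also
reported alongside the per-protein indicator fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

from .seqcore import (
    KmerIndex,
    TranscriptRecord,
    search_protein_vs_transcripts,
)


@dataclass
class CoverageReport:
    assembly_id: str
    benchmark_id: str
    n_benchmark: int
    n_recovered: int
    n_alignments: int
    n_transcripts: int
    min_len: int
    sig_threshold: float

    @property
    def fraction(self) -> float:
        return self.n_recovered / self.n_benchmark


def filter_transcripts(
    transcripts: Sequence[TranscriptRecord], min_len: int = 250
) -> List[TranscriptRecord]:
    """Drop short transcripts and keep the longest isoform per locus.

    Length ties are broken toward the lexicographically smallest isoform id,
    making the filter deterministic under input reordering.
    """
    best: Dict[str, TranscriptRecord] = {}
    for record in transcripts:
        if record.length < min_len:
            continue
        prev = best.get(record.locus_id)
        if (
            prev is None
            or record.length > prev.length
            or (record.length == prev.length and record.isoform_id < prev.isoform_id)
        ):
            best[record.locus_id] = record
    return [best[k] for k in sorted(best)]


def coverage_fraction(
    benchmark: Dict[str, str],
    transcripts: Sequence[TranscriptRecord],
    sig_threshold: float = 1e-10,
    assembly_id: str = "assembly",
    benchmark_id: str = "benchmark",
    min_len: int = 250,
    mode: str = "fast",
    index: Optional[KmerIndex] = None,
) -> CoverageReport:
    """Fraction of benchmark proteins with >= 1 significant hit.

    ``transcripts`` are assumed pre-filtered if an ``index`` is supplied;
    otherwise :func:`filter_transcripts` is applied first.
    """
    if not benchmark:
        raise ValueError("benchmark protein set is empty")
    if index is None:
        transcripts = filter_transcripts(transcripts, min_len=min_len)
        if mode == "fast":
            index = KmerIndex(transcripts)
    n_recovered = 0
    n_alignments = 0
    for name in benchmark:
        hits = search_protein_vs_transcripts(
            benchmark[name],
            transcripts,
            sig_threshold=sig_threshold,
            query_id=name,
            mode=mode,
            index=index,
        )
        if hits:
            n_recovered += 1
            n_alignments += len(hits)
    return CoverageReport(
        assembly_id=assembly_id,
        benchmark_id=benchmark_id,
        n_benchmark=len(benchmark),
        n_recovered=n_recovered,
        n_alignments=n_alignments,
        n_transcripts=len(transcripts),
        min_len=min_len,
        sig_threshold=sig_threshold,
    )


def write_coverage_tsv(reports: Sequence[CoverageReport], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "species\tn_transcripts\tn_benchmark\tn_significant\t"
            "n_alignments\tfraction\n"
        )
        for r in reports:
            fh.write(
                f"{r.assembly_id}\t{r.n_transcripts}\t{r.n_benchmark}\t"
                f"{r.n_recovered}\t{r.n_alignments}\t{r.fraction:.4f}\n"
            )


__all__ = [
    "CoverageReport",
    "filter_transcripts",
    "coverage_fraction",
    "write_coverage_tsv",
]
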