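"""Diagnostic-feature classification of H3-family variants.

A candidate protein is interpreted through a global alignment to canonical
H3 and classified into one of five labels:

``CenH3``
    extended loop1 (>= 1 inserted residue in the loop1 window), at least two
    of the three diagnostic fold residues (Gln/Phe/Thr) substituted, and a
    non-homologous N-terminal tail (identity < 50%).
``H3`` / ``H3.3``
    near-identical fold (>= 90% identity), no loop1 extension, all diagnostic
    residues canonical; H3.3 additionally carries the variant residues at the
    four H3/H3.3-distinguishing positions.
``H3-like``
    significant fold homology that fits none of the above — e.g. an H3
    paralog missing many canonical fold residues.
``non-histone``
    no significant fold homology at all.

Candidates whose reading frame is interrupted by internal stop codons are
retained but flagged putatively nonfunctional and are never called CenH3.
All thresholds are configurable through :class:`ClassifierThresholds`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Union

from .references import DEFAULT_REFERENCE, H3Reference
from . import seqcore
from .seqcore import (
    AlignmentResult,
    SearchHit,
    TranscriptRecord,
    align_global,
    evalue_of,
    local_score,
    search_protein_vs_transcripts,
)

NONFUNCTIONAL_NOTE = "putatively nonfunctional"


@dataclass
class ClassifierThresholds:
    min_loop1_extension: int = 1
    min_diagnostic_substitutions: int = 2
    max_ntail_identity: float = 50.0
    min_h3_fold_identity: float = 90.0
    min_h33_substitutions: int = 2
    loop1_coverage_fraction: float = 0.5  # below this the window is "unaligned"
    loop1_slack: int = 6  # columns of tolerated insertion mislocalization


DEFAULT_THRESHOLDS = ClassifierThresholds()


@dataclass
class Candidate:
    """A protein pulled out of an assembly by fold homology search."""

    id: str
    protein: str
    source_id: str = ""
    frame: int = 0
    best_hit: Optional[SearchHit] = None
    nonfunctional: bool = False


@dataclass
class HistoneCall:
    candidate_id: str
    label: str  # H3 | H3.3 | CenH3 | H3-like | non-histone
    loop1_extension: Optional[int] = None  # None = loop1 window unaligned
    diagnostic_states: Dict[int, str] = field(default_factory=dict)
    fold_identity: float = 0.0
    ntail_identity: float = 0.0
    notes: str = ""


# --------------------------------------------------------------------------
# candidate discovery
# --------------------------------------------------------------------------


def _protein_from_hit(hit: SearchHit, frame_protein: str) -> Candidate:
    """Extract the candidate protein around a translated hit.

    The candidate is the maximal stop-free segment of the hit's reading
    frame overlapping the aligned span; if the span itself contains internal
    stops, the candidate is flagged putatively nonfunctional.
    """
    n_subject = sum(1 for c in hit.aligned_subject if c != "-")
    span_start, span_end = hit.subject_start, hit.subject_start + n_subject
    span_has_stop = "*" in frame_protein[span_start:span_end]

    # maximal '*'-free segment overlapping the span
    best = (0, 0)
    seg_start = 0
    for i, c in enumerate(frame_protein + "*"):
        if c == "*":
            if seg_start < span_end and i > span_start:  # overlaps span
                if i - seg_start > best[1] - best[0]:
                    best = (seg_start, i)
            seg_start = i + 1
    protein = frame_protein[best[0] : best[1]]
    return Candidate(
        id=f"{hit.subject_id}|frame{hit.frame:+d}",
        protein=protein,
        source_id=hit.subject_id,
        frame=hit.frame,
        best_hit=hit,
        nonfunctional=span_has_stop,
    )


def find_h3_candidates(
    transcripts_or_proteins: Union[Sequence[TranscriptRecord], Dict[str, str]],
    reference: H3Reference = DEFAULT_REFERENCE,
    sig_threshold: float = 1e-10,
    queries: Optional[Dict[str, str]] = None,
    iterative: bool = False,
) -> List[Candidate]:
    """All sequences with a significant fold alignment to the H3 query set.

    ``queries`` defaults to canonical H3 + H3.3 alone; pass a richer set
    (e.g. :func:`censcan.references.default_query_set`) to mirror an
    iterative search already primed with known CenH3 homologs.  With
    ``iterative=True`` one extra search round is run with newly found
    candidate proteins added to the query set.
    """
    if queries is None:
        from .references import CANONICAL_H3, H3_3

        queries = {"H3_canonical": CANONICAL_H3, "H3.3": H3_3}

    if isinstance(transcripts_or_proteins, dict):
        return _find_in_proteins(
            transcripts_or_proteins, queries, sig_threshold
        )

    transcripts = list(transcripts_or_proteins)
    found = _search_round(transcripts, queries, sig_threshold)
    if iterative and found:
        extra = dict(queries)
        for cand in found.values():
            if cand.protein and not cand.nonfunctional:
                extra[cand.id] = cand.protein
        found = _search_round(transcripts, extra, sig_threshold)
    return [found[k] for k in sorted(found)]


def _search_round(
    transcripts: Sequence[TranscriptRecord],
    queries: Dict[str, str],
    sig_threshold: float,
) -> Dict[str, Candidate]:
    best: Dict[str, SearchHit] = {}
    for qid, qseq in queries.items():
        for hit in search_protein_vs_transcripts(
            qseq, transcripts, sig_threshold=sig_threshold, query_id=qid
        ):
            prev = best.get(hit.subject_id)
            if prev is None or hit.evalue < prev.evalue:
                best[hit.subject_id] = hit
    by_transcript = {t.id: t for t in transcripts}
    out: Dict[str, Candidate] = {}
    for tid, hit in best.items():
        frames = seqcore.translate_six_frames(by_transcript[tid].seq)
        out[tid] = _protein_from_hit(hit, frames[hit.frame])
    return out


def _find_in_proteins(
    proteins: Dict[str, str], queries: Dict[str, str], sig_threshold: float
) -> List[Candidate]:
    db_len = 3 * sum(len(p) for p in proteins.values())
    out: List[Candidate] = []
    for pid in proteins:
        seq = proteins[pid]
        if not seq:
            continue
        best_score = max(local_score(q, seq) for q in queries.values())
        best_qlen = max(len(q) for q in queries.values())
        if evalue_of(best_score, best_qlen, db_len) < sig_threshold:
            out.append(Candidate(id=pid, protein=seq, source_id=pid))
    return out


# --------------------------------------------------------------------------
# feature measurements on a global alignment to canonical H3
# --------------------------------------------------------------------------


def _annotated_columns(aln: AlignmentResult):
    """Yield (candidate_char, h3_char, h3_pos_or_None, last_h3_pos)."""
    last = aln.subject_start
    for a, b in zip(aln.aligned_query, aln.aligned_subject):
        pos = None
        if b != "-":
            last += 1
            pos = last
        yield a, b, pos, last


def measure_loop1_extension(
    aln: AlignmentResult,
    reference: H3Reference = DEFAULT_REFERENCE,
    coverage_fraction: float = 0.5,
    slack: int = 6,
) -> Optional[int]:
    """Candidate insertion columns whose flanks fall in the loop1 window.

    ``slack`` widens the accepted flank interval on both sides: with
    substitutions around the loop, global alignment localizes an insertion
    only to within a few columns, so demanding the gap sit exactly inside
    the window would miss genuine extensions.  Negatives are unaffected —
    equal-length H3 variants align without gaps in the fold.

    Returns ``None`` (an explicit "unaligned" signal, distinct from 0) when
    the candidate covers less than ``coverage_fraction`` of the window.
    """
    lo, hi = reference.loop1_window
    covered = 0
    extension = 0
    for a, b, pos, last in _annotated_columns(aln):
        if pos is not None and lo <= pos <= hi and a != "-":
            covered += 1
        if b == "-" and a != "-" and lo - 1 - slack <= last <= hi + slack:
            extension += 1
    window = hi - lo + 1
    if covered / window < coverage_fraction:
        return None
    return extension


def diagnostic_residue_states(
    aln: AlignmentResult, reference: H3Reference = DEFAULT_REFERENCE
) -> Dict[int, str]:
    """State at each diagnostic position: canonical / substituted / unaligned."""
    states = {pos: "unaligned" for pos in reference.diagnostic_positions}
    for a, b, pos, _ in _annotated_columns(aln):
        if pos in states:
            if a == "-":
                states[pos] = "unaligned"
            elif a == reference.diagnostic_positions[pos]:
                states[pos] = "canonical"
            else:
                states[pos] = "substituted"
    return states


def _region_identity(aln: AlignmentResult, start: int, end: int) -> float:
    """Percent identity over columns attributed to H3 positions start..end."""
    cols = 0
    matches = 0
    for a, b, pos, last in _annotated_columns(aln):
        in_region = (pos is not None and start <= pos <= end) or (
            pos is None and start <= last < end
        )
        if not in_region:
            continue
        cols += 1
        if a == b and a != "-":
            matches += 1
    if cols == 0:
        return 0.0
    return 100.0 * matches / cols


def _h33_substitution_count(
    aln: AlignmentResult, reference: H3Reference
) -> int:
    count = 0
    for a, b, pos, _ in _annotated_columns(aln):
        if pos in reference.h3_3_positions and a != "-":
            if a != reference.sequence[pos - 1]:
                count += 1
    return count


# --------------------------------------------------------------------------
# classification
# --------------------------------------------------------------------------


def classify_variant(
    candidate: Union[Candidate, str],
    reference: H3Reference = DEFAULT_REFERENCE,
    thresholds: ClassifierThresholds = DEFAULT_THRESHOLDS,
    candidate_id: str = "candidate",
    sig_threshold: float = 1e-10,
) -> HistoneCall:
    """Classify one candidate protein into the five-way H3-family labels."""
    if isinstance(candidate, str):
        candidate = Candidate(id=candidate_id, protein=candidate)
    notes: List[str] = []
    if candidate.nonfunctional:
        notes.append(NONFUNCTIONAL_NOTE)

    if not candidate.protein:
        return HistoneCall(candidate.id, "non-histone", notes="empty protein")

    fold_score = local_score(candidate.protein, reference.sequence)
    fold_evalue = evalue_of(
        fold_score, len(reference.sequence), 3 * max(len(candidate.protein), 1)
    )
    if candidate.best_hit is None and fold_evalue >= sig_threshold:
        return HistoneCall(
            candidate.id, "non-histone", notes="; ".join(notes) or ""
        )

    aln = align_global(
        candidate.protein, reference.sequence,
        query_id=candidate.id, subject_id="H3_canonical",
    )
    loop1 = measure_loop1_extension(
        aln, reference, thresholds.loop1_coverage_fraction,
        slack=thresholds.loop1_slack,
    )
    states = diagnostic_residue_states(aln, reference)
    fold_identity = _region_identity(aln, reference.fold_start, reference.fold_end)
    ntail_identity = _region_identity(aln, 1, reference.ntail_end)
    n_substituted = sum(1 for s in states.values() if s == "substituted")
    all_canonical = all(s == "canonical" for s in states.values())
    h33_subs = _h33_substitution_count(aln, reference)

    cenh3_ok = (
        loop1 is not None
        and loop1 >= thresholds.min_loop1_extension
        and n_substituted >= thresholds.min_diagnostic_substitutions
        and ntail_identity < thresholds.max_ntail_identity
        and not candidate.nonfunctional
    )
    core_h3_ok = (
        fold_identity >= thresholds.min_h3_fold_identity
        and loop1 == 0
        and all_canonical
    )
    if cenh3_ok:
        label = "CenH3"
    elif core_h3_ok and h33_subs == 0:
        label = "H3"
    elif core_h3_ok and h33_subs >= thresholds.min_h33_substitutions:
        label = "H3.3"
    else:
        label = "H3-like"

    return HistoneCall(
        candidate_id=candidate.id,
        label=label,
        loop1_extension=loop1,
        diagnostic_states=states,
        fold_identity=fold_identity,
        ntail_identity=ntail_identity,
        notes="; ".join(notes),
    )


def classify_assembly(
    transcripts: Sequence[TranscriptRecord],
    reference: H3Reference = DEFAULT_REFERENCE,
    thresholds: ClassifierThresholds = DEFAULT_THRESHOLDS,
    queries: Optional[Dict[str, str]] = None,
    sig_threshold: float = 1e-10,
) -> List[tuple]:
    """Find and classify all H3-family candidates in an assembly.

    Returns a list of (Candidate, HistoneCall) pairs.
    """
    candidates = find_h3_candidates(
        transcripts, reference, sig_threshold, queries=queries
    )
    return [
        (c, classify_variant(c, reference, thresholds, sig_threshold=sig_threshold))
        for c in candidates
    ]


def write_calls_tsv(calls: Sequence[HistoneCall], path,
                    reference: H3Reference = DEFAULT_REFERENCE) -> None:
    positions = sorted(reference.diagnostic_positions)
    header = ["candidate_id", "label", "loop1_extension"]
    header += [f"state@{p}" for p in positions]
    header += ["fold_identity", "ntail_identity", "notes"]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for call in calls:
            row = [
                call.candidate_id,
                call.label,
                "unaligned" if call.loop1_extension is None else str(call.loop1_extension),
            ]
            row += [call.diagnostic_states.get(p, "unaligned") for p in positions]
            row += [
                f"{call.fold_identity:.1f}",
                f"{call.ntail_identity:.1f}",
                call.notes,
            ]
            fh.write("\t".join(row) + "\n")


__all__ = [
    "ClassifierThresholds",
    "DEFAULT_THRESHOLDS",
    "Candidate",
    "HistoneCall",
    "NONFUNCTIONAL_NOTE",
    "find_h3_candidates",
    "measure_loop1_extension",
    "diagnostic_residue_states",
    "classify_variant",
    "classify_assembly",
    "write_calls_tsv",
]
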