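"""Bundled reference data: canonical H3, H3.3, and labeled CenH3 / CenpC panels.

Canonical H3 is effectively invariant across insects, which is what makes it a
reliable anchor for variant classification: every candidate is interpreted in
canonical-H3 coordinates after a global alignment.  The reference annotation
below fixes, once, the coordinates shared by the synthetic generator and the
classifier:

* the histone-fold domain (alpha1-L1-alpha2-L2-alpha3 core),
* the loop1 window, the insertion-prone region whose extension is diagnostic
  for CenH3,
* the three diagnostic residues Gln/Phe/Thr whose replacement is diagnostic
  for CenH3.  In mature-sequence coordinates (no initiator methionine) these
  are Gln68, Phe84 and Thr118; much of the literature counts the initiator
  methionine and therefore cites the first two as 69 and 85.
* the four positions whose substitutions distinguish the replication
  independent variant H3.3 from canonical H3 (residues 31, 87, 89, 90 ->
  S, A, I, G).  H3.3 is otherwise almost identical to H3 and is the
  classifier's closest confounder.

The CenH3 reference panels (host/animal-style and fungal-style contaminant
donors) and the CenpC motif / cupin seed alignments are *synthetic* fixtures:
deterministically constructed sequences with the diagnostic architecture of
the real families, not database accessions.  They are regenerated by
``analysis/00_build_reference_panels.py`` and shipped under ``censcan/data``
with ``synthetic_`` filenames.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Tuple

# Mature (initiator-Met-cleaved) canonical H3, 135 aa. Landmarks: K4, K9, K27,
# K36, K56, K79, T118, K122.
CANONICAL_H3 = (
    "ARTKQTARKSTGGKAPRKQLATKAARKSAPATGGVKKPHRYRPGTVALREIRRYQKSTELLIRKLPFQRLVREIA"
    "QDFKTDLRFQSSAVMALQEASEAYLVGLFEDTNLCAIHAKRVTIMPKDIQLARRIRGERA"
)

# H3.3 differs from canonical H3 at four positions: 31 A->S, 87 S->A,
# 89 V->I, 90 M->G.
_H33_SUBS = {31: "S", 87: "A", 89: "I", 90: "G"}


def _apply_subs(seq: str, subs: Dict[int, str]) -> str:
    chars = list(seq)
    for pos, res in subs.items():
        chars[pos - 1] = res
    return "".join(chars)


H3_3 = _apply_subs(CANONICAL_H3, _H33_SUBS)


@dataclass(frozen=True)
class H3Reference:
    """Canonical-H3 anchor with the fixed coordinates used across the package.

    All positions are 1-based coordinates on ``sequence`` (mature numbering).
    """

    sequence: str = CANONICAL_H3
    fold_start: int = 63
    fold_end: int = 135
    loop1_window: Tuple[int, int] = (80, 88)  # inclusive; contains Phe84
    diagnostic_positions: Dict[int, str] = field(
        default_factory=lambda: {68: "Q", 84: "F", 118: "T"}
    )
    h3_3_positions: Dict[int, str] = field(default_factory=lambda: dict(_H33_SUBS))

    def __post_init__(self) -> None:
        lo, hi = self.loop1_window
        if not (self.fold_start <= lo <= hi <= self.fold_end):
            raise ValueError("loop1 window must lie inside the histone fold")
        for pos, res in self.diagnostic_positions.items():
            if not (self.fold_start <= pos <= self.fold_end):
                raise ValueError(f"diagnostic position {pos} outside the fold")
            if self.sequence[pos - 1] != res:
                raise ValueError(
                    f"reference residue at {pos} is {self.sequence[pos - 1]}, "
                    f"annotation says {res}"
                )

    @property
    def fold_length(self) -> int:
        return self.fold_end - self.fold_start + 1

    @property
    def ntail_end(self) -> int:
        """Last residue of the N-terminal tail (everything before the fold)."""
        return self.fold_start - 1


DEFAULT_REFERENCE = H3Reference()


def _read_fasta_resource(name: str) -> Dict[str, str]:
    text = resources.files("censcan.data").joinpath(name).read_text()
    seqs: Dict[str, str] = {}
    sid = None
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            sid = line[1:].split()[0]
            seqs[sid] = ""
        else:
            seqs[sid] += line
    return seqs


def load_host_cenh3_panel() -> Dict[str, str]:
    """Animal-style CenH3 reference panel (synthetic fixture)."""
    return _read_fasta_resource("synthetic_cenh3_host_panel.fasta")


def load_contaminant_cenh3_panel() -> Dict[str, str]:
    """Fungal-style CenH3 panel used as contaminant donors (synthetic fixture)."""
    return _read_fasta_resource("synthetic_cenh3_contaminant_panel.fasta")


def contaminant_donor() -> Tuple[str, str]:
    """The designated contaminant donor sequence (first panel entry)."""
    panel = load_contaminant_cenh3_panel()
    name = sorted(panel)[0]
    return name, panel[name]


def load_cenpc_motif_seed() -> Dict[str, str]:
    """Aligned seed set for the CenpC motif profile (synthetic fixture)."""
    return _read_fasta_resource("synthetic_cenpc_motif_seed.fasta")


def load_cupin_seed() -> Dict[str, str]:
    """Aligned seed set for the CenpC-type cupin domain profile (synthetic)."""
    return _read_fasta_resource("synthetic_cupin_seed.fasta")


def load_noncenpc_cupin_panel() -> Dict[str, str]:
    """Non-CenpC cupin sequences for the cupin clade test (synthetic fixture)."""
    return _read_fasta_resource("synthetic_noncenpc_cupin_panel.fasta")


def default_query_set() -> Dict[str, str]:
    """Default H3-family query set for homology search.

    Mirrors an iterative search seeded with canonical H3 and extended with
    confirmed CenH3 homologs from both host and contaminant lineages.
    """
    queries = {"H3_canonical": CANONICAL_H3, "H3.3": H3_3}
    queries.update(load_host_cenh3_panel())
    queries.update(load_contaminant_cenh3_panel())
    return queries


__all__ = [
    "CANONICAL_H3",
    "H3_3",
    "H3Reference",
    "DEFAULT_REFERENCE",
    "load_host_cenh3_panel",
    "load_contaminant_cenh3_panel",
    "contaminant_donor",
    "load_cenpc_motif_seed",
    "load_cupin_seed",
    "load_noncenpc_cupin_panel",
    "default_query_set",
]
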