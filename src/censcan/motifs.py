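"""Profile (PSSM) detection of the CenpC motif and cupin domain.

CenpC, the inner-kinetochore partner of CenH3, carries two short conserved
regions usable for cross-species homology detection: the CenpC motif (which
binds the CenH3 C-terminus) and, in most animal and fungal CenpCs, a
C-terminal cupin fold.  Detection here is by position-specific scoring
matrix: a log-odds profile built from a seed alignment is slid along each
protein, and the best window's significance is a permutation p-value — the
add-one-smoothed fraction of within-protein shuffles whose best window
scores at least as high.  Shuffling preserves composition, so the p-value is
a composition-corrected tail probability; it is not comparable in magnitude
to HMM-comparison significance values, only in role.

Because cupin folds occur outside CenpC too, a cupin hit counts toward a
CenpC architecture only when a clade test against CenpC-type vs non-CenpC
cupins (reusing the placement machinery) sides with the CenpC-type clade.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np

from .phylogeny import PlacementVerdict

PROFILE_ALPHABET = "ARNDCQEGHILKMFPSTWYV"
_AA_INDEX = {c: i for i, c in enumerate(PROFILE_ALPHABET)}


@dataclass
class ProfileModel:
    """Log-odds position-specific score matrix (bits) over 20 amino acids."""

    name: str
    matrix: np.ndarray  # (width, 20) log2-odds
    background: np.ndarray  # (20,)
    pseudocount: float

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(PROFILE_ALPHABET[j] for j in self.matrix.argmax(axis=1))


@dataclass
class MotifHit:
    protein_id: str
    motif: str
    offset: int  # 0-based
    score: float  # bits
    pvalue: float


def build_profile(
    seed_alignment: Dict[str, str],
    pseudocount: float = 0.5,
    name: str = "motif",
    background: Optional[np.ndarray] = None,
) -> ProfileModel:
    """Per-column frequencies with additive pseudocounts, as log-odds bits.

    Columns that are all-gap are rejected; gap characters otherwise simply
    do not contribute to their column's counts.
    """
    if len(seed_alignment) < 3:
        raise ValueError("need >= 3 aligned seed sequences")
    rows = list(seed_alignment.values())
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ValueError("seed alignment is ragged")
    (width,) = widths
    if width < 5:
        raise ValueError("profile width must be >= 5")
    if background is None:
        background = np.full(20, 1.0 / 20.0)
    background = np.asarray(background, dtype=float)

    counts = np.zeros((width, 20))
    for row in rows:
        for j, c in enumerate(row.upper()):
            if c in _AA_INDEX:
                counts[j, _AA_INDEX[c]] += 1.0
    if np.any(counts.sum(axis=1) == 0):
        raise ValueError("seed alignment contains an all-gap column")
    freqs = counts + pseudocount * background
    freqs /= freqs.sum(axis=1, keepdims=True)
    matrix = np.log2(freqs / background)
    return ProfileModel(
        name=name, matrix=matrix, background=background, pseudocount=pseudocount
    )


def _window_scores(profile: ProfileModel, protein: str) -> np.ndarray:
    codes = np.array([_AA_INDEX.get(c, -1) for c in protein.upper()])
    n = len(codes) - profile.width + 1
    scores = np.zeros(n)
    for j in range(profile.width):
        col = profile.matrix[j]
        window = codes[j : j + n]
        scores += np.where(window >= 0, col[np.clip(window, 0, 19)], 0.0)
    return scores


def scan_profile(
    profile: ProfileModel,
    protein: str,
    protein_id: str = "protein",
    n_null: int = 999,
    seed: int = 0,
) -> MotifHit:
    """Best-scoring window plus its permutation-null p-value."""
    if len(protein) < profile.width:
        raise ValueError(
            f"protein length {len(protein)} < profile width {profile.width}"
        )
    scores = _window_scores(profile, protein)
    best = int(scores.argmax())
    observed = float(scores[best])

    rng = np.random.default_rng(seed)
    chars = np.array(list(protein))
    exceed = 0
    for _ in range(n_null):
        rng.shuffle(chars)
        null_best = float(_window_scores(profile, "".join(chars)).max())
        if null_best >= observed:
            exceed += 1
    pvalue = (exceed + 1) / (n_null + 1)
    return MotifHit(
        protein_id=protein_id, motif=profile.name, offset=best,
        score=observed, pvalue=pvalue,
    )


def call_cenpc_architecture(
    motif_hit: Optional[MotifHit],
    cupin_hit: Optional[MotifHit],
    cupin_verdict: Optional[PlacementVerdict] = None,
    p_threshold: float = 1e-3,
) -> str:
    """Architecture label from the two scans and the cupin clade test.

    A missing hit (``None``) counts as absent.  A significant cupin only
    counts when no clade test is supplied or the clade test attributes it to
    the CenpC-type cupin clade (verdict ``host``).
    """
    motif_present = motif_hit is not None and motif_hit.pvalue <= p_threshold
    cupin_present = cupin_hit is not None and cupin_hit.pvalue <= p_threshold
    if cupin_present and cupin_verdict is not None:
        cupin_present = cupin_verdict.verdict == "host"
    if motif_present and cupin_present:
        return "motif+cupin"
    if motif_present:
        return "motif-only"
    if cupin_present:
        return "cupin-only"
    return "none"


# --------------------------------------------------------------------------
# serialization: plain text matrix format
# --------------------------------------------------------------------------


def write_profile(profile: ProfileModel, path) -> None:
    """Plain text: name, alphabet, background row, then width score rows."""
    with open(path, "w") as fh:
        fh.write(f"# profile {profile.name}\n")
        fh.write(f"# pseudocount {profile.pseudocount}\n")
        fh.write("alphabet\t" + "\t".join(PROFILE_ALPHABET) + "\n")
        fh.write(
            "background\t" + "\t".join(f"{b:.6f}" for b in profile.background) + "\n"
        )
        for row in profile.matrix:
            fh.write("\t".join(f"{v:.6f}" for v in row) + "\n")


def read_profile(path) -> ProfileModel:
    name = "motif"
    pseudocount = 0.0
    background = None
    rows: List[List[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# profile"):
                name = line.split(maxsplit=2)[2]
            elif line.startswith("# pseudocount"):
                pseudocount = float(line.split()[2])
            elif line.startswith("alphabet"):
                alphabet = line.split("\t")[1:]
                if "".join(alphabet) != PROFILE_ALPHABET:
                    raise ValueError("unexpected profile alphabet")
            elif line.startswith("background"):
                background = np.array([float(x) for x in line.split("\t")[1:]])
            elif line:
                rows.append([float(x) for x in line.split("\t")])
    return ProfileModel(
        name=name,
        matrix=np.array(rows),
        background=background,
        pseudocount=pseudocount,
    )


def write_motif_hits_tsv(hits: Sequence[MotifHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tmotif\toffset\tscore_bits\tpvalue\n")
        for h in hits:
            fh.write(
                f"{h.protein_id}\t{h.motif}\t{h.offset}\t{h.score:.3f}\t"
                f"{h.pvalue:.4g}\n"
            )


__all__ = [
    "PROFILE_ALPHABET",
    "ProfileModel",
    "MotifHit",
    "build_profile",
    "scan_profile",
    "call_cenpc_architecture",
    "write_profile",
    "read_profile",
    "write_motif_hits_tsv",
]
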