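"""Cross-homolog pocket comparison: alignment, residue mapping, superposition.

Given the significant-CSP residue lists of two homologous RNA-recognition
motifs, this module answers whether they describe the same binding pocket:

* :func:`global_align` — Needleman–Wunsch global alignment with affine gaps
  (BLOSUM62, gap open 10, extend 0.5 by default; a gap of length L costs
  ``open + (L−1)·extend``).
* :func:`map_equivalent_residues` — the residue-number correspondence of the
  mutually aligned (non-gap) columns.
* :func:`superpose_kabsch` — optimal least-squares rigid superposition of the
  mapped Cα atoms (Kabsch/SVD with proper-rotation correction) and its RMSD.
* :func:`compare_pockets` — conserved significant pairs and a Jaccard-style
  overlap on the mapped correspondence.
* :func:`annotate_sse` — label residues with declared secondary-structure
  elements (β-strands / α-helices as labelled intervals), to summarise how a
  pocket clusters on the β-sheet surface of an RRM fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.spatial.transform import Rotation

from .errors import ConfigError, DegenerateInputError, InputError, LookupError_
from .shift_io import AMINO_ACIDS_1, SequenceRecord, StructureCA

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# sequence alignment
# ---------------------------------------------------------------------------

@dataclass
class AlignmentResult:
    """A global alignment as ordered residue-number column pairs.

    ``aligned_columns[i] = (resnum_A | None, resnum_B | None)``; ``None``
    marks a gap. ``identity_fraction`` is identical columns divided by
    columns where both sides are non-gap.
    """

    aligned_columns: list[tuple[int | None, int | None]]
    score: float
    identity_fraction: float
    aligned_a: str = ""
    aligned_b: str = ""

    def to_dict(self) -> dict:
        return {
            "score": self.score,
            "identity_fraction": self.identity_fraction,
            "aligned_a": self.aligned_a,
            "aligned_b": self.aligned_b,
        }


def global_align(
    a: SequenceRecord,
    b: SequenceRecord,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> AlignmentResult:
    """Needleman–Wunsch global alignment with affine gap penalties.

    ``gap_open`` is the cost of a gap of length 1; each additional gapped
    position adds ``gap_extend``. End gaps are penalised like internal ones.
    """
    if not a.sequence or not b.sequence:
        raise InputError("cannot align empty sequences")
    for rec in (a, b):
        bad = set(rec.sequence) - AMINO_ACIDS_1 - {"X"}
        if bad:
            raise InputError(f"sequence {rec.identifier!r}: invalid letters {sorted(bad)}")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    alignments = aligner.align(a.sequence, b.sequence)
    best = alignments[0]
    ga, gb = str(best[0]), str(best[1])

    columns: list[tuple[int | None, int | None]] = []
    ia, ib = a.first_residue_number, b.first_residue_number
    n_match = n_both = 0
    for ca, cb in zip(ga, gb):
        ra = ia if ca != "-" else None
        rb = ib if cb != "-" else None
        columns.append((ra, rb))
        if ca != "-" and cb != "-":
            n_both += 1
            if ca == cb:
                n_match += 1
        if ca != "-":
            ia += 1
        if cb != "-":
            ib += 1
    identity = n_match / n_both if n_both else 0.0
    return AlignmentResult(columns, float(best.score), identity, ga, gb)


@dataclass
class ResidueMap:
    """Ordered (resnum_A, resnum_B) pairs, strictly increasing on both sides."""

    pairs: list[tuple[int, int]]

    def __post_init__(self) -> None:
        for (a0, b0), (a1, b1) in zip(self.pairs, self.pairs[1:]):
            if a1 <= a0 or b1 <= b0:
                raise InputError("residue map must be strictly increasing on both sides")
        self._a_to_b = dict(self.pairs)
        self._b_to_a = {b: a for a, b in self.pairs}

    def map_a_to_b(self, resnum_a: int) -> int | None:
        return self._a_to_b.get(resnum_a)

    def map_b_to_a(self, resnum_b: int) -> int | None:
        return self._b_to_a.get(resnum_b)

    def __len__(self) -> int:
        return len(self.pairs)

    @classmethod
    def shift(cls, start_a: int, end_a: int, offset: int) -> "ResidueMap":
        """Constant-offset map: A residue k ↔ B residue k + offset."""
        return cls([(k, k + offset) for k in range(start_a, end_a + 1)])


def map_equivalent_residues(alignment: AlignmentResult) -> ResidueMap:
    """Residue correspondence of the mutually aligned (non-gap) columns."""
    pairs = [
        (ra, rb) for ra, rb in alignment.aligned_columns
        if ra is not None and rb is not None
    ]
    return ResidueMap(pairs)


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

@dataclass
class SuperpositionResult:
    """Least-squares rigid superposition of mapped Cα pairs.

    ``rotation @ x_b + translation ≈ x_a`` for the mapped atoms; ``rmsd`` is
    the residual root-mean-square deviation over the ``n_atoms`` pairs.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    def to_dict(self) -> dict:
        return {
            "rmsd": float(self.rmsd),
            "n_atoms": self.n_atoms,
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
        }


def superpose_kabsch(
    a: StructureCA, b: StructureCA, residue_map: ResidueMap
) -> SuperpositionResult:
    """Optimal rigid superposition of B onto A over the mapped Cα pairs.

    Solved by the Kabsch/SVD construction with the determinant correction
    that excludes improper rotations (reflections).
    """
    if len(residue_map) < 3:
        raise DegenerateInputError("need at least 3 mapped residues to superpose")
    res_a = [p[0] for p in residue_map.pairs]
    res_b = [p[1] for p in residue_map.pairs]
    xa = a.coords(res_a)
    xb = b.coords(res_b)
    ca_, cb_ = xa.mean(axis=0), xb.mean(axis=0)
    rot, _ = Rotation.align_vectors(xa - ca_, xb - cb_)
    matrix = rot.as_matrix()
    translation = ca_ - matrix @ cb_
    # recompute the residual from the transformed coordinates: the solver's
    # rssd loses precision to cancellation when the fit is near-exact
    resid = xa - (xb @ matrix.T + translation)
    rmsd = float(np.sqrt((resid ** 2).sum(axis=1).mean()))
    if _is_collinear(xa) or _is_collinear(xb):
        logger.warning(
            "mapped Cα are (near-)collinear: the rotation about the axis is "
            "undetermined, though the RMSD is still minimal"
        )
    return SuperpositionResult(matrix, translation, rmsd, len(residue_map))


def _is_collinear(x: np.ndarray, rtol: float = 1e-8) -> bool:
    centered = x - x.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    return bool(s[1] <= rtol * max(s[0], 1.0))


# ---------------------------------------------------------------------------
# pocket comparison
# ---------------------------------------------------------------------------

@dataclass
class PocketComparison:
    significant_a: list[int]
    significant_b: list[int]
    conserved_pairs: list[tuple[int, int]]
    jaccard_mapped: float

    table_columns = ("residue_a", "residue_b")

    def to_table(self) -> list[dict]:
        return [{"residue_a": a, "residue_b": b} for a, b in self.conserved_pairs]

    def to_dict(self) -> dict:
        return {
            "significant_a": self.significant_a,
            "significant_b": self.significant_b,
            "conserved_pairs": [list(p) for p in self.conserved_pairs],
            "n_conserved": len(self.conserved_pairs),
            "jaccard_mapped": self.jaccard_mapped,
        }


def compare_pockets(
    sig_a: list[int], sig_b: list[int], residue_map: ResidueMap
) -> PocketComparison:
    """Overlap of two significant-residue sets under a residue correspondence.

    ``conserved_pairs`` are mapped pairs significant on both sides;
    ``jaccard_mapped`` divides their count by the mapped pairs significant on
    either side. Significant residues outside the mapped range cannot be
    compared and only count as unshared (with a warning).
    """
    set_a, set_b = set(sig_a), set(sig_b)
    unmapped_a = [r for r in sorted(set_a) if residue_map.map_a_to_b(r) is None]
    unmapped_b = [r for r in sorted(set_b) if residue_map.map_b_to_a(r) is None]
    if unmapped_a or unmapped_b:
        logger.warning(
            "significant residues outside the mapped range: A=%s B=%s",
            unmapped_a, unmapped_b,
        )
    conserved = []
    either = 0
    for ra, rb in residue_map.pairs:
        in_a, in_b = ra in set_a, rb in set_b
        if in_a and in_b:
            conserved.append((ra, rb))
        if in_a or in_b:
            either += 1
    either += len(unmapped_a) + len(unmapped_b)
    jaccard = len(conserved) / either if either else 0.0
    return PocketComparison(sorted(set_a), sorted(set_b), conserved, jaccard)


# ---------------------------------------------------------------------------
# secondary-structure annotation
# ---------------------------------------------------------------------------

def annotate_sse(
    residues: list[int],
    sse_ranges: dict[str, tuple[int, int]],
    structured_core: tuple[int, int] = (23, 100),
) -> dict[int, str]:
    """Label residues by secondary-structure element.

    ``sse_ranges`` maps element names (e.g. ``"b1"``, ``"a2"``) to inclusive
    residue intervals, which must not overlap. Residues inside the structured
    core but outside every element are ``"loop"``; residues outside the core
    are ``"disordered"``.
    """
    intervals = sorted(sse_ranges.items(), key=lambda kv: kv[1][0])
    for (name1, (_, end1)), (name2, (start2, _)) in zip(intervals, intervals[1:]):
        if start2 <= end1:
            raise ConfigError(f"SSE intervals {name1} and {name2} overlap")
    out: dict[int, str] = {}
    for res in residues:
        label = None
        for name, (start, end) in intervals:
            if start <= res <= end:
                label = name
                break
        if label is None:
            label = "loop" if structured_core[0] <= res <= structured_core[1] else "disordered"
        out[res] = label
    return out


def group_by_sse(labels: dict[int, str]) -> dict[str, list[int]]:
    """Group labelled residues by element (the pocket-clustering summary)."""
    groups: dict[str, list[int]] = {}
    for res, label in sorted(labels.items()):
        groups.setdefault(label, []).append(res)
    return groups


def pymol_selection(name: str, residues: list[int], chain: str = "A") -> str:
    """A PyMOL-style selection string for a residue list (plain text export)."""
    resi = "+".join(str(r) for r in sorted(residues))
    return f"select {name}, chain {chain} and resi {resi}"
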