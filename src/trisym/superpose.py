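"""Rigid-body least-squares superposition and cross-protein core alignment.

The workhorse is the Kabsch algorithm (SVD solution of the orthogonal
Procrustes problem with a reflection guard).  On top of it,
:func:`core_align` finds the rigid *core* shared by two homologous chains:
starting from a sequence- or index-based residue correspondence, it
alternates superposition and removal of badly fitting pairs until the pair
set is stable — the standard iterative-trimming recipe for comparing
homologs whose loops diverge while their scaffold is conserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .structure_io import Protomer

__all__ = [
    "RigidTransform",
    "CoreAlignment",
    "DegenerateInputError",
    "AlignmentFailure",
    "kabsch",
    "core_align",
    "apply_transform",
]


class DegenerateInputError(ValueError):
    """Too few or degenerate points for a well-posed superposition."""


class AlignmentFailure(RuntimeError):
    """Core alignment could not retain enough residue pairs."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x ↦ R·x + t (R orthonormal, det +1)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("reflections are not rigid motions")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equal to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


@dataclass
class CoreAlignment:
    """Result of iterative core alignment: surviving residue pairs, the rigid
    transform mapping A onto B, and the C-alpha RMSD over the core."""

    pairs: list[tuple[int, int]]
    rmsd: float
    transform: RigidTransform
    rmsd_history: list[float] = field(default_factory=list)

    @property
    def n_core(self) -> int:
        return len(self.pairs)


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def kabsch(points_a: np.ndarray, points_b: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of paired points A onto B.

    Returns the proper rigid transform minimizing RMSD(R·A + t, B) and that
    minimal RMSD.  Requires at least 3 point pairs; near-collinear inputs
    produce a conditioning warning because the in-plane rotation is then
    poorly determined.
    """
    A = np.asarray(points_a, dtype=float)
    B = np.asarray(points_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("point sets must be matching N×3 arrays")
    n = A.shape[0]
    if n < 3:
        raise DegenerateInputError(f"need ≥ 3 point pairs, got {n}")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    H = A0.T @ B0
    U, S, Vt = np.linalg.svd(H)
    # two vanishing singular values ⇒ points (nearly) collinear
    if S[1] <= max(S[0] * 1e-8, 1e-12):
        warnings.warn(
            "point set is nearly collinear; rotation about the line is "
            "ill-conditioned",
            RuntimeWarning,
            stacklevel=2,
        )
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d if d != 0 else 1.0])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    transform = RigidTransform(R, t)
    return transform, _rmsd(transform.apply(A), B)


def apply_transform(protomer: Protomer, transform: RigidTransform) -> Protomer:
    """Protomer with every atom mapped through the rigid transform."""
    return protomer.with_coordinates(transform.apply)


def _sequence_seed_pairs(a: Protomer, b: Protomer) -> list[tuple[int, int]]:
    """Initial residue correspondence from global sequence alignment.

    Homologous receptors share fold more faithfully than sequence, so the
    seed only needs to be roughly right: BLOSUM62 with affine gaps, aligned
    columns become candidate pairs and structural trimming does the rest.
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aligner.mode = "global"
    aln = aligner.align(a.sequence().replace("X", "A"), b.sequence().replace("X", "A"))[0]
    pairs: list[tuple[int, int]] = []
    for (a_start, a_end), (b_start, b_end) in zip(*aln.aligned):
        for i, j in zip(range(a_start, a_end), range(b_start, b_end)):
            pairs.append((int(a.residue_numbers[i]), int(b.residue_numbers[j])))
    return pairs


def core_align(
    a: Protomer,
    b: Protomer,
    seed_mapping: str = "sequence",
    trim_cutoff: float = 3.5,
    max_iter: int = 10,
) -> CoreAlignment:
    """Iterative-trimming core alignment of protomer ``a`` onto ``b``.

    Parameters
    ----------
    seed_mapping:
        ``"sequence"`` seeds pairs by global sequence alignment (suitable for
        homologs); ``"index"`` pairs residues positionally (requires equal
        residue counts — suitable for conformers of one chain).
    trim_cutoff:
        After each superposition, all pairs whose C-alpha deviation exceeds
        this cutoff (Å) are dropped simultaneously.
    max_iter:
        Iteration limit; convergence is reached when no pair is dropped.

    With ``seed_mapping="index"`` and a cutoff no pair exceeds, the result
    equals a plain Kabsch superposition over all residues.
    """
    if len(a) < 10 or len(b) < 10:
        raise DegenerateInputError("core alignment needs protomers of ≥ 10 residues")
    if seed_mapping == "sequence":
        pairs = _sequence_seed_pairs(a, b)
    elif seed_mapping == "index":
        if len(a) != len(b):
            raise ValueError("index seeding requires equal-length protomers")
        pairs = list(zip(a.residue_numbers.tolist(), b.residue_numbers.tolist()))
    else:
        raise ValueError("seed_mapping must be 'sequence' or 'index'")

    ca_a, ca_b = a.ca, b.ca
    idx_a = {int(num): i for i, num in enumerate(a.residue_numbers)}
    idx_b = {int(num): i for i, num in enumerate(b.residue_numbers)}
    history: list[float] = []
    transform = RigidTransform.identity()
    rmsd = np.inf
    for _ in range(max_iter):
        if len(pairs) < 3:
            raise AlignmentFailure(
                f"fewer than 3 residue pairs survive trimming ({len(pairs)} left)"
            )
        pa = ca_a[[idx_a[i] for i, _ in pairs]]
        pb = ca_b[[idx_b[j] for _, j in pairs]]
        transform, rmsd = kabsch(pa, pb)
        history.append(rmsd)
        dev = np.linalg.norm(transform.apply(pa) - pb, axis=1)
        keep = dev <= trim_cutoff
        if keep.all():
            break
        pairs = [p for p, k in zip(pairs, keep) if k]
    return CoreAlignment(pairs=pairs, rmsd=rmsd, transform=transform,
                         rmsd_history=history)
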