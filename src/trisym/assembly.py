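"""C3-symmetric assembly generation and deterministic pose enumeration.

A cyclic homotrimer is fully described by the pose of one protomer relative
to the symmetry axis (taken as z): an orientation (z-y-z Euler angles applied
about the protomer centroid), a radial offset from the axis and an axial
offset along it.  The other two protomers follow by 120° rotations.  Candidate
assemblies are generated by exhaustive enumeration over a deterministic grid
of poses and ranked by a C-alpha contact score — a transparent stand-in for
shape-complementarity docking scores, sufficient to produce the ranked
candidate trimers that downstream geometric selection consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .structure_io import Conformer, Protomer
from .superpose import RigidTransform

__all__ = [
    "PoseParams",
    "PoseGrid",
    "ScoreBreakdown",
    "AssemblyModel",
    "replicate_c3",
    "score_assembly",
    "enumerate_c3_poses",
]

_CHAIN_NAMES = "ABCDEFGH"


@dataclass(frozen=True)
class PoseParams:
    """Generating pose of protomer copy 0 relative to the symmetry (z) axis.

    ``euler`` are intrinsic z-y-z angles in degrees rotating the protomer
    about its centroid; the centroid is then placed at
    (radial_offset, 0, axial_offset).
    """

    euler: tuple[float, float, float] = (0.0, 0.0, 0.0)
    radial_offset: float = 0.0
    axial_offset: float = 0.0

    def __post_init__(self):
        if self.radial_offset < 0:
            raise ValueError("radial_offset must be ≥ 0")

    def as_tuple(self) -> tuple[float, ...]:
        return (*self.euler, self.radial_offset, self.axial_offset)

    def placement(self, centroid: np.ndarray) -> RigidTransform:
        """Rigid transform taking the protomer to the copy-0 position."""
        R = Rotation.from_euler("zyz", self.euler, degrees=True).as_matrix()
        target = np.array([self.radial_offset, 0.0, self.axial_offset])
        return RigidTransform(R, target - R @ np.asarray(centroid))


@dataclass(frozen=True)
class ScoreBreakdown:
    """Contact/clash counts of an assembly and the combined score."""

    contacts: int
    clashes: int
    w_clash: float = 10.0

    def __post_init__(self):
        if self.contacts < 0 or self.clashes < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> float:
        return self.contacts - self.w_clash * self.clashes


@dataclass
class AssemblyModel:
    """Symmetry-related protomer copies plus the generating pose and score.

    ``extra_chains`` carries non-receptor chains (e.g. a ligand trimer kept
    from a template complex).
    """

    protomers: list[Protomer]
    pose: PoseParams | None = None
    score: ScoreBreakdown | None = None
    rank: int | None = None
    extra_chains: list[Protomer] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    @property
    def n_fold(self) -> int:
        return len(self.protomers)

    def as_conformer(self) -> Conformer:
        return Conformer(list(self.protomers) + list(self.extra_chains))

    def symmetry_rmsd(self) -> float:
        """RMSD between each copy rotated by 360°/n and the next copy (max
        over copies); 0 for an exact cyclic assembly."""
        n = self.n_fold
        R = Rotation.from_euler("z", 360.0 / n, degrees=True).as_matrix()
        worst = 0.0
        for i in range(n):
            a = self.protomers[i].ca @ R.T
            b = self.protomers[(i + 1) % n].ca
            worst = max(worst, float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1)))))
        return worst


def replicate_c3(protomer: Protomer, pose: PoseParams, n_fold: int = 3) -> AssemblyModel:
    """Exact cyclic assembly: copy 0 placed by ``pose``, remaining copies by
    360°/n rotations about the z axis.  Internal distances of each copy are
    preserved exactly (pure rigid motions)."""
    if n_fold < 2:
        raise ValueError("n_fold must be ≥ 2")
    place = pose.placement(protomer.ca.mean(axis=0))
    copies = []
    for k in range(n_fold):
        Rk = Rotation.from_euler("z", 360.0 * k / n_fold, degrees=True).as_matrix()
        tk = RigidTransform(Rk, np.zeros(3)).compose(place)
        copy = protomer.with_coordinates(tk.apply)
        copy.chain_id = _CHAIN_NAMES[k]
        copies.append(copy)
    return AssemblyModel(protomers=copies, pose=pose)


def score_assembly(
    assembly: AssemblyModel,
    contact_shell: float = 8.0,
    clash_cutoff: float = 4.0,
    w_clash: float = 10.0,
) -> ScoreBreakdown:
    """Count inter-protomer residue contacts and clashes (Cα–Cα metric).

    A contact is an unordered inter-protomer residue pair with Cα distance
    ≤ ``contact_shell``; a clash is one with distance ≤ ``clash_cutoff``
    (clashing pairs also count as contacts).  Boundary distances are
    included (≤ rule).  Score = contacts − w_clash · clashes.
    """
    coords = [p.ca for p in assembly.protomers]
    contacts = clashes = 0
    for i, j in combinations(range(len(coords)), 2):
        if len(coords[i]) * len(coords[j]) <= 4096:
            d = cdist(coords[i], coords[j])
            contacts += int(np.count_nonzero(d <= contact_shell))
            clashes += int(np.count_nonzero(d <= clash_cutoff))
        else:
            ta, tb = cKDTree(coords[i]), cKDTree(coords[j])
            contacts += ta.count_neighbors(tb, contact_shell)
            clashes += ta.count_neighbors(tb, clash_cutoff)
    return ScoreBreakdown(contacts=contacts, clashes=clashes, w_clash=w_clash)


def _grid_1d(rng: tuple[float, float], step: float, wrap: float | None = None) -> np.ndarray:
    lo, hi = rng
    if step <= 0:
        raise ValueError("grid step must be > 0")
    vals = np.arange(lo, hi + 0.5 * step, step)
    if wrap is not None:
        vals = vals[(vals - lo) < wrap - 1e-9] if (hi - lo) >= wrap else vals
    return vals


@dataclass(frozen=True)
class PoseGrid:
    """Deterministic search grid over pose parameters.

    Angle ranges are inclusive except that full 360° ranges omit the
    duplicate endpoint.  Defaults follow the package-wide grid resolution:
    15° angular, 2 Å radial/axial steps.
    """

    alpha_range: tuple[float, float] = (0.0, 360.0)
    beta_range: tuple[float, float] = (0.0, 180.0)
    gamma_range: tuple[float, float] = (0.0, 360.0)
    angular_step: float = 15.0
    radial_range: tuple[float, float] = (0.0, 30.0)
    radial_step: float = 2.0
    axial_range: tuple[float, float] = (0.0, 0.0)
    axial_step: float = 2.0

    def poses(self):
        for a in _grid_1d(self.alpha_range, self.angular_step, wrap=360.0):
            for b in _grid_1d(self.beta_range, self.angular_step, wrap=360.0):
                for g in _grid_1d(self.gamma_range, self.angular_step, wrap=360.0):
                    for r in _grid_1d(self.radial_range, self.radial_step):
                        for z in _grid_1d(self.axial_range, self.axial_step):
                            yield PoseParams(
                                (float(a), float(b), float(g)), float(r), float(z)
                            )


def enumerate_c3_poses(
    protomer: Protomer,
    grid: PoseGrid,
    top_k: int = 4,
    contact_shell: float = 8.0,
    clash_cutoff: float = 4.0,
    w_clash: float = 10.0,
    n_fold: int = 3,
) -> list[AssemblyModel]:
    """Exhaustively score the pose grid and return the ``top_k`` assemblies.

    Ranking is by total score descending, ties broken by fewer clashes,
    then lexicographically by pose parameters — fully deterministic.
    """
    scored: list[tuple[float, int, tuple, PoseParams, ScoreBreakdown]] = []
    centroid = protomer.ca.mean(axis=0)
    local = protomer.ca - centroid
    for pose in grid.poses():
        R0 = Rotation.from_euler("zyz", pose.euler, degrees=True).as_matrix()
        base = local @ R0.T + np.array(
            [pose.radial_offset, 0.0, pose.axial_offset]
        )
        contacts = clashes = 0
        for k in range(1, n_fold):
            Rk = Rotation.from_euler("z", 360.0 * k / n_fold, degrees=True).as_matrix()
            d = cdist(base, base @ Rk.T)
            contacts += int(np.count_nonzero(d <= contact_shell))
            clashes += int(np.count_nonzero(d <= clash_cutoff))
        # each unordered chain pair appears once in the k-loop for n=3
        # (pairs (0,1),(0,2) are counted; (1,2) is congruent to (0,1) by
        # symmetry), so rescale to all n(n-1)/2 pairs
        scale = (n_fold * (n_fold - 1) / 2) / (n_fold - 1)
        contacts = int(round(contacts * scale))
        clashes = int(round(clashes * scale))
        sb = ScoreBreakdown(contacts, clashes, w_clash)
        scored.append((-sb.total, sb.clashes, pose.as_tuple(), pose, sb))
    scored.sort(key=lambda item: (item[0], item[1], item[2]))
    out = []
    for rank, (_, _, _, pose, sb) in enumerate(scored[:top_k], start=1):
        model = replicate_c3(protomer, pose, n_fold=n_fold)
        model.score = sb
        model.rank = rank
        out.append(model)
    return out
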