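"""Ligand-bound (Holo) placement and hinge-domain rotation.

Ligand-bound geometry of a trimeric receptor can be borrowed from a solved
homologous receptor/ligand complex: each receptor protomer is superposed
onto one receptor chain of the template trimer (the ligand chains ride
along unmodified).  The splayed Holo arrangement generally strains the
connection to the membrane-proximal segments; :func:`hinge_rotate`
quantifies how far a rigid rotation of a membrane-proximal domain about a
hinge residue can close that distance, using a deterministic search over an
icosahedrally sampled set of rotation axes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .assembly import AssemblyModel
from .structure_io import Conformer, Protomer, RegionSpan
from .superpose import apply_transform, core_align

__all__ = [
    "HingeMove",
    "HingeSearch",
    "icosphere_directions",
    "place_on_template",
    "hinge_rotate",
    "residue_pair_distance",
]


@dataclass(frozen=True)
class HingeMove:
    """A rigid rotation of ``domain_span`` about an axis through the hinge
    residue's Cα."""

    hinge_residue: int
    domain_span: RegionSpan
    axis: np.ndarray
    angle: float

    def __post_init__(self):
        axis = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(axis)
        if n == 0:
            raise ValueError("axis must be non-zero")
        object.__setattr__(self, "axis", axis / n)


@dataclass(frozen=True)
class HingeSearch:
    """Deterministic search space for hinge moves.

    ``subdivisions=2`` gives 162 icosahedrally distributed axis directions
    (≥ the 92 of one subdivision level); angles are scanned in
    ``angle_step``-degree increments over ``angle_range``.
    """

    hinge_residue: int
    domain_span: RegionSpan
    subdivisions: int = 2
    angle_range: tuple[float, float] = (-90.0, 90.0)
    angle_step: float = 2.0


def icosphere_directions(subdivisions: int = 2) -> np.ndarray:
    """Unit directions from a subdivided icosahedron (12, 42, 162, … points),
    in a deterministic order."""
    phi = (1 + np.sqrt(5)) / 2
    verts = [
        (-1, phi, 0), (1, phi, 0), (-1, -phi, 0), (1, -phi, 0),
        (0, -1, phi), (0, 1, phi), (0, -1, -phi), (0, 1, -phi),
        (phi, 0, -1), (phi, 0, 1), (-phi, 0, -1), (-phi, 0, 1),
    ]
    faces = [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ]
    verts = [np.array(v, dtype=float) / np.linalg.norm(v) for v in verts]
    for _ in range(subdivisions):
        midpoint_cache: dict[tuple[int, int], int] = {}

        def midpoint(i: int, j: int) -> int:
            key = (min(i, j), max(i, j))
            if key not in midpoint_cache:
                m = verts[i] + verts[j]
                verts.append(m / np.linalg.norm(m))
                midpoint_cache[key] = len(verts) - 1
            return midpoint_cache[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
        faces = new_faces
    return np.array(verts)


def place_on_template(
    protomer: Protomer,
    template_complex: Conformer,
    receptor_chain_ids: tuple[str, str, str],
    seed_mapping: str = "sequence",
    trim_cutoff: float = 3.5,
) -> AssemblyModel:
    """Superpose one copy of ``protomer`` onto each of three receptor chains
    of a template complex.

    Non-receptor chains of the template (the ligand trimer) are carried into
    the result unmodified as ``extra_chains``.  Per-copy core-alignment RMSDs
    are recorded in ``metadata["per_copy_rmsd"]``.
    """
    if len(receptor_chain_ids) != 3:
        raise ValueError("a trimeric template needs exactly 3 receptor chains")
    copies, rmsds = [], []
    for k, cid in enumerate(receptor_chain_ids):
        tpl_chain = template_complex.chain(cid)  # KeyError if absent
        aln = core_align(protomer, tpl_chain, seed_mapping=seed_mapping,
                         trim_cutoff=trim_cutoff)
        copy = apply_transform(protomer, aln.transform)
        copy.chain_id = "ABC"[k]
        copies.append(copy)
        rmsds.append(aln.rmsd)
    ligands = [
        p for p in template_complex.protomers if p.chain_id not in receptor_chain_ids
    ]
    return AssemblyModel(
        protomers=copies,
        extra_chains=ligands,
        metadata={"per_copy_rmsd": rmsds,
                  "template_chains": tuple(receptor_chain_ids)},
    )


def _apply_move(protomer: Protomer, move: HingeMove) -> Protomer:
    file_span = move.domain_span.in_scheme("file", protomer.numbering)
    pivot = protomer.ca_of(move.hinge_residue)
    R = Rotation.from_rotvec(np.radians(move.angle) * move.axis).as_matrix()
    new_atoms = []
    for num, atom_dict in zip(protomer.residue_numbers, protomer.atoms):
        if int(num) in file_span:
            new_atoms.append(
                {n: R @ (p - pivot) + pivot for n, p in atom_dict.items()}
            )
        else:
            new_atoms.append(dict(atom_dict))
    return replace(protomer, atoms=new_atoms)


def hinge_rotate(
    protomer: Protomer,
    search: HingeSearch,
    target_point: np.ndarray,
    anchor_residue: int,
) -> tuple[Protomer, HingeMove, float]:
    """Rigidly rotate ``domain_span`` about the hinge to bring the anchor
    residue's Cα as close as possible to ``target_point``.

    The search is an exhaustive deterministic scan over icosahedral axis
    directions × angle grid (the identity move is always included, so the
    achieved distance never exceeds the initial one).  Ties are broken by
    smaller |angle|, then by axis order.  Returns the moved protomer, the
    best move and the achieved distance.
    """
    span = search.domain_span.in_scheme("file", protomer.numbering)
    in_span = np.array([int(n) in span for n in protomer.residue_numbers])
    if in_span.all():
        raise ValueError(
            "domain_span covers the whole chain; hinge rotation is degenerate"
        )
    if not in_span.any():
        raise ValueError("domain_span contains no residues of the protomer")
    target = np.asarray(target_point, dtype=float)
    pivot = protomer.ca_of(search.hinge_residue)
    anchor = protomer.ca_of(anchor_residue)
    if anchor_residue not in span:
        raise ValueError("anchor residue must lie inside domain_span")

    lo, hi = search.angle_range
    angles = np.arange(lo, hi + 0.5 * search.angle_step, search.angle_step)
    axes = icosphere_directions(search.subdivisions)
    rel = anchor - pivot

    # vectorized objective: anchor position under every (axis, angle);
    # the identity move seeds the search, so achieved ≤ initial always
    dist, angle, axis = float(np.linalg.norm(anchor - target)), 0.0, np.array([0.0, 0.0, 1.0])
    best_key = (dist, 0.0)
    for ax in axes:
        rotvecs = np.radians(angles)[:, None] * ax[None, :]
        pts = Rotation.from_rotvec(rotvecs).apply(rel) + pivot
        dists = np.linalg.norm(pts - target, axis=1)
        i = int(np.lexsort((np.abs(angles), dists))[0])
        key = (float(dists[i]), float(abs(angles[i])))
        if key < best_key:
            best_key = key
            dist, angle, axis = float(dists[i]), float(angles[i]), ax
    move = HingeMove(search.hinge_residue, search.domain_span, axis, angle)
    return _apply_move(protomer, move), move, dist


def residue_pair_distance(
    a: Protomer, residue_a: int, b: Protomer, residue_b: int, scheme: str = "file"
) -> float:
    """Cα–Cα distance between one residue of each of two chains (e.g. a
    receptor/ligand contact of interest on a Holo assembly)."""
    return float(np.linalg.norm(a.ca_of(residue_a, scheme) - b.ca_of(residue_b, scheme)))
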