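"""Synthetic structures with known ground truth.

Every stage of the pipeline can be exercised offline with generated inputs
that emulate the shapes encountered in real receptor modeling: a lone
protomer with an internal unresolved span and a homolog covering it, a
C3-symmetric transmembrane-like helix bundle with known radius/tilt/phase,
a multi-conformer ensemble whose core is rigid while the termini fray, and
a two-domain chain related to its reference by a recorded hinge move.  All
generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

from .assembly import AssemblyModel, PoseParams, replicate_c3
from .holo import HingeMove, _apply_move
from .structure_io import Conformer, Ensemble, NumberingMap, Protomer, RegionSpan

__all__ = [
    "make_ideal_helix",
    "make_ridged_helix",
    "make_c3_bundle",
    "make_packed_bundle",
    "make_noisy_ensemble",
    "make_gapped_pair",
    "make_two_domain",
]

# canonical α-helix parameters
HELIX_RISE = 1.5
HELIX_TWIST = 100.0
HELIX_RADIUS = 2.3

_AA3 = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR "
    "TRP TYR VAL"
).split()


def _protomer_from_ca(
    ca: np.ndarray,
    chain_id: str = "A",
    start_number: int = 1,
    numbering: NumberingMap | None = None,
) -> Protomer:
    n = len(ca)
    return Protomer(
        chain_id=chain_id,
        residue_numbers=np.arange(start_number, start_number + n),
        residue_names=["ALA"] * n,
        atoms=[{"CA": np.asarray(p, dtype=float)} for p in ca],
        numbering=numbering or NumberingMap(),
    )


def make_ideal_helix(
    n_residues: int,
    rise: float = HELIX_RISE,
    twist: float = HELIX_TWIST,
    radius: float = HELIX_RADIUS,
    tilt: float = 0.0,
    azimuth: float = 0.0,
    chain_id: str = "A",
    start_number: int = 1,
) -> Protomer:
    """Cα trace of an ideal α-helix whose axis starts along z, then is
    tilted by ``tilt`` degrees (about y) and swung by ``azimuth`` degrees
    (about z).  ``radius=0`` degenerates to a straight axial trace, handy
    when a closed-form ring distance is wanted.  Deterministic (no seed)."""
    if n_residues < 4:
        raise ValueError("a helix needs ≥ 4 residues")
    k = np.arange(n_residues)
    theta = np.radians(twist * k)
    ca = np.column_stack([radius * np.cos(theta), radius * np.sin(theta), rise * k])
    ca -= ca.mean(axis=0)
    R = Rotation.from_euler("zy", [azimuth, tilt], degrees=True).as_matrix()
    return _protomer_from_ca(ca @ R.T, chain_id, start_number)


def make_ridged_helix(
    n_residues: int = 18,
    bump: float = 2.0,
    knob_phase: float = 0.0,
    chain_id: str = "A",
    start_number: int = 1,
) -> Protomer:
    """Ideal helix with one knobby face: residues whose azimuth lies within
    ~20° of ``knob_phase`` protrude ``bump`` Å beyond the backbone radius,
    mimicking a ridge of large side chains.  Unlike a smooth cylinder, such
    a helix packs into a bundle at a unique spin angle, which makes it the
    right protomer for docking-recovery fixtures."""
    k = np.arange(n_residues)
    theta = np.radians(HELIX_TWIST * k)
    radius = HELIX_RADIUS + bump * (
        np.cos(theta - np.radians(knob_phase)) > 0.94
    )
    ca = np.column_stack(
        [radius * np.cos(theta), radius * np.sin(theta), HELIX_RISE * k]
    )
    ca -= ca.mean(axis=0)
    return _protomer_from_ca(ca, chain_id, start_number)


def make_packed_bundle(
    n_residues: int = 18,
    knob_phase: float = 0.0,
    bump: float = 2.0,
    alpha_step: float = 15.0,
    radial_range: tuple[float, float] = (3.0, 11.0),
    radial_step: float = 2.0,
    contact_shell: float = 8.0,
    clash_cutoff: float = 4.0,
    w_clash: float = 10.0,
) -> AssemblyModel:
    """C3 bundle of ridged helices planted at its *packing pose*.

    The generator performs its own brute-force geometric packing search
    (plain all-pairs distance loops, independent of the assembly module):
    over the spin/radius grid it finds the pose with the best
    contacts − w·clashes balance — the tightest clash-free, most buried
    arrangement, i.e. the bundle's dominant interface.  The chosen pose is
    recorded in ``metadata["true_pose"]`` so that a search over the same
    grid can be asked to recover it.
    """
    from scipy.spatial.distance import cdist

    helix = make_ridged_helix(n_residues, bump=bump, knob_phase=knob_phase)
    local = helix.ca - helix.ca.mean(axis=0)
    R120 = Rotation.from_euler("z", 120, degrees=True).as_matrix()
    R240 = Rotation.from_euler("z", 240, degrees=True).as_matrix()
    best = None
    for a in np.arange(0.0, 360.0, alpha_step):
        Ra = Rotation.from_euler("z", a, degrees=True).as_matrix()
        for r in np.arange(radial_range[0], radial_range[1] + 0.5 * radial_step,
                           radial_step):
            base = local @ Ra.T + np.array([r, 0.0, 0.0])
            chains = (base, base @ R120.T, base @ R240.T)
            contacts = clashes = 0
            for i in range(3):
                for j in range(i + 1, 3):
                    d = cdist(chains[i], chains[j])
                    contacts += int(np.count_nonzero(d <= contact_shell))
                    clashes += int(np.count_nonzero(d <= clash_cutoff))
            score = contacts - w_clash * clashes
            key = (-score, clashes, (float(a), 0.0, 0.0, float(r), 0.0))
            if best is None or key < best[0]:
                best = (key, PoseParams((float(a), 0.0, 0.0), float(r), 0.0))
    pose = best[1]
    model = replicate_c3(helix, pose)
    model.metadata["true_pose"] = pose
    model.metadata["protomer"] = helix
    return model


def make_c3_bundle(
    n_residues: int = 24,
    ring_radius: float = 8.0,
    tilt: float = 0.0,
    phase: float = 0.0,
    axial_shift: float = 0.0,
    helix_radius: float = HELIX_RADIUS,
    start_number: int = 1,
) -> AssemblyModel:
    """C3 bundle of ideal helices with its generating pose recorded.

    The single helix is built axis-along-z and centered, then posed with
    Euler angles (phase about z, tilt about y, 0) at ``ring_radius`` from
    the C3 axis.  For ``helix_radius=0`` and ``tilt=0`` every residue ring
    distance equals ``ring_radius·√3`` exactly.
    """
    helix = make_ideal_helix(
        n_residues, radius=helix_radius, start_number=start_number
    )
    pose = PoseParams(euler=(phase, tilt, 0.0), radial_offset=ring_radius,
                      axial_offset=axial_shift)
    model = replicate_c3(helix, pose)
    model.metadata["true_pose"] = pose
    model.metadata["protomer"] = helix
    return model


def make_noisy_ensemble(
    bundle: AssemblyModel,
    n_conformers: int = 15,
    sigma_core: float = 0.2,
    sigma_end: float = 2.0,
    core_span: tuple[int, int] | None = None,
    seed: int = 0,
) -> Ensemble:
    """Ensemble of conformers of a bundle with rigid-core/floppy-end noise.

    Isotropic Gaussian displacement is applied per atom; its σ equals
    ``sigma_core`` inside ``core_span`` (residue numbers, inclusive;
    default: central third) and ramps linearly up to ``sigma_end`` at the
    chain termini — the flexibility profile typical of a membrane-embedded
    helix bundle solved by NMR.  The default of 15 conformers matches the
    usual size of deposited NMR ensembles.
    """
    if not (0 <= sigma_core <= sigma_end):
        raise ValueError("need 0 ≤ sigma_core ≤ sigma_end")
    rng = np.random.default_rng(seed)
    ref = bundle.protomers[0].residue_numbers
    if core_span is None:
        lo = int(ref[len(ref) // 3])
        hi = int(ref[2 * len(ref) // 3])
    else:
        lo, hi = core_span
    first, last = int(ref[0]), int(ref[-1])

    def sigma_of(num: int) -> float:
        if lo <= num <= hi:
            return sigma_core
        if num < lo:
            frac = (lo - num) / max(lo - first, 1)
        else:
            frac = (num - hi) / max(last - hi, 1)
        return sigma_core + frac * (sigma_end - sigma_core)

    conformers = []
    for _ in range(n_conformers):
        protomers = []
        for p in bundle.protomers:
            atoms = []
            for num, atom_dict in zip(p.residue_numbers, p.atoms):
                s = sigma_of(int(num))
                atoms.append(
                    {n: pos + rng.normal(0.0, s, size=3) if s > 0 else pos.copy()
                     for n, pos in atom_dict.items()}
                )
            protomers.append(
                Protomer(p.chain_id, p.residue_numbers.copy(),
                         list(p.residue_names), atoms, p.numbering)
            )
        conformers.append(Conformer(protomers))
    return Ensemble(conformers)


def _smooth_chain(n: int, seed: int, fold: str = "coil") -> np.ndarray:
    """Random smooth Cα trace with 3.8 Å virtual bonds.

    ``fold="coil"`` turns freely (a compact globular-ish blob);
    ``fold="rod"`` biases every step along +z, giving the elongated shape of
    a stacked-domain receptor ectodomain.  No self-avoidance is enforced.
    """
    rng = np.random.default_rng(seed)
    if fold == "rod":
        # straight superhelical trace (non-accumulating noise): compact and
        # elongated along z, like stacked extracellular modules
        R, dtheta = 2.5, 60.0
        chord = 2 * R * np.sin(np.radians(dtheta / 2))
        rise = np.sqrt(3.8**2 - chord**2)
        k = np.arange(n)
        theta = np.radians(dtheta * k) + rng.uniform(0, 2 * np.pi)
        pts = np.column_stack(
            [R * np.cos(theta), R * np.sin(theta), rise * k]
        ) + rng.normal(0.0, 0.15, size=(n, 3))
        return pts
    direction = np.array([1.0, 0.0, 0.0])
    pts = [np.zeros(3)]
    for _ in range(n - 1):
        step = direction + 0.45 * rng.normal(size=3)
        direction = step / np.linalg.norm(step)
        pts.append(pts[-1] + 3.8 * direction)
    return np.array(pts)


def make_gapped_pair(
    protein_length: int = 80,
    deleted_span: tuple[int, int] = (40, 55),
    seed: int = 0,
    offset: bool = True,
    fold: str = "coil",
) -> tuple[Protomer, Protomer]:
    """(target-with-gap, full template) pair from one synthetic fold.

    The template is a smooth random chain; the target is the same chain with
    ``deleted_span`` (residue numbers, inclusive) removed and, when
    ``offset`` is set, displaced by a rigid motion so that completion must
    actually superpose rather than copy.  The span must be internal."""
    lo, hi = deleted_span
    if lo <= 1 or hi >= protein_length:
        raise ValueError("deleted span must be internal to the chain")
    if lo > hi:
        raise ValueError("deleted span is empty")
    ca = _smooth_chain(protein_length, seed, fold)
    # a varied sequence keeps sequence-seeded alignment informative
    names_rng = np.random.default_rng(seed + 3)
    names = [
        _AA3[i] for i in names_rng.integers(0, len(_AA3), size=protein_length)
    ]
    template = Protomer(
        "T", np.arange(1, protein_length + 1), list(names),
        [{"CA": p.copy()} for p in ca], NumberingMap(),
    )
    keep = [i for i in range(protein_length) if not (lo <= i + 1 <= hi)]
    target_ca = ca[keep]
    if offset:
        rng = np.random.default_rng(seed + 1)
        R = Rotation.from_rotvec(rng.normal(size=3)).as_matrix()
        t = rng.uniform(-20, 20, size=3)
        target_ca = target_ca @ R.T + t
    target = Protomer(
        "A",
        np.array([i + 1 for i in keep]),
        [names[i] for i in keep],
        [{"CA": p.copy()} for p in target_ca],
        NumberingMap(),
    )
    return target, template


def make_two_domain(
    lengths: tuple[int, int] = (20, 20),
    hinge_angle: float = 35.0,
    seed: int = 0,
) -> tuple[Protomer, Protomer, HingeMove]:
    """Two rigid segments joined at a hinge, with the recorded move applied.

    Returns ``(bent, straight_reference, move)``: the reference is a single
    smooth chain; ``bent`` has its second domain rotated by ``hinge_angle``
    degrees about a seeded axis through the hinge residue's Cα.  Inverting
    the move recovers the reference."""
    n1, n2 = lengths
    ref = _protomer_from_ca(_smooth_chain(n1 + n2, seed))
    rng = np.random.default_rng(seed + 7)
    # axis drawn from the icosahedral direction set, so the exact inverse
    # move lies inside the deterministic hinge-search space
    from .holo import icosphere_directions

    dirs = icosphere_directions(2)
    axis = dirs[int(rng.integers(len(dirs)))]
    move = HingeMove(
        hinge_residue=n1,
        domain_span=RegionSpan(n1 + 1, n1 + n2, "file"),
        axis=axis,
        angle=float(hinge_angle),
    )
    return _apply_move(ref, move), ref, move
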