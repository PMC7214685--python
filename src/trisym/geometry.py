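"""Geometric analysis of trimeric assemblies.

These operations quantify the questions a symmetric-receptor model has to
answer: how wide is the ring of a given residue across the three protomers
(and how variable is it across an NMR ensemble); are the termini of a
candidate trimer "close" or "remote"; which residues form the
inter-protomer interface; can a short unresolved linker physically bridge
the ectodomain to the transmembrane bundle; how steeply is a protomer
tilted against the membrane; and does anything intrude into the membrane
slab that should not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .structure_io import Conformer, Ensemble, Protomer, RegionSpan

__all__ = [
    "RingStats",
    "TerminiClass",
    "BridgeVerdict",
    "RingCompatibility",
    "MembraneSlab",
    "ring_distance",
    "ensemble_ring_stats",
    "classify_termini",
    "interface_residues",
    "linker_bridge_feasible",
    "ring_compatibility",
    "tilt_angle",
    "membrane_violation",
]

#: default Å threshold separating "close" from "remote" termini rings;
#: chosen between the 14–21 Å ring distances of compact arrangements and the
#: ≥ 39 Å rings of splayed ones
CLOSE_THRESHOLD = 30.0

#: fully extended trans Cα–Cα virtual bond
PER_BOND_SPAN = 3.8
#: realistic (non-extended) effective span per bond
PER_BOND_SPAN_REALISTIC = 3.0


def _protomers(trimer) -> list[Protomer]:
    protomers = list(getattr(trimer, "protomers"))
    if len(protomers) < 2:
        raise ValueError("need an assembly of at least 2 protomers")
    return protomers


def ring_distance(trimer, residue: int, scheme: str = "file") -> float:
    """Mean pairwise inter-protomer Cα distance at one residue position.

    For a trimer this is the mean of the three pairwise distances.  Raises
    ``KeyError`` if any protomer lacks the residue.
    """
    pts = np.array([p.ca_of(residue, scheme) for p in _protomers(trimer)])
    n = len(pts)
    dists = [np.linalg.norm(pts[i] - pts[j]) for i in range(n) for j in range(i + 1, n)]
    return float(np.mean(dists))


@dataclass(frozen=True)
class RingStats:
    """Ring distance of one residue across an ensemble of trimer conformers."""

    residue: int
    scheme: str
    per_conformer: tuple[float, ...]
    mean: float
    sd: float


def ensemble_ring_stats(ensemble: Ensemble, residue: int, scheme: str = "file") -> RingStats:
    """Per-conformer ring distance plus mean and sample SD across conformers.

    The SD is taken across per-conformer means (n−1 denominator), so it
    measures conformational spread of the ring, not the within-conformer
    asymmetry.
    """
    values = [ring_distance(conf, residue, scheme) for conf in ensemble.conformers]
    if len(values) == 1:
        warnings.warn("single-conformer ensemble: sd reported as 0", stacklevel=2)
        sd = 0.0
    else:
        sd = float(np.std(values, ddof=1))
    return RingStats(residue, scheme, tuple(values), float(np.mean(values)), sd)


@dataclass(frozen=True)
class TerminiClass:
    """close/remote classification of both termini rings of a trimer."""

    nt_label: str
    ct_label: str
    nt_ring: float
    ct_ring: float
    threshold: float

    @property
    def label(self) -> str:
        return f"{self.nt_label} Nt/{self.ct_label} Ct"


def classify_termini(
    trimer,
    nt_residue: int,
    ct_residue: int,
    threshold: float = CLOSE_THRESHOLD,
    scheme: str = "file",
) -> TerminiClass:
    """Label each terminus ring ``close`` (ring ≤ threshold) or ``remote``."""
    nt = ring_distance(trimer, nt_residue, scheme)
    ct = ring_distance(trimer, ct_residue, scheme)
    lab = lambda r: "close" if r <= threshold else "remote"  # noqa: E731
    return TerminiClass(lab(nt), lab(ct), nt, ct, threshold)


def interface_residues(trimer, cutoff: float = 8.0) -> list[list[RegionSpan]]:
    """Per-protomer interface spans: residues with any inter-protomer Cα
    within ``cutoff`` (inclusive), merged into maximal spans tolerating a
    single-residue hole."""
    protomers = _protomers(trimer)
    coords = [p.ca for p in protomers]
    out: list[list[RegionSpan]] = []
    for i, p in enumerate(protomers):
        others = np.vstack([coords[j] for j in range(len(protomers)) if j != i])
        near = (cdist(coords[i], others) <= cutoff).any(axis=1)
        nums = p.residue_numbers[near]
        spans: list[RegionSpan] = []
        if nums.size:
            start = prev = int(nums[0])
            for n in map(int, nums[1:]):
                if n - prev <= 2:  # merge across holes of ≤ 1 residue
                    prev = n
                else:
                    spans.append(RegionSpan(start, prev, "file"))
                    start = prev = n
            spans.append(RegionSpan(start, prev, "file"))
        out.append(spans)
    return out


@dataclass(frozen=True)
class BridgeVerdict:
    """Can ``n_missing`` residues bridge two anchor points?"""

    n_missing: int
    required_span: float
    max_span: float

    @property
    def feasible(self) -> bool:
        return self.required_span <= self.max_span

    @property
    def slack(self) -> float:
        return self.max_span - self.required_span


def linker_bridge_feasible(
    n_missing: int,
    anchor_a: np.ndarray,
    anchor_b: np.ndarray,
    per_bond_span: float = PER_BOND_SPAN,
) -> BridgeVerdict:
    """Geometric feasibility of a missing linker.

    ``n_missing`` absent residues between two anchored ones contribute
    ``n_missing + 1`` Cα virtual bonds, hence a maximal reach of
    ``(n_missing + 1) · per_bond_span``.  The verdict compares that reach
    with the anchor separation.
    """
    if n_missing < 0:
        raise ValueError("n_missing must be ≥ 0")
    if per_bond_span <= 0:
        raise ValueError("per_bond_span must be > 0")
    required = float(np.linalg.norm(np.asarray(anchor_a, float) - np.asarray(anchor_b, float)))
    return BridgeVerdict(n_missing, required, (n_missing + 1) * per_bond_span)


@dataclass(frozen=True)
class RingCompatibility:
    """Compatibility of two ring widths within a tolerance."""

    ring_a: float
    ring_b: float
    tolerance: float

    @property
    def mismatch(self) -> float:
        return abs(self.ring_a - self.ring_b)

    @property
    def compatible(self) -> bool:
        return self.mismatch <= self.tolerance


def ring_compatibility(ring_a: float, ring_b: float, tolerance: float = 5.0) -> RingCompatibility:
    """Whether two stacked rings (e.g. ectodomain Ct ring vs TM Nt ring) can
    face each other: |ring_a − ring_b| ≤ tolerance."""
    if ring_a < 0 or ring_b < 0:
        raise ValueError("ring distances must be ≥ 0")
    return RingCompatibility(float(ring_a), float(ring_b), float(tolerance))


@dataclass(frozen=True)
class MembraneSlab:
    """Membrane represented by two parallel planes perpendicular to
    ``normal`` at signed offsets ``outer_z`` > ``inner_z`` (Å).  The default
    30 Å thickness is a hypothesis, not a measurement."""

    normal: np.ndarray = (0.0, 0.0, 1.0)
    outer_z: float = 15.0
    inner_z: float = -15.0

    def __post_init__(self):
        n = np.asarray(self.normal, dtype=float)
        norm = np.linalg.norm(n)
        if norm == 0:
            raise ValueError("normal must be non-zero")
        if self.outer_z <= self.inner_z:
            raise ValueError("outer_z must exceed inner_z")
        object.__setattr__(self, "normal", n / norm)


def tilt_angle(protomer: Protomer, slab: MembraneSlab, axis_method: str = "inertia") -> float:
    """Angle (degrees, folded into [0°, 90°]) between the protomer's
    principal axis and the membrane normal.

    ``axis_method="inertia"`` uses the dominant principal component of the
    Cα cloud; for nearly isotropic shapes this axis is undefined and a
    method error suggests ``"termini_vector"`` (straight line from first to
    last residue) instead.
    """
    ca = protomer.ca
    if len(ca) < 3:
        raise ValueError("tilt needs ≥ 3 residues")
    if axis_method == "inertia":
        centered = ca - ca.mean(axis=0)
        evals, evecs = np.linalg.eigh(centered.T @ centered)
        if evals[2] < 1.5 * evals[1]:
            raise ValueError(
                "principal axis is degenerate (near-spherical inertia); "
                "use axis_method='termini_vector'"
            )
        axis = evecs[:, 2]
    elif axis_method == "termini_vector":
        axis = ca[-1] - ca[0]
        if np.linalg.norm(axis) == 0:
            raise ValueError("termini coincide; axis undefined")
    else:
        raise ValueError("axis_method must be 'inertia' or 'termini_vector'")
    axis = axis / np.linalg.norm(axis)
    cosang = abs(float(np.dot(axis, slab.normal)))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def membrane_violation(
    trimer,
    slab: MembraneSlab,
    allowed_spans: list[RegionSpan] | None = None,
) -> list[tuple[str, int]]:
    """Residues whose Cα lies inside the slab without belonging to an
    allowed span (e.g. the declared TM span).  Returns (chain_id,
    residue_number) pairs; spans are interpreted in each protomer's file
    scheme via its numbering map."""
    allowed_spans = allowed_spans or []
    offenders: list[tuple[str, int]] = []
    for p in _protomers(trimer):
        file_spans = [s.in_scheme("file", p.numbering) for s in allowed_spans]
        z = p.ca @ slab.normal
        inside = (z > slab.inner_z) & (z < slab.outer_z)
        for num in map(int, p.residue_numbers[inside]):
            if not any(num in s for s in file_spans):
                offenders.append((p.chain_id, num))
    return offenders
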