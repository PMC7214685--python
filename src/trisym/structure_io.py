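"""Structure I/O, residue numbering schemes and gap detection.

Single-pass receptors of the TNF-receptor family are numbered in three
coexisting coordinate systems: the *file* numbering of a deposited PDB/mmCIF
entry, the *precursor* numbering of the full translated sequence, and the
*mature* numbering obtained after removing the signal peptide (16 residues
for CD95).  Literature positions freely alternate between precursor and
mature numbering, so every residue reference in this package carries an
explicit scheme tag and conversions go through :class:`NumberingMap`.

Parsing and writing of PDB/mmCIF is delegated to :mod:`gemmi`; this module
reduces structures to ordered C-alpha traces (:class:`Protomer`) grouped into
conformers and ensembles, which is the representation every downstream
geometric operation consumes.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

SCHEMES = ("file", "precursor", "mature")

__all__ = [
    "AtomSite",
    "NumberingMap",
    "RegionSpan",
    "Protomer",
    "Conformer",
    "Ensemble",
    "StructureParseError",
    "TopologyError",
    "NumberingError",
    "read_structure",
    "write_structure",
    "map_numbering",
    "detect_gaps",
    "span_length",
    "parse_span",
]


class StructureParseError(ValueError):
    """Raised when a PDB/mmCIF source cannot be parsed."""


class TopologyError(ValueError):
    """Raised when conformers of an ensemble disagree in topology."""


class NumberingError(ValueError):
    """Raised for out-of-domain numbering conversions."""


@dataclass(frozen=True)
class AtomSite:
    """One atom record: chain, residue identity (file numbering) and position."""

    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    position: np.ndarray
    insertion_code: str = ""

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError("position must be a finite 3-vector")
        if not self.residue_name:
            raise ValueError("residue_name must be non-empty")
        object.__setattr__(self, "position", pos)


@dataclass(frozen=True)
class NumberingMap:
    """Invertible mapping among file, precursor and mature residue numbering.

    precursor = file + ``file_to_precursor_offset``;
    mature = precursor − ``signal_peptide_length`` (defined only past the
    signal peptide).  The default signal peptide length of 16 residues is the
    CD95 value.
    """

    signal_peptide_length: int = 16
    file_to_precursor_offset: int = 0

    def convert(self, position: int, src: str, dst: str) -> int:
        return map_numbering(position, src, dst, self)


@dataclass(frozen=True)
class RegionSpan:
    """Inclusive residue interval in a declared numbering scheme."""

    start: int
    end: int
    scheme: str = "precursor"

    def __post_init__(self):
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown numbering scheme {self.scheme!r}")
        if self.start > self.end:
            raise ValueError(f"span start {self.start} > end {self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end

    def in_scheme(self, dst: str, numbering: NumberingMap) -> "RegionSpan":
        return RegionSpan(
            map_numbering(self.start, self.scheme, dst, numbering),
            map_numbering(self.end, self.scheme, dst, numbering),
            dst,
        )


def span_length(span: RegionSpan) -> int:
    """Number of residues in an inclusive span (end − start + 1)."""
    return len(span)


def parse_span(text: str, default_scheme: str | None = None) -> RegionSpan:
    """Parse ``"start-end:scheme"`` (scheme optional if a default is given)."""
    if ":" in text:
        rng, scheme = text.rsplit(":", 1)
    elif default_scheme is not None:
        rng, scheme = text, default_scheme
    else:
        raise ValueError(
            f"span {text!r} lacks a numbering scheme tag (use start-end:scheme)"
        )
    try:
        start_s, end_s = rng.split("-")
        return RegionSpan(int(start_s), int(end_s), scheme)
    except ValueError as exc:
        raise ValueError(f"cannot parse span {text!r}: {exc}") from exc


def map_numbering(position: int, src: str, dst: str, numbering: NumberingMap) -> int:
    """Convert a residue position between numbering schemes.

    Raises :class:`NumberingError` for positions outside the destination
    scheme's domain (e.g. a signal-peptide residue mapped to mature
    numbering, where it has no coordinate).
    """
    for scheme in (src, dst):
        if scheme not in SCHEMES:
            raise NumberingError(f"unknown numbering scheme {scheme!r}")
    if src == "mature" and position < 1:
        raise NumberingError(f"mature position {position} < 1")
    # through the precursor scheme as the hub
    if src == "file":
        precursor = position + numbering.file_to_precursor_offset
    elif src == "mature":
        precursor = position + numbering.signal_peptide_length
    else:
        precursor = position
    if dst == "file":
        return precursor - numbering.file_to_precursor_offset
    if dst == "mature":
        mature = precursor - numbering.signal_peptide_length
        if mature < 1:
            raise NumberingError(
                f"precursor position {precursor} lies in the signal peptide "
                f"(length {numbering.signal_peptide_length}); no mature coordinate"
            )
        return mature
    return precursor


@dataclass
class Protomer:
    """Ordered C-alpha trace of one chain.

    ``residue_numbers`` are in the file scheme and strictly increasing;
    ``atoms`` holds, per residue, a dict of atom name → 3-vector that always
    contains ``"CA"``.  ``numbering`` relates file numbering to precursor and
    mature schemes.
    """

    chain_id: str
    residue_numbers: np.ndarray
    residue_names: list[str]
    atoms: list[dict[str, np.ndarray]]
    numbering: NumberingMap = field(default_factory=NumberingMap)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        n = len(self.residue_numbers)
        if not (len(self.residue_names) == len(self.atoms) == n):
            raise ValueError("residue arrays must have equal length")
        if n and np.any(np.diff(self.residue_numbers) <= 0):
            raise ValueError(
                f"residue numbers of chain {self.chain_id} are not strictly increasing"
            )
        for i, d in enumerate(self.atoms):
            if "CA" not in d:
                raise ValueError(
                    f"residue {self.residue_numbers[i]} of chain {self.chain_id} lacks a CA"
                )

    def __len__(self) -> int:
        return len(self.residue_numbers)

    @property
    def ca(self) -> np.ndarray:
        """N×3 array of C-alpha coordinates in residue order."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([d["CA"] for d in self.atoms], dtype=float)

    def index_of(self, residue_number: int) -> int:
        idx = np.searchsorted(self.residue_numbers, residue_number)
        if idx >= len(self) or self.residue_numbers[idx] != residue_number:
            raise KeyError(
                f"residue {residue_number} not present in chain {self.chain_id}"
            )
        return int(idx)

    def ca_of(self, residue_number: int, scheme: str = "file") -> np.ndarray:
        num = map_numbering(residue_number, scheme, "file", self.numbering)
        return self.atoms[self.index_of(num)]["CA"]

    def sequence(self) -> str:
        """One-letter sequence (X for non-standard residues)."""
        return "".join(_THREE_TO_ONE.get(name, "X") for name in self.residue_names)

    def with_coordinates(self, transform_fn) -> "Protomer":
        """Protomer with every atom position mapped through ``transform_fn``."""
        new_atoms = [
            {name: transform_fn(pos) for name, pos in d.items()} for d in self.atoms
        ]
        return replace(self, atoms=new_atoms)

    def subset(self, residue_numbers) -> "Protomer":
        idx = [self.index_of(int(r)) for r in residue_numbers]
        return replace(
            self,
            residue_numbers=self.residue_numbers[idx],
            residue_names=[self.residue_names[i] for i in idx],
            atoms=[self.atoms[i] for i in idx],
        )


_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U", "PYL": "O",
}
ONE_TO_THREE = {v: k for k, v in reversed(_THREE_TO_ONE.items())}


@dataclass
class Conformer:
    """One model of a (possibly multi-chain) structure."""

    protomers: list[Protomer]

    def chain(self, chain_id: str) -> Protomer:
        for p in self.protomers:
            if p.chain_id == chain_id:
                return p
        raise KeyError(f"no chain {chain_id!r} in conformer")

    @property
    def chain_ids(self) -> list[str]:
        return [p.chain_id for p in self.protomers]

    def fingerprint(self) -> tuple:
        return tuple(
            (p.chain_id, tuple(int(n) for n in p.residue_numbers),
             tuple(tuple(sorted(d)) for d in p.atoms))
            for p in self.protomers
        )


@dataclass
class Ensemble:
    """Conformers sharing one topology (e.g. the models of an NMR entry)."""

    conformers: list[Conformer]

    def __post_init__(self):
        if not self.conformers:
            raise ValueError("ensemble requires at least one conformer")
        ref = self.conformers[0].fingerprint()
        for i, conf in enumerate(self.conformers[1:], start=2):
            if conf.fingerprint() != ref:
                raise TopologyError(
                    f"conformer {i} topology differs from conformer 1"
                )

    def __len__(self) -> int:
        return len(self.conformers)

    @property
    def topology_fingerprint(self) -> tuple:
        return self.conformers[0].fingerprint()


# ---------------------------------------------------------------------------
# reading


def _looks_like_cif(text: str) -> bool:
    head = text.lstrip()[:4000]
    return head.startswith("data_") or "_atom_site." in head


def _gemmi_structure(source: str | os.PathLike) -> gemmi.Structure:
    if isinstance(source, os.PathLike) or (
        isinstance(source, str) and "\n" not in source and os.path.exists(source)
    ):
        try:
            return gemmi.read_structure(os.fspath(source))
        except (RuntimeError, ValueError) as exc:
            raise StructureParseError(f"cannot parse {source}: {exc}") from exc
    text = str(source)
    try:
        if _looks_like_cif(text):
            block = gemmi.cif.read_string(text).sole_block()
            return gemmi.make_structure_from_block(block)
        return gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse structure content: {exc}") from exc


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins, ties go to the first listed
    return max(atoms, key=lambda a: a.occ)


def _protomer_from_chain(
    chain: gemmi.Chain, numbering: NumberingMap, include_het: bool
) -> Protomer | None:
    numbers: list[int] = []
    names: list[str] = []
    atoms: list[dict[str, np.ndarray]] = []
    seen: set[tuple[int, str]] = set()
    for res in chain:
        if res.het_flag == "H" and not (include_het and res.name == "MSE"):
            continue
        key = (res.seqid.num, res.seqid.icode)
        if key in seen:
            continue
        seen.add(key)
        by_name: dict[str, list[gemmi.Atom]] = {}
        for atom in res:
            by_name.setdefault(atom.name, []).append(atom)
        if "CA" not in by_name:
            logger.warning(
                "dropping residue %s%d of chain %s: no CA atom",
                res.name, res.seqid.num, chain.name,
            )
            continue
        if numbers and res.seqid.num <= numbers[-1]:
            # insertion codes or duplicated numbers cannot enter the ordered
            # trace; keep the first occurrence only
            logger.warning(
                "dropping residue %s%d%s of chain %s: non-increasing numbering",
                res.name, res.seqid.num, res.seqid.icode.strip(), chain.name,
            )
            continue
        numbers.append(res.seqid.num)
        names.append(res.name)
        atoms.append(
            {
                name: np.array(
                    [(a := _pick_altloc(group)).pos.x, a.pos.y, a.pos.z], dtype=float
                )
                for name, group in by_name.items()
            }
        )
    if not numbers:
        return None
    return Protomer(chain.name, np.array(numbers), names, atoms, numbering)


def read_structure(
    source: str | os.PathLike,
    model_policy: str = "all",
    numbering: NumberingMap | None = None,
) -> Ensemble:
    """Read a PDB or mmCIF source into an :class:`Ensemble` of C-alpha traces.

    Parameters
    ----------
    source:
        Path to a file, or the file content itself (PDB or mmCIF text).
    model_policy:
        ``"all"`` keeps one conformer per MODEL record; ``"first"`` keeps
        only the first model.
    numbering:
        Numbering map attached to every protomer (default: identity offset,
        CD95 signal-peptide length).

    Heteroatom residues are excluded (selenomethionine is retained); residues
    without a C-alpha are dropped with a warning; for alternate locations the
    highest-occupancy conformer is kept (ties: first listed).
    """
    if model_policy not in ("first", "all"):
        raise ValueError("model_policy must be 'first' or 'all'")
    numbering = numbering or NumberingMap()
    st = _gemmi_structure(source)
    if len(st) == 0:
        raise StructureParseError("no models in structure")
    models = [st[0]] if model_policy == "first" else list(st)
    conformers = []
    for model in models:
        protomers = [
            p
            for chain in model
            if (p := _protomer_from_chain(chain, numbering, include_het=True))
            is not None
        ]
        if not protomers:
            raise StructureParseError("model contains no polymer residues with CA")
        conformers.append(Conformer(protomers))
    return Ensemble(conformers)


# ---------------------------------------------------------------------------
# writing

_CHAIN_IDS = (
    "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
)


def write_structure(ensemble: Ensemble, path: str | os.PathLike | None = None) -> str:
    """Serialize an ensemble to PDB text (optionally also write to ``path``).

    Multi-conformer ensembles are emitted as MODEL/ENDMDL blocks; chains keep
    their IDs.  PDB's one-character chain field limits output to 62 chains.
    """
    n_chains = len(ensemble.conformers[0].protomers)
    if n_chains > len(_CHAIN_IDS):
        raise ValueError(f"PDB output supports at most {len(_CHAIN_IDS)} chains")
    st = gemmi.Structure()
    for i, conf in enumerate(ensemble.conformers, start=1):
        model = gemmi.Model(i)
        for j, prot in enumerate(conf.protomers):
            cid = prot.chain_id if len(prot.chain_id) == 1 else _CHAIN_IDS[j]
            chain = gemmi.Chain(cid)
            for num, name, atom_dict in zip(
                prot.residue_numbers, prot.residue_names, prot.atoms
            ):
                res = gemmi.Residue()
                res.name = name
                res.seqid = gemmi.SeqId(int(num), " ")
                for atom_name in sorted(atom_dict, key=lambda n: (n != "CA", n)):
                    atom = gemmi.Atom()
                    atom.name = atom_name
                    pos = atom_dict[atom_name]
                    atom.pos = gemmi.Position(*map(float, pos))
                    atom.element = gemmi.Element(atom_name[:1])
                    res.add_atom(atom)
                chain.add_residue(res)
            model.add_chain(chain)
        st.add_model(model)
    text = st.make_pdb_string()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


# ---------------------------------------------------------------------------
# gaps


def detect_gaps(protomer: Protomer) -> list[RegionSpan]:
    """Maximal runs of absent residue numbers between the first and last
    observed residues, sorted; empty list if the trace is contiguous.

    Spans are reported in the file numbering scheme.
    """
    if len(protomer) == 0:
        raise ValueError("protomer is empty")
    nums = protomer.residue_numbers
    spans = []
    for prev, nxt in zip(nums[:-1], nums[1:]):
        if nxt > prev + 1:
            spans.append(RegionSpan(int(prev) + 1, int(nxt) - 1, "file"))
    return spans
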