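"""Atomic structure I/O and geometry.

Reads and writes PDB-format coordinate files (via :mod:`gemmi`), assigns
hard-sphere radii for projection-approximation CCS calculations, and computes
the basic geometric observables used as equilibration indicators: the radius
of gyration (Rg) and the unfitted coordinate RMSD.

Structures are stored column-wise (a list of element symbols plus an (N, 3)
coordinate array in Å) so that downstream Monte-Carlo projection code can
operate on contiguous arrays.
"""

from __future__ import annotations

import io
import json
import logging
import os
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping

import gemmi
import numpy as np

logger = logging.getLogger("twimsccs")

__all__ = [
    "Atom",
    "Structure",
    "RadiusTable",
    "DEFAULT_RADIUS_TABLE",
    "PdbParseError",
    "ModelNotFoundError",
    "read_pdb",
    "write_pdb",
    "assign_radii",
    "radius_of_gyration",
    "rmsd",
]


class PdbParseError(ValueError):
    """Raised when a PDB source contains no usable ATOM/HETATM records."""


class ModelNotFoundError(KeyError):
    """Raised when the requested MODEL index is absent from a PDB file."""


@dataclass(frozen=True)
class Atom:
    """A single atom: element symbol, coordinates in Å, hard-sphere radius in Å.

    ``radius`` is ``None`` until assigned from a :class:`RadiusTable`.
    """

    element: str
    x: float
    y: float
    z: float
    radius: float | None = None


@dataclass
class Structure:
    """An ordered collection of atoms sharing one coordinate frame.

    Parameters
    ----------
    id : str
        Free-text identifier (PDB id, file stem, or synthetic label).
    elements : list of str
        Element symbol per atom, in file order.
    coords : (N, 3) ndarray
        Cartesian coordinates in Å.
    radii : (N,) ndarray or None
        Hard-sphere radii in Å; ``None`` until :func:`assign_radii` runs.
    model_index : int
        Which MODEL of a multi-model file these atoms came from (1-based).
    """

    id: str
    elements: list[str]
    coords: np.ndarray
    radii: np.ndarray | None = None
    model_index: int = 1

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_atoms, 3)")
        if len(self.elements) != len(self.coords):
            raise ValueError("elements and coords length mismatch")
        if len(self.coords) == 0:
            raise ValueError("a Structure must contain at least one atom")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.radii is not None:
            self.radii = np.asarray(self.radii, dtype=float)
            if self.radii.shape != (len(self.coords),):
                raise ValueError("radii must be one value per atom")
            if np.any(self.radii <= 0):
                raise ValueError("radii must be positive")
        if self.model_index < 1:
            raise ValueError("model_index is 1-based")

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def atoms(self) -> Iterator[Atom]:
        """Row-wise view of the structure as :class:`Atom` records."""
        for i, el in enumerate(self.elements):
            r = None if self.radii is None else float(self.radii[i])
            yield Atom(el, *map(float, self.coords[i]), radius=r)

    def translated(self, shift) -> "Structure":
        return replace(self, coords=self.coords + np.asarray(shift, dtype=float))

    def rotated(self, rotation_matrix) -> "Structure":
        R = np.asarray(rotation_matrix, dtype=float)
        return replace(self, coords=self.coords @ R.T)


@dataclass(frozen=True)
class RadiusTable:
    """Element → hard-sphere radius (Å) with a fallback for unlisted elements."""

    radii: Mapping[str, float] = field(default_factory=dict)
    default_radius: float = 2.7

    def __post_init__(self) -> None:
        if self.default_radius <= 0 or any(r <= 0 for r in self.radii.values()):
            raise ValueError("all radii must be positive")

    def lookup(self, element: str) -> float:
        key = element.capitalize()
        try:
            return float(self.radii[key])
        except KeyError:
            logger.warning(
                "element %r not in radius table; using default %.3f Å",
                element, self.default_radius,
            )
            return float(self.default_radius)

    @classmethod
    def from_json(cls, source) -> "RadiusTable":
        """Load ``{"H": 2.2, ..., "default": 2.7}`` from a path or stream."""
        if hasattr(source, "read"):
            data = json.load(source)
        else:
            with open(source) as fh:
                data = json.load(fh)
        default = float(data.pop("default", 2.7))
        return cls({str(k).capitalize(): float(v) for k, v in data.items()}, default)


#: Hard-sphere radii used for projection-approximation CCS: hydrogens at
#: 2.2 Å, every heavier element at 2.3 Å inflated to 2.7 Å effective collision
#: radius, following common projection-approximation parameterisations.
DEFAULT_RADIUS_TABLE = RadiusTable({"H": 2.2}, default_radius=2.7)


def _as_pdb_text(source) -> tuple[str, str]:
    """Return (pdb_text, identifier) from a path, text stream, or raw string."""
    if hasattr(source, "read"):
        return source.read(), getattr(source, "name", "stream")
    text = str(source)
    if "\n" not in text and os.path.exists(text):
        with open(text) as fh:
            name = os.path.splitext(os.path.basename(text))[0]
            return fh.read(), name
    return text, "inline"


def read_pdb(
    source,
    model_index: int | None = None,
    *,
    include_waters: bool = False,
    include_hetero: bool = True,
    structure_id: str | None = None,
) -> Structure:
    """Read ATOM/HETATM records of one MODEL from PDB-format text.

    Parameters
    ----------
    source : path, text stream, or PDB-format string
    model_index : int, optional
        1-based MODEL number. Defaults to the first model, matching the
        convention of comparing against a single representative conformer
        of an NMR ensemble.
    include_waters : bool
        Keep residues named HOH. Off by default: crystallographic waters are
        not part of the gas-phase ion.
    include_hetero : bool
        Keep HETATM records other than water (ligands, ions).

    Raises
    ------
    PdbParseError
        If no ATOM/HETATM records survive filtering.
    ModelNotFoundError
        If ``model_index`` exceeds the number of MODELs present.

    Notes
    -----
    The element symbol comes from PDB columns 77–78 when present; otherwise
    it is inferred from the atom-name field (gemmi's name-based inference),
    which is the common situation for PDB frames written by MD packages.
    """
    text, inferred_id = _as_pdb_text(source)
    st = gemmi.read_pdb_string(text)
    if len(st) == 0:
        raise PdbParseError("no ATOM/HETATM records found in PDB source")
    if model_index is None:
        model_index = 1
    if model_index > len(st):
        raise ModelNotFoundError(
            f"model {model_index} not found ({len(st)} model(s) present)"
        )
    model = st[model_index - 1]

    elements: list[str] = []
    coords: list[tuple[float, float, float]] = []
    for chain in model:
        for res in chain:
            if res.name == "HOH" and not include_waters:
                continue
            if res.het_flag == "H" and res.name != "HOH" and not include_hetero:
                continue
            for atom in res:
                elements.append(atom.element.name)
                coords.append((atom.pos.x, atom.pos.y, atom.pos.z))
    if not elements:
        raise PdbParseError("no atoms left after filtering waters/heteroatoms")
    gemmi_name = st.name.strip()
    if gemmi_name in ("", "string"):  # gemmi's placeholder for string input
        gemmi_name = ""
    sid = structure_id or (inferred_id if inferred_id != "inline" else "") \
        or gemmi_name or "inline"
    return Structure(sid, elements, np.array(coords), model_index=model_index)


def write_pdb(structure: Structure, target) -> None:
    """Write a structure as minimal single-chain PDB ATOM records.

    Coordinates are written at the format's fixed 3-decimal precision, so a
    read/write round trip is the identity on coordinates to 1e-3 Å.
    """
    st = gemmi.Structure()
    st.name = structure.id
    model = gemmi.Model(1)
    chain = gemmi.Chain("A")
    res = gemmi.Residue()
    res.name = "UNK"
    res.seqid = gemmi.SeqId(1, " ")
    for i, el in enumerate(structure.elements):
        atom = gemmi.Atom()
        # unique names keep records distinguishable; element carried in cols 77-78
        atom.name = f"{el}{i % 1000}"[:4]
        atom.element = gemmi.Element(el)
        atom.pos = gemmi.Position(*structure.coords[i])
        res.add_atom(atom)
    chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    text = st.make_pdb_string()
    if hasattr(target, "write"):
        target.write(text)
    else:
        with open(target, "w") as fh:
            fh.write(text)


def assign_radii(structure: Structure, table: RadiusTable | None = None) -> Structure:
    """Return a copy of ``structure`` with hard-sphere radii from ``table``.

    Unlisted elements receive the table's default radius (logged once per
    element).
    """
    table = table or DEFAULT_RADIUS_TABLE
    seen_unknown: set[str] = set()
    radii = np.empty(len(structure))
    for i, el in enumerate(structure.elements):
        key = el.capitalize()
        if key in table.radii:
            radii[i] = table.radii[key]
        else:
            if key not in seen_unknown:
                seen_unknown.add(key)
                logger.warning(
                    "element %r not in radius table; using default %.3f Å",
                    el, table.default_radius,
                )
            radii[i] = table.default_radius
    return replace(structure, radii=radii)


def radius_of_gyration(structure: Structure) -> float:
    """Mass-unweighted radius of gyration in Å.

    Rg = sqrt(mean over atoms of squared distance to the coordinate centroid).
    """
    centred = structure.coords - structure.coords.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(centred**2, axis=1))))


def rmsd(a: Structure, b: Structure) -> float:
    """Coordinate RMSD in Å between equal-length structures, without fitting.

    No Kabsch superposition is applied: the quantity answers "how far did the
    atoms move in the common frame", which is the question asked when judging
    whether an in vacuo trajectory has equilibrated.
    """
    if len(a) != len(b):
        raise ValueError(f"atom-count mismatch: {len(a)} vs {len(b)}")
    d = a.coords - b.coords
    return float(np.sqrt(np.mean(np.sum(d**2, axis=1))))
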