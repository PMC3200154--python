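"""Reading protein models and domain definitions.

A structural model is reduced to one representative point per residue: the
C-beta atom, or C-alpha for glycine — the coordinate that defines residue
contacts throughout the package.  PDB residue sequence numbers are taken
verbatim as 1-based target-sequence positions (the CASP server-model
convention); no renumbering is attempted and insertion codes are rejected.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

from enscon.errors import FormatError, StructureError

logger = logging.getLogger(__name__)

_SEGMENT_RE = re.compile(r"^\s*(\d+)\s*-\s*(\d+)\s*$")


@dataclass(frozen=True)
class ResidueRecord:
    """One residue with its representative-atom coordinate.

    Attributes
    ----------
    index : int
        1-based residue sequence number on the target sequence.
    aa : str
        Three-letter amino-acid code (upper case).
    coord : numpy.ndarray
        Representative atom position in Angstroms, shape (3,).
    """

    index: int
    aa: str
    coord: np.ndarray

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError(f"residue index must be >= 1, got {self.index}")
        coord = np.asarray(self.coord, dtype=float)
        if coord.shape != (3,) or not np.all(np.isfinite(coord)):
            raise ValueError("coord must be a finite 3-vector")
        object.__setattr__(self, "coord", coord)


@dataclass(frozen=True)
class StructureModel:
    """An ordered, single-chain structural model.

    Residue indices are strictly increasing; gaps are allowed because server
    models routinely omit residues they could not place.
    """

    model_id: str
    residues: tuple[ResidueRecord, ...]

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError("a model needs at least one residue")
        idx = [r.index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError(f"residue indices not strictly increasing in {self.model_id}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def indices(self) -> np.ndarray:
        return np.array([r.index for r in self.residues], dtype=int)

    @property
    def coords(self) -> np.ndarray:
        return np.array([r.coord for r in self.residues], dtype=float)


@dataclass(frozen=True)
class DomainDefinition:
    """A target domain as 1-based inclusive segments, e.g. [31-80,257-384].

    The domain length L (sum of segment lengths) is the reference length for
    prediction-list depths such as L/5.
    """

    target_id: str
    segments: tuple[tuple[int, int], ...]
    _members: frozenset[int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("a domain needs at least one segment")
        prev_end = 0
        for start, end in self.segments:
            if start > end:
                raise ValueError(f"inverted segment {start}-{end}")
            if start <= prev_end:
                raise ValueError("segments must be sorted and non-overlapping")
            prev_end = end
        members = frozenset(
            i for start, end in self.segments for i in range(start, end + 1)
        )
        object.__setattr__(self, "_members", members)

    @property
    def length(self) -> int:
        """Domain length L = sum of (end - start + 1) over segments."""
        return sum(end - start + 1 for start, end in self.segments)

    def __contains__(self, index: int) -> bool:
        return index in self._members

    def __str__(self) -> str:
        return ",".join(f"{a}-{b}" for a, b in self.segments)


def parse_domain(text: str, target_id: str = "") -> DomainDefinition:
    """Parse a comma-separated segment list like ``"31-80,257-384"``.

    Segments are 1-based inclusive ranges; they must be non-overlapping and
    in ascending order.  Raises :class:`FormatError` on malformed input.
    """
    parts = [p for p in text.split(",") if p.strip()]
    if not parts:
        raise FormatError(f"empty domain definition: {text!r}")
    segments = []
    for part in parts:
        m = _SEGMENT_RE.match(part)
        if not m:
            raise FormatError(f"malformed domain segment: {part!r}")
        segments.append((int(m.group(1)), int(m.group(2))))
    try:
        return DomainDefinition(target_id=target_id, segments=tuple(segments))
    except ValueError as exc:
        raise FormatError(str(exc)) from exc


def _representative_atom(res: gemmi.Residue, fallback_to_ca: bool) -> gemmi.Atom | None:
    """Pick CB (CA for GLY), honoring first-listed altloc."""
    wanted = "CA" if res.name == "GLY" else "CB"
    for atom in res:
        if atom.name == wanted:
            return atom
    if fallback_to_ca and wanted == "CB":
        for atom in res:
            if atom.name == "CA":
                return atom
    return None


def load_model(
    path: str | Path,
    fallback_to_ca: bool = False,
    chain: str | None = None,
) -> StructureModel:
    """Load one PDB model into a :class:`StructureModel`.

    Parameters
    ----------
    path : path
        PDB file with ATOM records for a single chain (or select one
        with `chain`).  Only the first MODEL of a multi-model file is read.
    fallback_to_ca : bool
        When a non-glycine residue lacks a CB atom, substitute its CA
        instead of skipping the residue.
    chain : str, optional
        Chain name to read when the file contains several chains.

    Raises
    ------
    StructureError
        Unreadable file, ambiguous chains, insertion codes, duplicate or
        decreasing residue numbers, or zero usable residues.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise StructureError(f"cannot read {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"{path}: no models in file")
    first = st[0]

    polymer_chains = [
        ch for ch in first if any(r.het_flag == "A" for r in ch)
    ]
    if not polymer_chains:
        raise StructureError(f"{path}: zero usable residues (no ATOM records)")
    if chain is not None:
        matches = [ch for ch in polymer_chains if ch.name == chain]
        if not matches:
            raise StructureError(f"{path}: chain {chain!r} not found")
        selected = matches[0]
    elif len(polymer_chains) == 1:
        selected = polymer_chains[0]
    else:
        names = [ch.name for ch in polymer_chains]
        raise StructureError(
            f"{path}: multiple chains {names} — select one with chain="
        )

    records: list[ResidueRecord] = []
    for res in selected:
        if res.het_flag != "A":
            continue
        if res.seqid.icode not in (" ", "", "\x00"):
            raise StructureError(
                f"{path}: insertion code {res.seqid.icode!r} at residue "
                f"{res.seqid.num} — renumber the model first"
            )
        atom = _representative_atom(res, fallback_to_ca)
        if atom is None:
            logger.warning(
                "%s: residue %s %d has no representative atom; skipped",
                path.name, res.name, res.seqid.num,
            )
            continue
        if res.name != "GLY" and atom.name == "CA":
            logger.info(
                "%s: residue %s %d lacks CB; using CA",
                path.name, res.name, res.seqid.num,
            )
        records.append(
            ResidueRecord(
                index=res.seqid.num,
                aa=res.name.upper(),
                coord=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
            )
        )
    if not records:
        raise StructureError(f"{path}: zero usable residues")
    try:
        return StructureModel(model_id=path.stem, residues=tuple(records))
    except ValueError as exc:
        raise StructureError(f"{path}: {exc}") from exc


def load_ensemble(
    directory: str | Path,
    fallback_to_ca: bool = False,
    chain: str | None = None,
    pattern: str = "*",
) -> list[StructureModel]:
    """Load every parseable model file in a directory.

    Files that fail to parse are logged and skipped; the returned list is
    sorted by model_id so the ensemble is independent of filesystem listing
    order.  Raises :class:`StructureError` when nothing is parseable.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise StructureError(f"not a directory: {directory}")
    models: list[StructureModel] = []
    for path in sorted(directory.glob(pattern)):
        if not path.is_file():
            continue
        try:
            models.append(load_model(path, fallback_to_ca=fallback_to_ca, chain=chain))
        except StructureError as exc:
            logger.warning("skipping %s: %s", path.name, exc)
    if not models:
        raise StructureError(f"{directory}: no parseable model files")
    models.sort(key=lambda m: m.model_id)
    return models


def write_model_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a model as a single-chain PDB file.

    The representative coordinate of each residue is written as that
    residue's CB atom (CA for glycine) so that writing and re-loading is the
    identity up to PDB coordinate precision (3 decimals).
    """
    st = gemmi.Structure()
    st.name = model.model_id
    gm = gemmi.Model("1")
    ch = gemmi.Chain("A")
    for rec in model.residues:
        res = gemmi.Residue()
        res.name = rec.aa
        res.seqid = gemmi.SeqId(rec.index, " ")
        atom = gemmi.Atom()
        atom.name = "CA" if rec.aa == "GLY" else "CB"
        atom.pos = gemmi.Position(*rec.coord)
        atom.element = gemmi.Element("C")
        res.add_atom(atom)
        ch.add_residue(res)
    gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))
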