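"""Structure, trajectory, segment-map and sequence I/O.

The interchange formats are deliberately plain: single- and multi-model PDB
for structures and conformational ensembles, JSON for residue segment maps,
FASTA for sequences.  Residue numbering is always the author numbering from
the input file (1-based, UniProt-style for the USP8 system, residues
402-1118); it is never reset or compacted.

PDB files are parsed with :mod:`gemmi`; a light pre-validation pass rejects
malformed coordinate records with the offending line number (gemmi itself is
lenient and would silently zero bad fields).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
from Bio import SeqIO

__all__ = [
    "Atom",
    "StructureModel",
    "TrajectoryEnsemble",
    "SegmentMap",
    "MotifHit",
    "PDBFormatError",
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
    "read_fasta",
    "scan_sh3bm",
    "read_segment_map",
    "write_segment_map",
    "complete_segment_map",
    "default_segment_map",
    "SH3BM_PATTERN",
]

# Proline-rich SH3-binding motif: P, any, V or I, D or N, R, any, any, K, P.
SH3BM_PATTERN = re.compile(r"P.[VI][DN]R..KP")
SH3BM_LENGTH = 9

AMINO_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")

#: Default residue segmentation of the modeled USP8 region (residues 402-1118):
#: the WW-like autoinhibitory domain, the 14-3-3 binding motif, the SH3-binding
#: motif, the catalytic deubiquitinase (DUB) domain, and the interdomain LINKER
#: covering everything else.
DEFAULT_SEGMENTS: dict[str, tuple[int, int]] = {
    "WW_like": (645, 684),
    "BM_14_3_3": (715, 720),
    "SH3BM": (738, 747),
    "DUB": (778, 1088),
}
DEFAULT_RANGE: tuple[int, int] = (402, 1118)


class PDBFormatError(ValueError):
    """Raised when a PDB file violates the expected dialect."""


@dataclass(frozen=True)
class Atom:
    """A single atom with author residue numbering preserved."""

    serial: int
    name: str
    element: str
    residue_index: int
    residue_name: str
    chain: str
    position: np.ndarray  # shape (3,), Angstrom

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError(f"atom serial {self.serial}: empty element symbol")
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom serial {self.serial}: non-finite position")
        object.__setattr__(self, "position", pos)


@dataclass
class StructureModel:
    """An ordered collection of atoms; the reference topology for an ensemble."""

    atoms: list[Atom]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("StructureModel requires at least one atom")
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("duplicate atom serials")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def residue_index_range(self) -> tuple[int, int]:
        idx = [a.residue_index for a in self.atoms]
        return (min(idx), max(idx))

    @property
    def coordinates(self) -> np.ndarray:
        """N x 3 array of positions in file order."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def atom_names(self) -> np.ndarray:
        return np.array([a.name for a in self.atoms])

    def residue_indices(self) -> np.ndarray:
        return np.array([a.residue_index for a in self.atoms], dtype=int)

    def selection_mask(self, atom_names: Iterable[str]) -> np.ndarray:
        wanted = set(atom_names)
        return np.array([a.name in wanted for a in self.atoms], dtype=bool)


@dataclass
class TrajectoryEnsemble:
    """A reference structure plus T coordinate frames (T x N x 3, Angstrom)."""

    reference: StructureModel
    frames: np.ndarray
    label: str
    frame_times: np.ndarray | None = None  # ns, optional

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must be a T x N x 3 array")
        if self.frames.shape[0] < 1:
            raise ValueError("ensemble needs at least one frame")
        if self.frames.shape[1] != len(self.reference):
            raise ValueError(
                f"frame atom count {self.frames.shape[1]} does not match "
                f"reference atom count {len(self.reference)}"
            )
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("non-finite coordinates in frames")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]


@dataclass(frozen=True)
class MotifHit:
    """One SH3-binding-motif match in a sequence."""

    start: int  # 1-based, in the caller's numbering
    matched: str


@dataclass
class SegmentMap:
    """Named closed residue intervals partitioning a modeled range.

    ``segments`` maps a segment name to one or more 1-based closed intervals.
    Named functional segments are single intervals; the LINKER produced by
    :func:`complete_segment_map` may span several disjoint intervals.
    """

    segments: dict[str, list[tuple[int, int]]]
    residue_range: tuple[int, int]

    def __post_init__(self) -> None:
        lo, hi = self.residue_range
        if lo > hi:
            raise ValueError("empty residue range")
        for name, intervals in self.segments.items():
            for start, end in intervals:
                if start > end:
                    raise ValueError(f"segment {name}: start {start} > end {end}")
                if start < lo or end > hi:
                    raise ValueError(
                        f"segment {name}: [{start},{end}] outside range [{lo},{hi}]"
                    )

    def segment_of(self, residue_index: int) -> str:
        for name, intervals in self.segments.items():
            for start, end in intervals:
                if start <= residue_index <= end:
                    return name
        raise KeyError(f"residue {residue_index} not covered by any segment")

    def lookup(self) -> dict[int, str]:
        """Residue index -> segment name over the whole range."""
        table: dict[int, str] = {}
        for name, intervals in self.segments.items():
            for start, end in intervals:
                for i in range(start, end + 1):
                    if i in table:
                        raise ValueError(f"residue {i} in both {table[i]} and {name}")
                    table[i] = name
        return table

    def is_partition(self) -> bool:
        lo, hi = self.residue_range
        try:
            table = self.lookup()
        except ValueError:
            return False
        return set(table) == set(range(lo, hi + 1))


def default_segment_map() -> SegmentMap:
    """The USP8 segment map (WW-like, 14-3-3 BM, SH3BM, DUB + LINKER) over 402-1118."""
    named = SegmentMap(
        segments={k: [v] for k, v in DEFAULT_SEGMENTS.items()},
        residue_range=DEFAULT_RANGE,
    )
    return complete_segment_map(named, DEFAULT_RANGE)


# ---------------------------------------------------------------------------
# PDB reading


_COORD_SLICES = ((30, 38), (38, 46), (46, 54))


def _validate_pdb_lines(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        if len(line) < 54:
            raise PDBFormatError(f"line {lineno}: truncated ATOM/HETATM record")
        for lo, hi in _COORD_SLICES:
            fieldtxt = line[lo:hi].strip()
            try:
                float(fieldtxt)
            except ValueError:
                raise PDBFormatError(
                    f"line {lineno}: malformed coordinate field {fieldtxt!r}"
                ) from None
        if line[26] != " ":
            raise PDBFormatError(
                f"line {lineno}: insertion code {line[26]!r} not supported"
            )


def _model_to_atoms(model: gemmi.Model, keep_het: str = "metals") -> list[Atom]:
    """Flatten one gemmi model, resolving altlocs to highest occupancy.

    ``keep_het``: 'metals' drops all HETATM records except metal ions (the
    zinc of the USP8 catalytic domain is retained); 'all' keeps everything.
    """
    atoms: list[Atom] = []
    for chain in model:
        for res in chain:
            if res.het_flag == "H" and keep_het == "metals":
                if not any(at.element.is_metal for at in res):
                    continue
            # group by atom name, resolve altloc by occupancy
            by_name: dict[str, gemmi.Atom] = {}
            for at in res:
                prev = by_name.get(at.name)
                if prev is None or at.occ > prev.occ:
                    by_name[at.name] = at
            for at in by_name.values():
                atoms.append(
                    Atom(
                        serial=at.serial,
                        name=at.name,
                        element=at.element.name.upper(),
                        residue_index=res.seqid.num,
                        residue_name=res.name,
                        chain=chain.name,
                        position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    )
                )
    return atoms


def read_structure(path: str | Path, keep_het: str = "metals") -> StructureModel:
    """Read the first model of a PDB file, preserving author numbering.

    Non-metal HETATM records (waters, buffer components) are dropped; metal
    ions are kept.  Alternate locations are resolved to the highest-occupancy
    conformer.  Insertion codes are rejected.
    """
    path = Path(path)
    text = path.read_text()
    _validate_pdb_lines(text)
    st = gemmi.read_pdb_string(text)
    if len(st) == 0:
        raise PDBFormatError(f"{path}: no models found")
    atoms = _model_to_atoms(st[0], keep_het=keep_het)
    if not atoms:
        raise PDBFormatError(f"{path}: no ATOM records")
    return StructureModel(atoms=atoms)


def read_trajectory(
    path: str | Path,
    reference: StructureModel | None = None,
    label: str = "",
    keep_het: str = "metals",
) -> TrajectoryEnsemble:
    """Read a multi-model PDB as an ensemble.

    Frames are ordered by MODEL number; atom correspondence is by serial
    order within each MODEL.  Every MODEL must contain exactly the reference
    atom count (the reference defaults to the first MODEL).
    """
    path = Path(path)
    text = path.read_text()
    _validate_pdb_lines(text)
    st = gemmi.read_pdb_string(text)
    if len(st) == 0:
        raise PDBFormatError(f"{path}: no models found")
    models = sorted(st, key=lambda m: m.num)
    per_model = [_model_to_atoms(m, keep_het=keep_het) for m in models]
    if reference is None:
        if not per_model[0]:
            raise PDBFormatError(f"{path}: no ATOM records in MODEL {models[0].num}")
        reference = StructureModel(atoms=per_model[0])
    n_ref = len(reference)
    frames = np.empty((len(per_model), n_ref, 3), dtype=float)
    for k, (model, atoms) in enumerate(zip(models, per_model)):
        if len(atoms) != n_ref:
            raise PDBFormatError(
                f"{path}: MODEL {model.num} has {len(atoms)} atoms, "
                f"expected {n_ref}"
            )
        frames[k] = [a.position for a in atoms]
    return TrajectoryEnsemble(
        reference=reference, frames=frames, label=label or path.stem
    )


# ---------------------------------------------------------------------------
# PDB writing


def _format_atom_line(atom: Atom, position: np.ndarray, serial: int) -> str:
    record = "HETATM" if atom.residue_name in ("ZN", "HOH") else "ATOM  "
    name = atom.name
    # PDB column convention: 1-3 character names start in column 14
    padded = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
    x, y, z = position
    return (
        f"{record}{serial:>5d} {padded} {atom.residue_name:<3s} {atom.chain:1s}"
        f"{atom.residue_index:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
        f"  1.00  0.00          {atom.element:>2s}"
    )


def write_structure(structure: StructureModel, path: str | Path) -> None:
    """Write a single-model PDB (3-decimal coordinate precision)."""
    lines = [
        _format_atom_line(a, a.position, i + 1)
        for i, a in enumerate(structure.atoms)
    ]
    Path(path).write_text("\n".join(lines) + "\nEND\n")


def write_trajectory(ensemble: TrajectoryEnsemble, path: str | Path) -> None:
    """Write an ensemble as a multi-model PDB."""
    out: list[str] = []
    for t in range(ensemble.n_frames):
        out.append(f"MODEL     {t + 1:>4d}")
        for i, atom in enumerate(ensemble.reference.atoms):
            out.append(_format_atom_line(atom, ensemble.frames[t, i], i + 1))
        out.append("ENDMDL")
    out.append("END")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Sequences and motif scanning


def read_fasta(path: str | Path) -> str:
    """Read the first record of a FASTA file as an upper-case string."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return str(records[0].seq).upper()


def scan_sh3bm(sequence: str, offset: int = 1) -> list[MotifHit]:
    """Find every SH3-binding-motif instance Px(V/I)(D/N)RxxKP.

    ``offset`` is the 1-based residue index of the first sequence position;
    hit starts are reported in that numbering.  Overlapping matches are all
    reported.
    """
    sequence = sequence.upper()
    bad = set(sequence) - AMINO_ALPHABET
    if bad:
        raise ValueError(f"non-standard amino acid letters: {sorted(bad)}")
    hits: list[MotifHit] = []
    for i in range(len(sequence) - SH3BM_LENGTH + 1):
        window = sequence[i : i + SH3BM_LENGTH]
        if SH3BM_PATTERN.fullmatch(window):
            hits.append(MotifHit(start=offset + i, matched=window))
    return hits


# ---------------------------------------------------------------------------
# Segment maps


def complete_segment_map(
    named: SegmentMap, residue_range: tuple[int, int] | None = None
) -> SegmentMap:
    """Fill every residue not covered by a named segment into LINKER.

    The result is a partition of the residue range: the LINKER segment holds
    the (possibly disjoint) complement of the named intervals, e.g. the
    unstructured interdomain region connecting the WW-like and DUB domains.
    """
    rng = residue_range or named.residue_range
    lo, hi = rng
    occupied: dict[int, str] = {}
    for name, intervals in named.segments.items():
        if name == "LINKER":
            continue
        for start, end in intervals:
            for i in range(start, end + 1):
                if i in occupied:
                    raise ValueError(
                        f"overlapping segments: residue {i} in both "
                        f"{occupied[i]} and {name}"
                    )
                occupied[i] = name
    linker: list[tuple[int, int]] = []
    run_start: int | None = None
    for i in range(lo, hi + 2):
        free = i <= hi and i not in occupied
        if free and run_start is None:
            run_start = i
        elif not free and run_start is not None:
            linker.append((run_start, i - 1))
            run_start = None
    segments = {
        name: list(intervals)
        for name, intervals in named.segments.items()
        if name != "LINKER"
    }
    segments["LINKER"] = linker
    return SegmentMap(segments=segments, residue_range=(lo, hi))


def read_segment_map(path: str | Path) -> SegmentMap:
    """Read a segment map from JSON and complete the LINKER.

    Format: ``{"segments": {"DUB": [778, 1088], ...}, "range": [402, 1118]}``.
    """
    data = json.loads(Path(path).read_text())
    rng = tuple(data["range"])
    segments = {
        name: [tuple(iv)] if not isinstance(iv[0], list) else [tuple(x) for x in iv]
        for name, iv in data["segments"].items()
    }
    named = SegmentMap(segments=segments, residue_range=rng)
    return complete_segment_map(named, rng)


def write_segment_map(segmap: SegmentMap, path: str | Path) -> None:
    data = {
        "segments": {
            name: intervals[0] if len(intervals) == 1 else intervals
            for name, intervals in segmap.segments.items()
            if name != "LINKER"
        },
        "range": list(segmap.residue_range),
    }
    Path(path).write_text(json.dumps(data, indent=2) + "\n")
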