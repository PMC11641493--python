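"""CA-geometry secondary-structure assignment and WT/mutant SSE comparison.

Assignment uses alpha-carbon distance criteria only (in the spirit of P-SEA),
so it works on reduced backbone representations and needs no hydrogen
placement.  For each residue ``i`` with at least four successors, the forward
distances d2 = |CA(i)-CA(i+2)|, d3 = |CA(i)-CA(i+3)|, d4 = |CA(i)-CA(i+4)|
are tested:

* helix window:  d2 in 5.5 +/- 0.7, d3 in 5.3 +/- 0.8, d4 in 6.4 +/- 0.9 (all three);
* strand window: d2 in 6.7 +/- 0.6 and d4 in 12.4 +/- 1.1.

When the helix (strand) criterion fires at ``i``, residues ``i .. i+4`` are
marked H (E); helix takes precedence where the two overlap.  The first and
last two residues of a chain are always coil, and runs shorter than 4 (H) or
3 (E) are demoted to coil.  Only the three-state alphabet {H, E, C} is used;
helix subtypes and strand topology are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure_io import StructureModel, TrajectoryEnsemble

__all__ = [
    "SSEThresholds",
    "SSESummary",
    "GainedRegion",
    "assign_sse",
    "helical_content",
    "gained_sse_regions",
]


@dataclass(frozen=True)
class SSEThresholds:
    """Distance windows (Angstrom) and minimum run lengths."""

    helix_d2: tuple[float, float] = (5.5, 0.7)  # (center, half-width)
    helix_d3: tuple[float, float] = (5.3, 0.8)
    helix_d4: tuple[float, float] = (6.4, 0.9)
    strand_d2: tuple[float, float] = (6.7, 0.6)
    strand_d4: tuple[float, float] = (12.4, 1.1)
    min_run_h: int = 4
    min_run_e: int = 3


@dataclass
class SSESummary:
    """Helical content and per-residue helix propensity for one model."""

    label: str
    helical_content: float  # % of residues labelled H, averaged over frames
    helix_propensity: dict[int, float]  # residue index -> fraction of frames H
    strand_content: float = 0.0


@dataclass(frozen=True)
class GainedRegion:
    """A residue interval helical in every mutant but not in the wild type."""

    interval: tuple[int, int]  # closed, 1-based
    mutant_propensity: float  # minimum over mutants, mean over residues
    wt_propensity: float


def _in_window(d: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    center, half = window
    return np.abs(d - center) <= half


def _enforce_min_runs(labels: np.ndarray, thresholds: SSEThresholds) -> np.ndarray:
    out = labels.copy()
    n = len(out)
    i = 0
    while i < n:
        j = i
        while j < n and out[j] == out[i]:
            j += 1
        run = out[i]
        length = j - i
        if (run == "H" and length < thresholds.min_run_h) or (
            run == "E" and length < thresholds.min_run_e
        ):
            out[i:j] = "C"
        i = j
    return out


_METALS = {"ZN", "MG", "MN", "FE", "NA", "K", "CU", "CO", "NI"}


def _ca_rows(structure: StructureModel) -> tuple[np.ndarray, np.ndarray]:
    """Row index and residue index of the CA atom of every amino-acid residue.

    Metal ions are exempt; any other residue without a CA is an error.
    """
    ca_of: dict[tuple[str, int], int] = {}
    amino: dict[tuple[str, int], None] = {}
    for row, atom in enumerate(structure.atoms):
        key = (atom.chain, atom.residue_index)
        if atom.element.upper() in _METALS:
            continue
        amino.setdefault(key, None)
        if atom.name == "CA":
            ca_of[key] = row
    missing = [key for key in amino if key not in ca_of]
    if missing:
        raise ValueError(f"residue {missing[0][1]} (chain {missing[0][0]}): missing CA atom")
    keys = list(amino)
    return (
        np.array([ca_of[k] for k in keys], dtype=int),
        np.array([k[1] for k in keys], dtype=int),
    )


def assign_sse(
    frame_coords: np.ndarray,
    structure: StructureModel,
    thresholds: SSEThresholds = SSEThresholds(),
) -> str:
    """Three-state SSE string (H/E/C) for one frame, one label per CA residue."""
    rows, residues = _ca_rows(structure)
    ca = np.asarray(frame_coords, dtype=float)[rows]
    n = len(ca)
    labels = np.full(n, "C", dtype="<U1")
    if n >= 5:
        d2 = np.linalg.norm(ca[2:] - ca[:-2], axis=1)  # d2[i] = |CA(i)-CA(i+2)|
        d3 = np.linalg.norm(ca[3:] - ca[:-3], axis=1)
        d4 = np.linalg.norm(ca[4:] - ca[:-4], axis=1)
        m = n - 4  # criteria defined for i = 0 .. m-1
        helix_at = (
            _in_window(d2[:m], thresholds.helix_d2)
            & _in_window(d3[:m], thresholds.helix_d3)
            & _in_window(d4[:m], thresholds.helix_d4)
        )
        strand_at = _in_window(d2[:m], thresholds.strand_d2) & _in_window(
            d4[:m], thresholds.strand_d4
        )
        for i in np.flatnonzero(strand_at):
            labels[i : i + 5] = "E"
        for i in np.flatnonzero(helix_at):  # helix wins over strand
            labels[i : i + 5] = "H"
    labels[:2] = "C"
    labels[-2:] = "C"
    labels = _enforce_min_runs(labels, thresholds)
    return "".join(labels)


def helical_content(
    ensemble: TrajectoryEnsemble,
    structure: StructureModel | None = None,
    thresholds: SSEThresholds = SSEThresholds(),
) -> SSESummary:
    """Frame-averaged helical content (%) and per-residue helix propensity."""
    structure = structure or ensemble.reference
    _, residues = _ca_rows(structure)
    h_counts = np.zeros(len(residues))
    e_frac = 0.0
    h_frac = 0.0
    for t in range(ensemble.n_frames):
        sse = assign_sse(ensemble.frames[t], structure, thresholds)
        arr = np.frombuffer(sse.encode(), dtype="S1")
        is_h = arr == b"H"
        h_counts += is_h
        h_frac += is_h.mean()
        e_frac += (arr == b"E").mean()
    t_total = ensemble.n_frames
    propensity = {
        int(r): float(c / t_total) for r, c in zip(residues, h_counts)
    }
    return SSESummary(
        label=ensemble.label,
        helical_content=100.0 * h_frac / t_total,
        helix_propensity=propensity,
        strand_content=100.0 * e_frac / t_total,
    )


def gained_sse_regions(
    wt: SSESummary,
    mutants: list[SSESummary],
    gain_threshold: float = 0.5,
    background_threshold: float = 0.1,
) -> list[GainedRegion]:
    """Maximal residue intervals helical in ALL mutants but not in the WT.

    A residue qualifies when its helix propensity is >= ``gain_threshold`` in
    every mutant and <= ``background_threshold`` in the wild type; qualifying
    residues are merged into maximal closed intervals.
    """
    if not mutants:
        return []
    residues = sorted(wt.helix_propensity)
    for m in mutants:
        if sorted(m.helix_propensity) != residues:
            raise ValueError("summaries cover different residue sets")
    qualifying = [
        r
        for r in residues
        if wt.helix_propensity[r] <= background_threshold
        and all(m.helix_propensity[r] >= gain_threshold for m in mutants)
    ]
    regions: list[GainedRegion] = []
    i = 0
    while i < len(qualifying):
        j = i
        while j + 1 < len(qualifying) and qualifying[j + 1] == qualifying[j] + 1:
            j += 1
        interval = (qualifying[i], qualifying[j])
        span = range(interval[0], interval[1] + 1)
        mut_prop = min(
            float(np.mean([m.helix_propensity[r] for r in span])) for m in mutants
        )
        wt_prop = float(np.mean([wt.helix_propensity[r] for r in span]))
        regions.append(
            GainedRegion(interval=interval, mutant_propensity=mut_prop, wt_propensity=wt_prop)
        )
        i = j + 1
    return regions
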