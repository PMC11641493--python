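"""Global ensemble descriptors: superposition, RMSD, RMSF, radius of gyration.

Conventions, fixed here once and used everywhere downstream:

* RMSD is computed over the backbone selection (atom names N, CA, C, O;
  whichever of those exist in the model) against frame 0 of the ensemble,
  after optimal rigid-body superposition of each frame onto that reference.
* RMSF is computed on CA atoms about the ensemble-mean structure.  Frames
  are first aligned to frame 0, the mean structure computed, frames realigned
  to that mean and the mean recomputed once (one refinement iteration).
* Standard deviations in summaries are population SDs (ddof=0).

All distances are in Angstrom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import StructureModel, TrajectoryEnsemble

__all__ = [
    "Superposition",
    "DescriptorSeries",
    "ResidueProfile",
    "SummaryRow",
    "BACKBONE_NAMES",
    "kabsch_superpose",
    "rmsd_series",
    "rmsf_per_residue",
    "radius_of_gyration_series",
    "radius_of_gyration",
    "summarize_model",
]

BACKBONE_NAMES = ("N", "CA", "C", "O")

# Monoisotopic-ish masses for the elements that occur in protein models.
_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06, "ZN": 65.38}


@dataclass(frozen=True)
class Superposition:
    """An optimal proper rigid-body fit of one point set onto another."""

    rotation: np.ndarray  # 3x3, det +1
    translation: np.ndarray  # 3-vector
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class DescriptorSeries:
    """A per-frame scalar descriptor (RMSD_backbone or RG) for one model."""

    metric: str
    values: np.ndarray
    label: str

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def std(self) -> float:
        return float(np.std(self.values))  # population


@dataclass
class ResidueProfile:
    """Per-residue RMSF for one model."""

    metric: str
    per_residue: dict[int, float]
    label: str

    @property
    def mean(self) -> float:
        return float(np.mean(list(self.per_residue.values())))

    @property
    def std(self) -> float:
        return float(np.std(list(self.per_residue.values())))


@dataclass
class SummaryRow:
    """One row of the per-model statistics table (means and population SDs)."""

    label: str
    rmsd_mean: float
    rmsd_std: float
    rmsf_mean: float
    rmsf_std: float
    rg_mean: float
    rg_std: float


def kabsch_superpose(
    mobile: np.ndarray,
    target: np.ndarray,
    weights: np.ndarray | None = None,
) -> Superposition:
    """Least-squares superposition of ``mobile`` onto ``target`` (Kabsch).

    Returns the proper rotation (reflections are corrected to det +1),
    translation, and the weighted RMSD after the fit.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and target must be matching N x 3 arrays")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 points")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
    wn = w / w.sum()

    mob_c = mobile - wn @ mobile
    tgt_c = target - wn @ target

    # degenerate (collinear) sets have a rank-deficient covariance
    cov = (mob_c * wn[:, None]).T @ tgt_c
    u, s, vt = np.linalg.svd((mob_c * wn[:, None]).T @ mob_c)
    if s[1] <= 1e-12 * max(s[0], 1.0):
        raise ValueError("degenerate (collinear) point set")

    u, s, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T

    translation = (wn @ target) - rotation @ (wn @ mobile)
    moved = mob_c @ rotation.T
    rmsd = float(np.sqrt(np.sum(wn[:, None] * (moved - tgt_c) ** 2)))
    return Superposition(rotation=rotation, translation=translation, rmsd=rmsd)


def _selection_coords(
    ensemble: TrajectoryEnsemble, atom_names: tuple[str, ...]
) -> np.ndarray:
    mask = ensemble.reference.selection_mask(atom_names)
    if not mask.any():
        raise ValueError(f"empty selection: no atoms named {atom_names}")
    return ensemble.frames[:, mask, :]


def rmsd_series(
    ensemble: TrajectoryEnsemble,
    reference_frame: int = 0,
    selection: tuple[str, ...] = BACKBONE_NAMES,
) -> DescriptorSeries:
    """Backbone RMSD of every frame from the reference frame, after superposition."""
    coords = _selection_coords(ensemble, selection)
    ref = coords[reference_frame]
    values = np.empty(ensemble.n_frames)
    for t in range(ensemble.n_frames):
        values[t] = kabsch_superpose(coords[t], ref).rmsd
    return DescriptorSeries(metric="RMSD_backbone", values=values, label=ensemble.label)


def rmsf_per_residue(
    ensemble: TrajectoryEnsemble, selection: tuple[str, ...] = ("CA",)
) -> ResidueProfile:
    """Per-residue RMSF about the ensemble-mean structure (CA atoms).

    RMSF_i = sqrt(<|x_i - <x_i>|^2>) over frames, after aligning all frames
    to the mean structure (mean seeded from a frame-0 alignment, then one
    realignment iteration).
    """
    if ensemble.n_frames < 2:
        raise ValueError("RMSF requires at least 2 frames")
    mask = ensemble.reference.selection_mask(selection)
    if not mask.any():
        raise ValueError(f"empty selection: no atoms named {selection}")
    coords = ensemble.frames[:, mask, :]
    residues = ensemble.reference.residue_indices()[mask]

    aligned = np.empty_like(coords)
    ref = coords[0]
    for t in range(coords.shape[0]):
        aligned[t] = kabsch_superpose(coords[t], ref).apply(coords[t])
    mean = aligned.mean(axis=0)
    for t in range(coords.shape[0]):
        aligned[t] = kabsch_superpose(coords[t], mean).apply(coords[t])
    mean = aligned.mean(axis=0)

    dev2 = np.sum((aligned - mean) ** 2, axis=2)  # T x N
    rmsf = np.sqrt(dev2.mean(axis=0))
    per_residue = {int(r): float(v) for r, v in zip(residues, rmsf)}
    return ResidueProfile(metric="RMSF", per_residue=per_residue, label=ensemble.label)


def radius_of_gyration(
    coords: np.ndarray, weights: np.ndarray | None = None
) -> float:
    """Rg of one frame: sqrt(sum w_i |x_i - xbar_w|^2 / sum w_i)."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 1:
        raise ValueError("need at least one atom")
    if weights is None:
        w = np.ones(coords.shape[0])
    else:
        w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    center = w @ coords
    return float(np.sqrt(np.sum(w[:, None] * (coords - center) ** 2)))


def radius_of_gyration_series(
    ensemble: TrajectoryEnsemble, mass_weighted: bool = False
) -> DescriptorSeries:
    """Per-frame radius of gyration over all atoms."""
    if mass_weighted:
        weights = np.array(
            [_MASSES.get(a.element, 12.011) for a in ensemble.reference.atoms]
        )
    else:
        weights = None
    values = np.array(
        [radius_of_gyration(ensemble.frames[t], weights) for t in range(ensemble.n_frames)]
    )
    return DescriptorSeries(metric="RG", values=values, label=ensemble.label)


def summarize_model(
    ensemble: TrajectoryEnsemble, mass_weighted_rg: bool = False
) -> SummaryRow:
    """Mean and population SD of RMSD, RMSF and Rg for one model.

    The RMSF mean/SD are taken over residues of the per-residue profile;
    RMSD and Rg over frames.
    """
    rmsd = rmsd_series(ensemble)
    rmsf = rmsf_per_residue(ensemble)
    rg = radius_of_gyration_series(ensemble, mass_weighted=mass_weighted_rg)
    return SummaryRow(
        label=ensemble.label,
        rmsd_mean=rmsd.mean,
        rmsd_std=rmsd.std,
        rmsf_mean=rmsf.mean,
        rmsf_std=rmsf.std,
        rg_mean=rg.mean,
        rg_std=rg.std,
    )
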