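"""Synthetic conformational ensembles with planted, exactly recoverable ground truth.

The generator emulates the qualitative contrast between a flexible, extended
wild-type ensemble and rigidified, compacted mutant ensembles:

* a deterministic CA-trace reference chain (a helical super-coil with
  3.8 A steps whose adjacent turns stay well separated, so the baseline
  contact graph is controlled);
* per-segment isotropic Gaussian jitter (per-axis sigma), scaled down in
  mutants to emulate reduced flexibility;
* global compaction of mutant coordinates about the centroid by a factor
  ``lambda <= 1``;
* *baseline pairs* forced into contact in every frame of every model (the
  shared interaction scaffold), and *planted pairs* forced into contact in
  mutants only and guaranteed well outside the contact cutoff in the WT --
  these are the ground truth for consensus-unique-pair recovery;
* an ideal alpha-helix carved into a chosen residue window in mutants only,
  the ground truth for gained-helix detection.

Jitter is i.i.d. per frame (no autocorrelation), which gives closed-form
expectations: per-residue RMSF -> sigma * sqrt(3), mutant/WT mean-Rg ratio
-> lambda.  Every ensemble is bitwise reproducible from (spec, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .interactions import InteractionRules
from .metrics import kabsch_superpose
from .structure_io import (
    Atom,
    SegmentMap,
    StructureModel,
    TrajectoryEnsemble,
    complete_segment_map,
    default_segment_map,
)

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "make_reference_chain",
    "generate_ensemble",
    "generate_study",
    "small_spec",
    "demo_spec",
    "small_segment_map",
]

# super-coil geometry: radius / pitch chosen so consecutive turns sit 12 A
# apart and no un-forced residue pair comes near the 4.5 A contact cutoff,
# even after compaction by lambda >= 0.85
_COIL_RADIUS = 14.0
_COIL_PITCH = 12.0
_CA_STEP = 3.8
_RESIDUES_PER_TURN = 23  # residue offset giving adjacent-turn partners

# ideal alpha-helix CA geometry
_HELIX_RISE = 1.5
_HELIX_TWIST_DEG = 100.0
_HELIX_RADIUS = 2.3

_DEFAULT_SIGMA = {
    "WW_like": 0.45,
    "BM_14_3_3": 0.55,
    "SH3BM": 0.50,
    "DUB": 0.40,
    "LINKER": 0.60,
}


@dataclass
class SyntheticSpec:
    """Full parameterization of one WT/mutant study; see module docstring."""

    n_residues: int = 120
    residue_range: tuple[int, int] = (402, 521)
    segment_map: SegmentMap | None = None
    per_segment_sigma: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_SIGMA)
    )
    mutant_sigma_scale: float = 0.5
    compaction: float = 0.9
    baseline_pairs: list[tuple[int, int]] = field(default_factory=list)
    planted_pairs: list[tuple[int, int, str]] = field(default_factory=list)
    planted_helix: tuple[int, int] | None = None
    helix_sigma: float = 0.1
    n_frames: int = 500
    seed: int = 0
    contact_target: float = 3.4  # forced-pair distance, A
    rules: InteractionRules = field(default_factory=InteractionRules)

    def __post_init__(self) -> None:
        lo, hi = self.residue_range
        if hi - lo + 1 != self.n_residues:
            raise ValueError("residue_range size does not match n_residues")
        if not 0.0 < self.compaction <= 1.0:
            raise ValueError("compaction must be in (0, 1]")
        if any(s <= 0 for s in self.per_segment_sigma.values()):
            raise ValueError("per-segment sigma must be positive")
        if self.segment_map is None:
            if self.residue_range == (402, 1118):
                self.segment_map = default_segment_map()
            else:
                self.segment_map = small_segment_map(self.residue_range)
        endpoints: list[int] = []
        for i, j in self.baseline_pairs:
            endpoints += [i, j]
        for i, j, kind in self.planted_pairs:
            if kind != "contact":
                raise ValueError("only 'contact' pairs can be planted on a CA trace")
            endpoints += [i, j]
        for r in endpoints:
            if not lo <= r <= hi:
                raise ValueError(f"forced-pair residue {r} outside range")
        for i, j in [(p[0], p[1]) for p in self.baseline_pairs] + [
            (p[0], p[1]) for p in self.planted_pairs
        ]:
            if abs(j - i) < self.rules.min_separation:
                raise ValueError(f"forced pair ({i},{j}) violates sequence separation")
        if len(endpoints) != len(set(endpoints)):
            raise ValueError("forced pairs must not share residues")
        if self.planted_helix is not None:
            a, b = self.planted_helix
            if not (lo <= a <= b <= hi):
                raise ValueError("planted helix outside residue range")
            guard = set(range(a - 4, b + 5))
            if guard & set(endpoints):
                raise ValueError("forced pairs too close to the planted helix")


@dataclass
class GroundTruth:
    """The generator's recoverable expectations for one ensemble."""

    label: str
    role: str
    expected_segment_rmsf: dict[str, float]  # sigma * sqrt(3), per segment
    expected_rg_ratio: float  # mutant/WT mean Rg (1.0 for WT)
    expected_consensus_pairs: list[tuple[int, int, str]]
    expected_gained_helix: tuple[int, int] | None


def small_segment_map(residue_range: tuple[int, int] = (402, 521)) -> SegmentMap:
    """A proportionally scaled-down USP8-style segment map for small systems."""
    lo, hi = residue_range
    span = hi - lo
    if span < 60:  # too small for four named segments: everything is LINKER
        return complete_segment_map(
            SegmentMap(segments={}, residue_range=residue_range), residue_range
        )
    named = SegmentMap(
        segments={
            "WW_like": [(lo + round(0.24 * span), lo + round(0.40 * span))],
            "BM_14_3_3": [(lo + round(0.44 * span), lo + round(0.48 * span))],
            "SH3BM": [(lo + round(0.52 * span), lo + round(0.57 * span))],
            "DUB": [(lo + round(0.63 * span), lo + round(0.92 * span))],
        },
        residue_range=residue_range,
    )
    return complete_segment_map(named, residue_range)


def make_reference_chain(
    n_residues: int,
    numbering: tuple[int, int] | None = None,
    seed: int = 0,
) -> StructureModel:
    """Deterministic CA-trace helical super-coil with ~3.8 A steps.

    Adjacent turns of the coil are one pitch (12 A) apart, so the closest
    non-bonded approach of the undisturbed chain is far outside the contact
    cutoff -- which is what makes planted contacts the unique ground truth.
    """
    if n_residues < 10:
        raise ValueError("need at least 10 residues")
    if numbering is None:
        numbering = (1, n_residues)
    lo, hi = numbering
    if hi - lo + 1 != n_residues:
        raise ValueError("numbering span does not match n_residues")
    c = _COIL_PITCH / (2 * np.pi)
    arc_per_rad = np.sqrt(_COIL_RADIUS**2 + c**2)
    theta = np.arange(n_residues) * _CA_STEP / arc_per_rad
    coords = np.column_stack(
        [_COIL_RADIUS * np.cos(theta), _COIL_RADIUS * np.sin(theta), c * theta]
    )
    rng = np.random.default_rng([seed, 1031])
    coords = coords + rng.normal(scale=0.03, size=coords.shape)
    atoms = [
        Atom(
            serial=k + 1,
            name="CA",
            element="C",
            residue_index=lo + k,
            residue_name="ALA",
            chain="A",
            position=coords[k],
        )
        for k in range(n_residues)
    ]
    return StructureModel(atoms=atoms)


def _ideal_helix(n: int) -> np.ndarray:
    twist = np.deg2rad(_HELIX_TWIST_DEG)
    k = np.arange(n)
    return np.column_stack(
        [
            _HELIX_RADIUS * np.cos(k * twist),
            _HELIX_RADIUS * np.sin(k * twist),
            k * _HELIX_RISE,
        ]
    )


def _carve_helix(base: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """Replace the given rows with an ideal helix rigid-fitted onto them."""
    helix = _ideal_helix(len(rows))
    fit = kabsch_superpose(helix, base[rows])
    out = base.copy()
    out[rows] = fit.apply(helix)
    return out


def _apply_forcing(
    frames: np.ndarray,
    row_i: int,
    row_j: int,
    targets: np.ndarray,
) -> None:
    """Symmetrically move atoms i and j to the target distance, in place."""
    xi = frames[:, row_i]
    xj = frames[:, row_j]
    mid = 0.5 * (xi + xj)
    diff = xj - xi
    dist = np.linalg.norm(diff, axis=1, keepdims=True)
    unit = diff / dist
    half = 0.5 * targets[:, None]
    frames[:, row_i] = mid - unit * half
    frames[:, row_j] = mid + unit * half


def _sigma_per_atom(spec: SyntheticSpec, scale: float, helix_rows: set[int]) -> np.ndarray:
    lookup = spec.segment_map.lookup()
    lo = spec.residue_range[0]
    sigma = np.empty(spec.n_residues)
    for k in range(spec.n_residues):
        seg = lookup[lo + k]
        sigma[k] = spec.per_segment_sigma[seg] * scale
        if k in helix_rows:
            sigma[k] = spec.helix_sigma
    return sigma


def _validate_base_geometry(
    spec: SyntheticSpec, base: np.ndarray, forced_rows: list[tuple[int, int]]
) -> None:
    """No un-forced eligible pair may approach the contact cutoff.

    This is the guarantee that makes the planted pair set the *exact*
    consensus ground truth: on the noiseless base geometry (with forced
    pairs at their target distance) every other eligible pair must stay at
    least 0.5 A clear of the contact cutoff.
    """
    test = base.copy()
    for ri, rj in forced_rows:
        frames = test[None, :, :].copy()
        _apply_forcing(frames, ri, rj, np.array([spec.contact_target]))
        test = frames[0]
    dist = cdist(test, test)
    n = spec.n_residues
    sep = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    eligible = np.triu(sep >= spec.rules.min_separation)
    forced_set = {tuple(sorted(p)) for p in forced_rows}
    bad = np.argwhere(eligible & (dist <= spec.rules.contact_cutoff + 0.5))
    for a, b in bad:
        if (min(a, b), max(a, b)) not in forced_set:
            lo = spec.residue_range[0]
            raise ValueError(
                f"ambiguous geometry: un-forced pair ({lo + a},{lo + b}) at "
                f"{dist[a, b]:.2f} A is too close to the contact cutoff"
            )


def generate_ensemble(
    spec: SyntheticSpec,
    role: str,
    label: str | None = None,
    replicate: int = 0,
    reference: StructureModel | None = None,
) -> tuple[TrajectoryEnsemble, GroundTruth]:
    """One synthetic ensemble (WT or mutant) plus its ground truth.

    ``replicate`` distinguishes multiple mutants generated from the same
    spec; it enters the random stream, so different mutants get independent
    jitter while remaining reproducible.  A custom ``reference`` chain may
    replace the default super-coil (it must match the spec's size and
    numbering).
    """
    if role not in ("WT", "mutant"):
        raise ValueError("role must be 'WT' or 'mutant'")
    is_mut = role == "mutant"
    label = label or ("WT" if not is_mut else f"MUT{replicate + 1}")

    if reference is None:
        reference = make_reference_chain(spec.n_residues, spec.residue_range, spec.seed)
    elif (
        len(reference) != spec.n_residues
        or reference.residue_index_range != spec.residue_range
    ):
        raise ValueError("custom reference does not match the spec's size/numbering")
    base = reference.coordinates
    lo = spec.residue_range[0]

    if is_mut:
        center = base.mean(axis=0)
        base = center + spec.compaction * (base - center)

    helix_rows: set[int] = set()
    if is_mut and spec.planted_helix is not None:
        a, b = spec.planted_helix
        rows = np.arange(a - lo, b - lo + 1)
        base = _carve_helix(base, rows)
        helix_rows = set(int(r) for r in rows)

    forced_rows = [(i - lo, j - lo) for i, j in spec.baseline_pairs]
    if is_mut:
        forced_rows += [(i - lo, j - lo) for i, j, _k in spec.planted_pairs]
    else:
        # the WT must keep planted pairs well outside the cutoff
        for i, j, _k in spec.planted_pairs:
            d = np.linalg.norm(base[i - lo] - base[j - lo])
            if d < spec.rules.contact_cutoff + 1.0:
                raise ValueError(
                    f"spec unsatisfiable: planted pair ({i},{j}) already at "
                    f"{d:.2f} A in the WT reference geometry"
                )

    _validate_base_geometry(spec, base, forced_rows)

    scale = spec.mutant_sigma_scale if is_mut else 1.0
    sigma = _sigma_per_atom(spec, scale, helix_rows)

    rng = np.random.default_rng([spec.seed, 9176, replicate, 1 if is_mut else 0])
    frames = base[None, :, :] + rng.normal(
        size=(spec.n_frames, spec.n_residues, 3)
    ) * sigma[None, :, None]
    for ri, rj in forced_rows:
        targets = spec.contact_target + rng.uniform(-0.2, 0.2, size=spec.n_frames)
        _apply_forcing(frames, ri, rj, targets)

    ensemble = TrajectoryEnsemble(reference=reference, frames=frames, label=label)
    truth = GroundTruth(
        label=label,
        role=role,
        expected_segment_rmsf={
            seg: s * scale * np.sqrt(3.0)
            for seg, s in spec.per_segment_sigma.items()
        },
        expected_rg_ratio=spec.compaction if is_mut else 1.0,
        expected_consensus_pairs=list(spec.planted_pairs),
        expected_gained_helix=spec.planted_helix if is_mut else None,
    )
    return ensemble, truth


def generate_study(
    spec: SyntheticSpec, mutant_labels: tuple[str, ...] = ("M1", "M2", "M3")
) -> tuple[TrajectoryEnsemble, list[TrajectoryEnsemble], GroundTruth]:
    """A WT ensemble plus one mutant ensemble per label, from one spec."""
    wt, _ = generate_ensemble(spec, "WT", label="WT")
    mutants = []
    truth = None
    for k, lab in enumerate(mutant_labels):
        ens, truth = generate_ensemble(spec, "mutant", label=lab, replicate=k)
        mutants.append(ens)
    if truth is None:
        raise ValueError("need at least one mutant label")
    return wt, mutants, truth


# ---------------------------------------------------------------------------
# Preset specs


def _forced_pair_slots(
    residue_range: tuple[int, int],
    exclude: list[tuple[int, int]],
    spacing: int = 10,
) -> list[tuple[int, int]]:
    """Candidate (i, i + one-turn) partner pairs on a regular grid.

    Partners one coil turn apart sit ~12 A from each other and their forcing
    midpoints fall in the empty gap between turns; a grid spacing of 10
    residues keeps distinct forced pairs out of each other's way.
    """
    lo, hi = residue_range
    guard = set()
    for a, b in exclude:
        guard |= set(range(a - 4, b + 5))
    slots = []
    i = lo + 3
    while i + _RESIDUES_PER_TURN <= hi - 2:
        j = i + _RESIDUES_PER_TURN
        if i not in guard and j not in guard:
            slots.append((i, j))
        i += spacing
    return slots


def demo_spec(seed: int = 0, n_frames: int = 300) -> SyntheticSpec:
    """The full-size demo study: USP8-like numbering 402-1118.

    Three mutants (generated from this spec with distinct replicate ids)
    share 15 planted persistent contacts inside the DUB domain, a planted
    helix at residues 610-615, and 10% compaction; 40 baseline contacts are
    common to all models including the WT.
    """
    residue_range = (402, 1118)
    helix = (610, 615)
    segmap = default_segment_map()
    rng = np.random.default_rng([seed, 2693])
    slots = _forced_pair_slots(residue_range, exclude=[helix])
    dub_lo, dub_hi = segmap.segments["DUB"][0]
    dub_slots = [s for s in slots if dub_lo <= s[0] and s[1] <= dub_hi]
    other_slots = [s for s in slots if s not in dub_slots]
    if len(dub_slots) < 15:
        raise ValueError("not enough DUB-internal slots for 15 planted pairs")
    planted_idx = rng.choice(len(dub_slots), size=15, replace=False)
    planted = [dub_slots[k] for k in sorted(planted_idx)]
    remaining = other_slots + [s for s in dub_slots if s not in planted]
    base_idx = rng.choice(len(remaining), size=40, replace=False)
    baseline = [remaining[k] for k in sorted(base_idx)]
    return SyntheticSpec(
        n_residues=717,
        residue_range=residue_range,
        segment_map=segmap,
        baseline_pairs=baseline,
        planted_pairs=[(i, j, "contact") for i, j in planted],
        planted_helix=helix,
        n_frames=n_frames,
        seed=seed,
    )


def small_spec(seed: int = 0, n_frames: int = 500, **overrides) -> SyntheticSpec:
    """A 120-residue spec for fast tests; no planted features by default."""
    return SyntheticSpec(n_frames=n_frames, seed=seed, **overrides)


# ---------------------------------------------------------------------------
# Spec (de)serialization


def spec_to_json(spec: SyntheticSpec, path: str | Path) -> None:
    data = {
        "n_residues": spec.n_residues,
        "residue_range": list(spec.residue_range),
        "per_segment_sigma": spec.per_segment_sigma,
        "mutant_sigma_scale": spec.mutant_sigma_scale,
        "compaction": spec.compaction,
        "baseline_pairs": [list(p) for p in spec.baseline_pairs],
        "planted_pairs": [list(p) for p in spec.planted_pairs],
        "planted_helix": list(spec.planted_helix) if spec.planted_helix else None,
        "helix_sigma": spec.helix_sigma,
        "n_frames": spec.n_frames,
        "seed": spec.seed,
        "contact_target": spec.contact_target,
        "segments": {
            name: intervals
            for name, intervals in spec.segment_map.segments.items()
            if name != "LINKER"
        },
    }
    Path(path).write_text(json.dumps(data, indent=2) + "\n")


def spec_from_json(path: str | Path) -> SyntheticSpec:
    data = json.loads(Path(path).read_text())
    rng = tuple(data["residue_range"])
    segmap = None
    if "segments" in data:
        named = SegmentMap(
            segments={
                name: [tuple(iv) for iv in intervals]
                for name, intervals in data["segments"].items()
            },
            residue_range=rng,
        )
        segmap = complete_segment_map(named, rng)
    return SyntheticSpec(
        n_residues=data["n_residues"],
        residue_range=rng,
        segment_map=segmap,
        per_segment_sigma=data.get("per_segment_sigma", dict(_DEFAULT_SIGMA)),
        mutant_sigma_scale=data.get("mutant_sigma_scale", 0.5),
        compaction=data.get("compaction", 0.9),
        baseline_pairs=[tuple(p) for p in data.get("baseline_pairs", [])],
        planted_pairs=[tuple(p) for p in data.get("planted_pairs", [])],
        planted_helix=tuple(data["planted_helix"]) if data.get("planted_helix") else None,
        helix_sigma=data.get("helix_sigma", 0.1),
        n_frames=data.get("n_frames", 500),
        seed=data.get("seed", 0),
        contact_target=data.get("contact_target", 3.4),
    )
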