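"""Residue-residue interaction detection, fingerprints, and WT/mutant comparison.

Interactions are detected per frame with explicit geometric rules at residue
resolution:

* ``contact``: any heavy-atom pair between two residues within 4.5 A;
* ``hbond``: any donor/acceptor heavy atom (N or O) pair within 3.5 A
  (no angle term -- the rule must also work on reduced representations);
* ``saltbridge``: side-chain nitrogen of Arg/Lys/His within 4.0 A of a
  side-chain carboxylate oxygen of Asp/Glu (either direction).

Residue pairs closer than 3 positions in sequence are excluded so trivially
bonded neighbours do not dominate the fingerprint.  A fingerprint is the
boolean (pair, kind) x frame occupancy matrix; the comparison layer computes
interaction diversity and frequency deltas, per-segment-category
redistribution, and the consensus pairs present in every mutant but absent
from the wild type.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .structure_io import SegmentMap, StructureModel, TrajectoryEnsemble

__all__ = [
    "InteractionRules",
    "InteractionEvent",
    "FingerprintMatrix",
    "ComparisonMetrics",
    "detect_interactions",
    "build_fingerprint",
    "diversity_and_frequency",
    "segment_shares",
    "segment_redistribution",
    "consensus_unique_pairs",
    "pair_category",
]

_BASIC_SIDECHAIN_N = {
    "ARG": {"NE", "NH1", "NH2"},
    "LYS": {"NZ"},
    "HIS": {"ND1", "NE2"},
}
_ACIDIC_SIDECHAIN_O = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
}


@dataclass(frozen=True)
class InteractionRules:
    """Geometric cutoffs (Angstrom) and the sequence-separation exclusion."""

    contact_cutoff: float = 4.5
    hbond_cutoff: float = 3.5
    saltbridge_cutoff: float = 4.0
    min_separation: int = 3  # same-chain pairs with |i - j| < this are excluded


@dataclass(frozen=True)
class InteractionEvent:
    frame: int
    pair: tuple[int, int]  # residue indices, i < j
    kind: str
    min_distance: float


@dataclass
class FingerprintMatrix:
    """(pair, kind) x frame boolean occupancy with per-pair frequencies."""

    pairs: list[tuple[tuple[int, int], str]]
    occupancy: np.ndarray  # n_pairs x T, bool
    label: str = ""

    @property
    def n_frames(self) -> int:
        return self.occupancy.shape[1]

    @property
    def frequency(self) -> np.ndarray:
        if len(self.pairs) == 0:
            return np.zeros(0)
        return self.occupancy.mean(axis=1)

    def present_set(
        self, presence_threshold: float = 0.0, kind_aware: bool = True
    ) -> set:
        """Rows passing the threshold (threshold 0 means present in >=1 frame)."""
        out = set()
        for row, f in zip(self.pairs, self.frequency):
            ok = f >= presence_threshold if presence_threshold > 0 else f > 0
            if ok:
                out.add(row if kind_aware else row[0])
        return out

    def diversity(self, presence_threshold: float = 0.0) -> int:
        return len(self.present_set(presence_threshold))

    def mean_events_per_frame(self) -> float:
        if len(self.pairs) == 0:
            return 0.0
        return float(self.occupancy.sum() / self.n_frames)


@dataclass
class ComparisonMetrics:
    """Cross-model interaction deltas, all relative to the wild type."""

    diversity_delta_pct: float
    frequency_delta_pct: float
    per_mutant_diversity_delta_pct: dict[str, float]
    per_mutant_frequency_delta_pct: dict[str, float]
    redistribution: dict[str, dict[str, float]]  # mutant -> category -> pp delta
    redistribution_mean: dict[str, float]  # category -> mean pp delta
    consensus_unique_pairs: list[dict]


class _ResidueLayout:
    """Atom-row bookkeeping for one structure, reused across frames."""

    def __init__(self, structure: StructureModel):
        keys: list[tuple[str, int]] = []
        key_to_ord: dict[tuple[str, int], int] = {}
        ridx = np.empty(len(structure), dtype=int)
        for row, atom in enumerate(structure.atoms):
            if not atom.element:
                raise ValueError(
                    f"atom serial {atom.serial}: missing element annotation"
                )
            key = (atom.chain, atom.residue_index)
            if key not in key_to_ord:
                key_to_ord[key] = len(keys)
                keys.append(key)
            ridx[row] = key_to_ord[key]
        self.keys = keys
        self.ridx = ridx
        self.n_res = len(keys)
        elements = np.array([a.element for a in structure.atoms])
        names = np.array([a.name for a in structure.atoms])
        resnames = np.array([a.residue_name for a in structure.atoms])
        self.heavy = np.flatnonzero(elements != "H")
        self.don_acc = np.flatnonzero(np.isin(elements, ("N", "O")))
        basic = np.zeros(len(structure), dtype=bool)
        acidic = np.zeros(len(structure), dtype=bool)
        for row in range(len(structure)):
            basic[row] = names[row] in _BASIC_SIDECHAIN_N.get(resnames[row], ())
            acidic[row] = names[row] in _ACIDIC_SIDECHAIN_O.get(resnames[row], ())
        self.basic_n = np.flatnonzero(basic)
        self.acidic_o = np.flatnonzero(acidic)

        res_index = np.array([k[1] for k in keys])
        chain_code = np.array([hash(k[0]) for k in keys])
        same_chain = chain_code[:, None] == chain_code[None, :]
        sep = np.abs(res_index[:, None] - res_index[None, :])
        self.res_index = res_index
        # eligible[a, b]: pair may interact (upper triangle applied later)
        self.eligible = ~same_chain | (sep >= 1)  # refined per rules at call time
        self.same_chain = same_chain
        self.sep = sep
        self.one_atom_per_residue = len(structure) == self.n_res

    def eligible_mask(self, min_separation: int) -> np.ndarray:
        ok = ~self.same_chain | (self.sep >= min_separation)
        return np.triu(ok, k=1) & np.triu(np.ones_like(ok), k=1)


def _min_dist_matrix(
    dist: np.ndarray, rows_a: np.ndarray, rows_b: np.ndarray, layout: _ResidueLayout
) -> np.ndarray:
    """Per-residue-pair minimum distance over the given atom subsets."""
    m = np.full((layout.n_res, layout.n_res), np.inf)
    if rows_a.size == 0 or rows_b.size == 0:
        return m
    sub = dist[np.ix_(rows_a, rows_b)]
    ra = layout.ridx[rows_a]
    rb = layout.ridx[rows_b]
    np.minimum.at(m, (ra[:, None], rb[None, :]), sub)
    return m


def _detect_frame(
    frame_coords: np.ndarray,
    layout: _ResidueLayout,
    rules: InteractionRules,
    frame: int,
) -> list[InteractionEvent]:
    dist = cdist(frame_coords, frame_coords)
    elig = layout.eligible_mask(rules.min_separation)

    heavy_min = _min_dist_matrix(dist, layout.heavy, layout.heavy, layout)
    heavy_min = np.minimum(heavy_min, heavy_min.T)
    hb_min = _min_dist_matrix(dist, layout.don_acc, layout.don_acc, layout)
    hb_min = np.minimum(hb_min, hb_min.T)
    sb_min = _min_dist_matrix(dist, layout.basic_n, layout.acidic_o, layout)
    sb_min = np.minimum(sb_min, sb_min.T)

    events: list[InteractionEvent] = []
    for kind, matrix, cutoff in (
        ("contact", heavy_min, rules.contact_cutoff),
        ("hbond", hb_min, rules.hbond_cutoff),
        ("saltbridge", sb_min, rules.saltbridge_cutoff),
    ):
        hits = np.argwhere(elig & (matrix <= cutoff))
        for a, b in hits:
            ra, rb = int(layout.res_index[a]), int(layout.res_index[b])
            pair = (min(ra, rb), max(ra, rb))
            events.append(InteractionEvent(frame, pair, kind, float(matrix[a, b])))
    events.sort(key=lambda e: (e.pair, e.kind))
    return events


def detect_interactions(
    frame_coords: np.ndarray,
    structure: StructureModel,
    rules: InteractionRules = InteractionRules(),
    frame: int = 0,
) -> list[InteractionEvent]:
    """All typed interaction events in one frame.

    Residue pairs are identified by residue index (i < j); pairs on the same
    chain separated by fewer than ``rules.min_separation`` positions are
    skipped.
    """
    frame_coords = np.asarray(frame_coords, dtype=float)
    if frame_coords.shape != (len(structure), 3):
        raise ValueError("frame_coords must be N x 3 matching the structure")
    layout = _ResidueLayout(structure)
    return _detect_frame(frame_coords, layout, rules, frame)


def build_fingerprint(
    ensemble: TrajectoryEnsemble,
    structure: StructureModel | None = None,
    rules: InteractionRules = InteractionRules(),
) -> FingerprintMatrix:
    """Occupancy matrix over all (pair, kind) rows observed in any frame."""
    structure = structure or ensemble.reference
    layout = _ResidueLayout(structure)
    per_frame: list[set] = []
    rows: dict[tuple[tuple[int, int], str], None] = {}
    for t in range(ensemble.n_frames):
        events = _detect_frame(ensemble.frames[t], layout, rules, frame=t)
        seen = {(e.pair, e.kind) for e in events}
        per_frame.append(seen)
        for key in seen:
            rows.setdefault(key, None)
    pair_list = sorted(rows, key=lambda pk: (pk[0], pk[1]))
    occupancy = np.zeros((len(pair_list), ensemble.n_frames), dtype=bool)
    index = {key: i for i, key in enumerate(pair_list)}
    for t, seen in enumerate(per_frame):
        for key in seen:
            occupancy[index[key], t] = True
    return FingerprintMatrix(pairs=pair_list, occupancy=occupancy, label=ensemble.label)


def diversity_and_frequency(
    wt: FingerprintMatrix,
    mutants: list[FingerprintMatrix],
    presence_threshold: float = 0.0,
) -> ComparisonMetrics:
    """Interaction diversity and frequency deltas of mutants versus WT.

    Diversity D = number of distinct (pair, kind) rows present at the
    threshold; frequency F = mean number of interaction events per frame.
    Deltas are 100 * (mutant - WT) / WT, averaged over mutants.
    """
    if not mutants:
        raise ValueError("need at least one mutant fingerprint")
    d_wt = wt.diversity(presence_threshold)
    if d_wt == 0:
        raise ValueError("WT diversity is zero; relative deltas undefined")
    f_wt = wt.mean_events_per_frame()
    per_d: dict[str, float] = {}
    per_f: dict[str, float] = {}
    for m in mutants:
        per_d[m.label] = 100.0 * (m.diversity(presence_threshold) - d_wt) / d_wt
        per_f[m.label] = 100.0 * (m.mean_events_per_frame() - f_wt) / f_wt
    return ComparisonMetrics(
        diversity_delta_pct=float(np.mean(list(per_d.values()))),
        frequency_delta_pct=float(np.mean(list(per_f.values()))),
        per_mutant_diversity_delta_pct=per_d,
        per_mutant_frequency_delta_pct=per_f,
        redistribution={},
        redistribution_mean={},
        consensus_unique_pairs=[],
    )


def pair_category(pair: tuple[int, int], segment_map: SegmentMap) -> str:
    """Unordered segment-pair category label, e.g. 'DUB-DUB' or 'DUB-LINKER'."""
    a = segment_map.segment_of(pair[0])
    b = segment_map.segment_of(pair[1])
    return "-".join(sorted((a, b)))


def segment_shares(fp: FingerprintMatrix, segment_map: SegmentMap) -> dict[str, float]:
    """Fraction of total interaction occupancy in each segment-pair category."""
    totals: dict[str, float] = {}
    grand = 0.0
    for (pair, _kind), row in zip(fp.pairs, fp.occupancy):
        cat = pair_category(pair, segment_map)
        occ = float(row.sum())
        totals[cat] = totals.get(cat, 0.0) + occ
        grand += occ
    if grand == 0:
        return {}
    return {cat: occ / grand for cat, occ in totals.items()}


def segment_redistribution(
    wt: FingerprintMatrix,
    mutants: list[FingerprintMatrix],
    segment_map: SegmentMap,
) -> tuple[dict[str, dict[str, float]], dict[str, float]]:
    """Per-category occupancy-share deltas (percentage points) vs WT.

    Returns (per-mutant deltas, mutant-averaged deltas), over the union of
    categories seen in any model.
    """
    wt_shares = segment_shares(wt, segment_map)
    per_mutant: dict[str, dict[str, float]] = {}
    cats: set[str] = set(wt_shares)
    mut_shares = {}
    for m in mutants:
        mut_shares[m.label] = segment_shares(m, segment_map)
        cats |= set(mut_shares[m.label])
    for m in mutants:
        per_mutant[m.label] = {
            cat: 100.0 * (mut_shares[m.label].get(cat, 0.0) - wt_shares.get(cat, 0.0))
            for cat in sorted(cats)
        }
    mean = {
        cat: float(np.mean([per_mutant[m.label][cat] for m in mutants]))
        for cat in sorted(cats)
    }
    return per_mutant, mean


def consensus_unique_pairs(
    wt: FingerprintMatrix,
    mutants: list[FingerprintMatrix],
    presence_threshold: float = 0.0,
    kind_aware: bool = True,
    segment_map: SegmentMap | None = None,
) -> list[dict]:
    """Pairs present in every mutant but absent from WT.

    Set algebra on present-pair sets: intersection over mutants minus the WT
    set.  With ``kind_aware`` (default) identity is (pair, kind); otherwise
    the amino-acid pair alone.  Each hit is annotated with its segment-pair
    category when a segment map is given.
    """
    if len(mutants) < 2:
        raise ValueError("consensus requires at least 2 mutants")
    if not 0.0 <= presence_threshold <= 1.0:
        raise ValueError("presence_threshold must be in [0, 1]")
    common = set.intersection(
        *(m.present_set(presence_threshold, kind_aware) for m in mutants)
    )
    unique = common - wt.present_set(presence_threshold, kind_aware)
    out = []
    for item in sorted(unique, key=lambda x: (x[0] if kind_aware else x)):
        pair = item[0] if kind_aware else item
        rec: dict = {
            "pair": list(pair),
            "kind": item[1] if kind_aware else None,
        }
        if segment_map is not None:
            rec["category"] = pair_category(pair, segment_map)
        out.append(rec)
    return out
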