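"""Independent reference implementations used only to cross-check the package.

Everything here is deliberately written along a different algorithmic route
than the library code: quaternion (Horn) superposition instead of SVD-Kabsch,
window-by-window motif matching instead of a compiled regex, and plain
nested-loop interaction enumeration instead of vectorized distance matrices.
"""

from __future__ import annotations

import numpy as np


def quaternion_rmsd(mobile: np.ndarray, target: np.ndarray, weights=None) -> float:
    """Optimal superposition RMSD via Horn's quaternion eigenvalue method."""
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    n = mobile.shape[0]
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    w = w / w.sum()
    mc = mobile - w @ mobile
    tc = target - w @ target

    # weighted correlation matrix
    s = (mc * w[:, None]).T @ tc
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(k)[-1]
    e0 = float(np.sum(w[:, None] * (mc**2 + tc**2)))
    return float(np.sqrt(max(e0 - 2.0 * lam, 0.0)))


_MOTIF_CHECKS = [
    lambda c: c == "P",
    lambda c: True,
    lambda c: c in "VI",
    lambda c: c in "DN",
    lambda c: c == "R",
    lambda c: True,
    lambda c: True,
    lambda c: c == "K",
    lambda c: c == "P",
]


def brute_force_motif_scan(sequence: str, offset: int = 1) -> list[tuple[int, str]]:
    """All 9-residue windows matching the SH3BM pattern, position by position."""
    hits = []
    for i in range(len(sequence) - 8):
        window = sequence[i : i + 9]
        if all(check(c) for check, c in zip(_MOTIF_CHECKS, window)):
            hits.append((offset + i, window))
    return hits


_BASIC_N = {
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
    "HIS": ("ND1", "NE2"),
}
_ACIDIC_O = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}


def brute_force_events(coords, structure, contact=4.5, hbond=3.5, saltbridge=4.0, min_sep=3):
    """Exhaustive typed interaction enumeration: plain loops, no vectorization.

    Returns a set of ((i, j), kind) residue-pair records for one frame.
    """
    residues: dict[tuple[str, int], list[int]] = {}
    for row, atom in enumerate(structure.atoms):
        residues.setdefault((atom.chain, atom.residue_index), []).append(row)
    keys = list(residues)
    found = set()
    for a in range(len(keys)):
        for b in range(a + 1, len(keys)):
            (ch_a, ri), (ch_b, rj) = keys[a], keys[b]
            if ch_a == ch_b and abs(ri - rj) < min_sep:
                continue
            pair = (min(ri, rj), max(ri, rj))
            for ra in residues[keys[a]]:
                for rb in residues[keys[b]]:
                    at_a = structure.atoms[ra]
                    at_b = structure.atoms[rb]
                    d = float(np.linalg.norm(np.asarray(coords[ra]) - np.asarray(coords[rb])))
                    if at_a.element != "H" and at_b.element != "H" and d <= contact:
                        found.add((pair, "contact"))
                    if (
                        at_a.element in ("N", "O")
                        and at_b.element in ("N", "O")
                        and d <= hbond
                    ):
                        found.add((pair, "hbond"))
                    ab_salt = at_a.name in _BASIC_N.get(
                        at_a.residue_name, ()
                    ) and at_b.name in _ACIDIC_O.get(at_b.residue_name, ())
                    ba_salt = at_b.name in _BASIC_N.get(
                        at_b.residue_name, ()
                    ) and at_a.name in _ACIDIC_O.get(at_a.residue_name, ())
                    if (ab_salt or ba_salt) and d <= saltbridge:
                        found.add((pair, "saltbridge"))
    return found


def brute_force_fingerprint(ensemble, structure=None, **rule_kwargs):
    """Per-frame recount: list of event sets, one per frame."""
    structure = structure or ensemble.reference
    return [
        brute_force_events(ensemble.frames[t], structure, **rule_kwargs)
        for t in range(ensemble.n_frames)
    ]


def brute_force_present(frame_sets, threshold=0.0):
    """Present-pair set from per-frame event sets."""
    t_total = len(frame_sets)
    counts: dict = {}
    for s in frame_sets:
        for key in s:
            counts[key] = counts.get(key, 0) + 1
    if threshold > 0:
        return {k for k, c in counts.items() if c / t_total >= threshold}
    return set(counts)


def ideal_helix(n, rise=1.5, twist_deg=100.0, radius=2.3):
    t = np.deg2rad(twist_deg) * np.arange(n)
    return np.column_stack([radius * np.cos(t), radius * np.sin(t), rise * np.arange(n)])
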