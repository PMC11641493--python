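"""Interaction detection, fingerprints, and the WT/mutant comparison algebra."""

import numpy as np
import pytest

from oracles import (
    brute_force_events,
    brute_force_fingerprint,
    brute_force_present,
)
from conftest import ca_structure, ensemble_from_frames
from trajdiff.structure_io import Atom, SegmentMap, StructureModel, complete_segment_map
from trajdiff.interactions import (
    FingerprintMatrix,
    InteractionRules,
    build_fingerprint,
    consensus_unique_pairs,
    detect_interactions,
    diversity_and_frequency,
    segment_redistribution,
    segment_shares,
)


def spread_positions(n, rng, spacing=20.0):
    """Residue anchor points far apart so only intended pairs interact."""
    return np.arange(n)[:, None] * [spacing, 0, 0] + rng.normal(scale=0.5, size=(n, 3))


def allatom_structure(rows):
    """rows: (name, element, residue_index, residue_name, position)."""
    atoms = [
        Atom(
            serial=k + 1,
            name=name,
            element=element,
            residue_index=ri,
            residue_name=rn,
            chain="A",
            position=np.asarray(pos, dtype=float),
        )
        for k, (name, element, ri, rn, pos) in enumerate(rows)
    ]
    return StructureModel(atoms=atoms)


def fingerprint_from_counts(pair_counts, t_total, label):
    """Build a FingerprintMatrix with given per-row occupancy counts."""
    pairs = list(pair_counts)
    occ = np.zeros((len(pairs), t_total), dtype=bool)
    for k, key in enumerate(pairs):
        occ[k, : pair_counts[key]] = True
    return FingerprintMatrix(pairs=pairs, occupancy=occ, label=label)


class TestDetectInteractions:
    def test_simple_contact(self):
        s = ca_structure([[0, 0, 0], [3, 0, 0]], residue_indices=[10, 15])
        events = detect_interactions(s.coordinates, s)
        assert len(events) == 1
        e = events[0]
        assert e.pair == (10, 15) and e.kind == "contact"
        assert e.min_distance == pytest.approx(3.0)

    def test_beyond_cutoff_no_event(self):
        s = ca_structure([[0, 0, 0], [6, 0, 0]], residue_indices=[10, 15])
        assert detect_interactions(s.coordinates, s) == []

    def test_sequence_separation_excluded(self):
        s = ca_structure([[0, 0, 0], [3, 0, 0]], residue_indices=[10, 12])
        assert detect_interactions(s.coordinates, s) == []

    def test_typed_events_match_bruteforce(self, rng):
        """Mixed contact/hbond/saltbridge toy frame equals exhaustive enumeration."""
        rows = [
            ("CA", "C", 1, "ARG", [0, 0, 0]),
            ("NH1", "N", 1, "ARG", [1.5, 1, 0]),
            ("CA", "C", 5, "ASP", [3.0, 0, 0]),
            ("OD1", "O", 5, "ASP", [3.2, 1.5, 0]),
            ("CA", "C", 9, "SER", [5.5, 0.5, 0]),
            ("OG", "O", 9, "SER", [5.0, 2.0, 0]),
            ("CA", "C", 13, "LYS", [40, 0, 0]),
            ("NZ", "N", 13, "LYS", [41, 1, 0]),
        ]
        s = allatom_structure(rows)
        got = {(e.pair, e.kind) for e in detect_interactions(s.coordinates, s)}
        assert got == brute_force_events(s.coordinates, s)

    def test_random_systems_match_bruteforce(self, rng):
        """Random small all-atom systems: vectorized path equals plain loops."""
        names = [("CA", "C"), ("NZ", "N"), ("OD1", "O"), ("CB", "C")]
        resnames = ["ALA", "LYS", "ASP", "ARG", "GLU", "HIS", "SER"]
        for _ in range(25):
            rows = []
            n_res = int(rng.integers(3, 9))
            for ri in range(n_res):
                anchor = rng.uniform(0, 15, size=3)
                rn = resnames[int(rng.integers(len(resnames)))]
                for _a in range(int(rng.integers(1, 4))):
                    name, elem = names[int(rng.integers(len(names)))]
                    rows.append(
                        (name, elem, 1 + ri * 4, rn, anchor + rng.normal(scale=1.5, size=3))
                    )
            # unique atom names within a residue are not required by the rules
            s = allatom_structure(rows)
            got = {(e.pair, e.kind) for e in detect_interactions(s.coordinates, s)}
            assert got == brute_force_events(s.coordinates, s)


class TestFingerprint:
    def test_static_ensemble_frequencies_are_one(self, rng):
        pos = spread_positions(6, rng, spacing=3.9)
        s = ca_structure(pos, residue_indices=[1, 5, 9, 13, 17, 21])
        ens = ensemble_from_frames(np.repeat(pos[None], 4, axis=0), structure=s)
        fp = build_fingerprint(ens)
        assert len(fp.pairs) > 0
        np.testing.assert_allclose(fp.frequency, 1.0)

    def test_half_occupancy(self):
        far = np.array([[0, 0, 0], [20, 0, 0]], dtype=float)
        near = np.array([[0, 0, 0], [3, 0, 0]], dtype=float)
        s = ca_structure(far, residue_indices=[1, 9])
        fp = build_fingerprint(ensemble_from_frames(np.array([far, near]), structure=s))
        assert fp.pairs == [((1, 9), "contact")]
        assert fp.frequency[0] == pytest.approx(0.5)

    def test_occupancy_matches_per_frame_recount(self, rng):
        frames = rng.uniform(0, 12, size=(5, 7, 3))
        s = ca_structure(frames[0], residue_indices=[1, 5, 9, 13, 17, 21, 25])
        ens = ensemble_from_frames(frames, structure=s)
        fp = build_fingerprint(ens)
        oracle_frames = brute_force_fingerprint(ens)
        for k, key in enumerate(fp.pairs):
            expected = [key in oracle_frames[t] for t in range(5)]
            assert list(fp.occupancy[k]) == expected
        # and no observed event is missing from the matrix
        assert set(fp.pairs) == brute_force_present(oracle_frames)


class TestDiversityFrequency:
    def test_identical_mutants_zero_deltas(self, rng):
        frames = rng.uniform(0, 10, size=(3, 6, 3))
        s = ca_structure(frames[0], residue_indices=[1, 5, 9, 13, 17, 21])
        wt = build_fingerprint(ensemble_from_frames(frames, structure=s, label="WT"))
        m1 = build_fingerprint(ensemble_from_frames(frames, structure=s, label="M1"))
        metrics = diversity_and_frequency(wt, [m1])
        assert metrics.diversity_delta_pct == 0.0
        assert metrics.frequency_delta_pct == 0.0

    def test_hand_computed_diversity_delta(self):
        """WT 10 rows, mutants 12 and 11 -> mean(20%, 10%) = 15%."""
        t = 4
        wt = fingerprint_from_counts({((i, i + 5), "contact"): t for i in range(10)}, t, "WT")
        m1 = fingerprint_from_counts({((i, i + 5), "contact"): t for i in range(12)}, t, "M1")
        m2 = fingerprint_from_counts({((i, i + 5), "contact"): t for i in range(11)}, t, "M2")
        metrics = diversity_and_frequency(wt, [m1, m2], presence_threshold=0.0)
        assert metrics.diversity_delta_pct == pytest.approx(15.0)

    def test_zero_wt_diversity_is_error(self):
        empty = FingerprintMatrix(pairs=[], occupancy=np.zeros((0, 3), dtype=bool), label="WT")
        m = fingerprint_from_counts({((1, 9), "contact"): 3}, 3, "M1")
        with pytest.raises(ValueError, match="diversity"):
            diversity_and_frequency(empty, [m])

    def test_threshold_monotonicity(self, rng):
        """Raising the presence threshold never increases diversity."""
        counts = {((i, i + 7), "contact"): int(rng.integers(1, 11)) for i in range(20)}
        fp = fingerprint_from_counts(counts, 10, "X")
        last = fp.diversity(0.0)
        for theta in (0.2, 0.4, 0.6, 0.8, 1.0):
            cur = fp.diversity(theta)
            assert cur <= last
            last = cur


SEGMAP = complete_segment_map(
    SegmentMap(segments={"DUB": [(50, 80)]}, residue_range=(1, 100)), (1, 100)
)


class TestRedistribution:
    def test_identical_models_zero_deltas(self):
        fp = fingerprint_from_counts({((55, 60), "contact"): 5, ((10, 55), "contact"): 5}, 5, "WT")
        fp2 = fingerprint_from_counts({((55, 60), "contact"): 5, ((10, 55), "contact"): 5}, 5, "M")
        per_mut, mean = segment_redistribution(fp, [fp2], SEGMAP)
        assert all(abs(v) < 1e-12 for v in mean.values())

    def test_hand_computed_share_shift(self):
        """WT 8:2 DUB-DUB:DUB-LINKER, mutant 6:4 -> +20 pp on DUB-LINKER."""
        wt = fingerprint_from_counts(
            {((55, 60), "contact"): 8, ((10, 55), "contact"): 2}, 10, "WT"
        )
        mut = fingerprint_from_counts(
            {((55, 60), "contact"): 6, ((10, 55), "contact"): 4}, 10, "M"
        )
        per_mut, mean = segment_redistribution(wt, [mut], SEGMAP)
        assert mean["DUB-LINKER"] == pytest.approx(20.0)
        assert mean["DUB-DUB"] == pytest.approx(-20.0)

    def test_shares_sum_to_one(self, rng):
        counts = {
            ((int(a), int(a) + 7), "contact"): int(rng.integers(1, 9))
            for a in rng.choice(np.arange(1, 90), size=12, replace=False)
        }
        fp = fingerprint_from_counts(counts, 8, "X")
        shares = segment_shares(fp, SEGMAP)
        assert sum(shares.values()) == pytest.approx(1.0, abs=1e-9)


class TestConsensus:
    def test_set_algebra(self):
        wt = fingerprint_from_counts({((3, 9), "contact"): 2}, 2, "WT")  # CD
        m1 = fingerprint_from_counts({((1, 7), "contact"): 2, ((3, 9), "contact"): 2}, 2, "M1")
        m2 = fingerprint_from_counts({((1, 7), "contact"): 2, ((5, 11), "contact"): 2}, 2, "M2")
        out = consensus_unique_pairs(wt, [m1, m2])
        assert [tuple(r["pair"]) for r in out] == [(1, 7)]

    def test_wt_superset_gives_empty(self):
        rows = {((1, 7), "contact"): 2, ((3, 9), "contact"): 2}
        wt = fingerprint_from_counts(rows, 2, "WT")
        m1 = fingerprint_from_counts({((1, 7), "contact"): 2}, 2, "M1")
        m2 = fingerprint_from_counts(rows, 2, "M2")
        assert consensus_unique_pairs(wt, [m1, m2]) == []

    def test_threshold_monotonicity_of_consensus(self, rng):
        t = 10
        def random_fp(label):
            return fingerprint_from_counts(
                {((i, i + 7), "contact"): int(rng.integers(0, 11)) for i in range(15)},
                t,
                label,
            )
        wt, m1, m2 = random_fp("WT"), random_fp("M1"), random_fp("M2")
        last = None
        for theta in (0.0, 0.3, 0.6, 0.9):
            cur = {tuple(r["pair"]) for r in consensus_unique_pairs(wt, [m1, m2], theta)}
            if last is not None:
                # pairs can ENTER when WT drops below the threshold, but the
                # intersection over mutants can only shrink
                inter = set.intersection(
                    *(m.present_set(theta) for m in (m1, m2))
                )
                assert {(p, "contact") for p in cur} <= inter
            last = cur

    def test_kind_agnostic_mode(self):
        wt = fingerprint_from_counts({((3, 9), "hbond"): 2}, 2, "WT")
        m1 = fingerprint_from_counts({((3, 9), "contact"): 2}, 2, "M1")
        m2 = fingerprint_from_counts({((3, 9), "contact"): 2}, 2, "M2")
        # kind-aware: (3,9) contact is not in WT's typed set
        assert len(consensus_unique_pairs(wt, [m1, m2], kind_aware=True)) == 1
        # kind-agnostic: the amino-acid pair is shared with WT
        assert consensus_unique_pairs(wt, [m1, m2], kind_aware=False) == []

    def test_comparison_functions_match_bruteforce_on_small_systems(self, rng):
        """End-to-end oracle equivalence on enumerable systems (<=8 residues, <=5 frames)."""
        res_ids = [1, 5, 9, 13, 17, 21, 25, 29]
        def random_ens(label):
            frames = rng.uniform(0, 14, size=(int(rng.integers(2, 6)), 8, 3))
            s = ca_structure(frames[0], residue_indices=res_ids)
            return ensemble_from_frames(frames, structure=s, label=label)
        wt_e, m1_e, m2_e = random_ens("WT"), random_ens("M1"), random_ens("M2")
        wt, m1, m2 = (build_fingerprint(e) for e in (wt_e, m1_e, m2_e))
        o_wt, o_m1, o_m2 = (
            brute_force_fingerprint(e) for e in (wt_e, m1_e, m2_e)
        )
        for theta in (0.0, 0.5):
            got = {
                (tuple(r["pair"]), r["kind"])
                for r in consensus_unique_pairs(wt, [m1, m2], theta)
            }
            expected = set.intersection(
                brute_force_present(o_m1, theta), brute_force_present(o_m2, theta)
            ) - brute_force_present(o_wt, theta)
            assert got == expected
        if brute_force_present(o_wt):
            metrics = diversity_and_frequency(wt, [m1, m2])
            assert metrics.per_mutant_diversity_delta_pct["M1"] == pytest.approx(
                100.0
                * (len(brute_force_present(o_m1)) - len(brute_force_present(o_wt)))
                / len(brute_force_present(o_wt))
            )
            f_wt = np.mean([len(s) for s in o_wt])
            f_m2 = np.mean([len(s) for s in o_m2])
            assert metrics.per_mutant_frequency_delta_pct["M2"] == pytest.approx(
                100.0 * (f_m2 - f_wt) / f_wt
            )
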