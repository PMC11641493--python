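"""One-command WT-versus-mutant ensemble comparison.

``run_comparison`` orchestrates every analysis stage over one wild-type and
N mutant ensembles: per-model descriptor summaries (RMSD / RMSF / Rg table),
interaction fingerprints with diversity/frequency/redistribution deltas and
consensus unique pairs, and the secondary-structure comparison with
gained-helix detection.  ``render_report`` writes the result as a set of
plain TSV/JSON files plus a human-readable digest; outputs are byte-stable
for identical inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .interactions import (
    ComparisonMetrics,
    FingerprintMatrix,
    InteractionRules,
    build_fingerprint,
    consensus_unique_pairs,
    diversity_and_frequency,
    segment_redistribution,
)
from .metrics import ResidueProfile, SummaryRow, rmsf_per_residue, summarize_model
from .sse import GainedRegion, SSESummary, SSEThresholds, gained_sse_regions, helical_content
from .structure_io import SegmentMap, TrajectoryEnsemble, read_segment_map, read_trajectory

__all__ = ["ComparisonParams", "ComparisonReport", "run_comparison", "run_comparison_ensembles", "render_report"]


@dataclass
class ComparisonParams:
    """All thresholds of the comparison, with their defaults resolved."""

    rules: InteractionRules = field(default_factory=InteractionRules)
    sse_thresholds: SSEThresholds = field(default_factory=SSEThresholds)
    presence_threshold: float = 0.5  # a pair is 'present' if in >=50% of frames
    kind_aware_pairs: bool = True
    gain_threshold: float = 0.5
    background_threshold: float = 0.1
    mass_weighted_rg: bool = False

    def resolved(self) -> dict:
        return {
            "rules": asdict(self.rules),
            "sse_thresholds": asdict(self.sse_thresholds),
            "presence_threshold": self.presence_threshold,
            "kind_aware_pairs": self.kind_aware_pairs,
            "gain_threshold": self.gain_threshold,
            "background_threshold": self.background_threshold,
            "mass_weighted_rg": self.mass_weighted_rg,
        }


@dataclass
class ComparisonReport:
    """Everything the comparison produced, plus provenance."""

    summary_rows: list[SummaryRow]
    metrics: ComparisonMetrics
    rmsf_profiles: dict[str, ResidueProfile]
    sse_summaries: dict[str, SSESummary]
    gained_regions: list[GainedRegion]
    fingerprints: dict[str, FingerprintMatrix]
    segment_map: SegmentMap
    provenance: dict


def run_comparison_ensembles(
    wt: TrajectoryEnsemble,
    mutants: list[TrajectoryEnsemble],
    segment_map: SegmentMap,
    params: ComparisonParams | None = None,
    provenance_inputs: dict | None = None,
) -> ComparisonReport:
    """Compare a WT ensemble against mutant ensembles already in memory."""
    params = params or ComparisonParams()
    if not mutants:
        raise ValueError("need at least one mutant ensemble")
    labels = [wt.label] + [m.label for m in mutants]
    if len(set(labels)) != len(labels):
        raise ValueError(f"model label collision: {labels}")
    wt_range = wt.reference.residue_index_range
    for m in mutants:
        if m.reference.residue_index_range != wt_range:
            raise ValueError(
                f"residue range of {m.label} {m.reference.residue_index_range} "
                f"does not match WT {wt_range}"
            )

    all_models = [wt] + mutants
    summary_rows = [
        summarize_model(e, mass_weighted_rg=params.mass_weighted_rg)
        for e in all_models
    ]
    rmsf_profiles = {e.label: rmsf_per_residue(e) for e in all_models}

    fingerprints = {
        e.label: build_fingerprint(e, rules=params.rules) for e in all_models
    }
    wt_fp = fingerprints[wt.label]
    mut_fps = [fingerprints[m.label] for m in mutants]
    metrics = diversity_and_frequency(wt_fp, mut_fps, params.presence_threshold)
    per_mut_shift, mean_shift = segment_redistribution(wt_fp, mut_fps, segment_map)
    metrics.redistribution = per_mut_shift
    metrics.redistribution_mean = mean_shift
    if len(mutants) >= 2:
        metrics.consensus_unique_pairs = consensus_unique_pairs(
            wt_fp,
            mut_fps,
            presence_threshold=params.presence_threshold,
            kind_aware=params.kind_aware_pairs,
            segment_map=segment_map,
        )

    sse_summaries = {
        e.label: helical_content(e, thresholds=params.sse_thresholds)
        for e in all_models
    }
    gained = gained_sse_regions(
        sse_summaries[wt.label],
        [sse_summaries[m.label] for m in mutants],
        gain_threshold=params.gain_threshold,
        background_threshold=params.background_threshold,
    )

    provenance = {
        "tool": "trajdiff",
        "version": __version__,
        "inputs": provenance_inputs or {"wt": wt.label, "mutants": [m.label for m in mutants]},
        "parameters": params.resolved(),
        "n_frames": {e.label: e.n_frames for e in all_models},
    }
    return ComparisonReport(
        summary_rows=summary_rows,
        metrics=metrics,
        rmsf_profiles=rmsf_profiles,
        sse_summaries=sse_summaries,
        gained_regions=gained,
        fingerprints=fingerprints,
        segment_map=segment_map,
        provenance=provenance,
    )


def run_comparison(
    wt_path: str | Path,
    mutant_paths: list[str | Path],
    segment_map_path: str | Path,
    params: ComparisonParams | None = None,
) -> ComparisonReport:
    """File-based entry point: multi-model PDB ensembles plus a JSON segment map."""
    for p in [wt_path, segment_map_path, *mutant_paths]:
        if not Path(p).exists():
            raise FileNotFoundError(f"input file not found: {p}")
    wt = read_trajectory(wt_path)
    mutants = [read_trajectory(p) for p in mutant_paths]
    segmap = read_segment_map(segment_map_path)
    inputs = {
        "wt": str(wt_path),
        "mutants": [str(p) for p in mutant_paths],
        "segment_map": str(segment_map_path),
    }
    return run_comparison_ensembles(
        wt, mutants, segmap, params, provenance_inputs=inputs
    )


# ---------------------------------------------------------------------------
# Rendering


def _summary_frame(report: ComparisonReport) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "Model": r.label,
                "RMSD_mean": round(r.rmsd_mean, 3),
                "RMSD_STD": round(r.rmsd_std, 3),
                "RMSF_mean": round(r.rmsf_mean, 3),
                "RMSF_STD": round(r.rmsf_std, 3),
                "RG_mean": round(r.rg_mean, 3),
                "RG_STD": round(r.rg_std, 3),
            }
            for r in report.summary_rows
        ]
    )


def render_report(report: ComparisonReport, out_dir: str | Path) -> list[Path]:
    """Write the full report; returns the paths written.

    Files: ``summary.tsv`` (per-model descriptor table), ``metrics.json``
    (interaction deltas + provenance), per-model fingerprint TSVs,
    ``rmsf.tsv``, ``sse_propensity.tsv``, ``gained_regions.tsv`` (1-based
    closed intervals), ``consensus_pairs.tsv`` and ``digest.txt``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write(path: Path, text: str) -> None:
        path.write_text(text)
        written.append(path)

    _write(out / "summary.tsv", _summary_frame(report).to_csv(sep="\t", index=False))

    payload = {
        "diversity_delta_pct": report.metrics.diversity_delta_pct,
        "frequency_delta_pct": report.metrics.frequency_delta_pct,
        "per_mutant_diversity_delta_pct": report.metrics.per_mutant_diversity_delta_pct,
        "per_mutant_frequency_delta_pct": report.metrics.per_mutant_frequency_delta_pct,
        "redistribution_pp": report.metrics.redistribution,
        "redistribution_mean_pp": report.metrics.redistribution_mean,
        "consensus_unique_pairs": report.metrics.consensus_unique_pairs,
        "gained_regions": [
            {
                "start": g.interval[0],
                "end": g.interval[1],
                "mutant_propensity": g.mutant_propensity,
                "wt_propensity": g.wt_propensity,
            }
            for g in report.gained_regions
        ],
        "helical_content_pct": {
            lab: s.helical_content for lab, s in report.sse_summaries.items()
        },
        "provenance": report.provenance,
    }
    _write(out / "metrics.json", json.dumps(payload, indent=2, sort_keys=True) + "\n")

    for label, fp in report.fingerprints.items():
        rows = [
            {
                "pair_i": pair[0],
                "pair_j": pair[1],
                "kind": kind,
                "frequency": round(float(freq), 6),
                "category": _safe_category(pair, report.segment_map),
            }
            for (pair, kind), freq in zip(fp.pairs, fp.frequency)
        ]
        df = pd.DataFrame(rows, columns=["pair_i", "pair_j", "kind", "frequency", "category"])
        _write(out / f"fingerprint_{label}.tsv", df.to_csv(sep="\t", index=False))

    residues = sorted(next(iter(report.rmsf_profiles.values())).per_residue)
    rmsf_df = pd.DataFrame(
        {
            "residue": residues,
            **{
                lab: [round(prof.per_residue[r], 4) for r in residues]
                for lab, prof in report.rmsf_profiles.items()
            },
        }
    )
    _write(out / "rmsf.tsv", rmsf_df.to_csv(sep="\t", index=False))

    sse_res = sorted(next(iter(report.sse_summaries.values())).helix_propensity)
    sse_df = pd.DataFrame(
        {
            "residue": sse_res,
            **{
                lab: [round(s.helix_propensity[r], 4) for r in sse_res]
                for lab, s in report.sse_summaries.items()
            },
        }
    )
    _write(out / "sse_propensity.tsv", sse_df.to_csv(sep="\t", index=False))

    gained_df = pd.DataFrame(
        [
            {
                "start": g.interval[0],
                "end": g.interval[1],
                "mutant_propensity": round(g.mutant_propensity, 4),
                "wt_propensity": round(g.wt_propensity, 4),
            }
            for g in report.gained_regions
        ],
        columns=["start", "end", "mutant_propensity", "wt_propensity"],
    )
    _write(out / "gained_regions.tsv", gained_df.to_csv(sep="\t", index=False))

    cons_df = pd.DataFrame(
        [
            {
                "pair_i": rec["pair"][0],
                "pair_j": rec["pair"][1],
                "kind": rec["kind"],
                "category": rec.get("category", ""),
            }
            for rec in report.metrics.consensus_unique_pairs
        ],
        columns=["pair_i", "pair_j", "kind", "category"],
    )
    _write(out / "consensus_pairs.tsv", cons_df.to_csv(sep="\t", index=False))

    _write(out / "digest.txt", _digest(report))
    return written


def _safe_category(pair, segment_map: SegmentMap) -> str:
    try:
        from .interactions import pair_category

        return pair_category(pair, segment_map)
    except KeyError:
        return "OUT_OF_MAP"


def _digest(report: ComparisonReport) -> str:
    lines = ["WT-versus-mutant ensemble comparison", "=" * 38, ""]
    lines.append("Per-model statistics (mean / population SD, Angstrom):")
    lines.append(_summary_frame(report).to_string(index=False))
    m = report.metrics
    lines += [
        "",
        f"Interaction diversity delta vs WT: {m.diversity_delta_pct:+.2f}% (mean over mutants)",
        f"Interaction frequency delta vs WT: {m.frequency_delta_pct:+.2f}%",
        f"Consensus pairs in all mutants, absent in WT: {len(m.consensus_unique_pairs)}",
    ]
    cats = {rec.get("category") for rec in m.consensus_unique_pairs if rec.get("category")}
    if cats:
        lines.append(f"  categories: {', '.join(sorted(cats))}")
    if m.redistribution_mean:
        lines.append("Interaction redistribution (mean pp delta vs WT):")
        for cat, delta in sorted(m.redistribution_mean.items()):
            lines.append(f"  {cat:>24s}: {delta:+.2f}")
    lines.append("")
    lines.append("Helical content (% residues, frame-averaged):")
    for lab, s in report.sse_summaries.items():
        lines.append(f"  {lab:>12s}: {s.helical_content:6.2f}")
    if report.gained_regions:
        lines.append("Helix gained in all mutants, absent in WT:")
        for g in report.gained_regions:
            lines.append(
                f"  residues {g.interval[0]}-{g.interval[1]} "
                f"(mutant propensity >= {g.mutant_propensity:.2f}, WT {g.wt_propensity:.2f})"
            )
    else:
        lines.append("No gained helix regions.")
    return "\n".join(lines) + "\n"
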