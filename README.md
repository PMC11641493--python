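# trajdiff

Comparative analysis of wild-type versus mutant protein conformational
ensembles, built around the USP8 deubiquitinase system (UniProt P40818,
modeled residues 402–1118).

Disease-associated point mutations in the interdomain region of USP8 — the
14-3-3 binding motif (residues 715–720), its flanks, and the nearby
SH3-binding motif (`Px(V/I)(D/N)RxxKP`, instance `PTVNRENKP` near residue
738) — are thought to rigidify and compact the protein, disrupting the
autoinhibitory contact between the WW-like domain (645–684) and the
catalytic DUB domain (778–1088). Quantifying that claim requires comparing a
wild-type conformational ensemble against several mutant ensembles along
three axes:

1. **Global descriptors.** Per-frame backbone RMSD against the starting
   coordinates (after optimal Kabsch superposition), per-residue RMSF about
   the ensemble-mean structure (CA atoms), and the radius of gyration
   Rg = √(Σᵢ wᵢ‖xᵢ−x̄‖²/Σᵢ wᵢ) — each summarized as mean ± population SD
   per model. A mobile, extended WT shows larger RMSD and Rg means than
   rigidified, compacted mutants.
2. **Interaction fingerprints.** Per-frame residue–residue interactions
   (heavy-atom contacts ≤ 4.5 Å, N/O–N/O hydrogen-bond proxies ≤ 3.5 Å,
   Arg/Lys/His–Asp/Glu salt bridges ≤ 4.0 Å; sequence separation ≥ 3) form a
   (pair, kind) × frame occupancy matrix per model. From these the pipeline
   reports the interaction-diversity and interaction-frequency change of
   mutants relative to WT, the redistribution of interaction occupancy
   between segment-pair categories (e.g. DUB–DUB versus DUB–LINKER), and the
   **consensus unique pairs**: interactions present in *every* mutant and
   absent from the WT.
3. **Secondary structure.** A CA-geometry (P-SEA-style) three-state
   assignment yields per-model helical content and per-residue helix
   propensity, from which the pipeline detects residue intervals that become
   helical in all mutants while remaining coil in the WT.

Real MD trajectories for this system are not publicly deposited, so the
package ships a synthetic ensemble generator that plants all of those
signals with known ground truth — per-segment flexibility, global
compaction λ, persistent mutant-only contacts, a mutant-only helix — which
is how the pipeline itself is validated end to end.

## Worked example

```sh
trajdiff demo --out demo_out --seed 2 --frames 60
```

generates a 717-residue WT ensemble plus three mutants (15 planted
DUB-internal contacts, a planted helix at residues 610–615, compaction
λ = 0.9) and runs the full comparison. The digest it prints:

```
Per-model statistics (mean / population SD, Angstrom):
Model  RMSD_mean  RMSD_STD  RMSF_mean  RMSF_STD  RG_mean  RG_STD
   WT      1.175     0.154      0.837     0.180  107.220   0.019
   M1      0.593     0.077      0.412     0.095   96.489   0.012
   M2      0.593     0.078      0.412     0.096   96.487   0.008
   M3      0.588     0.077      0.412     0.096   96.489   0.010

Interaction diversity delta vs WT: +37.50% (mean over mutants)
Interaction frequency delta vs WT: +37.50%
Consensus pairs in all mutants, absent in WT: 15
  categories: DUB-DUB
...
Helix gained in all mutants, absent in WT:
  residues 610-615 (mutant propensity >= 1.00, WT 0.00)
```

Reading it: the WT row dominates every mutant row on RMSD mean (more
mobile) and Rg mean (less compact; 107.2 Å versus 96.5 Å ≈ the planted
λ = 0.9). The 15 consensus pairs are exactly the planted ones, all
categorized DUB–DUB, and the one gained helix is exactly the planted
610–615 window. `demo_out/` additionally contains the per-model summary
table (`summary.tsv`), interaction metrics with provenance
(`metrics.json`), per-model fingerprints, RMSF and helix-propensity
profiles, and `ground_truth.json` with what was planted.

Other entry points: `trajdiff compare --wt WT.pdb --mutant M1.pdb
--mutant M2.pdb --segments segments.json --out DIR` analyzes existing
multi-model PDB ensembles; `trajdiff simulate --spec spec.json --out DIR`
writes synthetic ensembles to disk; `trajdiff scan-motif --fasta seq.fasta
--offset N` scans a sequence for the SH3-binding motif. The same
functionality is available as a library (`trajdiff.run_comparison`,
`trajdiff.generate_study`, ...).

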