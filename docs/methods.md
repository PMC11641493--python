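# Methods

This note records the models, conventions and numerical choices behind
`trajdiff`, and what the synthetic validation does and does not demonstrate.

## Scope and data model

The package compares one wild-type (WT) protein conformational ensemble
against N mutant ensembles. An ensemble is a reference structure (atoms with
author residue numbering preserved verbatim — for the USP8 system, UniProt
P40818 numbering over the modeled residues 402–1118) plus T coordinate
frames. The interchange format is multi-model PDB: it is plain text,
diff-able, and sufficient at the reduced system sizes the package targets.
Binary MD formats are deliberately not required; the package consumes
ensembles, it never produces real trajectories.

Residues are partitioned into named segments given as closed 1-based
intervals: by default the WW-like autoinhibitory domain [645, 684], the
14-3-3 binding motif [715, 720], the SH3-binding motif [738, 747], the
catalytic DUB domain [778, 1088], and LINKER — the explicit (possibly
disjoint) complement within [402, 1118]. Segment completion always yields a
partition; overlapping named intervals are an error, not a warning.

On the SH3-binding motif: the pattern `Px(V/I)(D/N)RxxKP` spans nine
residues, while the span conventionally quoted for the USP8 instance
(738–747) covers ten positions. The scanner reports 9-residue hits in the
caller's numbering (`PTVNRENKP` at offset 738 → hit 738–746) and leaves the
quoted-span discrepancy to the caller; it does not silently renumber.

## Global descriptors

* **Superposition.** Kabsch least-squares fitting via SVD of the weighted
  covariance matrix, with the determinant sign corrected so only proper
  rotations are returned. Degenerate (collinear, < 3 point) inputs are
  rejected. The implementation is cross-checked against an independent
  Horn quaternion-eigenvalue implementation to 1e-8 Å.
* **RMSD** is computed over the backbone selection {N, CA, C, O}
  (intersected with the atoms actually present — CA only, on reduced
  traces) against **frame 0** of each ensemble, i.e. deviation from the
  initial coordinates, after superposing each frame on that reference.
* **RMSF** is per-residue over CA atoms about the ensemble-mean structure:
  frames are aligned to frame 0, the mean computed, frames realigned to
  that mean, and the mean recomputed once (one refinement iteration;
  further iterations change values well below the reported precision).
  RMSF_i = √⟨‖x_i − ⟨x_i⟩‖²⟩. The global fit consumes six rigid-body
  degrees of freedom, deflating RMSF by a factor ≈ √(1 − 2/N); at the
  default N = 120 residues that is ≈ 0.8 %, far inside the 5 % tolerance
  used for closed-form checks.
* **Rg** = √(Σ wᵢ‖xᵢ − x̄_w‖²/Σ wᵢ) per frame, unit weights by default,
  element masses optionally.
* **Summaries** report the arithmetic mean and the *population* SD
  (ddof = 0) — over frames for RMSD/Rg, over residues for RMSF. The
  convention matters for small T and is fixed here once.

Metal ions (the catalytic-domain zinc) are retained as atoms but excluded
from backbone-based metrics by construction (their atom names are not in
the backbone selection, and they carry no CA).

## Interaction fingerprints

Detection is deliberately an explicit, documented geometric rule table
rather than a wrapper around an external fingerprinting package, so every
downstream number is auditable:

| kind | rule | cutoff |
|---|---|---|
| contact | any heavy-atom pair between two residues | ≤ 4.5 Å |
| hbond | any N/O heavy atom versus any N/O heavy atom | ≤ 3.5 Å |
| saltbridge | Arg NE/NH1/NH2, Lys NZ, His ND1/NE2 versus Asp OD1/OD2, Glu OE1/OE2 | ≤ 4.0 Å |

No hydrogen-bond angle term is applied: the rules must also operate on
reduced (CA-only) representations where hydrogens and donor geometry do not
exist. Same-chain residue pairs with |i − j| < 3 are excluded to suppress
trivially bonded neighbours; the threshold is configurable. On CA traces
only the contact channel can fire — typed-rule behaviour is exercised with
miniature all-atom fixtures.

A fingerprint is the boolean (pair, kind) × frame occupancy matrix of all
rows observed in at least one frame. Comparison metrics, WT-relative:

* **Diversity** D = number of distinct (pair, kind) rows whose occupancy
  frequency passes the presence threshold; Δ% = 100·(D_mut − D_WT)/D_WT,
  averaged over mutants (per-mutant values also reported).
* **Frequency** F = mean number of interaction events per frame (the
  alternative reading, per-pair mean occupancy, can be derived from the
  exported fingerprints; the per-frame event count is the headline).
* **Redistribution**: each pair belongs to an unordered segment-pair
  category (DUB–DUB, DUB–LINKER, ...); a model's category share is its
  fraction of total occupancy (shares sum to 1), and deltas are reported in
  percentage points versus WT, per mutant and mutant-averaged.
* **Consensus unique pairs**: (⋂ over mutants of present sets) minus the WT
  present set. Pair identity includes the interaction kind by default; a
  kind-agnostic mode (amino-acid pair only) is provided. The default
  presence threshold for the pipeline is 0.5 — "present" means occupied in
  at least half the frames — which makes the consensus set a statement
  about persistent interactions rather than single-frame noise. Threshold 0
  (present in ≥ 1 frame) and 1.0 (present in all frames) are the natural
  sensitivity bounds; raising the threshold can only shrink each model's
  present set, hence the mutant intersection.

## Secondary structure

Assignment uses CA-distance criteria only (P-SEA style), with forward
distances d2, d3, d4 from residue i:

* helix at i when d2 ∈ 5.5 ± 0.7 Å, d3 ∈ 5.3 ± 0.8 Å, d4 ∈ 6.4 ± 0.9 Å;
* strand at i when d2 ∈ 6.7 ± 0.6 Å and d4 ∈ 12.4 ± 1.1 Å.

A criterion firing at i marks residues i..i+4 (helix wins over strand where
they overlap), the first and last two residues of a chain are always coil,
and runs shorter than 4 (H) or 3 (E) are demoted to coil. This segment-wise
marking makes an ideal helix carved over exactly the residues [a, b]
produce H labels over exactly [a, b] — which is what lets gained-region
detection report planted intervals with exact boundaries. Hydrogen-bond
based assignment (DSSP-like) is a non-goal; orderings and gained-region
detection, not label-by-label parity with any particular tool, are the
contract.

Helical content is the frame-averaged percentage of H labels; per-residue
helix propensity is the fraction of frames labelled H. A **gained region**
is a maximal interval of residues with propensity ≥ 0.5 in *every* mutant
and ≤ 0.1 in the WT. The 0.5/0.1 thresholds are this package's choice: a
majority criterion for presence, and a 10 % allowance for transient
flickering in the negative control.

## The synthetic generator

The generator exists to give every downstream stage a recoverable target.
It emulates four features of the real WT-versus-mutant contrast — higher WT
mobility, larger WT Rg, mutant-consensus contacts, a mutant-only helix —
and nothing else.

* **Reference chain**: a deterministic helical super-coil (radius 14 Å,
  pitch 12 Å, CA step 3.8 Å, plus 0.03 Å seeded jitter). The geometry is
  chosen so that adjacent turns sit 12 Å apart: no eligible residue pair of
  the undisturbed chain comes anywhere near the 4.5 Å contact cutoff, even
  after 10 % compaction. That clearance is what makes planted contacts the
  *unique* ground truth, and it is asserted at generation time: if any
  un-forced eligible pair of the (forced, carved, compacted) base geometry
  comes within 0.5 Å of the cutoff, generation fails rather than producing
  an ambiguous study.
* **Flexibility**: i.i.d. per-frame Gaussian jitter with per-axis σ per
  segment (defaults 0.4–0.6 Å, WT), scaled by 0.5 in mutants. Independence
  across frames is intentional: it gives the closed-form checks
  RMSF → σ√3 and E[RMSD] relations exactly; time-correlated motion is a
  non-goal.
* **Compaction**: mutant coordinates scaled about the centroid by λ = 0.9,
  giving mean-Rg ratio λ to first order (jitter inflates Rg by < 0.1 % at
  these sizes).
* **Forced contacts**: a forced pair (i, j) is realized per frame by moving
  both partners symmetrically along their connecting line to a target
  distance 3.4 ± 0.2 Å. Partners are chosen one coil turn (23 residues)
  apart, so the pair meets in the empty gap between turns, away from both
  chains' neighbourhoods; distinct forced pairs are kept ≥ 10 residues
  apart on a slot grid so their meeting points cannot collide. *Baseline*
  pairs (40 in the demo) are forced in every model including the WT — they
  are the shared interaction scaffold that keeps WT diversity non-zero and
  gives the redistribution metric mass to move. *Planted* pairs (15 in the
  demo, all inside the DUB domain) are forced in mutants only, and the WT
  generator verifies they stay ≥ 1 Å outside the cutoff.
* **Planted helix**: ideal α-helix CA geometry (rise 1.5 Å, 100°/residue,
  radius 2.3 Å) rigid-fitted (Kabsch) onto the base positions of the target
  interval in mutants, replacing them; helix residues get reduced jitter
  (σ = 0.1 Å), reflecting the rigidity of formed secondary structure and
  keeping the distance criteria satisfied frame by frame.

Default sizes: 120 residues / T = 500 for unit-scale work; the demo study
is full-width (717 residues, numbering 402–1118, T = 300, three mutants) so
that segment categories, the planted DUB pairs and the 610–615 helix all
live at their native coordinates. The full demo comparison runs in well
under a minute per invocation.

**What passing means — and does not.** Exact recovery of planted ground
truth validates the pipeline's algebra and numerics: superposition, the
descriptor formulas, occupancy bookkeeping, set algebra, interval merging.
It does not validate physical realism. The synthetic chain is a CA trace
with i.i.d. jitter: no side chains (so no hbond/saltbridge channels at
scale), no solvent, no time correlation, no physically meaningful absolute
Rg (the super-coil is far more extended than a folded protein), and a WT
helical content of zero rather than the ~20 % of a real protein. Published
per-model statistics from real 100-ns trajectories of this system are
therefore *not* reproduction targets; the pipeline's contract on real data
is the set of orderings and set-algebra outputs, at the magnitudes the
input ensembles actually contain.

## Numerical and degenerate-input conventions

* Superposition: reflection correction always applied; N < 3 or collinear
  sets rejected; weights must be non-negative with positive sum.
* RMSD/RMSF require non-empty selections; RMSF requires T ≥ 2.
* Diversity deltas are undefined (error) when WT diversity is zero.
* Consensus requires ≥ 2 mutants; with one mutant the pipeline still
  reports deltas but no consensus set.
* PDB reading: author numbering kept; altlocs resolved to highest
  occupancy; non-metal HETATM records dropped, metals kept; insertion
  codes rejected; malformed coordinate fields rejected with the line
  number; model atom-count mismatches rejected with the MODEL number.
  Coordinates survive a write/read round trip to the format's 3-decimal
  precision.
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical (spec, seed) gives bitwise
  identical ensembles, and the comparison itself is deterministic.

## Known limitations

* Interaction typing at CA-only resolution degenerates to the contact
  channel; typed rules need all-atom (or at least N/O-bearing) input.
* The hbond rule has no angular term and will over-count at all-atom
  resolution relative to geometry-aware tools.
* The SSE assigner distinguishes no helix subtypes and no strand topology.
* Aromatic stacking, cation–π and water-mediated interactions are out of
  scope, as are interface fingerprints with a binding partner.
* Cross-chain residue pairs are identified by bare residue numbers; the
  intended domain is single-chain models.
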