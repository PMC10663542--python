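# Methods

This note records the models, conventions and numerical choices behind
hingemd, what the synthetic generators do and do not emulate, and the
design decisions that were genuinely open.

## Containers and units

Coordinates are ångström, times nanoseconds, residue numbering 1-based
with PDB insertion codes part of the residue key.  Multi-model PDB is the
canonical trajectory dialect so the entire pipeline runs on plain text;
DCD and XTC are adapters over MDAnalysis readers behind the same contract.
When a trajectory carries no usable time information, frames are spaced
0.1 ns apart — the 2000-frames-per-200-ns convention of the study design
this package reproduces — and the interval is a config value, not a
constant baked into analyses.

Crystal-file parsing is deterministic: alternate locations keep the
highest-occupancy copy (tie → first encountered), and format errors cite
the offending line number.  Hydrogens are optional everywhere; modules
that want them fall back to documented heavy-atom criteria.

## Hinge angle and conformational states

The hinge angle is the angle at the hinge domain's center of mass
subtended by the COMs of the two flanking domains.  COMs are
mass-weighted over heavy atoms by default (hydrogens included when
present, as crystal structures lack them); a Cα-only mode exists.  The
angle is clamped to [0°, 180°]; coincident COMs (arm < 1e-9 Å) are a
degenerate-geometry error, and the three domains must be pairwise
disjoint.

States: boomerang iff θ < threshold (default 140°), straight otherwise;
θ exactly at the threshold is straight so every frame gets a
deterministic label.  Shifts are raw frame-to-frame label changes with no
hysteresis — published shift counts on the order of 1700 per 20 000
frames are only consistent with raw crossing counts, and a configurable
debounce window (default 0, i.e. off) exists purely for robustness
studies.  Occupancy is label frequency; dwells are maximal constant-label
runs.

The unbiased check clusters frames agglomeratively (scipy, average
linkage) on the all-against-all matrix of pairwise superposed RMSDs over
a selection (typically Cα); medoid = frame minimizing the summed
within-cluster distance, ties → earliest frame; cluster ids are ordered
by medoid hinge angle (most bent first) when domains are supplied.  This
intentionally reproduces the *intent* of tree-cutting trajectory
clustering tools, not any specific tool's algorithm.

The default IZUMO1-like domain boundaries shipped with the package
(4HB 22–133, hinge 134–166, Ig-like 167–254 on one chain) are calibration
targets, not published values — no residue-level domain table is
available — and they are exactly the ranges the synthetic reference
structures embody (below).  Users analysing real structures should treat
them as a starting point and re-calibrate against the two crystal angles.

## Contact detection and scoring

Atom classes (donor, acceptor, cationic, anionic, aromatic ring member,
hydrophobic carbon) come from a documented name lookup over the 20
standard amino acids plus a registry of ligand templates; unknown
residues get empty classes and a logged warning, never an error.  Donor
hydrogens are identified by a bonding distance < 1.2 Å in the reference
coordinates.

Detector criteria (per frame):

* hydrogen bond — H···acceptor ≤ 2.5 Å and donor–H–acceptor ≥ 120°;
  without hydrogens, donor–acceptor ≤ 3.5 Å (fallback logged);
* salt bridge — any cationic heavy atom within 4.0 Å of an anionic one;
* π-stacking — ring centroids ≤ 5.5 Å and inter-normal angle ≤ 30°
  (parallel) or 60–90° (T-shaped), ring normals by least squares;
* hydrophobic — two hydrophobic carbons of different residues ≤ 4.0 Å.

The pair score sums w(d) = 1/(1 + exp(5·(d − 4.0 Å))) over inter-group
heavy-atom pairs within 6 Å.  This kernel is this package's declared
score contract: the scoring tool used in the original study does not
publish its formula, so we chose a monotone, smooth weight with midpoint
at a typical heavy-atom contact distance, under which the published
retention thresholds (mean score > 1.0 protein–protein, > 0.1
protein–ligand) behave as described.  Scores from this package are
comparable to each other, not to any other tool's absolute values.

Per-frame *presence* for lifetime counting uses threshold × 0.5
(configurable): the retention threshold is a mean-score criterion and the
source study never defines per-frame presence.  Lifetime fraction is
present-frames / total; episodes are maximal present runs.  A pair with a
mixed interaction character gets one label by fixed precedence
(hbond > salt bridge > π > hydrophobic > other), chosen as the dominant
per-frame detection.  "Persistent" is operationalized as lifetime
fraction ≥ 0.9; the consensus network counts, per pair, the runs in which
it was retained, and "formed in all runs" means retained in every
replica.

## SASA and buried interface area

Shrake–Rupley quadrature on a golden-section spiral: n points (default
960) per atom on the solvent sphere of radius r_vdW + probe (probe
1.4 Å), a point accessible iff outside every neighbour's solvent sphere.
The spiral is a fixed deterministic point set — no RNG — so results are
bit-identical across runs; at 960 points the isolated-sphere error is
below 1% and in practice at the 0.01% level.  vdW radii are a packaged
element-keyed table (Bondi-type values; unlisted elements fall back to
1.7 Å).

Contact area convention: per-side buried area
(SASA_A + SASA_B − SASA_AB)/2, clamped at 0 against quadrature noise.
This is the convention under which the published crystal-complex
interfaces measure 842–910 Å², and it was fixed once against that band.

## Binding events

Insertion depth = 1 − SASA(ligand in complex)/SASA(ligand alone), a
relative measure in [0, 1].  The reference pose that would anchor a
"full" insertion depth (the folate-receptor-α crystal complex) is an
external structure not shipped here, so depth is documented as relative.
Pocket-bound requires heavy-atom contacts (≤ 4 Å) with ≥ 3 distinct
pocket residues *and* depth ≥ 0.4; surface is any receptor contact short
of that; the series is smoothed with a 3-frame majority filter before
interval extraction (the raw series is kept).  The numeric bound
criterion is this package's operationalization — the narrative it mirrors
is qualitative.  Ion tracking treats the ion as a single heavy atom
(water coordination is out of scope), counts site residues with any heavy
atom within 3.0 Å, is bound at count ≥ 1, and reports the first frame
after which binding never recurs.

## Synthetic generators

All generators are pure functions of their parameter dataclasses (seed
included) using one RNG (`numpy.random.default_rng`); no global state.
Discrete-time per-frame transition probabilities are used throughout,
matching frame-sampled trajectory analysis; with frame spacing Δt they
map to rates as p ≈ k·Δt.

* **Hinge model** — hidden two-state Markov chain (defaults: p_sb =
  0.0125, p_bs = 0.0875 per frame, i.e. stationary boomerang occupancy
  0.125, matching the ~12–13% the study conditions produce; state means
  146.7°/129.4°, the two crystal angles; σ = 4°; 2000 frames per run).
  Angles are realized as a 9-bead, 3-domain molecule whose domain COMs
  subtend exactly the drawn angle (bead offsets sum to zero), so the
  geometry path closes exactly: with σ = 0 the recomputed angle equals
  the state mean to 1e-9°.
* **Telegraph contact** — on/off Markov chain (defaults p_on = 0.02,
  p_off = 0.08: stationary on-fraction 0.2, the published 400-of-2000-
  frame lifetime regime) with truncated-normal distance emissions around
  3 Å (on) and 8 Å (off).
* **Ligand capture** — a one-atom ligand starts 50 Å from the center of
  a 12-residue icosahedral cage (shell radius 3.5 Å), performs a Gaussian
  random walk (step SD 1 Å) with a weak drift (0.3 Å/frame) toward the
  pocket, is strongly steered inside twice the capture radius (3 Å) and
  absorbed within it.  The weak far-field drift is a deliberate deviation
  from a pure free walk: unbiased 3D diffusion from 50 Å essentially
  never finds a nanometre-scale pocket within a testable frame budget,
  while the event being emulated occurred within half of one 100 ns run;
  the funnel makes every seeded run produce a capture whose onset ground
  truth is exact.  Setting drift = 0 recovers the free walk.

What the generators do *not* emulate: solvation, force fields, realistic
protein geometry, correlated domain motions, multi-atom ligand
flexibility, or competing binding sites.  Passing parameter-recovery
tests therefore demonstrates that the estimators are correct and
well-calibrated on data whose generating process is known — not that the
biological conclusions of any particular study are reproduced.

## Synthetic stand-in reference structures

Two fixtures stand in for crystal structures that are not shipped with
the package:

* `synthetic_hinge_reference(conformation)` — a Cα-trace-scale bead model
  (one carbon per residue, 22–254) whose three domain clouds are
  deterministic point sets recentred so the domain COMs subtend exactly
  146.7° ("straight") or 129.4° ("boomerang").  It exercises the full
  structure → selection → COM → angle path at realistic size; because the
  two crystal conformation assignments are reported inconsistently in the
  literature this package always reports both angles side by side.
* `synthetic_interface_reference()` — two parallel 11×11 slabs of carbon
  pseudo-atoms (2.45 Å spacing, 4.6 Å gap) whose per-side buried area,
  856–866 Å² depending on the SASA implementation, falls inside the
  842–910 Å² crystal-interface band.  The geometry was fixed once against
  an independent SASA implementation (mdtraj) and then frozen.

Both are labelled synthetic in name and docstring; numbers computed from
them validate the pipeline's determinism and calibration, not the real
crystals.

## Statistical tolerances in the tests

Occupancy and lifetime-fraction recovery are tested within 3 standard
errors using the number of dwells/episodes as the effective sample size
(consecutive frames of a Markov chain are strongly correlated; dwell
count is the natural independent unit).  Mean episode length is tested
within 5% of 1/p_off at 10⁵ frames.  Per-frame transition probabilities
are tested within 5% relative error on a fixed 4-seed panel pooled to
4×10⁵ frames: a single 10⁵-frame run estimates p_sb = 0.0125 with ~3%
relative SD, so the 5% bound is only meaningful (≈3.8 SD) when pooled.
Capture onsets must match ground truth within ±2 frames (the 3-frame
majority filter can shift an onset by one frame) in 20 of 20 seeded runs.

## Problem sizes

Default test and acceptance runs use 2000-frame trajectories for the
study-condition statistics, 10⁵-frame chains for parameter recovery,
100 random configurations for detector/oracle equivalence, 400-frame
capture runs, and 960-point SASA quadrature; these sizes make every
statistical check well-powered while the whole suite completes in well
under a minute per module.

## Known limitations

* The contact score is a declared stand-in kernel, not a reimplementation
  of any published scoring tool; absolute score values are not
  cross-tool comparable.
* SASA is quadrature, not analytic; errors are at the quadrature level
  (≤1% at 960 points) and orientation-dependent at that level.
* Domain boundaries for real hinge proteins must be user-calibrated.
* π-stacking uses ring-centroid/normal geometry only (no offset-parallel
  subclassification); cation–π and water-mediated bridges are out of
  scope.
* The ion module tracks a single heavy atom; solvent coordination
  chemistry is not modelled.
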