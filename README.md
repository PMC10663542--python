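# hingemd

Trajectory analysis for hinged two-lobe proteins and their binding
interfaces: conformational-state classification from a three-domain hinge
angle, residue-level non-covalent contact detection and lifetime scoring,
buried interface (contact) area, and ligand/ion binding-event detection —
with seeded synthetic generators that provide exact ground truth for every
statistic the pipeline computes.

The package grew out of the analysis of the sperm–egg recognition complex
JUNO–IZUMO1: IZUMO1's ectodomain (a four-helix bundle, a hinge region and
an Ig-like domain) interconverts between a "straight" and a bent
"boomerang" shape, while its interface with JUNO is held together by a
large network of short-lived non-covalent bonds.  All machinery is generic:
any three-domain hinge definition, any two atom groups, any single-atom
ion, any registered ligand.

## The quantities it computes

**Hinge angle and states.** For three disjoint domains with centers of
mass COM₁, COM₂ (hinge), COM₃, the hinge angle is the angle at COM₂
subtended by COM₁ and COM₃.  A frame with θ < 140° is labelled
*boomerang*, otherwise *straight* (the threshold is configurable; equality
is straight).  From the per-frame labels the package derives state
occupancies, the shift count (raw frame-to-frame label changes), and
dwell-length statistics, plus an unbiased agglomerative clustering of
frames by pairwise superposed Cα RMSD as an independent check.

**Contacts and lifetimes.** Per frame, hydrogen bonds
(H···A ≤ 2.5 Å, ∠D–H–A ≥ 120°; heavy-atom 3.5 Å fallback without
hydrogens), salt bridges (≤ 4 Å), π-stacking (centroids ≤ 5.5 Å, parallel
or T-shaped) and hydrophobic contacts (≤ 4 Å) are detected geometrically.
Residue pairs are scored with the sigmoidal kernel
w(d) = 1/(1 + e^{5(d−4 Å)}) summed over inter-group heavy-atom pairs
within 6 Å; pairs are retained when the mean score exceeds 1.0
(protein–protein) or 0.1 (protein–ligand).  Lifetime fraction, contact
episodes and cross-replica consensus ("formed in all runs", "persistent")
follow from the per-frame scores.

**Buried interface area.** Shrake–Rupley SASA on a deterministic
960-point golden-spiral quadrature (probe 1.4 Å), and the per-side buried
area (SASA_A + SASA_B − SASA_AB)/2.

**Binding events.** Minimum-distance timelines, first contact, a
free / surface / pocket-bound state series with an insertion-depth series
(buried fraction of ligand SASA), and single-ion site residence with
coordination counts.

## Worked example

```sh
python examples/01_hinge_states.py
```

```
frames: 2000  threshold: 140.0 deg
boomerang occupancy: 12.9% (stationary law predicts 12.5%)
straight  occupancy: 87.1%
shifts (label changes): 182 (generator made 38 hidden transitions)
mean dwell: straight 18.9 frames, boomerang 2.8 frames
```

A 2000-frame two-state hinge trajectory (stationary boomerang probability
0.125, 4° angle noise) is classified at the 140° threshold: the occupancy
estimate recovers the hidden chain's stationary law, and the raw shift
count exceeds the 38 hidden transitions because noise re-crosses the
threshold within a state — exactly the behaviour raw crossing counts show
on real trajectories.  The other examples print contact lifetimes
(`02_contact_lifetimes.py`), the buried interface area of a crystal-scale
two-chain complex — 866 Å², inside the 842–910 Å² band the corresponding
crystal structures bury (`03_interface_area.py`) — and a full
diffusion-to-capture binding event with first contact, bound intervals and
insertion depth (`04_ligand_capture.py`).

There is also a thin CLI over the config-driven pipeline:

```sh
hingemd simulate hinge --seed 7 --out out/bundle
hingemd analyze all --config config.yaml --out out/run1
```

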