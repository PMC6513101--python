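# Methods

This note documents the models, conventions and design choices behind
`abtriage`, in the spirit of a methods appendix: what is computed, under
which assumptions, with which defaults, and what the synthetic tests do
and do not demonstrate about real data.

## Scope and philosophy

The package implements the *triage logic* of experimentally guided
antibody–antigen model selection — not molecular-mechanics scoring, FFT
docking, rotamer repacking or free-energy perturbation.  Wherever a
commercial or heavyweight component would normally sit (force-field
ΔΔG, FFT grid sampling, minimisation), `abtriage` substitutes a
transparent, deterministic stand-in whose behaviour is exactly specified
and unit-testable.  The claim is therefore about the *workflow*: given
per-pose mutational profiles and experimental phenotypes, the filtering,
ranking and panel-design rules are implemented faithfully and verifiably.

## Structure model

Structures are heavy-atom only; hydrogens are dropped on input because
homology models and NMR-derived inputs carry unreliable protonation, and
the energy model is residue-level anyway.  The PDB reader handles the
fixed-column ATOM/TER/END subset, keeps the first-listed alternate
location, and reports parse errors with line numbers.  Coordinates are in
Å, author numbering is 1-based.  IMGT labels and CDR/Vernier/FR
annotations come from an external tab-separated numbering map; antibody
numbering is a solved problem upstream and is deliberately not recomputed
here.

Superposition is closed-form Kabsch (SVD with reflection correction);
inputs with fewer than three pairs or collinear point sets raise a
degenerate-geometry error rather than returning an arbitrary rotation.

## Solvent-accessible surface area

SASA uses Shrake–Rupley sphere-point quadrature with element van der
Waals radii (C 1.70, N 1.55, O 1.52, S 1.80 Å), a 1.4 Å probe, and 960
points per atom on a deterministic golden-section spiral — chosen over a
randomised point set so results are reproducible without seeds.  The
isolated-atom value is within 1% of the analytic sphere and an occluded
pair is within 2% of the exact two-sphere spherical-cap solution (both
asserted in tests).

**Buried (contact) surface** is reported *per side*:
(SASA(binder) + SASA(target) − SASA(complex)) / 2.  Antibody–antigen
interfaces bury roughly 1600–2000 Å² in total, so the per-side convention
matches the ~700–1000 Å² magnitudes that docking reports usually print.
On the toy fixtures the value is smaller (~100 Å²) because the synthetic
interface is a single line of contacts, not a patch.

## Interaction classification

Cross-interface contacts between the binder (heavy+light) and antigen
chains are classified with default cutoffs:

| kind        | geometry                                                        | default |
|-------------|-----------------------------------------------------------------|---------|
| hbond       | N/O heavy-atom pair                                             | ≤ 3.5 Å |
| salt_bridge | side-chain cationic N (Lys NZ, Arg NE/NH, His ring N) to anionic O (Asp/Glu carboxylate, C-terminus) | ≤ 4.0 Å |
| pi_cation   | cation-group centroid to aromatic-ring centroid, and angle between the centroid–centroid vector and the ring normal | ≤ 6.0 Å, ≤ 60° |
| pi_pi       | ring centroid to ring centroid                                  | ≤ 5.5 Å |
| hydrophobic | apolar side-chain carbon pair                                   | ≤ 4.5 Å |

The π-cation defaults are deliberately wide enough that both canonical
geometries seen in engineered antibody–chemokine contacts — 4.9 Å at
28.5° and the weaker 5.7 Å at 51.5° — are classified as interactions; all
cutoffs are configurable.

Two conventions matter for the energy bookkeeping downstream:

* every kind is recorded **at most once per residue pair**, with the
  closest qualifying geometry.  The stand-in energy is residue-level, and
  per-atom multiplicity (e.g. a bidentate carboxylate) would otherwise
  swamp profiles;
* a residue pair that forms a salt bridge does **not** also emit an
  H-bond: the same nitrogen–oxygen pair satisfies both geometric
  definitions, and double-counting would break the "one salt bridge =
  −2.0 AU exactly" calibration.

The classifier is a declared stand-in for proprietary interaction
detectors whose criteria are not published; it is not a reproduction of
any of them.

## Stand-in energy and mutation model

`E_binding` is the sum of per-kind weights over detected interactions
plus a +5.0 AU penalty per cross-interface heavy-atom pair closer than
2.4 Å.  Weights (salt bridge −2.0, H-bond −1.0, π-cation −1.25, π–π
−0.75, hydrophobic −0.25 AU) calibrate the scale so that hotspot alanine
ΔΔE values land in the 1–4 AU range, which makes the triage thresholds of
0.00 and 0.50 AU meaningful.  Arbitrary units are intentional: the
numbers support *ordering and thresholding*, not thermodynamics.

Mutations are modelled without repacking or minimisation:

* **to Ala/Gly** — side-chain truncation at Cβ (Gly: at Cα); when the
  source residue is Gly, an idealised Cβ is constructed from the
  backbone;
* **to any other residue** — the side chain is replaced by a single
  pseudo side-chain centroid on the Cα→Cβ axis at a residue-specific
  reach (fixed table of mean Cβ→centroid distances, Gly 0.0 … Arg 4.1 Å),
  carrying the target residue's chemotypes (cationic, anionic, aromatic,
  polar, apolar).  Pseudo-centroid interactions use the class cutoffs
  widened by 1.0 Å and skip the angle test, acknowledging that one point
  cannot carry an orientation.

`ΔΔE_binding = E(mutant) − E(wild type)`; `ΔΔE_stability` is the change
in *intramolecular* clash count × the clash penalty, with same-residue
contacts and adjacent residues' backbone atoms excluded.  Two
accommodation modes mirror the two optimisation protocols such campaigns
run side by side: **rigid** counts every new clash, while **tolerant**
ignores new clashes against side chains of residues within 5.0 Å of the
mutated site (backbone clashes always count), standing in for local
minimisation with that radius.  The tolerant mode affects only the
stability term; the binding term is mode-independent.  Saturation scans
retain self-mutations (zero by definition) so a position always
contributes exactly 20 rows per mode.

## Pose sampling, clustering, blockade

The sampler is a seeded toy generator, not a docking engine: a uniform
random orientation (quaternion) and approach direction are drawn, the
binder slides inward until the minimum cross heavy-atom distance equals
the touch distance (4.0 Å — inside interaction range, outside clash
range), and the pose is accepted if it is clash-free, every required
residue is within 10.0 Å of the target, and no blocked residue is
interfacial at 5.0 Å.  Accepted poses are scored and sorted ascending
(ties by pose id — all tie-breaks in the package are deterministic).

Clustering is greedy leader clustering on binder Cα RMSD in the fixed
target frame (no re-superposition), walking in rank order with a 5.0 Å
threshold; labels are the leaders' ranks.

The blockade filter formalises "the antibody must sterically block
receptor engagement": the pose's antigen Cαs are superposed onto the
surrogate ligand of a receptor–ligand template complex through an
explicit residue-pair mapping, the antibody is carried along, and the
pose is flagged *blocking* when at least 25 antibody–receptor heavy-atom
pairs fall below 2.5 Å.  The count threshold trades off template
divergence (the surrogate is an analogue, not the real receptor) against
false positives from grazing contact.

## Triage rules

*Consistency filter*: a pose passes iff every non-binding **and**
reduced-binding mutation has ΔΔE ≥ 0.00 AU and every retained mutation
has ΔΔE ≤ 0.50 AU.  Reduced phenotypes are grouped with deleterious for
the lower bound — a partial knockout still has to cost something — and
additionally drive the ranking.  Violations are reported exhaustively
(mutation, value, rule), not short-circuited, so a triage report can be
audited line by line.

*Partial-knockout ranking*: among passing poses, the margin
`mean_reduced(ΔΔE(reduced) − min ΔΔE(full knockout))` orders poses
ascending, and poses in which every reduced ΔΔE lies strictly below every
full-knockout ΔΔE rank ahead of all others.  The source workflow
describes this selection qualitatively ("the reduced mutation should
score smaller than the full knockouts"); the margin is this package's
formalisation of it.

*Validation panel*: positions must be CDR or Vernier.  **Unique** =
interactions present in exactly one pose's profile; **singles** = ΔΔE
differing by ≥ 0.5 AU from at least 2 other poses (the discrimination
quantum is a design choice — no published value exists); **triples** =
five greedy 3-combinations of singles maximising the minimum pairwise
Euclidean distance between pose-wise ΔΔE-sum vectors (greedy max–min is
our construction; only the intent is prescribed); **controls** = one
position per chain with max |ΔΔE| ≤ 0.05 AU over all poses.  Categories
are emitted disjointly with deterministic tie-breaks.

## Maturation pipeline

Candidates are kept when ΔΔE_binding ≤ −1.0 AU and ΔΔE_stability ≤ +0.5
AU.  The binding filter is interpreted as "stabilising by at least 1 AU"
(negative sign) because accepted candidates in such campaigns are
invariably stabilising; the sign convention is exposed in the
configuration.  The dual-mode consensus intersects rigid- and
tolerant-mode acceptances keyed by (chain, position, mutant residue).
Pooling across methods counts each extra occurrence beyond the first as a
duplicate — the convention fixed by the 93 pooled → 6 duplicates → 87
unique arithmetic — and unique entries carry all contributing method
tags.  Panel selection is greedy in ascending ΔΔE_binding with at most 2
substitutions per position, optional round-robin across method tags, and
one appended control whose |ΔΔE| ≤ 0.05 AU under *every* method.

## Synthetic fixtures and what the tests show

Fixtures are idealised extended chains (Cα spacing 3.8 Å, alternating
±0.4 Å z-offset so the Cα trace is never collinear, Cβ pointing at the
10 Å-separated partner line).  Full heavy-atom side-chain templates are
installed only at planted positions; everything else is alanine, so the
interaction ground truth is exact.  Planted tips meet on the Cβ–Cβ
segment at the requested distance (±0.05 Å) and, for π-cation, ring
normal angle (±2°); infeasible requests fail loudly with the first
conflicting interaction named.

The standard study condition plants three strong hotspots (salt bridge,
π-cation at 4.9 Å/28.5°, H-bond), one hydrophobic-only weak site, and two
non-interacting controls.  Phenotypes follow from the planted truth:
strong → non-binding, weak-only → reduced, untouched → retained.  The
recovery experiment (20 seeds × [true pose + 200 decoys]) runs the full
scan → filter → rank pipeline and requires the true pose to rank first in
≥ 95% of seeds; with the defaults it recovers in 20/20.

These fixtures demonstrate the *logic*, not robustness to real
structures: extended chains have no folds, no conformational strain, no
competing partial interfaces, and phenotypes are noise-free.  On real
data the filter inherits every error of the upstream energy model, and a
pose can pass for the wrong reasons — which is precisely why the source
workflow validates with wet-lab panels.

## Numerical choices and degenerate inputs

* All tie-breaks are lexicographic/by-id; the pipeline is bit-stable for
  a fixed seed (asserted by a byte-identity test over two full runs).
* Touch placement uses bisection to |min distance − 4.0 Å| ≤ 1e−3.
* Kabsch rejects collinear point sets at a 1e−8 relative singular-value
  threshold.
* SASA requires ≥ 92 quadrature points (icosahedral floor).
* A mutation whose stated wild type disagrees with the structure is an
  error, not a warning; a residue lacking the atoms its class needs
  silently contributes no interaction of that class.
* The problem sizes used by tests and the acceptance script (toy chains
  of 10–20 residues, 200-decoy ensembles, 20 seeds) were chosen as the
  smallest sizes at which every rule in the pipeline is exercised with
  comfortable statistical margin.

## Known limitations

* The stand-in energy has no electrostatics, desolvation or entropy; AU
  values are not comparable across packages or protocols, and no
  cross-calibration to published AU scales is attempted (those scales
  differ between the protocols that produced them).
* Pseudo-centroid mutants cannot form orientation-dependent interactions
  correctly; gains predicted through them are coarse lower-bound hints.
* The pose sampler explores randomly; it retains a systematic-rotation
  option conceptually but makes no completeness claim an FFT engine
  would.
* Water-mediated contacts and hydration-site thermodynamics are out of
  scope; mmCIF input, flexible alignment and computed antibody numbering
  are likewise not provided.
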