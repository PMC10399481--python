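# Methods

`dualphore` implements the computational spine of a dual-target
structure-based virtual-screening campaign: pharmacophore feature
perception and RMSD matching, retrospective enrichment validation with the
Güner–Henry score, a two-target docking-energy threshold cascade,
molecular-dynamics stability readouts (RMSD/RMSF), and the assay
arithmetic used downstream (inhibition rates, four-parameter-logistic IC50
fits, potency ratios, calliper tumour volumes). Docking and MD engines are
out of scope: docking scores and trajectories are *inputs*, in plain CSV
and multi-model PDB/XYZ.

## Pharmacophore model and matching

A query is an ordered list of typed tolerance spheres — hydrogen-bond
donor, aromatic centroid, hydrophobic centroid — each with a centre (Å)
and radius (Å, default 1.0). Ligand-side annotation points are perceived
from 3D structures with explicit hydrogens:

- **donor** — every N or O with ≥1 bonded hydrogen; the point sits on the
  heavy atom and carries no direction. This is the simplest testable
  convention; commercial suites use richer (unpublished) typing.
- **aromatic** — the centroid of each 5–7-membered ring of the minimum
  cycle basis whose bonds all carry the SDF aromatic flag; when none of a
  ring's bonds is flagged, a geometric fallback accepts rings whose atoms
  fit a least-squares plane within 0.10 Å. There is no electronic
  aromaticity model: perception is format- and geometry-driven, hence
  deterministic.
- **hydrophobic** — the centroid of each maximal connected cluster of ≥3
  carbon/halogen atoms, excluding atoms bonded to N, O or any formally
  charged atom. Cluster size, planarity tolerance and ring-size range are
  configurable (`PerceptionRules`).

Matching requires *all* query features to be satisfied simultaneously. The
matcher enumerates every injective, type-compatible assignment of
annotation points to features and scores each by RMSD — after optimal
least-squares superposition restricted to proper rotations (`superpose`,
the default, for flexible placement) or on raw coordinates (`in_place`,
for pre-aligned poses). An assignment qualifies if its RMSD is below the
cutoff (default 1.0 Å) *and* every assigned point lies inside its
feature's sphere after the transform; the minimal-RMSD qualifying
assignment wins, with ties broken by lexicographically smallest mapping.
Because enumeration is exhaustive, results are exact; a configurable
ceiling (10⁶ assignments) raises an explicit capacity error instead of
truncating. Reflections are never used in superposition — a mirror-image
ligand must not match — which the Kabsch implementation enforces by
flipping the smallest singular direction when the rotation determinant
would be −1.

## Güner–Henry validation

Screening an activity-labelled library yields counts D (database size),
A (actives), Ht (hits), Ha (active hits), from which the usual family is
derived: % yield of actives (100·Ha/Ht), % ratio of actives (100·Ha/A),
enrichment factor E = Ha·D/(Ht·A), false negatives A−Ha, false positives
Ht−Ha, and

GH = [Ha(3A + Ht) / (4·Ht·A)] · [1 − (Ht − Ha)/(D − A)].

GH is 0 for a null model and 1 for ideal retrieval (Ht = Ha = A); scores
of 0.7–1 are conventionally labelled excellent, and the package reports
that band as a label only. Two domain conditions matter and are enforced:
Ht > 0 (otherwise yield, E and GH are undefined) and Ht − Ha ≤ D − A — a
screen cannot retrieve more inactives than the database holds, and outside
that domain the formula leaves [0, 1]. Full-precision values are always
retained; presentation rounding (GH to 2 decimals, E and percentages to
integers) mirrors how such tables are printed, e.g. counts (1500, 16, 19,
16) give GH = 1072/1216 · 1481/1484 = 0.8798… → 0.88.

## Dual-target cascade

Per-target threshold rules (`target, cutoff kcal/mol, strict`) filter a
compound × target score table; survivor lists are intersected (optionally
restricted to an upstream pharmacophore hit list) and the intersection is
ranked ascending by summed binding energy across the rule targets, ties
broken lexicographically by compound id. Thresholds are strict (<) by
default: with the packaged candidate table the −11.3/−11.7 kcal/mol pair
keeps all seven compounds (the weakest CARM1 binder, −11.32, passes a
strict −11.3 cut) and the summed-energy ranking puts CH-1 first at −24.78
kcal/mol. Both strictness and the ranking key are config-exposed;
monotonicity under cutoff relaxation is property-tested.

## Trajectory metrics

Coordinates are Ångström internally with dual Å/nm reporting (nm being the
MD plotting convention). RMSD series are computed against a chosen
reference frame over an atom selection (default Cα), with optional Kabsch
superposition on that selection; superposed RMSD can never exceed in-place
RMSD, and the series is invariant to a global rigid transform of all
frames. RMSF superposes every frame onto the selection's mean structure —
the provisional reference is the raw coordinate mean, refined by a fixed
two-iteration superposition pass, so the result is independent of frame
order — then averages per-atom fluctuations within each residue.
Reproducing any published trajectory's numeric RMSD plateau would require
the original multi-nanosecond trajectories and is explicitly not attempted;
correctness is certified on synthetic trajectories with known statistics
(isotropic jitter of per-coordinate scale σ gives RMSD and RMSF ≈ σ√3).

## Dose–response fitting

The sigmoidal model is the four-parameter logistic on log concentration,
response = bottom + (top − bottom)/(1 + (IC50/c)^hill), responses in
percent inhibition, concentrations molar. Fitting is ordinary least
squares (`scipy.optimize.curve_fit` on log10 IC50) with multi-start
initialisation: IC50 seeded at the concentration nearest half-maximal
response and hill started at 0.5, 1 and 2; the lowest residual sum of
squares wins. Top and bottom can be pinned (e.g. 100/0). The `converged`
flag is honest: flat response curves (range < 10⁻⁸) and fits with
top ≤ bottom come back unconverged rather than with a fabricated IC50.
Published IC50 tables are used only as inputs to ratio arithmetic
(reference IC50 / candidate IC50, one decimal), never as fit targets — the
underlying plate reads are not public.

## Synthetic data

The generators are pure functions of a `GeneratorSpec` (seed included), so
identical specs give byte-identical outputs. Their defaults define the
test conditions:

- **Labelled library** — 10 actives / 100 decoys (a reduced-scale version
  of the ~1500-molecule decoy-set design; the full-scale shape is one
  config change), feature jitter 0.2 Å per coordinate. Actives realise
  each query feature with an idealised fragment (hydroxyl at 0.96 Å O–H
  for donors, a regular 1.39 Å benzene hexagon for aromatics, a 1.54 Å
  three-carbon cluster for hydrophobics) placed so its annotation point
  lands at the feature centre + jitter. Fragments are chained through
  ether-oxygen bridges — deliberately, because a carbon linker would merge
  neighbouring hydrophobic clusters under the perception rules, while an
  ether oxygen breaks cluster connectivity and adds no donor. Decoys omit
  every fragment of one required kind, preferring donor over aromatic over
  hydrophobic (aromatic rings themselves spawn hydrophobic points, so only
  dropping donor/aromatic gives a structural non-match guarantee), and
  scramble the remaining positions. At zero jitter this construction makes
  retrieval provably ideal (Ha = A, FP = 0, GH = 1); a `jitter_warning`
  flag is set when the 95th-percentile displacement (≈2.8σ for a 3D
  Gaussian) exceeds the smallest feature radius.
- **Score tables** — full factorial compound × target; planted passers
  draw strictly below their target's cutoff (default −11.3/−11.7 kcal/mol
  with 0.05 margin and half-normal spread, sd 0.5), everything else
  strictly above, so cascade outcomes are exact by construction.
- **Dose–response** — 8 concentrations spanning 0.1 nM–1 µM, 3 replicates,
  true IC50 10 nM, hill 1, asymptotes 100/0, Gaussian noise with sd equal
  to `noise_pct` (default 2%) of the dynamic range.
- **Trajectories** — 200 Cα atoms on an ideal helix (100° turn, 1.5 Å
  rise), 100 frames at 10 ps, per-coordinate jitter 0.3 Å with a 5×
  multiplier on the 5 terminal residues at each end; frame 0 is the clean
  starting structure so RMSD against it measures the jitter directly.

What the generators do *not* emulate: real chemistry (fragment placements
can clash sterically; bridging geometry is non-physical), property-matched
decoys, conformational flexibility (one conformer per record), correlated
MD motion, or plate-level artefacts. Passing tests therefore certify the
*algorithms* — exact matching, correct statistics, correct funnels and
estimators — not predictive performance on real screening decks.

## Numerical choices and limitations

- Superposition uses SVD with a determinant correction; degenerate
  (all-collinear) covariance falls back to the proper branch. Queries with
  1–2 features are superposed with the same machinery (the optimum is
  attained though not unique).
- Sphere containment uses a 10⁻⁹ Å slack so exact-boundary constructions
  are stable.
- Score-table reading rejects duplicate (compound, target) pairs outright
  rather than guessing which score is right.
- The matcher is exponential in features per kind; fine for the intended
  ≤ 5-feature queries, guarded by the capacity ceiling otherwise.
- Published hit counts that depend on proprietary inputs (a 35 000-compound
  vendor library, unpublished per-compound scores of intermediate stages,
  wet-lab plate reads, real MD trajectories) cannot be recomputed here;
  the package reproduces every quantity derivable from printed tables and
  certifies everything else by construction on synthetic data.
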