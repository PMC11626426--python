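# Methods

`confdesc` computes conformationally-condensed descriptors of a conserved
reactive moiety from conformer ensembles, trains graph-network surrogates
that predict those descriptors directly from molecular structure, and applies
them in a linear rate model for virtual screening. This note records the
models, the numerical choices, and what the synthetic fixtures do and do not
establish.

## Condensed ensemble descriptors

For a property x evaluated on every conformer i of an ensemble with relative
energies ΔE_i (kcal/mol, re-zeroed to the ensemble minimum), five statistics
are reported:

- **boltz** — Boltzmann-weighted mean x̄ = Σ w_i x_i with
  w_i = exp(−ΔE_i/RT)/Σ_j exp(−ΔE_j/RT), R = 1.987204×10⁻³ kcal mol⁻¹ K⁻¹;
- **boltz_std** — the population-weighted standard deviation
  √(Σ w_i (x_i − x̄)²), no Bessel correction: the natural weighted analogue
  of a population σ;
- **min**, **max** — extremes over the windowed ensemble;
- **low_E** — the value at the first conformer with ΔE = 0 (first-in-order
  tie break, for determinism).

Temperature defaults to 298.15 K and is configurable. Statistics are computed
only over conformers inside the energy window (default 5.0 kcal/mol,
boundary inclusive), so min/max describe the accessible conformational range,
not arbitrary high-energy geometries. Missing per-conformer values make the
whole statistic missing for that molecule (logged); nothing is imputed.

The condensation has two exact limits used as tests: T→∞ reproduces the
arithmetic mean, T→0⁺ reproduces the low-E value. The test oracle re-evaluates
the same formulas in 50-digit `decimal` arithmetic, which is an independent
code path from the float64 NumPy production code.

## Moiety mapping

Conserved atoms are located by SMARTS and expanded by neighborhood rules:

- acid `[CX3](=[OX1])[OX2H1]` → C1 (carboxyl C), O2 (carbonyl O), O3
  (hydroxyl O); C4 is the heavy-atom neighbor of C1 that is not O2/O3
  (absent in formic acid — C4-dependent properties are then missing, not
  errors); H5 is the hydroxyl hydrogen.
- primary amine `[NX3;H2][CX4]` → N1, C2, and the two amine hydrogens H3/H4,
  whose atom properties are reported as a single averaged column (they are
  graph-symmetry equivalent).
- secondary amine `[NX3;H1]([CX4])[CX4]` → N1 and the amine hydrogen H4
  only; the two carbon neighbors are symmetric and carry no properties.

Multiple matches raise by default; a deterministic selection (lowest C1/N1
index) is available via `select_index` / `--moiety-index`. The library
assumes curated mono-functional substrates; polyfunctional filtering is a
caller responsibility. N-aryl amines do not match the `[CX4]` patterns and
are treated as outside the alkyl-amine classes.

## Conformer ensembles

Generated ensembles use ETKDG (v3) embedding with a fixed random seed and
MMFF94 relaxation (UFF fallback for elements outside MMFF coverage);
force-field energies relative to the ensemble minimum serve as ΔE_i.
Ingested ensembles (multi-frame XYZ or SDF with a `REL_ENERGY_KCAL` tag)
carry their own energies and a provenance label — the toolkit weights
whatever energies accompany the ensemble.

Deduplication is a greedy pass in ascending energy order dropping any
conformer whose best-fit heavy-atom RMSD (Kabsch superposition, no symmetry
permutation) to an already kept conformer is below 0.5 Å, so the lower-energy
representative of each cluster survives. The pipeline order is: generate →
dedup → energy-window (≤ 5.0 kcal/mol inclusive) → cap. The cap keeps the k
(default 20) lowest-energy conformers, ties resolved by input order.

## Geometric descriptors

All lengths in Å; radii default to the Bondi set (with the common extension
for boron). Unknown elements raise — no silent default radius.

- **Sterimol L/B1/B5** along a moiety bond axis (acid: C1→C4; primary amine:
  N1→C2). With u the unit axis and p_i substituent-atom positions measured
  from the attachment atom: L = max(p_i·u + r_i); perpendicular components
  q_i give B5 = max(|q_i| + r_i) and B1 = min over in-plane unit directions v
  of max(q_i·v + r_i). B1 is solved exactly: the objective is a pointwise max
  of shifted sinusoids of the direction angle, so its minimum lies at a
  branch minimum or a branch crossing; all O(n²) candidates are enumerated.
  The historical Verloop +0.40 Å L correction is off by default and
  switchable.
- **% buried volume**: share of a 3.5 Å sphere centred on an atom occupied by
  the scaled (×1.17) vdW spheres of all *other* atoms, hydrogens included,
  computed by counting a uniform Cartesian grid (0.05 Å spacing) inside the
  union. The descriptor probes the atom's environment, hence the central atom
  is excluded.
- **Pyramidalization** of a trivalent nitrogen: 360° minus the sum of the
  three bond angles (0° planar, 31.586° ideal sp³). Distance-from-plane and
  Agranat–Radhakrishnan definitions exist in the literature but are not
  implemented as defaults.
- **SASA** by Shrake–Rupley with 960 Fibonacci-sphere points per atom and a
  1.4 Å probe; **solvent-accessible volume** by midpoint grid integration
  (0.2 Å spacing) of the union of probe-inflated spheres, with boundary cells
  weighted by a linear antialiasing of the signed distance to the union
  surface — plain point counting at this spacing biases the volume low by up
  to ~1%, the antialiased rule is accurate to ~0.1%.
- **Point-charge dipole** |Σ q_i p_i| (1 e·Å = 4.80320 D), origin-independent
  only for neutral charge sets (warned otherwise). In the pipeline it is
  evaluated with Gasteiger charges — a cheap classical stand-in that makes
  the dipole column computable offline; quantum-chemistry dipoles, orbital
  energies, NBO charges, NMR shifts, IR frequencies and lone-pair terms are
  *ingested only*, never computed here.

Accuracy checks: B1 matches a 0.1°-resolution brute-force direction scan to
1e-3 Å (toy substituents keep perpendicular offsets ≤ 1 Å so the scan's own
first-order error at kink minima stays below that tolerance); %Vbur matches a
10⁶-sample Monte-Carlo oracle to 0.5 percentage points; isolated-atom SASA
and volume match 4π(r+1.4)² and (4/3)π(r+1.4)³ to 1% and 0.5%. All geometric
descriptors are rigid-motion invariant (exactly for the analytic ones, within
sampling tolerance for the stochastic ones).

## Surrogate models

Both models are scikit-learn-style estimators trained one per target
descriptor (single-task; multi-task readouts are deliberately absent). They
share a NumPy reverse-mode autodiff core (`confdesc.nn`) — float64, full
deterministic given the seed — with Adam, early stopping on validation MAE
and z-scored targets.

**2D (GINE).** Molecules are heavy-atom graphs; one-hot node blocks encode
atom type, valence electrons, chirality, formal charge, aromaticity, ring
membership/smallest-ring size, degree and total attached hydrogens, one-hot
edge blocks bond type, conjugation, ring membership and stereochemistry
(every block carries an "other" slot and sums to one). Message passing
follows the graph isomorphism network with edge features: aggregate
ReLU(h_j + W e_ij) over neighbors, combine with (1+ε)h_i, apply a two-layer
MLP. Readout is sum pooling (molecule targets), the mapped role atom's state
(atom targets) or summed projections of a role pair (bond targets). Defaults:
hidden 64, 3 layers, lr 3e-3, full-batch Adam — sized for CPU training on the
fixture-scale libraries this package ships with; all config-exposed.

**3D (directional message passing).** Each conformer becomes a radial graph:
every atom pair (covalent or not) within the cutoff (default 5.0 Å) is an
edge; hydrogens are explicit; nodes reuse the 2D atom featurizer; bonds are
not featurized. Messages live on directed edges, embedded from the endpoint
node states and a 16-function Gaussian radial basis of the distance;
interaction blocks (default 2) mix each incoming message m_kj into m_ji
gated by a 7-term cosine basis of the angle k-j-i. Since only distances and
angles enter, predictions are exactly invariant to rigid rotations and
translations. Edge→node→molecule pooling uses means by default (condensed
descriptors are intensive); a sum option serves extensive, counting-type
targets. Training uses conformer augmentation — each of up to 20 ensemble
conformers is an independent sample carrying the same ensemble-level label —
with molecule-level minibatches (default 16 molecules) to bound autodiff
memory, and splits are always by molecule, never by conformer. At prediction
time the per-conformer outputs are averaged, unweighted by default
(a Boltzmann-weighted option exists but is off).

## Rate model and screening

The screening layer regresses ln(k) on z-scored condensed descriptors by
ordinary least squares, after a 70:30 *y-equidistant* split: with targets
sorted ascending and n_train = ⌈0.7N⌉, training takes sorted positions
round(1 + (i−1)(N−1)/(n_train−1)) (round half-up, advance on collision), so
the extremes are always trained on and the train set spans the response
range. Whether the original recipe spaces sorted indices or equal y-values is
ambiguous; index spacing is the default here, both being deterministic.
Rank-deficient designs are rejected with the collinear columns named.
Screening applies the exported equation to the full acid × amine cross
product, skipping (and logging) pairs with missing descriptors, and agreement
between two descriptor sources is summarized by R²/MAE over the paired
predictions, optionally restricted to an open ln(k) interval such as
(−3.5, 2.5). A helper converts ln(k) to reaction time assuming
equal-concentration second-order kinetics at 0.5 M; the kinetic order is an
assumption of the helper, not a result, so nothing downstream depends on it.

## Synthetic fixtures: what they show and what they do not

The fixture module enumerates several hundred mono-functional acids and
amines (all alkyl trees to C8, halogenated and aryl variants) so that moiety
mapping, featurization and the pipeline run on realistic graphs. Toy
ensembles draw relative energies from an exponential distribution (scale
2 kcal/mol, clipped to [0, 8]) — mimicking the crowding of conformers near
the minimum — with property values from declared functions of the energy plus
stated Gaussian noise, and carry ground truth from the high-precision
condensation path. Surrogate-training labels are exactly computable: heavy
atom count and ring count (topological), and the ensemble mean of the mean
pairwise interatomic distance over all atoms (geometric; for a one-heavy-atom
molecule the convention includes hydrogens). The geometric label is the
2D-vs-3D discrimination probe: a 2D model must infer it from topology, a 3D
model reads the distances directly.

Passing these tests establishes that the mechanics are correct — exact
condensation, faithful steric geometry, learnable graph models, leak-free
splits. It does **not** establish chemical accuracy against quantum-chemistry
descriptor libraries: fixture properties are simple declared functions, not
DFT observables, and the enumerated molecules are far less diverse than a
curated substrate library.

## Problem sizes and other choices

Test and acceptance runs use deliberately compact problem sizes chosen as the
smallest that exercise each property cleanly: 500 toy ensembles (≤8
conformers) for condensation, 100 toy substituents for Sterimol, 50
configurations × 10⁶ Monte-Carlo samples for %Vbur, 200 molecules for 2D
learning sanity, 60 small flexible molecules (≤7 heavy atoms, ≤4 training
conformers) for the 2D/3D comparison, and 20 acids for the end-to-end
pipeline. The pipeline uses a 0.1 Å buried-volume grid (the 0.05 Å default of
the standalone function is used in the oracle comparisons; halving the
spacing moves results by <0.2%).

Known limitations: no metadynamics-grade conformer searching, no DFT-level
re-optimization or solvation; the 2D model cannot address hydrogen roles
(heavy-atom graphs); the B1 minimization assumes the first substituent atom
is near the axis (true for bonded substituents); equation-fit screening
inherits every bias of its descriptor inputs.
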