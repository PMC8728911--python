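# Methods

## The prediction problem

Four angles describe a protein backbone at residue *i*:

* φᵢ — torsion C_{i−1}–N_i–Cα_i–C_i (undefined at the first residue);
* ψᵢ — torsion N_i–Cα_i–C_i–N_{i+1} (undefined at the last residue);
* θᵢ — planar angle Cα_{i−1}–Cα_i–Cα_{i+1} (defined for 2 ≤ i ≤ L−1);
* τᵢ — torsion Cα_{i−1}–Cα_i–Cα_{i+1}–Cα_{i+2} (defined for 2 ≤ i ≤ L−2).

Torsions are reported on (−180°, 180°] under the IUPAC sign convention
(positive = clockwise rotation of the fourth point relative to the first,
viewed along the central bond); θ lies on [0°, 180°]. The peptide torsion ω
is treated as fixed at 180°.

The method predicts these angles per residue from sequence-derived profile
features, with the key structural idea that residues of different 3-state
secondary-structure (SS) classes — helix (H/G/I), sheet (E/B), coil (T/S/C)
under the DSSP-style collapse — occupy very different angle distributions, so
**each (SS class, angle) pair gets its own regressor**: twelve models in all.
Routing at inference uses the *predicted* SS class of each residue; accuracy
reports may stratify by the actual class, so both label tracks are carried.

## Features

Per residue, up to 56 features in a fixed block order:

| block | width | content |
|---|---|---|
| SS8 one-hot | 8 | predicted 8-state SS, alphabet order `HGIEBTSC` |
| PSSM | 20 | sequence-profile log-odds (PSI-BLAST ASCII layout) |
| 7PCP | 7 | per-amino-acid physicochemical constants (steric parameter, polarizability, volume, hydrophobicity, isoelectric point, helix and sheet propensity) |
| HMM | 20 | profile-HMM match-emission frequencies (HHsuite HHM layout), optional |
| ASA | 1 | predicted accessible surface area, optional |

A sliding window of size W ∈ {5, 9} stacks the per-residue vectors of the W
residues centred on each position (⌊W/2⌋ on each side); positions beyond the
chain contribute all-zero blocks, zero being the neutral value for every
block after normalization. Each configuration is named by a four-character
AHIW code: ASA on/off, HMM on/off, Range or Z-score input encoding, window
5 or 9 (e.g. `YYR9`). Inputs are encoded either to the training range,
x′ = (x − x_min)/(x_max − x_min), or to training Z-scores, x′ = (x − μ)/σ
(population σ). Statistics come from the training residues of the model's
own SS class; degenerate columns (x_max = x_min or σ = 0) map to 0, and
test-set values are deliberately not clipped to [0, 1]. Normalization is
applied uniformly to all columns including the one-hot block (range mode
leaves {0,1} unchanged).

The default setting per model follows the published selection:
helix φ/ψ/θ/τ = `YYR9`; sheet φ/θ/τ = `YYR9`, sheet ψ = `YYZ9`;
coil φ/θ = `YYR5`, coil ψ/τ = `YYR9`. Because settings differ per angle
within a class, normalization statistics are stored per (class, angle).

## Networks, loss, and schedule

Each regressor is a fully-connected network — three sigmoid hidden layers of
150 units, one linear output unit predicting the angle in degrees directly
(no sin/cos target encoding) — trained by SGD with momentum 0.9 from a
scaled-uniform ("glorot") initialisation. The loss is the mean periodic
absolute error over residues whose target is defined:

    AE(P, A) = min(D, 360 − D),   D = |P − A| mod 360.

Its subgradient with respect to the prediction is the sign of the wrapped
residual, which is what the backward pass uses. The learning rate starts at
0.01 and is halved whenever the monitored loss (validation loss by default;
configurable) fails to improve for three successive epochs; training stops
when the rate would fall below 10⁻¹⁵ or at `max_epochs` (default 300).
An epoch counts as stagnant when its loss fails to improve on the
*previous* epoch's; comparing against the best-so-far instead freezes
desk-scale runs, because one lucky early epoch sets an unbeatable "best"
while the network is still reorganising its hidden features, and the rate
then cascades to the floor before learning takes off. Best-so-far weights
are checkpointed and restored at the end of training.

Numerical choices: weights and activations are float32 (the loss is reported
in float64); the default batch size is 16 — at a few thousand training rows
this gives roughly the same *number of SGD updates per epoch* regime as a
large batch does on million-residue datasets, which is what the halving
schedule implicitly assumes; all randomness (init, batch shuffling) flows
from one integer seed per model derived from the bundle seed, so identical
seeds give bit-identical training histories. Raw predictions are wrapped to
(−180°, 180°]; θ, being planar, is additionally clamped to [0°, 180°].

## Evaluation

All errors are periodic AEs. Reports include: MAE per angle, overall and
stratified by actual SS class or by protein-length bins (1–100, …, 501–800,
plus an overflow bin); Spearman rank correlation (average ranks on ties;
undefined for constant vectors, reported as absent); relative improvement
over competing methods, (second-best − ours)/ours × 100 when ours is best,
(best − ours)/ours × 100 otherwise; Δ% = (method − reference)/reference × 100;
and threshold-coverage curves — for thresholds 6° and 12° and x on a 0–100%
grid in steps of 10, the percentage of proteins for which at least x% of
defined angles have AE ≤ threshold (inclusive). Coverage is produced per
angle type. An empty stratum is reported as absent, never as zero.

## Backbone reconstruction

A conformation is rebuilt from sequence plus φ/ψ by concatenating residue
templates. The bundled library holds one idealized template per amino acid
(local frame: Cα at the origin, C on +x, N in the xy-plane; canonical bond
lengths N–Cα 1.458 Å, Cα–C 1.525 Å, angle N–Cα–C 111.2°, tetrahedral Cβ,
none for glycine); a loader can instead harvest templates from a
user-supplied PDB file. Chains grow by sequential internal-coordinate (NeRF)
placement: each atom is positioned from a bond length, bond angle and
torsion relative to the three preceding atoms, with the peptide C–N bond
fixed at 1.33 Å, ω at 180°, and junction angles Cα–C–N 116.2° / C–N–Cα
121.7°. Extracting angles from a built chain returns the prescription to
better than 10⁻⁶ degrees, and rebuilding from extracted angles reproduces
coordinates to the same tolerance after superposition. Undefined terminal
torsions (φ₁, ψ_L) are simply never consumed. Structures are compared by
least-squares superposition RMSD (Kabsch SVD with reflection excluded),
over Cα atoms by default or the full N/Cα/C backbone by flag.

## Synthetic data

The generator makes the whole pipeline testable without downloads. It
emulates the statistical shape of the real inputs, not their evolutionary
content:

* SS is drawn as segments; segment-class probabilities are chosen so the
  stationary residue mix matches the configured fractions (default
  38/23/39 helix/sheet/coil, the typical globular mix); within a class the
  8-state letter is drawn per residue (e.g. H/G/I at 0.85/0.10/0.05 inside
  helices). Mean segment lengths default to 9/5/6 residues.
* φ/ψ are sampled from class-conditional mixtures of wrapped normals:
  tight basins for helix (−63 ± 6°, −42 ± 6°) and sheet (−120 ± 6°,
  135 ± 6°), a broad two/three-component mixture for coil. Coordinates are
  then built with the chain builder and θ/τ are *measured* from them, so
  the generated geometry, angle tables and feature files are mutually
  consistent by construction.
* Profile features are a low-order trigonometric polynomial of the
  residue's own four angles (sin/cos of φ, ψ, τ and the rescaled θ) with a
  *shared* coefficient matrix but a class-specific phase offset (0°, 120°,
  240°). The same feature pattern therefore means different angles in
  different classes: the class-conditional maps genuinely conflict, and only
  the SS track disambiguates them. Including τ/θ in the link keeps every
  regression target recoverable from its own residue's features; without
  it, τ is a six-angle function of the neighbourhood whose sample
  complexity swamps desk-scale training sets.
* Features are quantized exactly as their file formats quantize them
  (integer log-odds for the PSSM, integer −1000·log₂p for HHM emissions,
  two decimals for ASA), so in-memory arrays equal their file round-trips
  bit for bit. Gaussian noise (default 0.1 of each family's amplitude) is
  added before quantization; the predicted SS8 string equals the true one
  with per-residue corruption at rate 0.05 by default.

What the generator does **not** emulate: evolutionary correlations in real
profiles, sequence–structure dependence (sequences are uniform over the 20
amino acids), non-ideal bond geometry, chain breaks. Passing tests therefore
demonstrate that the machinery — encoding, routing, optimisation, schedule,
reconstruction, metrics — behaves correctly on data of the right shape, not
that the published real-data accuracies are reproduced; those depend on the
external benchmark sets and real PSI-BLAST/HHblits/SSpro8/SPOT-1D inputs,
which are out of scope here.

## Measuring the benefit of specialization

The value of routing residues to class-specific models is a statement about
regimes. With the full 3×150 architecture on a desk-scale dataset
(~3,000 training residues), a single pooled network has more than enough
capacity to gate on the SS8 one-hot block and fit all three conflicting
class maps, and — because it sees three times the data of any per-class
model — its variance advantage on noisy features can cancel or outweigh the
specialization benefit on the tight angles, leaving the routed bundle ahead
mainly on the broad τ target. The regime the method is designed for is the
opposite one: capacity binding relative to the task, as it is when training
on millions of residues. The specialization experiment therefore uses small
networks of equal capacity on both sides (three hidden layers of 30 units),
where the pooled model must spend its capacity disambiguating the
conflicting maps: there the routed bundle wins consistently (the test suite
requires at least 4 wins in 5 seeds), with the pooled model degrading most
on ψ exactly as the conflict analysis predicts. Both the test
suite and the acceptance script measure specialization in this
capacity-limited regime; the full-capacity pipeline is still what the
accuracy numbers are reported from.

## Problem sizes used by the tests and the acceptance script

Chosen as the package's own desk-scale defaults: the main pipeline runs use
100 proteins of 30–60 residues (≈4,500 residues, 70/15/15 split) trained for
100 epochs; the noiseless planted-signal run uses 150 proteins of 40–80
residues with balanced classes (≥2,000 residues per class) for 150 epochs;
the specialization comparison repeats the pipeline for five seeds with the
small (3×30) networks described above.

## Known limitations

* The 7PCP constants table follows the literature parameterisation in
  spirit; tests depend only on its shape (20×7) and determinism.
* The Fig-style one-hot ordering of the 8 states is fixed here as
  `HGIEBTSC`; any consumer of serialized feature matrices must use the
  declared order.
* θ prediction reuses the periodic loss although θ is planar; since
  θ ∈ [0°, 180°], D never exceeds 360 − D and the loss reduces to plain MAE.
* Reconstruction uses idealized intra-residue geometry; rebuilding a real
  structure from its own extracted φ/ψ yields a small but non-zero RMSD due
  to bond-length/angle differences, growing with chain length.
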