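# Methods

## Signal model of the synthetic plates

A thermofluorimetric melt curve of an aptamer–target mixture is modelled as
the sum of two independently melting species read out by an intercalating
dye, on a linear instrument baseline:

    F(T) = b0 + b1·T + Σ_s  a_s · c_s · θ_s(T) + ε,   ε ~ N(0, σ²) i.i.d.

Each species follows a two-state van 't Hoff unfolding equilibrium,

    θ(T) = 1 / (1 + exp[ −(ΔH_vH / R) (1/T − 1/Tm) ]),   T in kelvin,

which is strictly decreasing, equals ½ at Tm, and sharpens with the apparent
enthalpy ΔH_vH. The free and bound populations come from the 1:1 mass-action
balance: with total aptamer A, total target P and dissociation constant K_d,
the complex concentration is the physical root of
C² − C(A + P + K_d) + AP = 0, evaluated in the cancellation-free form
2AP / (s + √(s² − 4AP)), s = A + P + K_d. The bound species is
target-stabilised, so its Tm must exceed the free species' Tm; this ordering
is enforced at construction and is what makes "peak 1 = free, peak 2 =
bound" a valid labelling rule downstream.

### Default parameters

| parameter | default | rationale |
|---|---|---|
| scan | 4→80 °C, 0.5 °C steps | standard real-time-PCR melt protocol emulated by the generator |
| replicates | 3 + 3 blanks | three replicate tubes and three buffer-only blanks per plate |
| free/bound Tm | 35 / 60 °C | well-separated two-peak signature inside the scan window |
| ΔH_vH | 110 / 130 kcal/mol | cooperative melting of a multi-stem ~80-nt ssDNA fold (~8 kcal/mol per stacked bp over 15+ bp of stem) gives the sharp, ~6 °C FWHM derivative peaks such instruments record |
| amplitude | 1 a.u./nM | dye signal proportional to folded concentration; the constant dye background is folded into the baseline |
| K_d | 25 nM | no experimental value is available for this aptamer–target pair; chosen so the standard 1.25–80 nM gradient against a ~1.45 nM target spans sub- to super-saturation; configurable |
| baseline | 5 a.u. offset, −0.02 a.u./°C | mild dye bleaching; linear because the blanks subtract it exactly |
| noise | σ = 1% of the max clean signal | per-reading i.i.d. Gaussian; seed mandatory |

The generator emulates the statistical and thermodynamic structure of real
plate exports — two-peak signature, replicate scatter, blank wells, binding
saturation along a concentration gradient — but not intercalation kinetics,
multi-state unfolding, heating-rate dependence, quenching or aggregation.
Passing tests therefore demonstrate that the pipeline recovers what this
model generates; they do not certify performance on instrument quirks the
model omits (nonlinear baselines, temperature miscalibration, well-to-well
optical gain differences).

## Preprocessing

The pipeline order is fixed: average replicate wells → derivative →
blank-correct → normalize, with the blanks run through the same averaging
and derivative steps and subtracted **on the derivative curves**, not on raw
fluorescence. Instruments plot melting as positive peaks, so the derivative
step returns −dF/dT (labelled dF/dT in outputs for parity with instrument
plots; the sign convention is recorded in output metadata). Smoothing is
Savitzky–Golay (window 7, order 3, first derivative) — needed at realistic
noise; `window=1` degrades to central finite differences. Normalization is
an affine rescale of each curve to [0, 100], per curve rather than per
plate, matching how per-panel melt figures are drawn. A constant curve
cannot be rescaled; it maps to zeros with a logged warning and a
`degenerate` flag instead of raising, because blanks can legitimately be
flat.

## Peak quantification

The two-peak model is Gaussian + Gaussian + linear baseline, fitted by
bounded least squares (lmfit/Levenberg–Marquardt); melt-derivative peaks are
symmetric at this resolution and the Gaussian keeps areas analytic
(A = h·σ·√(2π)). Initialisation comes from detected peaks (prominence ≥ 5
normalized units, separation ≥ 2 °C); if only one peak is visible the second
component is seeded at the largest residual away from the first, so
shoulders still converge. The lower-centre component is labelled free, the
higher bound; a component whose fitted height falls below 1% of the curve
maximum is labelled `unassigned`. Non-convergence sets `converged=False`
with diagnostics rather than raising.

Two area estimators are provided deliberately:

- **fitted Gaussian areas** — used for Tm/height/area reporting and for the
  bound ratio when both peaks carry comparable signal;
- **nonparametric areas** (trapezoid over ±3σ around a detected peak) — used
  for cross-condition comparisons such as the gradient study, because when
  one peak is 50–100× larger than the other the Gaussian's slight mismatch
  to the true melt-peak shape leaves residuals on the dominant peak that are
  comparable to the minor peak itself and corrupt its fitted area. The
  trapezoid window around the well-separated minor peak is immune to this.

Cross-condition heatmaps default to normalized curves (that is what
per-panel 0–100 figures show, and it reproduces the familiar pattern of the
bound peak *appearing* to shrink at high aptamer excess), but the
mass-action monotonicity guarantees — bound area non-decreasing and
saturating below the stoichiometric cap, free area rising past saturation —
hold on absolute (blank-corrected, unnormalized) areas, and that is what the
gradient study and its tests assert. Per-curve normalization rescales every
condition by its own maximum and cannot preserve cross-condition ordering.

The recovery study (`aptamelt.workflows.tm_recovery_study`) uses a balanced
system — aptamer 20 nM, target 20 nM, K_d 5 nM — so both peaks carry
comparable signal; over 20 seeded plates at default noise the median |Tm
error| is well under 0.1 °C and the bound-ratio bias under 0.01. Problem
sizes throughout (153-point scans, 3 replicates, 20-run studies, 100 random
geometric fixtures) are the package's chosen study scale.

## Orthogonal buffer design

The L9 array is constructed over GF(3): for run indices (a, b) ∈ {0,1,2}²
the columns are a, b, a+b, a+2b (mod 3). This is strength-2 by construction:
any two columns contain each ordered level pair exactly once. The seed
(default 300, recorded in output) permutes the level-to-symbol assignment of
each column; seed semantics are necessarily this package's own, since
orthogonal-design software does not share a common seeding convention.
Validation is exhaustive — run count 9, per-column balance, pairwise
coverage — with named violating column pairs in the diagnostics.

Ionic strength is I = ½ Σ cᵢzᵢ². Because the varied ions enter as chloride
salts, the default adds Cl⁻ stoichiometrically (a cation of charge z at c mM
brings z·c of a monovalent counter-ion); the HEPES-Na buffer salt (20 mM,
treated as a fully dissociated 1:1 salt) is excluded by default and
available behind a flag. Both conventions give the same extremes over the
packaged nine-buffer table (buffer 6 minimum, buffer 4 maximum), which is
why the default choice is safe for ranking statements. Ranking uses mean
bound-peak Tm descending with bound-peak area and then buffer ID as
tie-breaks; peak height and area remain available as secondary keys.

## Structural metrics

Trajectories are multi-model PDB files read via Biopython's strict parser
(one frame per MODEL; atom tables must agree across models). RMSD uses the
Kabsch algorithm (centroid removal, SVD of the covariance, reflection
corrected to a proper rotation). RMSF superposes all frames onto an iterated
mean structure (two refinement passes by default), takes per-atom
√⟨|xᵢ−⟨xᵢ⟩|²⟩ and averages within residues; a `superpose_frames=False` mode
exists for trajectories already in a common frame (superposition itself
redistributes a single atom's motion across the centroid, which matters for
closed-form checks).

Hydrogen bonds are geometric: donor/acceptor are N/O heavy atoms of
different residues, donor–acceptor distance ≤ 3.5 Å, and — when the
structure contains hydrogens — a donor-attached hydrogen (≤ 1.25 Å) with
donor–H–acceptor angle ≥ 120°; without hydrogens the criterion degrades to
distance only. These defaults sit between common visualization-tool
conventions and are configurable and echoed in outputs. "Frequency" is
reported as occupancy — the fraction of frames in which a (donor, acceptor)
pair meets the criteria — with the distance averaged over frames present.
A binding site is operationalised as a (protein residue, nucleotide) pair
with any heavy-atom pair under 4.0 Å; trajectory mode keeps pairs present in
at least half the frames by default.

## Numerical notes and limitations

- Temperatures are °C at every interface and converted to kelvin only inside
  the thermodynamics; the logistic is evaluated in a saturation-safe form.
- The equilibrium root uses the cancellation-free quadratic form and agrees
  with a 200-step bisection oracle to better than 1e-9 across
  concentration scales.
- Ties in peak detection are broken by larger prominence; ties in buffer
  ranking by area then ID; degenerate inputs (flat curves, single-point
  selections, empty peak lists) produce flagged outputs, not exceptions.
- K_d, ΔH_vH and the dye model are stated assumptions, not measurements: no
  binding constant is estimated from melt data, unfolding is strictly
  two-state, and MM/GBSA-style energetics, docking and secondary/tertiary
  structure prediction are out of scope.
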