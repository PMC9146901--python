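# Methods

This note records the model, the conventions, the numerical machinery and
the design decisions behind `helixmech`, at the level a maintainer or a
careful user needs.  Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Rigid-base-pair model and frame convention

DNA is reduced to one orthonormal frame per base pair (origin at the
mid-frame between the complementary bases, x toward the minor groove, y
along the long base-pair axis, z the normal pointing 5′→3′ along the
leading strand).  A step between frames 1 and 2 is six numbers
θ = (tilt, roll, twist, shift, slide, rise); angles are kept in degrees
everywhere except inside trigonometric kernels, translations in ångströms.

The convention is the CEHS/3DNA mid-step scheme, written here in two
equivalent forms:

    A  = Rz(ω/2 − φ) Ry(Γ) Rz(ω/2 + φ)
       = Rz(ω/2) · exp([tilt, roll, 0]×) · Rz(ω/2)
    Rm = Rz(ω/2) · exp([tilt/2, roll/2, 0]×)          (mid-frame)
    (shift, slide, rise) = Rmᵀ (o₂ − o₁)

with Γ = √(tilt² + roll²) the bend magnitude and φ = atan2(tilt, roll) its
phase.  The second (Rodrigues) form is the one implemented: it is smooth in
(tilt, roll) with no gimbal singularity, which matters for the optimizer's
analytic derivatives.

Parameter extraction inverts the zyz Euler decomposition.  Two numerical
points: the bend angle is recovered with `atan2(|sin β| , cos β)` rather
than `arccos`, which loses half the significant digits near zero bend; and
when the two zyz angles individually wrap past ±π, their sum (the twist)
wraps by 2π while the bend phase shifts by π — both are corrected so the
round trip params → transform → params is identity to ~1e−12 over the
physical range (tilt, roll ∈ ±30°, twist ∈ 0–60°).

The convention is *pinned by symmetry, not by an external program*: reading
a step on the complementary strand (both frames rotated 180° about x, order
reversed) must negate exactly tilt and shift.  This holds analytically for
the scheme above and is enforced by a 10⁴-draw property test.  Any
implementation change that silently alters the Euler order or a sign will
fail that test.

## Sequence classes

The complement symmetry collapses 16 dimers into 10 unique classes and the
256 four-base contexts into 136 (16 contexts × 6 non-self-complementary
central dimers + 10 × 4 self-complementary).  The class representative is
the lexicographically smaller of a sequence and its reverse complement —
an arbitrary but fixed labeling; the stored potential is reflected
(tilt/shift signs and the corresponding covariance rows/columns) whenever a
lookup arrives in the complementary reading.  Self-complementary groups are
symmetrized before fitting by interleaving every record with its
complementary reading, which forces the tilt and shift means to cancel
exactly (the interleaving makes the cancellation exact in floating point,
not just to rounding).

## Curation

* Records flagged as chain ends or adjacent to melted base pairs never
  enter statistics.
* Culling removes, per round, every record with |θ_i − mean| > 3 sd in any
  of the six parameters, with moments recomputed on the retained set, until
  a round removes nothing; the reported round count includes that final
  verification round.  Zero-variance parameters are skipped in a round.
  Groups below 7 records are returned unculled with a warning — six
  parameters need at least that many observations for the moments to mean
  anything.  On a clean Gaussian class the procedure removes ~2% (the
  six-parameter union bound is ~1.6% per round, slightly amplified by
  iteration) — distinctly more than the 0.27% single-parameter tail, and a
  useful baseline when interpreting removal rates on contaminated data.
* The redundancy filter treats two structures as redundant when the longest
  common identical substring of their DNA (either strand orientation)
  exceeds 70% of the longer sequence's length *and* their protein-domain
  multisets match; the better-resolved member is kept.  Processing is
  best-resolution-first with structure id as tie-break, making the result
  independent of input order.  "Total DNA length" is read conservatively as
  the longer of the two sequences; substring matching is contiguous, not an
  alignment.

## Potentials

Covariances use denominator n (population moments — the moment identity
⟨Δθ_iΔθ_j⟩ = ⟨θ_iθ_j⟩ − ⟨θ_i⟩⟨θ_j⟩ taken literally), kT = 1 internally,
stiffness F = C⁻¹, configuration volume V_step = √det C in deg³·Å³ with no
unit normalization across the angle/translation blocks.  A singular
covariance marks the potential degenerate and energy evaluation refuses —
no pseudo-inverse is substituted, because the harmonic model presumes
full-rank dispersion and a silent Moore–Penrose stiffness would assign zero
energy to unobserved deformation modes.  With the sample-moment definitions
the mean self-energy of a fitting sample is exactly 3 kT (six half-kT
modes) up to the n/(n−1) factor, which the acceptance suite verifies at
n = 5000 within 2%.

Generic ("MN") step averages come in two forms.  Sequence-weighted: the
unweighted mean over the 16 dimers of their class means (tilt and shift
cancel by symmetry) and the average of class volumes.  Structure-weighted:
per replicate (default 300, seeded), ⌊0.7 · n_min⌋ raw samples are drawn
without replacement from each unique class; complementary dimers reuse the
same samples sign-flipped and self-complementary dimers contribute both
strand readings; the pooled mean and pooled-covariance volume are averaged
over replicates.  Note the two volume summaries answer different questions:
pooling classes of different *spreads* deflates the pooled volume relative
to the volume average (power-mean inequality), while scatter among class
*means* inflates it; which effect wins depends on the data, so no universal
ordering between the two is asserted.

Tetramer-level lookups for the two terminal steps of an open chain (no
flanking base) fall back to a dimer-level set attached to the tetramer set;
circular sequences have no terminal steps.

## Electrostatics

Screened Coulomb between base-pair centers: E = q_eff² ℓ_B Σ exp(−κr)/r in
kT, with the Bjerrum length ℓ_B and inverse Debye length κ computed from
physical constants (ε = 78.5, T = 300 K; κ⁻¹ ≈ 9.6 Å at 100 mM 1:1 salt —
computed, not hard-coded).  The per-phosphate charge default is −0.24 e
(counterion condensation) with both phosphates lumped at the bp center,
q_eff = −0.48 e; the lumping is a config knob because the underlying
convention is genuinely ambiguous.  Pairs closer than 11 bp along the
contour (circular distance min(|i−j|, n−|i−j|) for closed chains) are
excluded — short-range stacking is already in the elastic term; pairs at
separation ≥ 11 interact.  All included pairs are summed exactly, with no
distance cutoff.  Coincident centers are capped at 10⁶ kT and flagged so
the optimizer backs off rather than overflowing.

## Topology

Writhe uses the exact closed-form solid angle for polygon segment pairs
(the Klenin–Langowski method-1a formula); adjacent segments contribute
zero.  The twist of supercoiling is the ribbon twist of the base-pair
x-axis about the polygonal axis of bp origins: reference vectors are
projected perpendicular to each segment, parallel-transported across the
turn between successive segments, and the signed rotation angles
accumulated.  Lk = Tw + Wr; for a genuinely closed ribbon this is an
integer invariant regardless of how the frames were produced, so the
package's integer check (|Lk − round(Lk)| < 0.02, warning otherwise)
catches numerical inconsistency, not exotic inputs.  The step-parameter
twist Σθ₃/360 differs from the ribbon twist by a bend-precession
(geometric-phase) correction of order the squared per-step bend — about
0.6% of a 2.4°/step ring's uptake, ~4% at 6°/step — which is why uptake
magnitudes are tested at 150 bp and not on very tight rings.

## Optimization

Closed chains are reconstructed from the anchored first base pair; ring
closure is a constraint on the accumulated transform, not duplicated data.
The constraint is handled by an augmented Lagrangian on the terminal-frame
mismatch (position residual in Å, rotation residual as the Frobenius
mismatch of the terminal axes): inner L-BFGS-B solves at penalty weight 10
(kT/Å² and kT per squared Frobenius unit), multiplier updates between
them, and tenfold weight escalation only when the residual contracts by
less than 4× per stage.  Keeping the weight moderate matters twice over:
stiff penalties condition the problem badly (the closure couples every
angle through ~70 Å lever arms), and the multipliers, not the weight, push
the residual to tolerance (1e−4 Å, 1e−4 rad by default).

Inner solves are preconditioned by the diagonal elastic stiffness (each
variable scaled by its rest-state standard deviation) and capped at 300
iterations so multiplier updates happen frequently (inexact augmented
Lagrangian); the final stage polishes at gradient tolerance 1e−8.  These
termination settings are engineering choices, stated here because no
external convention fixes them.

Gradients are analytic throughout: the elastic part is F(θ − mean); the
electrostatic and closure parts chain through the frame accumulation with
suffix sums (O(n) rigid-body algebra per gradient after the O(n²) pair
forces), using the closed-form derivative of the Rodrigues map.  A
finite-difference property test holds the agreement to 1e−5 relative.

Topoisomer control: the starting structure is an exactly closed planar
circle (origins on a regular n-gon, frames following the tangent and
spinning by the accumulated twist), whose step-parameter twist is exactly
360·Lk/n and whose writhe is zero.  A loosely closed intermediate stage can
let a torsionally strained ring pass through itself and relax to the
neighboring topoisomer; the linking number is therefore recomputed at every
stage, and a detected jump restarts the whole run with a tenfold stiffer
initial closure (up to twice) before giving up with a topology error.  The
returned result always carries the target Lk to 0.02 turns.  Rings below
30 bp are accepted with a warning: the harmonic model is dubious at such
curvatures.

## Ring-closure propensity

J is estimated from the statistical weights of the optimized topoisomers,
J ∝ Σ_ΔLk exp(−E_opt/kT) over a window that must cover ΔLk ∈ {−1, 0, +1}
around the relaxed linking number (nearest integer — half-up — to the
intrinsic total twist).  The rigid-minimum treatment deliberately omits the
fluctuation (Jacobian) prefactor, so the supported scientific output is the
*relative* J of same-length sequences; absolute molar values require a
user-supplied calibration constant and are labeled calibrated estimates.
The window-truncation error is bounded by exp(−max scanned E) per omitted
topoisomer and reported with the result.

## Synthetic ensembles: what they do and do not show

The generator draws per-class multivariate Gaussians with B-DNA-like means
and a shared correlation pattern (roll–twist −0.45, twist–slide +0.50,
roll–slide −0.30, tilt–shift +0.30; couplings confined to the
strand-symmetric and strand-antisymmetric blocks so reflection maps each
class covariance onto itself), class-scaled spreads (AT stiffest, TA
softest), and an optional scale-inflated outlier component (default 5% at
4× spread) matching the quasi-Gaussian-core assumption behind 3-sd
culling.  Dimer-level tables default to 5000 draws per class and tetramer
tables to 300, the order of the curated structural counts they emulate.
The synthetic twist means are chosen so the 16-dimer average is 34.1°
(the 10.6 bp/turn consensus helical repeat) and the classic orderings hold
(CG < CA < TA; AG < GG < AA < GA; AT < AC < GC); they are constructions,
not measurements.

Passing tests on these ensembles demonstrates that the machinery —
classification, symmetrization, culling, fitting, optimization, topology —
is correct under controlled conditions.  It does not validate the
biological numbers of any real curated dataset: protein-specific
deformation signatures, non-Gaussian tails beyond the two-component
mixture, melted-state geometry and resolution-dependent error structure are
all outside the generator.  Quantities that require the real curated
ensemble (actual per-class means and volumes, absolute J-factors of
specific biological sequences, hotspot positions on a particular published
minicircle) are correspondingly out of scope of the test suite.

## Problem sizes

The test and acceptance runs use 150-bp rings (the natural size for
cyclization work), 60-bp rings for unit-level optimizer checks, 5000 draws
per class for moment recovery, 10⁴ draws for round-trip bounds and 10³
matrices for the volume identity — sizes at which every stochastic bound
tested has comfortable margin.

## Known limitations

* Harmonic, single-well potentials only; no anharmonicity, no multi-well
  states, no base-pair-level (intra-pair) degrees of freedom.
* No thermal fluctuations around optimized minima; J-factors are
  rigid-minimum estimates.
* Debye–Hückel is the only nonlocal term: no explicit ions, no
  Poisson–Boltzmann, no hard excluded volume (self-contact is discouraged,
  not forbidden).
* Energy minima of soft, strongly curved potential sets are local; the
  optimizer is deterministic from its circular start, and no basin-hopping
  is attempted.
* Frame fitting from atomic coordinates is out of scope: step-parameter
  tables are the input boundary.
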