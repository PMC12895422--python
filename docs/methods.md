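# Methods

This note records the models, conventions and numerical choices behind
the package, and what the test suite does and does not establish.

## Orbital sources

All three sources deliver the same `OrbitalSet` contract: S-orthonormal
MO coefficients, ascending energies (stable order within degeneracies,
as produced by the symmetric eigensolver), aufbau occupations (0/2), the
AO overlap, and an electron count.

**Converged SCF.** Restricted closed-shell SCF with DIIS (error matrix
FDS − SDF, subspace of 8), core-Hamiltonian start, convergence 10⁻¹⁰ on
both the density and the electronic energy. Open-shell inputs are
rejected: every formula downstream carries the restricted-spin factor 2.

**SAD.** Per element, a spherically averaged atomic density is converged
by restricted SCF with fractional occupations: electrons fill MO groups
degenerate within 10⁻⁶ Hartree equally (oxygen's 2p level carries 4/3
electrons per component), which keeps the atomic density rotationally
symmetric. Atomic densities are cached by (element, basis, functional).
The molecular guess density D₀ is their block-diagonal superposition;
one Fock build at D₀ and one generalized diagonalization yield the SAD
orbitals — no further iteration. D₀ itself is not idempotent, but the
aufbau density of the resulting orbitals is (D S D = 2D), which the
tests verify. For an isolated closed-shell atom the atomic density is
the SCF fixed point, so SAD orbital energies coincide with converged
ones — the Ne check.

**Tight-binding MOLDEN.** The basis is taken verbatim from the file
([GTO] with s/p and Cartesian d shells, contraction coefficients for
normalized primitives, p ordered x,y,z); the AO overlap is recomputed
with the package's own integral engine and the parsed MOs are re-checked
for S-orthonormality (10⁻⁴) and Tr(D S) = Σ occupations (10⁻⁶). Failures
raise a dialect-mismatch error rather than returning silently wrong
orbitals. Files with spherical-harmonic d/f sections ([5D]/[7F]) or
missing occupations are rejected. Valence-only electron counts are kept
as stored — no core back-filling, since the channel formulas involve
only frontier-orbital sums.

## Integrals and the effective potential

One- and two-electron integrals over contracted Cartesian Gaussians use
the McMurchie–Davidson scheme (Hermite expansion of orbital products;
Boys functions from Kummer's function with downward recursion). The
built-in basis table is STO-3G for H–Ne — sufficient for the desk-scale
molecule pool; other bases enter only through MOLDEN files. The engine
reproduces the standard minimal-basis restricted energies (H₂ at 0.74 Å:
−1.116759 Eh; H₂O: −74.963023 Eh), frozen as regression anchors in the
tests.

The supported effective potential is the hybrid exact-exchange family

    V_eff[D] = J[D] − ½ · x_HF · K[D],

with x_HF = 1 (functional name "hf"). Semilocal exchange–correlation
terms would require a DFT quadrature grid, which is outside this
backend's scope; the Coulomb + scaled-exact-exchange structure, the AO→MO
transform, the entrywise absolute value and an `include_exchange=False`
ablation flag (Coulomb only) are all retained. The Coulomb part is
cross-checked against an independent real-space oracle: the potential of
the density is evaluated in closed form per primitive s-pair (erf
kernels) and the MO matrix elements are integrated on a uniform grid
(spacing 0.15 bohr, extent ±6 bohr), agreeing with the analytic route to
better than 10⁻⁴ Hartree.

## Channels and images

Hole/particle weights are computed as max-shifted exponentials (weights
below 10⁻³⁰⁰ flush to zero), so any β ≥ 0 up to 10⁶ Hartree⁻¹ and beyond
is overflow-safe. Closed-form limits: β = 0 gives uniform averaging over
the occupied (virtual) space; β → ∞ collapses onto the frontier level.
When the HOMO or LUMO is exactly degenerate (HF's π lone pairs in the
fixture pool), the large-β limit is the *average* projector over the
degenerate level — the only orientation-invariant limit of the formula —
and the tests use a direct few-term evaluation of the weights as the
oracle.

Channel values are stored in Hartree; no unit conversion happens inside
the channel code. The ε channel has bitwise-zero off-diagonals. Images
are assembled over a window of up to N_MO/2 occupied and N_MO/2 virtual
MOs around the Fermi level with the HOMO pinned to pixel N_MO/2 − 1 and
the LUMO to N_MO/2 (0-based); missing occupied slots pad with zeros
toward index 0, missing virtuals toward N_MO − 1. Centering the frontier
pixels makes pixel positions comparable across molecules, which is what
gives the element-wise perturbation a well-defined shared pixel index.
A molecule with no virtual orbitals (He in a minimal basis) gets an
all-zero particle block. MO phase flips leave images bit-identical
(products of flipped coefficients are exact in IEEE arithmetic, and the
V channels take absolute values). Images are not normalized before
training; a standardization switch exists in the training configuration
and defaults off.

Datasets serialize to a single HDF5 file (pixels, padding counts,
molecule ids, optional 6-column target table in eV, provenance
attributes); round-trips are bitwise.

## Network and training protocol

The regressor is a VGG-style stack: (n_convs, out_channels) stages of
3×3 same-padding convolutions with ReLU, 2×2 ceil-mode max pooling
between stages, then fully connected layers with batch normalization and
ReLU, and a six-node linear output (order S1, S2, S3, T1, T2, T3, eV).
The constructor default ((2,16),(2,32), FC 64 — about 25k parameters at
N_MO = 8) is sized for desk-scale sets; `RVGGParams.vgg16()` provides
the classic full-depth stack for larger studies. Layers, AdamW
(decoupled weight decay 10⁻², β = 0.9/0.999) and backpropagation are
implemented directly on NumPy arrays and verified against central-difference
gradients.

Protocol defaults: RMSE loss over the six outputs; optional combined
loss adding `gap_loss_weight` × RMSE over (ΔE_S1−T1, ΔE_S2−S1, ΔE_T2−T1)
(weight 20 is the studied setting); batch size 128 (clipped to the
dataset); up to 2000 epochs; initial LR 10⁻³; LR × 0.8 when the best
validation loss has not improved by more than 10⁻⁶ for 10 consecutive
epochs (counter resets on improvement and after a reduction), floored at
10⁻⁶; no early stopping — the best-validation checkpoint is returned.
When the validation split is empty the training loss drives the plateau
schedule. Split fractions default to 0.8/0.08/0.12 (the 32000/3200/4800
ratio at n = 40000). Transfer learning re-initializes from a pretrained
checkpoint with every parameter trainable and LR 10⁻⁴. A single seed
controls initialization, shuffling and the split; identical
configuration and data reproduce identical histories exactly (pure
NumPy, no nondeterministic kernels).

## Evaluation, perturbations, calibration

The L1 deviation is the absolute error pooled over the six states. The
per-state report covers the six energies and the three gaps: MAE,
Pearson r, signed-error mean and standard deviation (ddof = 1),
directional exceedance probabilities P(err > t)/P(err < −t) at
t ∈ {0.1, 0.2, 0.3} eV, and Q–Q points of the empirical error quantiles
against a normal fitted by sample mean/std (plotting is left to the
caller; the points are the tested artifact).

Channel-wise perturbation multiplies every pixel of one channel by
1 + δ; element-wise perturbation multiplies the single diagonal ε pixel
at index p (the V channels are untouched, matching the δ·ε_p notation).
δ = 0 is a bitwise identity. %ΔL1 is computed from model predictions on
the perturbed versus original images.

Two-point calibration fits E_cal = a·E_pred + b exactly through two
anchor compounds and reports the MAE against experiment with the anchors
excluded.

## Fixture generator

The generator emulates a supervised excited-state dataset at desk scale:
pool geometries (H₂, He, LiH, HF, H₂O, NH₃, CH₂O, C₂H₄) are jittered by
clipped Gaussian displacements (σ = 0.02 Å, |Δ| ≤ 0.05 Å), orbitals come
from a configurable source (SAD by default), and the six targets are an
affine function of the frontier gap plus Gaussian noise (σ = 0.02 eV by
default), with planted singlet–triplet gaps of 0.5/0.6/0.7 eV so
E_Sn > E_Tn in expectation. Slopes (0.20/0.22/0.24) and offsets
(1.0/1.5/2.0 eV) put typical targets in the 2–10 eV window of real
low-lying excitations given minimal-basis frontier gaps. The default
dataset pool is the five lightest species with at least one virtual
orbital; He (no STO-3G virtual) is reserved for boundary tests. The
surrogate depends on exactly the frontier energies that the perturbation
analysis probes, giving that module a known-answer test.

What fixtures do *not* emulate: chemical diversity, realistic
excited-state physics (no configuration interaction — the targets are a
planted function), large molecules, or basis-set effects. Passing tests
establish that the machinery is correct and that the images carry the
frontier-energy signal; they say nothing about accuracy on real
excited-state data, which requires the external datasets and full-scale
training that are out of scope here.

## Problem sizes

The default test and acceptance runs use 16–48 molecules, 8×8 images,
300–800 training epochs and the compact architecture; full training-set
replication of large external datasets is out of scope. The acceptance
script completes in well under a minute on one CPU.

## Known limitations

* Named basis sets beyond STO-3G (H–Ne) are unavailable except through
  MOLDEN files; heavier elements need a MOLDEN-declared basis.
* The effective potential omits semilocal XC terms (hybrid exact
  exchange only); trends that hinge on the semilocal part of a
  particular functional are outside the backend's reach.
* Spherical-harmonic d/f MOLDEN dialects are rejected rather than
  transformed.
* The NumPy CNN is CPU-bound; the full VGG-16 preset is provided for
  completeness but is impractical to train at that scale here.
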