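# Methods

This note records the models implemented in `motorlab`, the numerical choices
behind them, what the synthetic generators do and do not emulate, and the
known limitations. It states no empirical result that the test suite and
`scripts/acceptance.py` do not themselves compute.

## Nonlinear capacitance (NLC)

**Model.** Membrane capacitance is modelled as the derivative of a two-state
Boltzmann charge–voltage relation plus a voltage-independent term:

C_m(V) = α Q_max e^{α(V−V_pk)} / (1 + e^{α(V−V_pk)})² + C_lin.

Parameters and units: α slope factor (mV⁻¹, > 0), V_pk voltage of peak charge
movement (mV), Q_max maximum charge transfer (fC, ≥ 0), C_lin linear
capacitance (pF, > 0). Useful identities, all unit-tested: the peak NLC is
α·Q_max/4 at V = V_pk; the curve is symmetric about V_pk; and the integral of
C_m − C_lin over voltage is exactly Q_max (the NLC is the derivative of a
charge curve). Because expression scales with membrane area, magnitudes are
cell-size-corrected: charge density = Q_max/C_lin (fC/pF) and
C_sp = (C_m − C_lin)/C_lin.

**Numerics.** Evaluation uses the algebraically identical
α Q_max / (4 cosh²(α(V−V_pk)/2)) + C_lin form, which cannot overflow at any
voltage; equivalence with the exp form is unit-tested to 1e−12 relative.
Fitting is bounded trust-region least squares (scipy) over all four
parameters, bounds α ∈ (0, 1] mV⁻¹, |V_pk| ≤ 500 mV, Q_max ≥ 0, C_lin > 0.
Auto-initialization: C_lin from the mean of the ~10 % most extreme-voltage
points, V_pk at the maximum of C_m − C_lin, Q_max from the peak height with an
α seed of 0.03 mV⁻¹. Standard errors come from the Jacobian-based covariance
at the solution scaled by the residual variance.

**Detectability.** NLC counts as detectable when the fit converged, V_pk lies
inside the measurement window (default ±200 mV), Q_max exceeds 3× its
standard error, and peak C_sp ≥ 0.005. The C_sp floor and the 3·SE rule are
package choices (no numeric criterion exists for "undetectable" in common
usage); both are module constants.

**Group statistics.** Two-group comparisons use Welch's t per parameter;
many-to-one comparisons against a control use Dunnett's test as implemented
in scipy. Charge density is computed per cell and then averaged, not from
pooled fits.

## Consensus thermostabilization design

Per-position conservation of the template residue is computed over the
non-gap symbols of the other alignment rows at the template's column, with
the template's own residue included in numerator and denominator. This
denominator choice is deliberate and degenerate-safe: a residue unique to the
template has conservation 1/(n+1) > 0, so threshold 0 reproduces the template
exactly (the identity design). The threshold test is strict — a residue is
kept when conserved in *more* than the threshold fraction — so ties at the
threshold are substituted. Consensus ties prefer the template residue, then
alphabetical order, for determinism. Columns where every other row is gapped
have undefined conservation and are never mutated. All rows are weighted
equally, including any duplicated or partial sequences the alignment carries.

Percent identity uses Needleman–Wunsch global alignment with BLOSUM62, gap
open 11 / extend 1 (the most common convention), counting matches over
aligned residue pairs with gap columns excluded; values are returned at full
precision and rounded only for display. Coordinates are 1-based ungapped
template positions everywhere, so preserve-list tokens like "S396" refer to
template residue numbering.

## MD anion-binding classification and electrostatics

Frames are classified from the three nearest-Cl⁻ distances r₁ (to R399-Cζ),
r₂ (S396-Oγ), r₃ (S398-Oγ): bound when 4 < r₁ < 10, 2 < r₂ < 6 and
2 < r₃ < 6 Å (strict inequalities); unbound when r₁ > 15, r₂ > 10 and
r₃ > 10 Å; intermediate otherwise. The two published windows do not tile
distance space — very close approaches (r₁ ≤ 4 Å) and the shell between the
windows fall in the explicit intermediate class, so every frame is accounted
for. The nearest ion is chosen per probe independently; r₁–r₃ may reference
different ions, and classification follows the distances as defined.

Release is the first frame of the first run of at least *m* consecutive
unbound frames, with m = 1 by default (no smoothing; a single unbound frame
marks release) and configurable; rebinding is the first bound frame after a
release.

Electrostatic decomposition is a direct Coulomb sum per named atom group:
E_group = Σᵢ k_e q_i q_ion / r_i with k_e = 332.0636 kcal·Å/(mol·e²) (Amber
convention), relative permittivity 1, no cutoff and no periodic images.
Partial charges are an input table (the force-field charges of the source
simulation). The "main-chain dipole" group of a residue comprises its
backbone N, H(N), C and O atoms — the atoms carrying the peptide-bond dipole
in standard force fields — with Cα excluded; this atom-set choice is the
package's own and is recorded here because force-field literature does not
fix it. Atoms within 0.1 Å of the ion are flagged as clashes but still
summed. Group energies over the bound-frame set are averaged and ranked.

## Structure superposition and displacement

Superposition is least-squares rigid (Kabsch, via Biopython's
SVDSuperimposer) on Cα atoms only; reflections are excluded, so the rotation
determinant is always +1. Fewer than three pairs, or a collinear selection,
is rejected. Domain displacement superposes model A onto model B on
gate-domain Cα atoms and reports the residual distance of a core reference
atom (default S398 Cα; the Cα-vs-side-chain choice is configurable). Residue
correspondence is by residue number, optionally through a user-supplied chain
mapping — no implicit cross-species sequence alignment. Helix-to-residue
domain assignments are configuration, not code, since numbering differs
between orthologs and constructs.

## ITC single-site model

Per-injection heats follow the exact quadratic mass balance
[MX] = ((M_t + X_t + K_d) − √((M_t + X_t + K_d)² − 4 M_t X_t))/2 with
M_t = n·[cell], under constant-volume displacement bookkeeping: injecting dV
scales existing cell concentrations by (1 − dV/V₀) and adds ligand
X_syr·dV/V₀, and the heat of injection i is
q_i = ΔH·V₀·([MX]_i − [MX]_{i−1}(1 − dV/V₀)) + q₀, crediting the complex
expelled from the cell. Units: mM, µL and kcal/mol, giving heats in µcal.
The cell volume defaults to 200 µL (the working volume of the MicroCal
ITC200-class instrument). Equilibrium (free·free = K_d·bound) and the
ΔH-sign antisymmetry of the heats are exact and unit-tested.

Fitting is least squares in (log K_d, ΔH, baseline), with n fixed at 1 by
default (single-site model) and optionally floated; the first injection
(customarily a small 0.4 µL pre-injection) is excluded by default. Fits are
flagged non-identifiable when the heats carry no curvature (baseline-only
data) or when the K_d uncertainty spans more than about two decades. The
default titration schedule is 20 injections (0.4 µL, then 19 × 2 µL),
0.03 mM sites in the cell, 200 mM ligand in the syringe, 20 °C. At this
schedule c = n[cell]/K_d ≈ 0.004 for K_d ≈ 7 mM — a low-c regime in which
K_d remains identifiable because the titration spans well past K_d (final
ligand ≈ 31 mM) and n is fixed; recovery degrades gracefully at still lower
c and is not asserted below c ≈ 0.05 per decade of noise.

## Synthetic data: what it emulates, and what it does not

* **Capacitance sweeps** are the Boltzmann model plus i.i.d. additive
  Gaussian noise on C_m (default 0.02 pF, i.e. 0.2 % of a 10 pF cell).
  Real recordings derive C_m from dual-sine admittance with
  series-resistance and drift artefacts; none of that is modelled, so
  parameter-recovery results bound estimation error under ideal noise only.
* **Trajectories** place one ion against three fixed probe pseudo-atoms in a
  minimal collinear geometry; the ion's position is sampled uniformly along
  the axis within the y-range that puts (r₁, r₂, r₃) strictly inside the
  intended class windows (for the intermediate class, inside the shell
  between the windows). Classification depends only on distances, so this
  minimal geometry exercises the classifier fully, but it contains no
  protein dynamics, no competing ions and no gradual unbinding pathway.
  Sampling is uniform in time at a fixed frame interval.
* **Alignments** give each non-template row the template residue with the
  planted per-column probability and a fixed alternative residue otherwise,
  then gap cells at a flat rate. Real alignments have phylogenetic
  correlation between rows and more than two residues per column; measured
  conservation is binomial around the planted value (±0.05 at n = 1000),
  slightly enriched by the template's own count at small n.
* **Structure pairs** are a jittered helical toy with gate residues 1–8 and
  core residues 101–108; the second model translates the core selection
  rigidly. Displacement recovery is exact by construction and does not test
  map quality, missing atoms or numbering mismatches.
* **Titrations** add Gaussian noise to the forward-model heats; real
  thermograms additionally carry integration and baseline-correction error.

All generators require an explicit seed and are byte-deterministic given the
spec; with zero noise each reproduces its analytic model to machine
precision.

## Problem sizes

The recovery demonstrations use the cohort sizes of the study design they
emulate: 22 simulated cells for the wild-type NLC set, 5 and 6 for the I500L
and V353F sets, 61-point sweeps at 5 mV spacing, 20-injection titrations with
50 replicates, 10³-frame trajectories, and alignments of up to 1000 rows.
These sizes keep the full suite and the acceptance script to a few seconds
each on one CPU.

## Known limitations

* The NLC model is the symmetric two-state form; asymmetric or
  multi-state charge movement is out of scope.
* No raw-current processing: sweeps enter as (V, C_m) pairs.
* The Coulomb decomposition is unscreened vacuum electrostatics by design
  (it decomposes a force-field interaction, not a solvated free energy).
* Percent identity depends mildly on the alignment scoring convention; the
  BLOSUM62/11/1 choice is recorded in the module and in output metadata.
* The ITC fitter assumes background heats of dilution have already been
  subtracted, as is standard upstream practice.
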