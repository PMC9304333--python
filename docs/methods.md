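# Methods

This note documents the models, estimators and numerical choices behind
`protonspec`, the assumptions they rest on, and what the synthetic
(surrogate) data can and cannot validate.

## Excess-proton tracking

Every hydrogen is assigned to its nearest oxygen under minimum-image
periodic boundaries; an oxygen with exactly three assigned hydrogens is a
hydronium ion and all three of its hydrogens are excess-proton
*candidates*.  A candidate becomes a selected excess proton only if it
changes its assigned oxygen at some point — i.e. actually transfers — and
it is then tracked over the entire contiguous interval during which it
belongs to *any* hydronium.  This dynamic criterion avoids the rapid
identity switching ("special-pair dance") that a
largest-OH-distance rule would produce, and guarantees that a track never
changes proton identity, so it carries no spurious discontinuities.

Tracked protons are projected onto the special-pair coordinates of their
transient H₅O₂⁺ complex: *R*<sub>OO</sub> is the minimum-image distance
between the two nearest water oxygens, and *d* is the signed projection
of the proton's offset from the O–O midpoint onto the O–O axis.

Bookkeeping choices the underlying physics does not dictate:

* equidistant hydrogen-to-oxygen ties go to the lowest oxygen index
  (deterministic);
* the flanking-oxygen pair is re-evaluated every frame, but its ordering —
  and hence the sign of *d* — is inherited while both oxygens persist;
  when the partner water changes, the sign convention is re-anchored to
  keep sign(*d*) continuous.  The sign is fixed per track so that *d* > 0
  initially on the bonded-oxygen side;
* the flanking pair is simply the two nearest oxygens (no distance
  cutoff): the transient H₅O₂⁺ is defined by proximity, and chloride is
  never a flanking partner;
* frames where the proton's *second*-nearest heavy neighbor (after its
  bonded oxygen) is a chloride ion are flagged and excluded from
  free-energy and spectral statistics.  In concentrated HCl such
  configurations are a few percent of all frames;
* when two protons of one hydronium both transfer later, both become
  tracks and shared frames appear in each — statistics are per excess
  proton.

## Free-energy landscape

*F*(*d*, *R*<sub>OO</sub>) = −ln(*P*/*P*<sub>max</sub>) in units of
k<sub>B</sub>T, from a 2D histogram with default bin widths of 0.02 Å in
both coordinates (configurable).  The bin grid is symmetric about
*d* = 0 and counts are averaged with their mirror image before taking the
logarithm, so the physical midplane symmetry *F*(*d*) = *F*(−*d*) is
exact by construction and the gauge is min *F* = 0.

Fixed-*R*<sub>OO</sub> cuts are fitted to the quartic

  *F*(*d*) = *F*<sub>d=0</sub> (1 + γ₂ *d*² + γ₄ *d*⁴),

which is linear in (*F*<sub>d=0</sub>, *F*<sub>d=0</sub>γ₂,
*F*<sub>d=0</sub>γ₄) and solved by weighted least squares with
count weights (Poisson errors of −ln *P* scale as 1/√counts).  Cuts need
at least five populated bins spanning *d* = 0, at least 200 counts
(default) and are fitted over |*d*| ≤ 0.45 Å.  For γ₂ < 0 the wells sit
at *d** = √(−γ₂/(2γ₄)) and the relative barrier is
*F*<sub>d=0</sub> γ₂²/(4γ₄); γ₄ ≤ 0 or a non-positive
*F*<sub>d=0</sub> raises a fit error rather than returning nonsense.

Because γ₂ crosses zero linearly in *R*<sub>OO</sub> while γ₄ stays
nearly constant, *d**² grows linearly above the barrier onset — the
branch *d**(*R*<sub>OO</sub>) is a parabola in the (*d*, *R*<sub>OO</sub>)
plane.  It is fitted as a straight line through the (*R*<sub>OO</sub>,
*d**²) points of all double-well cuts; the onset *R*₀ is where that line
reaches zero.  The transition state is the *R*<sub>OO</sub> minimizing
the absolute *d* = 0 free energy, refined by a local parabola through the
three cuts around the discrete minimum (a three-point parabola on an
asymmetric profile carries an O(h²) location bias, well below the bin
width).

## Transfer paths and waiting times

A **complete** transfer path runs from the last crossing of
*d**(*R*<sub>OO</sub>) on one side of the midplane to the first crossing
of −*d** on the other side; an **incomplete** path crosses *d* = 0 but
returns to the starting side's *d** before reaching the far side.  Both
are extended backward and forward to the nearest discrete turning points
(first sign change of the finite-difference velocity of *d*), and both
definitions are evaluated with a single forward scan that keeps paths
disjoint in time.  *R*<sub>OO</sub> at the decisive midplane crossing is
linearly interpolated between frames; durations stay integer multiples of
the sampling step, as histogram resolution warrants.  Below the barrier
onset *d** = 0, reaching the far branch and crossing the midplane
coincide; paths whose endpoints fall in that region are classified by
whichever branch condition triggers first.

Path-duration histograms are fitted by the Erlang distribution

  p(t) = t^(β−1)/(β−1)! · (β/τ_TP)^β · e^(−β t/τ_TP),

whose mean is τ_TP for every integer shape β.  β is scanned exhaustively
(1…10) with amplitude and τ fitted per shape by least squares over the
main peak, default range [0, 3·median] — the long tail is excluded, and
the whole procedure is scale-equivariant.

Waiting times are first-passage intervals between crossing *d** on one
side and first crossing *d** on the opposite side; intervals restart at
each completed passage, and short back-and-forth recrossing intervals are
retained (they carry real spectral weight).  The mean defines τ_TW.  The
exponential-shape diagnostic uses the **Lilliefors-corrected** KS test
(the exponential rate is estimated from the same sample, so a plain KS
p-value would be anti-conservative).

## Trajectory and spectral decomposition

With the branch *d**(*R*<sub>OO</sub>(t)) and the path segments in hand,

* d_TW(t) = sign(occupied branch) · d*(R_OO(t)), where frames with
  *d* = 0 inherit the previous frame's branch,
* d_TP(t) = d(t) − d_TW(t) inside complete and incomplete paths, zero
  elsewhere,
* d_NM(t) = d(t) − d_TW(t) − d_TP(t),

so the reconstruction is exact by definition (the residual identities are
bitwise; re-summing the three parts reproduces *d* to floating-point
rounding).  Spectrally, the waiting and path components are auto-spectra
of d_TW and d_TP with a bare proton charge of 1 e (one-component dipole),
and the normal-mode spectrum is *defined* as total minus the two — every
cross-correlation lands in the normal-mode term, which may therefore dip
locally negative while TW and TP stay nonnegative.

## Spectra

The absorption spectrum follows linear response,

  χ(ω) = (C(0) − i (ω/2) C̃⁺(ω)) / (V k_B T ε₀ D),

with C(t) the equilibrium autocorrelation of the dipole (or
charge-weighted coordinate) summed over its D components.  C(t) is
estimated by the Fourier route with the finite-length bias correction
1/(L_t − t) and truncated at half the series length to control the
variance blow-up of the correction factor (configurable).  The static
dipole mean is removed first, so C(0) is the fluctuation amplitude and
finite windows carry no artificial zero-frequency spike.  No taper window
is applied.

Two equivalent spectral routes are implemented:

* **series route** — when the correlation function originates from a
  sampled series, Re C̃⁺ is taken as half the periodogram of the
  mean-free series (the exact discrete Wiener–Khinchin identity), which
  makes ωχ″ ∝ ω²|p̃(ω)|² manifestly nonnegative at every grid point;
* **analytic route** — when C(t) is supplied directly, a one-sided cosine
  transform is used; treating C as piecewise linear between samples
  multiplies the DTFT by a sinc² factor that removes the sampling-alias
  bias (verified to 1% against the Debye closed form up to a quarter of
  the Nyquist frequency).

For charged subsystems the current route is preferred: the polarization
periodogram is recovered as |j̃(ω)|²/ω², which is origin-independent and
drift-free.  When the current is produced internally by centered finite
differences, the exact discrete derivative gain sin(ω Δt)/Δt replaces ω,
so both routes agree to high accuracy below the Nyquist frequency; the
ω = 0 bin is excluded.

Gaussian smoothing convolves on the wavenumber grid with edge
renormalization (kernel truncated at 8.5 σ, so integrated weight is
preserved to better than 10⁻⁶ away from the edges).  Defaults follow the
resolution of each spectrum class: 55 cm⁻¹ for bulk spectra, 20 cm⁻¹ for
complex difference spectra, 50 cm⁻¹ for excess-proton spectra, 3 cm⁻¹
for experimental data.  Difference spectra are
ωΔχ″ = ωχ″_solution/c_W − ωχ″_water/c_W⁰, optionally divided further by
c_HCl; grids are interpolated when they differ.  Subsystem decomposition
computes the remainder spectrum from the remainder autocorrelation alone
and attributes *all* cross terms to the subsystem (the chloride
convention).

Dipole assembly uses Wannier centers at −2 e and pseudopotential core
charges for nuclei (H +1, O +6, Cl +7).  Some electronic-structure
outputs print the Wannier charge magnitude without its sign; a doubly
occupied center is physically −2 e and the package implements it that
way, with a configurable override and a total-charge check for
full-system requests.  Positions are unwrapped in time (cumulative
minimum-image displacements) so molecular dipoles stay continuous across
the periodic boundary.

Characteristic times convert to band positions as ν̃ = 1/(c τ); for
transfer paths the crossing is half an oscillation period, so the band
sits at ν̃ = 1/(2 c τ_TP).  Spectral peaks are read off by a local
parabolic interpolation over five grid points of the smoothed spectrum,
inside a stated read-off window (100–1000 cm⁻¹ for the THz-side bands,
300–3000 cm⁻¹ for the transfer-path band).

## Experimental THz conversion

Transmitted intensities convert to extinction via Beer–Lambert,
α_solution = ln(I_water/I_solution)/d + α_water, with the bulk-water
extinction supplied as a reference table.  Extinction converts to ωχ″ by
fitting a sum of damped-harmonic-oscillator bands
χ(ω) = Σ s_k ω₀k²/(ω₀k² − ω² − iγ_k ω) (plus an optional Debye term)
through the weak-absorption forward model α = 2πν̃ χ″/n_b, and
evaluating the analytic, Kramers–Kronig-consistent χ″ of the fitted
model on the measured band.  The band count grows until a BIC-style
penalty stops paying (capped at 8 in the 30–650 cm⁻¹ window); a direct
pointwise inversion of the same forward model is provided as a
cross-check.  The band-model route is numerically stable on band-limited
data and linear in the band amplitudes.

## The Langevin surrogate

The surrogate emulates the *statistical* structure of excess-proton
dynamics so the full chain is testable without ab initio data: two
coupled coordinates (d, R_OO) under underdamped Langevin dynamics on

  F(d, R) = F_q (1 + γ₂(R) d² + γ₄ d⁴) + V_conf(R)   [k_B T],

with γ₂ linear in R (zero at the onset R₀) and γ₄ constant, so
*d**(R) is exactly a parabola in the plane.  The calibration pins the
surface to the landscape of concentrated aqueous HCl and is solved in
closed form:

* onset R₀ = 2.39 Å and global minima at (2.51 Å, ±0.2 Å) fix the slope
  ρ = d*²/(R−R₀) = 1/3 Å, hence γ₂(R) = −g(R−R₀) with g = 1250/3 Å⁻³
  and γ₄ = g/(2ρ) = 625 Å⁻⁴ (γ₂(2.51) = −50 Å⁻²);
* the well depth F_q·γ₂²/(4γ₄) = 125 (R−R₀)² k_BT must equal the 1.8 k_BT
  absolute d = 0 energy at 2.51 Å so the global minimum is gauged to
  zero, giving F_q = 1.8 k_BT;
* the valley profile F(d*(R), R) is a sixth-order polynomial in
  x = R − 2.51 whose quadratic coefficient sets the oxygen-oscillation
  curvature (default 204.8 k_BT/Å², the 400 cm⁻¹ mode at the 9 u reduced
  mass of two waters) and whose cubic/quartic coefficients are solved
  from the transition-state conditions (absolute d = 0 energy 0.9 k_BT,
  stationary, at 2.42 Å); two fixed higher-order shape constants keep the
  profile single-welled and confining, and the calibration verifies all
  of this at build time.

All five anchors hold exactly in the continuous surface, and the
package's own histogram-plus-fits pipeline recovers them from a 10⁶-step
run (250 ps at Δt = 0.25 fs, the problem size used in the validation
suite) to within ≈0.005 Å in positions and ≈0.1 k_BT in barrier heights.

Integration is BAOAB splitting — velocity half-kicks and drift half-steps
around an exact Ornstein–Uhlenbeck velocity update — which satisfies
fluctuation–dissipation at the configured temperature, is bitwise
deterministic given the seed, and passes an equipartition check to 2% at
10⁶ steps.  The potential is pinned to the calibration temperature
(300 K) while the configured temperature controls only the noise, so the
noiseless limit relaxes deterministically.  A stability guard requires
Δt·ω < 0.2 for the stiffest *thermally accessible* curvature (within
10 k_BT of the minimum); the scaled-barrier runs used in Arrhenius tests
therefore use Δt = 0.15 fs.  `barrier_scale` multiplies the whole
surface, which preserves all geometric anchors while raising every
barrier proportionally.

Masses default to 1 u (proton) and 9 u (reduced mass of two rigid
waters).  Friction constants are fixed package constants, chosen once so
that the mean waiting time of the default surface falls in the
200–300 fs range: friction_d = 0.5 fs⁻¹, friction_r = 0.06 fs⁻¹.

**What the surrogate does and does not reproduce.**  It reproduces the
anchored landscape, Arrhenius growth of τ_TW with barrier height against
a weakly varying τ_TP, the time-scale ordering
τ_TW > τ_ROO > τ_TP > min(τ_NM), and exponential waiting statistics in
the rare-event regime (relative barriers ≳ 4 k_BT).  Known, documented
departures from real acid-solution data:

* the d-integrated marginal of the anchored surface pins the effective
  R-oscillation curvature near 340 k_BT/Å², so the measured R band sits
  at ≈550–610 cm⁻¹ (τ_ROO ≈ 52–65 fs) rather than in the 400 cm⁻¹
  region: the printed anchors leave no freedom to soften it at the
  specified reduced mass, and friction moves it only marginally;
* white-noise (Markovian) friction cannot combine a ≈200 fs waiting time
  with a ≈14 fs path time at the anchored barrier heights; the surrogate's
  τ_TW/τ_TP separation is ≈6 versus ≈20 in ab initio data.  Two visible
  consequences: (i) the default surrogate's waiting distribution shows a
  resolvable short-time dead-time, so the Lilliefors test rejects strict
  exponentiality at ≥200 intervals (it passes in the rare-event regime);
  (ii) the ω²-weighted floor from the frame-sharp d_TW branch flips,
  together with the in-path vibration band, buries the 1/(2 c τ_TP)
  transfer-path feature, so ωχ″_TP rises toward a knee instead of
  peaking there — in measured ab initio spectra, where crossings are
  faster and smoother, the same construction produces a clear peak;
* no special-pair dance, no solvent polarization enhancement, no
  chloride dynamics and no absolute spectral amplitudes — the surrogate
  is a test harness, not a water model.

Passing tests on surrogate data therefore validate the *estimators and
bookkeeping* (segmentation, fits, decomposition identities, spectral
routes, calibration recovery), not the quantitative spectral shapes of
real HCl solutions.

Atom-level rendering places the H₅O₂⁺ complex with its O–O axis along x
at the box center, the excess proton at the prescribed (d, R_OO), two
idealized water hydrogens per oxygen (0.97 Å, 104.5°), and optionally
spectator waters, a chloride and Wannier centers (four per O/Cl at short
tetrahedral offsets) that make each water neutral; the proton tracker
recovers (d, R_OO) from the rendered frames to 10⁻⁸ Å.

## Degenerate inputs and error behavior

Inconsistent atom counts, unknown element symbols, non-commensurate
Wannier/nuclei sampling rates, zero-oxygen frames, empty track tables,
unfittable cuts (γ₄ ≤ 0), all-single-well landscapes, too few path
durations (<50) and missing volume/temperature metadata all raise typed,
stage-labeled errors rather than propagating silently.  Time-scale
summaries flag absent components instead of failing.

## Known limitations

* Cubic periodic cells only; no binary electronic-structure output
  formats (extended-XYZ is the interchange format; velocities are
  finite-differenced, never parsed).
* No nuclear quantum corrections anywhere in the spectral chain.
* The Kramers–Kronig conversion assumes the weak-absorption forward
  model; strong-absorption etalon and interface corrections are out of
  scope, as is sample-thickness determination.
* Waiting-time and Erlang statistics assume a single continuous track per
  analysis unit; pooling across tracks is a simple concatenation.
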