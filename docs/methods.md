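# Methods

## The problem

Confocal Raman microspectroscopy of drug-inoculated cells yields a time
series of spectra in which the signatures of the drug, of its binding to
intracellular targets, and of the downstream cellular response are
superimposed on a large, essentially constant cellular background.  The
classical bilinear mixture model is

    D = C S,        D ∈ R^(N×J),  C ∈ R^(N×I),  S ∈ R^(I×J)

with N spectra (time points), J wavenumber channels and I chemical
components.  Plain MCR-ALS resolves C and S under soft constraints
(non-negativity), but its solutions retain rotational and intensity
ambiguity and ignore the kinetics that generated the data.

`hsmcr` implements the *hard-and-soft* variant: selected columns of C are
forced to obey a pharmacokinetic ODE system whose rate constants are refit
inside every ALS iteration by bounded nonlinear least squares.  The output
is therefore not only (C, S) but also the kinetic constants themselves.

## Kinetic models

The built-in system describes saturating uptake of a drug at constant dose
D, followed by a slower cellular response driven by the amount of bound
drug:

    dNb/dt = (Nrecp − Nb) · Kup · D
    dNr/dt = (Nresp − Nr) · Kresp · Nb

| parameter | meaning                      | units                | default start |
|-----------|------------------------------|----------------------|---------------|
| Kup       | uptake rate                  | h⁻¹ per unit dose    | user supplied |
| Kresp     | response rate                | h⁻¹ per unit bound   | user supplied |
| Nrecp     | binding capacity             | a.u. (concentration) | 1.0           |
| Nresp     | response capacity            | a.u. (concentration) | 1.0           |
| D         | dose (held fixed in the fit) | dimensionless        | 1.0           |

Both states start at zero (no pre-bound drug, no pre-existing response);
initial states are configurable.  Only the product `Kup·D` enters the
equations, so `Kup` and `D` are jointly identifiable and `D` is treated as
a known constant.  Integration uses adaptive explicit Runge–Kutta (RK45,
rtol 1e-8, atol 1e-10); the systems are non-stiff over the relevant
parameter ranges.  Closed-form solutions of both built-in systems serve as
independent oracles in the test suite.  Custom systems are declared in the
configuration as lists of rate expressions, parsed symbolically (only the
declared state/parameter symbols are admitted) and compiled — never
executed as arbitrary code.

## The hard-and-soft loop

Each iteration performs

1. **S step** — per wavenumber channel, exact least squares for the
   component spectra, with per-component non-negativity.
2. **C step** — per time point, the mirrored solve for concentrations.
3. **Kinetic refit** — the free kinetic parameters are refit to the linked
   soft concentration columns by trust-region-reflective least squares with
   bounds k ≥ 0, warm-started from the previous iteration's estimate.
4. **Hard substitution** — the linked columns of C are replaced by the ODE
   solution at the refit constants; the remaining columns pass through.

Non-negativity is enforced by active-set NNLS (Lawson–Hanson), not by
clipping; clipping is not a minimizer and would destroy the monotone
lack-of-fit property of the soft algorithm.  Mixed free/non-negative
problems are solved exactly by projecting the free block out and running
NNLS on the projected problem.  The unconstrained solution is accepted
whenever it already satisfies the bounds (it is then the global optimum).

**Convergence.**  The fitting error is the sum of squared residuals (SSR)
of D − C·S; `%LOF = 100·sqrt(SSR/ΣD²)` is reported for logging.  The loop
stops when the SSR changes by less than 1% (``rel_tol``) for 20 consecutive
iterations (``patience``) or after 200 iterations (``max_iter``).  An SSR
below 1e-12 of ΣD² stops immediately: at that level the history is
numerical noise and the relative-change rule is meaningless.

**Initialization.**  C₀ holds the ODE solution at the starting constants in
the linked columns and constant 1.0 in unconstrained columns — the least
informative profile consistent with a time-invariant background component.
A purely soft run (no kinetic link) starts from the truncated SVD instead,
since an all-ones C₀ would be rank deficient.

**Properties and trade-offs.**

* With the kinetic link disabled, the lack of fit is non-increasing (each
  half step solves its least-squares problem exactly).
* With the link enabled, the hard substitution may *raise* the lack of fit;
  that is the price of the hard model, and only finiteness of the history
  plus the stop rule are guaranteed.
* Intensity ambiguity: scaling a constrained component's spectrum by α and
  its capacity by 1/α leaves the reconstruction invariant, so **capacity
  parameters are recovered only up to scale**.  The response rate couples to
  the binding profile's scale through the product `Kresp·Nrecp`; quoting
  `Kresp` in absolute h⁻¹ therefore assumes the binding profile's scale.
  Capacities are initialized at unity — the natural order of magnitude for
  area-normalized data — which pins that scale in practice; absolute
  calibration would require relating Raman intensity to concentration.
* Component ordering: constrained components occupy the lowest indices, in
  model state order, which fixes reporting and avoids label switching.
* A component profile that collapses to all-zero is frozen at its previous
  value with a warning and the run continues; fewer than two time points
  per free kinetic parameter triggers an identifiability warning (fits of
  the two-state model to coarse 8-point experimental grids are known to
  confuse binding and response).

## Preprocessing

Spectra are normalized to the area of the phenylalanine band: trapezoidal
integration over 988–1023 cm⁻¹ above a straight baseline fitted by least
squares through **all** grid points in the 986–990 and 1021–1025 cm⁻¹
anchor windows jointly (robust on 2 cm⁻¹ grids, where each window holds
several points; two-point interpolation would not be).  Window membership
is a closed interval with 1e-9 cm⁻¹ tolerance.  Integration uses the native
(possibly non-uniform) grid; nothing assumes uniform time or wavenumber
spacing.  A non-positive band area raises an error naming the row.  Rank
evidence is reported as the full singular spectrum with explained-variance
fractions; the package never auto-selects the component count.

## The synthetic data generator

The generator emulates a doxorubicin-inoculation time course:

* **cell spectrum** — Gaussian bands at canonical cellular Raman positions
  (phenylalanine 1005, amide III ~1250 and amide I ~1660, CH₂ deformation
  1450, nucleic-acid bands 785/811 cm⁻¹, …) plus a small constant offset;
* **binding signature** — positive drug bands at 440, 460 and 1211 cm⁻¹
  and *negative* entries at 785 and 811 cm⁻¹, so the bilinear product
  subtracts the nucleic-acid intensity lost on intercalation;
* **response signature** — centred on the 1450 cm⁻¹ protein band.

Pure spectra are sums of Gaussian bands (default FWHM 10 cm⁻¹) on a
400–1800 cm⁻¹ axis at 2 cm⁻¹ spacing, because only band positions — not
full lineshapes — are prescribed by the phenomenology.  Concentration
profiles come from the ODE pair at the default constants Kup = 0.25 h⁻¹,
Kresp = 0.05 h⁻¹, unit dose and capacities: a rapid uptake saturating
within ~15 h followed by a response developing over the full 72 h window,
the qualitative regime observed experimentally.  Signature amplitudes
(0.25 binding, 0.15 response, relative to the unit-height phenylalanine
band) keep every simulated intensity positive at the default settings;
amplitude combinations that would go negative are clipped with a warning.

Noise is additive uniform on [0, f·max(D)) with f = 0.01 by default —
mirroring a `rand`-based 1% noise floor referenced to the global maximum
intensity — and is seedable.  The generator returns the ground-truth C and
S alongside the dataset, so round-trip tests can reconstruct exactly.

What the generator does **not** emulate: fluorescence baseline drift,
cosmic rays, detector response, cell-to-cell heterogeneity, or
compartment-dependent band intensities.  Passing tests therefore show the
estimator is correct under the stated model, not that real spectra satisfy
that model.

## Problem sizes and numerical choices

The recovery benchmark in `scripts/acceptance.py` uses 12 replicates of the
full 145×701 dataset with starting rates 4× (Kup) and 10× (Kresp) away from
the generating values; the test suite uses 20 replicates for the same
check.  Each fit typically converges by the patience rule in ~30
iterations.  Rank decisions use a 1e-10 relative singular-value threshold.
NNLS design matrices are rejected as ill-conditioned when rank deficient
(condition number reported).  The embedded kinetic refit degrades to a
warning — never an exception — so a single bad optimizer step cannot abort
the ALS loop.

## Known limitations

* Capacities (and any quantity coupled to profile scale) are reported in
  arbitrary units; see the intensity-ambiguity note above.
* Two-component experimental designs with coarse, irregular time grids can
  identify the uptake rate but generally not the response system.
* Multi-dataset (augmented-matrix) MCR, closure/unimodality constraints,
  and uncertainty intervals on the constants are out of scope.
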