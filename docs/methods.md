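# Methods

## Scope and data flow

fepbench is the analysis layer of a relative binding-affinity study.  All
sampling is upstream: molecular-dynamics engines produce per-λ
perturbation energies and reduced-potential matrices, QM engines produce
energy components and vibrational frequencies, docking produces scores.
The package turns those into free-energy estimates with uncertainties,
convergence verdicts, network-composed relative affinities, composite
binding scores, and benchmark statistics.  Energies are kJ/mol
throughout; the gas constant is R = 8.31446×10⁻³ kJ/mol/K; the default
simulation temperature is 300 K and the default thermochemistry
temperature 298.15 K at 1 atm.

## Free-energy estimators

Given samples of the perturbation energy ΔU between adjacent coupling
states (the 13-point λ schedule 0, 0.05, 0.1, 0.2, …, 0.9, 0.95, 1 is the
default grid):

* **EA** (Zwanzig): ΔG = −kT ln⟨e^(−ΔU/kT)⟩.  Every exponential average in
  the package is evaluated with log-sum-exp shifting, so no input scale
  can overflow.  The standard error is the delta-method propagation of the
  weight variance.
* **BAR**: the self-consistent Bennett equation in its Fermi-function form
  with the ln(n_F/n_R) sample-size term.  The residual is strictly
  monotone in ΔG, so the solver is a bisection bracketed by the forward
  and negated-backward EA estimates (expanded if needed), converged to
  10⁻⁶ kJ/mol by default with a 500-iteration cap.  Bisection was chosen
  over Newton-type updates because convergence is guaranteed and no
  derivative is needed.  The reported SE is Bennett's asymptotic variance
  evaluated at the solution and is flagged `asymptotic`.
* **TI**: trapezoidal quadrature of ⟨dU/dλ⟩ on the λ grid.  No quadrature
  rule is canonical for this workflow, so the simplest defensible one is
  used and recorded in the estimate metadata; no spline smoothing.
* **MBAR**: self-consistent iteration on the multistate equations, seeded
  by stagewise BAR so typical problems converge in ~10 sweeps; stopping
  when the largest per-state change is below tol (default 10⁻⁸ kJ/mol for
  point estimates, 10⁻⁶ inside the bootstrap).  The endpoint SE uses the
  standard asymptotic covariance of the estimated free energies in its
  SVD form.  A nonparametric bootstrap (default 100 replicates, snapshots
  resampled within each state) provides the work-value uncertainty used
  for downstream error propagation; failed replicates are dropped and
  counted.

The test suite validates all four against a harmonic alchemy toy whose
free energy is exact, checks the two-state MBAR/BAR equivalence to
10⁻⁶ kJ/mol, and cross-checks the MBAR optimum against an independent
convex minimisation of the MBAR objective (scipy BFGS with analytic
gradient) — a different algorithm and code path from the package's
iteration.

## Overlap diagnostics

The six per-window measures compare the forward perturbation-energy
distribution with the negated backward one on a shared energy axis
(negation puts both on the forward axis; this choice is recorded here
because conventions differ).  Histogram measures use the union range of
both sample sets with 50 equal-width bins by default (configurable); a
degenerate zero-width range collapses to a single bin.

* **Ω** — Bhattacharyya coefficient Σ√(p·q) over shared bins; 1 means
  perfect overlap.  Against the Gaussian closed form exp(−Δμ²/8σ²) the
  histogram estimate is accurate to ~0.01 at n = 10⁴.
* **K_AB, Π** — the original equations behind the 0–2 overlap scale and
  the bias metric are not reprinted in the study and are implemented here
  as documented formulations reproducing the quoted limiting behaviour.
  K_AB = c_A·(2 − c_B), where c_A is the probability mass of the first
  distribution lying in bins populated by the second (and vice versa):
  disjoint supports give 0, matched supports ≈1, and a narrow first
  distribution nested inside a much wider second approaches 2.  Π is the
  sampling-adequacy criterion √(2 ln N) − √(2s), evaluated in both
  directions and reported as the minimum, with s the Kullback–Leibler
  divergence of the target from the sampled distribution in a
  Gaussian-moment approximation (chosen over histogram KL for robustness
  at n ≈ 100).  It goes negative exactly when the dissimilarity outruns
  what N samples can cover; fewer than 10 samples per direction sets a
  warning flag.
* **w_max** — the largest normalized Boltzmann weight in the EA; above
  0.3 a single snapshot dominates.
* **ΔΔG_EA** — |ΔG_EA,fwd + ΔG_EA,bwd|.  Note this is zero only for
  estimators that are exact (e.g. constant work); sample-wise negated
  lists retain a positive Jensen gap ln⟨e^x⟩ + ln⟨e^−x⟩ ≥ 0.
* **ΔΔG_TI** — |BAR − TI| for the window; requires dU/dλ samples and is
  omitted (not failed) without them.

Thresholds: Ω < 0.7, K_AB < 0.7, Π < 0.5 (alarming), w_max > 0.3,
ΔΔG_EA > 4 kJ/mol, ΔΔG_TI > 4 kJ/mol.  A window is flagged for an
additional intermediate λ when at least two measures fail or whenever Π
is negative — Π alone below 0.5 but positive is recorded as a failing
flag without forcing refinement.  The proposed new λ is the window
midpoint: the simplest deterministic rule, since only "intermediate" is
prescribed.  The decision is advisory; running the extra simulations is
upstream work.

## Perturbation networks

Edges carry ΔΔG = ΔG_bind(to) − ΔG_bind(from).  Relative affinities
between any two ligands sum signed edge values along the shortest path
(fewest edges); on the study's tree-shaped graphs the path is unique.
Standard errors combine in quadrature; correlations between paths sharing
edges are ignored, which slightly understates the error of overlapping
pairs.  Ring-flippable ligands contribute two conformer candidates per
edge; the selected one minimises the implied ΔG_bind of the non-reference
ligand (max value for X→ref edges, min for ref→X, first-listed on ties).
For an edge between two non-reference ligands the rule is undefined and
an explicit pre-recorded selection is required.  Non-binders (assay
ceiling 50 µM, affinity bound −24.6 kJ/mol) are excluded from comparison
tables by default and from reference choice always; they can be included
as data points at the bound.

Three comparison schemes mirror the study: a fixed reference ligand, all
pairs reachable within two perturbations, and all pairs.

## Composite QM/MM score

ΔG_bind = ΔG_BQ(COSMO) + ΔE_bsc + ΔE_disp + ΔG_therm + ΔE_strain +
(ΔG_solv,COSMO-RS − ΔG_solv,COSMO).  The component table stores the
ligand-relaxation column as printed (negative); assembly negates it, the
only sign convention consistent with both the tabulated totals and the
positive 10–61 kJ/mol strain range.  The `as_submitted` variant flips the
solvation difference's sign, reproducing the originally submitted scores
(which carried that sign error); the two variants differ by exactly
2·(ΔG_RS − ΔG_COSMO) per ligand.  The reduced column ΔG′ is implemented
as "exclude ΔG_therm only" because the tabulated numbers satisfy
ΔG′ = ΔG_bind − ΔG_therm exactly, even though the caption describes
excluding the relaxation term too; both exclusion sets are exposed.

Quasi-RRHO thermochemistry: per-mode G = ZPE + E_vib(T) − T·S with
S = w·S_HO + (1−w)·S_FR, damping w = 1/(1+(ω₀/ω)⁴), ω₀ = 100 cm⁻¹.  The
free-rotor moment μ = h/(8π²ν) is capped via μ′ = μB_av/(μ+B_av) with
B_av = 10⁻⁴⁴ kg·m², following the interpolation model's published
parameters.  Only vibrational contributions are computed (translation and
rotation largely cancel in the interaction-energy assembly the modes feed
into); imaginary modes are filtered and counted, never silently used.

## Benchmark metrics

MAD, translated MAD (subtract the mean signed error first — an exact
identity with the MAD of detrended data, tested as such), maximum error,
Pearson R with regression slope of calculated on experimental, and
Kendall τ-b (tie-corrected; ties do occur in the fixture data).  For
relative affinities whose sign depends on an arbitrary perturbation
direction, the antisymmetrized mode augments each pair (x, y) with
(−x, −y), making R and the through-origin slope direction-invariant;
fixture tests record which mode reproduces which published block (plain
for the with-water comparisons, antisymmetrized for the no-water ones).
IC₅₀ converts via ΔG = RT ln(IC₅₀/1 M); at the stated 300 K the 50 µM
ceiling gives −24.70 kJ/mol, while the commonly quoted −24.6 corresponds
to 298 K — the temperature is an explicit argument.

The parametric bootstrap (default 500 replicates) adds independent
Gaussian noise per point to the calculated series (its per-point SE) and
the experimental series (default σ = 1.7 kJ/mol), recomputes each metric,
and reports the replicate mean and SD; replicates where a metric is
undefined are dropped and counted.  With all uncertainties zero the
bootstrap returns the point estimates with exactly zero SE.

## Synthetic generators

* **Harmonic alchemy**: U_λ = ½k(λ)x², k(λ) linear from k0 to k1 — linear
  interpolation rather than soft-core because the exact closed form
  ΔA = (kT/2)ln(k1/k0) is the point; soft-core shapes belong to the
  engines.  Defaults mirror the study cadence: 100 samples per state
  (1 ns sampled every 10 ps), 300 K, the 13-point schedule.
* **Gaussian work pairs**: forward N(μ_f, σ²), backward N(−μ_f + σ²/kT,
  σ²), the unique Gaussian pair satisfying the Crooks relation, with
  implied ΔG = μ_f − σ²/(2kT); σ controls the overlap.  A histogram
  log-ratio regression of the two densities recovers slope 1/kT, which
  the tests check.
* **Networks**: edge values are true node differences plus Gaussian
  noise; edges touching a reference carry a decoy conformer displaced
  8 kJ/mol unfavourably (the magnitude of typical conformer splits in the
  fixture data), so selection can be validated against the plant.

What the generators do not emulate: time-correlated samples (snapshots
are independent; real trajectories need subsampling by correlation time),
non-Gaussian work tails, force-field error, or conformational
heterogeneity beyond the planted decoys.  Passing tests therefore
demonstrate correctness of the estimators and decision rules, not that
any particular simulation protocol converges.

## Fixtures, sizes, and determinism

The packaged tables carry the study's printed values at 0.1 kJ/mol
precision and are verified against SHA-256 checksums on load; every
fixture-based assertion uses tolerances reflecting that rounding
(0.15 kJ/mol for assembled totals; 0.55 for integer-printed column
means).  Statistical acceptance checks run 100 seeds at the default
problem sizes above, which keeps the whole suite under a minute on one
core.  Every stochastic routine takes a seed; the pipeline fans a single
master seed into per-stage sub-seeds through `numpy.random.SeedSequence`
spawn keys, and reruns with the same seed are bit-identical (tested).
JSON outputs serialize at full precision; rounding to the study's 0.1
style is presentation only.

## Known limitations

* K_AB and Π are faithful to the documented limiting behaviour of their
  scale, not transcriptions of the original equations; absolute values
  between the calibration points should be read comparatively.
* Path-SE quadrature ignores shared-edge correlations across pairs.
* No cycle-closure correction or weighted least-squares network
  estimation: the study's graphs are trees, where neither applies.
* The BAR SE is asymptotic and can be optimistic for very small or very
  skewed samples; the MBAR bootstrap is the conservative alternative.
* Whole-complex continuum-solvation rescoring (PB/GB style) is
  deliberately absent; the workflow this package mirrors rejected it as
  unstable, and the composite score uses the COSMO big-QM route instead.
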