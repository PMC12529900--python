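# Methods

## The problem

³¹P NMR of B-DNA reports on backbone conformation: each internucleotide
phosphate's chemical shift δ³¹P and three-bond coupling ³J(P,H3′) is an
ensemble average over the backbone conformers the phosphate visits.  The
classical interpretation uses a two-state BI/BII picture distinguished by
the sign of ε − ζ.  This package implements a finer-grained interpretive
framework built on the NtC structural alphabet, in which a dinucleotide
step is classified into discrete conformer classes by all nine backbone
torsions t = (δₙ, χₙ, εₙ, ζₙ, αₙ₊₁, βₙ₊₁, γₙ₊₁, δₙ₊₁, χₙ₊₁), and each
class carries its own phosphate NMR parameters: a shielding constant σᵢ
(ppm) and a coupling Jᵢ (Hz).

## Classification

A snapshot is assigned to the class minimizing the squared circular
distance Σₜ d(t_class, t_snap)², where d is the signed minimal arc in
(−180°, 180°].  Torsions are periodic, so the plain difference of a
nominal formula would misrank snapshots near the 0/360 branch cut (359°
and 1° are 2° apart); the minimal-arc form fixes that while leaving the
ranking identical everywhere else.  The square root and the 1/9 of an
RMSD are omitted — the argmin is invariant to monotone transforms.  Exact
ties (measure zero) are broken toward the lexicographically smallest
class id, so assignment is fully deterministic.  All nine torsions are
weighted equally, including the glycosidic χ angles.  Every frame is
assigned to its nearest class by default; an optional squared-distance
cutoff can leave outlier frames unassigned, in which case they are
excluded from both numerator and denominator of the population weights.

## Populations and torsion distributions

Per step, the population weight of class i is the relative occurrence
wᵢ = Nᵢ/N over the N classified frames; weights are stored alongside the
exact integer counts so Σᵢ wᵢ = 1 holds to ~1e-16 and is asserted at
1e-12.  Class-conditional torsion distributions are normalized counts on
a fixed grid of 36 half-open 10° bins [10°(k−1), 10°k); a value of
exactly 360° is normalized to 0° and lands in bin 1.  No smoothing or
kernel density estimation is applied — the discretization is part of the
method's definition.  For the shielding dependence a joint 36×36
histogram over the phosphate-flanking pair (α, ζ) is used; a
product-of-marginals variant is available behind a flag for comparison,
since with correlated (α, ζ) fluctuations the two genuinely differ.

## Ensemble averaging and referencing

Two averaging schemes produce per-step observables:

* **Population weighting**: σ = Σᵢ wᵢσᵢ and J = Σᵢ wᵢJᵢ with the scalar
  class parameters.
* **Probability averaging**: for the BI-family (BB00, BB01) and
  BII-family (BB04, BB07) classes the scalar is replaced by the
  expectation of the class's parameter dependence under its torsion
  distribution — Σₖⱼ Pᵢ(αₖ, ζⱼ)σᵢ(αₖ, ζⱼ) for the shielding and
  Σₖ Pᵢ(εₖ)Jᵢ(εₖ) for the coupling.  All other classes contribute their
  scalars.  Surfaces and curves are treated as piecewise-constant on the
  10° bins, matching the discrete double sum; interpolation would change
  results and is deliberately not offered.  When every surface/curve is
  constant at the class scalar, probability averaging collapses exactly
  onto population weighting, which is asserted at 1e-12.

Chemical shifts are referenced internally to the A6pT7 phosphate of the
Dickerson–Drew dodecamer: calculated shifts as δ = σ(A6pT7) − σ (larger
shielding ⇒ smaller shift), measured shifts as δ = δ′ − δ′(A6pT7) where
δ′ is against the external standard.  The reference step's δ is exactly
0 by construction in both conventions, which removes any bias from an
imperfect theoretical description of the external standard.

## The deviation metric

Agreement between calculated and measured per-step values is scored as

    MAD = sqrt( (1/N) Σᵢ (X_calc,i − X_exp,i)² ),   X ∈ {J, δ}.

The quantity is called "MAD" in parts of the ³¹P literature despite
being the root-mean-square form; recomputing the published per-table
summaries of the Dickerson–Drew observables from their printed per-step
columns reproduces 1.16 ppm / 2.46 Hz / 2.61 Hz only under the RMS
reading (the mean-|·| form would give ≈0.54 ppm for the first), so the
RMS form is what this package implements, keeping the field's label.
One published summary (0.27 ppm) recomputes to 0.28 ppm from the rounded
printed columns; this input-rounding sensitivity is tolerated at ±0.01.

## BI′/BII′ population fitting

Roughly 60–80% of phosphate populations sit in BB00/BB01/BB04/BB07.  The
fit groups BB00+BB01 as BI′ and BB04+BB07 as BII′, holds the
within-group ratios fixed at their input (simulation) values, leaves all
other class populations untouched, and adjusts, per phosphate
independently, the fraction x of the combined pool mass assigned to
BII′.  The population-weighted observable is affine in x, so each step
is an exact scalar solve; solutions outside [0, 1] are clamped to the
boundary and flagged rather than rejected, since experimental noise can
push the algebraic solution slightly off the simplex.  A group that
starts with zero mass falls back to an equal within-group split so the
fit can still move mass into it.  Steps with a degenerate map (equal
pool-level observables) or an empty pool are skipped with their input
populations retained and the reason recorded.

The two-stage protocol fits x per step to the measured ³J first; the
refitted populations of the reference step then refresh σ(A6pT7), and
the second stage refits x against the δ data re-referenced to that
updated standard.  The δ stage overwrites the J-stage fractions — a
regularized compromise between the stages is a possible alternative
semantics, but the overwrite is the simplest consistent reading and is
what is implemented.  Fitting always uses population weighting (scalar
parameters), matching how fitted observable columns are defined.

## Temperature differentials

For a series of per-temperature observables and populations sharing a
step set, the analysis reports Δδ(T) = δ(T) − δ(T₀) and sectional
population changes Δw for BI = {BB00, BB01}, BII = {BB04, BB07} and
"rest", against a baseline T₀ = 20 °C by default.  The three sections
partition the population, so Δw sums to zero at every (step, T);
baseline rows are identically zero, and swapping baselines negates the
differentials.  No trend fitting or smoothing is applied.  The total
shift dispersion at one temperature is reported as max δ − min δ over
the (≥2) steps.

## Synthetic data: what it emulates and what it does not

The generators stand in for three inputs the package would otherwise
need from outside: microsecond MD trajectories, a QM-derived class
parameter table, and measured observable tables.

* **Trajectories** are drawn per step from a known NtC mixture, each
  frame adding independent wrapped-Gaussian noise (default sd 8°, a
  typical single-well torsional fluctuation width) to the nine
  class-defining torsions.  The default duplex mimics the Dickerson–Drew
  dodecamer's 11 steps with BI-dominated stem steps and elevated
  BII-family populations toward the termini, 2000 frames per step by
  default (enough to resolve populations of a few percent while keeping
  a full run in seconds).  Real MD differs in ways that matter for
  realism but not for correctness of the pipeline algebra: torsions
  fluctuate in correlated modes, class dwell times are autocorrelated,
  and transitions are not i.i.d. draws.  Passing tests therefore
  validate counting, averaging, referencing, fitting and differential
  algebra — not force-field realism.
* **The synthetic class table** contains eight classes (BB00, BB01,
  BB04, BB07 plus four minor classes) at B-DNA-like torsion centers
  separated by ≥40° in at least one torsion, with a small seeded jitter
  so distinct seeds give distinct tables.  Its σ/J scalars are plausible
  but synthetic; no claim is made of matching any QM parametrization.
  Real class-definition tables are loaded from CSV and drop in without
  code changes.
* **Parameter dependences** are filled with a Karplus-type curve
  A cos²ε + B cos ε + C (defaults A=15.3, B=−6.2, C=1.5 Hz, fixed
  arbitrary values in the range typical of ³J(P,H) couplings) and a
  first-harmonic periodic surface in (α, ζ) of 1.5 ppm amplitude, both
  shifted per class so their value at the class-defining bin equals the
  class scalar — the consistency invariant that ties the two averaging
  schemes together.
* **Experimental tables** are forward-computed (population weighting +
  internal referencing) from known populations with independent Gaussian
  noise per observable; the reference step's δ is re-zeroed after
  noising because internal referencing is exact by definition.

All generators are pure functions of (specification, seed), drawn from
`numpy` Generator streams spawned per step, so runs are reproducible
bit-for-bit.

## Numerical choices

* Angles are normalized to [0, 360) everywhere; the bin convention is
  half-open with 360° wrapping to bin 1.
* Signed circular differences live in (−180°, 180°]; +180° is the
  canonical representative of the half-turn.
* Population tables validate Σw = 1 at 1e-9 on construction (count-based
  tables are exact to float division); acceptance-level assertions use
  1e-12.
* The affine fit solves in closed form — no iterative optimizer — so
  "solver tolerance" is float arithmetic, ~1e-15 relative; degeneracy is
  declared below a slope of 1e-12.
* Zero-population classes are dropped from weight storage; a class with
  frames in the weights but an empty histogram is rejected as
  inconsistent input.

## Known limitations

* The per-class NMR parameters shipped in the synthetic table are not
  QM-derived; quantitative comparison to measured DNA spectra requires a
  user-supplied class table (and, for probability averaging, surfaces
  and curves).
* Solvation/Mg²⁺ effects enter only as alternative parameter tables;
  nothing is computed about solvent.
* The fit adjusts one scalar per phosphate and cannot reshape within
  the BI′ or BII′ groups or touch residual classes; irregular steps
  dominated by non-pool classes are fit-limited by design.
* No thermodynamic modelling (van 't Hoff analysis) is attempted on the
  temperature series; only raw differentials are reported.
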