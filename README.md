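# ntcnmr

Interpretation of ³¹P NMR observables in B-DNA through populations of
NtC backbone conformers.

## The problem

The ³¹P chemical shift δ³¹P and the three-bond coupling ³J(P,H3′) of a
DNA backbone phosphate are ensemble averages over the conformers the
backbone visits.  The classical interpretation reduces backbone dynamics
to a two-state BI/BII equilibrium (sign of ε − ζ); `ntcnmr` implements a
finer framework based on the NtC structural alphabet, in which each
dinucleotide step is classified by all nine backbone torsions
t = (δₙ, χₙ, εₙ, ζₙ, αₙ₊₁, βₙ₊₁, γₙ₊₁, δₙ₊₁, χₙ₊₁) into discrete
conformer classes, each carrying its own phosphate shielding σᵢ and
coupling Jᵢ.  It is aimed at NMR spectroscopists and simulators who want
to confront MD-derived conformer populations with measured spectra.

The pipeline:

1. **Classification** — assign each torsion snapshot to the class
   minimizing Σₜ d(t_class, t_snap)² with circular (minimal-arc)
   differences.
2. **Populations** — per-step class weights wᵢ = Nᵢ/N, plus
   class-conditional torsion distributions on a 10° grid.
3. **Averaging** — population weighting σ = Σ wᵢσᵢ, J = Σ wᵢJᵢ, or
   probability averaging, which replaces the BI/BII-family scalars by
   expectations of σᵢ(α, ζ) and Jᵢ(ε) dependences under the class's
   torsion distribution.
4. **Referencing** — internal standard (A6pT7 for the Dickerson–Drew
   dodecamer): δ = σ(ref) − σ, and for experiments δ = δ′ − δ′(ref).
5. **Scoring** — RMS deviation MAD = √((1/N) Σ (X_calc − X_exp)²).
6. **Fitting** — per-phosphate adjustment of the BII′ fraction of the
   combined BI′ = {BB00, BB01} / BII′ = {BB04, BB07} pool to measured
   ³J, then to δ³¹P with the reference refreshed in between.
7. **Temperature analysis** — Δδ(T) and sectional Δw against a 20 °C
   baseline.

A synthetic-data module generates class tables, mixture trajectories
with wrapped-Gaussian torsion noise, and noisy experimental tables, so
the full pipeline runs and is tested without any external data.  See
`docs/methods.md` for the model details and assumptions.

## Worked example

```python
import ntcnmr as n

table = n.synthetic_class_table(seed=1)              # 8 NtC classes
spec = n.default_duplex_spec(n_frames=2000)          # 11-step duplex
traj, labels = n.sample_trajectory(spec, table, seed=1)
assignments = n.classify_trajectory(traj, table)
weights = n.population_weights(assignments)
obs = n.reference_delta(
    [n.population_average(w, table) for w in weights.values()]
)
for o in obs:
    print(f"{o.step_id:<9} delta = {o.delta:+.2f} ppm   J = {o.j_coupling:.2f} Hz")
```

```
C1pG2     delta = +1.21 ppm   J = 4.86 Hz
G2pC3     delta = +0.27 ppm   J = 2.96 Hz
C3pG4     delta = +0.57 ppm   J = 3.57 Hz
G4pA5     delta = +1.10 ppm   J = 4.88 Hz
A5pA6     delta = +0.08 ppm   J = 2.55 Hz
A6pT7     delta = +0.00 ppm   J = 2.36 Hz
T7pT8     delta = +0.08 ppm   J = 2.53 Hz
T8pC9     delta = +0.11 ppm   J = 2.62 Hz
C9pG10    delta = +1.08 ppm   J = 4.40 Hz
G10pC11   delta = +0.95 ppm   J = 4.56 Hz
C11pG12   delta = +1.31 ppm   J = 4.73 Hz
```

The reference step A6pT7 sits at exactly 0 ppm; the BI-dominated stem
steps (A5pA6…T8pC9) show small shifts and couplings, while the
BII-enriched tail steps carry larger ones — the qualitative stem/tail
contrast the method is built to quantify.  Fitting the BII′ fractions to
an experimental table then goes through `n.fit_equilibrium(exp, weights,
table)`, which returns per-step fitted populations, Δw and MAD reports.

A command-line interface mirrors the stages:

```sh
ntcnmr simulate --out-prefix run --seed 2 --n-frames 2000
ntcnmr classify --traj run.trajectory.csv --classes run.classes.csv --out run.assignments.csv
ntcnmr average  --traj run.trajectory.csv --classes run.classes.csv --out run.observables.csv
ntcnmr fit      --weights run.weights.csv --classes run.classes.csv --exp run.experiment.csv --out-prefix run
ntcnmr score    --calc calc.csv --exp exp.csv
ntcnmr tscan    --manifest series.csv --baseline 20 --out diffs.tsv
```

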