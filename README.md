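# mirrorbreak

Linear-stability screening of mass-action chemical reaction networks for
**spontaneous mirror symmetry breaking (SMSB)** — the dynamical origin of
homochirality.  Given a plain-text mechanism (species, reactions, *dual
pairs* of mirror-image reactions sharing a rate constant), `mirrorbreak`
decides whether symmetry-breaking unstable steady states can exist and
emits concrete rate-constant sets that realise them, verified by numeric
eigenanalysis and ODE integration.

Six analyses are provided, each building on the previous:

1. **Trace-determinant plane** — stability classification of 2-species
   networks from the symbolic Jacobian.
2. **Stoichiometric network analysis (SNA)** — Clarke's factorisation
   `J = S·diag(E·j)·K·diag(h)`: exact extreme-current enumeration (double
   description over integers), the current matrix `V(J)`, and instability
   screening via the trace-determinant, principal-minor ("mineurs") or
   characteristic-polynomial heuristics.  Dual pairs can be encoded as
   extra stoichiometric rows, which drastically reduces the number of
   extreme currents.
3. **Six categories** — template classification of every chiral reaction
   (synthesis / decompositions / autocatalysis / limited
   enantioselectivity / inhibition), a linear rate balance and the two
   Frank-type inequalities, solved symbolically into nested intervals.
4. **Frank inequality, nonlinear** — `J11 − J12 > 0` over rate constants
   and concentrations at the mirror-symmetric state (report only; the
   system is nonlinear and is not sampled).
5. **Frank inequality + SNA** — the same inequality on the current matrix,
   where it is *linear* in the convex parameters `j` and can be sampled.
6. **Multi-pair reduction** — for networks with several enantiomeric
   pairs: the `[A B; B A]` block symmetry of `V(J)` is verified and the
   reduced matrix `V′ = A − B` (one row per pair) is analysed with the
   same machinery.

The sampler replaces a computer-algebra backend: exact Fourier–Motzkin
elimination turns linear equality/strict-inequality systems into nested
intervals, a heuristic substitutes pseudo-random values for the most
frequent variable to linearise nonlinear systems, and current-space
samples are converted to rate constants through `v = E·j` with
enantiomer-equal concentrations (all in exact rational arithmetic, so dual
rate constants come out exactly equal and every released sample satisfies
every original constraint on re-substitution).

## Command line

```sh
# run every enabled algorithm on a bundled mechanism, report to stdout
mirrorbreak --model Kondepudi-Nelson --seed 1 > kn.out

# user model files use the same restricted key/value dialect
mirrorbreak --model path/to/My-Model.txt --only 5,6 --out samples/

mirrorbreak --list-fixtures    # bundled mechanisms
mirrorbreak --model Kondepudi-Nelson --latex t   # LaTeX rendering
```

Sampled rate sets are written as `*.simu.json` files; trajectories from
`mirrorbreak.verification.integrate` can be exported as CSV.

Bundled mechanisms include the Kondepudi–Nelson model, the explicit
reversible Frank model (with and without CSTR flows), the two-replicator
network with two enantiomeric pairs, a limited-enantioselectivity (LES)
scheme with both dual-pair variants, a Calvin-type CSTR+LES model, an APED
dimerisation block and two asymmetric-autocatalysis schemes.

## Model file dialect

```python
modelname = 'Kondepudi-Nelson'
species = ['L', 'D']            # first two must be an enantiomeric pair
reactions = [
    "      <->  L",             # reversible: forward then backward index
    "L + D  ->   ",             # irreversible; coefficients as "2 L"
]
dual_pairs = [(0, 1)]           # optional; mirror pairs are auto-detected
enantiomeric_pairs = [(0, 1)]   # optional, for multi-pair networks
analyses = { "sna": {"enabled": True, "dual-pairs-in-ec": True}, }
```

Values are literals (never executed).  Multi-way rate equalities (e.g. a
common CSTR flow) are declared as pairs sharing the first element:
`(1, 2), (1, 3), ...`.

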