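# Methods

This note documents the models implemented in `chaforge`, their
assumptions, the defaults that matter, and what the synthetic-data tests do
and do not demonstrate.

## Sequence-level checks

Strands are strict-ACGT DNA, 5'→3'. Duplex search counts only perfect
Watson–Crick pairs (A·T, G·C, no wobble), because strand-displacement
circuits are designed on exact complementarity; the search reports the
longest contiguous antiparallel segment with 1-based coordinates (internal
code is 0-based half-open). G-quadruplex capability is assessed by motif
counting — at least four maximal G-tracts of a chosen minimum length
(≥ 3 for the hairpin tails, ≥ 2 resolves the thrombin aptamer's two-tier
quadruplex) — not by folding thermodynamics: the structural ensemble below
is pseudoknot-free and cannot represent quadruplexes, so the two views are
deliberately separated.

## Loop-based thermodynamics

A secondary structure on one or more ordered strands is a non-crossing set
of pairs; its free energy is the sum over the loops of its base-pairing
graph. The shipped parameter set uses the unified DNA nearest-neighbour
stacking free energies at 37 °C and size-dependent hairpin/bulge/interior
penalties with Jacobson–Stockmayer logarithmic extrapolation beyond the
tabulated sizes; multiloops cost `a + b·(branches) + c·(unpaired)`
(3.4 / 0.4 / 0.1 kcal/mol) and exterior faces are free, so the all-unpaired
structure scores exactly 0. Simplifications, chosen so that the dynamic
programmes and the exhaustive oracle score *identically* the same model:
no coaxial stacking, no dangles, no terminal-AT penalties, no interior-loop
asymmetry terms. Temperature defaults to 310.15 K; the Boltzmann constant
is the gas constant in kcal/(mol·K).

Minimum hairpin loop is 3 unpaired bases (universal convention). MFE ties
are broken deterministically by the DP scan order (options are replaced
only on strict improvement), which keeps repeated runs identical.

### Dynamic programmes and the enumeration oracle

The partition function is computed by an interval DP (sum-product; a
min-plus twin with traceback yields the MFE). Two-loops are scanned up to
30 total unpaired bases (the usual MAXLOOP convention); explicitly supplied
structures with larger loops are still scored finitely via the
extrapolation. For sequences the exhaustive enumerator can handle (guarded
at 22 nt, where the scan cap never binds), the DP must agree with
enumeration to 1e-9 relative on Q and exactly on the MFE minimum — this
oracle equivalence, not any particular parameter value, is the correctness
surface, so the energy tables are documented constants rather than tested
claims.

### Multi-strand complexes

For an ordered complex the DP runs on the concatenation with *nicks*
between strands, under the polymer-graph rule: each loop may expose at most
one nick, and a nick-containing loop is scored as an exterior face (0).
For a fixed strand ordering these structures are exactly the connected
pseudoknot-free structures of the complex; the test oracle instead decides
connectivity by union-find over strands, keeping the two routes
independent. A complex's Q additionally includes an association penalty of
1.96 kcal/mol per strand beyond the first (1 M standard state) and is
divided by the rotational symmetry order of its necklace (the A·A
homodimer exercises this). One consequence of omitting coaxial/initiation
terms at the loop level: a complex held by a single base pair has ΔG = 0
for that structure.

## Tube equilibrium

Complexes up to `L` strands (default 4 — tetramer by-products are the
largest species of interest in the designed tube) are enumerated as
rotation-distinct orderings. Equilibrium concentrations minimise
`Σ_j x_j (log x_j − log Q_j − 1)` under mass conservation `A x = x⁰`
(totals entered in nM, solved in molar with a 1 M reference). The solver
maximises the concave dual `g(λ) = λ·x⁰ − Σ_j Q_j e^{A_jᵀλ}` by Newton
iterations with backtracking; near the optimum, where dual improvements
fall below floating-point resolution, a step is also accepted when it
shrinks the mass-balance residual (Newton still contracts quadratically
there), so the logged objective `−g` is monotone to within rounding.
Initialisation is deterministic from the ideal no-complex state
(`λ_i = log x⁰_i − log Q_i`). Convergence demands a relative mass-balance
residual of 1e-10 (at most 200 iterations); the primal is recovered as
`x_j = Q_j e^{A_jᵀλ}`, which is itself the law-of-mass-action/KKT
certificate reported with each solution. Complexes with `Q_j = 0` (no
connected structure possible) are held at zero.

## Circuit kinetics

The triggered circuit is modelled at the domain level with 8 species and 5
elementary mass-action reactions (trigger release; reversible S+H1
opening; catalytic S·H1 + H2 → duplex + S; bimolecular H1+H2 leak). The
protein target is represented as a single strand complementary to the
aptamer — the standard abstraction for strand-displacement simulation;
aptamer–protein binding biophysics is out of scope. Defaults:
bimolecular steps 1e-3 /nM/s (≈ 1e6 /M/s, typical of long-toehold
displacement), reverse opening 1e-3 /s, leak 1e-8 /nM/s. These are a
configuration surface chosen to realise the intended regime — fast
triggered assembly, slow leak, with/without-target ratio comfortably above
10× — not fitted constants; published descriptions of this circuit report
an endpoint ratio of the same order (tens). Integration uses LSODA at
rtol 1e-9 / atol 1e-12, tight enough that the four structural moiety
conservation sums drift below 1e-6 relative and concentrations never go
negative beyond integrator-tolerance dust (no clipping is applied).
Deterministic ODEs only: at nM × µL scales stochastic effects are
negligible and the reference behaviour is smooth.

Assay-condition initials are 1 nM target, 50 nM Aptamer·S probe, 300 nM
each hairpin, 7200 s endpoint.

## Assay analytics

Signal is an affine map of species concentrations:
`gain · (g4_per_duplex · [duplex] + leak_weight · [hairpin]) + background`,
with `g4_per_duplex = 2` — one signalling quadruplex at each end of the
assembled duplex; the count is a parameter because the duplex architecture
itself does not fix how many fold functionally. No enzyme kinetics of the
DNAzyme/TMB channel is modelled; the colorimetric channel reuses the same
affine transduction with its own gain and background.

Calibration fits ordinary least squares of signal on lg(concentration in
nM) using per-concentration replicate means (matching how triplicate
calibration points with error bars are presented; a per-replicate fit is
available). Blanks (X = 0) are excluded; the reported `r` is the Pearson
correlation of the means with lg X — chosen over r² where a bare
"correlation coefficient" is ambiguous.

The 3σ/S detection limit is reported in two forms, because with a
lg-scale slope the literal quotient has units of *decades*: the literal
`3σ/|S|`, and the calibration inversion `X` such that
`Y(X) = F₀ + 3σ`. Published single-number LODs for assays of this type are
not recomputable without the raw blank readouts, which exist only as
figures; the worked examples here therefore use hand-computable inputs.

## Synthetic data

The calibration generator draws
`Y = a·lg X + b + N(0, σ²)` at the assay's concentration series
(0, 0.01, 0.05, 0.1, 0.5, 1, 10, 50 nM; 0 is the blank) with 3 replicates,
using the published calibration coefficients (721.64, 3432.27) as the
generating line so the fitting path is self-validating. The replicate
noise σ defaults to 50 signal units — a free parameter, as true replicate
noise is not printed; the blank mean defaults to the line's value half a
decade below the lowest calibrator. Noise is homoscedastic Gaussian:
triplicate error bars are symmetric and roughly constant, and endpoint
readouts identify nothing richer. Serum backgrounds are emulated as a
positive blank offset (potassium-induced quadruplex background) with
unchanged spread.

What passing these tests shows: the estimators recover what the model
generates, at the stated noise, replication and design. What they do not
show: robustness to heteroscedastic or non-Gaussian noise, plate/drift
effects, spectral overlap, or pipetting error — none of which the
generator emulates.

In the recovery studies, "within 3 standard errors" uses the SE implied by
the known generator noise (σ/√replicates per mean). With only three
residual degrees of freedom an SE *estimated* from the residuals would
turn the check into a t₃ criterion with ~94 % nominal coverage, which
would misreport a correctly working estimator.

## Problem sizes

Oracle-equivalence checks use 50 random sequences of 8–18 nt (enumeration
grows combinatorially beyond that); the dimer closed-form grid spans 100
(K, totals) points over K = 1e3–1e15; the designed S/H1/H2 tube is solved
with all 44 complexes up to tetramers; kinetics runs the full 7200 s
endpoint; recovery studies use 200 seeds. These sizes make the entire
suite run in seconds while exercising every code path at full fidelity.

## Known limitations

* Pseudoknots, G-quadruplexes, wobble pairs and chemical modifications are
  outside the structural ensemble.
* Energy parameters are a documented, internally consistent set, not a
  fitted reproduction of any published tool's output; absolute ΔG values
  should be read comparatively.
* The kinetic model has no sequence-level reaction enumeration, no fuel
  exhaustion beyond the modelled species, and no temperature dependence of
  rates.
* The equilibrium solver assumes a dilute ideal solution (no activity
  coefficients).
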