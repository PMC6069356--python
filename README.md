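# chaforge

Simulation-assisted design and analysis of **catalytic hairpin assembly
(CHA)** biosensor circuits, built around an aptamer-triggered, enzyme-free,
label-free thrombin sensor.

## The problem

A CHA sensor detects a protein target with four DNA oligos: a
thrombin-binding **Aptamer** pre-hybridised to a trigger strand **S**, and
two metastable hairpins **H1** and **H2** whose assembled duplex carries a
G-quadruplex-forming tail at each end. Target binding liberates S; S opens
H1; H2 then displaces S from the opened hairpin, producing an H1:H2 duplex
and recycling S for another round. Each target molecule therefore generates
many signalling quadruplexes (read out by NMM fluorescence or a
hemin/TMB colorimetric channel). Before any wet-lab work, the design must be
vetted *in silico*: do the hairpins fold as intended, does the untriggered
mix stay off, does the triggered circuit amplify, and what sensitivity does
the calibration imply?

`chaforge` is a toolkit for exactly that workflow, aimed at DNA
nanotechnologists designing strand-displacement circuits.

## What it computes

* **Sequence checks** — reverse complements, the longest antiparallel
  Watson–Crick duplex between two strands (probe/recognition segments), and
  G-tract scanning as a quadruplex-capability proxy.
* **Secondary-structure thermodynamics** — a loop-based nearest-neighbour
  model with free energy `ΔG(s) = Σ_loop ΔG(loop)`, partition function
  `Q = Σ_{s∈Γ} e^{−ΔG(s)/kT}`, Boltzmann probabilities
  `p(s) = e^{−ΔG(s)/kT}/Q`, and MFE prediction, by interval dynamic
  programming validated against exhaustive enumeration.
* **Test-tube equilibria** — complexes up to L strands enumerated as
  necklaces, each with a multi-strand partition function `Q_j` over
  *connected* pseudoknot-free structures; equilibrium concentrations solve
  `min_x Σ_j x_j (log x_j − log Q_j − 1)` subject to `A x = x⁰`, via a
  damped Newton method on the dual (strand potentials), with mass-balance
  and law-of-mass-action certificates.
* **Circuit kinetics** — deterministic mass-action ODEs of the triggered
  circuit (trigger release, reversible hairpin opening, catalytic duplex
  formation, bimolecular leak), with structural conservation laws and the
  with/without-target amplification ratio.
* **Assay analytics** — affine transduction (2 quadruplexes per duplex),
  ΔF and F/F₀ metrics, the log-linear calibration `Y = a·lg X + b`, and the
  `3σ/S` limit of detection (reported both literally in decades and
  inverted through the calibration to a concentration).
* **Synthetic data** — seeded generators for calibration readouts, blanks
  (with a serum-background mode) and designed hairpin panels.

## Worked example

```bash
chaforge demo --seed 7 --out demo_out
```

runs the full pipeline on the built-in oligo panel and prints:

```
amplification_ratio     45.8873
duplex_terminal_nM      291.063
calibration_slope       725.641
calibration_intercept   3425.41
calibration_r           0.999365
lod_decades             0.140627
lod_nM                  0.00446609
```

Reading these numbers: a single 1 nM dose of target converts 291 nM of
hairpins into signalling duplexes within two hours (≈ 291 turnovers per
trigger), 46× the leak-only background — the circuit amplifies. The
synthetic triplicate calibration (noise sd 50) refits the generating
log-linear law closely (slope ≈ 726 signal units per decade, r ≈ 0.999),
and the 3σ/S rule on 10 synthetic blanks puts the detection limit at
≈ 0.0045 nM (4.5 pM) via calibration inversion. `demo_out/` additionally
holds the H1/H2 MFE dot-brackets, the solved S/H1/H2 tube (the H1:H2 duplex
dominates every by-product complex), and the tidy kinetic time course.

Individual stages are available as `chaforge fixtures | structure | tube |
simulate | calibrate | synth`; see `chaforge COMMAND --help`.

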