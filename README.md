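# nucbarrier

Single-molecule analysis of the nucleosome as a mechanical barrier: the
complete computational chain from raw optical-tweezers traces to
per-base-pair maps and energies of the histone–DNA interactions that an
elongating RNA polymerase II must overcome.

The package is aimed at single-molecule biophysicists working with
dual-trap unzipping and transcription assays on nucleosomal templates
(the 147-bp '601' nucleosome positioning sequence, NPS). It provides,
as a library plus a `nucbarrier` command line:

- **Polymer mechanics** (`nucbarrier.polymer`) — extensible worm-like
  chain (dsDNA, Marko–Siggia interpolation with an enthalpic F/K term)
  and extensible freely jointed chain (ssDNA) elasticity; composite
  tether forward model and its inversion, converting a force–extension
  pair (F, s) into the number of unzipped base pairs
  `N = (s − z_ds(F) L_ds) / (2 ℓ_ss z_ss(F))`; per-bp unzipping work
  `ΔE(F) = 2 F z_ss ℓ_ss − ∫ F_FJC dx`; elastic-parameter fitting.
- **Unzipping pipeline** (`nucbarrier.unzip`) — force-weighted residence
  ("topography") maps of the unzipping fork, trace registration by the
  rescaling–correlation method exploiting the template's two tandem NPS
  copies 197 bp apart, and transition (rip) counting.
- **Equilibrium energetics** (`nucbarrier.hopping`) — Boltzmann
  inversion of fixed-trap-separation hopping data:
  `E(N) = −kBT ln P(N)` minus the tether-stretching and trap-bead
  energies, differenced per bp, stitched across trap separations, and
  subtracted bare-vs-nucleosome to yield the DNA–octamer interaction
  profile; equilibrium pulling-curve prediction.
- **Transcription pipeline** (`nucbarrier.txn`) — registration of Pol II
  trajectories against the 8 × 64 bp "molecular ruler" (one
  sequence-encoded pause per repeat; ~21 nm periodicity at 10 pN),
  median dwell-time ("transcriptional") maps, crossing/arrest
  statistics, pause-free velocities, backtrack detection and 2/3-state
  hidden-Markov fits of hopping segments.
- **Ratchet model** (`nucbarrier.ratchet`) — the mechanical model of
  Pol II crossing the nucleosome: a 2-D energy landscape
  `E(j, w) = E_L(w − j) + Σ_{i≤w} φ_i` over polymerase position j and
  base pairs unwrapped w (linker bending energy + per-bp unwrapping cost
  φ), Boltzmann-weighted effective stepping rates, analytic mean
  first-passage dwell times with a bounded 3-bp backtracking pathway,
  exact stochastic simulation, and the inverse problem — fitting φ to an
  observed dwell-time profile by bounded least squares.
- **Synthetic data** (`nucbarrier.synth`) — kinetic Monte-Carlo
  generators for constant-velocity/constant-force unzipping traces,
  equilibrium hopping traces, and ratchet-model transcription
  trajectories, with trap-coupled measurement noise; every analysis
  stage is covered by a generator→analysis closure test.

## Worked example

Generate two synthetic unzipping traces of a WT-like nucleosome and
build the aggregated topography map:

```sh
$ nucbarrier synth unzip --seed 1 --out traces/t0.tsv
[synth] wrote traces/t0.tsv (26704 samples, constant_velocity)
$ nucbarrier synth unzip --seed 2 --out traces/t1.tsv
$ nucbarrier unzip-map --traces traces --out map.tsv
[unzip-map] wrote map.tsv (2 traces)
```

The map's largest force-weighted residence values sit at the proximal
dimer barrier a few bp inside the NPS — the fork dwells at the base of
the first strong histone–DNA contact region:

```
top force-weighted residence bins (bp into the NPS, pN s):
    12.5    22.67
    13.5    29.39
    14.5    31.28
    15.5    27.53
```

On the model side, the mean dwell-time profile of Pol II for a uniform
1 kBT/bp interaction profile:

```python
>>> import numpy as np
>>> from nucbarrier import InteractionProfile, mean_dwell_profile
>>> pos, dwell = mean_dwell_profile(InteractionProfile(np.ones(147)), j_start=-5)
position (bp)  mean dwell (s)
        -2      0.040     # before the NPS: bare (k0^0)^-1
         0      0.194     # barrier builds as the linker shortens
        47      0.633     # steady-state crossing dwell
total predicted crossing time: 90.5 s
```

Positions before the NPS dwell at the bare inverse stepping rate
(0.04 s); inside the NPS, the cost of unwrapping DNA ahead of the
enzyme slows each step roughly 16-fold for this uniform profile.

## Layout

```
src/nucbarrier/
  polymer.py   elasticity and tether conversion      unzip.py    topography maps
  hopping.py   Boltzmann inversion                   txn.py      transcription pipeline
  ratchet.py   Pol II mechanical model               synth.py    data generators
  io.py        TSV formats, config, pipeline         cli.py      command line
  _sim.py      numba stochastic-simulation kernels
  data/        template sequences (FASTA)
docs/methods.md   model assumptions, parameters, numerical choices
```
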