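# Methods

This note documents the models implemented in `nucbarrier`, the
assumptions behind them, the parameters that matter, and the numerical
and design choices made where more than one reasonable option existed.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Polymer mechanics of the unzipping tether

The tether is a composite of double-stranded handles and the
single-stranded DNA released by the unzipping fork.

- **dsDNA** — extensible worm-like chain. The Marko–Siggia
  interpolation augmented with an enthalpic term is solved for the
  fractional extension `z` at given force by bracketed bisection
  (64 iterations, far below the 1e-10 tolerance target):
  `F Lp/kBT = 1/4(1−u)^−2 − 1/4 + u`, `z = u + F/K`. The high-force
  expansion `z ≈ 1 − (kBT/4FLp)^{1/2} + F/K` is used only as a
  cross-check in tests. Defaults: persistence length 35.4 nm, stretch
  modulus 1020 pN, rise 0.34 nm/bp.
- **ssDNA** — extensible freely jointed chain,
  `z = [coth(Fb/kBT) − kBT/Fb](1 + F/K)`, with the series expansion
  `z → Fb/3kBT` below `Fb/kBT = 1e-8` to avoid cancellation.
  Two parameter conventions are exposed as named presets and both are
  first-class: `"fitted"` (Kuhn 1.45 nm, modulus 975 pN) for the
  extension→bp conversion of pulling traces, `"hopping"` (segment
  1.03 nm, modulus 1000 pN) for equilibrium landscape work. The handle
  length likewise appears as 1850 bp (pulling conversion) or 1848 bp
  (hopping analysis); both are plain constructor arguments.
- `kBT = 4.11 pN nm` throughout; energies are kept in kBT internally
  and converted only at interfaces.

The per-bp unzipping work at force F is the work done by the pulling
force carrying the two freshly released bases to their equilibrium
extension minus the FJC elastic energy stored in them; the elastic
integral uses adaptive quadrature of the numerically inverted FJC
relation, and an integration-by-parts identity
(`ΔE = ∫_0^F x_ss dF'`) is asserted in tests to 1e-6 relative.

Extensions below the handles-only curve (possible under noise) convert
to N = 0 with a warning flag rather than raising.

`fit_tether_params` (lmfit Levenberg–Marquardt behind the module
surface) fits the ssDNA Kuhn length, ssDNA modulus and an extension
offset absorbing bead-size variation, with dsDNA constants held fixed;
it refuses curves spanning under 10 pN of force, where the Kuhn length
and modulus are not jointly identifiable.

## Topography maps and trace registration

Pulling traces are converted sample-by-sample to unzipped bp and
normalized to the start of the second NPS copy (bp 249 of the stem;
subtract 248). Force-weighted residence maps sum per-sample forces in
half-open position bins and divide by the sampling rate, giving
rate-independent pN·s; time maps count samples over the rate. Default
binning is 0.5 bp for alignment, 1 bp for presentation maps.

Registration exploits the template redundancy: identical positions on
the two tandem NPS copies must sit 197 bp apart. Traces are stretched
by `N' = 436 − (197/f)(436 − N)` over a factor grid (default 170–197,
step 0.25) and the factor maximizing the raw product correlation
`Σ Res(i)·Res(i+197)` between the two copies' 0.5-bp histograms is
selected (for nucleosomal traces, the first copy is correlated against
a bare-DNA template map instead). Raw products, not normalized
correlations, are used — the statistic weights strong features most.

Rip counting is automatic local-maxima detection (threshold supplied
per dataset, minimum separation default 3 bp); the choice of threshold
is deliberately exposed because barrier amplitudes differ strongly
between histone compositions.

One bookkeeping wrinkle is kept verbatim rather than resolved: the
alignment anchor is 436 bp while the unzippable duplex is 434 bp plus a
4-base loop (872 ss bases on full unzip). The two constants disagree by
2 bp; each is used exactly where the respective procedure specifies it.

## Boltzmann inversion of hopping data

At a fixed trap separation D the fork's state N is Boltzmann-distributed
in the total energy: unzipping free energy + tether stretch energy +
trap bead energy. The inversion takes `−ln P(N)`, subtracts the two
mechanical terms, and differences consecutive N.

- The force assigned to each integer N is solved from mechanical
  equilibrium (`x_tether(F; N) + F/k_series = D`) rather than read from
  the noisy per-sample force — deterministic and smooth.
- The two traps act in series; the bead term is `F²/2k_series` with
  `k_series` half the per-trap stiffness (default 0.3 pN/nm per trap).
  The per-trap-displacement alternative differs only by an N-independent
  constant at fixed separation and so cancels in the differencing.
- States with occupancy below `min_prob` (default 0 in the API; the
  closure tests use 1e-3, i.e. ≳100 counts at 10^5 samples) are masked,
  never interpolated: below that, counting noise on `ln P` dominates
  the per-bp signal.
- Overlapping separations are averaged unweighted, as a plain mean per
  bp (inverse-variance weighting is available but off by default);
  gaps are flagged as missing (NaN, support 0), never zero.
- Interaction profiles are bare-subtracted per bp on shared support
  only.

The predicted equilibrium pulling curve Boltzmann-averages force and
extension over N with the same total energy; it refuses separations
whose thermal ensemble runs off the landscape's support (edge weight
above 5%).

## The Pol II ratchet model

State: polymerase leading edge j (bp from the NPS start) and base pairs
unwrapped w ≥ j. Energy:

```
E(j, w) = E_L(w − j) + Σ_{i=1..w} φ_i        (kBT)
```

`φ_i ≥ 0` is the net cost of unwrapping bp i from the octamer. The
equivalent bookkeeping that sums the (negative) binding energies of the
still-wrapped base pairs differs from this form only by a constant at
fixed j and yields identical Boltzmann weights; the unwrapping-cost
convention keeps φ positive and matches the fit bounds (0–15 kBT).
The fully unwrapped state w = 147 carries no linker term: the octamer
has released the DNA and no longer constrains the chain ahead. Without
that exemption the final two positions would be unpassable, an artifact
of extending the linker geometry past the point where the model's own
assumptions (equilibrated wrapping of an attached nucleosome) end; the
terminal 10 bp are excluded from fitting for the same reason.

**Linker energy.** `E_L(n)` is the minimized bending energy of a
discrete worm-like chain of n segments (0.34 nm each, bending stiffness
from the 35.4 nm persistence length), clamped tangentially at the point
where the wrapped DNA leaves the superhelix (contact radius from the
canonical superhelix radius 4.18 nm and pitch 2.39 nm), in a planar
geometry. The polymerase threads the DNA, so its steric center lies
one enzyme radius (7 nm) behind the leading edge along the chain
direction; overlap between the polymerase and octamer (3.2 nm) spheres
is penalized by a stiff harmonic (8 kBT/nm², a numerically convenient
stand-in for hard-core exclusion). Optimization is deterministic:
L-BFGS with analytic gradients from five fixed arc-shaped starts; the
resulting table is cleaned by a running minimum (monotone
non-increasing by construction) and cached per geometry.

Two design points deserve emphasis. First, the geometry is planar
rather than a full 3-D spiral: the out-of-plane freedom only lowers
energies marginally, and the linker-energy table is the exchange format
— any alternative geometry can be swapped in without touching the
kinetics. Second, the threading placement of the steric center is what
makes short linkers (a few bp) geometrically possible at finite energy;
with the center at the chain end, the landscape minimum under a uniform
1 kBT/bp profile pins near 61–65 bp unwrapped for any steric stiffness,
irreconcilable with the model's calibration point (minimum at ~52 bp
unwrapped for a polymerase at bp 47), which the defaults reproduce at
51. A consequence of this geometry is that linker energies decay to
zero within ~7 bp — a shorter steric horizon than the ~30 bp sometimes
quoted for chain-end geometries; the non-local dwell→φ peak shift of a
few bp follows from this horizon.

**Kinetics.** Zero-force constants: main-pathway k0 = 25 1/s (the
harmonic combination of the 88 and 35 1/s sequential transitions at
saturating NTP), backtrack entry (35/66)·6.9 1/s (the bare backstep
rate weighted by the occupancy of the backtrack-eligible state),
backtrack diffusion 1.3 1/s each way, maximum depth 3 bp. Force tilts
rates by `exp(±δ ℓ f/kBT)` with δ0 = 0.64 (main pathway) and
δfb = 0.5 (backtracked); the backtracked forward step uses δfb, the
convention of the effective-rate equations (a flag selects δ0
instead). Assuming wrapping equilibrates much faster than stepping,
each bare rate is Boltzmann-averaged over w:

```
k_eff(j) = k_bare(f) · Σ_w e^{−E(j,w)} e^{−δ ΔE(j,w)} / Σ_w e^{−E(j,w)}
```

computed entirely in log-space (logsumexp), so flat landscapes reduce
to the bare laws at machine precision and no configuration can
overflow. Backtracked states at depth q use the effective rates of the
physical position j − q (the alternative — all rates at j — is not
implemented as it double-counts the landscape at the entry position).

**Dwell times.** The dwell at position j is the mean first-passage time
from the on-pathway state at j to j+1: a 4-state (q = 0..3) linear
system per position. Positions before the NPS are reported at the
conventional `(k0^0)^-1 = 0.04 s`; the stochastic simulator propagates
the actual force-dependent bare kinetics there, so analytic/simulated
comparisons are made for j ≥ 0. The Gillespie simulator is exact on
the same state graph; because main-pathway positions are entered only
through q = 0, per-position passage times are independent and ensemble
means converge to the analytic profile — the module's primary oracle.

**Inverse fit.** φ is fitted to a dwell profile (smoothed by a 3-bp
local average) by trust-region-reflective least squares, bounds
0–15 kBT, uniform 1 kBT initialization, no regularization. The dwell
at j depends on φ only within the backtrack span behind and the steric
horizon ahead, so the Jacobian is banded; declaring that band lets the
solver build it by grouped finite differences, cutting the fit to
seconds. Identifiability is reported as Jacobian column norms — the
terminal φ values (never ahead of a fitted position) are structurally
unconstrained, and the bounded fit leaves them at their initialization.

## The molecular ruler and trace registration

The registration problem is to convert nm of transcribed contour into
template bp. The ruler contributes eight pauses spaced exactly 64 bp;
at 10 pN the model converts bp to nm with the dsDNA fractional
extension (one repeat ≈ 20.8 nm; the acceptance benchmark compares
this against the reported 21.1 ± 0.3 nm at its reported 0.1-nm
precision).

Detection proceeds in three stages, all operating on the residence
sample positions of the ruler region (window anchored at the
trajectory start, hence translation invariant):

1. **Fold scan** — candidate periods 19–23 nm (0.01 steps); the
   residence profile folded modulo the period concentrates the pauses
   into one phase bin; the peak-to-median ratio of the folded histogram
   scores each candidate and defines the registration quality (failure
   below 4, e.g. featureless drift).
2. **Comb refinement** — the top distinct candidates are refined by
   direct Nelder–Mead maximization of the comb score, the
   kernel-weighted log-residence summed over the eight predicted pause
   positions, with the kernel width annealed 1.0 → 0.15 nm. The log
   damps any single dominant dwell so threading all repeats beats
   parking one tooth on a large unrelated pause (backtrack pauses of
   comparable duration occur anywhere).
3. **Trimmed tooth regression** — each tooth is replaced by the modal
   residence position near its prediction; weak or outlying teeth are
   dropped and a weighted line fit gives the final period and phase,
   accepted only if it threads at least as many teeth as the comb
   optimum.

A single trace occasionally lacks enough pause residence to pin the
period (a repeat may simply not pause). `register_ensemble` therefore
registers trace sets the way the experiment does: the ensemble median
period is imposed on every trace and only the phase is refit per trace.
Under the default synthetic conditions this keeps the registration
error within the 3-bp accuracy budget everywhere on the NPS.

Conversions: 64 bp per detected period; pause sites anchored to bp 59
of each repeat; the absolute repeat index assumes the trace starts
within half a repeat of the ruler start. The leading edge adds the
16-bp polymerase footprint ("Pol II progress", the center + 17 bp
convention, sits one bp ahead of the leading edge and is exposed as a
named constant).

Crossing statistics follow the stated rules: crossing time is the
leading-edge traversal of the 147 bp; only traces reaching the stall
site count; a terminal motionless (±3 bp) segment of ≥ 300 s inside the
NPS is an arrest, split at the dyad (bp 73). Pause-free velocity
inverts the mean of the three fastest per-bp median residence times in
a region. Backtrack detection (thresholds declared, not inferred from
any source: depth ≥ 2 bp below the running maximum, duration ≥ 1 s) and
the 2/3-state Gaussian HMM (hmmlearn EM; states relabeled by ascending
mean, degenerate fits flagged when means are closer than 0.5 bp)
complete the per-trace statistics. HMM emissions are positions;
per-second rates are per-sample transition probabilities times the
sampling rate, adequate for rates well below the sampling rate.

## Synthetic data

The generators exist so that every analysis stage has a
generator→analysis closure test; they emulate the statistical structure
of the real assays, not the instrument.

- **Landscapes** — flat duplex baseline 2.5 kBT/bp (consistent with
  bare-DNA unzipping in the 17–20 pN range; the generator's equilibrium
  plateau under the default trap is ~17 pN) plus Gaussian interaction
  bumps. The WT-like fixture places bumps at the canonical topography
  peak positions (17…122 bp into the NPS) with a default 2.5-bp width —
  measured interaction features span a few bp.
- **Fork kinetic Monte Carlo** — continuous-time walk over N with
  Metropolis rates `a·min(1, e^{−ΔA})` on the total energy (landscape +
  stretch + trap), which satisfy detailed balance, so equilibrium
  occupancies are exact regardless of the attempt frequency a (default
  1e6 1/s; a is not an observable and only sets the time scale).
  Constant-velocity protocols interpolate the energy tables on a
  0.25-nm separation grid and refresh rates at least once per sample
  interval. The tether mechanics are precomputed on a force grid once
  and combined per N (the composite tether is linear in base counts).
- **Noise** — extension sd 0.5 nm. In trap-coupled protocols the force
  record co-varies rigidly with the extension record through the series
  trap stiffness (both derive from the same bead signal), plus a
  0.05 pN independent detector residual; the force-clamp protocol gets
  independent 0.2 pN force jitter. Modeling the two channels as
  independent white noise would inflate the per-sample bp uncertainty
  to ~1.3 bp and make the single-bp state resolution of the equilibrium
  analysis impossible — inconsistent with the assays being emulated.
- **Transcription traces** — the ratchet simulator with the ruler
  prepended: bare kinetics upstream, the main-pathway rate divided by
  100 at each repeat's pause site (pauses of a couple of seconds,
  dominant over spontaneous backtrack pauses, as in the assay the ruler
  was designed for), positions converted at the dsDNA extension per bp
  and sampled at 800 Hz with 0.5 nm position noise.

What the generators do *not* emulate: instrument drift, 1/f noise, bead
rotation, photobleaching-adjacent artifacts, sequence-dependent pausing
outside the ruler, histone eviction/hexasome intermediates, and any
trans-acting factors. Closure tests passing on this synthetic data
therefore validate the analysis logic and its statistical calibration,
not robustness to those real-data pathologies.

## Problem sizes of the shipped checks

The test suite and acceptance script run: tether fits on 120–150-point
noise-free curves; topography closures with 3–4 constant-velocity
traces; Boltzmann-inversion closures with 10^5 samples per separation
at 5–6 separations (recovery RMS target 0.25 kBT/bp); dwell-time
equivalence with 10^4 stochastic crossings per φ fixture (3-SE band
with a family-level multiplicity correction); the φ fit round trip on
a three-peak fixture (< 2% dwell RMS); and ruler registration on
5-trace ensembles (≤ 3 bp everywhere on the NPS). These sizes are the
package's reference conditions; all scale up linearly if larger runs
are wanted.

## Known limitations

- The linker geometry is a deliberate minimal model; absolute linker
  energies (and hence the exact steric horizon) depend on the planar
  simplification, the contact-point convention and the steric
  stiffness. The calibration point above is the constraint they are
  set by; swapping in a different geometry only requires a replacement
  linker-energy table.
- Boltzmann inversion assumes equilibrated hopping; it is not valid for
  the irreversible transitions deeper in the nucleosome, and no
  deconvolution of bead/linker fluctuations from P(N) is attempted.
- The HMM rate estimates use per-sample transition probabilities and
  degrade as rates approach the sampling rate.
- Single-trace ruler registration can fail or err beyond 3 bp when a
  trace happens to pause weakly; ensemble registration is the supported
  path to the stated accuracy.
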