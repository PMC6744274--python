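"""Synthetic single-molecule data with the statistical structure the
analysis pipeline assumes.

Three generators emulate the three experimental protocols:

* `gen_unzip_trace` — kinetic Monte-Carlo motion of the unzipping fork on
  a per-bp energy landscape coupled to the tether + trap mechanics, for
  constant-velocity (20 nm/s) and constant-force (28 pN) protocols,
  sampled at 800 Hz;
* `gen_hopping_trace` — the same fork at a fixed trap separation
  (equilibrium hopping), sampled at 2.5 kHz;
* `gen_txn_trace` — a Pol II ratchet-model trajectory preceded by the
  8 x 64 bp molecular-ruler region with its sequence-encoded pause sites,
  at 10 pN assisting force, sampled at 800 Hz.

Fork transitions use Metropolis rates ``attempt * min(1, exp(-dA))`` on
the total energy, which obey detailed balance, so equilibrium occupancies
are exact regardless of the attempt frequency (a non-observable; only the
time scale depends on it).  All generators are bit-reproducible for a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError
from .hopping import EnergyLandscape, TrapModel
from .polymer import (PolymerParams, TetherComposition, fractional_extension,
                      unzip_energy_increment)
from .ratchet import (InteractionProfile, NucleosomeGeometry, PolIIKinetics,
                      _sim_rate_tables)
from .trace import Trace, TxnTrace
from .txn import RulerSpec

__all__ = [
    "LandscapeSpec",
    "NoiseSpec",
    "gen_landscape",
    "wt_interaction_peaks",
    "gen_unzip_trace",
    "gen_hopping_trace",
    "gen_txn_trace",
]

#: typical per-bp duplex unzipping energy; consistent with bare DNA
#: unzipping in the 17-20 pN force range
DEFAULT_BASELINE_KBT = 2.5
DEFAULT_ATTEMPT_RATE = 1e6  # 1/s


@dataclass(frozen=True)
class NoiseSpec:
    """Additive white measurement noise (standard deviations).

    In trap-coupled protocols (fixed separation, constant velocity) the
    force and extension records derive from the same bead-position
    signal, so their fluctuations are rigidly anticorrelated through the
    trap stiffness: a bead excursion ``dx`` appears as ``+dx`` on the
    extension and ``-k_series dx`` on the force.  The generators honor
    that constraint — it is what gives the assay its single-bp
    resolution — and add only a small independent force-detector
    residual.  ``force_sd_pn`` is the independent force jitter of the
    force-clamp (constant-force) protocol.
    """

    extension_sd_nm: float = 0.5
    force_sd_pn: float = 0.2
    force_residual_sd_pn: float = 0.05
    position_sd_nm: float = 0.5

    def __post_init__(self) -> None:
        if min(self.extension_sd_nm, self.force_sd_pn,
               self.force_residual_sd_pn, self.position_sd_nm) < 0:
            raise ValidationError("noise standard deviations must be >= 0")


@dataclass
class LandscapeSpec:
    """Constructor for a synthetic per-bp unzipping landscape.

    ``peaks`` are (position_bp, height_kBT, width_bp) Gaussian bumps on a
    flat duplex baseline; positions are in unzipped-bp template
    coordinates (the second NPS starts at bp 249).
    """

    length_bp: int = 434
    baseline_kbt: float = DEFAULT_BASELINE_KBT
    peaks: list = field(default_factory=list)


def wt_interaction_peaks(height_kbt: float = 3.0,
                         width_bp: float = 2.5) -> list:
    """Interaction-peak template mimicking a WT nucleosome topography map.

    Peak positions (bp into the NPS) follow the canonical unzipping map of
    a WT nucleosome; heights are a uniform default unless overridden.
    Positions are relative to the second NPS start; add 248 for template
    coordinates.
    """
    positions = [17, 22, 26, 31, 35, 41, 52, 61, 69, 109, 112, 122]
    return [(p, height_kbt, width_bp) for p in positions]


def gen_landscape(spec: LandscapeSpec) -> EnergyLandscape:
    """Deterministic per-bp landscape: baseline plus Gaussian bumps."""
    n = np.arange(1, spec.length_bp + 1)
    e = np.full(spec.length_bp, float(spec.baseline_kbt))
    for pos, height, width in spec.peaks:
        e += height * np.exp(-0.5 * ((n - pos) / width) ** 2)
    return EnergyLandscape(positions=n, per_bp_energy=e,
                           provenance="bare" if not spec.peaks else "nucleosome")


# ----------------------------------------------------------------------
# tether mechanics tables (vectorized over force once, shared across N)

def _mech_tables(comp: TetherComposition, params: PolymerParams,
                 trap: TrapModel, n_max: int,
                 f_max: float = 60.0, n_f: int = 1200):
    """Force-parametrized separation/energy relations for N = 0..n_max.

    The composite tether is linear in the base counts, so the dsDNA and
    ssDNA contributions are computed once on a force grid and combined per
    N: ``x(F, N) = x_handles(F) + 2 N z_ss(F) l_ss``.  Returns the force
    grid and callables evaluated by interpolation.
    """
    f = np.linspace(1e-6, f_max, n_f)
    z_ds = fractional_extension(f, "ds", params)
    z_ss = fractional_extension(f, "ss", params)
    x_handle = z_ds * comp.n_ds_bp * params.ds_rise + params.extension_offset
    x_per_bp = 2.0 * z_ss * params.ss_rise
    # work integrals int_0^F x dF' by cumulative trapezoid
    w_handle = np.concatenate([[0.0], np.cumsum(
        0.5 * (x_handle[1:] + x_handle[:-1]) * np.diff(f))])
    w_per_bp = np.concatenate([[0.0], np.cumsum(
        0.5 * (x_per_bp[1:] + x_per_bp[:-1]) * np.diff(f))])
    return f, x_handle, x_per_bp, w_handle, w_per_bp


def _total_energy_table(landscape: EnergyLandscape, d_grid: np.ndarray,
                        comp: TetherComposition, params: PolymerParams,
                        trap: TrapModel, tilt_per_bp: float = 0.0):
    """A(N, D) in kBT for all integer N and a separation grid.

    Total energy = cumulative landscape + tether stretch energy + trap
    bead energy, each evaluated at the force balancing N at separation D.
    Also returns the matching force table F(N, D).
    """
    n_max = int(landscape.positions.max())
    f, x_handle, x_per_bp, w_handle, w_per_bp = _mech_tables(
        comp, params, trap, n_max)
    ks = trap.series_stiffness
    cum = landscape.cumulative_at(np.arange(n_max + 1))
    a = np.empty((n_max + 1, len(d_grid)))
    force = np.empty_like(a)
    for n in range(n_max + 1):
        x = x_handle + n * x_per_bp
        w = w_handle + n * w_per_bp
        d_of_f = x + f / ks
        e_mech = (f * x - w + f * f / (2.0 * ks)) / params.kBT
        f_n = np.interp(d_grid, d_of_f, f)
        a[n] = cum[n] + np.interp(d_grid, d_of_f, e_mech) - tilt_per_bp * n
        force[n] = f_n
    return a, force


def _rng_seed(seed: int) -> int:
    return int(seed) & 0x7FFFFFFF


def gen_hopping_trace(landscape: EnergyLandscape, trap_separation: float,
                      comp: TetherComposition | None = None,
                      params: PolymerParams | None = None,
                      trap: TrapModel | None = None,
                      attempt_rate: float = DEFAULT_ATTEMPT_RATE,
                      duration: float = 40.0,
                      sample_rate: float = 2500.0,
                      noise: NoiseSpec | None = None,
                      seed: int = 0) -> Trace:
    """Equilibrium hopping trace of the fork at a fixed trap separation.

    A continuous-time Markov chain over N with detailed-balance
    (Metropolis) rates on the total energy; the emitted record carries the
    deterministic force/extension of each sampled N plus white noise.
    """
    from ._sim import fork_ssa

    comp = comp or TetherComposition(n_ds_bp=1848)
    params = params or PolymerParams.preset("hopping")
    trap = trap or TrapModel()
    noise = noise or NoiseSpec()
    d_grid = np.array([trap_separation])
    a, force = _total_energy_table(landscape, d_grid, comp, params, trap)
    n_init = int(np.argmin(a[:, 0]))
    n_samples = int(round(duration * sample_rate))
    samples = fork_ssa(a, a.shape[0] - 1, trap_separation, 0.0,
                       trap_separation, 1.0, duration, sample_rate,
                       n_samples, attempt_rate, n_init, _rng_seed(seed))
    rng = np.random.default_rng(_rng_seed(seed) + 1)
    f_s = force[samples, 0]
    x_s = trap_separation - f_s / trap.series_stiffness
    t = np.arange(n_samples) / sample_rate
    dx = rng.normal(0.0, noise.extension_sd_nm, n_samples)
    df = (-trap.series_stiffness * dx
          + rng.normal(0.0, noise.force_residual_sd_pn, n_samples))
    return Trace(
        time=t,
        force=f_s + df,
        extension=x_s + dx,
        sample_rate=sample_rate, protocol="fixed_separation",
        metadata={"separation_nm": float(trap_separation),
                  "seed": int(seed), "true_n_init": n_init},
    )


def gen_unzip_trace(landscape: EnergyLandscape,
                    protocol: str = "constant_velocity",
                    comp: TetherComposition | None = None,
                    params: PolymerParams | None = None,
                    trap: TrapModel | None = None,
                    speed_nm_s: float = 20.0,
                    hold_force_pn: float = 28.0,
                    d_start: float | None = None,
                    d_end: float | None = None,
                    duration: float | None = None,
                    attempt_rate: float = DEFAULT_ATTEMPT_RATE,
                    sample_rate: float = 800.0,
                    noise: NoiseSpec | None = None,
                    seed: int = 0) -> Trace:
    """Unzipping trace: fork kMC on the landscape + tether/trap mechanics.

    ``constant_velocity`` moves the traps apart at ``speed_nm_s`` from a
    separation where the intact construct carries ~10 pN up to full unzip
    (rates refresh every sample interval); ``constant_force`` tilts the
    landscape by the per-bp mechanical energy gain at the hold force.
    """
    from ._sim import fork_ssa

    comp = comp or TetherComposition(n_ds_bp=1850)
    params = params or PolymerParams.preset("hopping")
    trap = trap or TrapModel()
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(_rng_seed(seed) + 1)
    n_max = int(landscape.positions.max())

    if protocol == "constant_velocity":
        f_grid, x_handle, x_per_bp, _, _ = _mech_tables(comp, params, trap, n_max)
        ks = trap.series_stiffness
        if d_start is None:
            d_start = float(np.interp(10.0, f_grid, x_handle + f_grid / ks))
        if d_end is None:
            d_end = float(np.interp(
                35.0, f_grid, x_handle + n_max * x_per_bp + f_grid / ks))
        if duration is None:
            duration = (d_end - d_start) / speed_nm_s
        d_grid = np.arange(d_start - 1.0, d_end + speed_nm_s * duration
                           - (d_end - d_start) + 2.0, 0.25)
        a, force = _total_energy_table(landscape, d_grid, comp, params, trap)
        n_samples = int(round(duration * sample_rate))
        samples = fork_ssa(a, n_max, d_start, speed_nm_s, float(d_grid[0]),
                           0.25, duration, sample_rate, n_samples,
                           attempt_rate, 0, _rng_seed(seed))
        t = np.arange(n_samples) / sample_rate
        d_t = d_start + speed_nm_s * t
        # per-sample force: interpolate the force table at (N_sample, D(t))
        idx = np.clip(((d_t - d_grid[0]) / 0.25), 0, len(d_grid) - 2)
        i0 = idx.astype(int)
        frac = idx - i0
        f_s = (force[samples, i0] * (1 - frac) + force[samples, i0 + 1] * frac)
        x_s = d_t - f_s / trap.series_stiffness
        dx = rng.normal(0.0, noise.extension_sd_nm, n_samples)
        f_s = f_s - trap.series_stiffness * dx + rng.normal(
            0.0, noise.force_residual_sd_pn, n_samples)
        x_s = x_s + dx
    elif protocol == "constant_force":
        de = unzip_energy_increment(hold_force_pn, params)
        d_grid = np.array([0.0])
        cum = landscape.cumulative_at(np.arange(n_max + 1))
        a = (cum - de * np.arange(n_max + 1))[:, None]
        if duration is None:
            duration = 10.0
        n_samples = int(round(duration * sample_rate))
        samples = fork_ssa(a, n_max, 0.0, 0.0, 0.0, 1.0, duration,
                           sample_rate, n_samples, attempt_rate, 0,
                           _rng_seed(seed))
        t = np.arange(n_samples) / sample_rate
        z_ds = fractional_extension(hold_force_pn, "ds", params)
        z_ss = fractional_extension(hold_force_pn, "ss", params)
        x_s = (z_ds * comp.n_ds_bp * params.ds_rise
               + z_ss * 2.0 * samples * params.ss_rise
               + params.extension_offset
               + rng.normal(0.0, noise.extension_sd_nm, n_samples))
        # force clamp: independent feedback jitter
        f_s = hold_force_pn + rng.normal(0.0, noise.force_sd_pn, n_samples)
    else:
        raise ValidationError(f"unknown unzip protocol {protocol!r}")

    return Trace(
        time=t,
        force=f_s,
        extension=x_s,
        sample_rate=sample_rate, protocol=protocol,
        metadata={"seed": int(seed), "protocol": protocol,
                  "true_n_final": int(samples[-1])},
    )


def gen_txn_trace(phi: InteractionProfile,
                  kin: PolIIKinetics | None = None,
                  geom: NucleosomeGeometry | None = None,
                  force: float = 10.0,
                  ruler: RulerSpec | None = None,
                  ruler_pause_strength: float = 100.0,
                  params: PolymerParams | None = None,
                  noise: NoiseSpec | None = None,
                  sample_rate: float = 800.0,
                  t_max: float = 2000.0,
                  post_nps_bp: int = 30,
                  seed: int = 0) -> TxnTrace:
    """Pol II transcription trajectory through ruler + nucleosome.

    The trajectory starts upstream of the molecular ruler, pauses at the
    sequence-encoded site of each 64-bp repeat (main-pathway rate divided
    by ``ruler_pause_strength`` there), crosses the NPS governed by the
    ratchet-model effective rates for ``phi``, and ends ``post_nps_bp``
    past the NPS (the stall site).  Template bp are converted to nm with
    the dsDNA extension per bp at the assisting force; white position
    noise is added and the record is sampled at 800 Hz.
    """
    from ._sim import polii_ssa

    kin = kin or PolIIKinetics()
    geom = geom or NucleosomeGeometry()
    ruler = ruler or RulerSpec()
    params = params or PolymerParams()
    noise = noise or NoiseSpec()
    j_start = ruler.template_start_bp() - 5
    j_end = geom.n_tot + post_nps_bp
    grid, k0, kb1, kf, kb = _sim_rate_tables(phi, kin, geom, force,
                                             j_start, j_end)
    # sequence-encoded ruler pauses: slow the main-pathway rate at the
    # pause site of each repeat
    for r in range(ruler.n_repeats):
        site = ruler.template_start_bp() + r * ruler.repeat_bp + ruler.pause_site_bp - 1
        k0[site - grid[0]] /= ruler_pause_strength
    n_samples = int(round(t_max * sample_rate))
    arrivals, samples, _, crossed = polii_ssa(
        k0, kb1, kf, kb, int(grid[0]), int(j_start), int(j_end),
        kin.max_backtrack, float(t_max), float(sample_rate), n_samples,
        _rng_seed(seed))
    # trim the hold after reaching the stall site to a short plateau
    if crossed:
        t_cross = arrivals[-1]
        keep = min(n_samples, int((t_cross + 20.0) * sample_rate))
    else:
        keep = n_samples
    rng = np.random.default_rng(_rng_seed(seed) + 1)
    nm_per_bp = float(fractional_extension(force, "ds", params) * params.ds_rise)
    t = np.arange(keep) / sample_rate
    pos_nm = (samples[:keep] - j_start) * nm_per_bp
    pos_nm = pos_nm + rng.normal(0.0, noise.position_sd_nm, keep)
    return TxnTrace(
        time=t, position=pos_nm, force=force, sample_rate=sample_rate,
        metadata={"seed": int(seed), "j_start": int(j_start),
                  "nm_per_bp": nm_per_bp, "crossed": bool(crossed),
                  "arrival_times": arrivals},
    )
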