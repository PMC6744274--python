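"""Equilibrium energy landscapes from fixed-trap-separation hopping data.

At a fixed trap separation the unzipping fork fluctuates among a handful of
discrete states (numbers of unzipped base pairs N).  If those fluctuations
are equilibrated, the occupancy P(N) is Boltzmann distributed in the *total*
energy of the system — the DNA unzipping free energy plus the elastic
energy of stretching the tether plus the energy of displacing the beads in
the traps.  Removing the two mechanical terms and differencing consecutive
base pairs yields the per-bp unzipping energy; overlapping trap separations
are averaged ("stitched") into one landscape, and subtracting the bare-DNA
landscape from a nucleosomal one isolates the DNA–octamer interaction
energy profile.

Energies are in kBT throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .exceptions import DomainError, ValidationError
from .polymer import (PolymerParams, TetherComposition, stretch_energy,
                      tether_extension)
from .trace import Trace
from .unzip import SECOND_NPS_OFFSET_BP

__all__ = [
    "TrapModel",
    "EnergyLandscape",
    "UnzipDistribution",
    "force_at_separation",
    "mechanical_energy",
    "unzip_distribution",
    "landscape_segment",
    "stitch_segments",
    "interaction_profile",
    "align_landscape_shift",
    "equilibrium_pulling_curve",
]


@dataclass(frozen=True)
class TrapModel:
    """Two-trap compliance; bead displacement energy enters as 1/2 k x^2.

    The two traps act as springs in series with the tether, so their
    series-equivalent stiffness is half the per-trap value.
    """

    stiffness_per_trap: float = 0.3  # pN/nm

    def __post_init__(self) -> None:
        if self.stiffness_per_trap <= 0:
            raise ValidationError("trap stiffness must be > 0")

    @property
    def series_stiffness(self) -> float:
        return 0.5 * self.stiffness_per_trap


@dataclass
class EnergyLandscape:
    """Per-basepair unzipping (or interaction) energies.

    ``positions`` are integer N (count of unzipped duplex bp, template
    coordinates), ``per_bp_energy[i]`` is the energy to unzip bp
    ``positions[i]`` (from N-1 to N) in kBT, ``cumulative_energy`` its
    running sum over the supported range, and ``support_counts`` the number
    of trap separations (or segments) contributing at each bp; zero marks a
    gap, in which case the per-bp value is NaN, never silently zero.
    """

    positions: np.ndarray
    per_bp_energy: np.ndarray
    cumulative_energy: np.ndarray = None
    provenance: str = "bare"  # bare | nucleosome | interaction
    support_counts: np.ndarray = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions)
        self.per_bp_energy = np.asarray(self.per_bp_energy, dtype=float)
        if self.positions.shape != self.per_bp_energy.shape:
            raise ValidationError("positions/per_bp_energy shape mismatch")
        if self.support_counts is None:
            self.support_counts = np.where(np.isfinite(self.per_bp_energy), 1, 0)
        self.support_counts = np.asarray(self.support_counts)
        if self.cumulative_energy is None:
            filled = np.where(np.isfinite(self.per_bp_energy),
                              self.per_bp_energy, 0.0)
            self.cumulative_energy = np.cumsum(filled)
        self.cumulative_energy = np.asarray(self.cumulative_energy, dtype=float)

    def cumulative_at(self, n) -> np.ndarray:
        """Cumulative energy up to and including bp n (0 below support)."""
        n = np.asarray(n)
        idx = np.searchsorted(self.positions, n, side="right") - 1
        out = np.where(idx >= 0, self.cumulative_energy[np.clip(idx, 0, None)], 0.0)
        return out


@dataclass
class UnzipDistribution:
    """Probability mass over integer numbers of unzipped base pairs."""

    n: np.ndarray          # integer unzipped-bp states
    p: np.ndarray          # probabilities, sum to 1
    separation: float = float("nan")  # trap separation, nm
    n_samples: int = 0

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n)
        self.p = np.asarray(self.p, dtype=float)
        if self.n.shape != self.p.shape or len(self.n) == 0:
            raise ValidationError("distribution must be non-empty and consistent")
        if not np.isclose(self.p.sum(), 1.0):
            raise ValidationError("probabilities must sum to 1")


def force_at_separation(n_unzipped: float, separation: float,
                        comp: TetherComposition, params: PolymerParams,
                        trap: TrapModel, f_max: float = 120.0) -> float:
    """Force balancing the tether with N bp unzipped at a trap separation.

    Solves ``x_tether(F; N) + F / k_series = separation`` — deterministic
    and smooth, unlike reading the noisy per-sample force.
    """
    c = comp.with_unzipped(n_unzipped)

    def gap(f):
        return (tether_extension(f, c, params) + f / trap.series_stiffness
                - separation)

    if gap(1e-9) >= 0:
        return 0.0
    if gap(f_max) < 0:
        raise DomainError(
            f"separation {separation} nm not reachable below {f_max} pN")
    return brentq(gap, 1e-9, f_max, xtol=1e-10, rtol=1e-12)


def mechanical_energy(n_unzipped: float, separation: float,
                      comp: TetherComposition, params: PolymerParams,
                      trap: TrapModel) -> float:
    """Stretching + trap energy (kBT) of the state with N bp unzipped.

    Evaluated at the force balancing that N at the given separation; the
    trap term uses the series-equivalent spring, ``F^2 / (2 k_series)``.
    """
    f = force_at_separation(n_unzipped, separation, comp, params, trap)
    e_stretch = stretch_energy(f, comp.with_unzipped(n_unzipped), params)
    e_trap = f * f / (2.0 * trap.series_stiffness) / params.kBT
    return float(e_stretch + e_trap)


def unzip_distribution(trace: Trace, comp: TetherComposition,
                       params: PolymerParams,
                       normalized_positions: bool = False) -> UnzipDistribution:
    """Occupancy histogram over integer unzipped-bp states of a hopping trace.

    Per-sample N from the composite-tether inversion, rounded to the
    nearest integer; the histogram is normalized to unit mass.  Positions
    are template N (not NPS-normalized) unless requested otherwise.
    """
    if len(trace) == 0:
        raise ValidationError("empty hopping trace")
    if trace.protocol != "fixed_separation":
        raise ValidationError("unzip_distribution expects a fixed_separation trace")
    from .polymer import unzipped_bp
    n = unzipped_bp(trace.force, trace.extension, comp, params)
    n_int = np.rint(n).astype(int)
    lo, hi = n_int.min(), n_int.max()
    states = np.arange(lo, hi + 1)
    counts = np.bincount(n_int - lo, minlength=len(states)).astype(float)
    if normalized_positions:
        states = states - SECOND_NPS_OFFSET_BP
    return UnzipDistribution(states, counts / counts.sum(),
                             separation=trace.metadata.get("separation_nm",
                                                           float("nan")),
                             n_samples=len(trace))


def landscape_segment(dist: UnzipDistribution, trap: TrapModel,
                      comp: TetherComposition, params: PolymerParams,
                      separation: float | None = None,
                      min_prob: float = 0.0,
                      provenance: str = "bare") -> EnergyLandscape:
    """Boltzmann inversion of one trap separation's occupancy distribution.

    ``E_rel(N) = -ln P(N)`` (kBT); subtracting the mechanical (stretch +
    trap) energy at each N gives the cumulative unzipping energy up to an
    irrelevant constant, and first differences give per-bp energies.
    Zero-probability interior states are masked (NaN), not interpolated.
    """
    if separation is None:
        separation = dist.separation
    if not np.isfinite(separation):
        raise ValidationError("trap separation required for inversion")
    if (dist.p > min_prob).sum() < 2:
        raise ValidationError("need >= 2 populated states to difference")
    e_rel = np.where(dist.p > min_prob, -np.log(np.maximum(dist.p, 1e-300)),
                     np.nan)
    mech = np.array([mechanical_energy(int(n), separation, comp, params, trap)
                     for n in dist.n])
    cum = e_rel - mech
    per_bp = np.full(len(dist.n) - 1, np.nan)
    valid = np.isfinite(cum)
    for i in range(1, len(dist.n)):
        if valid[i] and valid[i - 1]:
            per_bp[i - 1] = cum[i] - cum[i - 1]
    return EnergyLandscape(positions=dist.n[1:], per_bp_energy=per_bp,
                           provenance=provenance,
                           metadata={"separation_nm": float(separation)})


def stitch_segments(segments, provenance: str | None = None) -> EnergyLandscape:
    """Average overlapping per-bp segments into one landscape.

    The unweighted mean over all trap separations spanning a given bp is
    used; bp covered by no segment are flagged as gaps (NaN, support 0).
    """
    segments = list(segments)
    if not segments:
        raise ValidationError("no segments to stitch")
    lo = min(int(s.positions.min()) for s in segments)
    hi = max(int(s.positions.max()) for s in segments)
    positions = np.arange(lo, hi + 1)
    total = np.zeros(len(positions))
    count = np.zeros(len(positions), dtype=int)
    for seg in segments:
        for n, e in zip(seg.positions, seg.per_bp_energy):
            if np.isfinite(e):
                i = int(n) - lo
                total[i] += e
                count[i] += 1
    per_bp = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return EnergyLandscape(positions=positions, per_bp_energy=per_bp,
                           provenance=provenance or segments[0].provenance,
                           support_counts=count)


def interaction_profile(nucleosome: EnergyLandscape,
                        bare: EnergyLandscape) -> EnergyLandscape:
    """DNA–octamer interaction energy: nucleosome minus bare, on shared support."""
    common = np.intersect1d(nucleosome.positions, bare.positions)
    if len(common) == 0:
        raise ValidationError("landscapes share no supported base pairs")
    i_n = np.searchsorted(nucleosome.positions, common)
    i_b = np.searchsorted(bare.positions, common)
    diff = nucleosome.per_bp_energy[i_n] - bare.per_bp_energy[i_b]
    support = np.where(np.isfinite(diff), 1, 0)
    if support.sum() == 0:
        raise ValidationError("no base pair is supported by both landscapes")
    return EnergyLandscape(positions=common, per_bp_energy=diff,
                           provenance="interaction", support_counts=support)


def align_landscape_shift(landscape: EnergyLandscape,
                          reference: EnergyLandscape,
                          max_shift_bp: int = 10) -> int:
    """Integer-bp shift registering a landscape onto a reference.

    Cross-correlates the per-bp energy features over candidate shifts
    (no x-scaling) and returns the shift that maximizes the overlap
    correlation; apply as ``positions + shift``.
    """
    best_shift, best_score = 0, -np.inf
    ref_pos = reference.positions
    ref_val = np.where(np.isfinite(reference.per_bp_energy),
                       reference.per_bp_energy, 0.0)
    val = np.where(np.isfinite(landscape.per_bp_energy),
                   landscape.per_bp_energy, 0.0)
    for shift in range(-max_shift_bp, max_shift_bp + 1):
        shifted = landscape.positions + shift
        common, i_l, i_r = np.intersect1d(shifted, ref_pos,
                                          return_indices=True)
        if len(common) < 2:
            continue
        score = float(np.dot(val[i_l], ref_val[i_r]))
        if score > best_score:
            best_shift, best_score = shift, score
    return best_shift


def total_state_energy(landscape: EnergyLandscape, n_states: np.ndarray,
                       separation: float, trap: TrapModel,
                       comp: TetherComposition,
                       params: PolymerParams) -> np.ndarray:
    """Total energy (kBT) of each unzipped-bp state at one trap separation."""
    cum = landscape.cumulative_at(n_states)
    mech = np.array([mechanical_energy(int(n), separation, comp, params, trap)
                     for n in n_states])
    return cum + mech


def equilibrium_pulling_curve(landscape: EnergyLandscape, separations,
                              trap: TrapModel, comp: TetherComposition,
                              params: PolymerParams,
                              edge_weight_tol: float = 0.05):
    """Predicted equilibrium (force, extension) curve from a landscape.

    At each trap separation the observables are Boltzmann averages over N
    with total energy = cumulative landscape + stretching + trap terms.
    Raises if the thermally relevant N range runs off the landscape's
    support (the prediction would then depend on unknown energies).
    """
    n_states = landscape.positions[landscape.support_counts > 0]
    if len(n_states) < 2:
        raise ValidationError("landscape support too small for a prediction")
    forces, extensions = [], []
    for sep in np.atleast_1d(np.asarray(separations, dtype=float)):
        a = total_state_energy(landscape, n_states, sep, trap, comp, params)
        w = np.exp(-(a - a.min()))
        w /= w.sum()
        if w[0] > edge_weight_tol or w[-1] > edge_weight_tol:
            missing = (int(n_states[0]) - 1 if w[0] > edge_weight_tol
                       else int(n_states[-1]) + 1)
            raise ValidationError(
                f"landscape does not cover the ensemble at separation {sep} nm: "
                f"significant weight at support edge, need bp {missing}")
        f_n = np.array([force_at_separation(int(n), sep, comp, params, trap)
                        for n in n_states])
        x_n = np.array([tether_extension(f, comp.with_unzipped(int(n)), params)
                        for f, n in zip(f_n, n_states)])
        forces.append(float(np.dot(w, f_n)))
        extensions.append(float(np.dot(w, x_n)))
    return np.asarray(forces), np.asarray(extensions)
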