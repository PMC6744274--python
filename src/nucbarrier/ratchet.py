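"""Mechanical ratchet model of Pol II transcription through the nucleosome.

Pol II cannot actively peel DNA off the histone octamer; it advances by
rectifying spontaneous unwrapping fluctuations of the nucleosomal DNA.
The model tracks two coordinates: the polymerase position ``j`` (leading
edge, bp from the NPS start) and the number of base pairs unwrapped from
the octamer, ``w``.  Their joint energy is

``E_jw = E_L(w - j) + sum_{i<=w} phi_i``

where ``E_L`` is the bending energy of the DNA linker between polymerase
and nucleosome (zero once the linker is long enough for the steric
spheres to clear, steep for short linkers) and ``phi_i >= 0`` is the
cost of unwrapping base pair ``i`` from the octamer.  (The equivalent
formulation sums the negative binding energies of the still-wrapped base
pairs; the two differ by a constant at fixed ``j`` and give identical
Boltzmann weights.)  Unwrapping equilibrates much faster than stepping, so
each bare stepping rate is replaced by its Boltzmann-weighted average over
``w``; backtracking (up to 3 bp, with distinct entry and diffusion rates)
makes the per-position dwell a mean first-passage time of a small birth-
death chain.  The inverse problem — which interaction profile ``phi``
produces an observed dwell-time profile — is solved by bounded nonlinear
least squares.

All energies in kBT, rates in 1/s, positions in bp.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares, minimize
from scipy.special import logsumexp

from .exceptions import ConvergenceError, DomainError, ValidationError

__all__ = [
    "PolIIKinetics",
    "NucleosomeGeometry",
    "InteractionProfile",
    "linker_energy",
    "linker_energy_table",
    "landscape",
    "effective_rates",
    "mean_dwell_profile",
    "simulate_trajectory",
    "simulate_ensemble",
    "fit_interaction_energies",
    "PRE_NPS_DWELL_S",
    "PROGRESS_OFFSET_BP",
]

#: dwell time used for positions before the NPS, (k0^0)^-1
PRE_NPS_DWELL_S = 0.04
#: "Pol II progress" (center + 17 bp) sits 1 bp ahead of the leading edge
#: (leading edge = active site + 16 bp)
PROGRESS_OFFSET_BP = 1

_INF_ENERGY = 1e30


@dataclass(frozen=True)
class PolIIKinetics:
    """Zero-force Pol II stepping constants and force/landscape couplings.

    The main-pathway forward rate ``k0_0`` combines the two sequential
    reversible transitions of the three-state elongation scheme (88 and
    35 1/s) into one irreversible 25 1/s step at saturating NTP.  The
    backtrack-entry rate is the bare 6.9 1/s weighted by the 35/66
    occupancy of the backtrack-eligible state.  Backtracking is bounded at
    3 bp.  ``delta0``/``delta_fb`` locate the transition states of the
    main-pathway and backtrack steps; the force- and landscape-tilts enter
    as ``exp(+/- delta * dE)``.
    """

    k0_0: float = 25.0
    kb1_0: float = (35.0 / 66.0) * 6.9
    kf_0: float = 1.3
    kb_0: float = 1.3
    delta0: float = 0.64
    delta_fb: float = 0.5
    step_nm: float = 0.34
    kBT: float = 4.11
    max_backtrack: int = 3
    #: which splitting factor tilts the backtracked forward step with force;
    #: the effective-rate equations use delta_fb
    kf_force_delta: str = "delta_fb"  # or "delta0"

    def __post_init__(self) -> None:
        for name in ("k0_0", "kb1_0", "kf_0", "kb_0"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in ("delta0", "delta_fb"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")

    def bare_rates(self, force_pn: float) -> tuple[float, float, float, float]:
        """(k0, kb1, kf, kb) at the given assisting force, flat landscape."""
        lf = self.step_nm * force_pn / self.kBT
        d_kf = self.delta_fb if self.kf_force_delta == "delta_fb" else self.delta0
        return (self.k0_0 * np.exp(self.delta0 * lf),
                self.kb1_0 * np.exp(-(1.0 - self.delta_fb) * lf),
                self.kf_0 * np.exp(d_kf * lf),
                self.kb_0 * np.exp(-(1.0 - self.delta_fb) * lf))


@dataclass(frozen=True)
class NucleosomeGeometry:
    """Steric and wrap geometry entering the linker bending energy.

    The octamer is a steric sphere (radius ``r_nuc``) at the center of the
    DNA superhelix (radius ``superhelix_radius``); Pol II is a steric
    sphere of radius ``r_pol``.  The linker — the DNA between the Pol II
    leading edge and the first wrapped base pair — is a discrete
    worm-like chain, one 0.34-nm segment per bp, clamped tangentially at
    the point where the wrapped DNA leaves the superhelix.  The enzyme
    threads the DNA, so its steric center sits one polymerase radius
    *behind* the leading edge along the incoming DNA direction; short
    linkers therefore force the chain to turn sharply so that the two
    spheres clear each other.  Sphere overlap is penalized by a stiff
    harmonic (``steric_stiffness``), a numerically convenient stand-in
    for hard-core exclusion; with the defaults the landscape under a
    uniform 1 kBT/bp interaction profile at polymerase position 47 bp has
    its minimum near 51-52 bp unwrapped, the model's published
    calibration point.
    """

    r_nuc: float = 3.2            # nm
    r_pol: float = 7.0            # nm
    persistence_length: float = 35.4  # nm
    n_tot: int = 147              # bp wrappable on the octamer
    superhelix_radius: float = 4.18   # nm
    superhelix_pitch: float = 2.39    # nm (sets the contact offset)
    rise: float = 0.34            # nm per bp
    steric_stiffness: float = 8.0     # kBT / nm^2
    max_linker_table_bp: int = 60

    def __post_init__(self) -> None:
        for name in ("r_nuc", "r_pol", "persistence_length",
                     "superhelix_radius", "rise", "steric_stiffness"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")


@dataclass
class InteractionProfile:
    """Per-bp DNA-octamer unwrapping cost phi_i, i = 1..n_tot (kBT)."""

    phi: np.ndarray

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        if self.phi.ndim != 1 or not np.all(np.isfinite(self.phi)):
            raise ValidationError("phi must be a finite 1-D array")

    def cumulative(self) -> np.ndarray:
        """cum[w] = sum_{i=1..w} phi_i, length n_tot + 1 with cum[0] = 0."""
        return np.concatenate([[0.0], np.cumsum(self.phi)])


# ----------------------------------------------------------------------
# linker bending energy

_CLAMP_ANGLE = -0.5 * np.pi  # exit tangent of the wrapped DNA, planar frame


def _chain_energy_grad(alpha: np.ndarray, r_c: float, ell: float,
                       stiff: float, k_st: float, r_min: float,
                       r_pol: float):
    """Bending + steric energy of the planar clamped chain, with gradient.

    ``alpha`` are segment direction angles; the chain starts at the
    contact point ``(r_c, 0)`` with a clamped tangent, and the polymerase
    steric center continues ``r_pol`` beyond the chain end along the last
    segment direction (the enzyme threads the DNA).
    """
    a_prev = np.concatenate([[_CLAMP_ANGLE], alpha[:-1]])
    d_ang = alpha - a_prev
    e_bend = stiff * np.sum(1.0 - np.cos(d_ang))
    cos_a, sin_a = np.cos(alpha), np.sin(alpha)
    cx = r_c + ell * cos_a.sum() + r_pol * cos_a[-1]
    cy = ell * sin_a.sum() + r_pol * sin_a[-1]
    dist = np.hypot(cx, cy)
    delta = r_min - dist
    e = e_bend + (k_st * delta * delta if delta > 0 else 0.0)

    grad = stiff * np.sin(d_ang)
    grad[:-1] -= stiff * np.sin(d_ang[1:])
    if delta > 0 and dist > 1e-12:
        ux, uy = cx / dist, cy / dist
        d_dist = ell * (-sin_a * ux + cos_a * uy)
        d_dist[-1] += r_pol * (-sin_a[-1] * ux + cos_a[-1] * uy)
        grad += -2.0 * k_st * delta * d_dist
    return e, grad


def _optimize_linker(n: int, geom: NucleosomeGeometry) -> float:
    """Minimize the chain energy for an n-bp linker (deterministic restarts)."""
    ell = geom.rise
    stiff = geom.persistence_length / ell  # kBT per joint for (1 - cos)
    # contact point offset from the octamer center: superhelix radius with
    # the pitch contributing through the axial rise of the contact turn
    r_c = float(np.hypot(geom.superhelix_radius, geom.superhelix_pitch / (2 * np.pi)))
    r_min = geom.r_nuc + geom.r_pol
    k_st = geom.steric_stiffness
    if n == 0:
        # no joints: the polymerase sits at the contact, center along the clamp
        cx = r_c + geom.r_pol * np.cos(_CLAMP_ANGLE)
        cy = geom.r_pol * np.sin(_CLAMP_ANGLE)
        delta = r_min - np.hypot(cx, cy)
        return float(k_st * delta * delta) if delta > 0 else 0.0
    best = np.inf
    for theta in (0.0, np.pi / 6, np.pi / 3, 0.5 * np.pi, 2 * np.pi / 3):
        # initial guess: uniform arc turning by theta away from the octamer
        alpha0 = _CLAMP_ANGLE + theta * np.arange(1, n + 1) / n
        res = minimize(_chain_energy_grad, alpha0,
                       args=(r_c, ell, stiff, k_st, r_min, geom.r_pol),
                       jac=True, method="L-BFGS-B",
                       options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-10})
        if res.fun < best:
            best = float(res.fun)
    if not np.isfinite(best):
        raise ConvergenceError(
            f"linker optimizer failed at n={n} with geometry {geom!r}")
    return max(best, 0.0)


_LINKER_CACHE: dict = {}


def linker_energy_table(geom: NucleosomeGeometry | None = None) -> np.ndarray:
    """Cached table E_L(n) for n = 0..max_linker_table_bp (kBT).

    Monotone non-increasing by construction (a longer chain can always
    shadow a shorter one's shape); small optimizer wiggles are cleaned by
    a running minimum from short to long linkers.
    """
    geom = geom or NucleosomeGeometry()
    key = geom
    if key not in _LINKER_CACHE:
        raw = np.array([_optimize_linker(n, geom)
                        for n in range(geom.max_linker_table_bp + 1)])
        table = np.minimum.accumulate(raw)
        table[table < 1e-9] = 0.0
        _LINKER_CACHE[key] = table
    return _LINKER_CACHE[key]


def linker_energy(n_linker: int, geom: NucleosomeGeometry | None = None) -> float:
    """Bending energy (kBT) of an n-bp DNA linker between Pol II and octamer."""
    if n_linker < 0:
        raise DomainError("linker length must be >= 0 bp")
    geom = geom or NucleosomeGeometry()
    table = linker_energy_table(geom)
    if n_linker >= len(table):
        return 0.0
    return float(table[n_linker])


def _el(n: np.ndarray, table: np.ndarray) -> np.ndarray:
    """Table lookup with E = +inf for negative linkers, 0 beyond the table."""
    n = np.asarray(n)
    out = np.where(n < 0, _INF_ENERGY, 0.0)
    valid = (n >= 0) & (n < len(table))
    out = np.where(valid, table[np.clip(n, 0, len(table) - 1)], out)
    return out


def _e_jw(j: int, w: np.ndarray, table: np.ndarray, cum: np.ndarray,
          n_tot: int) -> np.ndarray:
    """Landscape energies E_jw for one j over an array of w.

    Forbidden configurations (negative linker) are +inf.  The fully
    unwrapped state ``w = n_tot`` carries no linker energy: the octamer
    has released the DNA and no longer constrains the chain ahead.
    """
    e = _el(w - j, table) + cum[w]
    return np.where((w == n_tot) & (w >= j), cum[n_tot], e)


# ----------------------------------------------------------------------
# landscape and effective rates

def landscape(j: int, w, phi: InteractionProfile,
              geom: NucleosomeGeometry | None = None):
    """Energy E_jw (kBT) of polymerase at bp j with w bp unwrapped."""
    geom = geom or NucleosomeGeometry()
    w_arr = np.atleast_1d(np.asarray(w))
    if np.any(w_arr < 0) or np.any(w_arr > geom.n_tot):
        raise DomainError(f"w must lie in [0, {geom.n_tot}]")
    if np.any(w_arr < j):
        raise DomainError("w >= j required: the linker cannot be negative")
    table = linker_energy_table(geom)
    cum = phi.cumulative()
    e = _e_jw(j, w_arr, table, cum, geom.n_tot)
    return e if np.ndim(w) else float(e[0])


def effective_rates(j_grid, phi: InteractionProfile, kin: PolIIKinetics,
                    geom: NucleosomeGeometry | None = None,
                    force: float = 10.0):
    """Boltzmann-averaged stepping rates over the unwrapping coordinate.

    For each polymerase position j, every bare rate is multiplied by
    ``< exp(-delta * dE_jw) >`` where the average is over the equilibrium
    ensemble of w at that j and ``dE_jw`` is the landscape change of the
    step.  Computed entirely in log-space.  Returns a dict of arrays
    ``k0_eff``, ``kb1_eff``, ``kf_eff``, ``kb_eff`` aligned with
    ``j_grid``; rates reduce exactly to the bare laws on a flat landscape.
    """
    geom = geom or NucleosomeGeometry()
    kin = kin or PolIIKinetics()
    j_grid = np.atleast_1d(np.asarray(j_grid, dtype=int))
    table = linker_energy_table(geom)
    cum = phi.cumulative()
    n_tot = geom.n_tot
    k0_b, kb1_b, kf_b, kb_b = kin.bare_rates(force)

    d_kf = kin.delta_fb if kin.kf_force_delta == "delta_fb" else kin.delta0
    # matrix of E_{j,w} over the full w range; forbidden (w < j) rows
    # carry +inf and drop out of the log-sums
    w = np.arange(0, n_tot + 1)
    e_mat = np.vstack([_e_jw(j, w, table, cum, n_tot) for j in j_grid])
    e_fwd = np.vstack([_e_jw(j + 1, w, table, cum, n_tot) for j in j_grid])
    e_bwd = np.vstack([_e_jw(j - 1, w, table, cum, n_tot) for j in j_grid])
    with np.errstate(invalid="ignore"):
        de_fwd = np.where(e_mat >= _INF_ENERGY, np.inf, e_fwd - e_mat)
        de_bwd = np.where(e_mat >= _INF_ENERGY, -np.inf, e_mat - e_bwd)
    log_w = np.where(e_mat >= _INF_ENERGY, -np.inf, -e_mat)
    log_z = logsumexp(log_w, axis=1)
    fac_b = (1.0 - kin.delta_fb) * de_bwd
    k0_eff = k0_b * np.exp(
        logsumexp(log_w - kin.delta0 * np.where(np.isinf(de_fwd), np.inf, de_fwd),
                  axis=1) - log_z)
    kf_eff = kf_b * np.exp(
        logsumexp(log_w - d_kf * np.where(np.isinf(de_fwd), np.inf, de_fwd),
                  axis=1) - log_z)
    kb1_eff = kb1_b * np.exp(logsumexp(log_w + fac_b, axis=1) - log_z)
    kb_eff = kb_b * np.exp(logsumexp(log_w + fac_b, axis=1) - log_z)
    return {"j": j_grid, "k0_eff": k0_eff, "kb1_eff": kb1_eff,
            "kf_eff": kf_eff, "kb_eff": kb_eff}


def _rate_tables(phi, kin, geom, force, j_min, j_max):
    """Effective-rate arrays over j_min..j_max inclusive (index j - j_min)."""
    grid = np.arange(j_min, j_max + 1)
    r = effective_rates(grid, phi, kin, geom, force)
    return grid, r


def mean_dwell_profile(phi: InteractionProfile, kin: PolIIKinetics | None = None,
                       geom: NucleosomeGeometry | None = None,
                       force: float = 10.0,
                       j_start: int = 0, j_end: int | None = None):
    """Analytic mean dwell time (s) at each polymerase position.

    The dwell at j is the mean first-passage time from the on-pathway
    state at j to the on-pathway state at j+1, accounting for backtrack
    excursions up to ``max_backtrack`` bp; a 4-state linear system per
    position.  Backtracked states at depth q use the effective rates of
    the physical position j - q.  Positions before the NPS (j < 0) use the
    zero-force main-pathway dwell (k0_0)^-1 = 0.04 s.

    Returns (positions j, dwell times).
    """
    kin = kin or PolIIKinetics()
    geom = geom or NucleosomeGeometry()
    if j_end is None:
        j_end = geom.n_tot - 1
    if j_end < j_start:
        raise ValidationError("j_end must be >= j_start")
    positions = np.arange(j_start, j_end + 1)
    dwell = np.full(len(positions), PRE_NPS_DWELL_S)
    inside = positions >= 0
    if not np.any(inside):
        return positions, dwell
    q_max = kin.max_backtrack
    j_lo = max(0, positions[inside].min() - q_max)
    grid, rates = _rate_tables(phi, kin, geom, force, j_lo - 0, j_end)

    def rate_at(name, j):
        if j < grid[0]:
            # positions before the NPS entrance: flat landscape, bare rate
            bare = dict(zip(("k0_eff", "kb1_eff", "kf_eff", "kb_eff"),
                            kin.bare_rates(force)))
            return bare[name]
        return rates[name][j - grid[0]]

    for i, j in enumerate(positions):
        if j < 0:
            continue
        k0 = rate_at("k0_eff", j)
        kb1 = rate_at("kb1_eff", j)
        f = [rate_at("kf_eff", j - q) for q in range(1, q_max + 1)]
        b = [rate_at("kb_eff", j - q) for q in range(1, q_max)] + [0.0]
        # unknowns T_0..T_qmax; A T = 1
        m = q_max + 1
        a = np.zeros((m, m))
        rhs = np.ones(m)
        a[0, 0] = k0 + kb1
        if m > 1:
            a[0, 1] = -kb1
        for q in range(1, m):
            a[q, q] = f[q - 1] + b[q - 1]
            a[q, q - 1] = -f[q - 1]
            if q + 1 < m:
                a[q, q + 1] = -b[q - 1]
        if a[0, 0] <= 0:
            raise ConvergenceError(f"no escape route from position {j}")
        dwell[i] = np.linalg.solve(a, rhs)[0]
    return positions, dwell


def _sim_rate_tables(phi, kin, geom, force, j_start, j_end):
    """Effective-rate arrays covering j_start - max_backtrack .. j_end."""
    q_max = kin.max_backtrack
    grid = np.arange(j_start - q_max, j_end + 1)
    # the nucleosome modifies rates only while it is ahead (0 <= j <= n_tot);
    # upstream and downstream of the NPS the bare force-dependent laws apply
    inside = (grid >= 0) & (grid < geom.n_tot)
    k0 = np.empty(len(grid))
    kb1 = np.empty(len(grid))
    kf = np.empty(len(grid))
    kb = np.empty(len(grid))
    k0_b, kb1_b, kf_b, kb_b = kin.bare_rates(force)
    k0[:], kb1[:], kf[:], kb[:] = k0_b, kb1_b, kf_b, kb_b
    if np.any(inside):
        r = effective_rates(grid[inside], phi, kin, geom, force)
        k0[inside] = r["k0_eff"]
        kb1[inside] = r["kb1_eff"]
        kf[inside] = r["kf_eff"]
        kb[inside] = r["kb_eff"]
    return grid, k0, kb1, kf, kb


def _run_ssa(tables, j_start, j_end, q_max, t_max, sample_rate, seed):
    from ._sim import polii_ssa

    grid, k0, kb1, kf, kb = tables
    n_samples = int(t_max * sample_rate) if sample_rate > 0 else 0
    arrivals, samples, n_emitted, crossed = polii_ssa(
        k0, kb1, kf, kb, int(grid[0]), int(j_start), int(j_end), q_max,
        float(t_max), float(sample_rate), n_samples, int(seed) & 0x7FFFFFFF)
    out = {
        "positions": np.arange(j_start, j_end + 1),
        "arrival_times": arrivals,
        "crossed": bool(crossed),
    }
    if sample_rate > 0:
        out["t"] = np.arange(n_emitted) / sample_rate
        out["position"] = samples[:n_emitted]
    return out


def simulate_trajectory(phi: InteractionProfile, kin: PolIIKinetics | None = None,
                        geom: NucleosomeGeometry | None = None,
                        force: float = 10.0, seed: int = 0,
                        t_max: float = 1e4, j_start: int = -20,
                        j_end: int | None = None, sample_rate: float = 0.0):
    """Exact stochastic simulation of one Pol II crossing.

    Event-driven simulation on the (position, backtrack-depth) state graph
    with position-dependent effective rates; reproducible for a given seed.

    Returns a dict with ``arrival_times`` (first time each main-pathway
    position j_start..j_end is reached; NaN where never reached),
    ``crossed`` and, when ``sample_rate > 0``, uniformly sampled
    ``t``/``position`` arrays of the physical position.
    """
    kin = kin or PolIIKinetics()
    geom = geom or NucleosomeGeometry()
    if t_max <= 0:
        raise ValidationError("t_max must be > 0")
    if j_end is None:
        j_end = geom.n_tot
    tables = _sim_rate_tables(phi, kin, geom, force, j_start, j_end)
    return _run_ssa(tables, j_start, j_end, kin.max_backtrack, t_max,
                    sample_rate, seed)


def simulate_ensemble(phi: InteractionProfile, n_traj: int,
                      kin: PolIIKinetics | None = None,
                      geom: NucleosomeGeometry | None = None,
                      force: float = 10.0, seed: int = 0,
                      t_max: float = 1e5, j_start: int = -20,
                      j_end: int | None = None) -> np.ndarray:
    """Arrival-time matrix (n_traj x positions) of independent crossings.

    Rate tables are built once and shared; trajectory ``i`` uses seed
    ``seed + i``.  Row differences give per-position passage (dwell) times.
    """
    kin = kin or PolIIKinetics()
    geom = geom or NucleosomeGeometry()
    if j_end is None:
        j_end = geom.n_tot
    tables = _sim_rate_tables(phi, kin, geom, force, j_start, j_end)
    rows = []
    for i in range(n_traj):
        out = _run_ssa(tables, j_start, j_end, kin.max_backtrack, t_max,
                       0.0, seed + i)
        rows.append(out["arrival_times"])
    return np.vstack(rows)


@dataclass
class InteractionFit:
    """Result of `fit_interaction_energies`."""

    profile: InteractionProfile
    dwell_model: np.ndarray
    dwell_target: np.ndarray
    positions: np.ndarray
    residual_rms: float
    jacobian_column_norms: np.ndarray = None
    success: bool = True
    message: str = ""


def smooth_dwell(values: np.ndarray, span_bp: int = 3) -> np.ndarray:
    """Local average over a span (edge bins use the available neighbors)."""
    kernel = np.ones(span_bp) / span_bp
    padded = np.pad(np.asarray(values, float), span_bp // 2, mode="edge")
    return np.convolve(padded, kernel, mode="valid")


def fit_interaction_energies(dwell_positions, dwell_values,
                             kin: PolIIKinetics | None = None,
                             geom: NucleosomeGeometry | None = None,
                             force: float = 10.0,
                             bounds: tuple[float, float] = (0.0, 15.0),
                             init: float = 1.0,
                             smooth_span_bp: int = 3,
                             exclude_terminal_bp: int = 10,
                             xtol: float = 1e-8,
                             max_nfev: int | None = None) -> InteractionFit:
    """Fit the per-bp interaction profile phi to a dwell-time profile.

    The experimental dwell times are smoothed with a ``smooth_span_bp``
    local average; model dwell times from `mean_dwell_profile` are matched
    in bounded least squares (trust-region reflective).  Because the model
    cannot describe the final wrap-release, the last
    ``exclude_terminal_bp`` positions are excluded from the residual.
    phi is initialized uniformly at ``init`` kBT with no regularization.
    The Jacobian column norms at the solution expose locally
    unidentifiable directions (dwell times depend on energies *ahead* of
    the polymerase only, so the terminal phi values are never constrained).
    """
    kin = kin or PolIIKinetics()
    geom = geom or NucleosomeGeometry()
    pos = np.asarray(dwell_positions, dtype=int)
    target = smooth_dwell(np.asarray(dwell_values, float), smooth_span_bp)
    keep = (pos >= 0) & (pos <= geom.n_tot - 1 - exclude_terminal_bp)
    if keep.sum() < 5:
        raise ValidationError("dwell profile must cover the NPS interior")
    pos_fit, target_fit = pos[keep], target[keep]
    n_phi = geom.n_tot

    def model_dwell(phi_vec):
        prof = InteractionProfile(phi_vec)
        p, d = mean_dwell_profile(prof, kin, geom, force,
                                  j_start=int(pos_fit.min()),
                                  j_end=int(pos_fit.max()))
        return d[np.searchsorted(p, pos_fit)]

    def residual(phi_vec):
        return model_dwell(phi_vec) - target_fit

    # the dwell at position j is sensitive to phi only over the unwrapping
    # window just ahead of (and the backtrack span behind) the polymerase,
    # so the Jacobian is banded; declaring the band lets the solver build
    # it with grouped finite differences
    horizon = int(np.argmax(linker_energy_table(geom) <= 0.0)) or \
        geom.max_linker_table_bp
    band = kin.max_backtrack + horizon + 6
    sparsity = np.zeros((len(pos_fit), n_phi), dtype=np.int8)
    for row, j in enumerate(pos_fit):
        lo = max(0, j - band)
        hi = min(n_phi, j + band + 1)
        sparsity[row, lo:hi] = 1

    res = least_squares(residual, np.full(n_phi, float(init)),
                        bounds=(bounds[0], bounds[1]), method="trf",
                        xtol=xtol, ftol=1e-8, gtol=1e-8,
                        x_scale=1.0, max_nfev=max_nfev,
                        jac_sparsity=sparsity)
    dwell_fit = model_dwell(res.x)
    rms = float(np.sqrt(np.mean((dwell_fit - target_fit) ** 2)))
    jac = res.jac
    if jac is not None and not isinstance(jac, np.ndarray):
        jac = np.asarray(jac.todense()) if hasattr(jac, "todense") else None
    jac_norms = np.linalg.norm(jac, axis=0) if jac is not None else None
    if not res.success:
        return InteractionFit(InteractionProfile(res.x), dwell_fit, target_fit,
                              pos_fit, rms, jac_norms, False,
                              f"fit did not converge: {res.message}")
    return InteractionFit(InteractionProfile(res.x), dwell_fit, target_fit,
                          pos_fit, rms, jac_norms, True, res.message)
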