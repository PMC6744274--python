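"""Transcription-trace pipeline: ruler registration and Pol II statistics.

A transcription trace records contour transcribed (nm) at constant
assisting force.  Absolute registration in base pairs uses the *molecular
ruler* engineered upstream of the nucleosome: eight tandem 64-bp repeats,
each with one sequence-encoded pause site at its 59th nucleotide.  The
pausing pattern makes the residence-time profile of the trace periodic in
nm with the physical length of one repeat (~21.1 nm at 10 pN); detecting
that period and its phase converts nm to template bp, anchored so that
pause sites fall on bp 59 + 64k.  Registered traces are reduced to median
dwell-time maps over the 147-bp NPS, crossing times and arrest
probabilities, pause-free velocities, backtrack statistics and two/three
state hidden-Markov fits of hopping segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import AlignmentError, ValidationError
from .trace import TxnTrace
from .unzip import NPS_LENGTH_BP, ResidenceMap

__all__ = [
    "RulerSpec",
    "detect_ruler",
    "register_bp",
    "dwell_map",
    "crossing_stats",
    "CrossingStats",
    "pause_free_velocity",
    "backtrack_events",
    "fit_hopping_hmm",
    "HmmFit",
    "DYAD_BP",
]

#: pseudo-two-fold symmetry axis of the 147-bp wrap (0-based bp)
DYAD_BP = 73


@dataclass(frozen=True)
class RulerSpec:
    """Geometry of the 8 x 64 bp molecular ruler upstream of the NPS."""

    n_repeats: int = 8
    repeat_bp: int = 64
    pause_site_bp: int = 59       # within each repeat, 1-based
    expected_period_nm: float = 21.1
    gap_to_nps_bp: int = 46       # bp between the last repeat and the NPS

    def __post_init__(self) -> None:
        if not 1 <= self.pause_site_bp <= self.repeat_bp:
            raise ValidationError("pause_site_bp must lie within the repeat")

    def template_start_bp(self) -> int:
        """Start of the first repeat, bp relative to the NPS start."""
        return -(self.n_repeats * self.repeat_bp + self.gap_to_nps_bp)


def detect_ruler(trace: TxnTrace, ruler: RulerSpec | None = None,
                 period_grid=None, n_phase_bins: int = 64,
                 quality_threshold: float = 4.0):
    """Detect the ruler periodicity of a transcription trace.

    The residence-time profile of the ruler region is folded modulo each
    candidate period (default grid 19-23 nm, 0.01 nm steps); the true
    period concentrates the pause residence into a single phase bin.  The
    quality score is the peak-to-median ratio of the best folded
    histogram; below ``quality_threshold`` (e.g. featureless drift) the
    trace cannot be registered and an AlignmentError is raised.

    Returns (period_nm, phase_offset_nm, quality); the phase offset is
    the nm position (mod period) of the repeat pause site.
    """
    ruler = ruler or RulerSpec()
    if period_grid is None:
        period_grid = np.arange(19.0, 23.0 + 1e-9, 0.01)
    pos = np.asarray(trace.position, dtype=float)
    # restrict to the region expected to contain the repeats, anchored at
    # the start of the trajectory (translation invariant)
    p0 = float(np.quantile(pos, 0.001))
    window_hi = ruler.n_repeats * float(np.max(period_grid)) + 10.0
    sel = (pos >= p0) & (pos <= p0 + window_hi)
    if sel.sum() < 100:
        raise AlignmentError("trace does not span the ruler region")
    p = pos[sel]
    # stage 1: fold the residence profile at each candidate period; score
    # by the peak-to-median ratio of the folded histogram
    scored = []
    for period in np.asarray(period_grid, dtype=float):
        phase = np.mod(p, period)
        hist, edges = np.histogram(phase, bins=n_phase_bins,
                                   range=(0.0, period))
        med = np.median(hist)
        score = (hist.max() + 1.0) / (med + 1.0)
        centers = 0.5 * (edges[:-1] + edges[1:])
        scored.append((float(score), float(period),
                       float(centers[np.argmax(hist)])))
    scored.sort(reverse=True)
    quality = scored[0][0]
    if quality < quality_threshold:
        raise AlignmentError(
            f"ruler registration failed: quality {quality:.2f} < "
            f"{quality_threshold} (no periodic pausing detected)")
    # keep top candidates that are not near-duplicates of a better period
    candidates = []
    for score, period, phase in scored:
        if all(abs(period - c[0]) > 0.15 for c in candidates):
            candidates.append((period, phase))
        if len(candidates) >= 8:
            break

    # stage 2: refine each candidate by maximizing the comb score — the
    # kernel-weighted log-residence summed over the eight predicted pause
    # positions — directly over (period, phase).  The kernel width is
    # annealed so that a slightly misaligned comb is first pulled onto
    # the pauses and then localized to sub-0.1-nm precision; the log
    # damps any single dominant dwell so that threading all repeats
    # beats parking one tooth on a large unrelated pause.
    from scipy.optimize import minimize as _minimize

    p_sub = p[::2] if len(p) > 50000 else p
    k_idx = np.arange(ruler.n_repeats)

    def comb_score(theta, sigma):
        period_t, phase_t = theta
        s = 0.0
        for k in k_idx:
            w = np.exp(-0.5 * ((p_sub - phase_t - k * period_t) / sigma) ** 2).sum()
            s += np.log1p(w)
        return -s

    t_lo, t_hi = float(np.min(period_grid)), float(np.max(period_grid))
    best = None
    for period0, phase0 in candidates:
        theta = np.array([period0, phase0])
        for sigma in (1.0, 0.45, 0.25, 0.15):
            res = _minimize(comb_score, theta, args=(sigma,),
                            method="Nelder-Mead",
                            options={"xatol": 1e-3, "fatol": 1e-3,
                                     "maxiter": 300})
            theta = res.x
        if not (t_lo <= theta[0] <= t_hi):
            continue
        score = -comb_score(theta, 0.25)
        if best is None or score > best[0]:
            best = (score, float(theta[0]), float(theta[1]))
    if best is None:
        raise AlignmentError("ruler refinement failed for all candidates")
    _, period, phase = best

    # stage 3: trimmed regression on the reliable teeth.  Individual
    # repeats may carry little pause residence (the polymerase happened
    # not to dwell) or a nearby spurious backtrack cluster; such teeth
    # bias the comb fit.  Each tooth is replaced by the modal residence
    # position near its prediction, teeth with weak capture or large
    # residuals are dropped, and a straight-line fit of the remainder
    # gives the final period and phase.
    modes, ks, weights = [], [], []
    for k in k_idx:
        target = phase + k * period
        m = np.abs(p - target) < 0.8
        if m.sum() < 30:
            continue
        sub = p[m]
        hist, edges = np.histogram(sub, bins=16)
        mode = 0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1])
        tight = sub[np.abs(sub - mode) < 0.3]
        if len(tight) < 20:
            continue
        modes.append(float(tight.mean()))
        ks.append(int(k))
        weights.append(float(len(tight)))
    if len(ks) >= 5:
        ks_a = np.asarray(ks)
        modes_a = np.asarray(modes)
        w_a = np.asarray(weights)
        med_w = np.median(w_a)
        slope, intercept = np.polyfit(ks_a, modes_a, 1, w=np.sqrt(w_a))
        resid = np.abs(modes_a - (intercept + slope * ks_a))
        keep = (resid < 0.5) & (w_a > 0.1 * med_w)
        if keep.sum() >= 4:
            slope, intercept = np.polyfit(ks_a[keep], modes_a[keep], 1,
                                          w=np.sqrt(w_a[keep]))

            def threaded(period_t, phase_t):
                """Teeth whose local residence mode sits on the comb."""
                n_ok = 0
                for k in k_idx:
                    target = phase_t + k * period_t
                    m = np.abs(p - target) < 0.8
                    if m.sum() < 30:
                        continue
                    sub = p[m]
                    hist, edges = np.histogram(sub, bins=16)
                    mode = 0.5 * (edges[np.argmax(hist)]
                                  + edges[np.argmax(hist) + 1])
                    if abs(mode - target) < 0.35:
                        n_ok += 1
                return n_ok

            if (t_lo <= slope <= t_hi
                    and threaded(slope, intercept)
                    >= threaded(period, phase)):
                period, phase = float(slope), float(intercept)
    return period, phase, quality


def refit_phase(trace: TxnTrace, period_nm: float,
                ruler: RulerSpec | None = None) -> float:
    """Best comb phase for a trace at a fixed (consensus) period.

    Phase candidates come from folding the ruler-region residence at the
    given period; each is refined by an annealed 1-D comb-score
    optimization and polished by a trimmed intercept estimate over the
    modal tooth positions.  Used by `register_ensemble` after the period
    has been pinned across traces.
    """
    from scipy.optimize import minimize_scalar

    ruler = ruler or RulerSpec()
    pos = np.asarray(trace.position, dtype=float)
    p0 = float(np.quantile(pos, 0.001))
    window_hi = ruler.n_repeats * (period_nm + 1.0) + 10.0
    p = pos[(pos >= p0) & (pos <= p0 + window_hi)]
    if len(p) < 100:
        raise AlignmentError("trace does not span the ruler region")
    k_idx = np.arange(ruler.n_repeats)

    def comb_score(phase_t, sigma):
        s = 0.0
        for k in k_idx:
            w = np.exp(-0.5 * ((p - phase_t - k * period_nm) / sigma) ** 2).sum()
            s += np.log1p(w)
        return -s

    hist, edges = np.histogram(np.mod(p, period_nm), bins=64,
                               range=(0.0, period_nm))
    order = np.argsort(hist)[::-1][:3]
    best = None
    for i in order:
        phase = 0.5 * (edges[i] + edges[i + 1])
        for sigma in (1.0, 0.45, 0.25, 0.15):
            res = minimize_scalar(comb_score, args=(sigma,),
                                  bounds=(phase - 0.6, phase + 0.6),
                                  method="bounded",
                                  options={"xatol": 1e-4})
            phase = float(res.x)
        # trimmed intercept over modal tooth positions
        offs, wts = [], []
        for k in k_idx:
            target = phase + k * period_nm
            m = np.abs(p - target) < 0.8
            if m.sum() < 30:
                continue
            sub = p[m]
            h, e = np.histogram(sub, bins=16)
            mode = 0.5 * (e[np.argmax(h)] + e[np.argmax(h) + 1])
            tight = sub[np.abs(sub - mode) < 0.3]
            if len(tight) >= 20 and abs(mode - target) < 0.5:
                offs.append(float(tight.mean()) - k * period_nm)
                wts.append(float(len(tight)))
        if len(offs) >= 3:
            phase = float(np.average(offs, weights=wts))
        score = -comb_score(phase, 0.2)
        if best is None or score > best[0]:
            best = (score, phase)
    if best is None:
        raise AlignmentError("phase refit failed")
    return best[1]


def register_ensemble(traces, ruler: RulerSpec | None = None,
                      footprint_bp: int | None = None,
                      start_offset_bp: float = 5.0):
    """Register a set of traces with a consensus ruler period.

    Each trace's period is detected independently; the ensemble median
    pins the physical repeat length (single traces occasionally lack
    enough pause residence to determine it alone), each trace's phase is
    then refit at the consensus period, and all traces are registered.
    Traces failing ruler detection are dropped.  Returns (registered
    traces, consensus period).
    """
    ruler = ruler or RulerSpec()
    detected = []
    for tr in traces:
        try:
            period, phase, _ = detect_ruler(tr, ruler)
        except AlignmentError:
            continue
        detected.append((tr, period))
    if not detected:
        raise AlignmentError("no trace could be registered")
    consensus = float(np.median([d[1] for d in detected]))
    out = []
    for tr, _ in detected:
        phase = refit_phase(tr, consensus, ruler)
        out.append(register_bp(tr, consensus, phase, ruler,
                               start_offset_bp=start_offset_bp,
                               footprint_bp=footprint_bp))
    return out, consensus


def register_bp(trace: TxnTrace, period_nm: float, phase_offset_nm: float,
                ruler: RulerSpec | None = None,
                start_offset_bp: float = 5.0,
                footprint_bp: int | None = None) -> TxnTrace:
    """Convert trace positions to template bp via the detected ruler.

    Linear nm -> bp conversion at 64 bp per detected period, with the
    phase anchored so that pause sites map onto bp 59 + 64 k of the
    ruler.  The absolute repeat index assumes the trace starts within
    half a repeat of the ruler start (``start_offset_bp`` bp before it).
    Positions are normalized to the NPS start; the leading edge adds the
    polymerase footprint.  Registration metadata is recorded on the trace.
    """
    ruler = ruler or RulerSpec()
    if footprint_bp is None:
        footprint_bp = TxnTrace.FOOTPRINT_BP
    bp_per_nm = ruler.repeat_bp / period_nm
    # expected nm position of the first pause given the pre-ruler run-in
    expected_first = (ruler.pause_site_bp - 1 + start_offset_bp) / \
        ruler.repeat_bp * period_nm
    k0 = int(round((expected_first - phase_offset_nm) / period_nm))
    first_pause_nm = phase_offset_nm + k0 * period_nm
    first_pause_bp = ruler.template_start_bp() + ruler.pause_site_bp - 1
    registered = (np.asarray(trace.position, float) - first_pause_nm) \
        * bp_per_nm + first_pause_bp
    trace.registered_bp = registered
    trace.leading_edge_bp = registered + footprint_bp
    trace.registration = {
        "period_nm": float(period_nm),
        "phase_offset_nm": float(phase_offset_nm),
        "footprint_bp": int(footprint_bp),
    }
    return trace


def dwell_map(traces, bin_width: float = 1.0, stat: str = "median",
              span: tuple[float, float] = (0.0, float(NPS_LENGTH_BP))) -> ResidenceMap:
    """Per-bp residence time of the Pol II leading edge, median across traces."""
    traces = list(traces)
    if not traces:
        raise ValidationError("no traces")
    lo, hi = span
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    rows = []
    for tr in traces:
        if tr.leading_edge_bp is None:
            raise ValidationError("trace is not registered (run register_bp)")
        counts, _ = np.histogram(tr.leading_edge_bp, bins=edges)
        rows.append(counts / tr.sample_rate)
    stack = np.vstack(rows)
    vals = np.median(stack, axis=0) if stat == "median" else stack.mean(axis=0)
    return ResidenceMap(centers, vals, bin_width, mode="time",
                        aggregation=stat, n_traces=len(traces))


@dataclass
class CrossingStats:
    """Population statistics of NPS barrier crossing."""

    crossing_times: np.ndarray
    ccdf_t: np.ndarray
    ccdf_p: np.ndarray
    n_entered: int
    n_crossed: int
    n_arrested: int
    arrest_positions: np.ndarray
    p_crossing: float
    p_arrest: float
    p_arrest_pre_dyad: float
    p_arrest_post_dyad: float
    per_trace: list = field(default_factory=list)


def crossing_stats(traces, nps_span: float = float(NPS_LENGTH_BP),
                   arrest_threshold_s: float = 300.0,
                   arrest_motion_bp: float = 3.0) -> CrossingStats:
    """Crossing times, CCDF and arrest statistics of registered traces.

    The crossing time is the duration for the leading edge to traverse
    the full NPS; only traces that exit the NPS (reach the stall site)
    contribute.  A trace whose terminal segment sits still (within
    ``arrest_motion_bp``) for at least ``arrest_threshold_s`` inside the
    NPS is classified as arrested, with its arrest position split at the
    dyad.
    """
    times, arrests, per_trace = [], [], []
    n_entered = n_crossed = 0
    for tr in traces:
        if tr.leading_edge_bp is None:
            raise ValidationError("trace is not registered")
        le = tr.leading_edge_bp
        t = tr.time
        entered = np.nonzero(le >= 0.0)[0]
        if len(entered) == 0:
            per_trace.append({"entered": False})
            continue
        n_entered += 1
        t_in = t[entered[0]]
        exited = np.nonzero(le >= nps_span)[0]
        if len(exited) > 0:
            ct = t[exited[0]] - t_in
            times.append(ct)
            n_crossed += 1
            per_trace.append({"entered": True, "crossed": True,
                              "crossing_time_s": float(ct)})
            continue
        # terminal pause duration at the final position
        final = le[-1]
        still = np.abs(le - final) <= arrest_motion_bp
        # last contiguous still block
        idx = len(still) - 1
        while idx > 0 and still[idx - 1]:
            idx -= 1
        pause_s = t[-1] - t[idx]
        if pause_s >= arrest_threshold_s and 0.0 <= final < nps_span:
            arrests.append(float(final))
            per_trace.append({"entered": True, "crossed": False,
                              "arrested": True, "arrest_bp": float(final)})
        else:
            per_trace.append({"entered": True, "crossed": False,
                              "arrested": False})
    times = np.sort(np.asarray(times, dtype=float))
    arrests = np.asarray(arrests, dtype=float)
    ccdf_t = np.concatenate([[0.0], times])
    ccdf_p = (1.0 - np.arange(len(ccdf_t)) / max(len(times), 1))
    pre = float(np.mean(arrests < DYAD_BP)) if len(arrests) else 0.0
    return CrossingStats(
        crossing_times=times, ccdf_t=ccdf_t, ccdf_p=ccdf_p,
        n_entered=n_entered, n_crossed=n_crossed, n_arrested=len(arrests),
        arrest_positions=arrests,
        p_crossing=n_crossed / n_entered if n_entered else float("nan"),
        p_arrest=len(arrests) / n_entered if n_entered else float("nan"),
        p_arrest_pre_dyad=pre,
        p_arrest_post_dyad=1.0 - pre if len(arrests) else 0.0,
        per_trace=per_trace,
    )


def pause_free_velocity(rmap: ResidenceMap, region: tuple[float, float],
                        n_fastest: int = 3) -> float:
    """Pause-free velocity (nt/s) from the fastest sites of a dwell map.

    To discount sequence bias, the ``n_fastest`` sites (smallest median
    residence time) within the region are averaged and inverted.
    """
    lo, hi = region
    sel = (rmap.positions >= lo) & (rmap.positions < hi) & (rmap.values > 0)
    vals = np.sort(rmap.values[sel])
    if len(vals) < n_fastest:
        raise ValidationError(
            f"region {region} has {len(vals)} usable sites, "
            f"need >= {n_fastest}")
    return float(1.0 / np.mean(vals[:n_fastest]))


def backtrack_events(trace: TxnTrace, min_depth_bp: float = 2.0,
                     min_duration_s: float = 1.0,
                     noise_tol_bp: float = 0.5):
    """Detect backtracks: rearward excursions below the running maximum.

    An event is a contiguous excursion at least ``noise_tol_bp`` below
    the running maximum whose depth reaches ``min_depth_bp`` and whose
    duration (until the running maximum is re-attained) is at least
    ``min_duration_s``.  Returns a list of (start_time_s, depth_bp,
    duration_s).
    """
    if trace.leading_edge_bp is None:
        raise ValidationError("trace is not registered")
    pos = trace.leading_edge_bp
    t = trace.time
    runmax = np.maximum.accumulate(pos)
    deficit = runmax - pos
    below = deficit > noise_tol_bp
    events = []
    i = 0
    n = len(pos)
    while i < n:
        if below[i]:
            j = i
            while j < n and below[j]:
                j += 1
            depth = float(deficit[i:j].max())
            duration = float(t[min(j, n - 1)] - t[i])
            if depth >= min_depth_bp and duration >= min_duration_s:
                events.append((float(t[i]), depth, duration))
            i = j
        else:
            i += 1
    return events


@dataclass
class HmmFit:
    """Gaussian-emission HMM fit of a hopping segment."""

    means_bp: np.ndarray          # sorted ascending
    sigmas_bp: np.ndarray
    transition_rates: np.ndarray  # per-second rate matrix estimate
    state_path: np.ndarray        # decoded, relabeled to sorted means
    dwell_times_s: np.ndarray     # mean dwell per state, 1/sum(exit rates)
    log_likelihood: float
    converged: bool
    degenerate: bool


def fit_hopping_hmm(segment, n_states: int = 2, sample_rate: float = 800.0,
                    seed: int = 0, n_iter: int = 200,
                    degenerate_sep_bp: float = 0.5) -> HmmFit:
    """Fit a 2- or 3-state Gaussian HMM to a position hopping segment.

    Trained by expectation-maximization (hmmlearn); states are relabeled
    by ascending mean so the decoding is invariant to label permutations.
    A fit whose state means are closer than ``degenerate_sep_bp`` is
    flagged degenerate (e.g. a constant signal cannot support 2 states).
    """
    from hmmlearn.hmm import GaussianHMM

    y = np.asarray(segment, dtype=float).reshape(-1, 1)
    if len(y) < 200:
        raise ValidationError("hopping segment too short (need >= 200 samples)")
    if n_states not in (2, 3):
        raise ValidationError("n_states must be 2 or 3")
    model = GaussianHMM(n_components=n_states, covariance_type="diag",
                        n_iter=n_iter, random_state=int(seed) & 0x7FFFFFFF,
                        tol=1e-4)
    model.fit(y)
    if not model.monitor_.converged:
        from .exceptions import ConvergenceError

        raise ConvergenceError(
            "HMM expectation-maximization did not converge; log-likelihood "
            f"trail: {list(model.monitor_.history)}")
    order = np.argsort(model.means_.ravel())
    means = model.means_.ravel()[order]
    sigmas = np.sqrt(model.covars_.reshape(n_states, -1)[:, 0])[order]
    trans_p = model.transmat_[np.ix_(order, order)]
    # per-second rates from per-sample transition probabilities
    rates = trans_p * sample_rate
    np.fill_diagonal(rates, 0.0)
    exit_rates = rates.sum(axis=1)
    dwells = np.where(exit_rates > 0, 1.0 / np.maximum(exit_rates, 1e-12),
                      np.inf)
    raw_path = model.predict(y)
    relabel = np.empty(n_states, dtype=int)
    relabel[order] = np.arange(n_states)
    degenerate = bool(np.any(np.diff(means) < degenerate_sep_bp))
    return HmmFit(means_bp=means, sigmas_bp=sigmas, transition_rates=rates,
                  state_path=relabel[raw_path], dwell_times_s=dwells,
                  log_likelihood=float(model.monitor_.history[-1]),
                  converged=True, degenerate=degenerate)
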