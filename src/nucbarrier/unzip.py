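"""Unzipping-trace pipeline: bp conversion, residence maps, alignment, rips.

A constant-velocity (20 nm/s) or constant-force unzipping trace is reduced
to a per-base-pair *topography map*: the force-weighted residence time of
the unzipping fork at each position along the template.  Registration
uses the template's built-in redundancy — the stem carries two tandem
copies of the 147-bp '601' nucleosome positioning sequence (NPS) exactly
197 bp apart, so a trace can be stretched by a single scale factor until
the two copies' residence signatures correlate best at a 197-bp lag.

Coordinates are bp of unzipped duplex, normalized to the start of the
second NPS (bp 249 of the stem) by subtracting 248; the first NPS and the
Y-stem then sit at negative positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .exceptions import AlignmentError, ValidationError
from .polymer import PolymerParams, TetherComposition, unzipped_bp
from .trace import Trace

__all__ = [
    "ResidenceMap",
    "SECOND_NPS_OFFSET_BP",
    "RESCALE_ANCHOR_BP",
    "NPS_REPEAT_SPACING_BP",
    "NPS_LENGTH_BP",
    "to_bp_coordinates",
    "rescale_positions",
    "residence_histogram",
    "align_trace",
    "count_rips",
    "aggregate_maps",
]

#: second NPS begins at bp 249 of the stem; subtracting this normalizes to it
SECOND_NPS_OFFSET_BP = 248
#: total unzippable bp held fixed by the rescaling map
RESCALE_ANCHOR_BP = 436
#: distance between identical positions on the two tandem NPS copies
NPS_REPEAT_SPACING_BP = 197
#: length of the 601 nucleosome positioning sequence
NPS_LENGTH_BP = 147


@dataclass
class ResidenceMap:
    """Per-base-pair residence statistic over a registered coordinate.

    ``positions`` are bin centers (bp relative to the second NPS start),
    ``values`` either force-weighted residence (pN s) or residence time (s).
    """

    positions: np.ndarray
    values: np.ndarray
    bin_width: float
    mode: str = "force_weighted"      # or "time"
    aggregation: str = "single"       # single | mean | median
    n_traces: int = 1
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.shape != self.values.shape:
            raise ValidationError("positions/values shape mismatch")
        if len(self.positions) > 1 and np.any(np.diff(self.positions) <= 0):
            raise ValidationError("positions must be monotonic increasing")
        if np.any(self.values < -1e-12):
            raise ValidationError("residence values must be >= 0")

    def same_binning(self, other: "ResidenceMap") -> bool:
        return (self.positions.shape == other.positions.shape
                and np.allclose(self.positions, other.positions)
                and np.isclose(self.bin_width, other.bin_width))


def to_bp_coordinates(trace: Trace, comp: TetherComposition,
                      params: PolymerParams | None = None,
                      normalize: bool = True) -> np.ndarray:
    """Per-sample unzipped-bp positions, normalized to the second NPS start.

    Applies the composite-tether inversion sample by sample and subtracts
    248 bp so that position 0 is the first bp of the second NPS.
    """
    if params is None:
        raise ValidationError("elastic parameters are required for bp conversion")
    if trace.protocol not in ("constant_velocity", "constant_force"):
        raise ValidationError(
            f"bp conversion expects a pulling trace, got {trace.protocol!r}")
    n = unzipped_bp(trace.force, trace.extension, comp, params)
    return n - SECOND_NPS_OFFSET_BP if normalize else n


def rescale_positions(positions, factor: float,
                      anchor: float = RESCALE_ANCHOR_BP):
    """Affine stretch of unzipped-bp positions holding the final bp fixed.

    ``N' = anchor - (197/factor) (anchor - N)``.  With the default anchor
    of 436 bp this is the map used to force identical positions on the two
    NPS copies to sit exactly 197 bp apart; factor 197 is the identity.
    For positions already normalized to the second NPS start pass
    ``anchor = 436 - 248 = 188``.
    """
    if factor <= 0:
        raise ValidationError("rescaling factor must be > 0")
    positions = np.asarray(positions, dtype=float)
    return anchor - (NPS_REPEAT_SPACING_BP / factor) * (anchor - positions)


def residence_histogram(positions, force=None, mode: str = "force_weighted",
                        bin_width: float = 1.0, sample_rate: float = 800.0,
                        pos_range: tuple[float, float] | None = None) -> ResidenceMap:
    """Residence map of the fork over position bins.

    ``force_weighted`` sums the forces of all samples falling in a bin and
    divides by the sample rate (units pN s, rate-independent); ``time``
    counts samples over the sample rate (units s).  Bins are half-open
    ``[left, right)``.
    """
    positions = np.asarray(positions, dtype=float)
    if mode not in ("force_weighted", "time"):
        raise ValidationError(f"unknown mode {mode!r}")
    if mode == "force_weighted":
        if force is None:
            raise ValidationError("force array required for force_weighted mode")
        force = np.asarray(force, dtype=float)
        if force.shape != positions.shape:
            raise ValidationError("positions/force shape mismatch")
    if len(positions) == 0:
        return ResidenceMap(np.empty(0), np.empty(0), bin_width, mode=mode)
    if pos_range is None:
        lo = np.floor(positions.min() / bin_width) * bin_width
        hi = np.ceil(positions.max() / bin_width) * bin_width + bin_width
    else:
        lo, hi = pos_range
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    weights = force / sample_rate if mode == "force_weighted" else None
    counts, _ = np.histogram(positions, bins=edges, weights=weights)
    if mode == "time":
        counts = counts / sample_rate
    centers = 0.5 * (edges[:-1] + edges[1:])
    return ResidenceMap(centers, counts.astype(float), bin_width, mode=mode)


def _window_values(rmap: ResidenceMap, lo: float, hi: float) -> np.ndarray:
    sel = (rmap.positions >= lo) & (rmap.positions < hi)
    return rmap.values[sel]


def _interp_at(rmap: ResidenceMap, at: np.ndarray) -> np.ndarray:
    return np.interp(at, rmap.positions, rmap.values, left=0.0, right=0.0)


def align_trace(positions, force, template: ResidenceMap | None = None,
                factor_grid=None, bin_width: float = 0.5,
                sample_rate: float = 800.0,
                first_nps_window: tuple[float, float] = (-197.0, -40.0)):
    """Find the rescaling factor that best registers a trace.

    Parameters
    ----------
    positions : normalized unzipped-bp samples (second-NPS origin)
    force : per-sample forces (pN)
    template : reference residence map of the first NPS built from bare-DNA
        traces.  If None (bare-DNA self-alignment) the trace's own first-NPS
        histogram is correlated against itself shifted by +197 bp.
    factor_grid : candidate stretch factors, default 170..197 step 0.25.

    Returns
    -------
    (best_factor, rescaled_positions, best_correlation)

    The correlation is the raw product sum ``sum_i Res(i) Res(i + 197)``
    (self-alignment) or ``sum_i Res_trace(i) Res_template(i)`` over the
    first-NPS window, evaluated on 0.5-bp bins.
    """
    if factor_grid is None:
        factor_grid = np.arange(170.0, 197.0 + 1e-9, 0.25)
    positions = np.asarray(positions, dtype=float)
    force = np.asarray(force, dtype=float)
    anchor = RESCALE_ANCHOR_BP - SECOND_NPS_OFFSET_BP  # 188 in normalized coords
    lo, hi = first_nps_window
    best = (None, -np.inf)
    for factor in np.asarray(factor_grid, dtype=float):
        resc = rescale_positions(positions, factor, anchor=anchor)
        rmap = residence_histogram(resc, force, mode="force_weighted",
                                   bin_width=bin_width, sample_rate=sample_rate,
                                   pos_range=(lo, hi + NPS_REPEAT_SPACING_BP))
        sel = (rmap.positions >= lo) & (rmap.positions < hi)
        first = rmap.values[sel]
        if template is None:
            partner = _interp_at(rmap, rmap.positions[sel] + NPS_REPEAT_SPACING_BP)
        else:
            partner = _interp_at(template, rmap.positions[sel])
        corr = float(np.dot(first, partner))
        if corr > best[1]:
            best = (float(factor), corr)
    if best[0] is None or best[1] <= 0:
        raise AlignmentError("all-zero residence histograms: cannot align")
    factor, corr = best
    return factor, rescale_positions(positions, factor, anchor=anchor), corr


def count_rips(rmap: ResidenceMap, threshold: float,
               min_separation_bp: float = 3.0):
    """Count unzipping transitions as residence-map peaks above a threshold.

    Peaks are local maxima with value > threshold separated by at least
    ``min_separation_bp``.  Returns (count, peak positions in bp).
    """
    if threshold <= 0:
        raise ValidationError("threshold must be > 0")
    if len(rmap.values) == 0:
        return 0, np.empty(0)
    distance = max(1, int(round(min_separation_bp / rmap.bin_width)))
    idx, _ = find_peaks(rmap.values, height=threshold, distance=distance)
    return len(idx), rmap.positions[idx]


def aggregate_maps(maps, stat: str = "mean") -> ResidenceMap:
    """Element-wise mean or median of identically binned residence maps."""
    maps = list(maps)
    if not maps:
        raise ValidationError("no maps to aggregate")
    first = maps[0]
    for m in maps[1:]:
        if not first.same_binning(m):
            raise ValidationError("residence maps have mismatched binning")
    stack = np.vstack([m.values for m in maps])
    if stat == "mean":
        vals = stack.mean(axis=0)
    elif stat == "median":
        vals = np.median(stack, axis=0)
    else:
        raise ValidationError(f"unknown aggregation statistic {stat!r}")
    return ResidenceMap(first.positions.copy(), vals, first.bin_width,
                        mode=first.mode, aggregation=stat, n_traces=len(maps))
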