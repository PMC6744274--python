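"""Equilibrium hopping analysis: Boltzmann inversion and stitching."""

import numpy as np
import pytest

from nucbarrier.exceptions import ValidationError
from nucbarrier.hopping import (EnergyLandscape, TrapModel, UnzipDistribution,
                                equilibrium_pulling_curve, force_at_separation,
                                interaction_profile, landscape_segment,
                                mechanical_energy, stitch_segments,
                                unzip_distribution)
from nucbarrier.polymer import tether_extension
from nucbarrier.trace import Trace


def trace_from_states(n_states, comp, params, sep=None, trap=None,
                      rate=2500.0):
    """Noise-free fixed-separation trace visiting the given integer N."""
    n_states = np.asarray(n_states)
    if sep is None:
        forces = np.full(len(n_states), 17.0)
        ext = np.array([tether_extension(17.0, comp.with_unzipped(n), params)
                        for n in n_states])
    else:
        forces = np.array([force_at_separation(int(n), sep, comp, params,
                                               trap) for n in n_states])
        ext = sep - forces / trap.series_stiffness
    t = np.arange(len(n_states)) / rate
    return Trace(time=t, force=forces, extension=ext, sample_rate=rate,
                 protocol="fixed_separation",
                 metadata={"separation_nm": sep if sep else float("nan")})


def sep_for(n_center, f0, comp, params, trap):
    return (tether_extension(f0, comp.with_unzipped(n_center), params)
            + f0 / trap.series_stiffness)


class TestUnzipDistribution:
    def test_point_mass(self, hopping_comp, hopping_params):
        tr = trace_from_states([260] * 50, hopping_comp, hopping_params)
        d = unzip_distribution(tr, hopping_comp, hopping_params)
        assert d.p.max() == pytest.approx(1.0)
        assert d.n[np.argmax(d.p)] == 260

    def test_equal_two_state_occupancy(self, hopping_comp, hopping_params):
        tr = trace_from_states([255, 265] * 100, hopping_comp, hopping_params)
        d = unzip_distribution(tr, hopping_comp, hopping_params)
        assert d.p[d.n == 255] == pytest.approx(0.5)
        assert d.p[d.n == 265] == pytest.approx(0.5)

    def test_normalization(self, hopping_comp, hopping_params):
        rng = np.random.default_rng(0)
        tr = trace_from_states(rng.integers(250, 270, 500), hopping_comp,
                               hopping_params)
        d = unzip_distribution(tr, hopping_comp, hopping_params)
        assert d.p.sum() == pytest.approx(1.0)

    def test_empty_trace_rejected(self, hopping_comp, hopping_params):
        with pytest.raises(ValidationError):
            tr = Trace(time=[], force=[], extension=[],
                       protocol="fixed_separation")
            unzip_distribution(tr, hopping_comp, hopping_params)


class TestLandscapeSegment:
    def test_boltzmann_difference(self, hopping_comp, hopping_params, trap):
        """Per-bp energy = -ln(P ratio) minus the mechanical-energy
        difference of the two states at the fixed separation."""
        sep = sep_for(260, 17.0, hopping_comp, hopping_params, trap)
        p_ratio = np.exp(-2.0)
        d = UnzipDistribution(np.array([260, 261]),
                              np.array([1.0, p_ratio]) / (1.0 + p_ratio),
                              separation=sep)
        seg = landscape_segment(d, trap, hopping_comp, hopping_params)
        mech = (mechanical_energy(261, sep, hopping_comp, hopping_params, trap)
                - mechanical_energy(260, sep, hopping_comp, hopping_params,
                                    trap))
        assert seg.per_bp_energy[0] == pytest.approx(2.0 - mech, abs=1e-9)

    def test_interior_gap_masked_not_interpolated(self, hopping_comp,
                                                  hopping_params, trap):
        sep = sep_for(260, 17.0, hopping_comp, hopping_params, trap)
        d = UnzipDistribution(np.array([259, 260, 261]),
                              np.array([0.5, 0.0, 0.5]), separation=sep)
        seg = landscape_segment(d, trap, hopping_comp, hopping_params)
        assert np.isnan(seg.per_bp_energy).all()

    def test_needs_two_states(self, hopping_comp, hopping_params, trap):
        d = UnzipDistribution(np.array([260]), np.array([1.0]),
                              separation=950.0)
        with pytest.raises(ValidationError):
            landscape_segment(d, trap, hopping_comp, hopping_params)


class TestStitchSegments:
    def _seg(self, n0, values):
        vals = np.asarray(values, float)
        return EnergyLandscape(positions=np.arange(n0, n0 + len(vals)),
                               per_bp_energy=vals)

    def test_single_segment_identity(self):
        seg = self._seg(10, [1.0, 2.0, 3.0])
        st = stitch_segments([seg])
        assert np.allclose(st.per_bp_energy, seg.per_bp_energy)

    def test_exact_overlap_unchanged(self):
        st = stitch_segments([self._seg(10, [1, 2, 3]),
                              self._seg(11, [2, 3, 4])])
        assert np.allclose(st.per_bp_energy, [1, 2, 3, 4])
        assert list(st.support_counts) == [1, 2, 2, 1]

    def test_symmetric_offsets_average_out(self):
        d = 0.4
        st = stitch_segments([self._seg(10, np.array([1, 2, 3]) + d),
                              self._seg(10, np.array([1, 2, 3]) - d)])
        assert np.allclose(st.per_bp_energy, [1, 2, 3])

    def test_disjoint_gap_flagged_missing(self):
        st = stitch_segments([self._seg(10, [1, 2]), self._seg(15, [5, 6])])
        gap = (st.positions > 11) & (st.positions < 15)
        assert np.isnan(st.per_bp_energy[gap]).all()
        assert (st.support_counts[gap] == 0).all()


class TestInteractionProfile:
    def _land(self, n0, values):
        return EnergyLandscape(positions=np.arange(n0, n0 + len(values)),
                               per_bp_energy=np.asarray(values, float))

    def test_identical_landscapes_give_zero(self):
        a = self._land(5, [1.0, 2.0, 3.0])
        b = self._land(5, [1.0, 2.0, 3.0])
        prof = interaction_profile(a, b)
        assert np.allclose(prof.per_bp_energy, 0.0)
        assert prof.provenance == "interaction"

    def test_no_overlap_rejected(self):
        with pytest.raises(ValidationError):
            interaction_profile(self._land(0, [1.0, 1.0]),
                                self._land(10, [1.0, 1.0]))

    def test_masked_bps_never_contribute(self):
        nuc = self._land(5, [1.0, np.nan, 3.0])
        bare = self._land(5, [0.5, 0.5, 0.5])
        prof = interaction_profile(nuc, bare)
        assert np.isnan(prof.per_bp_energy[1])
        assert prof.support_counts[1] == 0


@pytest.fixture(scope="module")
def closure(hopping_comp, hopping_params, trap):
    from nucbarrier.synth import LandscapeSpec, gen_hopping_trace, \
        gen_landscape

    peaks = [(248 + p, h, 2.5) for p, h in
             [(17, 3.0), (26, 3.0), (31, 3.5), (35, 3.0)]]
    bare = gen_landscape(LandscapeSpec())
    nuc = gen_landscape(LandscapeSpec(peaks=peaks))
    segs_nuc, segs_bare = [], []
    for i, nc in enumerate(range(244, 296, 10)):
        sep = sep_for(nc, 16.5, hopping_comp, hopping_params, trap)
        for land, segs, seed in ((nuc, segs_nuc, 10 + i),
                                 (bare, segs_bare, 50 + i)):
            tr = gen_hopping_trace(land, sep, hopping_comp,
                                   hopping_params, trap, duration=40.0,
                                   seed=seed)
            d = unzip_distribution(tr, hopping_comp, hopping_params)
            segs.append(landscape_segment(d, trap, hopping_comp,
                                          hopping_params, min_prob=1e-3))
    return (gen_landscape(LandscapeSpec()), nuc,
            stitch_segments(segs_bare), stitch_segments(segs_nuc))

class TestInversionClosure:
    """Generate hopping traces from a known landscape and invert them
    back; the stitched per-bp energies must recover the truth."""

    def test_landscape_rms_recovery(self, closure):
        bare_true, nuc_true, bare_est, nuc_est = closure
        sel = nuc_est.support_counts > 0
        truth = nuc_true.per_bp_energy[
            np.searchsorted(nuc_true.positions, nuc_est.positions[sel])]
        rms = np.sqrt(np.mean((nuc_est.per_bp_energy[sel] - truth) ** 2))
        assert rms < 0.25

    def test_interaction_profile_recovery(self, closure):
        bare_true, nuc_true, bare_est, nuc_est = closure
        prof = interaction_profile(nuc_est, bare_est)
        sel = np.isfinite(prof.per_bp_energy)
        truth = (nuc_true.per_bp_energy - bare_true.per_bp_energy)[
            np.searchsorted(nuc_true.positions, prof.positions[sel])]
        err = prof.per_bp_energy[sel] - truth
        # mean absolute error per bp within the stated budget
        assert np.mean(np.abs(err)) < 0.3
        # each injected barrier appears as a local maximum at its position
        pos_rel = prof.positions[sel] - 248
        vals = prof.per_bp_energy[sel]
        for peak in (17, 26, 31):
            window = (pos_rel >= peak - 4) & (pos_rel <= peak + 4)
            if window.sum() < 3:
                continue  # outside the sampled hopping range
            local = pos_rel[window][np.argmax(vals[window])]
            assert abs(local - peak) <= 2, (peak, local)

    def test_error_decreases_with_samples(self, hopping_comp, hopping_params,
                                          trap):
        from nucbarrier.synth import LandscapeSpec, gen_hopping_trace, \
            gen_landscape

        land = gen_landscape(LandscapeSpec())
        sep = sep_for(260, 16.5, hopping_comp, hopping_params, trap)
        errs = []
        for dur in (4.0, 40.0):
            tr = gen_hopping_trace(land, sep, hopping_comp, hopping_params,
                                   trap, duration=dur, seed=77)
            d = unzip_distribution(tr, hopping_comp, hopping_params)
            seg = landscape_segment(d, trap, hopping_comp, hopping_params,
                                    min_prob=5e-3)
            sel = np.isfinite(seg.per_bp_energy)
            truth = land.per_bp_energy[
                np.searchsorted(land.positions, seg.positions[sel])]
            errs.append(np.sqrt(np.mean((seg.per_bp_energy[sel] - truth) ** 2)))
        assert errs[1] < errs[0]


class TestDetailedBalance:
    def test_edge_fluxes_balance(self, hopping_comp, hopping_params, trap):
        """At equilibrium the number of N -> N+1 and N+1 -> N transitions
        across any edge agree within counting error."""
        from nucbarrier.synth import LandscapeSpec, gen_hopping_trace, \
            gen_landscape

        land = gen_landscape(LandscapeSpec())
        sep = sep_for(260, 16.5, hopping_comp, hopping_params, trap)
        tr = gen_hopping_trace(land, sep, hopping_comp, hopping_params, trap,
                               duration=20.0, seed=5,
                               attempt_rate=2e4)
        from nucbarrier.polymer import unzipped_bp

        n = np.rint(unzipped_bp(tr.force, tr.extension, hopping_comp,
                                hopping_params)).astype(int)
        steps = np.diff(n)
        up = (steps > 0).sum()
        down = (steps < 0).sum()
        assert abs(up - down) <= 4 * np.sqrt(up + down + 1)


class TestEquilibriumPullingCurve:
    def test_deep_single_well_equals_fixed_n_curve(self, hopping_comp,
                                                   hopping_params, trap):
        # a deep well at N = 260 pins the ensemble
        per_bp = np.full(434, 2.5)
        per_bp[259] = -30.0  # huge drop into N=260
        per_bp[260] = 35.0   # and a huge wall after it
        land = EnergyLandscape(positions=np.arange(1, 435),
                               per_bp_energy=per_bp)
        sep = sep_for(260, 16.5, hopping_comp, hopping_params, trap)
        f, x = equilibrium_pulling_curve(land, [sep], trap, hopping_comp,
                                         hopping_params)
        f_fixed = force_at_separation(260, sep, hopping_comp, hopping_params,
                                      trap)
        assert f[0] == pytest.approx(f_fixed, abs=1e-6)

    def test_matches_generator_time_average(self, hopping_comp,
                                            hopping_params, trap):
        from nucbarrier.synth import LandscapeSpec, gen_hopping_trace, \
            gen_landscape

        land = gen_landscape(LandscapeSpec())
        full = EnergyLandscape(positions=land.positions,
                               per_bp_energy=land.per_bp_energy)
        sep = sep_for(255, 16.5, hopping_comp, hopping_params, trap)
        f, _ = equilibrium_pulling_curve(full, [sep], trap, hopping_comp,
                                         hopping_params)
        tr = gen_hopping_trace(land, sep, hopping_comp, hopping_params, trap,
                               duration=20.0, seed=21)
        assert f[0] == pytest.approx(tr.force.mean(), abs=0.05)

    def test_uniform_energy_shift_raises_plateau_force(self, hopping_comp,
                                                       hopping_params, trap):
        base = np.full(434, 2.5)
        low = EnergyLandscape(positions=np.arange(1, 435), per_bp_energy=base)
        high = EnergyLandscape(positions=np.arange(1, 435),
                               per_bp_energy=base + 1.0)
        sep = sep_for(260, 16.5, hopping_comp, hopping_params, trap)
        f_low, _ = equilibrium_pulling_curve(low, [sep], trap, hopping_comp,
                                             hopping_params)
        f_high, _ = equilibrium_pulling_curve(high, [sep], trap, hopping_comp,
                                              hopping_params)
        assert f_high[0] > f_low[0]

    def test_incomplete_landscape_rejected(self, hopping_comp, hopping_params,
                                           trap):
        land = EnergyLandscape(positions=np.arange(255, 266),
                               per_bp_energy=np.full(11, 2.5))
        sep = sep_for(265, 16.5, hopping_comp, hopping_params, trap)
        with pytest.raises(ValidationError, match="separation"):
            equilibrium_pulling_curve(land, [sep], trap, hopping_comp,
                                      hopping_params)
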