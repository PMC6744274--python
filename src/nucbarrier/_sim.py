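"""Numba kernels for event-driven stochastic simulation.

Two exact SSA loops: the Pol II (position, backtrack-depth) walk with
position-dependent effective rates, and the unzipping-fork birth-death
walk on a total-energy table (landscape + tether stretch + trap), used for
hopping and pulling trace generation.  Rates are piecewise constant
between uniform sample instants, which is exact for fixed conditions and
refreshes moving-trap rates at the sampling rate.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def polii_ssa(k0, kb1, kf, kb, grid0, j_start, j_end, q_max,
              t_max, sample_rate, n_samples, seed):
    """Simulate one Pol II trajectory; returns (arrivals, samples, n, crossed).

    Rate arrays are indexed by ``j - grid0``.  ``arrivals[i]`` is the first
    time main-pathway position ``j_start + i`` is reached (NaN if never).
    ``samples`` holds the physical position (p - q) at uniform times when
    ``sample_rate > 0``.
    """
    np.random.seed(seed)
    n_pos = j_end - j_start + 1
    arrivals = np.full(n_pos, np.nan)
    arrivals[0] = 0.0
    samples = np.zeros(n_samples)
    p = j_start
    q = 0
    t = 0.0
    k_sample = 0
    crossed = False
    while t < t_max:
        if q == 0:
            i = p - grid0
            r_fwd = k0[i]
            r_bwd = kb1[i]
        else:
            i = p - q - grid0
            r_fwd = kf[i]
            r_bwd = kb[i] if q < q_max else 0.0
        total = r_fwd + r_bwd
        if total <= 0.0:
            break
        dt = -np.log(np.random.random()) / total
        t_new = t + dt
        if sample_rate > 0.0:
            while k_sample < n_samples and k_sample / sample_rate <= min(t_new, t_max):
                samples[k_sample] = p - q
                k_sample += 1
        if t_new >= t_max:
            t = t_max
            break
        t = t_new
        if np.random.random() * total < r_fwd:
            if q == 0:
                p += 1
                idx = p - j_start
                if np.isnan(arrivals[idx]):
                    arrivals[idx] = t
                if p >= j_end:
                    crossed = True
                    break
            else:
                q -= 1
        else:
            q += 1
    # hold the final position for any remaining samples
    while k_sample < n_samples:
        samples[k_sample] = p - q
        k_sample += 1
    return arrivals, samples, n_samples, crossed


@njit(cache=True)
def passage_times_chain(k0, kb1, kf, kb, q_max, n_repeats, seed):
    """First-passage times of the 4-state backtrack chain at one position.

    Scalar rates; returns ``n_repeats`` independent passage times from the
    on-pathway state to the next position — the stochastic oracle for the
    analytic mean-dwell computation.
    """
    np.random.seed(seed)
    out = np.empty(n_repeats)
    for rep in range(n_repeats):
        t = 0.0
        q = 0
        while True:
            if q == 0:
                r_fwd = k0
                r_bwd = kb1
            else:
                r_fwd = kf
                r_bwd = kb if q < q_max else 0.0
            total = r_fwd + r_bwd
            t += -np.log(np.random.random()) / total
            if np.random.random() * total < r_fwd:
                if q == 0:
                    break
                q -= 1
            else:
                q += 1
        out[rep] = t
    return out


@njit(cache=True)
def fork_ssa(a_table, n_max, d0, velocity, d_grid0, d_step,
             t_max, sample_rate, n_samples, attempt, n_init, seed):
    """Unzipping-fork walk on a (N, separation) total-energy table.

    ``a_table`` has shape (n_max + 1, n_d); energies in kBT on a uniform
    separation grid starting at ``d_grid0`` with spacing ``d_step``
    (``n_d = 1`` for separation-independent protocols).  Transition rates
    are Metropolis, ``attempt * min(1, exp(-dA))``, which satisfies
    detailed balance with respect to the table.  Returns integer fork
    positions at uniform sample instants.
    """
    np.random.seed(seed)
    n_d = a_table.shape[1]
    samples = np.zeros(n_samples, dtype=np.int64)
    n = n_init
    t = 0.0
    k_sample = 0

    while k_sample < n_samples:
        # energy lookup at current separation
        if n_d == 1:
            a_here = a_table[n, 0]
            a_up = a_table[n + 1, 0] if n < n_max else 1e30
            a_dn = a_table[n - 1, 0] if n > 0 else 1e30
        else:
            d = d0 + velocity * t
            x = (d - d_grid0) / d_step
            i = int(x)
            if i < 0:
                i = 0
            if i > n_d - 2:
                i = n_d - 2
            frac = x - i
            if frac < 0.0:
                frac = 0.0
            if frac > 1.0:
                frac = 1.0
            a_here = a_table[n, i] * (1 - frac) + a_table[n, i + 1] * frac
            a_up = (a_table[n + 1, i] * (1 - frac) + a_table[n + 1, i + 1] * frac
                    if n < n_max else 1e30)
            a_dn = (a_table[n - 1, i] * (1 - frac) + a_table[n - 1, i + 1] * frac
                    if n > 0 else 1e30)
        da_up = a_up - a_here
        da_dn = a_dn - a_here
        k_up = attempt * (np.exp(-da_up) if da_up > 0 else 1.0)
        k_dn = attempt * (np.exp(-da_dn) if da_dn > 0 else 1.0)
        total = k_up + k_dn
        t_next_sample = k_sample / sample_rate
        if total <= 0.0:
            t = t_next_sample
            samples[k_sample] = n
            k_sample += 1
            continue
        dt = -np.log(np.random.random()) / total
        # refresh rates at least once per sample interval (moving trap)
        horizon = t_next_sample
        if t + dt >= horizon:
            t = horizon
            samples[k_sample] = n
            k_sample += 1
            continue
        t += dt
        if np.random.random() * total < k_up:
            n += 1
        else:
            n -= 1
        if t >= t_max:
            break
    while k_sample < n_samples:
        samples[k_sample] = n
        k_sample += 1
    return samples
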