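"""Numba direct-method kernel for the nucleation simulator.

Implements the same stochastic process as the pure-Python first-reaction
driver in :mod:`gturcsim.engine` using the mathematically equivalent direct
(total-propensity) formulation: draw one Exp(ΣK) waiting time, then pick a
channel with probability k_i/ΣK.  All rates are recomputed from the state
after every event; channel order (closure, associations, dissociations) is
identical in the summation and the selection pass so the two walks agree
bit-for-bit.

Lateral-bond bookkeeping matches the lattice module: non-seam neighbours
pair same layers at weight 1; across the seam the dimer at layer i on the
last protofilament half-overlaps layers i and i+1 on protofilament 0
(weight 0.5 each).  In the open conformation no lateral bonds exist.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["run_kmc"]


@njit(cache=True)
def _prospective_weight(h, n_pf, half_seam):
    if n_pf == 1:
        return 0.0
    total = 0.0
    for p in range(n_pf - 1):
        total += min(h[p], h[p + 1])
    last = n_pf - 1
    if half_seam:
        total += 0.5 * min(h[last], h[0])
        total += 0.5 * min(h[last], max(h[0] - 1, 0))
    else:
        total += min(h[last], h[0])
    return total


@njit(cache=True)
def _lateral_weight(h, n_pf, half_seam, p, L):
    """Lateral contact weight of the occupied site (p, L) in the closed
    conformation; 0.5-resolution is carried as an integer count of halves."""
    if n_pf == 1:
        return 0.0
    last = n_pf - 1
    w = 0.0
    # left neighbour
    if p == 0:
        if half_seam:
            if h[last] >= L:
                w += 0.5
            if L - 1 >= 1 and h[last] >= L - 1:
                w += 0.5
        else:
            if h[last] >= L:
                w += 1.0
    else:
        if h[p - 1] >= L:
            w += 1.0
    # right neighbour
    if p == last:
        if half_seam:
            if h[0] >= L:
                w += 0.5
            if h[0] >= L + 1:
                w += 0.5
        else:
            if h[0] >= L:
                w += 1.0
    else:
        if h[p + 1] >= L:
            w += 1.0
    return w


@njit(cache=True)
def _run_core(
    n_pf,
    half_seam,
    rise,
    k_on,
    dg_ab,
    dg_lat,
    dg_gamma,
    dg_conf,
    k_conf,
    literal_sign,
    conc_M,
    t_max,
    length_max,
    seed_mode,
    nucl_length,
    stop_after_nucl,
    terminal_only,
    tallest_criterion,
    max_height,
    seed,
    trace_t,
    trace_sum,
):
    np.random.seed(seed)
    h = np.zeros(n_pf, dtype=np.int64)
    closed = seed_mode  # seed mode starts from a closed template
    t = 0.0
    nucl_time = np.inf
    closure_h = np.zeros(n_pf, dtype=np.int64)
    closure_n = -1.0
    n_events = 0
    S = 0  # total dimers
    maxh = 0  # tallest protofilament (first-passage record)
    k_assoc = k_on * conc_M
    # koff lookup by half-lateral-weight index 0..4 (0, 0.5, 1, 1.5, 2)
    koff_gamma = np.empty(5)
    koff_ab = np.empty(5)
    for i in range(5):
        koff_gamma[i] = k_on * np.exp(dg_gamma + 0.5 * i * dg_lat)
        koff_ab[i] = k_on * np.exp(dg_ab + 0.5 * i * dg_lat)
    lat_sign = dg_lat if literal_sign else -abs(dg_lat)
    n_lat = 0.0
    sum_max = length_max / rise * n_pf
    nucl_sum = nucl_length / rise * n_pf
    ktr = 0
    ntr = trace_t.shape[0]

    while True:
        # ---- pass 1: total propensity (order: closure, assoc, dissoc) ----
        R = 0.0
        k_close = 0.0
        if not closed:
            n_lat = _prospective_weight(h, n_pf, half_seam)
            barrier = dg_conf + n_lat * lat_sign
            k_close = k_conf * np.exp(-barrier)
            R += k_close
        for p in range(n_pf):
            if max_height == 0 or h[p] < max_height:
                R += k_assoc
        for p in range(n_pf):
            hp = h[p]
            if hp == 0:
                continue
            if terminal_only:
                if closed:
                    w = _lateral_weight(h, n_pf, half_seam, p, hp)
                    R += koff_gamma[int(2.0 * w)] if hp == 1 else koff_ab[int(2.0 * w)]
                else:
                    R += koff_gamma[0] if hp == 1 else koff_ab[0]
            else:
                if closed:
                    for L in range(1, hp + 1):
                        w = _lateral_weight(h, n_pf, half_seam, p, L)
                        R += koff_gamma[int(2.0 * w)] if L == 1 else koff_ab[int(2.0 * w)]
                else:
                    R += koff_gamma[0] + (hp - 1) * koff_ab[0]

        if R <= 0.0:
            # absorbing state: nothing can ever happen again
            while ktr < ntr and trace_t[ktr] <= t_max:
                trace_sum[ktr] = S
                ktr += 1
            t = t_max
            break

        u = np.random.random()
        while u <= 0.0:
            u = np.random.random()
        dt = -np.log(u) / R
        if t + dt >= t_max:
            while ktr < ntr and trace_t[ktr] <= t_max:
                trace_sum[ktr] = S
                ktr += 1
            t = t_max
            break
        # record trace samples falling inside (t, t+dt] with the pre-event state
        while ktr < ntr and trace_t[ktr] <= t + dt:
            trace_sum[ktr] = S
            ktr += 1
        t = t + dt

        # ---- pass 2: channel selection, identical order ----
        target = np.random.random() * R
        acc = 0.0
        done = False
        if not closed:
            acc += k_close
            if target < acc:
                closed = True
                if not seed_mode and nucl_time == np.inf:
                    nucl_time = t
                    for p in range(n_pf):
                        closure_h[p] = h[p]
                    closure_n = n_lat
                done = True
        if not done:
            for p in range(n_pf):
                if max_height == 0 or h[p] < max_height:
                    acc += k_assoc
                    if target < acc:
                        h[p] += 1
                        S += 1
                        if h[p] > maxh:
                            maxh = h[p]
                        done = True
                        break
        if not done:
            for p in range(n_pf):
                hp = h[p]
                if hp == 0:
                    continue
                if terminal_only:
                    if closed:
                        w = _lateral_weight(h, n_pf, half_seam, p, hp)
                        acc += koff_gamma[int(2.0 * w)] if hp == 1 else koff_ab[int(2.0 * w)]
                    else:
                        acc += koff_gamma[0] if hp == 1 else koff_ab[0]
                    if target < acc:
                        S -= hp - (hp - 1)
                        h[p] = hp - 1
                        done = True
                        break
                else:
                    hit_layer = 0
                    if closed:
                        for L in range(1, hp + 1):
                            w = _lateral_weight(h, n_pf, half_seam, p, L)
                            acc += koff_gamma[int(2.0 * w)] if L == 1 else koff_ab[int(2.0 * w)]
                            if target < acc:
                                hit_layer = L
                                break
                    else:
                        acc += koff_gamma[0]
                        if target < acc:
                            hit_layer = 1
                        else:
                            # uniform over the hp-1 identical upper channels
                            rem = target - acc
                            block = (hp - 1) * koff_ab[0]
                            if rem < block:
                                hit_layer = 2 + int(rem / koff_ab[0])
                                if hit_layer > hp:
                                    hit_layer = hp
                                acc += block
                            else:
                                acc += block
                    if hit_layer > 0:
                        S -= hp - (hit_layer - 1)
                        h[p] = hit_layer - 1
                        done = True
                        break
                if done:
                    break
        if not done:
            # floating-point residue in the walk: execute the last channel
            # of the selection order (top dissociation of the last occupied
            # protofilament, else the last association, else closure)
            for p in range(n_pf - 1, -1, -1):
                if h[p] > 0:
                    h[p] -= 1
                    S -= 1
                    done = True
                    break
            if not done:
                for p in range(n_pf - 1, -1, -1):
                    if max_height == 0 or h[p] < max_height:
                        h[p] += 1
                        S += 1
                        done = True
                        break
            if not done and not closed:
                closed = True
                if not seed_mode and nucl_time == np.inf:
                    nucl_time = t
                    for p in range(n_pf):
                        closure_h[p] = h[p]
                    closure_n = _prospective_weight(h, n_pf, half_seam)

        n_events += 1

        if seed_mode and nucl_time == np.inf:
            reached = (maxh * rise >= nucl_length) if tallest_criterion else (S >= nucl_sum)
        else:
            reached = False
        if seed_mode and nucl_time == np.inf and reached:
            nucl_time = t
            if stop_after_nucl:
                break
        if (not seed_mode) and stop_after_nucl and nucl_time < np.inf:
            break
        if S >= sum_max:
            break

    return nucl_time, t, closure_h, closure_n, n_events


def run_kmc(
    *,
    n_pf,
    half_seam,
    rise,
    k_on,
    dg_ab,
    dg_lat,
    dg_gamma,
    dg_conf,
    k_conf,
    literal_sign,
    conc_M,
    t_max,
    length_max,
    seed_mode,
    nucl_length,
    stop_after_nucl,
    terminal_only,
    tallest_criterion,
    max_height,
    seed,
    trace_t,
):
    trace_sum = np.full(trace_t.shape[0], -1, dtype=np.int64)
    nucl_time, t_end, closure_h, closure_n, n_events = _run_core(
        np.int64(n_pf),
        bool(half_seam),
        float(rise),
        float(k_on),
        float(dg_ab),
        float(dg_lat),
        float(dg_gamma),
        float(dg_conf),
        float(k_conf),
        bool(literal_sign),
        float(conc_M),
        float(t_max),
        float(length_max),
        bool(seed_mode),
        float(nucl_length),
        bool(stop_after_nucl),
        bool(terminal_only),
        bool(tallest_criterion),
        np.int64(max_height),
        np.int64(seed),
        trace_t.astype(np.float64),
        trace_sum,
    )
    return nucl_time, t_end, closure_h, closure_n, n_events, trace_sum
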