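"""Independent brute-force oracles used only by the test suite.

The dip oracle evaluates Hartigan's definition directly: for each candidate
mode position it solves a small linear program for the closest cdf that is
convex left of the mode and concave right of it (an atom permitted at the
mode), and minimizes the sup-norm distance to the empirical cdf.  It shares
no code with the package implementation.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import linprog


def dip_bruteforce(samples) -> float:
    """Dip via LP minimization over unimodal cdfs, enumerating mode positions."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    v = np.unique(x)
    if v.size == 1:
        return 0.0
    counts = np.searchsorted(x, v, side="right")
    F = counts / n  # F(v_j); F just left of v_j is F[j-1] (0 for j=0)

    modes = list(v)
    modes += [0.5 * (a + b) for a, b in zip(v[:-1], v[1:])]
    modes += [v[0] - 1.0, v[-1] + 1.0]

    best = np.inf
    for m in modes:
        val = _dip_lp_for_mode(v, F, m)
        if val is not None:
            best = min(best, val)
    return float(best)


def _dip_lp_for_mode(v, F, m) -> float | None:
    knots = np.unique(np.concatenate([v, [m]]))
    p = knots.size
    mi = int(np.searchsorted(knots, m))
    # variables: g_0..g_{p-1} (G at knots), gl (left limit at the mode), t
    ngl = p
    nt = p + 1
    nvar = p + 2
    A, b = [], []

    def row(pairs, rhs):
        r = np.zeros(nvar)
        for j, c in pairs:
            r[j] += c
        A.append(r)
        b.append(rhs)

    def left_value_index(i):
        # G(knots[i]^-): the jump is only allowed at the mode
        return ngl if i == mi else i

    # monotonicity with gl inserted just before g_mi
    seq = list(range(0, mi)) + [ngl, mi] + list(range(mi + 1, p))
    for a1, a2 in zip(seq[:-1], seq[1:]):
        row([(a1, 1.0), (a2, -1.0)], 0.0)
    # bounds handled via variable bounds [0, 1]

    # convexity on knots <= mode (left-limit value at the mode itself)
    lidx = [(knots[i], i) for i in range(0, mi)] + [(m, ngl)]
    for (xa, ia), (xb, ib), (xc, ic) in zip(lidx[:-2], lidx[1:-1], lidx[2:]):
        # slope(a,b) <= slope(b,c)
        row(
            [(ib, (xc - xa)), (ia, -(xc - xb)), (ic, -(xb - xa))],
            0.0,
        )
    # concavity on knots >= mode (right value at the mode)
    ridx = [(m, mi)] + [(knots[i], i) for i in range(mi + 1, p)]
    for (xa, ia), (xb, ib), (xc, ic) in zip(ridx[:-2], ridx[1:-1], ridx[2:]):
        row(
            [(ib, -(xc - xa)), (ia, (xc - xb)), (ic, (xb - xa))],
            0.0,
        )

    def F_at(xq):
        j = int(np.searchsorted(v, xq, side="right")) - 1
        return 0.0 if j < 0 else F[j]

    def F_left(xq):
        j = int(np.searchsorted(v, xq, side="left")) - 1
        return 0.0 if j < 0 else F[j]

    # sup-norm constraints at knots and their left limits
    for i in range(p):
        fi = F_at(knots[i])
        row([(i, 1.0), (nt, -1.0)], fi)    # g_i - t <= F_i
        row([(i, -1.0), (nt, -1.0)], -fi)  # -g_i - t <= -F_i
        fl = F_left(knots[i])
        li = left_value_index(i)
        row([(li, 1.0), (nt, -1.0)], fl)
        row([(li, -1.0), (nt, -1.0)], -fl)
    # tails
    row([(left_value_index(0), 1.0), (nt, -1.0)], 0.0)   # limit left of first knot
    row([(p - 1, -1.0), (nt, -1.0)], -1.0)               # 1 - g_last <= t

    c = np.zeros(nvar)
    c[nt] = 1.0
    bounds = [(0.0, 1.0)] * (p + 1) + [(0.0, 1.0)]
    res = linprog(c, A_ub=np.array(A), b_ub=np.array(b), bounds=bounds, method="highs")
    if not res.success:
        return None
    return float(res.fun)


def all_small_samples(max_n=8, values=(0.0, 1.0, 2.0), min_n=4):
    """Every sorted multiset of the given values with min_n <= n <= max_n."""
    for n in range(min_n, max_n + 1):
        for comb in itertools.combinations_with_replacement(values, n):
            yield np.array(comb, dtype=float)


def lif_isi_closed_form(i_pa, r_mohm, gain, tau_m, v_rest, v_thr, v_reset, refractory_ms):
    """Closed-form interspike interval (ms) of a LIF neuron under constant current."""
    drive = r_mohm * gain * i_pa * 1e-3  # mV
    if drive <= (v_thr - v_rest):
        return np.inf
    t = tau_m * np.log((drive - (v_reset - v_rest)) / (drive - (v_thr - v_rest)))
    return t + refractory_ms
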