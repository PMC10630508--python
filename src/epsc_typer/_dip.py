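"""Hartigan & Hartigan dip statistic of unimodality, with the modal interval.

The dip of a sample is the smallest sup-norm distance between its empirical
cdf and any unimodal cdf (convex up to the mode, concave after, an atom
permitted at the mode).  The algorithm below follows the classical
greatest-convex-minorant / least-concave-majorant iteration: the candidate
modal interval ``[x_lo, x_hi]`` is shrunk until the gap between the two
hulls inside it is explained by the deviations already committed outside
it; the dip is half the largest committed deviation.

Only the sorted sample is needed; ties are handled exactly, which matters
because event features can repeat after rounding.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["dip_statistic", "DipResult"]


class DipResult:
    """Dip statistic plus the modal interval that attains it.

    Attributes
    ----------
    dip : float
        The dip statistic, in ``[0, 0.25]``.
    modal_interval : tuple of float
        ``(lo, hi)`` endpoints (data values) of the modal interval.
    """

    __slots__ = ("dip", "modal_interval")

    def __init__(self, dip: float, modal_interval: tuple[float, float]):
        self.dip = dip
        self.modal_interval = modal_interval

    def __iter__(self):
        return iter((self.dip, self.modal_interval))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        lo, hi = self.modal_interval
        return f"DipResult(dip={self.dip:.6g}, modal_interval=({lo:.6g}, {hi:.6g}))"


def _hull_lower(xs: np.ndarray, ys: np.ndarray, idx: np.ndarray) -> list[int]:
    """Monotone-chain lower convex hull; returns positions into ``idx``."""
    hull: list[int] = []
    for p in range(len(idx)):
        i = idx[p]
        while len(hull) >= 2:
            a, b = idx[hull[-2]], idx[hull[-1]]
            # pop b when slope(a,b) > slope(b,i): b lies above chord a->i
            if (ys[b] - ys[a]) * (xs[i] - xs[b]) > (ys[i] - ys[b]) * (xs[b] - xs[a]):
                hull.pop()
            else:
                break
        hull.append(p)
    return hull


def dip_statistic(samples: np.ndarray) -> DipResult:
    """Compute Hartigan's dip and modal interval of a 1-D sample.

    Parameters
    ----------
    samples : array-like
        At least 4 finite values.

    Returns
    -------
    DipResult
        ``dip`` in ``[0, 0.25]`` and the modal interval ``(lo, hi)``.

    Raises
    ------
    ValueError
        If fewer than 4 values, or any value is not finite.
    """
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n < 4:
        raise ValueError(f"dip statistic needs at least 4 samples, got {n}")
    if not np.all(np.isfinite(x)):
        raise ValueError("dip statistic requires finite samples")
    if x[0] == x[-1]:
        warnings.warn("all samples equal; dip is degenerate (0)", stacklevel=2)
        return DipResult(0.0, (float(x[0]), float(x[0])))

    # cdf corner heights: lower corners for the convex side, upper for concave
    y_lo = (np.arange(n)) / n          # F(x_i^-) = (i-1)/n, 0-based i
    y_hi = (np.arange(n) + 1.0) / n    # F(x_i)   = i/n

    # representatives per distinct x: first index for the lower hull
    # (smallest corner), last index for the upper hull (largest corner)
    low, high = 0, n - 1
    best_d = 0.0

    for _ in range(2 * n + 10):
        sel = np.arange(low, high + 1)
        first = np.ones(sel.size, dtype=bool)
        first[1:] = x[sel[1:]] != x[sel[:-1]]
        last = np.ones(sel.size, dtype=bool)
        last[:-1] = x[sel[:-1]] != x[sel[1:]]

        gcm_idx = sel[first]
        lcm_idx = sel[last]
        gpos = _hull_lower(x, y_lo, gcm_idx)
        gcm = gcm_idx[gpos]
        # upper hull of (x, y_hi) == lower hull of (x, -y_hi)
        lpos = _hull_lower(x, -y_hi, lcm_idx)
        lcm = lcm_idx[lpos]

        # hull curves evaluated at every sample index in the window
        c_at = np.interp(x[sel], x[gcm], y_lo[gcm])
        l_at = np.interp(x[sel], x[lcm], y_hi[lcm])

        # largest gap between the two hull curves inside [low, high];
        # candidates live at hull vertices, paired with the endpoint of the
        # chord of the opposite hull that covers them
        cand_g = l_at[gcm - low] - y_lo[gcm]
        jr = np.minimum(np.searchsorted(x[lcm], x[gcm], side="left"), lcm.size - 1)
        pair_g = lcm[jr]
        cand_l = y_hi[lcm] - c_at[lcm - low]
        jl = np.maximum(np.searchsorted(x[gcm], x[lcm], side="right") - 1, 0)
        pair_l = gcm[jl]

        gaps = np.concatenate([cand_g, cand_l])
        igs = np.concatenate([gcm, pair_l])
        ihs = np.concatenate([pair_g, lcm])
        d = float(gaps.max())
        near = gaps >= d - 1e-15
        widths = x[ihs] - x[igs]
        k = int(np.flatnonzero(near)[np.argmax(widths[near])])
        ig, ih = int(igs[k]), int(ihs[k])

        if d <= best_d + 1e-15:
            break

        # deviations committed outside the shrunken modal interval
        dl = float(np.max(y_hi[low : ig + 1] - c_at[: ig - low + 1]))
        du = float(np.max(l_at[ih - low :] - y_lo[ih : high + 1]))
        best_d = max(best_d, dl, du)
        if ig == low and ih == high:
            break
        low, high = ig, ih
        if low >= high:
            break

    return DipResult(best_d / 2.0, (float(x[low]), float(x[high])))
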