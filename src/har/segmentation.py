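"""Greedy Gaussian segmentation (GGS) and the fixed-window baseline.

The model: within each segment the multichannel samples are i.i.d. draws
from a multivariate normal whose mean and covariance are segment-specific.
For breakpoints ``b_0 = 0 < b_1 < ... < b_K < b_{K+1} = T`` the objective is
the covariance-regularised Gaussian log-likelihood

    Phi(b) = sum_i psi_i,
    psi_i  = -(n_i/2) * (m ln 2pi + ln det(Sigma_i) + tr(Sigma_i^{-1} S_i)),

with ``S_i`` the biased sample covariance of segment i (n_i samples, m
channels) and ``Sigma_i = S_i + (lambda/n_i) I`` the regularised plug-in
covariance.  At lambda = 0 the trace term equals m and psi is the maximised
Gaussian log-likelihood.

The greedy heuristic adds one breakpoint at a time — the single split over
all segments and admissible positions with the largest Phi gain — and then
repeatedly re-optimises each breakpoint within its flanking segments until a
full sweep changes nothing.  Phi strictly increases on every accepted move
and positions are finite, so the procedure terminates.

Everything is built on prefix sums of x and x x^T, so evaluating a candidate
segment costs O(m^2) and split scans are vectorised over candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class Segmentation:
    """Breakpoints plus per-segment Gaussian parameters and the objective.

    ``breakpoints`` has K+2 entries, 0 and T included; segment i is the
    half-open ``[breakpoints[i], breakpoints[i+1])``.
    """

    breakpoints: np.ndarray
    means: np.ndarray  # (K+1, m)
    covariances: np.ndarray  # (K+1, m, m), regularised
    objective: float
    lam: float
    addition_history: list[float] = field(default_factory=list)
    adjustment_history: list[float] = field(default_factory=list)

    @property
    def K(self) -> int:
        return len(self.breakpoints) - 2

    @property
    def segments(self) -> list[tuple[int, int]]:
        b = self.breakpoints
        return [(int(b[i]), int(b[i + 1])) for i in range(len(b) - 1)]


class _Cumulants:
    """Prefix sums enabling O(m^2) segment mean/covariance queries."""

    def __init__(self, x: np.ndarray):
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 2:
            raise ValueError("expected a (T, m) sample matrix")
        if not np.isfinite(x).all():
            raise ValueError("non-finite samples")
        self.T, self.m = x.shape
        self.s1 = np.vstack([np.zeros((1, self.m)), np.cumsum(x, axis=0)])
        outer = x[:, :, None] * x[:, None, :]
        self.s2 = np.concatenate(
            [np.zeros((1, self.m, self.m)), np.cumsum(outer, axis=0)], axis=0
        )

    def moments(self, a, b):
        """Segment mean and biased covariance for [a, b); a, b may be arrays."""
        a = np.asarray(a)
        b = np.asarray(b)
        n = (b - a).astype(np.float64)
        mean = (self.s1[b] - self.s1[a]) / n[..., None]
        ex2 = (self.s2[b] - self.s2[a]) / n[..., None, None]
        cov = ex2 - mean[..., :, None] * mean[..., None, :]
        return n, mean, cov

    def psi(self, a, b, lam: float):
        """Regularised segment log-likelihood; vectorised over a/b arrays."""
        n, _, cov = self.moments(a, b)
        m = self.m
        eye = np.eye(m)
        sigma = cov + (lam / n)[..., None, None] * eye
        sign, logdet = np.linalg.slogdet(sigma)
        if lam > 0:
            # tr(Sigma^{-1} S) = m - (lam/n) tr(Sigma^{-1})
            inv_tr = np.trace(np.linalg.inv(sigma), axis1=-2, axis2=-1)
            tr_term = m - (lam / n) * inv_tr
        else:
            tr_term = np.full(np.shape(n), float(m))
        val = -(n / 2.0) * (m * _LOG2PI + logdet + tr_term)
        return np.where(sign > 0, val, -np.inf)


def ggs_objective(
    x: np.ndarray, breakpoints, lam: float = 0.0, min_seg_len: int = 1
) -> float:
    """Phi(b): sum of regularised segment log-likelihoods (additive)."""
    c = _Cumulants(x)
    b = np.asarray(breakpoints, dtype=int)
    _validate_breakpoints(b, c.T, min_seg_len)
    return float(np.sum(c.psi(b[:-1], b[1:], lam)))


def _validate_breakpoints(b: np.ndarray, T: int, min_seg_len: int) -> None:
    if b[0] != 0 or b[-1] != T:
        raise ValueError(f"breakpoints must start at 0 and end at T={T}, got {b}")
    if np.any(np.diff(b) <= 0):
        raise ValueError(f"breakpoints must be strictly increasing, got {b}")
    if np.any(np.diff(b) < min_seg_len):
        raise ValueError(f"segment shorter than min_seg_len={min_seg_len}: {b}")


def _best_split(c: _Cumulants, a: int, b: int, lam: float, min_seg_len: int):
    """Best single split of [a, b); returns (gain, position) or (-inf, -1)."""
    lo, hi = a + min_seg_len, b - min_seg_len
    if hi < lo:
        return -np.inf, -1
    t = np.arange(lo, hi + 1)
    base = float(c.psi(a, b, lam))
    gains = c.psi(np.full_like(t, a), t, lam) + c.psi(t, np.full_like(t, b), lam) - base
    with np.errstate(invalid="ignore"):
        k = int(np.nanargmax(gains)) if np.any(np.isfinite(gains)) else -1
    if k < 0:
        return -np.inf, -1
    return float(gains[k]), int(t[k])


def ggs(
    x: np.ndarray,
    K: int,
    lam: float = 0.0,
    min_seg_len: int = 5,
    force_K: bool = False,
) -> Segmentation:
    """Greedy Gaussian segmentation with K interior breakpoints.

    Splits are added one at a time at the position of largest Phi gain
    (ties -> smallest index); addition stops early when the best gain is
    <= 0 unless ``force_K``.  A bottom-up adjustment phase then re-optimises
    each breakpoint within its flanking segments until a full sweep makes no
    change.
    """
    c = _Cumulants(x)
    T = c.T
    if K < 0 or T < (K + 1) * min_seg_len:
        raise ValueError(f"K={K} infeasible for T={T} with min_seg_len={min_seg_len}")
    b = [0, T]
    addition_history = [float(c.psi(0, T, lam))]
    # cached best split per segment, keyed by (start, end)
    cache: dict[tuple[int, int], tuple[float, int]] = {
        (0, T): _best_split(c, 0, T, lam, min_seg_len)
    }
    while len(b) - 2 < K:
        best = (-np.inf, -1, -1)  # gain, position, segment index
        for i in range(len(b) - 1):
            seg = (b[i], b[i + 1])
            gain, pos = cache[seg]
            if gain > best[0]:
                best = (gain, pos, i)
        gain, pos, i = best
        if pos < 0:
            break  # no admissible split anywhere
        if gain <= 0 and not force_K:
            break
        left, right = b[i], b[i + 1]
        b.insert(i + 1, pos)
        del cache[(left, right)]
        cache[(left, pos)] = _best_split(c, left, pos, lam, min_seg_len)
        cache[(pos, right)] = _best_split(c, pos, right, lam, min_seg_len)
        addition_history.append(addition_history[-1] + gain)

    bp = np.asarray(b, dtype=int)
    adjustment_history: list[float] = []
    # bottom-up adjustment: move each interior breakpoint to the best
    # position between its neighbours; sweep until stable
    tol = 1e-9
    for _ in range(1000):
        moved = False
        for i in range(1, len(bp) - 1):
            left, right = int(bp[i - 1]), int(bp[i + 1])
            lo, hi = left + min_seg_len, right - min_seg_len
            if hi < lo:
                continue
            t = np.arange(lo, hi + 1)
            vals = c.psi(np.full_like(t, left), t, lam) + c.psi(t, np.full_like(t, right), lam)
            cur = float(
                c.psi(left, int(bp[i]), lam) + c.psi(int(bp[i]), right, lam)
            )
            k = int(np.argmax(vals))
            if vals[k] > cur + tol and t[k] != bp[i]:
                bp[i] = t[k]
                adjustment_history.append(float(vals[k] - cur))
                moved = True
        if not moved:
            break

    n, means, covs = (_Cumulants.moments(c, bp[:-1], bp[1:]))
    sigma = covs + (lam / n)[:, None, None] * np.eye(c.m)
    objective = float(np.sum(c.psi(bp[:-1], bp[1:], lam)))
    return Segmentation(
        breakpoints=bp,
        means=means,
        covariances=sigma,
        objective=objective,
        lam=lam,
        addition_history=addition_history,
        adjustment_history=adjustment_history,
    )


def objective_curve(
    x: np.ndarray,
    K_max: int,
    lam: float = 0.0,
    min_seg_len: int = 5,
) -> tuple[pd.DataFrame, int]:
    """Phi after each greedy addition, K = 0..K_max, plus an elbow suggestion.

    The elbow is the K maximising the negative second difference of the
    curve (the sharpest flattening).
    """
    seg = ggs(x, K_max, lam=lam, min_seg_len=min_seg_len, force_K=True)
    phi = seg.addition_history
    curve = pd.DataFrame({"K": np.arange(len(phi)), "objective": phi})
    if len(phi) >= 3:
        second = np.asarray(phi[2:]) - 2 * np.asarray(phi[1:-1]) + np.asarray(phi[:-2])
        elbow = int(np.argmin(second)) + 1
    else:
        elbow = len(phi) - 1
    return curve, elbow


def fixed_windows(T: int, rate_hz: float, size_s: float) -> list[tuple[int, int]]:
    """Non-overlapping fixed-size windows partitioning [0, T).

    Window length is ``round(size_s * rate_hz)`` samples.  A final partial
    window of >= 2 samples is kept; a shorter remainder is merged into the
    last full window.
    """
    w = int(round(size_s * rate_hz))
    if w < 2:
        raise ValueError(f"window of {size_s} s at {rate_hz} Hz spans {w} < 2 samples")
    if T < 2:
        raise ValueError(f"stream of {T} samples cannot be windowed")
    edges = list(range(0, T + 1, w))
    if edges[-1] != T:
        remainder = T - edges[-1]
        if remainder >= 2 or len(edges) == 1:
            edges.append(T)
        else:
            edges[-1] = T
    return [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]
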