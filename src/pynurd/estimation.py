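"""Poisson log-likelihood, gradient, and coordinate binary-search maximization.

The read count of exonic segment ``j`` is modelled as Poisson with rate

    lambda_j = l_j * w * sum_i b_ij * theta_i

where ``l_j`` is the segment length, ``w`` the library read total, ``b_ij``
the (bias-corrected) structure matrix and ``theta_i >= 0`` the expression of
isoform ``i`` in expected reads per base per sequenced read (RPKM is
``theta * 1e9``).  Segments are treated as independent, giving the concave
log-likelihood

    log L(theta) = -w * sum_j sum_i l_j b_ij theta_i
                   + sum_j x_j log(l_j w sum_i b_ij theta_i)
                   - sum_j log(x_j!)

Because the objective is concave, each coordinate restriction is a concave
univariate function whose derivative is monotone non-increasing, so the 1-D
maximizer is found by bisection on the partial derivative — no step size is
needed and each search takes at most ceil(log2(interval / eps)) iterations.
Multi-isoform genes are solved by cycling these 1-D searches (coordinate
binary search); concavity makes the ascent converge to the global optimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import gammaln


@dataclass
class OptimizerConfig:
    """Tolerances for the coordinate binary search.

    ``eps`` is the relative precision of each 1-D search: the bisection
    interval for coordinate i is shrunk to ``eps`` times its initial width,
    which makes the precision scale-free in theta.  Sweeps stop when a full
    cycle improves the log-likelihood by less than ``loglik_tol``.
    """

    eps: float = 1e-10
    max_sweeps: int = 5000
    loglik_tol: float = 1e-11
    theta_upper_factor: float = 2.0

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.max_sweeps < 1:
            raise ValueError("max_sweeps must be >= 1")


@dataclass
class ExpressionEstimate:
    """Per-isoform expression of one gene at the likelihood maximum."""

    gene_id: str
    theta: np.ndarray
    loglik: float
    iterations: int
    converged: bool
    unidentifiable: bool = False
    loglik_trace: list[float] = field(default_factory=list)

    @property
    def rpkm(self) -> np.ndarray:
        return theta_to_rpkm(self.theta)


def theta_to_rpkm(theta):
    """Reads per base per sequenced read -> reads per kilobase per million reads."""
    return np.asarray(theta, dtype=np.float64) * 1e9


def log_likelihood(
    theta: np.ndarray,
    x: np.ndarray,
    lengths: np.ndarray,
    b: np.ndarray,
    w: float,
) -> float:
    """Poisson log-likelihood of segment counts ``x`` at expression ``theta``.

    Segments with ``x_j = 0`` contribute only the ``-lambda_j`` penalty
    (0 * log 0 := 0).  If some segment has ``x_j > 0`` but zero rate, the
    likelihood is 0 and ``-inf`` is returned.
    """
    theta = np.asarray(theta, dtype=np.float64)
    if (theta < 0).any():
        raise ValueError("theta must be non-negative")
    x = np.asarray(x, dtype=np.float64)
    lengths = np.asarray(lengths, dtype=np.float64)
    b = np.atleast_2d(np.asarray(b, dtype=np.float64))
    s = theta @ b  # (n,) mixture rate per base, sum_i b_ij theta_i
    pos = x > 0
    if (s[pos] <= 0).any():
        return -math.inf
    ll = -w * float(lengths @ s)
    lam = lengths[pos] * w * s[pos]
    ll += float(x[pos] @ np.log(lam)) - float(gammaln(x[pos] + 1).sum())
    return ll


def gradient_component(
    theta: np.ndarray,
    i: int,
    x: np.ndarray,
    lengths: np.ndarray,
    b: np.ndarray,
    w: float,
) -> float:
    """Partial derivative of the log-likelihood with respect to ``theta_i``.

    Returns ``+inf`` when some observed segment (x_j > 0, b_ij > 0) has zero
    rate: the gradient points inward from the boundary theta = 0.
    """
    theta = np.asarray(theta, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    lengths = np.asarray(lengths, dtype=np.float64)
    b = np.atleast_2d(np.asarray(b, dtype=np.float64))
    bi = b[i]
    s = theta @ b
    grad = -w * float(lengths @ bi)
    pos = x > 0
    if ((s <= 0) & pos & (bi > 0)).any():
        return math.inf
    use = pos & (bi > 0)
    if use.any():
        grad += float((x[use] * bi[use] / s[use]).sum())
    return grad


def binary_search_root(
    g: Callable[[float], float],
    lo: float,
    hi: float,
    eps: float,
    return_iterations: bool = False,
):
    """Locate the sign change of a monotone non-increasing function by bisection.

    Returns ``lo`` if ``g(lo) <= 0`` (root at or below the interval), ``hi``
    if ``g(hi) >= 0``, otherwise the midpoint of a bracketing interval of
    width <= ``eps``.  Terminates within ceil(log2((hi - lo) / eps))
    bisections.  NaN at an endpoint is an error; infinite endpoint values are
    legitimate boundary sentinels.
    """
    if not lo < hi:
        raise ValueError("need lo < hi")
    if eps <= 0:
        raise ValueError("eps must be positive")
    g_lo, g_hi = g(lo), g(hi)
    if math.isnan(g_lo) or math.isnan(g_hi):
        raise ValueError("g is NaN at an interval endpoint")
    iters = 0
    if g_lo <= 0:
        root = lo
    elif g_hi >= 0:
        root = hi
    else:
        while hi - lo > eps:
            mid = 0.5 * (lo + hi)
            iters += 1
            if g(mid) > 0:
                lo = mid
            else:
                hi = mid
        root = 0.5 * (lo + hi)
    if return_iterations:
        return root, iters
    return root


def coordinate_ascent(
    grads: Sequence[Callable[[np.ndarray], float]],
    x0: np.ndarray,
    lower: np.ndarray,
    upper: np.ndarray,
    eps: float,
    value_fn: Callable[[np.ndarray], float] | None = None,
    tol: float = 1e-10,
    max_sweeps: int = 200,
    order: Sequence[int] | None = None,
):
    """Maximize a concave function by cyclic 1-D bisection on partial derivatives.

    ``grads[i](x)`` is the partial derivative along coordinate i; each inner
    step replaces ``x[i]`` by the bisection root on ``[lower[i], upper[i]]``
    with absolute precision ``eps * (upper[i] - lower[i])``.  Sweeps cycle the
    coordinates in ``order`` (default 0..d-1) until the objective improves by
    less than ``tol`` or ``max_sweeps`` is hit.

    Returns ``(x, trace, inner_steps, converged)`` where ``trace`` holds the
    objective value after every inner step (empty when ``value_fn`` is None,
    in which case convergence is declared on the sup-norm step instead).
    """
    x = np.array(x0, dtype=np.float64)
    d = len(x)
    order = list(range(d)) if order is None else list(order)
    trace: list[float] = []
    inner = 0
    converged = False
    prev_val = value_fn(x) if value_fn is not None else None
    for _ in range(max_sweeps):
        x_prev = x.copy()
        for i in order:
            def g1(v: float, i: int = i) -> float:
                xt = x.copy()
                xt[i] = v
                return grads[i](xt)

            span = upper[i] - lower[i]
            x[i] = binary_search_root(g1, lower[i], upper[i], eps * span)
            inner += 1
            if value_fn is not None:
                trace.append(value_fn(x))
        if value_fn is not None:
            if trace[-1] - prev_val < tol:
                converged = True
                break
            prev_val = trace[-1]
        else:
            if np.abs(x - x_prev).max() < tol:
                converged = True
                break
    return x, trace, inner, converged


def closed_form_single_isoform(
    x: np.ndarray, lengths: np.ndarray, b_row: np.ndarray, w: float
) -> float:
    """Exact maximizer for m = 1: theta = sum_j x_j / (w * sum_j l_j * b_j)."""
    denom = w * float(np.asarray(lengths, dtype=float) @ np.asarray(b_row, dtype=float))
    if denom <= 0:
        return 0.0
    return float(np.asarray(x, dtype=float).sum()) / denom


def coordinate_binary_search(
    x: np.ndarray,
    lengths: np.ndarray,
    b: np.ndarray,
    w: float,
    config: OptimizerConfig | None = None,
    gene_id: str = "",
) -> ExpressionEstimate:
    """Maximize the segment-count log-likelihood over theta >= 0.

    Each coordinate's search interval is [0, hi_i] with
    ``hi_i = theta_upper_factor * sum_j x_j / (w * min_{j: b_ij>0} l_j b_ij)``,
    which always contains the coordinate-wise maximizer (the partial
    derivative is negative beyond ``sum_j x_j / (w sum_j l_j b_ij)``).
    Genes with all-zero counts return theta = 0 immediately; an isoform whose
    ``b`` row is entirely zero is unidentifiable and pinned at 0.  Two
    isoforms with identical ``b`` rows are flagged ``unidentifiable`` (any
    split between them yields the same likelihood).
    """
    cfg = config or OptimizerConfig()
    x = np.asarray(x, dtype=np.float64)
    lengths = np.asarray(lengths, dtype=np.float64)
    b = np.atleast_2d(np.asarray(b, dtype=np.float64))
    m = b.shape[0]
    total = float(x.sum())

    unident = _has_duplicate_rows(b)

    if total == 0:
        theta = np.zeros(m)
        ll = log_likelihood(theta, x, lengths, b, w)
        return ExpressionEstimate(gene_id, theta, ll, 0, True, unident, [ll])

    active = [i for i in range(m) if (b[i] > 0).any()]
    if not active:
        theta = np.zeros(m)
        ll = log_likelihood(theta, x, lengths, b, w)
        return ExpressionEstimate(gene_id, theta, ll, 0, True, True, [ll])
    upper = np.zeros(m)
    theta0 = np.zeros(m)
    for i in active:
        mask = b[i] > 0
        upper[i] = cfg.theta_upper_factor * total / (w * float((lengths[mask] * b[i, mask]).min()))
        theta0[i] = total / (m * w * float(lengths @ b[i]))

    # Specialised sweep loop: the rate vector s_j = sum_i b_ij theta_i is
    # maintained incrementally and the 1-D partial derivative along
    # coordinate i reduces to  -w sum_j l_j b_ij + sum_j x_j b_ij/(s0_j + v b_ij)
    # with s0 the rate contribution of the other isoforms.
    pos = x > 0
    lw = lengths * w
    log_fact = float(gammaln(x[pos] + 1).sum())
    x_pos, lw_pos = x[pos], lw[pos]

    def ll_from_s(s: np.ndarray) -> float:
        sp = s[pos]
        if (sp <= 0).any():
            return -math.inf
        return -float(lw @ s) + float(x_pos @ np.log(lw_pos * sp)) - log_fact

    lin_coef = [w * float(lengths @ b[i]) for i in range(m)]
    coord_data = []
    for i in range(m):
        mask = pos & (b[i] > 0)
        coord_data.append((x[mask] * b[i, mask], b[i, mask], mask))

    theta = theta0.copy()
    trace: list[float] = []
    inner = 0
    converged = False
    prev_val = ll_from_s(theta @ b)
    for sweep in range(cfg.max_sweeps):
        sweep_start = theta.copy()
        for i in active:
            theta[i] = 0.0
            s0 = theta @ b
            xb, bim, mask = coord_data[i]
            s0m = s0[mask]

            def g(v: float) -> float:
                denom = s0m + v * bim
                if (denom <= 0).any():
                    return math.inf
                return -lin_coef[i] + float((xb / denom).sum())

            theta[i] = binary_search_root(g, 0.0, upper[i], cfg.eps * upper[i])
            inner += 1
            trace.append(ll_from_s(theta @ b))
        if sweep > 0:
            # pattern move: exact concave line search along the sweep's net
            # displacement, which kills the slow ridge direction when b rows
            # are nearly collinear; t = 0 is interior, so ascent is preserved
            theta = _pattern_move(theta, sweep_start, x, lengths, b, w, pos, cfg.eps)
            inner += 1
            trace.append(ll_from_s(theta @ b))
        if trace[-1] - prev_val < cfg.loglik_tol:
            converged = True
            break
        prev_val = trace[-1]
    ll = ll_from_s(theta @ b)
    return ExpressionEstimate(gene_id, theta, ll, inner, converged, unident, trace)


def _pattern_move(
    theta: np.ndarray,
    previous: np.ndarray,
    x: np.ndarray,
    lengths: np.ndarray,
    b: np.ndarray,
    w: float,
    pos: np.ndarray,
    eps: float,
) -> np.ndarray:
    """Maximize the log-likelihood along theta + t * (theta - previous), t >= -1.

    The restriction of a concave function to a line is concave, so the same
    bisection on the directional derivative applies.  The interval keeps
    theta + t * d componentwise non-negative and every observed segment's
    rate positive; t in the interval includes 0, so the move never decreases
    the log-likelihood (up to bisection precision).
    """
    d = theta - previous
    if not np.abs(d).sum() > 0:
        return theta
    bd = d @ b
    s = theta @ b
    lin = w * float(lengths @ bd)

    t_lo, t_hi = -1.0, math.inf
    for ti, di in zip(theta, d):
        if di > 0:
            t_lo = max(t_lo, -ti / di)
        elif di < 0:
            t_hi = min(t_hi, -ti / di)
    margin = 1e-9
    for sj, bdj, xj in zip(s, bd, x):
        if xj > 0 and bdj < 0:
            t_hi = min(t_hi, -sj / bdj * (1 - margin))
        elif xj > 0 and bdj > 0:
            t_lo = max(t_lo, -sj / bdj * (1 - margin))
    if not math.isfinite(t_hi):
        t_hi = 1e6
    if not t_lo < 0 < t_hi:
        return theta

    mask = pos & (bd != 0)
    xbd = x[mask] * bd[mask]
    bdm = bd[mask]
    sm = s[mask]

    def g(t: float) -> float:
        denom = sm + t * bdm
        if (denom <= 0).any():
            return math.inf if t < 0 else -math.inf
        return -lin + float((xbd / denom).sum())

    t_star = binary_search_root(g, t_lo, t_hi, eps * (t_hi - t_lo))
    return np.maximum(theta + t_star * d, 0.0)


def _has_duplicate_rows(b: np.ndarray, rtol: float = 1e-12) -> bool:
    m = b.shape[0]
    for i in range(m):
        for k in range(i + 1, m):
            if np.allclose(b[i], b[k], rtol=rtol, atol=1e-15):
                return True
    return False
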