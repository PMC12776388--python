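"""Gil-Pelaez inversion of the quadratic test statistic's distribution.

The log-likelihood-ratio statistic for a pair of Gaussian hypotheses in
whitened coordinates is

    Z = sum_i [ X_i^2 - (X_i - m_i)^2 / lam_i ],

a quadratic form in independent standard normals under either hypothesis.
Each coordinate contributes a term  a V^2 + b V + c  with V ~ N(0,1), which
collapses to the canonical representation

    Z = gamma0 + sum_j w_j * Q_j + s * G,

where Q_j ~ noncentral chi-square(1, delta_j^2), G ~ N(0,1), all independent.
The CDF is recovered from the closed-form characteristic function through the
Gil-Pelaez formula

    F_Z(z) = 1/2 - (1/pi) * Int_0^inf Im[e^{-i w z} phi(w)] / w dw,

written here in magnitude/phase (Imhof) form: the integrand is
rho(u) sin(theta(u)) / u with closed-form rho and theta.  The integrand has a
finite u -> 0 limit (E[Z] - z) and only polynomial envelope decay when no
Gaussian component is present, so the tail is summed lobe-by-lobe between
successive sign changes with Wynn-epsilon acceleration of the alternating
series.  A Chernoff bound on the MGF clamps far-tail evaluations.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import integrate, optimize

__all__ = ["QuadForm", "quad_form_for_hypothesis", "gil_pelaez_cdf"]

_A_TINY = 1e-14  # |a| below this: coordinate treated as purely linear in V


@dataclass(frozen=True)
class QuadForm:
    """Canonical quadratic-form law: gamma0 + sum w_j*ncx2(1, delta2_j) + s*N(0,1)."""

    w: np.ndarray       # nonzero chi-square weights
    delta2: np.ndarray  # noncentrality parameters, same length as w
    s2: float           # variance of the pure-Gaussian part
    gamma0: float       # additive constant

    @property
    def mean(self) -> float:
        return self.gamma0 + float(np.sum(self.w * (1.0 + self.delta2)))

    @property
    def var(self) -> float:
        return self.s2 + float(np.sum(2.0 * self.w**2 * (1.0 + 2.0 * self.delta2)))

    def theta(self, u):
        """Phase of e^{-iu(z-gamma0)} * phi(u) without the -u*x term."""
        u = np.asarray(u, dtype=float)
        wu = np.multiply.outer(u, self.w)           # (..., J)
        t = 0.5 * np.arctan(2.0 * wu)
        t += wu * self.delta2 / (1.0 + 4.0 * wu**2)
        return t.sum(axis=-1)

    def log_rho(self, u):
        """Log magnitude of phi at frequency u."""
        u = np.asarray(u, dtype=float)
        wu2 = np.multiply.outer(u, self.w) ** 2
        out = -0.25 * np.log1p(4.0 * wu2).sum(axis=-1)
        out -= (2.0 * wu2 * self.delta2 / (1.0 + 4.0 * wu2)).sum(axis=-1)
        out -= 0.5 * self.s2 * u**2
        return out

    def cumulant(self, t: float) -> float:
        """log MGF at t; requires 2*w_j*t < 1 for every j."""
        arg = 1.0 - 2.0 * self.w * t
        if np.any(arg <= 0):
            return np.inf
        val = self.gamma0 * t + 0.5 * self.s2 * t * t
        val += float(np.sum(-0.5 * np.log(arg) + self.w * self.delta2 * t / arg))
        return val


def quad_form_for_hypothesis(m: np.ndarray, lam: np.ndarray, hypothesis: str) -> QuadForm:
    """Canonical law of Z = sum X^2 - (X-m)^2/lam under H0 or H1.

    Under H0 the whitened data X are standard normal; under H1 they are
    N(m_i, lam_i).  Either way each coordinate is a quadratic a V^2 + b V + c
    in a standard normal V.
    """
    m = np.asarray(m, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if hypothesis == "H0":
        a = 1.0 - 1.0 / lam
        b = 2.0 * m / lam
        c = -(m**2) / lam
    elif hypothesis == "H1":
        a = lam - 1.0
        b = 2.0 * m * np.sqrt(lam)
        c = m**2
    else:  # pragma: no cover - guarded by callers
        raise ValueError(f"hypothesis must be 'H0' or 'H1', got {hypothesis!r}")

    quad = np.abs(a) > _A_TINY
    w = a[quad]
    delta2 = (b[quad] / (2.0 * w)) ** 2
    gamma0 = float(np.sum(c[quad] - b[quad] ** 2 / (4.0 * w)) + np.sum(c[~quad]))
    s2 = float(np.sum(b[~quad] ** 2))
    return QuadForm(w=w, delta2=delta2, s2=s2, gamma0=gamma0)


# ---------------------------------------------------------------------------
# quadrature machinery


@lru_cache(maxsize=8)
def _leggauss(order: int):
    x, wts = np.polynomial.legendre.leggauss(order)
    return x, wts


def _gl_integrate(f, a: np.ndarray, b: np.ndarray, order: int) -> float:
    """Gauss-Legendre on a batch of intervals [a_k, b_k], summed."""
    x, wts = _leggauss(order)
    mid = 0.5 * (a + b)
    half = 0.5 * (b - a)
    nodes = (mid[:, None] + half[:, None] * x[None, :]).ravel()
    vals = f(nodes).reshape(len(a), order)
    return float(np.sum(vals @ wts * half))


def _wynn_epsilon(sums: np.ndarray) -> float:
    """Wynn's epsilon acceleration of a slowly converging (alternating) series.

    Builds the epsilon table column by column; even columns are the
    convergence estimates, and the deepest even entry is returned.
    """
    e0 = np.zeros(len(sums) + 1)
    e1 = np.asarray(sums, dtype=float)
    best = e1[-1]
    col = 1
    while len(e1) >= 2:
        diff = np.diff(e1)
        safe = np.abs(diff) > 1e-300
        e2 = e0[1:len(e1)] + np.where(safe, 1.0 / np.where(safe, diff, 1.0), 1e300)
        e0, e1 = e1, e2
        col += 1
        if col % 2 == 1 and len(e1) and abs(e1[-1]) < 1e290:
            best = e1[-1]
    return best


def _chernoff_tail(qf: QuadForm, z: float, upper: bool) -> float:
    """Chernoff bound on P(Z >= z) (upper=True) or P(Z <= z)."""
    w = qf.w
    if upper:
        t_max = np.inf if not np.any(w > 0) else 0.5 / w.max()
        sign = 1.0
    else:
        t_max = np.inf if not np.any(w < 0) else -0.5 / w.min()
        sign = -1.0
    if not np.isfinite(t_max):
        if qf.s2 == 0 and len(w) and np.all(sign * w < 0):
            # statistic bounded in this direction at gamma0
            if sign * (z - qf.gamma0) >= 0:
                return 0.0
        t_max = 1e6 / max(np.sqrt(qf.var), 1e-12)
    best = 1.0
    for frac in (0.9999, 0.999, 0.99, 0.9, 0.5, 0.1, 0.01, 1e-3, 1e-4):
        t = sign * t_max * frac
        k = qf.cumulant(t)
        if np.isfinite(k):
            best = min(best, float(np.exp(min(k - t * z, 0.0))))
    return best


def _lower_support(qf: QuadForm):
    if qf.s2 == 0 and len(qf.w) and np.all(qf.w > 0):
        return qf.gamma0
    return -np.inf


def _upper_support(qf: QuadForm):
    if qf.s2 == 0 and len(qf.w) and np.all(qf.w < 0):
        return qf.gamma0
    return np.inf


def _psi_prime_bound(qf: QuadForm, u: float) -> float:
    """Decreasing bound on |d theta / du| excluding the -x*u term."""
    wu2 = (qf.w * u) ** 2
    return float(np.sum(np.abs(qf.w) * (1.0 + qf.delta2) / (1.0 + 4.0 * wu2)))


def _integrand_factory(qf: QuadForm, z: float):
    x = z - qf.gamma0
    mean_minus_z = qf.mean - z

    def f(u):
        u = np.asarray(u, dtype=float)
        scalar = u.ndim == 0
        u = np.atleast_1d(u)
        out = np.empty_like(u)
        tiny = u < 1e-12
        out[tiny] = mean_minus_z
        ub = u[~tiny]
        out[~tiny] = np.exp(qf.log_rho(ub)) * np.sin(qf.theta(ub) - x * ub) / ub
        return out[0] if scalar else out

    return f


_CLAMP = 1e-13
_MAX_LOBES = 400
_X_TINY_REL = 1e-9


def gil_pelaez_cdf(z: float, qf: QuadForm) -> float:
    """CDF of the quadratic-form law at z, by Gil-Pelaez inversion.

    Absolute error is well below the 1e-4 contract; the closed-form Gaussian
    and scaled-chi-square special cases are matched to ~1e-8 or better.
    """
    z = float(z)
    if len(qf.w) == 0 and qf.s2 == 0:
        raise ValueError("degenerate quadratic form: Z is constant")
    if z <= _lower_support(qf):
        return 0.0
    if z >= _upper_support(qf):
        return 1.0
    if _chernoff_tail(qf, z, upper=True) < _CLAMP:
        return 1.0
    if _chernoff_tail(qf, z, upper=False) < _CLAMP:
        return 0.0

    x = z - qf.gamma0
    f = _integrand_factory(qf, z)
    sd = np.sqrt(qf.var)

    if qf.s2 > 0:
        # Gaussian factor: exponential envelope decay, truncate and integrate.
        s = np.sqrt(qf.s2)
        u_max = np.sqrt(2.0 * 77.0) / s
        half_cycles = int(u_max * (abs(x) + _psi_prime_bound(qf, 0.0)) / np.pi) + 8
        n_seg = min(max(64, 3 * half_cycles), 8000)
        edges = np.linspace(0.0, u_max, n_seg + 1)
        integral = _gl_integrate(f, edges[:-1], edges[1:], order=10)
    else:
        integral = _polynomial_tail_integral(qf, z, x, f, sd)

    val = 0.5 - integral / np.pi
    return min(1.0, max(0.0, val))


def _polynomial_tail_integral(qf: QuadForm, z: float, x: float, f, sd: float) -> float:
    """Integral of rho*sin(theta)/u over (0, inf) with polynomial envelope."""
    x_eff = abs(x)
    w_absmax = float(np.abs(qf.w).max())
    if x_eff < _X_TINY_REL * (1.0 + sd):
        return _stationary_phase_integral(qf, f, w_absmax)

    # u_f: beyond this point the total phase is strictly monotone in u
    u_f = 0.5 / w_absmax
    while _psi_prime_bound(qf, u_f) > 0.5 * x_eff and u_f < 1e12:
        u_f *= 2.0

    head, _ = integrate.quad(f, 0.0, u_f, limit=400)

    # lobes between successive crossings of theta_total = k*pi
    def theta_total(u):
        return float(qf.theta(np.asarray([u]))[0] - x * u)

    sgn = -1.0 if x > 0 else 1.0  # direction theta_total moves for large u
    th = theta_total(u_f)
    k = np.floor(th / np.pi) if sgn < 0 else np.ceil(th / np.pi)
    u_prev = u_f
    lobes = []
    partial = head
    sums = []
    est_prev = None
    log_rho_floor = np.log(1e-16 * max(1.0, abs(head)) + 1e-300)
    for _ in range(_MAX_LOBES):
        target = k * np.pi if theta_total(u_prev) != k * np.pi else (k + sgn) * np.pi
        # bracket the next crossing; phase speed is within [x/2, 3x/2] past u_f
        lo = u_prev
        hi = u_prev + 2.2 * np.pi / (0.5 * x_eff)
        g = lambda u: theta_total(u) - target
        glo, ghi = g(lo), g(hi)
        if glo == 0.0:
            lo += 1e-9 * max(1.0, u_prev)
            glo = g(lo)
        expand = 0
        while glo * ghi > 0 and expand < 60:
            hi += 2.0 * np.pi / (0.5 * x_eff)
            ghi = g(hi)
            expand += 1
        if glo * ghi > 0:
            break  # no further crossing found; envelope negligible anyway
        u_next = optimize.brentq(g, lo, hi, xtol=1e-12 * max(1.0, hi))
        # wide lobes (slow oscillation) span decades of the algebraic envelope;
        # subdivide geometrically so fixed-order Gauss stays accurate
        ratio = u_next / u_prev
        if ratio > 1.3:
            n_sub = int(np.ceil(np.log(ratio) / np.log(1.25)))
            edges = np.geomspace(u_prev, u_next, n_sub + 1)
        else:
            edges = np.array([u_prev, u_next])
        lobe = _gl_integrate(f, edges[:-1], edges[1:], order=16)
        partial += lobe
        sums.append(partial)
        u_prev = u_next
        k += sgn
        if len(sums) >= 8:
            est = _wynn_epsilon(np.array(sums[-40:]))
            if est_prev is not None and abs(est - est_prev) < 1e-11 * (1.0 + abs(est)):
                return est
            est_prev = est
        if qf.log_rho(np.asarray([u_next]))[0] < log_rho_floor and len(sums) >= 12:
            break
    if len(sums) >= 8:
        return _wynn_epsilon(np.array(sums[-40:]))
    return partial


def _stationary_phase_integral(qf: QuadForm, f, w_absmax: float) -> float:
    """Near the phase-stationary z the integrand barely oscillates; integrate
    directly on geometric segments out to an envelope-based cutoff."""
    n_quad = len(qf.w)
    c_w = float(np.prod((2.0 * np.abs(qf.w)) ** -0.5))
    # tail beyond U is bounded by c_w * (2/n) * U^{-n/2}
    u_cut = (c_w * (2.0 / n_quad) / 1e-8) ** (2.0 / n_quad)
    u_cut = min(max(u_cut, 10.0 / w_absmax), 1e7)
    u0 = 0.05 / w_absmax
    head, _ = integrate.quad(f, 0.0, u0, limit=200)
    edges = np.geomspace(u0, u_cut, 600)
    return head + _gl_integrate(f, edges[:-1], edges[1:], order=10)
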