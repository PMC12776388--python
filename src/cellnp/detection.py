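"""Neyman-Pearson detection for Gaussian hypothesis pairs.

Given two Gaussian class-conditionals (low-dose H0 vs high-dose H1 models of
log responses), the likelihood-ratio test is canonicalized by whitening H0 and
diagonalizing the transformed H1 covariance.  In those coordinates the
log-likelihood ratio is monotone in the quadratic statistic

    Z = sum_i [ x_i^2 - (x_i - m_i)^2 / lam_i ],

whose distribution under either hypothesis follows from closed-form
characteristic functions inverted with the Gil-Pelaez formula.  Thresholds for
a target false-alarm probability, detection probabilities, ROC curves and
inverse operating points are all solved on that scalar statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize

from ._inversion import QuadForm, gil_pelaez_cdf, quad_form_for_hypothesis
from .errors import DegenerateStatisticError, DimensionMismatchError
from .models import GaussianCondition

__all__ = [
    "CanonicalPair",
    "DetectionOperatingPoint",
    "ROCCurve",
    "canonicalize",
    "test_statistic",
    "char_fn",
    "cdf_test_statistic",
    "solve_threshold",
    "detection_probability",
    "operating_point",
    "roc_curve",
    "pfa_at_pd",
    "decision_region_1d",
]

_DEGENERATE_TOL = 1e-12


@dataclass(frozen=True)
class CanonicalPair:
    """Whitened hypothesis pair: H0 -> N(0, I), H1 -> N(m, diag(lam)).

    ``transform`` and ``offset`` map a raw log-response vector y to canonical
    coordinates x = transform @ (y - offset).  Coordinates where lam_i = 1 and
    m_i = 0 carry no discrimination information and are flagged degenerate.
    """

    m: np.ndarray
    lam: np.ndarray
    transform: np.ndarray
    offset: np.ndarray
    degenerate_mask: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        m = np.atleast_1d(np.asarray(self.m, dtype=float))
        lam = np.atleast_1d(np.asarray(self.lam, dtype=float))
        if m.shape != lam.shape:
            raise DimensionMismatchError("m and lam must have the same length")
        if np.any(lam <= 0):
            raise ValueError("all canonical eigenvalues must be positive")
        mask = (np.abs(lam - 1.0) <= _DEGENERATE_TOL) & (np.abs(m) <= _DEGENERATE_TOL)
        for name, arr in (
            ("m", m),
            ("lam", lam),
            ("transform", np.atleast_2d(np.asarray(self.transform, dtype=float))),
            ("offset", np.atleast_1d(np.asarray(self.offset, dtype=float))),
            ("degenerate_mask", mask),
        ):
            arr.setflags(write=False)
            object.__setattr__(self, name, arr)

    @property
    def dim(self) -> int:
        return self.m.shape[0]

    @property
    def is_degenerate(self) -> bool:
        return bool(self.degenerate_mask.all())

    def active(self) -> tuple[np.ndarray, np.ndarray]:
        """(m, lam) restricted to informative coordinates."""
        keep = ~self.degenerate_mask
        return self.m[keep], self.lam[keep]

    def to_canonical(self, y: np.ndarray) -> np.ndarray:
        """Map raw observations (rows) into canonical coordinates."""
        y = np.atleast_2d(np.asarray(y, dtype=float))
        return (y - self.offset) @ self.transform.T

    def quad_form(self, hypothesis: str) -> QuadForm:
        if self.is_degenerate:
            raise DegenerateStatisticError(
                "hypotheses coincide: the test statistic is identically zero"
            )
        m, lam = self.active()
        return quad_form_for_hypothesis(m, lam, _check_hypothesis(hypothesis))


@dataclass(frozen=True)
class DetectionOperatingPoint:
    """One point of the detector: threshold z_th with its (P_FA, P_D)."""

    z_th: float
    pfa: float
    pd: float

    @property
    def pm(self) -> float:
        """Miss probability, 1 - P_D."""
        return 1.0 - self.pd


@dataclass(frozen=True)
class ROCCurve:
    pfa_grid: np.ndarray
    pd_values: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        pfa = np.asarray(self.pfa_grid, dtype=float)
        pd = np.asarray(self.pd_values, dtype=float)
        if pfa.shape != pd.shape:
            raise DimensionMismatchError("pfa grid and pd values differ in length")
        object.__setattr__(self, "pfa_grid", pfa)
        object.__setattr__(self, "pd_values", pd)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"pfa": self.pfa_grid, "pd": self.pd_values})


def _check_hypothesis(hypothesis: str) -> str:
    if hypothesis not in ("H0", "H1"):
        raise ValueError(f"hypothesis must be 'H0' or 'H1', got {hypothesis!r}")
    return hypothesis


def _eigh_sorted(cov: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric eigendecomposition, eigenvalues descending, signs fixed so the
    largest-magnitude component of each eigenvector is positive."""
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    for j in range(vecs.shape[1]):
        k = np.argmax(np.abs(vecs[:, j]))
        if vecs[k, j] < 0:
            vecs[:, j] = -vecs[:, j]
    return vals, vecs


def canonicalize(h0: GaussianCondition, h1: GaussianCondition) -> CanonicalPair:
    """Whiten H0 and diagonalize the transformed H1 covariance.

    With Sigma = U D U^T, the whitening map D^{-1/2} U^T sends H0 to N(0, I);
    the transformed H1 covariance C = D^{-1/2} U^T Theta U D^{-1/2} is then
    rotated onto its eigenbasis C = V Lam V^T, giving canonical coordinates
    x = V^T D^{-1/2} U^T (y - mu) in which both hypotheses have independent
    components: H0 -> N(0, I), H1 -> N(m, diag(lam)).
    """
    if h0.dim != h1.dim:
        raise DimensionMismatchError(f"h0 has dim {h0.dim}, h1 has dim {h1.dim}")
    d_vals, u = _eigh_sorted(h0.cov)
    whiten = (u / np.sqrt(d_vals)).T  # D^{-1/2} U^T
    c = whiten @ h1.cov @ whiten.T
    lam, v = _eigh_sorted(0.5 * (c + c.T))
    transform = v.T @ whiten
    m = transform @ (h1.mean - h0.mean)
    return CanonicalPair(m=m, lam=lam, transform=transform, offset=h0.mean)


def test_statistic(x: np.ndarray, pair: CanonicalPair) -> float:
    """Quadratic LRT statistic Z = sum_i [x_i^2 - (x_i - m_i)^2 / lam_i]."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if x.shape[-1] != pair.dim:
        raise DimensionMismatchError(
            f"observation has length {x.shape[-1]}, pair has dim {pair.dim}"
        )
    terms = x**2 - (x - pair.m) ** 2 / pair.lam
    terms = np.where(pair.degenerate_mask, 0.0, terms)
    return terms.sum(axis=-1)


def char_fn(omega, pair: CanonicalPair, hypothesis: str):
    """Characteristic function of Z under H0 or H1, as a product over
    coordinates of the closed-form per-coordinate factors.

    Under H0 each factor is (1 - 2j*w*(lam-1)/lam)^{-1/2}
    * exp(w*m^2*(1-2j*w) / (j*lam + 2*w*(lam-1))); under H1 the same with the
    roles of the variances exchanged.  Each radicand has real part exactly 1,
    so the principal square-root branch is continuous in omega.
    """
    _check_hypothesis(hypothesis)
    omega = np.asarray(omega, dtype=float)
    m, lam = pair.m, pair.lam
    w = omega[..., None]
    if hypothesis == "H0":
        factors = (1.0 - 2.0j * w * (lam - 1.0) / lam) ** -0.5
        factors = factors * np.exp(
            w * m**2 * (1.0 - 2.0j * w) / (1.0j * lam + 2.0 * w * (lam - 1.0))
        )
    else:
        factors = (1.0 - 2.0j * w * (lam - 1.0)) ** -0.5
        factors = factors * np.exp(
            -w * m**2 * (1.0 + 2.0j * w) / (1.0j + 2.0 * w * (lam - 1.0))
        )
    factors = np.where(pair.degenerate_mask, 1.0 + 0.0j, factors)
    out = factors.prod(axis=-1)
    return complex(out) if out.ndim == 0 else out


def cdf_test_statistic(z: float, pair: CanonicalPair, hypothesis: str) -> float:
    """F_Z(z; H) via Gil-Pelaez inversion of the closed-form CF."""
    return gil_pelaez_cdf(z, pair.quad_form(_check_hypothesis(hypothesis)))


def solve_threshold(pair: CanonicalPair, alpha: float) -> float:
    """Threshold z_th with P_FA = 1 - F_Z(z_th; H0) = alpha.

    The H0 CDF is monotone; the root is bracketed by geometric expansion
    around the H0 mean +- 10 SD and refined by bisection (Brent).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    qf = pair.quad_form("H0")
    target = 1.0 - alpha

    def f(z):
        return gil_pelaez_cdf(z, qf) - target

    sd = max(np.sqrt(qf.var), 1e-12)
    lo, hi = qf.mean - 10.0 * sd, qf.mean + 10.0 * sd
    span = 10.0 * sd
    while f(lo) > 0.0:
        span *= 2.0
        lo -= span
    while f(hi) < 0.0:
        span *= 2.0
        hi += span
    return float(optimize.brentq(f, lo, hi, xtol=1e-6 * max(1.0, sd), rtol=8.9e-16))


def detection_probability(pair: CanonicalPair, z_th: float) -> float:
    """P_D = 1 - F_Z(z_th; H1)."""
    return 1.0 - cdf_test_statistic(z_th, pair, "H1")


def false_alarm_probability(pair: CanonicalPair, z_th: float) -> float:
    """P_FA = 1 - F_Z(z_th; H0)."""
    return 1.0 - cdf_test_statistic(z_th, pair, "H0")


def operating_point(
    h0: GaussianCondition, h1: GaussianCondition, alpha: float
) -> DetectionOperatingPoint:
    """Canonicalize, solve the threshold at P_FA = alpha, evaluate P_D."""
    pair = canonicalize(h0, h1)
    z_th = solve_threshold(pair, alpha)
    return DetectionOperatingPoint(
        z_th=z_th,
        pfa=false_alarm_probability(pair, z_th),
        pd=detection_probability(pair, z_th),
    )


def roc_curve(
    h0: GaussianCondition,
    h1: GaussianCondition,
    pfa_grid: Sequence[float],
) -> ROCCurve:
    """P_D as a function of P_FA over a strictly increasing grid."""
    pfa_grid = np.asarray(pfa_grid, dtype=float)
    if np.any((pfa_grid <= 0) | (pfa_grid >= 1)):
        raise ValueError("pfa grid values must lie strictly inside (0, 1)")
    if np.any(np.diff(pfa_grid) <= 0):
        raise ValueError("pfa grid must be strictly increasing")
    pair = canonicalize(h0, h1)
    pd_values = np.array(
        [detection_probability(pair, solve_threshold(pair, a)) for a in pfa_grid]
    )
    meta = {"dim": pair.dim, "m": pair.m.tolist(), "lam": pair.lam.tolist()}
    return ROCCurve(pfa_grid=pfa_grid, pd_values=pd_values, metadata=meta)


def pfa_at_pd(
    h0: GaussianCondition, h1: GaussianCondition, target_pd: float
) -> float:
    """Smallest P_FA whose NP test reaches P_D >= target_pd.

    Inverts the monotone ROC by bisection on alpha.
    """
    if not 0.0 < target_pd < 1.0:
        raise ValueError(f"target_pd must be in (0, 1), got {target_pd}")
    pair = canonicalize(h0, h1)

    def pd_of(alpha: float) -> float:
        return detection_probability(pair, solve_threshold(pair, alpha))

    lo, hi = 1e-6, 1.0 - 1e-9
    if pd_of(lo) >= target_pd:
        return lo
    alpha = optimize.brentq(
        lambda a: pd_of(a) - target_pd, lo, hi, xtol=1e-7, rtol=1e-10
    )
    return float(alpha)


def decision_region_1d(pair: CanonicalPair, z_th: float) -> list[tuple[float, float]]:
    """Rejection region {x : Z(x) > z_th} in canonical x-space, for N = 1.

    The statistic is quadratic in x, so the region is a union of at most two
    intervals: two unbounded rays when lam > 1, a bounded interval (possibly
    empty) when lam < 1, and a single ray when lam = 1.  Diagnostic only; the
    decision itself is a single threshold on Z.
    """
    if pair.dim != 1:
        raise DimensionMismatchError("decision_region_1d requires a univariate pair")
    if pair.is_degenerate:
        raise DegenerateStatisticError("hypotheses coincide; no decision region")
    m, lam = float(pair.m[0]), float(pair.lam[0])
    # Z(x) = a x^2 + b x + c
    a = 1.0 - 1.0 / lam
    b = 2.0 * m / lam
    c = -(m**2) / lam - z_th
    if abs(a) < 1e-14:
        # linear: b x + c > 0
        if b > 0:
            return [(-c / b, np.inf)]
        return [(-np.inf, -c / b)]
    disc = b * b - 4.0 * a * c
    if disc < 0.0:
        # no real roots: parabola entirely one side
        return [(-np.inf, np.inf)] if a > 0 else []
    if disc == 0.0:
        # double root: strict inequality excludes the single tangent point
        if a <= 0:
            return []
        r = -b / (2.0 * a)
        return [(-np.inf, r), (r, np.inf)]
    r1 = (-b - np.sqrt(disc)) / (2.0 * a)
    r2 = (-b + np.sqrt(disc)) / (2.0 * a)
    lo, hi = min(r1, r2), max(r1, r2)
    if a > 0:
        return [(-np.inf, lo), (hi, np.inf)]
    return [(lo, hi)]
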