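"""Plain Monte-Carlo estimators of every probability the analytic pipeline
produces: independent verification in tests and the fallback for dimensions
the deterministic quadrature does not cover.

Randomness contract: all draws come from numpy's PCG64 generator; each
operation derives an independent stream from (seed, operation tag) via
SeedSequence spawn keys, so results are bit-reproducible per (n, seed) and
portable across releases.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .detection import CanonicalPair, test_statistic
from .errors import DegenerateStatisticError
from .models import GaussianCondition, as_mixture
from .mixtures import log_likelihood_ratio

__all__ = [
    "McEstimate",
    "sample_condition",
    "sample_test_statistic",
    "mc_operating_point",
    "mc_cdf",
    "mc_char_fn",
]


@dataclass(frozen=True)
class McEstimate:
    """A simulated probability with its binomial standard error."""

    value: float
    se: float
    n: int
    seed: int

    def to_dict(self) -> dict:
        return {"value": self.value, "se": self.se, "n": self.n, "seed": self.seed}


def _rng(seed: int, tag: str) -> np.random.Generator:
    """PCG64 stream keyed by (seed, crc32(tag))."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(zlib.crc32(tag.encode()),))
    return np.random.Generator(np.random.PCG64(ss))


def _binomial_estimate(hits: np.ndarray, n: int, seed: int) -> McEstimate:
    p = float(np.mean(hits))
    return McEstimate(value=p, se=float(np.sqrt(p * (1.0 - p) / n)), n=n, seed=seed)


def sample_condition(model, n: int, seed: int) -> np.ndarray:
    """n rows of draws from a Gaussian or mixture class-conditional."""
    if n < 1:
        raise ValueError("n must be positive")
    rng = _rng(seed, "sample_condition")
    return _draw(model, n, rng)


def _draw(model, n: int, rng: np.random.Generator) -> np.ndarray:
    if isinstance(model, GaussianCondition):
        chol = np.linalg.cholesky(model.cov)
        return model.mean + rng.standard_normal((n, model.dim)) @ chol.T
    model = as_mixture(model)
    labels = rng.choice(len(model.components), size=n, p=np.asarray(model.weights))
    out = np.empty((n, model.dim))
    for k, comp in enumerate(model.components):
        mask = labels == k
        if mask.any():
            chol = np.linalg.cholesky(comp.cov)
            out[mask] = comp.mean + rng.standard_normal((int(mask.sum()), comp.dim)) @ chol.T
    return out


def sample_test_statistic(
    pair: CanonicalPair, hypothesis: str, n: int, seed: int
) -> np.ndarray:
    """Draws of Z directly in canonical coordinates."""
    if pair.is_degenerate:
        raise DegenerateStatisticError("hypotheses coincide")
    rng = _rng(seed, f"sample_z_{hypothesis}")
    x = rng.standard_normal((n, pair.dim))
    if hypothesis == "H1":
        x = pair.m + x * np.sqrt(pair.lam)
    elif hypothesis != "H0":
        raise ValueError(f"hypothesis must be 'H0' or 'H1', got {hypothesis!r}")
    return test_statistic(x, pair)


def mc_operating_point(
    h0,
    h1,
    threshold_spec: tuple[str, float],
    n: int,
    seed: int,
) -> tuple[McEstimate, McEstimate]:
    """Empirical (P_FA, P_D) of a fixed decision rule.

    ``threshold_spec`` is ("z_th", value) to threshold the canonical quadratic
    statistic of a Gaussian pair, or ("log_gamma", value) to threshold the
    log-likelihood ratio (works for mixtures).
    """
    kind, value = threshold_spec
    rng0 = _rng(seed, "mc_op_h0")
    rng1 = _rng(seed, "mc_op_h1")
    y0 = _draw(h0, n, rng0)
    y1 = _draw(h1, n, rng1)
    if kind == "z_th":
        from .detection import canonicalize

        pair = canonicalize(h0, h1)
        stat0 = test_statistic(pair.to_canonical(y0), pair)
        stat1 = test_statistic(pair.to_canonical(y1), pair)
    elif kind == "log_gamma":
        m0, m1 = as_mixture(h0), as_mixture(h1)
        stat0 = log_likelihood_ratio(y0, m0, m1)
        stat1 = log_likelihood_ratio(y1, m0, m1)
    else:
        raise ValueError(f"unknown threshold kind {kind!r}")
    return (
        _binomial_estimate(stat0 > value, n, seed),
        _binomial_estimate(stat1 > value, n, seed),
    )


def mc_cdf(
    pair: CanonicalPair, z: float, hypothesis: str, n: int, seed: int
) -> McEstimate:
    """Empirical F_Z(z; H) from n simulated statistic draws."""
    zs = sample_test_statistic(pair, hypothesis, n, seed)
    return _binomial_estimate(zs <= z, n, seed)


def mc_char_fn(
    pair: CanonicalPair, omega: float, hypothesis: str, n: int, seed: int
) -> tuple[complex, float, float]:
    """Sample mean of e^{j*omega*Z} with per-part standard errors.

    Returns (estimate, se_real, se_imag).
    """
    if omega == 0:
        return 1.0 + 0.0j, 0.0, 0.0
    zs = sample_test_statistic(pair, hypothesis, n, seed)
    vals = np.exp(1j * omega * zs)
    est = complex(vals.mean())
    se_re = float(np.std(vals.real, ddof=1) / np.sqrt(n))
    se_im = float(np.std(vals.imag, ddof=1) / np.sqrt(n))
    return est, se_re, se_im
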