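"""Gaussian and mixture class-conditional models of log-scale responses.

A hypothesis about the cell's environment (e.g. "low TNF" vs "high TNF") is
represented by the distribution of the log-transformed response vector under
that hypothesis.  Log responses are modeled as multivariate Gaussian, so each
hypothesis is a :class:`GaussianCondition`; heterogeneous populations are
weighted mixtures of genotype-specific Gaussians (:class:`MixtureCondition`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DimensionMismatchError, NotSPDError

_SYM_TOL = 1e-10


def _check_spd(cov: np.ndarray, tol: float = _SYM_TOL) -> np.ndarray:
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise NotSPDError(f"covariance must be square, got shape {cov.shape}")
    scale = max(1.0, float(np.abs(cov).max()))
    if np.abs(cov - cov.T).max() > tol * scale:
        raise NotSPDError("covariance is not symmetric within tolerance")
    cov = 0.5 * (cov + cov.T)
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals.min() <= 0:
        raise NotSPDError(
            f"covariance is not positive-definite (min eigenvalue {eigvals.min():g})"
        )
    return cov


@dataclass(frozen=True)
class GaussianCondition:
    """Mean vector and covariance of log responses under one hypothesis.

    Parameters
    ----------
    mean : array-like, shape (N,)
        Mean of ln-responses.
    cov : array-like, shape (N, N)
        Symmetric positive-definite covariance of ln-responses.
    n : int, optional
        Number of cells the model was fitted on (0 for analytic models).
    estimator : str
        Covariance estimator tag; ``"unbiased"`` means the n-1 divisor.
    """

    mean: np.ndarray
    cov: np.ndarray
    n: int = 0
    estimator: str = "unbiased"
    log_scale: bool = True

    def __post_init__(self) -> None:
        mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
        cov = _check_spd(cov)
        if mean.shape[0] != cov.shape[0]:
            raise DimensionMismatchError(
                f"mean has length {mean.shape[0]} but cov is {cov.shape}"
            )
        mean.setflags(write=False)
        cov.setflags(write=False)
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", cov)

    @property
    def dim(self) -> int:
        return self.mean.shape[0]

    def marginal(self, indices: Sequence[int]) -> "GaussianCondition":
        """Gaussian of a coordinate subset (e.g. one time point of two)."""
        idx = list(indices)
        return GaussianCondition(
            mean=self.mean[idx],
            cov=self.cov[np.ix_(idx, idx)],
            n=self.n,
            estimator=self.estimator,
            log_scale=self.log_scale,
        )

    def to_dict(self) -> dict:
        return {
            "dim": self.dim,
            "mean": self.mean.tolist(),
            "cov": self.cov.tolist(),
            "n": self.n,
            "estimator": self.estimator,
            "log_scale": self.log_scale,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, payload: dict) -> "GaussianCondition":
        return cls(
            mean=np.asarray(payload["mean"], dtype=float),
            cov=np.asarray(payload["cov"], dtype=float),
            n=int(payload.get("n", 0)),
            estimator=str(payload.get("estimator", "unbiased")),
            log_scale=bool(payload.get("log_scale", True)),
        )

    @classmethod
    def from_json(cls, path) -> "GaussianCondition":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


_WEIGHT_TOL = 1e-12


@dataclass(frozen=True)
class MixtureCondition:
    """beta-weighted mixture of Gaussian class-conditionals.

    Models a heterogeneous population: with probability ``weights[k]`` a cell
    follows ``components[k]``.  Used for wild-type / knockout mixes where a
    fraction beta of cells carries the knockout.
    """

    components: tuple
    weights: tuple = field(default=())

    def __post_init__(self) -> None:
        comps = tuple(self.components)
        if not comps:
            raise ValueError("mixture needs at least one component")
        w = np.asarray(
            self.weights if len(self.weights) else [1.0 / len(comps)] * len(comps),
            dtype=float,
        )
        if w.shape[0] != len(comps):
            raise DimensionMismatchError("one weight per component required")
        if np.any(w < 0):
            raise ValueError("mixture weights must be nonnegative")
        if abs(w.sum() - 1.0) > _WEIGHT_TOL:
            raise ValueError(f"mixture weights sum to {w.sum():.15g}, not 1")
        dims = {c.dim for c in comps}
        if len(dims) != 1:
            raise DimensionMismatchError(f"components have mixed dims {sorted(dims)}")
        object.__setattr__(self, "components", comps)
        object.__setattr__(self, "weights", tuple(float(x) for x in w))

    @property
    def dim(self) -> int:
        return self.components[0].dim

    def marginal(self, indices: Sequence[int]) -> "MixtureCondition":
        return MixtureCondition(
            components=tuple(c.marginal(indices) for c in self.components),
            weights=self.weights,
        )

    def to_dict(self) -> dict:
        return {
            "dim": self.dim,
            "weights": list(self.weights),
            "components": [c.to_dict() for c in self.components],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "MixtureCondition":
        return cls(
            components=tuple(
                GaussianCondition.from_dict(c) for c in payload["components"]
            ),
            weights=tuple(payload["weights"]),
        )


def as_mixture(model) -> MixtureCondition:
    """Wrap a GaussianCondition as a single-component mixture (idempotent)."""
    if isinstance(model, MixtureCondition):
        return model
    return MixtureCondition(components=(model,), weights=(1.0,))
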