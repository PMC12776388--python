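"""NP detection for heterogeneous (mixture) populations.

When a fraction beta of the population carries the knockout, each hypothesis
becomes a two-component Gaussian mixture (same composition under H0 and H1,
different doses).  The mixture likelihood ratio admits no scalar sufficient
statistic, so the likelihood ratio itself is thresholded and the error
probabilities are obtained by deterministic trapezoid quadrature of the
mixture densities over the decision region {LLR > log gamma} on a bounded
grid (N <= 2); the Monte-Carlo oracle covers higher dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .errors import DimensionMismatchError, UnsupportedDimensionError
from .models import GaussianCondition, MixtureCondition, as_mixture

__all__ = [
    "GridSpec",
    "MixtureOperatingPoint",
    "MixtureErrorProbs",
    "mixture_condition",
    "log_likelihood_ratio",
    "mixture_error_probs",
    "mixture_solve_threshold",
    "beta_sweep_pd",
    "beta_sweep_pfa",
]

_DEFAULT_POINTS = {1: 4001, 2: 801}
_DEFAULT_K_SD = 8.0


@dataclass(frozen=True)
class GridSpec:
    """Bounded quadrature grid: per-dimension [lo, hi] and point counts.

    By default the range covers every component mean +- k_sd marginal SDs
    (k_sd = 8 leaves < 1e-6 of Gaussian mass outside in each tail).
    """

    ranges: tuple[tuple[float, float], ...]
    points: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.ranges) != len(self.points):
            raise DimensionMismatchError("one point count per dimension required")
        for (lo, hi), p in zip(self.ranges, self.points):
            if not lo < hi:
                raise ValueError(f"invalid range [{lo}, {hi}]")
            if p < 3:
                raise ValueError("at least 3 points per dimension required")
        object.__setattr__(
            self, "ranges", tuple((float(a), float(b)) for a, b in self.ranges)
        )
        object.__setattr__(self, "points", tuple(int(p) for p in self.points))

    @property
    def dim(self) -> int:
        return len(self.ranges)

    @classmethod
    def cover(
        cls,
        conditions: Sequence,
        k_sd: float = _DEFAULT_K_SD,
        points: tuple[int, ...] | None = None,
    ) -> "GridSpec":
        """Grid covering every component of every condition to +- k_sd SDs."""
        comps = []
        for cond in conditions:
            comps.extend(as_mixture(cond).components)
        dim = comps[0].dim
        if dim not in _DEFAULT_POINTS and points is None:
            raise UnsupportedDimensionError(
                f"deterministic quadrature supports N in (1, 2); got N={dim}"
            )
        los = np.full(dim, np.inf)
        his = np.full(dim, -np.inf)
        for c in comps:
            sd = np.sqrt(np.diag(c.cov))
            los = np.minimum(los, c.mean - k_sd * sd)
            his = np.maximum(his, c.mean + k_sd * sd)
        pts = points if points is not None else (_DEFAULT_POINTS[dim],) * dim
        return cls(ranges=tuple(zip(los, his)), points=tuple(pts))

    def refine(self, factor: int = 2) -> "GridSpec":
        """Same ranges with (points-1)*factor + 1 points per dimension."""
        return GridSpec(
            ranges=self.ranges,
            points=tuple((p - 1) * factor + 1 for p in self.points),
        )

    def nodes_and_weights(self) -> tuple[np.ndarray, np.ndarray]:
        """Tensor-product trapezoid nodes (P, N) and weights (P,)."""
        axes, wts = [], []
        for (lo, hi), p in zip(self.ranges, self.points):
            ax = np.linspace(lo, hi, p)
            w = np.full(p, ax[1] - ax[0])
            w[0] *= 0.5
            w[-1] *= 0.5
            axes.append(ax)
            wts.append(w)
        mesh = np.meshgrid(*axes, indexing="ij")
        nodes = np.stack([m.ravel() for m in mesh], axis=-1)
        weight = wts[0]
        for w in wts[1:]:
            weight = np.multiply.outer(weight, w)
        return nodes, weight.ravel()


class MixtureErrorProbs(NamedTuple):
    pfa: float
    pd: float
    tail_bound: float  # quadrature mass unaccounted for outside the grid


@dataclass(frozen=True)
class MixtureOperatingPoint:
    """LLR threshold log_gamma with its mixture (P_FA, P_D).

    ``conservative`` flags thresholds where an LLR atom prevented matching the
    target false-alarm level exactly; the reported point is then the largest
    region with pfa <= alpha (randomized tests are out of scope).
    """

    log_gamma: float
    pfa: float
    pd: float
    conservative: bool = False


def mixture_condition(
    components: Sequence[GaussianCondition], weights: Sequence[float]
) -> MixtureCondition:
    """Validated beta-weighted mixture; beta = 0/1 collapse to one component."""
    comps = list(components)
    w = [float(x) for x in weights]
    if abs(sum(w) - 1.0) > 1e-12:
        raise ValueError(f"mixture weights sum to {sum(w):.15g}, not 1")
    keep = [(c, x) for c, x in zip(comps, w) if x > 0.0]
    if not keep:
        raise ValueError("at least one positive weight required")
    comps, w = zip(*keep)
    return MixtureCondition(components=tuple(comps), weights=tuple(w))


def _mixture_logpdf(y: np.ndarray, mixture: MixtureCondition) -> np.ndarray:
    y = np.atleast_2d(np.asarray(y, dtype=float))
    logs = np.stack(
        [
            np.log(wk)
            + stats.multivariate_normal.logpdf(y, mean=c.mean, cov=c.cov)
            for c, wk in zip(mixture.components, mixture.weights)
        ],
        axis=0,
    )
    return logsumexp(logs, axis=0)


def log_likelihood_ratio(y: np.ndarray, h0, h1) -> np.ndarray:
    """ln p(y; H1) - ln p(y; H0) for mixture (or Gaussian) hypotheses,
    computed with log-sum-exp stability."""
    h0, h1 = as_mixture(h0), as_mixture(h1)
    if h0.dim != h1.dim:
        raise DimensionMismatchError("hypothesis dimensions differ")
    y = np.asarray(y, dtype=float)
    scalar = y.ndim == 1
    out = _mixture_logpdf(y, h1) - _mixture_logpdf(y, h0)
    return float(out[0]) if scalar and out.shape == (1,) else out


class MixtureTest:
    """Precomputed LLR and density masses on a quadrature grid.

    Repeated threshold evaluations (bisection, sweeps) then cost one
    vectorized comparison each.
    """

    def __init__(self, h0, h1, grid: GridSpec | None = None):
        self.h0 = as_mixture(h0)
        self.h1 = as_mixture(h1)
        if self.h0.dim != self.h1.dim:
            raise DimensionMismatchError("hypothesis dimensions differ")
        if grid is None:
            grid = GridSpec.cover([self.h0, self.h1])
        if grid.dim != self.h0.dim:
            raise DimensionMismatchError("grid dimension does not match models")
        self.grid = grid
        nodes, weights = grid.nodes_and_weights()
        lp0 = _mixture_logpdf(nodes, self.h0)
        lp1 = _mixture_logpdf(nodes, self.h1)
        self.llr = lp1 - lp0
        self.mass0 = np.exp(lp0) * weights
        self.mass1 = np.exp(lp1) * weights
        self.tail_bound = max(
            abs(1.0 - self.mass0.sum()), abs(1.0 - self.mass1.sum())
        )
        if self.h0.dim == 1:
            # exact sub-cell integration against the piecewise-linear LLR
            # interpolant (the 1-D boundary may cut several cells when the
            # mixture LLR is non-monotone)
            self._x1 = nodes[:, 0]
            self._f0 = np.exp(lp0)
            self._f1 = np.exp(lp1)
        else:
            # sorted-by-LLR suffix masses with fractional inclusion of the
            # straddling node: the many boundary cells of a 2-D region have
            # roughly canceling sub-cell errors, validated against Monte Carlo
            order = np.argsort(self.llr)
            self._llr_sorted = self.llr[order]
            self._m0_sorted = self.mass0[order]
            self._m1_sorted = self.mass1[order]
            self._suffix0 = np.concatenate(
                [np.cumsum(self._m0_sorted[::-1])[::-1], [0.0]]
            )
            self._suffix1 = np.concatenate(
                [np.cumsum(self._m1_sorted[::-1])[::-1], [0.0]]
            )

    def _error_probs_1d(self, log_gamma: float) -> tuple[float, float]:
        l, x = self.llr, self._x1
        h = x[1] - x[0]
        above = l > log_gamma
        lo_in, hi_in = above[:-1], above[1:]
        out = []
        for f in (self._f0, self._f1):
            f_lo, f_hi = f[:-1], f[1:]
            full = np.where(lo_in & hi_in, 0.5 * h * (f_lo + f_hi), 0.0)
            cross = lo_in ^ hi_in
            dl = l[1:] - l[:-1]
            t = np.where(cross, (log_gamma - l[:-1]) / np.where(dl == 0, 1.0, dl), 0.0)
            f_c = f_lo + t * (f_hi - f_lo)
            upper = np.where(
                cross & hi_in, 0.5 * (1.0 - t) * h * (f_c + f_hi), 0.0
            )
            lower = np.where(cross & lo_in, 0.5 * t * h * (f_lo + f_c), 0.0)
            out.append(float(full.sum() + upper.sum() + lower.sum()))
        return out[0], out[1]

    def error_probs(self, log_gamma: float) -> MixtureErrorProbs:
        """Mass of {LLR > log_gamma} under each hypothesis."""
        if self.h0.dim == 1:
            pfa, pd = self._error_probs_1d(log_gamma)
            return MixtureErrorProbs(
                pfa=pfa, pd=pd, tail_bound=float(self.tail_bound)
            )
        asc = self._llr_sorted
        k = int(np.searchsorted(asc, log_gamma, side="right"))
        pfa = self._suffix0[k]
        pd = self._suffix1[k]
        if 0 < k <= len(asc) - 1:
            d = asc[k] - asc[k - 1]
            if d > 0:
                frac = (asc[k] - log_gamma) / d
                pfa += frac * self._m0_sorted[k - 1]
                pd += frac * self._m1_sorted[k - 1]
        return MixtureErrorProbs(
            pfa=float(pfa), pd=float(pd), tail_bound=float(self.tail_bound)
        )

    def _solve(self, value: float, which: str) -> tuple[float, float]:
        """Bisection for log_gamma where pfa (or pd) crosses ``value``; both
        maps are monotone nonincreasing in log_gamma.  Returns (lo, hi) with
        prob(lo) > value >= prob(hi)."""
        attr = 0 if which == "pfa" else 1
        lo = float(self.llr.min()) - 1.0  # region = everything
        hi = float(self.llr.max()) + 1.0  # region = empty set
        for _ in range(100):
            mid = 0.5 * (lo + hi)
            p = self.error_probs(mid)[attr]
            if p > value:
                lo = mid
            else:
                hi = mid
            if hi - lo < 1e-13 * max(1.0, abs(hi)):
                break
        return lo, hi

    def solve_threshold(self, alpha: float, tol: float = 1e-4) -> MixtureOperatingPoint:
        if not 0.0 < alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {alpha}")
        # the pfa <= alpha (smaller-region) side: conservative under atoms
        _, log_gamma = self._solve(alpha, "pfa")
        probs = self.error_probs(log_gamma)
        return MixtureOperatingPoint(
            log_gamma=log_gamma,
            pfa=probs.pfa,
            pd=probs.pd,
            conservative=abs(probs.pfa - alpha) > tol,
        )

    def solve_pfa_at_pd(self, target_pd: float, tol: float = 1e-4) -> MixtureOperatingPoint:
        if not 0.0 < target_pd < 1.0:
            raise ValueError(f"target_pd must be in (0, 1), got {target_pd}")
        # the pd >= target (larger-region) side so the detection floor holds
        log_gamma, _ = self._solve(target_pd, "pd")
        probs = self.error_probs(log_gamma)
        return MixtureOperatingPoint(
            log_gamma=log_gamma,
            pfa=probs.pfa,
            pd=probs.pd,
            conservative=abs(probs.pd - target_pd) > tol,
        )


def mixture_error_probs(
    h0, h1, log_gamma: float, grid: GridSpec | None = None
) -> MixtureErrorProbs:
    """(P_FA, P_D) of the rule LLR(y) > log_gamma, by grid quadrature."""
    return MixtureTest(h0, h1, grid).error_probs(log_gamma)


def mixture_solve_threshold(
    h0, h1, alpha: float, grid: GridSpec | None = None
) -> MixtureOperatingPoint:
    """Threshold with mixture P_FA = alpha (bisection on the monotone map)."""
    return MixtureTest(h0, h1, grid).solve_threshold(alpha)


def _mix(beta: float, wt: GaussianCondition, ko: GaussianCondition) -> MixtureCondition:
    if beta <= 0.0:
        return as_mixture(wt)
    if beta >= 1.0:
        return as_mixture(ko)
    return MixtureCondition(components=(wt, ko), weights=(1.0 - beta, beta))


def _variants(dim: int, labels: Sequence[str] | None):
    """Coordinate subsets analyzed separately plus the joint set."""
    if dim == 1:
        return [((0,), labels[0] if labels else "t0")]
    out = [((i,), labels[i] if labels else f"t{i}") for i in range(dim)]
    out.append((tuple(range(dim)), labels[dim] if labels and len(labels) > dim else "joint"))
    return out


def beta_sweep_pd(
    wt_h0: GaussianCondition,
    ko_h0: GaussianCondition,
    wt_h1: GaussianCondition,
    ko_h1: GaussianCondition,
    beta_grid: Sequence[float],
    alpha: float,
    variant_labels: Sequence[str] | None = None,
    grid_points: tuple[int, ...] | None = None,
):
    """P_D at fixed alpha versus the knockout fraction beta.

    For each beta, H0 = (1-beta) WT + beta KO at the low dose and H1 the same
    composition at the high dose.  Each single coordinate (time point) and
    the joint set are analyzed as separate variants.
    """
    import pandas as pd

    rows = []
    for idx, label in _variants(wt_h0.dim, variant_labels):
        marg = lambda g: g.marginal(idx)
        for beta in beta_grid:
            test = MixtureTest(
                _mix(beta, marg(wt_h0), marg(ko_h0)),
                _mix(beta, marg(wt_h1), marg(ko_h1)),
                grid=None
                if grid_points is None
                else GridSpec.cover(
                    [
                        _mix(beta, marg(wt_h0), marg(ko_h0)),
                        _mix(beta, marg(wt_h1), marg(ko_h1)),
                    ],
                    points=tuple(grid_points[: len(idx)]),
                ),
            )
            op = test.solve_threshold(alpha)
            rows.append(
                {
                    "beta": float(beta),
                    "variant": label,
                    "pfa": op.pfa,
                    "pd": op.pd,
                    "alpha_or_target": float(alpha),
                    "mode": "fixed_pfa",
                }
            )
    return pd.DataFrame(rows)


def beta_sweep_pfa(
    wt_h0: GaussianCondition,
    ko_h0: GaussianCondition,
    wt_h1: GaussianCondition,
    ko_h1: GaussianCondition,
    beta_grid: Sequence[float],
    target_pd: float,
    variant_labels: Sequence[str] | None = None,
    grid_points: tuple[int, ...] | None = None,
):
    """Smallest P_FA achieving P_D >= target_pd, versus beta."""
    import pandas as pd

    rows = []
    for idx, label in _variants(wt_h0.dim, variant_labels):
        marg = lambda g: g.marginal(idx)
        for beta in beta_grid:
            h0 = _mix(beta, marg(wt_h0), marg(ko_h0))
            h1 = _mix(beta, marg(wt_h1), marg(ko_h1))
            test = MixtureTest(
                h0,
                h1,
                grid=None
                if grid_points is None
                else GridSpec.cover([h0, h1], points=tuple(grid_points[: len(idx)])),
            )
            op = test.solve_pfa_at_pd(target_pd)
            rows.append(
                {
                    "beta": float(beta),
                    "variant": label,
                    "pfa": op.pfa,
                    "pd": op.pd,
                    "alpha_or_target": float(target_pd),
                    "mode": "fixed_pd",
                }
            )
    return pd.DataFrame(rows)
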