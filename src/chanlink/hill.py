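"""Hill concentration-response fitting.

The peak current response I at ligand concentration X follows

    I / I_max = 1 / (1 + (EC50 / X)**n)

with EC50 the half-maximal concentration and n the Hill slope. Fits are
unweighted bounded least squares started from a coarse log-grid scan, run
per oocyte and pooled across oocytes after per-oocyte normalization to the
measured top-concentration response.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .exceptions import NonIdentifiableError

__all__ = ["hill_response", "HillModel", "HillResults", "fit_hill",
           "pooled_fit", "PooledHillResults"]

EC50_BOUNDS = (1e-10, 1e-1)  # molar
SLOPE_BOUNDS = (0.2, 5.0)


def hill_response(x, ec50: float, n: float, imax: float = 1.0):
    """Hill curve; x = 0 maps to 0 and x = inf to imax."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    pos = x > 0
    with np.errstate(over="ignore"):
        out[pos] = imax / (1.0 + (ec50 / x[pos]) ** n)
    out[np.isinf(x)] = imax
    return out if out.ndim else float(out)


@dataclass
class HillResults:
    """Fitted Hill parameters with diagnostics.

    ``covariance`` is the asymptotic covariance of ``param_names``
    (log10(EC50), n, and I_max unless normalized), scaled by the residual
    variance.
    """

    ec50: float
    n: float
    imax: float
    rss: float
    n_points: int
    conc_range: tuple
    normalized: bool
    covariance: np.ndarray | None = None
    param_names: tuple = ()
    n_oocytes: int = 1

    def fraction(self, x):
        """Normalized response in [0, 1]."""
        return hill_response(x, self.ec50, self.n, 1.0)

    def predict(self, x):
        return hill_response(x, self.ec50, self.n, self.imax)

    @property
    def stderr(self) -> dict:
        if self.covariance is None:
            return {}
        se = np.sqrt(np.clip(np.diag(self.covariance), 0, None))
        return dict(zip(self.param_names, se))

    def summary(self) -> str:
        se = self.stderr
        lines = [
            "Hill concentration-response fit",
            "-------------------------------",
            f"EC50   : {self.ec50:.4g} M"
            + (f"  (log10 se {se.get('log10_ec50', float('nan')):.2g})" if se else ""),
            f"slope n: {self.n:.3g}" + (f"  (se {se.get('n', float('nan')):.2g})" if se else ""),
            f"I_max  : {self.imax:.4g}" + ("  (normalized)" if self.normalized else ""),
            f"RSS    : {self.rss:.4g}   points: {self.n_points}   oocytes: {self.n_oocytes}",
        ]
        return "\n".join(lines)


class HillModel:
    """Least-squares Hill model for one concentration-response data set.

    ``normalize=True`` fixes I_max = 1 (responses already scaled);
    otherwise I_max is a free positive parameter. Optional per-point
    ``weights`` multiply the residuals.
    """

    def __init__(self, concentration, response, normalize: bool = False, weights=None):
        x = np.asarray(concentration, dtype=float)
        y = np.asarray(response, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("concentration and response must be 1-D and equal length")
        if np.any(x < 0):
            raise ValueError("negative concentrations are not allowed")
        if np.unique(x[x > 0]).size < 3:
            raise ValueError("at least 3 distinct positive concentrations are required")
        self.x, self.y = x, y
        self.w = np.ones_like(y) if weights is None else np.sqrt(np.asarray(weights, float))
        self.normalize = normalize

    def _grid_scan(self, ec50_grid, n_grid):
        best = (np.inf, None)
        for ec50 in ec50_grid:
            for n in n_grid:
                f = hill_response(self.x, ec50, n)
                if self.normalize:
                    imax = 1.0
                else:
                    denom = np.sum(self.w ** 2 * f * f)
                    imax = np.sum(self.w ** 2 * f * self.y) / denom if denom > 0 else 0.0
                    if imax <= 0:
                        continue
                rss = np.sum((self.w * (self.y - imax * f)) ** 2)
                if rss < best[0]:
                    best = (rss, (ec50, n, imax))
        if best[1] is None:
            raise NonIdentifiableError("grid scan found no admissible Hill parameters")
        return best[1]

    def fit(
        self,
        ec50_bounds: tuple = EC50_BOUNDS,
        n_bounds: tuple = SLOPE_BOUNDS,
        grid: tuple = (40, 17),
        param_space: str = "log",
    ) -> HillResults:
        """Grid-scan initialisation followed by bounded least squares.

        ``param_space`` selects whether EC50 is optimized as log10(EC50)
        (default) or linearly; both converge to the same optimum on
        well-posed data.
        """
        if np.ptp(self.y) < 1e-12 * max(1.0, np.max(np.abs(self.y))):
            raise NonIdentifiableError("all responses are equal: EC50 and slope are not identifiable")
        if param_space not in ("log", "linear"):
            raise ValueError("param_space must be 'log' or 'linear'")
        xpos = self.x[self.x > 0]
        lo = max(ec50_bounds[0], xpos.min() / 1e3)
        hi = min(ec50_bounds[1], xpos.max() * 1e3)
        ec50_grid = np.logspace(np.log10(lo), np.log10(hi), grid[0])
        n_grid = np.linspace(n_bounds[0], n_bounds[1], grid[1])
        ec50_0, n_0, imax_0 = self._grid_scan(ec50_grid, n_grid)

        log_space = param_space == "log"

        def unpack(theta):
            ec50 = 10.0 ** theta[0] if log_space else theta[0]
            n = theta[1]
            imax = 1.0 if self.normalize else theta[2]
            return ec50, n, imax

        def resid(theta):
            ec50, n, imax = unpack(theta)
            return self.w * (hill_response(self.x, ec50, n, imax) - self.y)

        e0 = np.log10(ec50_0) if log_space else ec50_0
        eb = (np.log10(lo), np.log10(hi)) if log_space else (lo, hi)
        theta0 = [e0, n_0]
        lower = [eb[0], n_bounds[0]]
        upper = [eb[1], n_bounds[1]]
        names = ["log10_ec50" if log_space else "ec50", "n"]
        if not self.normalize:
            theta0.append(imax_0)
            lower.append(1e-12)
            upper.append(np.inf)
            names.append("imax")
        sol = least_squares(resid, theta0, bounds=(lower, upper), method="trf")
        ec50, n, imax = unpack(sol.x)
        rss = float(2.0 * sol.cost)
        dof = self.y.size - sol.x.size
        cov = None
        if dof > 0:
            jtj = sol.jac.T @ sol.jac
            try:
                cov = np.linalg.pinv(jtj) * (rss / dof)
            except np.linalg.LinAlgError:  # pragma: no cover
                cov = None
        return HillResults(
            ec50=float(ec50), n=float(n), imax=float(imax), rss=rss,
            n_points=int(self.y.size), conc_range=(float(xpos.min()), float(xpos.max())),
            normalized=self.normalize, covariance=cov, param_names=tuple(names),
        )


def _apply_exclusions(x, y, exclude_conc):
    if not len(exclude_conc):
        return x, y
    keep = np.ones(x.shape, dtype=bool)
    for c in exclude_conc:
        keep &= ~np.isclose(x, c, rtol=1e-6, atol=0.0)
    return x[keep], y[keep]


def fit_hill(concentration, response, normalize: bool = False,
             exclude_conc: Sequence[float] = (), **fit_kwargs) -> HillResults:
    """One-shot Hill fit of (concentration, response) pairs."""
    x = np.asarray(concentration, dtype=float)
    y = np.asarray(response, dtype=float)
    x, y = _apply_exclusions(x, y, exclude_conc)
    return HillModel(x, y, normalize=normalize).fit(**fit_kwargs)


@dataclass
class PooledHillResults:
    """A pooled fit across oocytes plus the per-oocyte fits."""

    pooled: HillResults
    per_oocyte: list = field(default_factory=list)

    def summary(self) -> str:
        parts = [self.pooled.summary(), "", f"per-oocyte fits: {len(self.per_oocyte)}"]
        for i, r in enumerate(self.per_oocyte):
            parts.append(f"  oocyte {i}: EC50 {r.ec50:.4g} M, n {r.n:.3g}")
        return "\n".join(parts)


def pooled_fit(
    datasets: Sequence[tuple],
    normalize_each: bool = True,
    exclude_conc: Sequence[float] = (),
    weight_oocytes_equally: bool = False,
) -> PooledHillResults:
    """Fit the union of several oocytes' points after per-oocyte normalization.

    Each dataset is a (concentration, response) pair. With
    ``normalize_each`` every oocyte's responses are divided by its measured
    response at its highest retained concentration, so amplitude scale drops
    out before pooling; I_max remains a free parameter (the measured top
    response sits below the Hill asymptote whenever the top concentration is
    not fully saturating, so the fitted normalized I_max is typically
    slightly above 1). By default every point carries equal weight;
    ``weight_oocytes_equally`` reweights points by 1/n_i so each oocyte
    contributes equally.
    """
    if not datasets:
        raise ValueError("at least one dataset is required")
    xs, ys, ws, singles = [], [], [], []
    for conc, resp in datasets:
        x = np.asarray(conc, dtype=float)
        y = np.asarray(resp, dtype=float)
        x, y = _apply_exclusions(x, y, exclude_conc)
        if normalize_each:
            top = y[np.argmax(x)]
            if top == 0:
                raise NonIdentifiableError("top-concentration response is zero; cannot normalize")
            y = y / abs(top)
        singles.append(HillModel(x, y).fit())
        xs.append(x)
        ys.append(y)
        ws.append(np.full(x.shape, 1.0 / x.size if weight_oocytes_equally else 1.0))
    pooled = HillModel(
        np.concatenate(xs), np.concatenate(ys),
        weights=np.concatenate(ws),
    ).fit()
    pooled.n_oocytes = len(datasets)
    return PooledHillResults(pooled=pooled, per_oocyte=singles)
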