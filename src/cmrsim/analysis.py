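"""Curve fitting and plotting of CMR results.

Two functional forms describe the sweeps: a saturating exponential in
population size, CMR(N) = a - b*exp(-c*N) (exponential rise at small N,
plateau at large N), and a quadratic in log-log coordinates for the
dependence on gene number, log10 CMR = c0 + c1*log10 n + c2*(log10 n)^2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit

from .cmr import CMREstimate


@dataclass(frozen=True)
class CMRCurve:
    """CMR estimates along population size for one covariate setting."""

    sizes: np.ndarray
    estimates: Tuple[CMREstimate, ...]
    covariate: str = ""
    covariate_value: object = None

    def __post_init__(self):
        sizes = np.asarray(self.sizes, dtype=float)
        object.__setattr__(self, "sizes", sizes)
        if sizes.size != len(self.estimates):
            raise ValueError("sizes and estimates must align")
        if sizes.size and (np.diff(np.sort(sizes)).min(initial=np.inf) <= 0):
            raise ValueError("population sizes must be distinct")

    @property
    def cmr_means(self) -> np.ndarray:
        return np.array([e.mean for e in self.estimates])


class FitError(RuntimeError):
    """Curve fit failed to converge; carries the optimizer diagnostics."""


@dataclass(frozen=True)
class ExponentialFit:
    """Parameters of CMR(N) = a - b*exp(-c*N) plus residual sum of squares."""

    a: float
    b: float
    c: float
    rss: float

    def predict(self, N) -> np.ndarray:
        N = np.asarray(N, dtype=float)
        return self.a - self.b * np.exp(-self.c * N)


def _saturating(N, a, b, c):
    return a - b * np.exp(-c * N)


def fit_exponential(curve, cmr: Optional[Sequence[float]] = None) -> ExponentialFit:
    """Least-squares fit of CMR(N) = a - b*exp(-c*N), a, b, c >= 0.

    Accepts a :class:`CMRCurve` or two arrays (N, CMR); needs at least 4
    points.  Initialized from the data (a <- max CMR, b <- a - min CMR,
    c <- 1/median N).  Non-convergence raises :class:`FitError` with the
    optimizer's message.
    """
    if cmr is None:
        N = np.asarray(curve.sizes, dtype=float)
        y = curve.cmr_means
    else:
        N = np.asarray(curve, dtype=float)
        y = np.asarray(cmr, dtype=float)
    order = np.argsort(N)
    N, y = N[order], y[order]
    if N.size < 4:
        raise ValueError("fit_exponential needs at least 4 points")
    a0 = float(y.max())
    b0 = max(a0 - float(y.min()), 1e-12 * max(a0, 1.0))
    c0 = 1.0 / float(np.median(N))
    try:
        popt, _ = curve_fit(
            _saturating,
            N,
            y,
            p0=(a0, b0, c0),
            bounds=([0.0, 0.0, 0.0], [np.inf, np.inf, np.inf]),
            maxfev=20_000,
        )
    except RuntimeError as err:
        raise FitError(f"exponential fit did not converge: {err}") from err
    resid = y - _saturating(N, *popt)
    return ExponentialFit(a=float(popt[0]), b=float(popt[1]), c=float(popt[2]),
                          rss=float(np.dot(resid, resid)))


@dataclass(frozen=True)
class LogLogQuadraticFit:
    """Coefficients (c0, c1, c2) of log10 y = c0 + c1*x + c2*x^2 with
    x = log10 n, plus per-point residuals in log10 space."""

    coefficients: Tuple[float, float, float]
    residuals: np.ndarray

    def predict(self, n) -> np.ndarray:
        x = np.log10(np.asarray(n, dtype=float))
        c0, c1, c2 = self.coefficients
        return 10.0 ** (c0 + c1 * x + c2 * x * x)


def fit_quadratic_loglog(n: Sequence[float], cmr: Sequence[float]) -> LogLogQuadraticFit:
    """OLS of log10 CMR on log10 n and its square; needs >= 3 strictly
    positive points."""
    n = np.asarray(n, dtype=float)
    y = np.asarray(cmr, dtype=float)
    if n.size < 3:
        raise ValueError("fit_quadratic_loglog needs at least 3 points")
    if (n <= 0).any() or (y <= 0).any():
        raise ValueError("all gene numbers and CMR values must be positive")
    x = np.log10(n)
    ly = np.log10(y)
    # highest degree first from polyfit; re-order to (c0, c1, c2)
    c2, c1, c0 = np.polyfit(x, ly, 2)
    resid = ly - (c0 + c1 * x + c2 * x * x)
    return LogLogQuadraticFit(coefficients=(float(c0), float(c1), float(c2)),
                              residuals=resid)


def reference_overlay(rates=None) -> List[Dict]:
    """Per-base per-generation mutation-rate bands for annotating CMR
    plots, one band per species, e.g. A. thaliana 6.5e-9 to 7.1e-9.

    ``rates`` defaults to the bundled biological-rates fixture; an empty
    table yields no bands.  Purely presentational — never feeds the
    simulator.
    """
    if rates is None:
        from .fixtures import load_fixture

        rates = load_fixture("bio_rates")
    if len(rates) == 0:
        return []
    sub = rates[(rates["basis"] == "per_base") & (rates["unit"] == "per_generation")]
    bands = []
    for species, grp in sub.groupby("species", sort=False):
        bands.append(
            {
                "species": species,
                "low": float(grp["rate_low"].min()),
                "high": float(grp["rate_high"].max()),
            }
        )
    return bands


# ---------------------------------------------------------------------------
# publication-style plots

def plot_cmr_vs_popsize(curves: Sequence[CMRCurve], path, fit: bool = True) -> None:
    """CMR against population size, one line per covariate value, with
    optional saturating-exponential fits."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for curve in curves:
        label = f"{curve.covariate}={curve.covariate_value}" if curve.covariate else None
        pts = ax.plot(curve.sizes, curve.cmr_means, "o", label=label)
        if fit and curve.sizes.size >= 4:
            try:
                f = fit_exponential(curve)
            except (FitError, ValueError):
                continue
            grid = np.linspace(curve.sizes.min(), curve.sizes.max(), 200)
            ax.plot(grid, f.predict(grid), "-", color=pts[0].get_color())
    ax.set_xlabel("population size N")
    ax.set_ylabel("critical mutation rate")
    ax.set_yscale("log")
    if any(c.covariate for c in curves):
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_cmr_vs_genes(
    gene_numbers: Sequence[float],
    cmrs: Sequence[float],
    path,
    gene_length: int = 1000,
    bands: Optional[List[Dict]] = None,
) -> None:
    """Log-log plot of CMR against gene number with the fitted quadratic,
    a 1/L reference line, and optional biological-rate bands."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = np.asarray(gene_numbers, dtype=float)
    y = np.asarray(cmrs, dtype=float)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(n, y, "o", label="simulated CMR")
    if n.size >= 3:
        f = fit_quadratic_loglog(n, y)
        grid = np.logspace(np.log10(n.min()), np.log10(n.max()), 200)
        ax.plot(grid, f.predict(grid), "-", label="quadratic fit")
    ax.plot(n, 1.0 / (n * gene_length), "--", color="gray", label="1/L")
    for band in bands or []:
        ax.axhspan(band["low"], band["high"], alpha=0.2)
        ax.text(n.min(), band["high"], band["species"], fontsize=7, va="bottom")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("gene number n")
    ax.set_ylabel("critical mutation rate")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
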