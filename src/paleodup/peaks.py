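"""Ks distributions, kernel density estimates and multi-Gaussian peak fits.

The procedure mirrors the classical WGD-dating workflow: one Ks value per
syntenic block (the median over its unsaturated anchor pairs), a Gaussian
kernel density estimate of those block medians, and a least-squares fit of
a sum of k Gaussians to the *density curve* (not EM on the raw values; an
EM fit is available as a cross-check). The number of components is chosen
by a small-sample-corrected information criterion computed on the curve
residuals, with ties broken toward fewer components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, signal, stats

from .errors import ConfigurationError, DataError
from .kaks import KS_WINDOW
from .model import SyntenicBlock

GRID_POINTS = 512
MIN_PAIRS_PER_BLOCK = 3


@dataclass
class KsDistribution:
    """A set of Ks values (block medians by default) with a label."""

    values: np.ndarray
    source_label: str = ""
    window: tuple[float, float] = KS_WINDOW

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        lo, hi = self.window
        if self.values.size and (self.values.min() < lo or self.values.max() > hi):
            raise DataError("Ks values outside the configured window")


@dataclass
class DensityCurve:
    """A smoothed density on a uniform Ks grid (normalised over the window).

    ``n_values`` is the number of data points behind the KDE; it sets the
    expected sampling-noise level of the curve, used by the default
    peak-count selection rule.
    """

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    n_values: int | None = None

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))

    @property
    def mode(self) -> float:
        return float(self.grid[int(np.argmax(self.density))])


@dataclass
class PeakModel:
    """Fitted Gaussian mixture over a density curve.

    ``components`` are (weight, mean, sd) sorted by ascending mean;
    ``selection_score`` is the information-criterion value of the selected
    model and ``selection_trace`` maps each candidate k to its score.
    """

    components: list[tuple[float, float, float]]
    n_components: int
    fit_rss: float
    selection_score: float
    selection_trace: dict[int, float] = field(default_factory=dict)

    @property
    def means(self) -> list[float]:
        return [mu for _, mu, _ in self.components]


def block_median_ks(
    kaks_rows: pd.DataFrame,
    blocks: list[SyntenicBlock] | None = None,
    window: tuple[float, float] = KS_WINDOW,
    min_pairs: int = MIN_PAIRS_PER_BLOCK,
    source_label: str = "block medians",
) -> KsDistribution:
    """One representative Ks per block: the median over its usable pairs.

    Usable pairs are unsaturated and inside the Ks window; blocks with
    fewer than ``min_pairs`` usable pairs are dropped. If ``blocks`` is
    given, each block's ``median_ks`` attribute is filled in place.
    """
    if "block_id" not in kaks_rows.columns or "ks" not in kaks_rows.columns:
        raise DataError("Ka/Ks table needs 'block_id' and 'ks' columns")
    lo, hi = window
    usable = kaks_rows[
        (~kaks_rows.get("saturated", False))
        & kaks_rows["ks"].notna()
        & (kaks_rows["ks"] >= lo)
        & (kaks_rows["ks"] <= hi)
    ]
    medians = usable.groupby("block_id")["ks"].agg(["median", "count"])
    medians = medians[medians["count"] >= min_pairs]["median"]
    if medians.empty:
        raise DataError("no blocks with enough usable Ks pairs")
    if blocks is not None:
        lookup = medians.to_dict()
        for blk in blocks:
            blk.median_ks = lookup.get(blk.block_id)
    return KsDistribution(medians.to_numpy(), source_label, window)


def kde(
    distribution: KsDistribution,
    bandwidth: float | str = "auto",
    grid_points: int = GRID_POINTS,
    window: tuple[float, float] | None = None,
) -> DensityCurve:
    """Gaussian-kernel density of a Ks distribution on a uniform grid.

    ``bandwidth="auto"`` uses Silverman's rule; a float is an absolute
    bandwidth in Ks units. The curve is renormalised to unit mass over the
    window (boundary correction).
    """
    values = np.asarray(distribution.values, dtype=float)
    if values.size < 10:
        raise DataError(f"need at least 10 Ks values for a KDE, got {values.size}")
    lo, hi = window if window is not None else distribution.window
    std = values.std(ddof=1)
    if std == 0:
        raise DataError("KDE undefined for constant values")
    if bandwidth == "auto":
        kde_obj = stats.gaussian_kde(values, bw_method="silverman")
        bw = float(kde_obj.factor * std)
    elif isinstance(bandwidth, (int, float)) and bandwidth > 0:
        kde_obj = stats.gaussian_kde(values, bw_method=bandwidth / std)
        bw = float(bandwidth)
    else:
        raise ConfigurationError("bandwidth must be 'auto' or a positive number")
    grid = np.linspace(lo, hi, grid_points)
    density = kde_obj(grid)
    mass = np.trapezoid(density, grid)
    if mass <= 0:
        raise DataError("density mass is zero over the window")
    return DensityCurve(grid, density / mass, bw, n_values=int(values.size))


def _gauss_sum(x: np.ndarray, params: np.ndarray) -> np.ndarray:
    total = np.zeros_like(x)
    for w, mu, sd in params.reshape(-1, 3):
        total += w * np.exp(-0.5 * ((x - mu) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))
    return total


def _initial_means(curve: DensityCurve, k: int) -> list[np.ndarray]:
    """Candidate starting mean vectors: local maxima first, then quantiles."""
    maxima = signal.argrelmax(curve.density, order=3)[0]
    order = maxima[np.argsort(curve.density[maxima])[::-1]]
    peak_means = list(curve.grid[order[:k]])
    starts = []
    if len(peak_means) >= 1:
        lo, hi = curve.grid[0], curve.grid[-1]
        padded = list(peak_means)
        q = 1
        while len(padded) < k:  # pad with evenly spaced extras
            padded.append(lo + (hi - lo) * q / (k + 1))
            q += 1
        starts.append(np.sort(np.array(padded[:k])))
    # always include an evenly spaced start as a second basin
    lo, hi = curve.grid[0], curve.grid[-1]
    starts.append(np.linspace(lo + (hi - lo) / (k + 1), hi - (hi - lo) / (k + 1), k))
    return starts


def _fit_k(curve: DensityCurve, k: int) -> tuple[np.ndarray, float] | None:
    x, y = curve.grid, curve.density
    lo, hi = float(x[0]), float(x[-1])
    width = hi - lo
    # a KDE contains no structure narrower than its kernel, so components
    # narrower than the bandwidth are sub-resolution artefacts
    sd_min = max(2.0 * curve.bandwidth, float(x[1] - x[0]))
    best = None
    for means0 in _initial_means(curve, k):
        sd0 = max(2 * curve.bandwidth, width / (6 * k))
        p0 = []
        for mu in means0:
            w0 = max(float(np.interp(mu, x, y)) * sd0 * np.sqrt(2 * np.pi), 1e-3)
            p0.extend([min(w0, 2.0), mu, sd0])
        lower = [1e-6, lo, sd_min] * k
        upper = [10.0, hi, width] * k
        try:
            res = optimize.least_squares(
                lambda p: _gauss_sum(x, p) - y,
                np.array(p0),
                bounds=(np.array(lower), np.array(upper)),
                max_nfev=4000,
            )
        except Exception:
            continue
        if not res.success and res.status <= 0:
            continue
        rss = float(np.sum(res.fun**2))
        if best is None or rss < best[1] - 1e-15:
            best = (res.x, rss)
    return best


def _aicc(rss: float, n: int, p: int) -> float:
    if n - p - 1 <= 0:
        return np.inf
    return n * np.log(max(rss, 1e-300) / n) + 2 * p + 2 * p * (p + 1) / (n - p - 1)


def _kde_noise_rms(curve: DensityCurve) -> float:
    """Expected RMS sampling error of the KDE ordinates.

    Pointwise, Var[f^(x)] ~ f(x) R(K) / (n h) with R(K) = 1/(2 sqrt(pi))
    for a Gaussian kernel; averaged over the grid this gives the noise
    floor below which curve residuals carry no information.
    """
    if not curve.n_values:
        raise ConfigurationError("curve lacks n_values; use criterion='aicc' or 'bic'")
    r_k = 1.0 / (2.0 * np.sqrt(np.pi))
    var = curve.density * r_k / (curve.n_values * curve.bandwidth)
    return float(np.sqrt(var.mean()))


def fit_gaussian_peaks(
    curve: DensityCurve,
    max_components: int = 4,
    criterion: str = "noise",
) -> PeakModel:
    """Least-squares fit of 1..max_components Gaussians to the density curve.

    Multi-start (initial means at the largest local maxima, plus an evenly
    spaced start). The component count is chosen by ``criterion``:

    * ``"noise"`` (default): the smallest k whose residual RMS is within
      the KDE's expected sampling error — KDE residuals are smooth and
      autocorrelated, so classical information criteria computed on the
      grid ordinates systematically over-fit; the noise floor rule stops
      as soon as the fit is as good as the curve is trustworthy. The
      selection score is max(residual RMS / noise RMS, 1) with an
      infinitesimal preference for fewer components.
    * ``"aicc"`` / ``"bic"``: classical criteria on the grid residuals.

    Ties break toward fewer components. Deterministic given the curve and
    settings.
    """
    if criterion not in ("noise", "aicc", "bic"):
        raise ConfigurationError("criterion must be 'noise', 'aicc' or 'bic'")
    n = curve.grid.size
    noise = _kde_noise_rms(curve) if criterion == "noise" else None
    fits: dict[int, tuple[np.ndarray, float]] = {}
    trace: dict[int, float] = {}
    for k in range(1, max_components + 1):
        fit = _fit_k(curve, k)
        if fit is None:
            continue
        params, rss = fit
        p = 3 * k
        if criterion == "noise":
            score = max(np.sqrt(rss / n) / noise, 1.0) + 1e-6 * k
        elif criterion == "aicc":
            score = _aicc(rss, n, p)
        else:
            score = n * np.log(max(rss, 1e-300) / n) + p * np.log(n)
        fits[k] = (params, rss)
        trace[k] = float(score)
    if not fits:
        raise DataError(
            f"Gaussian peak fit failed to converge for all k in 1..{max_components}"
        )
    best_k = min(trace, key=lambda k: (round(trace[k], 9), k))
    params, rss = fits[best_k]
    comps = sorted(
        [(float(w), float(mu), float(sd)) for w, mu, sd in params.reshape(-1, 3)],
        key=lambda c: c[1],
    )
    return PeakModel(comps, best_k, rss, trace[best_k], trace)


def fit_mixture_em(values: np.ndarray, n_components: int, seed: int = 0) -> PeakModel:
    """EM Gaussian-mixture fit on raw Ks values (cross-check for the LS fit)."""
    from sklearn.mixture import GaussianMixture

    values = np.asarray(values, dtype=float).reshape(-1, 1)
    gm = GaussianMixture(
        n_components=n_components, n_init=5, random_state=seed, covariance_type="full"
    ).fit(values)
    comps = sorted(
        [
            (float(w), float(mu[0]), float(np.sqrt(cov[0, 0])))
            for w, mu, cov in zip(gm.weights_, gm.means_, gm.covariances_)
        ],
        key=lambda c: c[1],
    )
    return PeakModel(comps, n_components, float("nan"), float(gm.bic(values)))
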