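"""Evolutionary-rate correction, WGD dating and LTR insertion dating.

All dating rests on the molecular-clock relation Ks = 2 r T: a pair of
sequences that diverged T years ago at synonymous rate r (substitutions per
site per year) accumulates Ks substitutions per synonymous site between
them. Cross-lineage rate differences are handled with a correction
coefficient rho = Ks_out(reference) / Ks_out(species): the ratio of the two
lineages' ortholog-peak Ks values against a common outgroup rescales any Ks
observed in a species onto the reference lineage's clock.

LTR retrotransposon insertion dating uses the same clock on the element's
two terminal repeats, identical at insertion: lambda is the mismatch
proportion of their alignment, K = -0.75 ln(1 - 4 lambda / 3) the
Jukes–Cantor distance, and T = K / (2 r).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from Bio import Align

from .errors import ConfigurationError, DataError
from .peaks import DensityCurve, KsDistribution, kde
from .simcore import LTR_RATE


@dataclass(frozen=True)
class RateCorrection:
    """Ks correction coefficient of one species against a reference."""

    reference_species: str
    species: str
    ks_out_ref: float
    ks_out_species: float

    @property
    def rho(self) -> float:
        return self.ks_out_ref / self.ks_out_species

    def correct(self, observed_ks: float) -> float:
        """Rescale a Ks observed in this species onto the reference clock."""
        return observed_ks * self.rho


@dataclass(frozen=True)
class SubstitutionRate:
    """A synonymous substitution rate with its calibration."""

    r: float  # substitutions / site / year
    calibration_ks: float | None = None
    calibration_age_ma: float | None = None
    node_label: str = ""


@dataclass(frozen=True)
class WgdAgeEstimate:
    """A dated WGD peak: age = peak_ks / (2 r), in Ma."""

    peak_ks: float
    rate: float
    age_ma: float
    ci_ma: tuple[float, float] | None = None


@dataclass
class LTRPair:
    """One LTR element's 5'/3' divergence and insertion age."""

    element_id: str
    lam: float | None = None  # nucleic-acid diversity (mismatch proportion)
    K: float | None = None  # JC genetic distance
    T_ma: float | None = None  # insertion age
    saturated: bool = False


def correction_coefficient(
    ortholog_peaks: dict[str, float], reference: str
) -> list[RateCorrection]:
    """Correction coefficients rho = Ks_out(ref) / Ks_out(species).

    ``ortholog_peaks`` maps each species to the Ks peak of its orthologs
    against a common outgroup. The reference species gets rho = 1.
    """
    if reference not in ortholog_peaks:
        raise ConfigurationError(f"reference species {reference!r} not in the peak map")
    for sp, peak in ortholog_peaks.items():
        if not peak > 0:
            raise DataError(f"non-positive ortholog peak Ks for {sp!r}: {peak}")
    ref_peak = ortholog_peaks[reference]
    return [
        RateCorrection(reference, sp, ref_peak, peak)
        for sp, peak in ortholog_peaks.items()
    ]


def calibrate_rate(
    corrected_ks: float, calibration_age_ma: float, label: str = ""
) -> SubstitutionRate:
    """Rate from a calibration node: r = Ks / (2 * age in years)."""
    if corrected_ks <= 0 or calibration_age_ma <= 0:
        raise ConfigurationError("corrected Ks and calibration age must be positive")
    r = corrected_ks / (2.0 * calibration_age_ma * 1e6)
    return SubstitutionRate(r, corrected_ks, calibration_age_ma, label)


def date_wgd(
    peak_ks: float,
    rate: SubstitutionRate | float,
    bootstrap_values: np.ndarray | None = None,
    n_boot: int = 200,
    seed: int = 0,
) -> WgdAgeEstimate:
    """Date a WGD from its Ks peak: T = Ks / (2 r), reported in Ma.

    If ``bootstrap_values`` (the block medians behind the peak) are given,
    a percentile CI is computed by resampling them and re-locating the
    nearest density mode.
    """
    r = rate.r if isinstance(rate, SubstitutionRate) else float(rate)
    if peak_ks <= 0 or r <= 0:
        raise ConfigurationError("peak Ks and rate must be positive")
    age_ma = peak_ks / (2.0 * r) / 1e6
    ci = None
    if bootstrap_values is not None and len(bootstrap_values) >= 10:
        rng = np.random.default_rng(seed)
        values = np.asarray(bootstrap_values, dtype=float)
        ages = []
        for _ in range(n_boot):
            sample = rng.choice(values, size=values.size, replace=True)
            dist = KsDistribution(sample, window=(min(sample.min(), 0.0), sample.max()))
            curve = kde(dist, window=dist.window)
            # nearest local mode to the reported peak
            dens, grid = curve.density, curve.grid
            modes = [
                grid[i]
                for i in range(1, grid.size - 1)
                if dens[i] >= dens[i - 1] and dens[i] >= dens[i + 1]
            ]
            m = min(modes, key=lambda x: abs(x - peak_ks)) if modes else curve.mode
            ages.append(m / (2.0 * r) / 1e6)
        ci = (float(np.percentile(ages, 2.5)), float(np.percentile(ages, 97.5)))
    return WgdAgeEstimate(peak_ks, r, age_ma, ci)


def _nucleotide_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.match_score = 5.0
    aligner.mismatch_score = -4.0
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aligner.mode = "global"
    return aligner


def ltr_divergence(ltr_5p: str, ltr_3p: str, element_id: str = "") -> LTRPair:
    """Nucleic-acid diversity lambda of an element's two LTR copies.

    The copies are globally aligned; lambda = mismatches / aligned non-gap
    columns (gap columns excluded).
    """
    if not ltr_5p or not ltr_3p:
        raise DataError(f"element {element_id or '?'}: empty LTR sequence")
    a = _nucleotide_aligner().align(ltr_5p.upper(), ltr_3p.upper())[0]
    s1, s2 = str(a[0]), str(a[1])
    comparable = mismatches = 0
    for x, y in zip(s1, s2):
        if x == "-" or y == "-":
            continue
        comparable += 1
        mismatches += x != y
    if comparable == 0:
        raise DataError(f"element {element_id or '?'}: no comparable alignment columns")
    return LTRPair(element_id, lam=mismatches / comparable)


def ltr_insertion_time(pair: LTRPair, r: float = LTR_RATE) -> LTRPair:
    """Fill in K = -0.75 ln(1 - 4 lambda/3) and T = K / (2 r) in Ma.

    lambda >= 3/4 saturates the Jukes–Cantor correction: the pair is
    flagged and left undated.
    """
    if pair.lam is None:
        raise DataError("lambda not computed; run ltr_divergence first")
    if r <= 0:
        raise ConfigurationError("substitution rate must be positive")
    if pair.lam >= 0.75:
        pair.saturated = True
        pair.K = None
        pair.T_ma = None
        return pair
    pair.K = -0.75 * math.log1p(-4.0 * pair.lam / 3.0)
    pair.T_ma = pair.K / (2.0 * r) / 1e6
    return pair


def date_ltr_cohort(
    pairs: list[tuple[str, str, str]] | "object",
    r: float = LTR_RATE,
) -> list[LTRPair]:
    """Align and date a whole cohort of (element_id, 5' LTR, 3' LTR) tuples.

    Also accepts a :class:`paleodup.simcore.LTRCohort` (its true ages are
    ignored).
    """
    items = getattr(pairs, "pairs", pairs)
    out = []
    for item in items:
        element_id, s5, s3 = item[0], item[1], item[2]
        out.append(ltr_insertion_time(ltr_divergence(s5, s3, element_id), r))
    return out


def ltr_burst_profile(
    pairs: list[LTRPair], bandwidth: float | str = "auto", grid_points: int = 512
) -> tuple[DensityCurve, float]:
    """KDE over per-element K values; returns (curve, modal K)."""
    ks = np.array([p.K for p in pairs if p.K is not None], dtype=float)
    if ks.size < 10:
        raise DataError(f"need at least 10 dateable LTR pairs, got {ks.size}")
    hi = float(ks.max()) * 1.2 + 1e-6
    if ks.std(ddof=1) <= 1e-9 * max(1.0, abs(float(ks.mean()))):
        # degenerate cohort: all elements at the same K; the density is a
        # point mass and the mode is that value
        grid = np.linspace(0.0, hi, grid_points)
        density = np.zeros_like(grid)
        density[int(np.argmin(np.abs(grid - ks[0])))] = 1.0
        step = grid[1] - grid[0] if grid_points > 1 else 1.0
        return DensityCurve(grid, density / (density.sum() * step), 0.0, ks.size), float(ks[0])
    dist = KsDistribution(ks, "LTR K", window=(0.0, hi))
    curve = kde(dist, bandwidth=bandwidth, grid_points=grid_points, window=(0.0, hi))
    return curve, curve.mode
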