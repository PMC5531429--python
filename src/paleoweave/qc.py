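"""Authentication-layer estimators for ancient samples: genetic sex from
Y-read fractions, mtDNA and X-chromosome contamination rates, and the
5'-end deamination damage profile."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy.optimize import curve_fit

from .simdata import SitePileup, deamination_susceptible_code

Z95 = 1.959963984540054


@dataclass
class QcResult:
    ry: Optional[float] = None
    ry_ci: Optional[Tuple[float, float]] = None
    sex_call: Optional[str] = None
    mt_contamination: Optional[float] = None
    mt_contamination_ci: Optional[Tuple[float, float]] = None
    x_contamination: Optional[float] = None
    x_contamination_flag: str = ""
    damage_curve: Optional[dict] = None
    damage_fit: Optional[Tuple[float, float]] = None  # (delta_hat, d_half_hat)
    extras: dict = field(default_factory=dict)


def _binomial_ci(k: int, n: int) -> Tuple[float, float]:
    p = k / n
    half = Z95 * np.sqrt(max(p * (1 - p), 0.0) / n)
    return (max(0.0, p - half), min(1.0, p + half))


def sex_from_counts(
    n_y_reads: int,
    n_xy_reads: int,
    t_low: float = 0.016,
    t_high: float = 0.075,
) -> QcResult:
    """Genetic sex from the Y fraction of sex-chromosome reads.

    Ry = nY / (nX + nY) with a normal-approximation binomial CI; the call is
    XX when the CI upper bound is below ``t_low``, XY when the lower bound is
    above ``t_high``, indeterminate otherwise. The default thresholds follow
    the shotgun-data convention of the originating method and are
    configurable.
    """
    if n_xy_reads <= 0:
        raise ValueError("need at least one sex-chromosome read")
    ry = n_y_reads / n_xy_reads
    lo, hi = _binomial_ci(n_y_reads, n_xy_reads)
    if hi < t_low:
        call = "XX"
    elif lo > t_high:
        call = "XY"
    else:
        call = "indeterminate"
    return QcResult(ry=ry, ry_ci=(lo, hi), sex_call=call)


def mt_contamination(n_mismatch: int, n_total: int) -> QcResult:
    """Contamination from mismatches at mtDNA haplogroup-defining sites."""
    if n_total <= 0:
        raise ValueError("need at least one read at defining sites")
    rate = n_mismatch / n_total
    return QcResult(mt_contamination=rate, mt_contamination_ci=_binomial_ci(n_mismatch, n_total))


def x_contamination(r_snp: float, r_adj: float, fbar: float) -> QcResult:
    """Excess-mismatch moment estimator of male X-chromosome contamination.

    A male carries one X, so any minor-allele reads at polymorphic X sites in
    excess of the error baseline (mismatch rate at adjacent non-polymorphic
    sites) indicate a second DNA source: c = (r_snp - r_adj)/(fbar - r_adj),
    with fbar the mean minor-allele frequency of the contaminating
    population at those sites. Clamped to [0, 1].
    """
    res = QcResult()
    if fbar <= r_adj:
        res.x_contamination = float("nan")
        res.x_contamination_flag = "undefined: fbar <= adjacent-site error rate"
        return res
    c = (r_snp - r_adj) / (fbar - r_adj)
    if c < 0:
        res.x_contamination_flag = "negative raw estimate clamped to 0"
    res.x_contamination = float(np.clip(c, 0.0, 1.0))
    return res


def damage_profile(pileup: SitePileup, max_d: int = 20) -> QcResult:
    """Observed C→T (and strand-complement G→A) rate by 5'-distance, with an
    exponential-decay fit rate(d) = delta * 2^(-d / d_half).

    Eligible reads carry the deamination-susceptible allele at a transition
    site; the observed rate counts conversions to the product allele.
    """
    sus = deamination_susceptible_code(pileup.sites)
    site_sus = sus[pileup.site_idx]
    eligible = (site_sus >= 0) & (pileup.true_allele == site_sus)
    d = pileup.dist5[eligible]
    converted = pileup.observed[eligible] == (1 - site_sus[eligible])

    ds, rates, ns = [], [], []
    for dist in range(max_d + 1):
        sel = d == dist
        n = int(sel.sum())
        if n == 0:
            continue
        ds.append(dist)
        ns.append(n)
        rates.append(float(converted[sel].mean()))
    curve = {"distance": np.array(ds), "rate": np.array(rates), "n": np.array(ns)}

    fit = None
    if len(ds) >= 3 and max(rates) > 0:
        model = lambda x, delta, dh: delta * np.power(2.0, -x / dh)
        try:
            popt, _ = curve_fit(
                model,
                np.array(ds, dtype=float),
                np.array(rates),
                p0=[max(rates), 2.0],
                sigma=1.0 / np.sqrt(np.array(ns)),
                bounds=([0.0, 0.05], [0.75, 50.0]),
                maxfev=10000,
            )
            fit = (float(popt[0]), float(popt[1]))
        except RuntimeError:
            fit = None
    return QcResult(damage_curve=curve, damage_fit=fit)


# ---------------------------------------------------------------------------
# Simulation helpers used by the QC validation suite
# ---------------------------------------------------------------------------


def simulate_sex_counts(
    sex: str,
    n_x_sites: int,
    coverage_lambda: float,
    rng: np.random.Generator,
    y_alignable_frac: float = 0.099,
    mismap_rate: float = 0.001,
) -> Tuple[int, int]:
    """Poisson read counts over the sex chromosomes for a simulated individual.

    A male carries one X and a Y whose alignable content yields an expected
    Y-read fraction of roughly y_alignable_frac / (0.5 + y_alignable_frac);
    a female contributes only a small Y mismapping rate.
    """
    if sex == "XY":
        n_x = rng.poisson(coverage_lambda * n_x_sites * 0.5)
        n_y = rng.poisson(coverage_lambda * n_x_sites * y_alignable_frac)
    elif sex == "XX":
        n_x = rng.poisson(coverage_lambda * n_x_sites * 1.0)
        n_y = rng.poisson(coverage_lambda * n_x_sites * mismap_rate)
    else:
        raise ValueError("sex must be 'XX' or 'XY'")
    return int(n_y), int(n_x + n_y)


def simulate_x_mismatch_rates(
    contamination: float,
    fbar: float,
    error_rate: float,
    n_reads: int,
    rng: np.random.Generator,
) -> Tuple[float, float]:
    """(r_snp, r_adj) under the moment model for a male X chromosome."""
    p_mismatch_snp = error_rate + contamination * fbar
    k_snp = rng.binomial(n_reads, p_mismatch_snp)
    k_adj = rng.binomial(n_reads, error_rate)
    return k_snp / n_reads, k_adj / n_reads
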