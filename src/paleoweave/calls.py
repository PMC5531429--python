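"""Genotype representations, site/genotype filters, and the imputation
accuracy / reference-bias evaluation framework.

Internal coordinates are 0-based half-open throughout; VCF/EIGENSTRAT
1-based coordinates are converted at the I/O boundary (see ``paleoweave.io``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .simdata import SitePileup, TRANSVERSION

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Diploid dosages {0,1,2} or haploid {0,1}; ``MISSING`` (-1) elsewhere.

    ``gp`` optionally carries per-call posterior triplets (hom-ref, het,
    hom-alt) summing to 1.
    """

    values: np.ndarray  # (n_individuals, n_sites) int8
    ploidy: int
    individuals: list
    sites: pd.DataFrame
    gp: Optional[np.ndarray] = None  # (n_individuals, n_sites, 3)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.ploidy not in (1, 2):
            raise ValueError("ploidy must be 1 or 2")
        if self.ploidy == 1 and np.any(self.values > 1):
            raise ValueError("haploid matrix contains dosage 2")
        if np.any(self.values > 2):
            raise ValueError("dosage above 2")
        if self.gp is not None:
            s = np.nansum(self.gp, axis=2)
            ok = np.isnan(s) | (np.abs(s - 1.0) < 1e-5) | (s == 0)
            if not np.all(ok):
                raise ValueError("GP triplets must sum to 1")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_sites(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            values=self.values.copy(),
            ploidy=self.ploidy,
            individuals=list(self.individuals),
            sites=self.sites.copy(),
            gp=None if self.gp is None else self.gp.copy(),
        )

    def take_sites(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            values=self.values[:, idx],
            ploidy=self.ploidy,
            individuals=list(self.individuals),
            sites=self.sites.iloc[idx].reset_index(drop=True),
            gp=None if self.gp is None else self.gp[:, idx],
        )


def from_panel(panel, pops: Sequence[str]) -> GenotypeMatrix:
    """Truth diploid genotypes for the given panel populations."""
    mats, inds = [], []
    for pop in pops:
        mats.append(panel.diploid_dosages(pop))
        inds.extend(f"{pop}_{i}" for i in range(panel.n_individuals(pop)))
    return GenotypeMatrix(
        values=np.vstack(mats),
        ploidy=2,
        individuals=inds,
        sites=panel.sites.copy(),
    )


# ---------------------------------------------------------------------------
# Pseudo-haploid calling
# ---------------------------------------------------------------------------


def pseudo_haploid_call(pileup: SitePileup, seed: int) -> GenotypeMatrix:
    """One uniformly chosen read's allele per individual-site; else missing.

    This is the most common representation of low-coverage ancient variant
    data: each individual is haploid, with the sampled read allele as its
    call.
    """
    rng = np.random.default_rng([seed, 6])
    n_ind = pileup.n_individuals
    n_sites = len(pileup.sites)
    values = np.full((n_ind, n_sites), MISSING, dtype=np.int8)
    if pileup.n_reads:
        # pick a uniform read per (individual, site): random priority then first
        prio = rng.random(pileup.n_reads)
        order = np.lexsort((prio, pileup.site_idx, pileup.ind_idx))
        ii = pileup.ind_idx[order]
        ss = pileup.site_idx[order]
        first = np.ones(len(order), dtype=bool)
        first[1:] = (ii[1:] != ii[:-1]) | (ss[1:] != ss[:-1])
        values[ii[first], ss[first]] = pileup.observed[order][first]
    return GenotypeMatrix(
        values=values,
        ploidy=1,
        individuals=list(pileup.individuals),
        sites=pileup.sites.copy(),
    )


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------


@dataclass
class SiteFilterSpec:
    maf_min: float = 0.0
    gp_min: float = 0.0
    transversions_only: bool = False
    require_complete: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.maf_min <= 0.5):
            raise ValueError("maf_min must lie in [0, 0.5]")
        if not (0 <= self.gp_min <= 1):
            raise ValueError("gp_min must lie in [0, 1]")


@dataclass
class FilterReport:
    n_sites_in: int
    genotypes_masked_gp: int = 0
    sites_dropped_transversion: int = 0
    sites_dropped_complete: int = 0
    sites_dropped_maf: int = 0
    n_sites_out: int = 0

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _cohort_maf(values: np.ndarray, ploidy: int) -> np.ndarray:
    valid = values >= 0
    alt = np.where(valid, values, 0).sum(axis=0)
    tot = ploidy * valid.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)
    return np.minimum(p, 1 - p)


def apply_filters(matrix: GenotypeMatrix, spec: SiteFilterSpec):
    """Apply the analysis filters in order GP → transversion → completeness → MAF.

    The GP filter masks individual genotypes whose max posterior falls below
    ``gp_min``; the remaining filters drop sites. MAF is computed on the
    retained (post-masking) calls. Returns (filtered matrix, FilterReport).
    The operation is idempotent.
    """
    if spec.gp_min > 0 and matrix.gp is None:
        raise ValueError("gp_min > 0 requires a matrix with GP")
    out = matrix.copy()
    report = FilterReport(n_sites_in=matrix.n_sites)

    if spec.gp_min > 0:
        gpmax = np.nanmax(np.nan_to_num(out.gp, nan=0.0), axis=2)
        mask = (out.values >= 0) & (gpmax < spec.gp_min)
        report.genotypes_masked_gp = int(mask.sum())
        out.values[mask] = MISSING

    keep = np.ones(out.n_sites, dtype=bool)
    if spec.transversions_only:
        tv = (out.sites["mutation_class"] == TRANSVERSION).to_numpy()
        report.sites_dropped_transversion = int((~tv & keep).sum())
        keep &= tv
    if spec.require_complete:
        complete = (out.values >= 0).all(axis=0)
        report.sites_dropped_complete = int((~complete & keep).sum())
        keep &= complete
    if spec.maf_min > 0:
        maf = _cohort_maf(out.values, out.ploidy)
        ok = ~np.isnan(maf) & (maf >= spec.maf_min)
        report.sites_dropped_maf = int((~ok & keep).sum())
        keep &= ok

    out = out.take_sites(np.flatnonzero(keep))
    report.n_sites_out = out.n_sites
    return out, report


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------


@dataclass
class AlleleFrequencyTable:
    """Populations × sites alt-allele frequency estimates with allele counts."""

    populations: list
    freqs: np.ndarray  # (n_pops, n_sites), NaN where n = 0
    counts: np.ndarray  # (n_pops, n_sites) allele sample counts
    sites: pd.DataFrame

    def pop_index(self, name: str) -> int:
        return self.populations.index(name)

    def freq(self, name: str) -> np.ndarray:
        return self.freqs[self.pop_index(name)]


def allele_frequencies(matrix: GenotypeMatrix, labels: dict) -> AlleleFrequencyTable:
    """Missing-aware per-population alt-allele frequencies.

    ``labels`` maps individual id → population. Haploid calls contribute one
    allele, diploid two.
    """
    unlabelled = [i for i in matrix.individuals if i not in labels]
    if unlabelled:
        raise ValueError(f"unlabelled individuals: {unlabelled[:5]}")
    pops = sorted(set(labels[i] for i in matrix.individuals))
    freqs = np.full((len(pops), matrix.n_sites), np.nan)
    counts = np.zeros((len(pops), matrix.n_sites), dtype=np.int64)
    for pi, pop in enumerate(pops):
        rows = [k for k, ind in enumerate(matrix.individuals) if labels[ind] == pop]
        if not rows:
            raise ValueError(f"empty population {pop!r}")
        vals = matrix.values[rows]
        valid = vals >= 0
        alt = np.where(valid, vals, 0).sum(axis=0)
        n = matrix.ploidy * valid.sum(axis=0)
        counts[pi] = n
        with np.errstate(invalid="ignore"):
            freqs[pi] = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
    return AlleleFrequencyTable(populations=pops, freqs=freqs, counts=counts, sites=matrix.sites.copy())


def combined_allele_frequencies(
    matrices: Sequence[GenotypeMatrix], labels: dict
) -> AlleleFrequencyTable:
    """Allele frequencies pooling matrices of different ploidy on shared sites.

    Haploid calls contribute one allele and diploid two to the same
    population counts (e.g. pseudo-haploid ancients pooled with diploid
    moderns).
    """
    base = matrices[0]
    pops = sorted({labels[i] for m in matrices for i in m.individuals})
    alt = np.zeros((len(pops), base.n_sites))
    n = np.zeros((len(pops), base.n_sites), dtype=np.int64)
    for m in matrices:
        if m.n_sites != base.n_sites:
            raise ValueError("matrices must share the site set")
        for k, ind in enumerate(m.individuals):
            pi = pops.index(labels[ind])
            valid = m.values[k] >= 0
            alt[pi] += np.where(valid, m.values[k], 0)
            n[pi] += m.ploidy * valid
    with np.errstate(invalid="ignore"):
        freqs = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
    return AlleleFrequencyTable(populations=pops, freqs=freqs, counts=n, sites=base.sites.copy())


def merge_frequency_tables(*tables: AlleleFrequencyTable) -> AlleleFrequencyTable:
    """Stack tables computed on the same site set."""
    base = tables[0]
    pops, freqs, counts = [], [], []
    for t in tables:
        if t.freqs.shape[1] != base.freqs.shape[1]:
            raise ValueError("site sets differ")
        pops.extend(t.populations)
        freqs.append(t.freqs)
        counts.append(t.counts)
    return AlleleFrequencyTable(pops, np.vstack(freqs), np.vstack(counts), base.sites)


# ---------------------------------------------------------------------------
# Imputation accuracy
# ---------------------------------------------------------------------------

GENOTYPE_CLASSES = ("hom_ref", "het", "hom_alt")


@dataclass
class AccuracyTable:
    """Concordance stratified by truth genotype class and MAF bin."""

    table: pd.DataFrame  # maf_bin, genotype_class, n_compared, n_concordant, accuracy
    missingness: float
    bin_width: float

    def pooled_accuracy(self, genotype_class: Optional[str] = None) -> float:
        t = self.table
        if genotype_class is not None:
            t = t[t["genotype_class"] == genotype_class]
        n = t["n_compared"].sum()
        return float(t["n_concordant"].sum() / n) if n else float("nan")


def imputation_accuracy(
    truth: GenotypeMatrix,
    calls: GenotypeMatrix,
    bin_width: float = 0.005,
    reference_freqs: Optional[np.ndarray] = None,
) -> AccuracyTable:
    """Stratified concordance between truth and (imputed-like) calls.

    MAF per site comes from ``reference_freqs`` (alt-allele frequencies) if
    given, else from the truth cohort. Missing calls are excluded from both
    numerator and denominator and reported as overall missingness.
    """
    if truth.values.shape != calls.values.shape:
        raise ValueError("truth and calls must be aligned on individuals x sites")
    if reference_freqs is None:
        maf = _cohort_maf(truth.values, truth.ploidy)
    else:
        rf = np.asarray(reference_freqs, dtype=float)
        maf = np.minimum(rf, 1 - rf)
    n_bins = int(np.ceil(0.5 / bin_width))
    bins = np.clip(np.floor(np.nan_to_num(maf) / bin_width).astype(int), 0, n_bins - 1)

    t = truth.values
    c = calls.values
    comparable = (t >= 0) & (c >= 0)
    missing = (t >= 0) & (c < 0)
    missingness = float(missing.sum() / max((t >= 0).sum(), 1))

    rows = []
    bin_mat = np.broadcast_to(bins, t.shape)
    for b in np.unique(bin_mat[comparable]):
        for cls_i, cls in enumerate(GENOTYPE_CLASSES):
            sel = comparable & (bin_mat == b) & (t == cls_i)
            n_cmp = int(sel.sum())
            if n_cmp == 0:
                continue
            n_con = int((t[sel] == c[sel]).sum())
            rows.append((b * bin_width, cls, n_cmp, n_con, n_con / n_cmp))
    table = pd.DataFrame(
        rows, columns=["maf_bin", "genotype_class", "n_compared", "n_concordant", "accuracy"]
    )
    return AccuracyTable(table=table, missingness=missingness, bin_width=bin_width)


# ---------------------------------------------------------------------------
# Reference-bias harness
# ---------------------------------------------------------------------------


def _single_sample_freqs(matrix: GenotypeMatrix, row: int) -> np.ndarray:
    vals = matrix.values[row].astype(float)
    vals[vals < 0] = np.nan
    return vals / matrix.ploidy


def reference_bias_dtest(
    calls_variant: GenotypeMatrix,
    calls_truth: GenotypeMatrix,
    panel_freqs: AlleleFrequencyTable,
    outgroup: str,
    individual: int = 0,
    block_size_bp: int = 5_000_000,
):
    """Test whether a call set drags one individual toward panel populations.

    For each panel population R (≠ outgroup) computes
    D(outgroup, R; truth_calls, variant_calls), treating the two call sets of
    the one individual as single-sample "populations". A call set biased
    toward R yields excess R–variant sharing, i.e. positive D/Z.
    Returns a list of FStatResult.
    """
    from . import fstats  # deferred; fstats consumes this module's tables

    if len(panel_freqs.populations) < 2:
        raise ValueError("panel must contain at least 2 populations")
    ft = _single_sample_freqs(calls_truth, individual)
    fv = _single_sample_freqs(calls_variant, individual)
    table = AlleleFrequencyTable(
        populations=panel_freqs.populations + ["__truth__", "__variant__"],
        freqs=np.vstack([panel_freqs.freqs, ft, fv]),
        counts=np.vstack(
            [
                panel_freqs.counts,
                np.where(np.isnan(ft), 0, calls_truth.ploidy),
                np.where(np.isnan(fv), 0, calls_variant.ploidy),
            ]
        ),
        sites=panel_freqs.sites,
    )
    blocks = fstats.BlockSpec.from_positions(
        table.sites["position_bp"].to_numpy(), block_size_bp=block_size_bp
    )
    results = []
    for r in panel_freqs.populations:
        if r == outgroup:
            continue
        results.append(fstats.d_stat(table, (outgroup, r, "__truth__", "__variant__"), blocks))
    return results
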