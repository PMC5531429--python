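"""Li–Stephens chromosome painting, coancestry matrices and haplotype
donation statistics.

Each recipient haplotype is modelled as an imperfect mosaic of the donor
haplotypes: a hidden Markov chain over K donors in which, across an interval
of g cM, the chain keeps its donor with probability e^(-rho g) and otherwise
jumps to a donor drawn uniformly (1/K, self-return included), and each site's
allele matches the copied donor with probability 1 - theta. Forward–backward
posteriors give, per donor, the expected copied map length (posterior mass
times interval length) and the expected number of chunks (posterior
switch-in events, plus the first site's donor probability).

The coancestry matrix aggregates donor haplotypes to donor individuals; its
expected-length rows conserve total map length per recipient haplotype.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import mannwhitneyu


@dataclass
class PaintingParams:
    """Copying-model parameters.

    ``rho_per_cM`` is the switch intensity per cM; if None it is set to
    K/100 (about one expected switch per cM per 100 donors).
    ``mismatch_prob`` is the per-site copying error theta; if None a
    Watterson-style value t/(2(K+t)) with t = 1/sum_{k<K} 1/k is used.
    """

    rho_per_cM: Optional[float] = None
    mismatch_prob: Optional[float] = None

    def resolve(self, n_donors: int) -> Tuple[float, float]:
        rho = self.rho_per_cM if self.rho_per_cM is not None else n_donors / 100.0
        if self.mismatch_prob is not None:
            theta = self.mismatch_prob
        elif n_donors > 1:
            t = 1.0 / np.sum(1.0 / np.arange(1, n_donors))
            theta = t / (2.0 * (n_donors + t))
        else:
            theta = 0.01
        if rho <= 0 or not (0 < theta < 0.5):
            raise ValueError("need rho > 0 and 0 < theta < 0.5")
        return float(rho), float(theta)


def _site_weights(site_cM: np.ndarray, map_length_cM: float) -> np.ndarray:
    """Map-length weights per site: midpoint boundaries plus chromosome ends."""
    s = np.asarray(site_cM, dtype=float)
    bounds = np.empty(len(s) + 1)
    bounds[0] = 0.0
    bounds[-1] = map_length_cM
    bounds[1:-1] = 0.5 * (s[:-1] + s[1:])
    return np.diff(bounds)


def ls_paint(
    recipient: np.ndarray,
    donors: np.ndarray,
    site_cM: np.ndarray,
    map_length_cM: float,
    params: PaintingParams = PaintingParams(),
) -> Tuple[np.ndarray, np.ndarray]:
    """Paint one recipient haplotype against K donor haplotypes.

    Returns (expected chunk counts, expected copied lengths in cM), each of
    shape (K,). Computations use scaled forward–backward and are stable to
    hundreds of donors and tens of thousands of sites.
    """
    donors = np.asarray(donors)
    if donors.ndim != 2 or donors.shape[0] < 1:
        raise ValueError("need at least one donor haplotype")
    K, S = donors.shape
    if len(recipient) != S:
        raise ValueError("recipient/donor site mismatch")
    rho, theta = params.resolve(K)

    match = donors == recipient[None, :]
    emis = np.where(match, 1.0 - theta, theta)  # (K, S)

    gaps = np.diff(np.asarray(site_cM, dtype=float))
    stay = np.exp(-rho * gaps)  # (S-1,)

    # forward (scaled so each alpha column sums to 1)
    alpha = np.empty((S, K))
    c = np.empty(S)
    a0 = emis[:, 0] / K
    c[0] = a0.sum()
    if c[0] <= 0 or not np.isfinite(c[0]):
        raise FloatingPointError("non-finite likelihood at site 0")
    alpha[0] = a0 / c[0]
    for s in range(1, S):
        a = stay[s - 1]
        pred = a * alpha[s - 1] + (1.0 - a) / K
        un = pred * emis[:, s]
        c[s] = un.sum()
        if c[s] <= 0 or not np.isfinite(c[s]):
            raise FloatingPointError(f"non-finite likelihood at site {s}")
        alpha[s] = un / c[s]

    # backward and accumulation in one pass from the right
    beta = np.ones(K)
    chunks = np.zeros(K)
    gamma_last = alpha[S - 1] * beta
    lengths_gamma = np.empty((S, K))
    lengths_gamma[S - 1] = gamma_last
    for s in range(S - 2, -1, -1):
        a = stay[s]
        eb = emis[:, s + 1] * beta / c[s + 1]
        # switch-in posterior mass for donor j: sum_{i != j} xi_s(i, j)
        chunks += (1.0 - a) / K * (1.0 - alpha[s]) * eb
        beta = a * eb + (1.0 - a) / K * eb.sum()
        lengths_gamma[s] = alpha[s] * beta
    chunks += lengths_gamma[0]  # first site's donor opens a chunk

    w = _site_weights(site_cM, map_length_cM)
    lengths = lengths_gamma.T @ w
    return chunks, lengths


def ls_paint_bruteforce(
    recipient: np.ndarray,
    donors: np.ndarray,
    site_cM: np.ndarray,
    map_length_cM: float,
    params: PaintingParams = PaintingParams(),
) -> Tuple[np.ndarray, np.ndarray]:
    """Exhaustive donor-path enumeration oracle for tiny fixtures.

    Enumerates all K^S donor paths with exact transition/emission weights and
    returns the same (expected chunks, expected lengths) as :func:`ls_paint`.
    Only feasible for a handful of sites and donors.
    """
    donors = np.asarray(donors)
    K, S = donors.shape
    rho, theta = params.resolve(K)
    gaps = np.diff(np.asarray(site_cM, dtype=float))
    stay = np.exp(-rho * gaps)
    w = _site_weights(site_cM, map_length_cM)

    emis = np.where(donors == recipient[None, :], 1.0 - theta, theta)
    total = 0.0
    exp_chunks = np.zeros(K)
    exp_len = np.zeros(K)
    for path in itertools.product(range(K), repeat=S):
        pr = emis[path[0], 0] / K
        for s in range(1, S):
            a = stay[s - 1]
            t = a + (1.0 - a) / K if path[s] == path[s - 1] else (1.0 - a) / K
            pr *= t * emis[path[s], s]
        total += pr
        exp_chunks[path[0]] += pr
        for s in range(1, S):
            if path[s] != path[s - 1]:
                exp_chunks[path[s]] += pr
        for s in range(S):
            exp_len[path[s]] += pr * w[s]
    return exp_chunks / total, exp_len / total


# ---------------------------------------------------------------------------
# Cohort painting
# ---------------------------------------------------------------------------


@dataclass
class CoancestryMatrix:
    """Recipients × donor individuals: expected chunk counts and copied cM."""

    recipients: list
    donors: list
    chunks: np.ndarray  # (n_recipients, n_donors)
    lengths: np.ndarray  # (n_recipients, n_donors), cM
    labels: dict  # individual -> population
    map_length_cM: float

    def donor_group_chunks(self, groups: Optional[Sequence[str]] = None) -> pd.DataFrame:
        """Chunk counts aggregated over donor populations."""
        donor_pops = [self.labels[d] for d in self.donors]
        df = pd.DataFrame(self.chunks, index=self.recipients, columns=self.donors)
        agg = df.T.groupby(np.asarray(donor_pops)).sum().T
        if groups is not None:
            agg = agg[list(groups)]
        return agg

    def to_frame(self, what: str = "chunks") -> pd.DataFrame:
        data = self.chunks if what == "chunks" else self.lengths
        return pd.DataFrame(data, index=self.recipients, columns=self.donors)


def paint_all(
    haplotypes: np.ndarray,
    individuals: Sequence[str],
    labels: dict,
    site_cM: np.ndarray,
    map_length_cM: float,
    params: PaintingParams = PaintingParams(),
    recipient_ids: Optional[Sequence[str]] = None,
    donor_ids: Optional[Sequence[str]] = None,
) -> CoancestryMatrix:
    """Paint every recipient individual against the donor set.

    ``haplotypes`` is (2N, S) with rows 2i, 2i+1 belonging to individual i.
    By default all-vs-all with leave-self-out: each individual's two
    haplotypes are painted against all other individuals' haplotypes.
    Explicit recipient/donor id lists restrict either side; a recipient
    appearing among the donors is still excluded from its own donor set.
    """
    individuals = list(individuals)
    n = len(individuals)
    if haplotypes.shape[0] != 2 * n:
        raise ValueError("haplotypes must have two rows per individual")
    if n < 2:
        raise ValueError("painting needs at least 2 individuals")
    recipients = list(recipient_ids) if recipient_ids is not None else individuals
    donor_pool = list(donor_ids) if donor_ids is not None else individuals
    if recipient_ids is None and donor_ids is None and n < 3:
        raise ValueError("all-vs-all painting needs at least 3 individuals")

    idx = {ind: i for i, ind in enumerate(individuals)}
    chunks = np.zeros((len(recipients), len(donor_pool)))
    lengths = np.zeros((len(recipients), len(donor_pool)))
    for ri, rec in enumerate(recipients):
        dset = [d for d in donor_pool if d != rec]
        if not dset:
            raise ValueError(f"recipient {rec!r} has no donors")
        rows = np.array([j for d in dset for j in (2 * idx[d], 2 * idx[d] + 1)])
        dh = haplotypes[rows]
        col_of = {d: k for k, d in enumerate(donor_pool)}
        for hap_row in (2 * idx[rec], 2 * idx[rec] + 1):
            ch, le = ls_paint(haplotypes[hap_row], dh, site_cM, map_length_cM, params)
            for k, d in enumerate(dset):
                c = col_of[d]
                chunks[ri, c] += ch[2 * k] + ch[2 * k + 1]
                lengths[ri, c] += le[2 * k] + le[2 * k + 1]
    return CoancestryMatrix(
        recipients=recipients,
        donors=donor_pool,
        chunks=chunks,
        lengths=lengths,
        labels=dict(labels),
        map_length_cM=map_length_cM,
    )


# ---------------------------------------------------------------------------
# Donation statistics
# ---------------------------------------------------------------------------


def donation_differential(
    matrix: CoancestryMatrix, donor_x: str, donor_ref: str
) -> pd.Series:
    """Per-recipient chunk-count differential d_r = c_{r,X} - c_{r,ref}.

    Donor individuals themselves are excluded from the returned series.
    Swapping X and ref negates the differential.
    """
    jx = matrix.donors.index(donor_x)
    jr = matrix.donors.index(donor_ref)
    d = matrix.chunks[:, jx] - matrix.chunks[:, jr]
    s = pd.Series(d, index=matrix.recipients)
    return s.drop(index=[r for r in (donor_x, donor_ref) if r in s.index])


def donation_contrast_test(
    d_values: pd.Series, group_a: Sequence[str], group_b: Sequence[str]
) -> Tuple[float, float]:
    """Two-sided Mann–Whitney U comparing differentials between two groups.

    Exact enumeration when n_A + n_B <= 20 (and no ties); normal
    approximation with tie correction otherwise. Returns (U, p).
    """
    a = d_values.loc[list(group_a)].to_numpy(dtype=float)
    b = d_values.loc[list(group_b)].to_numpy(dtype=float)
    method = "exact" if (len(a) + len(b) <= 20 and len(np.unique(np.r_[a, b])) == len(a) + len(b)) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class DonationContrast:
    group1: list
    group2: list
    targets: list
    median1: np.ndarray  # raw per-target median donation, group 1
    median2: np.ndarray
    normalized1: np.ndarray
    normalized2: np.ndarray
    tvd: float
    signed_differences: np.ndarray  # raw median1 - median2 per target
    field_note: str = ""


def tvd_donation(
    matrix: CoancestryMatrix,
    group1: Sequence[str],
    group2: Sequence[str],
    targets: Sequence[str],
) -> DonationContrast:
    """Total variation distance between group median donation profiles.

    For each group the per-target (donor-population) median chunk donation is
    taken across group members, the two vectors are normalized to sum 1, and
    TVD = 1/2 sum |v1 - v2|. Raw signed per-target differences are kept for
    the circle-size style display of absolute donation shifts.
    """
    if not len(group1) or not len(group2):
        raise ValueError("groups must be non-empty")
    agg = matrix.donor_group_chunks()
    missing = set(targets) - set(agg.columns)
    if missing:
        raise ValueError(f"targets not among donor populations: {sorted(missing)}")
    m1 = agg.loc[list(group1), list(targets)].median(axis=0).to_numpy()
    m2 = agg.loc[list(group2), list(targets)].median(axis=0).to_numpy()
    n1 = m1 / m1.sum() if m1.sum() > 0 else m1
    n2 = m2 / m2.sum() if m2.sum() > 0 else m2
    tvd = 0.5 * float(np.abs(n1 - n2).sum())
    return DonationContrast(
        group1=list(group1),
        group2=list(group2),
        targets=list(targets),
        median1=m1,
        median2=m2,
        normalized1=n1,
        normalized2=n2,
        tvd=tvd,
        signed_differences=m1 - m2,
    )


def tvd_vectors(v1: np.ndarray, v2: np.ndarray) -> float:
    """TVD between two already-normalized probability vectors."""
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    return 0.5 * float(np.abs(v1 / v1.sum() - v2 / v2.sum()).sum())


# ---------------------------------------------------------------------------
# PCA and clustering on the coancestry matrix
# ---------------------------------------------------------------------------


def coancestry_pca(matrix: CoancestryMatrix, n_components: int = 10):
    """PCA of the column-centered chunk-count matrix via SVD.

    Returns (coordinates, explained_variance, explained_variance_ratio).
    Component signs are fixed by making the largest-magnitude loading
    positive, so results are deterministic.
    """
    X = matrix.chunks - matrix.chunks.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    k = min(n_components, len(s))
    for j in range(k):
        i_max = np.argmax(np.abs(vt[j]))
        if vt[j, i_max] < 0:
            vt[j] *= -1
            u[:, j] *= -1
    coords = u[:, :k] * s[:k]
    n = X.shape[0]
    ev = s[:k] ** 2 / max(n - 1, 1)
    total_var = (s**2).sum() / max(n - 1, 1)
    ratio = ev / total_var if total_var > 0 else np.zeros_like(ev)
    return coords, ev, ratio


def _dm_loglik(counts: np.ndarray, alpha: float) -> float:
    """Multinomial-Dirichlet marginal log-likelihood of one pooled count row."""
    A = alpha * len(counts)
    N = counts.sum()
    return float(
        gammaln(A) - gammaln(A + N) + np.sum(gammaln(alpha + counts) - gammaln(alpha))
    )


def greedy_cluster(matrix: CoancestryMatrix, prior_concentration: float = 1.0):
    """Greedy agglomeration of recipients by donation profile.

    Merge score is the gain in multinomial-Dirichlet marginal log-likelihood
    of the pooled chunk-count rows under a shared versus separate cluster
    parameter (symmetric Dirichlet prior, per-donor concentration
    ``prior_concentration`` / n_donors). Merging proceeds greedily while some
    merge improves the score; ties break on the smallest index pair. Returns
    (partition as list of recipient-id lists, merge log). This is a
    deterministic stand-in for a full MCMC cluster search.
    """
    counts = matrix.chunks.copy()
    alpha = prior_concentration / counts.shape[1]
    clusters = [[i] for i in range(len(matrix.recipients))]
    sums = [counts[i].copy() for i in range(len(matrix.recipients))]
    lls = [_dm_loglik(s, alpha) for s in sums]
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                gain = _dm_loglik(sums[i] + sums[j], alpha) - lls[i] - lls[j]
                if best is None or gain > best[0] + 1e-12:
                    best = (gain, i, j)
        if best is None or best[0] <= 0:
            break
        gain, i, j = best
        merges.append(([matrix.recipients[k] for k in clusters[i]],
                       [matrix.recipients[k] for k in clusters[j]], gain))
        clusters[i] = clusters[i] + clusters[j]
        sums[i] = sums[i] + sums[j]
        lls[i] = _dm_loglik(sums[i], alpha)
        del clusters[j], sums[j], lls[j]
    partition = [[matrix.recipients[k] for k in c] for c in clusters]
    return partition, merges
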