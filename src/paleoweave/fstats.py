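"""D-, f3-, f4-statistics and F4-ratio admixture proportions with weighted
block-jackknife standard errors.

Sign convention: with D = sum (p1-p2)(p3-p4) / sum (p1+p2-2 p1 p2)(p3+p4-2 p3 p4),
D > 0 indicates excess allele sharing between P1–P3 and between P2–P4
(ABBA > BABA). D and f4 are antisymmetric in (P1,P2) and in (P3,P4) and
invariant to simultaneous allele relabelling p -> 1-p at any site.

Sites with a missing frequency in any argument population are skipped per
statistic (complete case per test). Standard errors use the weighted
delete-one-block jackknife for ratio statistics (Busing, Meijer &
van der Leeden 1999), with block weights proportional to the number of sites
used per block; for equal weights it reduces to the textbook unweighted
jackknife.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .calls import AlleleFrequencyTable

DEFAULT_BLOCK_BP = 5_000_000


@dataclass
class BlockSpec:
    """Assignment of retained sites to contiguous genomic blocks."""

    block_id: np.ndarray  # per-site block index
    n_blocks: int

    @classmethod
    def from_positions(cls, positions: np.ndarray, block_size_bp: int = DEFAULT_BLOCK_BP) -> "BlockSpec":
        positions = np.asarray(positions)
        raw = (positions // block_size_bp).astype(int)
        _, bid = np.unique(raw, return_inverse=True)
        return cls(block_id=bid, n_blocks=int(bid.max()) + 1 if len(bid) else 0)

    @classmethod
    def equal_count(cls, n_sites: int, n_blocks: int) -> "BlockSpec":
        bid = np.minimum(np.arange(n_sites) * n_blocks // n_sites, n_blocks - 1)
        return cls(block_id=bid, n_blocks=n_blocks)


@dataclass
class FStatResult:
    statistic: str
    populations: Tuple[str, ...]
    estimate: float
    se: float
    z: float
    n_blocks: int
    n_sites_used: int
    degenerate: bool = False
    note: str = ""

    def __repr__(self) -> str:  # compact, admixtools-log style
        args = ", ".join(self.populations)
        return (
            f"{self.statistic}({args}) = {self.estimate:+.6f} "
            f"SE {self.se:.6f} Z {self.z:+.2f} (n={self.n_sites_used})"
        )


def block_jackknife(
    numerators: np.ndarray,
    denominators: np.ndarray,
    weights: Optional[np.ndarray] = None,
) -> Tuple[float, float]:
    """Weighted delete-one-block jackknife for a ratio statistic.

    ``numerators`` and ``denominators`` are per-block sums; the estimate is
    sum(num)/sum(den). Weights default to block site counts and must be
    positive for blocks carrying data. Returns (estimate, SE). Permutation
    of block order leaves both unchanged.
    """
    num = np.asarray(numerators, dtype=float)
    den = np.asarray(denominators, dtype=float)
    if weights is None:
        weights = np.ones_like(num)
    m = np.asarray(weights, dtype=float)
    keep = m > 0
    num, den, m = num[keep], den[keep], m[keep]
    g = len(num)
    if g < 2:
        raise ValueError("need at least 2 non-empty blocks")
    N, D = num.sum(), den.sum()
    if D == 0:
        return float("nan"), float("nan")
    theta = N / D
    loo = (N - num) / (D - den)
    n = m.sum()
    h = n / m
    theta_dot = g * theta - float(((1.0 - m / n) * loo).sum())
    tau = h * theta - (h - 1.0) * loo
    var = float(((tau - theta_dot) ** 2 / (h - 1.0)).sum()) / g
    return float(theta), float(np.sqrt(var))


def _freq_rows(freqs: AlleleFrequencyTable, pops) -> np.ndarray:
    return np.vstack([freqs.freq(p) for p in pops])


def _complete(p: np.ndarray) -> np.ndarray:
    return ~np.isnan(p).any(axis=0)


def _per_block_sums(values: np.ndarray, block_id: np.ndarray, n_blocks: int) -> np.ndarray:
    return np.bincount(block_id, weights=values, minlength=n_blocks)


def _ratio_result(
    name: str,
    pops: Tuple[str, ...],
    num_s: np.ndarray,
    den_s: np.ndarray,
    blocks: BlockSpec,
    used: np.ndarray,
) -> FStatResult:
    bid = blocks.block_id[used]
    n_used = int(used.sum())
    nb = blocks.n_blocks
    numb = _per_block_sums(num_s, bid, nb)
    denb = _per_block_sums(den_s, bid, nb)
    wb = np.bincount(bid, minlength=nb).astype(float)
    if (wb > 0).sum() < 2:
        raise ValueError("fewer than 2 blocks with data")
    if denb[wb > 0].sum() == 0:
        return FStatResult(name, pops, float("nan"), float("nan"), float("nan"),
                           int((wb > 0).sum()), n_used, degenerate=True,
                           note="zero denominator")
    est, se = block_jackknife(numb, denb, wb)
    if se == 0:
        return FStatResult(name, pops, est, 0.0, float("nan"),
                           int((wb > 0).sum()), n_used, degenerate=True,
                           note="zero jackknife SE")
    return FStatResult(name, pops, est, se, est / se, int((wb > 0).sum()), n_used)


# ---------------------------------------------------------------------------
# The statistics
# ---------------------------------------------------------------------------


def d_stat(freqs: AlleleFrequencyTable, quartet, blocks: BlockSpec) -> FStatResult:
    """Patterson's D for the quartet (P1, P2, P3, P4)."""
    p = _freq_rows(freqs, quartet)
    used = _complete(p)
    p1, p2, p3, p4 = p[:, used]
    num = (p1 - p2) * (p3 - p4)
    den = (p1 + p2 - 2 * p1 * p2) * (p3 + p4 - 2 * p3 * p4)
    return _ratio_result("D", tuple(quartet), num, den, blocks, used)


def f4(freqs: AlleleFrequencyTable, quartet, blocks: BlockSpec) -> FStatResult:
    """f4 = mean over sites of (p1 - p2)(p3 - p4)."""
    p = _freq_rows(freqs, quartet)
    used = _complete(p)
    p1, p2, p3, p4 = p[:, used]
    num = (p1 - p2) * (p3 - p4)
    den = np.ones_like(num)
    return _ratio_result("f4", tuple(quartet), num, den, blocks, used)


def f3_outgroup(
    freqs: AlleleFrequencyTable,
    trio,
    blocks: BlockSpec,
    correct_bias: bool = True,
) -> FStatResult:
    """Outgroup f3(C; A, B) = mean (pC - pA)(pC - pB) [- hC/(nC-1) correction].

    The finite-sample correction h_C = pC(1-pC)/(nC-1) removes the upward
    bias from sampling noise in C; it is skipped (with a note) when any used
    site has nC <= 1.
    """
    c, a, b = trio
    p = _freq_rows(freqs, (c, a, b))
    used = _complete(p)
    pc, pa, pb = p[:, used]
    num = (pc - pa) * (pc - pb)
    note = ""
    if correct_bias:
        nc = freqs.counts[freqs.pop_index(c)][used].astype(float)
        if np.any(nc <= 1):
            note = "bias correction skipped: nC <= 1 at some sites"
        else:
            num = num - pc * (1 - pc) / (nc - 1)
    den = np.ones_like(num)
    res = _ratio_result("f3", (c, a, b), num, den, blocks, used)
    res.note = note or res.note
    return res


@dataclass
class F4RatioConfig:
    """Population roles for the admixture-proportion ratio.

    alpha = f4(O, A_ind1; X, Out2) / f4(O, A_ind1; A_ind2, Out2), the
    proportion of X's ancestry derived from the source represented by
    A_ind1/A_ind2, with Out2 a reference for the other ancestry side.
    """

    outgroup: str
    a_ind1: str
    a_ind2: str
    target: str  # X, the admixed population
    out2: str


def f4_ratio(freqs: AlleleFrequencyTable, config: F4RatioConfig, blocks: BlockSpec) -> FStatResult:
    """Admixture proportion by the ratio of two f4 statistics.

    Both f4s are evaluated on the common complete-case site set, and the
    whole ratio is jackknifed (numerator and denominator recomputed per
    delete-one-block sample). The result is flagged unreliable when the
    denominator f4 has |Z| < 2.
    """
    pops = (config.outgroup, config.a_ind1, config.a_ind2, config.target, config.out2)
    p = _freq_rows(freqs, pops)
    used = _complete(p)
    po, pa1, pa2, px, pout2 = p[:, used]
    num = (po - pa1) * (px - pout2)
    den = (po - pa1) * (pa2 - pout2)
    res = _ratio_result("f4_ratio", pops, num, den, blocks, used)
    res.statistic = "f4_ratio"

    # denominator reliability check
    den_res = _ratio_result("f4", pops, den, np.ones_like(den), blocks, used)
    if not np.isfinite(den_res.z) or abs(den_res.z) < 2:
        res.degenerate = True
        res.note = (res.note + "; " if res.note else "") + "denominator f4 |Z| < 2: alpha unreliable"
    return res
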