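"""Independent reference implementations (oracles) and tiny simulators used
by the test suite. These deliberately share no code with the package paths
they check."""

from __future__ import annotations

import numpy as np
import pandas as pd

from paleoweave.calls import AlleleFrequencyTable


# ---------------------------------------------------------------------------
# Naive per-site f/D statistics
# ---------------------------------------------------------------------------


def naive_d(p1, p2, p3, p4) -> float:
    num = den = 0.0
    for a, b, c, d in zip(p1, p2, p3, p4):
        num += (a - b) * (c - d)
        den += (a + b - 2 * a * b) * (c + d - 2 * c * d)
    return num / den


def naive_f4(p1, p2, p3, p4) -> float:
    vals = [(a - b) * (c - d) for a, b, c, d in zip(p1, p2, p3, p4)]
    return sum(vals) / len(vals)


def naive_f3(pc, pa, pb, nc=None) -> float:
    vals = []
    for i, (c, a, b) in enumerate(zip(pc, pa, pb)):
        v = (c - a) * (c - b)
        if nc is not None:
            v -= c * (1 - c) / (nc[i] - 1)
        vals.append(v)
    return sum(vals) / len(vals)


def textbook_jackknife(loo_estimates, full_estimate, g) -> float:
    """Unweighted delete-one jackknife SE from leave-one-out estimates."""
    loo = np.asarray(loo_estimates)
    mean = loo.mean()
    return float(np.sqrt((g - 1) / g * ((loo - mean) ** 2).sum()))


# ---------------------------------------------------------------------------
# Frequency-table builders
# ---------------------------------------------------------------------------


def make_freq_table(freq_dict, counts=None, positions=None) -> AlleleFrequencyTable:
    pops = list(freq_dict)
    freqs = np.vstack([np.asarray(freq_dict[p], dtype=float) for p in pops])
    n_sites = freqs.shape[1]
    if counts is None:
        counts = np.full_like(freqs, 20, dtype=np.int64)
    if positions is None:
        positions = np.arange(n_sites) * 10_000
    positions = np.asarray(positions)
    sites = pd.DataFrame(
        {
            "position_bp": positions,
            "genetic_pos_cM": positions / positions.max() * 100 if n_sites > 1 else [0.0],
            "ref_allele": ["A"] * n_sites,
            "alt_allele": ["C"] * n_sites,
            "mutation_class": ["transversion"] * n_sites,
        }
    )
    return AlleleFrequencyTable(populations=pops, freqs=freqs, counts=np.asarray(counts), sites=sites)


def sample_pop_freq(q, n_dip, rng):
    """Sampled alt-allele frequency of n_dip diploids at population freq q."""
    return rng.binomial(2 * n_dip, q) / (2 * n_dip)


def bn_draw(p, F, rng):
    p = np.clip(p, 1e-9, 1 - 1e-9)  # guard exact fixation from upstream draws
    return rng.beta(p * (1 - F) / F, (1 - p) * (1 - F) / F)


def null_quartet_table(seed, n_sites=10_000, n_dip=10, F=0.1):
    """Four populations drifting independently from a shared ancestor (a star
    tree): the D expectation is zero for any quartet ordering."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.05, 0.95, n_sites)
    freqs = {}
    for name in ("P1", "P2", "P3", "P4"):
        q = bn_draw(p, F, rng)
        freqs[name] = sample_pop_freq(q, n_dip, rng)
    return make_freq_table(freqs, counts=np.full((4, n_sites), 2 * n_dip))


def admixed_ratio_table(seed, alpha=0.25, n_sites=50_000, n_dip=10, F=0.15):
    """Frequency-level admixture-ratio fixture.

    X = alpha * (source-1 branch) + (1 - alpha) * (source-2 branch); A_ind1
    and A_ind2 are two further-drifted samples of source 1, Out2 of source 2,
    O of the root. alpha is recovered by
    f4(O, A1; X, Out2) / f4(O, A1; A2, Out2).
    """
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.05, 0.95, n_sites)
    q1 = bn_draw(p, F, rng)  # source-1 branch
    q2 = bn_draw(p, F, rng)  # source-2 branch
    Fi = 0.02  # extra individual-level drift
    freqs = {
        "O": sample_pop_freq(bn_draw(p, Fi, rng), n_dip, rng),
        "A1": sample_pop_freq(bn_draw(q1, Fi, rng), n_dip, rng),
        "A2": sample_pop_freq(bn_draw(q1, Fi, rng), n_dip, rng),
        "X": sample_pop_freq(alpha * q1 + (1 - alpha) * q2, n_dip, rng),
        "Out2": sample_pop_freq(bn_draw(q2, Fi, rng), n_dip, rng),
    }
    return make_freq_table(freqs, counts=np.full((5, n_sites), 2 * n_dip))


def geneflow_quartet_table(seed, gamma=0.2, n_sites=50_000, n_dip=10, F=0.1):
    """Quartet where P3 received ``gamma`` ancestry from P2's source."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.05, 0.95, n_sites)
    q1 = bn_draw(p, F, rng)
    q2 = bn_draw(p, F, rng)
    q3_base = bn_draw(p, F, rng)
    q3 = (1 - gamma) * q3_base + gamma * q2
    q4 = bn_draw(p, F, rng)
    freqs = {k: sample_pop_freq(q, n_dip, rng) for k, q in
             zip(("P1", "P2", "P3", "P4"), (q1, q2, q3, q4))}
    return make_freq_table(freqs, counts=np.full((4, n_sites), 2 * n_dip))


# ---------------------------------------------------------------------------
# EHH pair-counting oracle
# ---------------------------------------------------------------------------


def ehh_pair_oracle(haps, core_idx, core_allele, target_idx) -> float:
    carriers = [h for h in haps if h[core_idx] == core_allele]
    lo, hi = min(core_idx, target_idx), max(core_idx, target_idx)
    n = len(carriers)
    same = 0
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += 1
            if np.array_equal(carriers[i][lo : hi + 1], carriers[j][lo : hi + 1]):
                same += 1
    return same / total


# ---------------------------------------------------------------------------
# Small cohort builders
# ---------------------------------------------------------------------------


def two_source_config(seed=0, n_sites=1500, F=0.1, n_samples=8, n_founders=40,
                      **overrides):
    from paleoweave.simdata import SimConfig, SourceSpec

    return SimConfig(
        n_sites=n_sites,
        chrom_length_bp=30_000_000,
        chrom_length_morgans=1.0,
        sources=[
            SourceSpec("A", F, n_founders, n_samples),
            SourceSpec("B", F, n_founders, n_samples),
        ],
        seed=seed,
        **overrides,
    )
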