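"""Polygenic score computation and temporal/ancestry analyses.

Scores are average per-allele effects: for individual i,
score_i = sum_j beta_j * dosage_ij / (2 * n_sites_used_i), with dosages
counted on the effect allele. This mirrors the default of the standard
scoring tool; a sum mode is available. Case-control odds ratios are
converted to liability-scale effects as beta = ln(OR) / 1.81.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .calls import GenotypeMatrix
from .simdata import EffectPanel


def or_to_beta(odds_ratio, alternative_parse: bool = False):
    """Liability-scale effect size from a case-control odds ratio.

    Default is ln(OR) / 1.81; ``alternative_parse`` gives ln(OR / 1.81)
    instead (the other reading of the same conversion phrase).
    """
    orr = np.asarray(odds_ratio, dtype=float)
    if np.any(orr <= 0):
        raise ValueError("odds ratio must be positive")
    out = np.log(orr / 1.81) if alternative_parse else np.log(orr) / 1.81
    return float(out) if np.isscalar(odds_ratio) else out


@dataclass
class ScoreResult:
    scores: pd.Series  # per individual
    n_sites_used: pd.Series
    n_missing: pd.Series
    centered: Optional[pd.Series] = None
    mode: str = "average"


def polygenic_score(
    genotypes: GenotypeMatrix,
    panel: EffectPanel,
    p_threshold: Optional[float] = None,
    missing_policy: str = "skip",
    mode: str = "average",
) -> ScoreResult:
    """Per-individual polygenic score from an effect panel.

    Effect alleles are aligned to the matrix: effect allele = alt uses the
    dosage as is; = ref uses ploidy - dosage. ``missing_policy`` is "skip"
    (drop the SNP for that individual) or "mean_impute" (substitute the
    cohort mean dosage of the effect allele). SNPs with p above
    ``p_threshold`` are excluded when a threshold is given.
    """
    if missing_policy not in ("skip", "mean_impute"):
        raise ValueError("missing_policy must be 'skip' or 'mean_impute'")
    t = panel.table
    if p_threshold is not None:
        t = t[t["p_value"] <= p_threshold]
    site_idx = t["site_idx"].to_numpy()
    if np.any(site_idx >= genotypes.n_sites):
        raise ValueError("panel refers to sites outside the matrix")
    ref = genotypes.sites["ref_allele"].to_numpy()[site_idx]
    alt = genotypes.sites["alt_allele"].to_numpy()[site_idx]
    eff = t["effect_allele"].to_numpy()
    is_alt = eff == alt
    if not np.all(is_alt | (eff == ref)):
        bad = np.flatnonzero(~(is_alt | (eff == ref)))[:3]
        raise ValueError(f"effect allele matches neither ref nor alt at panel rows {bad}")

    g = genotypes.values[:, site_idx].astype(float)
    miss = g < 0
    g[miss] = np.nan
    dos = np.where(is_alt[None, :], g, genotypes.ploidy - g)
    beta = t["beta"].to_numpy()

    if np.all(np.isnan(dos)):
        raise ValueError("no usable SNPs for scoring")

    if missing_policy == "mean_impute":
        col_mean = np.nanmean(dos, axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        dos = np.where(np.isnan(dos), col_mean[None, :], dos)

    used = (~np.isnan(dos)).sum(axis=1)
    if np.any(used == 0):
        raise ValueError("individual(s) with zero usable SNPs")
    contrib = np.nansum(dos * beta[None, :], axis=1)
    if mode == "average":
        scores = contrib / (genotypes.ploidy * used)
    elif mode == "sum":
        scores = contrib
    else:
        raise ValueError("mode must be 'average' or 'sum'")

    idx = pd.Index(genotypes.individuals)
    return ScoreResult(
        scores=pd.Series(scores, index=idx),
        n_sites_used=pd.Series(used, index=idx),
        n_missing=pd.Series(len(t) - used, index=idx),
        mode=mode,
    )


def center_scores(result: ScoreResult) -> ScoreResult:
    """Center scores at the dataset mean (idempotent on the centered field)."""
    centered = result.scores - result.scores.mean()
    return ScoreResult(
        scores=result.scores,
        n_sites_used=result.n_sites_used,
        n_missing=result.n_missing,
        centered=centered,
        mode=result.mode,
    )


def group_score_test(
    scores: pd.Series,
    group_a: Sequence[str],
    group_b: Sequence[str],
    n_perm: int = 10_000,
    seed: int = 0,
) -> dict:
    """Two-sided permutation test of the difference in group mean scores.

    Label permutation with add-one correction; a Mann–Whitney p-value is
    reported alongside for robustness. The permutation p is invariant to
    adding a constant to all scores.
    """
    a = scores.loc[list(group_a)].to_numpy(dtype=float)
    b = scores.loc[list(group_b)].to_numpy(dtype=float)
    obs = a.mean() - b.mean()
    pooled = np.r_[a, b]
    na = len(a)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(perm[:na].mean() - perm[na:].mean()) >= abs(obs) - 1e-15:
            count += 1
    p_perm = (count + 1) / (n_perm + 1)
    mw = stats.mannwhitneyu(a, b, alternative="two-sided")
    return {
        "mean_difference": float(obs),
        "p_permutation": float(p_perm),
        "p_mannwhitney": float(mw.pvalue),
        "n_a": na,
        "n_b": len(b),
    }


def ancestry_score_regression(
    mean_scores: Sequence[float], ancestry_proportions: Sequence[float]
) -> dict:
    """OLS of population mean score on ancestry proportion alpha.

    Returns slope, intercept, Pearson r and its t-test p; flagged degenerate
    when alpha has no variance.
    """
    y = np.asarray(mean_scores, dtype=float)
    x = np.asarray(ancestry_proportions, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 matched (score, ancestry) pairs")
    if np.allclose(x, x[0]):
        return {"slope": float("nan"), "intercept": float("nan"), "r": float("nan"),
                "p": float("nan"), "degenerate": True}
    res = stats.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r": float(res.rvalue),
        "p": float(res.pvalue),
        "degenerate": False,
    }
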