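"""Extended haplotype homozygosity (EHH) decay and furcation structure.

EHH at a target site, for the carriers of a core allele, is the probability
that two randomly chosen carrier chromosomes are identical over the closed
interval between core and target:
EHH = sum_h C(n_h, 2) / C(n_c, 2), where the n_h are the sizes of the
identity classes of the carriers over the interval. No carrier-frequency
floor is applied (low-frequency cores are kept). Haplotype input must be
complete (phased, no missing data).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

DERIVED = 1
ANCESTRAL = 0


def _check_haps(haplotypes: np.ndarray) -> np.ndarray:
    h = np.asarray(haplotypes)
    if h.ndim != 2:
        raise ValueError("haplotypes must be 2-D (n_haps, n_sites)")
    if not np.isin(h, (0, 1)).all():
        raise ValueError("haplotype input must be complete 0/1 data")
    return h


def _identity_class_sizes(segment: np.ndarray) -> np.ndarray:
    _, counts = np.unique(segment, axis=0, return_counts=True)
    return counts


def ehh_at(
    haplotypes: np.ndarray, core_idx: int, core_allele: int, target_idx: int
) -> float:
    """EHH of the core-allele carriers at one target site."""
    h = _check_haps(haplotypes)
    carriers = h[:, core_idx] == core_allele
    n_c = int(carriers.sum())
    if n_c < 2:
        raise ValueError("EHH undefined: fewer than 2 carriers of the core allele")
    lo, hi = sorted((core_idx, target_idx))
    seg = h[carriers, lo : hi + 1]
    counts = _identity_class_sizes(seg)
    pairs = (counts * (counts - 1) // 2).sum()
    return float(pairs / (n_c * (n_c - 1) // 2))


@dataclass
class EHHCurve:
    core_idx: int
    core_allele: int
    n_carriers: int
    target_idx: np.ndarray  # ordered site indices within the window (incl. core)
    positions: np.ndarray  # bp
    values: np.ndarray

    def at_distance(self, dist_bp: float, core_pos: int) -> float:
        """EHH at the window site closest to the requested distance from core."""
        d = np.abs(np.abs(self.positions - core_pos) - dist_bp)
        return float(self.values[np.argmin(d)])


def ehh_decay(
    haplotypes: np.ndarray,
    positions: np.ndarray,
    core_idx: int,
    max_dist_bp: float = 5_000_000,
) -> Tuple[Optional[EHHCurve], Optional[EHHCurve]]:
    """EHH curves for both core alleles over all sites within the window.

    Returns (derived-allele curve, ancestral-allele curve); a side with
    fewer than 2 carriers yields None. Monotone non-increasing decay away
    from the core is guaranteed because identity partitions refine as the
    interval grows.
    """
    h = _check_haps(haplotypes)
    positions = np.asarray(positions)
    core_pos = positions[core_idx]
    window = np.flatnonzero(np.abs(positions - core_pos) <= max_dist_bp)

    out = []
    for allele in (DERIVED, ANCESTRAL):
        carriers = h[:, core_idx] == allele
        n_c = int(carriers.sum())
        if n_c < 2:
            out.append(None)
            continue
        vals = np.array([ehh_at(h, core_idx, allele, t) for t in window])
        out.append(
            EHHCurve(
                core_idx=core_idx,
                core_allele=allele,
                n_carriers=n_c,
                target_idx=window,
                positions=positions[window],
                values=vals,
            )
        )
    return out[0], out[1]


def curve_frame(curve: EHHCurve, core_pos: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "position_bp": curve.positions,
            "distance_bp": curve.positions - core_pos,
            "core_allele": "derived" if curve.core_allele == DERIVED else "ancestral",
            "ehh": curve.values,
        }
    )


# ---------------------------------------------------------------------------
# Furcation structure
# ---------------------------------------------------------------------------


@dataclass
class FurcationNode:
    depth: int  # number of sites from the core along the chosen direction
    count: int  # carriers passing through this node
    allele_path: Tuple[int, ...] = ()
    children: List["FurcationNode"] = field(default_factory=list)

    def counts_at_depth(self, depth: int) -> int:
        if self.depth == depth:
            return self.count
        return sum(c.counts_at_depth(depth) for c in self.children)

    def rendered_children(self) -> List["FurcationNode"]:
        """Children as drawn: singleton branches are pruned from the display
        (their carriers remain in the parent's count)."""
        return [c for c in self.children if c.count > 1]


def furcation(
    haplotypes: np.ndarray,
    core_idx: int,
    core_allele: int,
    direction: str = "right",
) -> FurcationNode:
    """Bifurcation tree of the core-allele carriers along one direction.

    The root holds all carriers; each successive site splits every node by
    its allele. Node counts at any depth sum to the carrier count.
    """
    h = _check_haps(haplotypes)
    carriers = np.flatnonzero(h[:, core_idx] == core_allele)
    if len(carriers) < 1:
        raise ValueError("no carriers of the core allele")
    if direction == "right":
        sites = range(core_idx + 1, h.shape[1])
    elif direction == "left":
        sites = range(core_idx - 1, -1, -1)
    else:
        raise ValueError("direction must be 'left' or 'right'")

    root = FurcationNode(depth=0, count=len(carriers))
    frontier = [(root, carriers)]
    for depth, s in enumerate(sites, start=1):
        new_frontier = []
        for node, members in frontier:
            for allele in (0, 1):
                sub = members[h[members, s] == allele]
                if len(sub) == 0:
                    continue
                child = FurcationNode(
                    depth=depth,
                    count=len(sub),
                    allele_path=node.allele_path + (allele,),
                )
                node.children.append(child)
                new_frontier.append((child, sub))
        frontier = new_frontier
    return root
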