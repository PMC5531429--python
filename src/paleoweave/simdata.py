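"""Synthetic ancient-DNA cohort simulator.

Generates the statistical structure that the downstream analyses assume:

* several differentiated source populations (Balding–Nichols drift from a
  shared ancestral frequency) whose sampled haplotypes are founder mosaics,
  giving within-population haplotype sharing / LD;
* admixed "ancient" individuals built by a two-state Markov ancestry process
  along the genetic map, with truth tracts recorded;
* Poisson low-coverage read sampling with sequencing error and 5'-end
  C→T / G→A deamination damage;
* imputed-like diploid calls with MAF- and genotype-class-dependent error
  and per-call GP posterior triplets;
* a polygenic trait with known per-allele effects.

All randomness derives from a single root seed through named child streams
(``numpy.random.default_rng([seed, STREAM_ID, ...])``), so each stage is
independently reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# RNG stream key scheme: child generators are created as
# default_rng([root_seed, STREAM, extra...]) with the constants below.
# ---------------------------------------------------------------------------
STREAM_SOURCES = 1
STREAM_ADMIX = 2
STREAM_READS = 3
STREAM_IMPUTE = 4
STREAM_TRAIT = 5

_BASES = np.array(["A", "C", "G", "T"])
_TRANSITION_PAIRS = {frozenset({"A", "G"}), frozenset({"C", "T"})}

TRANSITION = "transition"
TRANSVERSION = "transversion"


class ConfigurationError(ValueError):
    """Raised for out-of-range or inconsistent simulation parameters."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class SourceSpec:
    name: str
    F: float  # Balding–Nichols drift parameter, in (0, 1)
    n_founders: int
    n_samples: int  # diploid individuals


@dataclass
class AdmixtureEvent:
    target_name: str
    source_a: str
    source_b: str
    alpha: float  # proportion of ancestry from source_a
    generations_g: float  # ancestry-switch intensity per Morgan
    n_samples: int  # diploid individuals
    # optional restriction of the copying pool: source pop name -> list of
    # diploid individual indices whose haplotypes may be copied from
    donor_individuals: Optional[dict] = None


@dataclass
class TraitConfig:
    n_causal: int
    heritability_target: float = 0.5
    n_null: int = 0  # extra near-zero-effect SNPs with uniform p-values


@dataclass
class SimConfig:
    n_sites: int = 5000
    chrom_length_bp: int = 50_000_000
    chrom_length_morgans: float = 1.0
    sources: Sequence[SourceSpec] = field(default_factory=list)
    admixture_events: Sequence[AdmixtureEvent] = field(default_factory=list)
    coverage_lambda: float = 1.0
    deamination_delta: float = 0.2
    seq_error_eps: float = 0.001
    founder_switch_rate_per_morgan: float = 30.0
    read_length: int = 60
    d_half: float = 2.0
    trait: Optional[TraitConfig] = None
    seed: int = 0

    def validate(self) -> None:
        if not np.isfinite(self.coverage_lambda) or self.coverage_lambda <= 0:
            raise ConfigurationError("coverage_lambda must be positive")
        if not (0 <= self.deamination_delta <= 0.5):
            raise ConfigurationError("deamination_delta must lie in [0, 0.5]")
        if not (0 <= self.seq_error_eps <= 0.1):
            raise ConfigurationError("seq_error_eps must lie in [0, 0.1]")
        if self.founder_switch_rate_per_morgan <= 0:
            raise ConfigurationError("founder_switch_rate_per_morgan must be > 0")
        if self.n_sites <= 0 or self.chrom_length_bp <= self.n_sites:
            raise ConfigurationError("need 0 < n_sites < chrom_length_bp")
        names = [s.name for s in self.sources] + [e.target_name for e in self.admixture_events]
        if len(set(names)) != len(names):
            raise ConfigurationError("population names must be unique")
        for s in self.sources:
            if not (0 < s.F < 1):
                raise ConfigurationError(f"source {s.name}: F must lie in (0, 1)")
            if s.n_founders < 1 or s.n_samples < 1:
                raise ConfigurationError(f"source {s.name}: counts must be >= 1")
        for e in self.admixture_events:
            if not (0 <= e.alpha <= 1):
                raise ConfigurationError(f"event {e.target_name}: alpha must lie in [0, 1]")
        if self.trait is not None and self.trait.n_causal > self.n_sites:
            raise ConfigurationError("n_causal must not exceed n_sites")


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------


@dataclass
class HaplotypePanel:
    """Phased 0/1 haplotypes with physical + genetic coordinates.

    ``haplotypes[pop]`` is a (2 * n_individuals, n_sites) uint8 matrix;
    haplotypes 2i and 2i+1 belong to diploid individual i.
    ``truth_tracts[pop][h]`` is the ordered list of (start_bp, end_bp,
    source_name) half-open intervals tiling [0, chrom_length_bp) for
    haplotype h of an admixed population.
    """

    sites: pd.DataFrame  # position_bp, genetic_pos_cM, ref_allele, alt_allele, mutation_class
    haplotypes: dict
    chrom_length_bp: int
    map_length_cM: float
    truth_tracts: dict = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def populations(self) -> list:
        return list(self.haplotypes)

    def n_individuals(self, pop: str) -> int:
        return self.haplotypes[pop].shape[0] // 2

    def diploid_dosages(self, pop: str) -> np.ndarray:
        """(n_individuals, n_sites) alt-allele dosage matrix for one population."""
        h = self.haplotypes[pop]
        return (h[0::2].astype(np.int16) + h[1::2]).astype(np.int8)

    def truth_ancestry_fraction(self, pop: str, source: str) -> np.ndarray:
        """Per-haplotype genome fraction assigned to ``source`` in truth tracts."""
        out = []
        for tracts in self.truth_tracts[pop]:
            tot = sum(e - s for s, e, src in tracts if src == source)
            out.append(tot / self.chrom_length_bp)
        return np.asarray(out)


@dataclass
class SitePileup:
    """Flat read records for a set of individuals at panel sites.

    Columns are parallel arrays; alleles are coded 0 = ref, 1 = alt.
    ``true_allele`` is carried for simulation-truth-aware estimators such as
    the damage profiler.
    """

    individuals: list
    sites: pd.DataFrame
    ind_idx: np.ndarray
    site_idx: np.ndarray
    observed: np.ndarray
    true_chrom: np.ndarray
    true_allele: np.ndarray
    dist5: np.ndarray
    damage_flag: np.ndarray

    @property
    def n_reads(self) -> int:
        return len(self.ind_idx)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "individual": [self.individuals[i] for i in self.ind_idx],
                "site_idx": self.site_idx,
                "observed_allele": self.observed,
                "true_chromosome_index": self.true_chrom,
                "distance_from_5prime_end": self.dist5,
                "damage_flag": self.damage_flag.astype(int),
            }
        )


@dataclass
class EffectPanel:
    """Per-SNP effect-allele panel for polygenic scoring."""

    table: pd.DataFrame  # site_idx, effect_allele, beta, odds_ratio, p_value

    def __post_init__(self) -> None:
        req = {"site_idx", "effect_allele", "beta", "p_value"}
        missing = req - set(self.table.columns)
        if missing:
            raise ValueError(f"EffectPanel missing columns: {sorted(missing)}")
        if len(self.table) and not np.all(np.isfinite(self.table["beta"].astype(float))):
            raise ValueError("beta must be finite")

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# Site table and source populations
# ---------------------------------------------------------------------------


def _draw_sites(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    pos = np.sort(rng.choice(config.chrom_length_bp, size=config.n_sites, replace=False))
    cm = pos / config.chrom_length_bp * config.chrom_length_morgans * 100.0
    ref_i = rng.integers(0, 4, size=config.n_sites)
    alt_i = (ref_i + rng.integers(1, 4, size=config.n_sites)) % 4
    ref = _BASES[ref_i]
    alt = _BASES[alt_i]
    mclass = np.array(
        [
            TRANSITION if frozenset({r, a}) in _TRANSITION_PAIRS else TRANSVERSION
            for r, a in zip(ref, alt)
        ]
    )
    return pd.DataFrame(
        {
            "position_bp": pos,
            "genetic_pos_cM": cm,
            "ref_allele": ref,
            "alt_allele": alt,
            "mutation_class": mclass,
        }
    )


def _founder_mosaic(
    founders: np.ndarray,
    n_haps: int,
    site_morgans: np.ndarray,
    total_morgans: float,
    rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample haplotypes as founder mosaics with Poisson(rate/Morgan) switches."""
    n_f, n_sites = founders.shape
    out = np.empty((n_haps, n_sites), dtype=np.uint8)
    for h in range(n_haps):
        n_sw = rng.poisson(rate * total_morgans)
        cuts = np.sort(rng.uniform(0.0, total_morgans, size=n_sw))
        seg_of_site = np.searchsorted(cuts, site_morgans, side="right")
        choice = rng.integers(0, n_f, size=n_sw + 1)
        out[h] = founders[choice[seg_of_site], np.arange(n_sites)]
    return out


def simulate_sources(config: SimConfig) -> HaplotypePanel:
    """Generate the differentiated source populations of a scenario.

    Per site an ancestral frequency p ~ U(0.05, 0.95) is drawn; population k
    gets q_k ~ Beta(p(1-F_k)/F_k, (1-p)(1-F_k)/F_k) (Balding–Nichols), founder
    haplotypes are iid Bernoulli(q_k), and sampled haplotypes are founder
    mosaics with switch rate ``founder_switch_rate_per_morgan``.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, STREAM_SOURCES])
    sites = _draw_sites(config, rng)
    p = rng.uniform(0.05, 0.95, size=config.n_sites)
    site_m = sites["genetic_pos_cM"].to_numpy() / 100.0
    total_m = config.chrom_length_morgans

    haplotypes = {}
    for spec in config.sources:
        a = p * (1.0 - spec.F) / spec.F
        b = (1.0 - p) * (1.0 - spec.F) / spec.F
        q = rng.beta(a, b)
        founders = (rng.random((spec.n_founders, config.n_sites)) < q).astype(np.uint8)
        haps = _founder_mosaic(
            founders,
            2 * spec.n_samples,
            site_m,
            total_m,
            config.founder_switch_rate_per_morgan,
            rng,
        )
        haplotypes[spec.name] = haps

    return HaplotypePanel(
        sites=sites,
        haplotypes=haplotypes,
        chrom_length_bp=config.chrom_length_bp,
        map_length_cM=config.chrom_length_morgans * 100.0,
    )


# ---------------------------------------------------------------------------
# Admixture
# ---------------------------------------------------------------------------


def simulate_admixed(
    panel: HaplotypePanel, event: AdmixtureEvent, seed: int
) -> HaplotypePanel:
    """Add an admixed population to the panel (mutates and returns it).

    Ancestry along each haplotype follows a two-state Markov process with
    stationary probabilities (alpha, 1-alpha) and potential-switch intensity
    ``generations_g`` per Morgan; at each potential switch the new state is a
    fresh draw from the stationary law, and runs of equal state are merged
    into truth tracts. Within each tract alleles are copied from one
    uniformly chosen haplotype of that tract's source population.
    """
    for src in (event.source_a, event.source_b):
        if src not in panel.haplotypes:
            raise ConfigurationError(f"unknown source population {src!r}")
    name_key = zlib.crc32(event.target_name.encode()) % (2**31)  # stable across processes
    rng = np.random.default_rng([seed, STREAM_ADMIX, name_key])

    total_m = panel.map_length_cM / 100.0
    site_m = panel.sites["genetic_pos_cM"].to_numpy() / 100.0
    L = panel.chrom_length_bp

    pools = {}
    for src in (event.source_a, event.source_b):
        haps = panel.haplotypes[src]
        if event.donor_individuals and src in event.donor_individuals:
            idx = np.asarray(event.donor_individuals[src], dtype=int)
            hap_rows = np.concatenate([2 * idx, 2 * idx + 1])
            hap_rows.sort()
            haps = haps[hap_rows]
        pools[src] = haps

    n_haps = 2 * event.n_samples
    out = np.empty((n_haps, panel.n_sites), dtype=np.uint8)
    all_tracts = []
    names = (event.source_a, event.source_b)
    for h in range(n_haps):
        n_sw = rng.poisson(event.generations_g * total_m)
        cuts = np.sort(rng.uniform(0.0, total_m, size=n_sw))
        states = (rng.random(n_sw + 1) >= event.alpha).astype(int)  # 0 = source_a
        # merge equal-state runs into tracts (boundaries in Morgans -> bp)
        bounds_m = np.concatenate([[0.0], cuts, [total_m]])
        tracts = []
        seg_start = 0
        for i in range(1, n_sw + 1):
            if states[i] != states[seg_start]:
                tracts.append((bounds_m[seg_start], bounds_m[i], states[seg_start]))
                seg_start = i
        tracts.append((bounds_m[seg_start], total_m, states[seg_start]))

        tract_records = []
        for t_i, (m0, m1, st) in enumerate(tracts):
            src = names[st]
            donor = rng.integers(0, pools[src].shape[0])
            lo = np.searchsorted(site_m, m0, side="left")
            hi = np.searchsorted(site_m, m1, side="left") if t_i < len(tracts) - 1 else panel.n_sites
            out[h, lo:hi] = pools[src][donor, lo:hi]
            bp0 = int(round(m0 / total_m * L))
            bp1 = int(round(m1 / total_m * L)) if t_i < len(tracts) - 1 else L
            if bp1 > bp0:
                tract_records.append((bp0, bp1, src))
        # guarantee tiling after rounding
        fixed = []
        prev_end = 0
        for s, e, src in tract_records:
            s = prev_end
            if e <= s:
                continue
            fixed.append((s, e, src))
            prev_end = e
        if fixed and fixed[-1][1] != L:
            s, e, src = fixed[-1]
            fixed[-1] = (s, L, src)
        if not fixed:
            fixed = [(0, L, names[states[0]])]
        all_tracts.append(fixed)

    panel.haplotypes[event.target_name] = out
    panel.truth_tracts[event.target_name] = all_tracts
    return panel


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

_DEAM_SUSCEPTIBLE = {frozenset({"C", "T"}): "C", frozenset({"A", "G"}): "G"}


def deamination_susceptible_code(sites: pd.DataFrame) -> np.ndarray:
    """Per-site code of the damage-susceptible allele: 0 = ref, 1 = alt, -1 = none.

    At C/T transition sites the C is deamination-susceptible (observed as T);
    at G/A sites the G (observed as A, the complementary-strand signature).
    """
    out = np.full(len(sites), -1, dtype=np.int8)
    ref = sites["ref_allele"].to_numpy()
    alt = sites["alt_allele"].to_numpy()
    for i, (r, a) in enumerate(zip(ref, alt)):
        key = frozenset({r, a})
        sus = _DEAM_SUSCEPTIBLE.get(key)
        if sus is not None:
            out[i] = 0 if r == sus else 1
    return out


def simulate_reads(
    panel: HaplotypePanel,
    individuals: Sequence,
    config: SimConfig,
) -> SitePileup:
    """Poisson low-coverage read sampling with error and 5' deamination.

    ``individuals`` is a sequence of (population, diploid_index) pairs. Depth
    per individual-site is Poisson(coverage_lambda); each read samples one
    chromosome uniformly, flips its allele with probability seq_error_eps,
    and — if the site is a transition whose true base on the read is the
    susceptible allele — is additionally converted to the damage product with
    probability delta * 2^(-d / d_half) for 5'-distance d ~ U{0..read_length-1}.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, STREAM_READS])
    sus = deamination_susceptible_code(panel.sites)
    n_sites = panel.n_sites

    labels, ind_l, site_l, obs_l, chrom_l, true_l, d_l, dmg_l = [], [], [], [], [], [], [], []
    for k, (pop, di) in enumerate(individuals):
        labels.append(f"{pop}_{di}")
        h0 = panel.haplotypes[pop][2 * di]
        h1 = panel.haplotypes[pop][2 * di + 1]
        depth = rng.poisson(config.coverage_lambda, size=n_sites)
        site_idx = np.repeat(np.arange(n_sites), depth)
        n = len(site_idx)
        chrom = rng.integers(0, 2, size=n).astype(np.int8)
        true = np.where(chrom == 0, h0[site_idx], h1[site_idx]).astype(np.int8)
        obs = true ^ (rng.random(n) < config.seq_error_eps).astype(np.int8)
        d = rng.integers(0, config.read_length, size=n).astype(np.int32)
        w = config.deamination_delta * np.power(2.0, -d / config.d_half)
        eligible = (sus[site_idx] >= 0) & (true == sus[site_idx])
        dmg = eligible & (rng.random(n) < w)
        obs = np.where(dmg, 1 - sus[site_idx], obs).astype(np.int8)
        ind_l.append(np.full(n, k, dtype=np.int32))
        site_l.append(site_idx.astype(np.int32))
        obs_l.append(obs)
        chrom_l.append(chrom)
        true_l.append(true)
        d_l.append(d)
        dmg_l.append(dmg)

    cat = lambda xs, dt: (np.concatenate(xs) if xs else np.empty(0, dtype=dt))
    return SitePileup(
        individuals=labels,
        sites=panel.sites,
        ind_idx=cat(ind_l, np.int32),
        site_idx=cat(site_l, np.int32),
        observed=cat(obs_l, np.int8),
        true_chrom=cat(chrom_l, np.int8),
        true_allele=cat(true_l, np.int8),
        dist5=cat(d_l, np.int32),
        damage_flag=cat(dmg_l, bool),
    )


# ---------------------------------------------------------------------------
# Imputed-like calls
# ---------------------------------------------------------------------------


@dataclass
class AccuracySchedule:
    """Per MAF-bin x genotype-class retention accuracy, bins of ``bin_width``.

    ``accuracy[b, c]`` is the probability that a truth genotype of class c
    (0 = hom-ref, 1 = het, 2 = hom-alt) in MAF bin b is emitted unchanged.
    Bins tile [0, 0.5]; a MAF of exactly 0.5 falls in the last bin.
    """

    bin_width: float
    accuracy: np.ndarray  # (n_bins, 3)

    def __post_init__(self) -> None:
        self.accuracy = np.asarray(self.accuracy, dtype=float)
        n_needed = int(np.ceil(0.5 / self.bin_width))
        if self.accuracy.shape != (n_needed, 3):
            raise ConfigurationError(
                f"accuracy table must be ({n_needed}, 3) for bin_width={self.bin_width}"
            )
        if np.any(self.accuracy < 0) or np.any(self.accuracy > 1):
            raise ConfigurationError("accuracies must lie in [0, 1]")

    @classmethod
    def constant(cls, acc_hom_ref: float, acc_het: float, acc_hom_alt: float,
                 bin_width: float = 0.005) -> "AccuracySchedule":
        n = int(np.ceil(0.5 / bin_width))
        return cls(bin_width, np.tile([acc_hom_ref, acc_het, acc_hom_alt], (n, 1)))

    def bin_of(self, maf: np.ndarray) -> np.ndarray:
        b = np.floor(np.asarray(maf) / self.bin_width).astype(int)
        return np.clip(b, 0, self.accuracy.shape[0] - 1)


def emulate_imputed_calls(truth, schedule: AccuracySchedule, seed: int):
    """Emulate imputation output from truth diploid genotypes.

    Each genotype is kept with its MAF-bin/class accuracy; otherwise it is
    replaced by one of the other two genotypes, the adjacent genotype being
    twice as likely as the opposite homozygote. The GP triplet puts mass
    u ~ U(0.90, 1.0) on the emitted call and splits the remainder between the
    other genotypes. Returns a diploid :class:`~paleoweave.calls.GenotypeMatrix`
    with GP. Missing truth genotypes stay missing.
    """
    from .calls import GenotypeMatrix  # local import to avoid a cycle

    if truth.ploidy != 2:
        raise ConfigurationError("emulate_imputed_calls needs diploid truth")
    rng = np.random.default_rng([seed, STREAM_IMPUTE])
    g = truth.values
    n_ind, n_sites = g.shape

    # cohort MAF per site (missing-aware)
    valid = g >= 0
    with np.errstate(invalid="ignore"):
        alt = np.where(valid, g, 0).sum(axis=0)
        tot = 2 * valid.sum(axis=0)
        p = np.where(tot > 0, alt / np.maximum(tot, 1), 0.0)
    maf = np.minimum(p, 1 - p)
    bins = schedule.bin_of(maf)

    out = g.copy()
    acc = schedule.accuracy[np.broadcast_to(bins, g.shape), np.clip(g, 0, 2)]
    acc = np.where(valid, acc, 1.0)
    keep = rng.random(g.shape) < acc
    flip = valid & ~keep
    u = rng.random(g.shape)
    # replacement: adjacent twice as likely as opposite homozygote
    repl = np.empty_like(g)
    repl[g == 0] = np.where(u[g == 0] < 2 / 3, 1, 2)
    repl[g == 1] = np.where(u[g == 1] < 0.5, 0, 2)
    repl[g == 2] = np.where(u[g == 2] < 2 / 3, 1, 0)
    out[flip] = repl[flip]

    gp = np.zeros((n_ind, n_sites, 3), dtype=np.float32)
    mass = rng.uniform(0.90, 1.0, size=g.shape)
    split = rng.random(g.shape)
    rem = 1.0 - mass
    emitted = np.clip(out, 0, 2)
    others = np.array([[1, 2], [0, 2], [0, 1]])
    oi = others[emitted]  # (n_ind, n_sites, 2)
    ii, jj = np.meshgrid(np.arange(n_ind), np.arange(n_sites), indexing="ij")
    gp[ii, jj, emitted] = mass
    gp[ii, jj, oi[..., 0]] = rem * split
    gp[ii, jj, oi[..., 1]] = rem * (1 - split)
    gp[~valid] = np.nan

    return GenotypeMatrix(
        values=out,
        ploidy=2,
        individuals=list(truth.individuals),
        sites=truth.sites,
        gp=gp,
    )


# ---------------------------------------------------------------------------
# Polygenic trait
# ---------------------------------------------------------------------------


def simulate_trait(panel: HaplotypePanel, trait: TraitConfig, seed: int):
    """Draw causal effects and compute true genetic values for all individuals.

    Causal sites are sampled without replacement; effects are
    N(0, heritability_target / n_causal) with the alt allele as effect allele
    and p-value 1e-8. ``n_null`` additional SNPs carry near-zero effects and
    p ~ U(0.1, 1), for p-threshold filtering exercises. Returns
    (EffectPanel, DataFrame of individual/population/true_value).
    """
    if trait.n_causal > panel.n_sites:
        raise ConfigurationError("n_causal must not exceed n_sites")
    rng = np.random.default_rng([seed, STREAM_TRAIT])

    records = []
    if trait.n_causal > 0:
        sigma = np.sqrt(trait.heritability_target / trait.n_causal)
        causal = rng.choice(panel.n_sites, size=trait.n_causal, replace=False)
        betas = rng.normal(0.0, sigma, size=trait.n_causal)
        for s, b in zip(causal, betas):
            records.append((int(s), panel.sites["alt_allele"].iloc[s], float(b), np.exp(1.81 * b), 1e-8))
    else:
        causal = np.empty(0, dtype=int)
        betas = np.empty(0)
    if trait.n_null > 0:
        pool = np.setdiff1d(np.arange(panel.n_sites), causal)
        nulls = rng.choice(pool, size=min(trait.n_null, len(pool)), replace=False)
        tiny = rng.normal(0.0, 1e-4, size=len(nulls))
        pvals = rng.uniform(0.1, 1.0, size=len(nulls))
        for s, b, pv in zip(nulls, tiny, pvals):
            records.append((int(s), panel.sites["alt_allele"].iloc[s], float(b), np.exp(1.81 * b), float(pv)))

    table = pd.DataFrame(
        records, columns=["site_idx", "effect_allele", "beta", "odds_ratio", "p_value"]
    )
    effect_panel = EffectPanel(table=table.sort_values("site_idx").reset_index(drop=True))

    rows = []
    beta_vec = np.zeros(panel.n_sites)
    beta_vec[causal] = betas
    for pop in panel.populations():
        dos = panel.diploid_dosages(pop).astype(float)
        vals = dos @ beta_vec
        for i, v in enumerate(vals):
            rows.append((f"{pop}_{i}", pop, float(v)))
    truth = pd.DataFrame(rows, columns=["individual", "population", "true_value"])
    return effect_panel, truth


# ---------------------------------------------------------------------------
# Truth-tract cross-checks
# ---------------------------------------------------------------------------


def tract_fraction_by_rescan(panel: HaplotypePanel, pop: str, source: str) -> np.ndarray:
    """Recompute truth ancestry fractions by scanning tract labels per haplotype.

    This is bookkeeping-equivalent to :meth:`HaplotypePanel.truth_ancestry_fraction`
    but walks the tract list independently; used as an exactness cross-check.
    """
    fracs = []
    for tracts in panel.truth_tracts[pop]:
        covered = 0
        pos = 0
        for s, e, src in tracts:
            if s != pos:
                raise AssertionError("tracts do not tile the chromosome")
            if src == source:
                covered += e - s
            pos = e
        if pos != panel.chrom_length_bp:
            raise AssertionError("tracts do not reach chromosome end")
        fracs.append(covered / panel.chrom_length_bp)
    return np.asarray(fracs)
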