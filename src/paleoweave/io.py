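"""Readers and writers for the supported interchange formats.

Formats: VCF (GT, optional GP), EIGENSTRAT geno/snp/ind, IMPUTE2 hap/sample,
plus TSVs for labels, effect panels, pileups and truth tracts. Positions are
1-based in VCF and .snp files and converted to the internal 0-based
half-open convention on read; alleles are taken verbatim (never strand
complemented).
"""

from __future__ import annotations

import os
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .calls import MISSING, GenotypeMatrix
from .simdata import EffectPanel, HaplotypePanel, SitePileup, _TRANSITION_PAIRS, TRANSITION, TRANSVERSION


class FormatError(ValueError):
    pass


def _mutation_class(ref: str, alt: str) -> str:
    return TRANSITION if frozenset({ref, alt}) in _TRANSITION_PAIRS else TRANSVERSION


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def write_vcf(path: str, matrix: GenotypeMatrix, chrom: str = "1", phased_haps: Optional[np.ndarray] = None) -> None:
    """Write a GenotypeMatrix as an uncompressed VCF (GT and, if present, GP).

    For diploid matrices without phase information genotypes are written
    unphased (0/1); ``phased_haps`` (2N x S) writes phased GT instead.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if matrix.gp is not None:
            fh.write('##FORMAT=<ID=GP,Number=G,Type=Float,Description="Genotype posterior">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(str(i) for i in matrix.individuals) + "\n")
        fmt = "GT:GP" if matrix.gp is not None else "GT"
        sites = matrix.sites
        for s in range(matrix.n_sites):
            pos1 = int(sites["position_bp"].iloc[s]) + 1
            row = [
                chrom,
                str(pos1),
                f"snp{s}",
                sites["ref_allele"].iloc[s],
                sites["alt_allele"].iloc[s],
                ".",
                "PASS",
                ".",
                fmt,
            ]
            for i in range(matrix.n_individuals):
                v = matrix.values[i, s]
                if phased_haps is not None:
                    gt = f"{phased_haps[2 * i, s]}|{phased_haps[2 * i + 1, s]}"
                elif matrix.ploidy == 1:
                    gt = "." if v < 0 else str(int(v))
                else:
                    gt = "./." if v < 0 else ("0/0", "0/1", "1/1")[int(v)]
                if matrix.gp is not None:
                    trip = matrix.gp[i, s]
                    gp = "." if np.any(np.isnan(trip)) else ",".join(f"{x:.6f}" for x in trip)
                    row.append(f"{gt}:{gp}")
                else:
                    row.append(gt)
            fh.write("\t".join(row) + "\n")


def read_vcf(path: str) -> GenotypeMatrix:
    """Read GT (+GP) from a VCF into a GenotypeMatrix (diploid or haploid)."""
    from cyvcf2 import VCF

    vcf = VCF(path)
    individuals = list(vcf.samples)
    rows, gts, gps = [], [], []
    has_gp = False
    ploidy = 2
    for idx, var in enumerate(vcf):
        if len(var.ALT) != 1:
            raise FormatError(f"record {idx + 1}: only biallelic sites supported")
        rows.append(
            (
                var.POS - 1,
                var.REF,
                var.ALT[0],
                _mutation_class(var.REF, var.ALT[0]),
            )
        )
        gt = var.genotype.array()
        if gt.shape[1] == 2:  # haploid records: allele + phase column
            ploidy = 1
            dose = np.where(gt[:, 0] < 0, MISSING, gt[:, 0])
        else:
            a = gt[:, 0]
            b = gt[:, 1]
            dose = np.where((a < 0) | (b < 0), MISSING, a + b)
        gts.append(dose.astype(np.int8))
        try:
            gp = var.format("GP")
        except KeyError:
            gp = None
        if gp is not None:
            has_gp = True
            gps.append(gp)
        else:
            gps.append(None)
    if not rows:
        raise FormatError("empty VCF")
    sites = pd.DataFrame(rows, columns=["position_bp", "ref_allele", "alt_allele", "mutation_class"])
    sites["genetic_pos_cM"] = np.nan
    values = np.vstack(gts).T
    gp_arr = None
    if has_gp:
        gp_arr = np.full((len(individuals), len(rows), 3), np.nan, dtype=np.float32)
        for s, g in enumerate(gps):
            if g is not None:
                gp_arr[:, s, :] = g
        # renormalize away the fixed-precision rounding of the text format
        tot = gp_arr.sum(axis=2, keepdims=True)
        with np.errstate(invalid="ignore"):
            gp_arr = np.where(tot > 0, gp_arr / tot, gp_arr)
    return GenotypeMatrix(values=values, ploidy=ploidy, individuals=individuals, sites=sites, gp=gp_arr)


def write_phased_vcf(path: str, panel: HaplotypePanel, pops: Sequence[str], chrom: str = "1") -> None:
    """Write phased haplotypes of the given panel populations as VCF."""
    from .calls import from_panel

    mat = from_panel(panel, pops)
    haps = np.vstack([panel.haplotypes[p] for p in pops])
    write_vcf(path, mat, chrom=chrom, phased_haps=haps)


# ---------------------------------------------------------------------------
# EIGENSTRAT
# ---------------------------------------------------------------------------


def write_eigenstrat(prefix: str, matrix: GenotypeMatrix, labels: Optional[dict] = None, chrom: str = "1") -> None:
    """Write geno/snp/ind files. geno codes reference-allele counts; 9 = missing."""
    with open(prefix + ".geno", "w") as fh:
        for s in range(matrix.n_sites):
            line = []
            for i in range(matrix.n_individuals):
                v = matrix.values[i, s]
                line.append("9" if v < 0 else str(int(matrix.ploidy - v)))
            fh.write("".join(line) + "\n")
    with open(prefix + ".snp", "w") as fh:
        for s in range(matrix.n_sites):
            pos1 = int(matrix.sites["position_bp"].iloc[s]) + 1
            cm = matrix.sites["genetic_pos_cM"].iloc[s]
            gpos = 0.0 if pd.isna(cm) else cm / 100.0
            fh.write(
                f"snp{s}\t{chrom}\t{gpos:.6f}\t{pos1}\t"
                f"{matrix.sites['ref_allele'].iloc[s]}\t{matrix.sites['alt_allele'].iloc[s]}\n"
            )
    with open(prefix + ".ind", "w") as fh:
        for ind in matrix.individuals:
            pop = labels.get(ind, "pop") if labels else "pop"
            fh.write(f"{ind}\tU\t{pop}\n")


def read_eigenstrat(prefix: str) -> Tuple[GenotypeMatrix, dict]:
    """Read geno/snp/ind; returns (matrix, labels). 9 is honored as missing."""
    snp = pd.read_csv(
        prefix + ".snp",
        sep=r"\s+",
        header=None,
        names=["id", "chrom", "genetic_pos_M", "position_1based", "ref_allele", "alt_allele"],
    )
    ind = pd.read_csv(prefix + ".ind", sep=r"\s+", header=None, names=["id", "sex", "pop"])
    genolines = []
    with open(prefix + ".geno") as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if len(line) != len(ind):
                raise FormatError(f"{prefix}.geno line {ln}: expected {len(ind)} columns")
            genolines.append([int(c) for c in line])
    geno = np.asarray(genolines, dtype=np.int8).T  # individuals x sites
    if len(genolines) != len(snp):
        raise FormatError("geno/snp length mismatch")
    ploidy = 1 if geno[(geno >= 0) & (geno != 9)].max(initial=0) <= 1 else 2
    values = np.where(geno == 9, MISSING, ploidy - geno).astype(np.int8)
    sites = pd.DataFrame(
        {
            "position_bp": snp["position_1based"] - 1,
            "genetic_pos_cM": snp["genetic_pos_M"] * 100.0,
            "ref_allele": snp["ref_allele"],
            "alt_allele": snp["alt_allele"],
            "mutation_class": [
                _mutation_class(r, a) for r, a in zip(snp["ref_allele"], snp["alt_allele"])
            ],
        }
    )
    matrix = GenotypeMatrix(values=values, ploidy=ploidy, individuals=list(ind["id"]), sites=sites)
    return matrix, dict(zip(ind["id"], ind["pop"]))


# ---------------------------------------------------------------------------
# IMPUTE2 hap/sample
# ---------------------------------------------------------------------------


def write_impute2(prefix: str, panel: HaplotypePanel, pops: Sequence[str]) -> None:
    """Write phased haplotypes as IMPUTE2 .hap (2N allele columns) + .sample."""
    haps = np.vstack([panel.haplotypes[p] for p in pops])
    sites = panel.sites
    with open(prefix + ".hap", "w") as fh:
        for s in range(panel.n_sites):
            head = (
                f"snp{s} snp{s} {int(sites['position_bp'].iloc[s]) + 1} "
                f"{sites['ref_allele'].iloc[s]} {sites['alt_allele'].iloc[s]}"
            )
            fh.write(head + " " + " ".join(str(int(a)) for a in haps[:, s]) + "\n")
    with open(prefix + ".sample", "w") as fh:
        fh.write("ID_1 ID_2 missing\n0 0 0\n")
        for pop in pops:
            for i in range(panel.n_individuals(pop)):
                fh.write(f"{pop}_{i} {pop}_{i} 0\n")


def read_impute2_haps(prefix: str) -> Tuple[np.ndarray, list, pd.DataFrame]:
    """Read .hap/.sample; returns (haplotypes (2N x S), individual ids, sites)."""
    rows, hapcols = [], []
    with open(prefix + ".hap") as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if len(parts) < 7:
                raise FormatError(f"{prefix}.hap line {ln}: too few columns")
            rows.append((int(parts[2]) - 1, parts[3], parts[4]))
            try:
                hapcols.append([int(x) for x in parts[5:]])
            except ValueError as e:
                raise FormatError(f"{prefix}.hap line {ln}: {e}") from None
    sample = pd.read_csv(prefix + ".sample", sep=r"\s+")
    ids = list(sample["ID_1"].iloc[1:])  # skip the 0 0 0 type row
    haps = np.asarray(hapcols, dtype=np.uint8).T
    if haps.shape[0] != 2 * len(ids):
        raise FormatError(
            f"hap column count {haps.shape[0]} != 2 x {len(ids)} samples"
        )
    sites = pd.DataFrame(rows, columns=["position_bp", "ref_allele", "alt_allele"])
    sites["mutation_class"] = [
        _mutation_class(r, a) for r, a in zip(sites["ref_allele"], sites["alt_allele"])
    ]
    sites["genetic_pos_cM"] = np.nan
    return haps, ids, sites


# ---------------------------------------------------------------------------
# Small TSVs
# ---------------------------------------------------------------------------


def read_labels(path: str) -> dict:
    df = pd.read_csv(path, sep="\t", header=None, names=["individual", "population"])
    return dict(zip(df["individual"], df["population"]))


def write_labels(path: str, labels: dict) -> None:
    pd.DataFrame(sorted(labels.items())).to_csv(path, sep="\t", header=False, index=False)


def write_effect_panel(path: str, panel: EffectPanel) -> None:
    panel.table.to_csv(path, sep="\t", index=False)


def read_effect_panel(path: str) -> EffectPanel:
    return EffectPanel(table=pd.read_csv(path, sep="\t"))


def write_pileup(path: str, pileup: SitePileup) -> None:
    pileup.to_frame().to_csv(path, sep="\t", index=False)


def write_truth_tracts(path: str, panel: HaplotypePanel, pop: str) -> None:
    """Truth tracts as BED-like TSV (0-based half-open): hap, start, end, source."""
    with open(path, "w") as fh:
        fh.write("haplotype\tstart_bp\tend_bp\tsource\n")
        for h, tracts in enumerate(panel.truth_tracts[pop]):
            for s, e, src in tracts:
                fh.write(f"{pop}_h{h}\t{s}\t{e}\t{src}\n")


def write_coancestry(path: str, matrix) -> None:
    matrix.to_frame("chunks").to_csv(path, sep="\t")
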