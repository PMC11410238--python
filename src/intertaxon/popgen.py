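"""Population-genetic statistics from a biallelic SNP table.

Covers per-population nucleotide diversity pi and Watterson's theta_w,
Hudson-style Fst between populations, pairwise divergence between groups of
samples (or coordinate-matched genomes), variant filtering and --thin-style
spacing, generations since divergence from theta_w = 2*N_theta*mu, and a
neighbor-joining distance tree.

Genotypes are coded as alt-allele dosage per sample (0/1 haploid; diploids
collapse as 0/0 -> 0, 0/1 -> 1, 1/1 -> 2 of ``ploidy`` alleles). Allele
frequencies always count haplotypes, so n below is the haplotype count.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from .genome import Genome

DEFAULT_MU = 1.84e-10  # per-site per-generation single-base mutation rate (yeast)
DEFAULT_GENERATIONS_PER_YEAR = (164.0, 1870.0)


@dataclass
class VariantTable:
    """Biallelic SNP sites x samples with population labels.

    sites: DataFrame with columns chrom, pos (1-based), ref, alt, and
    optionally qual; genotypes: (n_sites, n_samples) int8 alt dosage,
    -1 = missing; depth: optional (n_sites, n_samples) read depth;
    L: callable genome length in bp.
    """

    sites: pd.DataFrame
    genotypes: np.ndarray
    samples: list[str]
    populations: dict[str, str]
    L: int
    ploidy: int = 1
    depth: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.genotypes.shape != (len(self.sites), len(self.samples)):
            raise ValueError("genotype matrix shape does not match sites x samples")
        if self.L <= 0:
            raise ValueError("callable length L must be positive")
        for chrom, grp in self.sites.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_indices(self, population: str | list[str]) -> np.ndarray:
        if isinstance(population, str):
            names = [s for s in self.samples if self.populations.get(s) == population]
        else:
            names = list(population)
        idx = np.array([self.samples.index(s) for s in names], dtype=int)
        if len(idx) == 0:
            raise ValueError(f"no samples for population {population!r}")
        return idx

    @classmethod
    def from_vcf(
        cls,
        path: str | Path,
        populations: dict[str, str],
        L: int | None = None,
    ) -> "VariantTable":
        """Read biallelic SNPs from a VCF (haploid or diploid genotypes).

        L defaults to the summed contig lengths in the header; a ValueError is
        raised when neither is available.
        """
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        samples = list(vcf.samples)
        rows, gts, depths = [], [], []
        ploidy = 1
        for var in vcf:
            if not var.is_snp or len(var.ALT) != 1:
                continue
            rows.append((var.CHROM, var.POS, var.REF, var.ALT[0], var.QUAL))
            dosage = []
            for g in var.genotypes:  # [allele0, allele1?, phased]
                alleles = [a for a in g[:-1] if a is not None]
                ploidy = max(ploidy, len(alleles))
                dosage.append(-1 if any(a < 0 for a in alleles) else sum(alleles))
            gts.append(dosage)
            try:
                fmt_dp = var.format("DP")
            except KeyError:
                fmt_dp = None
            depths.append(
                fmt_dp.reshape(-1).astype(float) if fmt_dp is not None else
                np.full(len(samples), np.nan)
            )
        if L is None:
            lengths = vcf.seqlens if vcf.seqnames else None
            if not lengths:
                raise ValueError("no contig lengths in VCF header; supply L explicitly")
            L = int(sum(lengths))
        sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "qual"])
        return cls(
            sites,
            np.asarray(gts, dtype=np.int8).reshape(len(rows), len(samples)),
            samples,
            populations,
            L,
            ploidy=ploidy,
            depth=np.asarray(depths, dtype=float).reshape(len(rows), len(samples))
            if depths else None,
        )


@dataclass
class DiversityResult:
    pi: float  # per-site pairwise diversity
    theta_w: float  # per-site Watterson estimator
    S: int
    n: int  # haplotype count
    L: int
    a_n: float


@dataclass
class FstResult:
    fst: float
    estimator: str
    numerator: float
    denominator: float
    n_sites: int


@dataclass
class DivergenceTimeResult:
    d: float
    mu: float
    generations: float
    generations_per_year: tuple[float, float]
    years_low: float
    years_high: float


def filter_variants(
    table: VariantTable, min_depth: float = 10.0, min_quality: float = 30.0
) -> VariantTable:
    """Depth strictly > min_depth in every sample, QUAL >= min_quality, no missing.

    Mirrors the FORMAT/DP>10 and minQ 30 convention plus the no-missing-data
    rule; sites lacking a depth annotation pass the depth filter.
    """
    keep = np.ones(table.n_sites, dtype=bool)
    keep &= ~np.any(table.genotypes < 0, axis=1)
    if "qual" in table.sites.columns:
        qual = table.sites["qual"].to_numpy(dtype=float)
        keep &= np.nan_to_num(qual, nan=np.inf) >= min_quality
    if table.depth is not None:
        depth_ok = np.nan_to_num(table.depth, nan=np.inf) > min_depth
        keep &= np.all(depth_ok, axis=1)
    return VariantTable(
        table.sites.loc[keep].reset_index(drop=True),
        table.genotypes[keep],
        table.samples,
        table.populations,
        table.L,
        table.ploidy,
        table.depth[keep] if table.depth is not None else None,
    )


def thin_variants(positions: list[int] | np.ndarray, min_spacing: int = 500) -> list[int]:
    """Greedy scan: keep the first site, then each site >= min_spacing from the last kept."""
    kept: list[int] = []
    last = None
    for pos in positions:
        if last is not None and pos < last:
            raise ValueError("positions must be sorted")
        if last is None or pos - last >= min_spacing:
            kept.append(int(pos))
            last = pos
    return kept


def _allele_freqs(table: VariantTable, idx: np.ndarray) -> tuple[np.ndarray, int]:
    g = table.genotypes[:, idx]
    if np.any(g < 0):
        raise ValueError("missing genotypes present; filter first")
    n_hap = len(idx) * table.ploidy
    return g.sum(axis=1) / n_hap, n_hap


def harmonic_number(n_minus_1: int) -> float:
    return sum(1.0 / i for i in range(1, n_minus_1 + 1))


def watterson_theta(S: int, n: int, L: int) -> float:
    """Per-site Watterson estimator S / (a_n * L), a_n = sum_{i<n} 1/i."""
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    if L <= 0:
        raise ValueError("L must be positive")
    return S / (harmonic_number(n - 1) * L)


def nucleotide_diversity(table: VariantTable, population: str | list[str]) -> DiversityResult:
    """Per-site pi (with the n/(n-1) small-sample factor) and theta_w for one population."""
    idx = table.sample_indices(population)
    p, n = _allele_freqs(table, idx)
    if n < 2:
        raise ValueError("population must contain at least 2 haplotypes")
    pi = float(np.sum(2.0 * p * (1.0 - p) * n / (n - 1)) / table.L)
    S = int(np.sum((p > 0) & (p < 1)))
    return DiversityResult(
        pi=pi, theta_w=watterson_theta(S, n, table.L), S=S, n=n, L=table.L,
        a_n=harmonic_number(n - 1),
    )


def pairwise_divergence(
    table_or_genomes: VariantTable | tuple[Genome, Genome],
    group_a: list[str] | None = None,
    group_b: list[str] | None = None,
) -> float:
    """Mean cross-group per-site difference fraction.

    With a VariantTable: mean over all cross-group sample pairs of (differing
    sites / L); groups must be disjoint. With two coordinate-matched genomes:
    the column-wise differing fraction.
    """
    if isinstance(table_or_genomes, tuple):
        a, b = table_or_genomes
        diff = total = 0
        for chrom in a.chromosomes:
            sa = np.frombuffer(a[chrom].encode("ascii"), dtype=np.uint8)
            sb = np.frombuffer(b[chrom].encode("ascii"), dtype=np.uint8)
            if len(sa) != len(sb):
                raise ValueError(f"genomes are not coordinate-matched on {chrom}")
            diff += int(np.sum(sa != sb))
            total += len(sa)
        return diff / total
    table = table_or_genomes
    if group_a is None or group_b is None:
        raise ValueError("two sample groups are required")
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    ia, ib = table.sample_indices(group_a), table.sample_indices(group_b)
    ga = table.genotypes[:, ia].astype(float)
    gb = table.genotypes[:, ib].astype(float)
    if np.any(ga < 0) or np.any(gb < 0):
        raise ValueError("missing genotypes present; filter first")
    if table.ploidy == 1:
        # mean over cross pairs of per-site differences, summed over sites
        diffs = sum(
            float(np.sum(ga[:, i] != gb[:, j]))
            for i in range(ga.shape[1])
            for j in range(gb.shape[1])
        )
        return diffs / (ga.shape[1] * gb.shape[1]) / table.L
    pa = ga.sum(axis=1) / (ga.shape[1] * table.ploidy)
    pb = gb.sum(axis=1) / (gb.shape[1] * table.ploidy)
    return float(np.sum(pa * (1 - pb) + pb * (1 - pa)) / table.L)


def hudson_fst(
    table: VariantTable, pop_a: str | list[str], pop_b: str | list[str]
) -> FstResult:
    """Hudson-style ratio-of-averages Fst.

    Per site: N = (p_a - p_b)^2 - p_a(1-p_a)/(n_a-1) - p_b(1-p_b)/(n_b-1),
    D = p_a(1-p_b) + p_b(1-p_a); Fst = sum N / sum D. A fixed difference at
    every site gives exactly 1.
    """
    ia, ib = table.sample_indices(pop_a), table.sample_indices(pop_b)
    pa, na = _allele_freqs(table, ia)
    pb, nb = _allele_freqs(table, ib)
    if na < 2 or nb < 2:
        raise ValueError("both populations need at least 2 haplotypes")
    num = (pa - pb) ** 2 - pa * (1 - pa) / (na - 1) - pb * (1 - pb) / (nb - 1)
    den = pa * (1 - pb) + pb * (1 - pa)
    informative = den > 0
    N, D = float(np.sum(num[informative])), float(np.sum(den[informative]))
    if D == 0:
        raise ValueError("no informative sites (all denominators zero)")
    return FstResult(
        fst=N / D, estimator="Hudson ratio-of-averages", numerator=N,
        denominator=D, n_sites=int(np.sum(informative)),
    )


def generations_since_divergence(
    d: float,
    mu: float = DEFAULT_MU,
    generations_per_year: tuple[float, float] = DEFAULT_GENERATIONS_PER_YEAR,
) -> DivergenceTimeResult:
    """Generations since the split: N_theta = d / (2 mu), from theta_w = 2 N_theta mu.

    Year bounds follow from a configurable generations-per-year range; the
    defaults bracket plausible wild-yeast generation counts and are a setting,
    not a measurement.
    """
    if mu <= 0:
        raise ValueError("mutation rate mu must be positive")
    if d < 0:
        raise ValueError("divergence d must be non-negative")
    lo_gy, hi_gy = generations_per_year
    if lo_gy <= 0 or hi_gy <= 0 or lo_gy > hi_gy:
        raise ValueError("generations_per_year must be an increasing positive pair")
    generations = d / (2.0 * mu)
    return DivergenceTimeResult(
        d=d, mu=mu, generations=generations,
        generations_per_year=(lo_gy, hi_gy),
        years_low=generations / hi_gy, years_high=generations / lo_gy,
    )


def nj_tree(distance_matrix: np.ndarray | list[list[float]], ids: list[str]) -> str:
    """Neighbor-joining Newick tree from a symmetric zero-diagonal matrix."""
    dm = np.asarray(distance_matrix, dtype=float)
    if dm.ndim != 2 or dm.shape[0] != dm.shape[1]:
        raise ValueError("distance matrix must be square")
    if dm.shape[0] < 3:
        raise ValueError("need at least 3 taxa")
    if not np.allclose(dm, dm.T, atol=0):
        raise ValueError("distance matrix must be symmetric")
    if not np.all(np.diag(dm) == 0):
        raise ValueError("distance matrix diagonal must be zero")
    tree = _skbio_nj(DistanceMatrix(dm, ids))
    return str(tree).strip()
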