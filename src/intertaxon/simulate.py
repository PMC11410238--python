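"""Synthetic lineage generator.

Emulates the statistical structure the delineation analysis assumes, with a
truth set for recovery tests: lineages diverged 1-7% from a common ancestor
by uniform substitutions, donor introgression tracts of the 2-79 kb scale,
chromosomal rearrangements (reciprocal/non-reciprocal translocations, an
inversion, a deletion), 20-40x Poisson read coverage per window, spore
viability decaying exponentially with divergence and halving per heterozygous
reciprocal translocation, and logistic growth curves.

No generative model is prescribed by the delineation method itself; every
distribution here is a configurable stand-in. Mutations are independent
uniform substitutions without indels; back-mutation is allowed, so two
branches evolved at per-branch fraction p and q differ at an expected
fraction p + q - (4/3)pq (two uniform choices among the three non-ancestral
bases coincide with probability 1/3).

Randomness: each operation derives its own ``numpy.random.Generator`` from
(seed, operation name, ordinal) so stages can be rerun independently and the
whole dataset is byte-reproducible from one integer seed.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import Genome, reverse_complement

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
SV_KINDS = {
    "reciprocal_translocation",
    "nonreciprocal_translocation",
    "inversion",
    "deletion",
}


def derive_rng(seed: int, operation: str, ordinal: int = 0) -> np.random.Generator:
    """One seeded generator per operation invocation.

    The stream is keyed on (seed, crc32(operation), ordinal) so that rerunning
    a single stage reproduces its output regardless of what ran before.
    """
    return np.random.default_rng([int(seed), zlib.crc32(operation.encode()), int(ordinal)])


@dataclass
class SVSpec:
    """One rearrangement event.

    kind:
      reciprocal_translocation  -- swap terminal segments of `donor` (from
          `breakpoint`) and `acceptor` (from `acceptor_breakpoint`).
      nonreciprocal_translocation -- cut [breakpoint, breakpoint+size) out of
          `donor` and insert it into `acceptor` at `acceptor_breakpoint`.
      inversion -- reverse-complement [breakpoint, breakpoint+size) of `donor`.
      deletion  -- remove [breakpoint, breakpoint+size) from `donor`.
    Breakpoints are 0-based.
    """

    kind: str
    donor: str
    breakpoint: int
    acceptor: str | None = None
    acceptor_breakpoint: int | None = None
    size: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in SV_KINDS:
            raise ValueError(f"unknown SV kind {self.kind!r}")
        if self.breakpoint < 0:
            raise ValueError("breakpoint must be >= 0")
        if self.kind in ("nonreciprocal_translocation", "inversion", "deletion"):
            if self.size is None or self.size < 1:
                raise ValueError(f"{self.kind} requires size >= 1")
        if self.kind in ("reciprocal_translocation", "nonreciprocal_translocation"):
            if self.acceptor is None:
                raise ValueError(f"{self.kind} names two chromosomes")
        if self.kind == "reciprocal_translocation" and self.acceptor_breakpoint is None:
            raise ValueError("reciprocal translocation requires both breakpoints")


@dataclass
class SimConfig:
    """Scenario parameters for one synthetic dataset."""

    ancestor_length: int = 500_000
    n_chromosomes: int = 1
    gc_content: float = 0.40
    branch_divergence: float = 0.035
    introgression_tracts: list[tuple[str, int, int, str]] = field(default_factory=list)
    sv_events: list[SVSpec] = field(default_factory=list)
    mean_coverage: float = 30.0
    n_samples_per_lineage: int = 3
    seed: int = 1

    def __post_init__(self) -> None:
        if self.ancestor_length <= 0:
            raise ValueError("ancestor_length must be positive")
        if self.n_chromosomes <= 0:
            raise ValueError("n_chromosomes must be positive")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must lie in [0, 1]")
        if not 0.0 <= self.branch_divergence <= 0.25:
            raise ValueError("branch_divergence must lie in [0, 0.25]")
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be positive")
        seen: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, length, _donor in self.introgression_tracts:
            if length <= 0 or start < 0:
                raise ValueError("introgression tracts need start >= 0 and length > 0")
            for s, e in seen.get(chrom, []):
                if start < e and s < start + length:
                    raise ValueError(f"overlapping introgression tracts on {chrom}")
            seen.setdefault(chrom, []).append((start, start + length))


@dataclass
class TruthSet:
    """Ground truth emitted alongside the synthetic genomes.

    variants: per-lineage list of (chrom, pos0, ref, alt), 0-based internally;
    introgressions: (chrom, start, end, donor), 0-based half-open;
    sv_events: applied events with old and new coordinates;
    expected_viability: per-cross expected percentages.
    """

    variants: dict[str, list[tuple[str, int, str, str]]] = field(default_factory=dict)
    introgressions: list[tuple[str, int, int, str]] = field(default_factory=list)
    sv_events: list[dict] = field(default_factory=list)
    expected_viability: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# sequence-level operations
# ---------------------------------------------------------------------------

def generate_ancestor(config: SimConfig) -> Genome:
    """Random ancestor with i.i.d. bases at the requested GC content."""
    rng = derive_rng(config.seed, "generate_ancestor")
    gc = config.gc_content
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    chroms: dict[str, str] = {}
    for i in range(config.n_chromosomes):
        draw = rng.choice(BASES, size=config.ancestor_length, p=probs)
        chroms[f"chr{i + 1}"] = draw.tobytes().decode("ascii")
    return Genome(chroms, name="ancestor")


def evolve_lineage(
    ancestor: Genome, divergence: float, seed: int, name: str = "lineage"
) -> tuple[Genome, TruthSet]:
    """Substitute a Binomial(L, divergence) number of sites, uniformly placed.

    Each mutated site receives a uniformly chosen different base; no indels,
    so descendant and ancestor stay coordinate-matched.
    """
    if not 0.0 <= divergence <= 0.25:
        raise ValueError("divergence must lie in [0, 0.25]")
    rng = derive_rng(seed, "evolve_lineage")
    chroms: dict[str, str] = {}
    variants: list[tuple[str, int, str, str]] = []
    for chrom, seq in ancestor.chromosomes.items():
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
        n_mut = rng.binomial(len(arr), divergence)
        if n_mut > 0:
            positions = np.sort(rng.choice(len(arr), size=n_mut, replace=False))
            # uniform among the three non-current bases: shift by 1..3 in base index
            cur_idx = np.searchsorted(BASES, arr[positions])
            new_idx = (cur_idx + rng.integers(1, 4, size=n_mut)) % 4
            for pos, ci, ni in zip(positions, cur_idx, new_idx):
                variants.append((chrom, int(pos), chr(BASES[ci]), chr(BASES[ni])))
            arr[positions] = BASES[new_idx]
        chroms[chrom] = arr.tobytes().decode("ascii")
    truth = TruthSet(variants={name: variants})
    return Genome(chroms, name=name), truth


def implant_introgression(
    recipient: Genome,
    donor: Genome,
    tracts: list[tuple[str, int, int, str]],
) -> tuple[Genome, TruthSet]:
    """Replace recipient sequence by donor sequence over each tract.

    Recipient and donor must be coordinate-matched (no prior rearrangements on
    the affected chromosomes). Tracts are (chrom, start, length, donor_label),
    0-based half-open; overlap is an error.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, length, _label in tracts:
        if chrom not in recipient or chrom not in donor:
            raise ValueError(f"tract chromosome {chrom!r} absent from genomes")
        if start < 0 or length <= 0 or start + length > len(recipient[chrom]):
            raise ValueError(f"tract out of bounds on {chrom}")
        if len(recipient[chrom]) != len(donor[chrom]):
            raise ValueError(f"recipient and donor differ in length on {chrom}")
        for s, e in by_chrom.get(chrom, []):
            if start < e and s < start + length:
                raise ValueError(f"overlapping tracts on {chrom}")
        by_chrom.setdefault(chrom, []).append((start, start + length))
    chroms = dict(recipient.chromosomes)
    intervals: list[tuple[str, int, int, str]] = []
    for chrom, start, length, label in tracts:
        seq = chroms[chrom]
        chroms[chrom] = seq[:start] + donor[chrom][start : start + length] + seq[start + length :]
        intervals.append((chrom, start, start + length, label))
    truth = TruthSet(introgressions=intervals)
    return Genome(chroms, recipient.name), truth


def apply_svs(genome: Genome, events: list[SVSpec]) -> tuple[Genome, TruthSet]:
    """Apply rearrangements in list order; truth keeps old and new coordinates.

    Total base count is conserved except by deletions.
    """
    chroms = dict(genome.chromosomes)
    records: list[dict] = []

    def _check(chrom: str, pos: int) -> None:
        if chrom not in chroms:
            raise ValueError(f"unknown chromosome {chrom!r}")
        if pos > len(chroms[chrom]):
            raise ValueError(f"breakpoint {pos} beyond end of {chrom} ({len(chroms[chrom])} bp)")

    for ev in events:
        if ev.kind == "reciprocal_translocation":
            _check(ev.donor, ev.breakpoint)
            _check(ev.acceptor, ev.acceptor_breakpoint)  # type: ignore[arg-type]
            a, b = ev.donor, ev.acceptor
            bp_a, bp_b = ev.breakpoint, ev.acceptor_breakpoint
            seg_a, seg_b = chroms[a][bp_a:], chroms[b][bp_b:]
            chroms[a] = chroms[a][:bp_a] + seg_b
            chroms[b] = chroms[b][:bp_b] + seg_a
            records.append(
                {
                    "kind": ev.kind,
                    "chromosomes": [a, b],
                    "old": {a: [bp_a, bp_a + len(seg_a)], b: [bp_b, bp_b + len(seg_b)]},
                    "new": {a: [bp_a, bp_a + len(seg_b)], b: [bp_b, bp_b + len(seg_a)]},
                    "sizes": [len(seg_a), len(seg_b)],
                }
            )
        elif ev.kind == "nonreciprocal_translocation":
            _check(ev.donor, ev.breakpoint + ev.size)  # type: ignore[operator]
            _check(ev.acceptor, ev.acceptor_breakpoint or 0)  # type: ignore[arg-type]
            seg = chroms[ev.donor][ev.breakpoint : ev.breakpoint + ev.size]
            chroms[ev.donor] = (
                chroms[ev.donor][: ev.breakpoint] + chroms[ev.donor][ev.breakpoint + ev.size :]
            )
            ins = ev.acceptor_breakpoint if ev.acceptor_breakpoint is not None else len(
                chroms[ev.acceptor]
            )
            chroms[ev.acceptor] = chroms[ev.acceptor][:ins] + seg + chroms[ev.acceptor][ins:]
            records.append(
                {
                    "kind": ev.kind,
                    "chromosomes": [ev.donor, ev.acceptor],
                    "old": {ev.donor: [ev.breakpoint, ev.breakpoint + ev.size]},
                    "new": {ev.acceptor: [ins, ins + ev.size]},
                    "sizes": [ev.size],
                }
            )
        elif ev.kind == "inversion":
            _check(ev.donor, ev.breakpoint + ev.size)  # type: ignore[operator]
            s, e = ev.breakpoint, ev.breakpoint + ev.size
            seq = chroms[ev.donor]
            chroms[ev.donor] = seq[:s] + reverse_complement(seq[s:e]) + seq[e:]
            records.append(
                {
                    "kind": ev.kind,
                    "chromosomes": [ev.donor],
                    "old": {ev.donor: [s, e]},
                    "new": {ev.donor: [s, e]},
                    "sizes": [ev.size],
                }
            )
        elif ev.kind == "deletion":
            _check(ev.donor, ev.breakpoint + ev.size)  # type: ignore[operator]
            s, e = ev.breakpoint, ev.breakpoint + ev.size
            seq = chroms[ev.donor]
            chroms[ev.donor] = seq[:s] + seq[e:]
            records.append(
                {
                    "kind": ev.kind,
                    "chromosomes": [ev.donor],
                    "old": {ev.donor: [s, e]},
                    "new": {ev.donor: [s, s]},
                    "sizes": [ev.size],
                }
            )
    truth = TruthSet(sv_events=records)
    return Genome(chroms, genome.name), truth


# ---------------------------------------------------------------------------
# evidence-level simulators
# ---------------------------------------------------------------------------

def simulate_coverage(
    genome: Genome, mean_cov: float, window: int = 1000, seed: int = 1
) -> pd.DataFrame:
    """Per-window mean mapping coverage with Poisson noise.

    Each window's mean coverage is Poisson(mean_cov * width) / width, i.e. the
    average of independent per-base Poisson depths. Columns: chrom, start,
    end (0-based half-open), mean_coverage.
    """
    if mean_cov <= 0:
        raise ValueError("mean_cov must be positive")
    if window < 1:
        raise ValueError("window must be >= 1")
    rng = derive_rng(seed, "simulate_coverage")
    rows = []
    for chrom, seq in genome.chromosomes.items():
        length = len(seq)
        starts = np.arange(0, length, window)
        ends = np.minimum(starts + window, length)
        widths = ends - starts
        cov = rng.poisson(mean_cov * widths) / widths
        for s, e, c in zip(starts, ends, cov):
            rows.append((chrom, int(s), int(e), float(c)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "mean_coverage"])


def expected_viability(
    divergence: float,
    n_het_reciprocal_translocations: int = 0,
    v0: float = 90.0,
    alpha: float = 39.0,
) -> float:
    """Expected spore viability (percent).

    v0 * exp(-alpha * divergence) * 0.5**s: exponential decay with nucleotide
    divergence plus the classical ~50% loss of balanced meiotic products per
    heterozygous reciprocal translocation.
    """
    if not 0 < v0 <= 100:
        raise ValueError("v0 must lie in (0, 100]")
    return v0 * float(np.exp(-alpha * divergence)) * 0.5 ** n_het_reciprocal_translocations


def simulate_cross(
    divergence: float,
    n_het_reciprocal_translocations: int = 0,
    v0: float = 90.0,
    alpha: float = 39.0,
    n_spores: int = 96,
    seed: int = 1,
) -> dict:
    """One tetrad-dissection cross: Binomial(n_spores, expected/100) viable."""
    if n_spores < 1:
        raise ValueError("n_spores must be >= 1")
    exp_pct = expected_viability(divergence, n_het_reciprocal_translocations, v0, alpha)
    rng = derive_rng(seed, "simulate_cross")
    viable = int(rng.binomial(n_spores, exp_pct / 100.0))
    return {
        "divergence": divergence,
        "n_het_reciprocal_translocations": n_het_reciprocal_translocations,
        "expected_viability": exp_pct,
        "dissected": n_spores,
        "viable": viable,
    }


def logistic_curve(t: np.ndarray, K: float, r: float, N0: float) -> np.ndarray:
    """N(t) = K / (1 + ((K - N0)/N0) e^{-rt})."""
    A = (K - N0) / N0
    return K / (1.0 + A * np.exp(-r * np.asarray(t, dtype=float)))


def simulate_growth(
    K: float,
    r: float,
    N0: float,
    duration: float = 48.0,
    step: float = 0.5,
    noise_sd: float = 0.0,
    seed: int = 1,
) -> pd.DataFrame:
    """Logistic OD trajectory sampled on a uniform grid, Gaussian noise, clipped at 0."""
    if not K > N0 > 0:
        raise ValueError("require K > N0 > 0")
    if r <= 0:
        raise ValueError("growth rate r must be positive")
    times = np.arange(0.0, duration + step / 2, step)
    od = logistic_curve(times, K, r, N0)
    if noise_sd > 0:
        rng = derive_rng(seed, "simulate_growth")
        od = od + rng.normal(0.0, noise_sd, size=od.shape)
    od = np.clip(od, 0.0, None)
    return pd.DataFrame({"time_h": times, "od": od})


# ---------------------------------------------------------------------------
# dataset assembly and text-format emission
# ---------------------------------------------------------------------------

def variants_between(a: Genome, b: Genome) -> list[tuple[str, int, str, str]]:
    """Column-wise diff of two coordinate-matched genomes (0-based positions)."""
    out: list[tuple[str, int, str, str]] = []
    for chrom in a.chromosomes:
        sa = np.frombuffer(a[chrom].encode("ascii"), dtype=np.uint8)
        sb = np.frombuffer(b[chrom].encode("ascii"), dtype=np.uint8)
        if len(sa) != len(sb):
            raise ValueError(f"genomes are not coordinate-matched on {chrom}")
        for pos in np.nonzero(sa != sb)[0]:
            out.append((chrom, int(pos), chr(sa[pos]), chr(sb[pos])))
    return out


def write_truth_vcf(
    variants: list[tuple[str, int, str, str]],
    samples_genotypes: dict[str, list[int]],
    path: str | Path,
    contigs: dict[str, int] | None = None,
) -> None:
    """Minimal haploid VCF (1-based positions) for the truth variant set."""
    samples = list(samples_genotypes)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if contigs:
            for chrom, length in contigs.items():
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for i, (chrom, pos0, ref, alt) in enumerate(variants):
            gts = "\t".join(str(samples_genotypes[s][i]) for s in samples)
            fh.write(f"{chrom}\t{pos0 + 1}\t.\t{ref}\t{alt}\t100\tPASS\t.\tGT\t{gts}\n")


def write_truth_bed(intervals: list[tuple[str, int, int, str]], path: str | Path) -> None:
    """BED (0-based half-open) of truth intervals."""
    with open(path, "w") as fh:
        for chrom, start, end, label in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{label}\n")


def simulate_dataset(config: SimConfig, outdir: str | Path) -> dict:
    """End-to-end default scenario; writes FASTA/VCF/TSV/CSV/JSON artifacts.

    Three lineages echo the study design: a reference, plus two sister
    lineages whose common stem diverged from the reference at roughly twice
    ``branch_divergence`` and which then split from each other at ~1%.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth_dir = outdir / "truth"
    truth_dir.mkdir(exist_ok=True)

    ancestor = generate_ancestor(config)
    reference, t_ref = evolve_lineage(
        ancestor, config.branch_divergence, config.seed, name="reference"
    )
    stem, _ = evolve_lineage(ancestor, config.branch_divergence, config.seed + 1, name="stem")
    sac, t_sac = evolve_lineage(stem, 0.005, config.seed + 2, name="SA-C-like")
    aus, t_aus = evolve_lineage(stem, 0.005, config.seed + 3, name="AUS-like")

    if config.introgression_tracts:
        sac, t_intro = implant_introgression(sac, reference, config.introgression_tracts)
    else:
        t_intro = TruthSet()
    if config.sv_events:
        sac_rearranged, t_sv = apply_svs(sac, config.sv_events)
    else:
        sac_rearranged, t_sv = sac, TruthSet()

    lineages = {"reference": reference, "SA-C-like": sac_rearranged, "AUS-like": aus}
    for label, g in lineages.items():
        g.to_fasta(outdir / f"lineage_{label}.fasta")

    # truth variants: column diff of the un-rearranged coordinate-matched genomes
    contigs = {c: len(s) for c, s in reference.chromosomes.items()}
    var_sac = variants_between(reference, sac)
    var_aus = variants_between(reference, aus)
    keys = sorted({(c, p) for c, p, _, _ in var_sac} | {(c, p) for c, p, _, _ in var_aus})
    alleles: dict[tuple[str, int], tuple[str, str]] = {}
    gt_sac, gt_aus = [], []
    sac_map = {(c, p): (r, a) for c, p, r, a in var_sac}
    aus_map = {(c, p): (r, a) for c, p, r, a in var_aus}
    merged: list[tuple[str, int, str, str]] = []
    for key in keys:
        ref_allele = (sac_map.get(key) or aus_map[key])[0]
        alt = (sac_map.get(key) or aus_map[key])[1]
        merged.append((key[0], key[1], ref_allele, alt))
        gt_sac.append(1 if key in sac_map else 0)
        gt_aus.append(1 if key in aus_map and aus_map[key][1] == alt else 0)
    write_truth_vcf(
        merged,
        {"SA-C-like": gt_sac, "AUS-like": gt_aus},
        outdir / "variants.vcf",
        contigs=contigs,
    )

    coverage = simulate_coverage(reference, config.mean_coverage, seed=config.seed)
    coverage.to_csv(outdir / "coverage.tsv", sep="\t", index=False)
    write_truth_bed(t_intro.introgressions, truth_dir / "introgressions.bed")
    with open(truth_dir / "sv_events.json", "w") as fh:
        json.dump(t_sv.sv_events, fh, indent=2, sort_keys=True)

    # crosses: every lineage pair, divergence measured from the emitted genomes
    rows = []
    pairs = [("reference", "SA-C-like"), ("reference", "AUS-like"), ("SA-C-like", "AUS-like")]
    div = {
        ("reference", "SA-C-like"): len(var_sac) / reference.total_length,
        ("reference", "AUS-like"): len(var_aus) / reference.total_length,
        ("SA-C-like", "AUS-like"): len(variants_between(sac, aus)) / reference.total_length,
    }
    n_rt = len([e for e in t_sv.sv_events if e["kind"] == "reciprocal_translocation"])
    het_rt = {
        ("reference", "SA-C-like"): n_rt,
        ("reference", "AUS-like"): 0,
        ("SA-C-like", "AUS-like"): n_rt,
    }
    truth_viab: dict[str, float] = {}
    for i, pair in enumerate(pairs):
        cross = simulate_cross(
            div[pair], het_rt[pair], n_spores=96, seed=config.seed * 10 + i
        )
        truth_viab[f"{pair[0]}x{pair[1]}"] = cross["expected_viability"]
        rows.append(
            {
                "parent_a": pair[0],
                "parent_b": pair[1],
                "dissected": cross["dissected"],
                "viable": cross["viable"],
                "identity_percent": 100.0 * (1.0 - div[pair]),
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "crosses.csv", index=False)

    # growth curves: per strain x condition triplicates, lineage-specific K
    conditions = ["glucose", "maltose"]
    lineage_K = {"reference": {"glucose": 1.0, "maltose": 0.9},
                 "SA-C-like": {"glucose": 1.0, "maltose": 0.45},
                 "AUS-like": {"glucose": 0.95, "maltose": 0.4}}
    growth_rows = []
    ordinal = 0
    for label in lineages:
        for s in range(config.n_samples_per_lineage):
            for cond in conditions:
                curve = simulate_growth(
                    K=lineage_K[label][cond], r=0.5, N0=0.05, duration=48.0, step=0.5,
                    noise_sd=0.01, seed=config.seed * 1000 + ordinal,
                )
                ordinal += 1
                for rep in range(3):
                    rep_curve = simulate_growth(
                        K=lineage_K[label][cond], r=0.5, N0=0.05, duration=48.0, step=0.5,
                        noise_sd=0.01, seed=config.seed * 1000 + ordinal,
                    )
                    ordinal += 1
                    for t, od in zip(rep_curve["time_h"], rep_curve["od"]):
                        growth_rows.append(
                            {
                                "strain": f"{label}_{s + 1}",
                                "lineage": label,
                                "condition": cond,
                                "replicate": rep + 1,
                                "time_h": t,
                                "od": od,
                            }
                        )
    pd.DataFrame(growth_rows).to_csv(outdir / "growth.csv", index=False)

    with open(truth_dir / "expected_viability.json", "w") as fh:
        json.dump(truth_viab, fh, indent=2, sort_keys=True)

    return {
        "lineages": lineages,
        "divergence": {f"{a}x{b}": d for (a, b), d in div.items()},
        "het_reciprocal_translocations": {f"{a}x{b}": v for (a, b), v in het_rt.items()},
        "truth": {
            "variants": merged,
            "introgressions": t_intro.introgressions,
            "sv_events": t_sv.sv_events,
            "expected_viability": truth_viab,
        },
    }
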