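"""Windowed introgression scan.

Candidate donor tracts are runs of non-overlapping 1-kb windows showing zero
SNP density against the donor together with robust (>20x) mapping coverage:
a window that is variant-free because reads map well is donor-identical
sequence, while a variant-free window with poor coverage is just unmappable.

Conventions: windows are 0-based half-open and tile every reference position
exactly once (the terminal window may be short); a 1-based SNP position p
falls in window floor((p-1)/w). Coverage must be strictly greater than the
threshold ("more than 20x"); the SNP rule is an inclusive <= max_snps with
default 0. Tracts merge consecutive flagged windows (up to max_gap unflagged
windows bridged, default 0) and must reach min_tract (default 2 kb, the
smallest reported signal scale) and contain at least one full-width window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class WindowStat:
    chrom: str
    start: int  # 0-based
    end: int  # half-open
    snp_count: int
    mean_coverage: float


@dataclass(frozen=True)
class IntrogressionTract:
    chrom: str
    start: int
    end: int
    length: int
    n_windows: int
    mean_coverage: float
    donor: str | None = None


def window_stats(
    variant_positions: dict[str, np.ndarray] | pd.DataFrame,
    coverage: pd.DataFrame,
    window: int = 1000,
) -> list[WindowStat]:
    """Per-window SNP count and mean coverage over the reference tiling.

    variant_positions: {chrom: 1-based SNP positions} or a DataFrame with
    chrom/pos columns. coverage: DataFrame chrom/start/end/mean_coverage
    (0-based half-open) covering the same reference; it defines the extent of
    each chromosome. Coverage is averaged into windows weighted by overlap.
    """
    if window < 100:
        raise ValueError("window must be >= 100 bp")
    if isinstance(variant_positions, pd.DataFrame):
        variant_positions = {
            chrom: grp["pos"].to_numpy()
            for chrom, grp in variant_positions.groupby("chrom", sort=False)
        }
    stats: list[WindowStat] = []
    for chrom, cov in coverage.groupby("chrom", sort=False):
        chrom_len = int(cov["end"].max())
        starts = np.arange(0, chrom_len, window)
        ends = np.minimum(starts + window, chrom_len)
        snp_counts = np.zeros(len(starts), dtype=int)
        pos = np.asarray(variant_positions.get(chrom, np.array([], dtype=int)))
        if len(pos):
            widx = (pos - 1) // window
            widx = widx[(widx >= 0) & (widx < len(starts))]
            np.add.at(snp_counts, widx, 1)
        depth = np.zeros(len(starts))
        weight = np.zeros(len(starts))
        for s, e, c in cov[["start", "end", "mean_coverage"]].itertuples(index=False):
            first, last = int(s) // window, (int(e) - 1) // window
            for w in range(first, min(last, len(starts) - 1) + 1):
                ov = min(e, ends[w]) - max(s, starts[w])
                if ov > 0:
                    depth[w] += c * ov
                    weight[w] += ov
        mean_cov = np.divide(depth, weight, out=np.zeros_like(depth), where=weight > 0)
        for i in range(len(starts)):
            stats.append(
                WindowStat(chrom, int(starts[i]), int(ends[i]), int(snp_counts[i]),
                           float(mean_cov[i]))
            )
    return stats


def flag_windows(
    stats: list[WindowStat], max_snps: int = 0, min_coverage: float = 20.0
) -> list[WindowStat]:
    """Windows with snp_count <= max_snps and mean coverage strictly > min_coverage."""
    return [w for w in stats if w.snp_count <= max_snps and w.mean_coverage > min_coverage]


def merge_tracts(
    flagged: list[WindowStat],
    window: int = 1000,
    max_gap_windows: int = 0,
    min_tract: int = 2000,
    donor: str | None = None,
) -> list[IntrogressionTract]:
    """Merge consecutive flagged windows into tracts and apply the length floor.

    Windows are consecutive when separated by at most max_gap_windows
    unflagged windows. Tracts shorter than min_tract, or consisting solely of
    a short terminal window, are dropped.
    """
    tracts: list[IntrogressionTract] = []
    by_chrom: dict[str, list[WindowStat]] = {}
    for w in sorted(flagged, key=lambda w: (w.chrom, w.start)):
        by_chrom.setdefault(w.chrom, []).append(w)
    for chrom, wins in by_chrom.items():
        run: list[WindowStat] = []
        for w in wins:
            if run and w.start - run[-1].end > max_gap_windows * window:
                tracts.extend(_emit(run, window, min_tract, donor))
                run = []
            run.append(w)
        tracts.extend(_emit(run, window, min_tract, donor))
    return tracts


def _emit(
    run: list[WindowStat], window: int, min_tract: int, donor: str | None
) -> list[IntrogressionTract]:
    if not run:
        return []
    start, end = run[0].start, run[-1].end
    length = end - start
    if length < min_tract:
        return []
    if not any(w.end - w.start == window for w in run):
        return []
    mean_cov = float(np.mean([w.mean_coverage for w in run]))
    return [IntrogressionTract(run[0].chrom, start, end, length, len(run), mean_cov, donor)]


def scan(
    variant_positions: dict[str, np.ndarray] | pd.DataFrame,
    coverage: pd.DataFrame,
    window: int = 1000,
    max_snps: int = 0,
    min_coverage: float = 20.0,
    max_gap_windows: int = 0,
    min_tract: int = 2000,
    donor: str | None = None,
) -> tuple[list[IntrogressionTract], pd.DataFrame]:
    """window_stats -> flag_windows -> merge_tracts; returns tracts + window report."""
    stats = window_stats(variant_positions, coverage, window)
    flagged = flag_windows(stats, max_snps, min_coverage)
    tracts = merge_tracts(flagged, window, max_gap_windows, min_tract, donor)
    flagged_keys = {(w.chrom, w.start) for w in flagged}
    report = pd.DataFrame(
        [
            {
                "chrom": w.chrom, "start": w.start, "end": w.end,
                "snp_count": w.snp_count, "mean_coverage": w.mean_coverage,
                "flagged": (w.chrom, w.start) in flagged_keys,
            }
            for w in stats
        ]
    )
    return tracts, report


def tracts_to_bed(tracts: list[IntrogressionTract], path) -> None:
    with open(path, "w") as fh:
        for t in tracts:
            label = t.donor or "introgression"
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\t{label}\t{t.n_windows}\t{t.mean_coverage:.2f}\n")
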