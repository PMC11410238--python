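"""Structural variants from whole-genome alignment blocks.

A query assembly aligned to a reference decomposes into collinear blocks
(ref chromosome, ref interval, query contig, query interval, strand). Chains
of blocks are classified into rearrangements:

* each query contig is assigned a primary reference chromosome by majority of
  aligned bases;
* a maximal run of blocks on a non-primary chromosome is a translocation
  (size = reference span); two translocations that mirror each other across
  two chromosomes are linked as a reciprocal pair, the rest are non-reciprocal;
* a maximal run of minus-strand blocks embedded in plus-strand context on one
  chromosome is an inversion;
* adjacent same-chromosome blocks with a large reference gap but a small query
  gap are a deletion (the converse an insertion);
* two disjoint query intervals aligning to one reference interval (reciprocal
  overlap >= 0.9) are a duplication.

Deletions/insertions whose interval is explained by a translocated segment
(the sequence moved rather than vanished) are suppressed. Downstream filters
keep events strictly larger than 1 kb and drop calls in exclusion regions
(e.g. rDNA).

Blocks can be read from a 9-column TSV (layout documented in read_blocks) or
produced by the built-in anchor aligner: genome-wide unique k-mers shared by
reference and query are chained by diagonal into blocks, which keeps the
pipeline self-contained on simulated assemblies.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import edlib
import numpy as np

from .genome import Genome, reverse_complement

BLOCK_COLUMNS = [
    "ref_chrom", "ref_start", "ref_end", "query", "query_start", "query_end",
    "strand", "identity", "length",
]


@dataclass(frozen=True)
class AlignmentBlock:
    """One collinear alignment segment; coordinates 1-based inclusive."""

    ref_chrom: str
    ref_start: int
    ref_end: int
    query: str
    query_start: int
    query_end: int
    strand: str
    identity: float  # percent

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.ref_start > self.ref_end or self.query_start > self.query_end:
            raise ValueError("block intervals must satisfy start <= end")
        if self.ref_end - self.ref_start < 0:
            raise ValueError("degenerate block")

    @property
    def ref_span(self) -> int:
        return self.ref_end - self.ref_start + 1

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start + 1


@dataclass
class StructuralVariant:
    event_id: int
    kind: str
    ref_chrom: str
    ref_start: int  # 1-based inclusive
    ref_end: int
    query: str
    query_start: int
    query_end: int
    size: int
    contig_primary: str  # reference chromosome the query contig mainly represents
    partner_id: int | None = None
    genes_overlapped: int | None = None


# ---------------------------------------------------------------------------
# block IO
# ---------------------------------------------------------------------------

def read_blocks(path: str | Path) -> list[AlignmentBlock]:
    """Read tab-separated alignment blocks, sorted by (query, query_start).

    Expected 9 columns (header optional):
    ref_chrom  ref_start  ref_end  query  query_start  query_end  strand
    identity  length -- coordinates 1-based inclusive, identity in percent.
    """
    blocks: list[AlignmentBlock] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "ref_chrom":  # header row
                continue
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 columns, got {len(fields)}")
            try:
                blocks.append(
                    AlignmentBlock(
                        ref_chrom=fields[0], ref_start=int(fields[1]), ref_end=int(fields[2]),
                        query=fields[3], query_start=int(fields[4]), query_end=int(fields[5]),
                        strand=fields[6], identity=float(fields[7]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    blocks.sort(key=lambda b: (b.query, b.query_start))
    return blocks


def write_blocks(blocks: list[AlignmentBlock], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(BLOCK_COLUMNS) + "\n")
        for b in sorted(blocks, key=lambda b: (b.query, b.query_start)):
            fh.write(
                f"{b.ref_chrom}\t{b.ref_start}\t{b.ref_end}\t{b.query}\t{b.query_start}"
                f"\t{b.query_end}\t{b.strand}\t{b.identity:.2f}\t{b.ref_span}\n"
            )


# ---------------------------------------------------------------------------
# anchor-based block aligner
# ---------------------------------------------------------------------------

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i


def _kmer_codes(seq: str, k: int) -> np.ndarray:
    """2-bit packed codes of all k-mers (k <= 31); positions with N get code 2^64-1."""
    b = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = len(b) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    codes = np.zeros(n, dtype=np.uint64)
    bad = np.zeros(n, dtype=bool)
    for j in range(k):
        codes = codes * np.uint64(4) + b[j : j + n].astype(np.uint64)
        bad |= b[j : j + n] == 255
    codes[bad] = np.uint64(0xFFFFFFFFFFFFFFFF)
    return codes


def _rc_kmer_codes(seq: str, k: int) -> np.ndarray:
    """Codes of the reverse complement of each k-mer, at the forward position."""
    b = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    comp = np.uint8(3) - b  # A<->T, C<->G; non-ACGT positions masked via `bad`
    n = len(b) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    codes = np.zeros(n, dtype=np.uint64)
    bad = np.zeros(n, dtype=bool)
    for j in range(k):
        codes = codes + comp[j : j + n].astype(np.uint64) * np.uint64(4) ** np.uint64(j)
        bad |= b[j : j + n] == 255
    codes[bad] = np.uint64(0xFFFFFFFFFFFFFFFF)
    return codes


def _unique_code_table(genome: Genome, k: int):
    """(sorted codes unique genome-wide, chrom index array, position array)."""
    all_codes, all_chrom, all_pos = [], [], []
    chrom_names = list(genome.chromosomes)
    for ci, chrom in enumerate(chrom_names):
        codes = _kmer_codes(genome[chrom], k)
        all_codes.append(codes)
        all_chrom.append(np.full(len(codes), ci, dtype=np.int32))
        all_pos.append(np.arange(len(codes), dtype=np.int64))
    codes = np.concatenate(all_codes)
    chroms = np.concatenate(all_chrom)
    pos = np.concatenate(all_pos)
    order = np.argsort(codes, kind="stable")
    codes, chroms, pos = codes[order], chroms[order], pos[order]
    dup = np.zeros(len(codes), dtype=bool)
    dup[1:] = codes[1:] == codes[:-1]
    dup[:-1] |= codes[1:] == codes[:-1]
    keep = ~dup & (codes != np.uint64(0xFFFFFFFFFFFFFFFF))
    return codes[keep], chroms[keep], pos[keep], chrom_names


def _segment_identity(ref_seq: str, query_seq: str, strand: str) -> float:
    """Percent identity of a block, estimated from sampled 500-bp alignments."""
    if strand == "-":
        query_seq = reverse_complement(query_seq)
    n = min(len(ref_seq), len(query_seq))
    if n == 0:
        return 0.0
    win = min(500, n)
    offsets = np.linspace(0, n - win, num=min(5, max(1, n // win)), dtype=int)
    idents = []
    for off in offsets:
        res = edlib.align(query_seq[off : off + win], ref_seq[off : off + win], mode="NW")
        cols = max(win, win + res["editDistance"])  # lower bound on columns
        idents.append(1.0 - res["editDistance"] / cols)
    return 100.0 * float(np.mean(idents))


def align_genomes(
    reference: Genome,
    query: Genome,
    k: int = 21,
    max_anchor_gap: int = 2000,
    diag_tolerance: int = 100,
    min_block: int = 200,
    min_anchors: int = 2,
) -> list[AlignmentBlock]:
    """Chain genome-wide-unique shared k-mers into collinear alignment blocks.

    Anchors are k-mers unique in both genomes; consecutive anchors join one
    block while the reference chromosome, strand and diagonal stay consistent
    (plus-strand diagonal ref-query constant; minus-strand ref+query constant)
    and the query gap stays below max_anchor_gap.
    """
    ref_codes, ref_chrom_idx, ref_pos, ref_names = _unique_code_table(reference, k)
    blocks: list[AlignmentBlock] = []
    for qchrom, qseq in query.chromosomes.items():
        fwd = _kmer_codes(qseq, k)
        rc = _rc_kmer_codes(qseq, k)
        # query-side genome-wide uniqueness proxy: unique within this scan set
        order = np.argsort(fwd, kind="stable")
        srt = fwd[order]
        dup = np.zeros(len(srt), dtype=bool)
        dup[1:] = srt[1:] == srt[:-1]
        dup[:-1] |= srt[1:] == srt[:-1]
        nonuniq = set(srt[dup].tolist())

        anchors = []  # (qpos, ref chrom idx, ref pos, strand)
        for strand, codes in (("+", fwd), ("-", rc)):
            idx = np.searchsorted(ref_codes, codes)
            idx[idx >= len(ref_codes)] = 0
            hit = ref_codes[idx] == codes
            for qpos in np.nonzero(hit)[0]:
                if fwd[qpos] in nonuniq:
                    continue
                j = idx[qpos]
                anchors.append((int(qpos), int(ref_chrom_idx[j]), int(ref_pos[j]), strand))
        anchors.sort(key=lambda a: a[0])

        run: list[tuple[int, int, int, str]] = []

        def _flush() -> None:
            if len(run) < min_anchors:
                run.clear()
                return
            qs, qe = run[0][0], run[-1][0] + k
            rps = [a[2] for a in run]
            rs, re = min(rps), max(rps) + k
            if qe - qs < min_block or re - rs < min_block:
                run.clear()
                return
            chrom = ref_names[run[0][1]]
            strand = run[0][3]
            ident = _segment_identity(reference[chrom][rs:re], qseq[qs:qe], strand)
            blocks.append(
                AlignmentBlock(chrom, rs + 1, re, qchrom, qs + 1, qe, strand, ident)
            )
            run.clear()

        for anchor in anchors:
            qpos, ci, rpos, strand = anchor
            if run:
                pq, pci, prp, pstrand = run[-1]
                diag = rpos - qpos if strand == "+" else rpos + qpos
                pdiag = prp - pq if pstrand == "+" else prp + pq
                if (
                    ci != pci
                    or strand != pstrand
                    or qpos - pq > max_anchor_gap
                    or abs(diag - pdiag) > diag_tolerance
                ):
                    _flush()
            run.append(anchor)
        _flush()
    blocks.sort(key=lambda b: (b.query, b.query_start))
    return blocks


# ---------------------------------------------------------------------------
# SV classification
# ---------------------------------------------------------------------------

def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    ov = min(a[1], b[1]) - max(a[0], b[0]) + 1
    if ov <= 0:
        return 0.0
    return min(ov / (a[1] - a[0] + 1), ov / (b[1] - b[0] + 1))


def call_svs(
    blocks: list[AlignmentBlock],
    gap_tolerance: int = 200,
    min_event: int = 50,
) -> list[StructuralVariant]:
    """Classify rearrangements from the block chains of one query assembly."""
    if not blocks:
        return []
    by_query: dict[str, list[AlignmentBlock]] = {}
    for b in sorted(blocks, key=lambda b: (b.query, b.query_start)):
        by_query.setdefault(b.query, []).append(b)

    events: list[StructuralVariant] = []
    next_id = 0

    def _emit(kind: str, ref_chrom: str, rs: int, re_: int, query: str,
              qs: int, qe: int, size: int, primary: str) -> StructuralVariant:
        nonlocal next_id
        ev = StructuralVariant(next_id, kind, ref_chrom, rs, re_, query, qs, qe, size, primary)
        next_id += 1
        events.append(ev)
        return ev

    for query, qblocks in by_query.items():
        aligned: dict[str, int] = {}
        for b in qblocks:
            aligned[b.ref_chrom] = aligned.get(b.ref_chrom, 0) + b.ref_span
        primary = max(sorted(aligned), key=lambda c: aligned[c])

        # translocations: maximal runs on a non-primary chromosome
        i = 0
        while i < len(qblocks):
            if qblocks[i].ref_chrom == primary:
                i += 1
                continue
            j = i
            while j + 1 < len(qblocks) and qblocks[j + 1].ref_chrom == qblocks[i].ref_chrom:
                j += 1
            run = qblocks[i : j + 1]
            rs = min(b.ref_start for b in run)
            re_ = max(b.ref_end for b in run)
            _emit("translocation", run[0].ref_chrom, rs, re_, query,
                  run[0].query_start, run[-1].query_end, re_ - rs + 1, primary)
            i = j + 1

        # per-chromosome chains: inversions and indels
        by_chrom: dict[str, list[AlignmentBlock]] = {}
        for b in qblocks:
            by_chrom.setdefault(b.ref_chrom, []).append(b)
        for chrom, chain in by_chrom.items():
            # the inverted segment is the embedded strand: fewer maximal runs
            # than its context (an inversion can exceed half the chromosome)
            runs_of = {"+": 0, "-": 0}
            for idx, b in enumerate(chain):
                if idx == 0 or chain[idx - 1].strand != b.strand:
                    runs_of[b.strand] += 1
            if runs_of["+"] == runs_of["-"]:
                plus_span = sum(b.ref_span for b in chain if b.strand == "+")
                minus_span = sum(b.ref_span for b in chain if b.strand == "-")
                minority = "-" if minus_span <= plus_span else "+"
            else:
                minority = "-" if runs_of["-"] < runs_of["+"] else "+"
            # inversion: maximal minority-strand runs embedded in majority context
            i = 0
            while i < len(chain):
                if chain[i].strand != minority:
                    i += 1
                    continue
                j = i
                while j + 1 < len(chain) and chain[j + 1].strand == minority:
                    j += 1
                if i > 0 or j < len(chain) - 1:  # embedded, not the whole chain
                    rs = min(b.ref_start for b in chain[i : j + 1])
                    re_ = max(b.ref_end for b in chain[i : j + 1])
                    _emit("inversion", chrom, rs, re_, query,
                          chain[i].query_start, chain[j].query_end, re_ - rs + 1, primary)
                i = j + 1
            # indels between adjacent same-strand blocks in query order
            for prev, cur in zip(chain, chain[1:]):
                if prev.strand != cur.strand:
                    continue
                if prev.strand == "+":
                    ref_gap = cur.ref_start - prev.ref_end - 1
                else:
                    ref_gap = prev.ref_start - cur.ref_end - 1
                query_gap = cur.query_start - prev.query_end - 1
                if ref_gap >= min_event and query_gap < gap_tolerance:
                    rs = (prev.ref_end + 1) if prev.strand == "+" else (cur.ref_end + 1)
                    _emit("deletion", chrom, rs, rs + ref_gap - 1, query,
                          prev.query_end, cur.query_start, ref_gap, primary)
                elif query_gap >= min_event and ref_gap < gap_tolerance:
                    _emit("insertion", chrom, prev.ref_end, cur.ref_start, query,
                          prev.query_end + 1, cur.query_start - 1, query_gap, primary)

    # duplications: >=2 disjoint query intervals on one reference interval
    all_blocks = [b for chain in by_query.values() for b in chain]
    for i, a in enumerate(all_blocks):
        for b in all_blocks[i + 1 :]:
            if a.ref_chrom != b.ref_chrom:
                continue
            same_query = a.query == b.query
            q_disjoint = (not same_query) or (
                a.query_end < b.query_start or b.query_end < a.query_start
            )
            if not q_disjoint:
                continue
            if _reciprocal_overlap(
                (a.ref_start, a.ref_end), (b.ref_start, b.ref_end)
            ) >= 0.9:
                rs = min(a.ref_start, b.ref_start)
                re_ = max(a.ref_end, b.ref_end)
                _emit("duplication", a.ref_chrom, rs, re_, b.query,
                      b.query_start, b.query_end, re_ - rs + 1, a.ref_chrom)

    # a deletion/insertion explained by a translocated segment is a move, not a loss
    translocations = [e for e in events if e.kind == "translocation"]
    kept: list[StructuralVariant] = []
    for ev in events:
        if ev.kind == "deletion" and any(
            t.ref_chrom == ev.ref_chrom
            and _reciprocal_overlap((t.ref_start, t.ref_end), (ev.ref_start, ev.ref_end)) >= 0.5
            for t in translocations
        ):
            continue
        if ev.kind == "insertion" and any(
            t.query == ev.query
            and not (t.query_end < ev.query_start or ev.query_end < t.query_start)
            for t in translocations
        ):
            continue
        kept.append(ev)
    return kept


def pair_reciprocal(svs: list[StructuralVariant]) -> list[StructuralVariant]:
    """Link mirrored translocations as reciprocal; label the rest non-reciprocal.

    A pair (t1, t2) is reciprocal when t1 is a segment of chromosome A sitting
    on the contig that primarily represents chromosome B, and t2 the converse.
    """
    out = [replace(ev) for ev in svs]
    trans = [ev for ev in out if ev.kind == "translocation"]
    used: set[int] = set()
    for t1 in trans:
        if t1.event_id in used:
            continue
        for t2 in trans:
            if t2.event_id in used or t2.event_id == t1.event_id:
                continue
            if t1.ref_chrom == t2.contig_primary and t2.ref_chrom == t1.contig_primary:
                t1.kind = t2.kind = "reciprocal_translocation"
                t1.partner_id, t2.partner_id = t2.event_id, t1.event_id
                used.update({t1.event_id, t2.event_id})
                break
    for ev in out:
        if ev.kind == "translocation":
            ev.kind = "nonreciprocal_translocation"
    return out


def filter_svs(
    svs: list[StructuralVariant],
    min_size: int = 1000,
    exclusion_regions: list[tuple[str, int, int]] | None = None,
) -> list[StructuralVariant]:
    """Keep events strictly larger than min_size and outside exclusion intervals.

    Exclusion intervals (e.g. the rDNA locus) are 1-based inclusive on the
    reference; any overlap removes the call.
    """
    out = []
    for ev in svs:
        if ev.size <= min_size:
            continue
        if exclusion_regions and any(
            ev.ref_chrom == chrom and ev.ref_start <= end and start <= ev.ref_end
            for chrom, start, end in exclusion_regions
        ):
            continue
        out.append(ev)
    return out


def read_gene_intervals(gff_path: str | Path) -> list[tuple[str, int, int]]:
    """Gene features (seqid, start, end), 1-based inclusive, from a GFF3 file."""
    import gffutils

    db = gffutils.create_db(
        str(gff_path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    return sorted(
        (f.seqid, f.start, f.end) for f in db.features_of_type("gene")
    )


def annotate_genes(
    svs: list[StructuralVariant],
    annotation: str | Path | list[tuple[str, int, int]],
) -> list[StructuralVariant]:
    """Count gene features overlapping each event's reference interval (>=1 bp)."""
    genes = (
        annotation if isinstance(annotation, list) else read_gene_intervals(annotation)
    )
    out = [replace(ev) for ev in svs]
    for ev in out:
        ev.genes_overlapped = sum(
            1 for chrom, start, end in genes
            if chrom == ev.ref_chrom and ev.ref_start <= end and start <= ev.ref_end
        )
    return out


def summarize(svs_by_strain: dict[str, list[StructuralVariant]]) -> dict:
    """Counts by class per strain plus the per-strain mean total."""
    kinds = sorted({ev.kind for svs in svs_by_strain.values() for ev in svs})
    per_strain = {
        strain: {
            "total": len(svs),
            **{kind: sum(1 for ev in svs if ev.kind == kind) for kind in kinds},
        }
        for strain, svs in svs_by_strain.items()
    }
    totals = [v["total"] for v in per_strain.values()]
    return {
        "per_strain": per_strain,
        "mean_svs_per_strain": float(np.mean(totals)) if totals else 0.0,
    }


def write_svs(svs: list[StructuralVariant], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "event_id\tkind\tref_chrom\tref_start\tref_end\tquery\tquery_start"
            "\tquery_end\tsize\tcontig_primary\tpartner_id\tgenes_overlapped\n"
        )
        for ev in svs:
            fh.write(
                f"{ev.event_id}\t{ev.kind}\t{ev.ref_chrom}\t{ev.ref_start}\t{ev.ref_end}"
                f"\t{ev.query}\t{ev.query_start}\t{ev.query_end}\t{ev.size}"
                f"\t{ev.contig_primary}\t{ev.partner_id if ev.partner_id is not None else '.'}"
                f"\t{ev.genes_overlapped if ev.genes_overlapped is not None else '.'}\n"
            )
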