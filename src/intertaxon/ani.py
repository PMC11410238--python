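"""Average nucleotide identity by orthology (OANI).

Both assemblies are cut into consecutive, non-overlapping fragments (default
1020 bp, trailing remainders dropped). Fragments are paired by reciprocal
best hit: fragment i of genome A pairs with fragment j of genome B iff j is
i's best-identity hit in B and i is j's best hit in A. OANI is 100x the mean
alignment identity over those orthologous pairs, each pair's identity taken
symmetrically (mean of the A->B and B->A alignment identities), and the value
is classified against the 95-96% species-delineation band: below the band the
pair of genomes is called distinct, above it conspecific, inside ambiguous.

Identity is matches / alignment columns of a global (Needleman-Wunsch) edit
alignment; gap columns count. Both strands are tried. Candidate subjects are
prefiltered by shared k-mers (default k=15) to avoid all-vs-all alignment;
a brute-force all-vs-all path is kept for oracle tests.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import edlib

from .genome import Genome, reverse_complement

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


class NoOrthologyError(ValueError):
    """Raised when two genomes share no reciprocal-best fragment pair."""


@dataclass(frozen=True)
class Fragment:
    """One fixed-length genome fragment (0-based start)."""

    genome_id: str
    chrom: str
    start: int
    length: int
    sequence: str
    index: int  # ordinal within its genome's fragment list


@dataclass(frozen=True)
class FragmentHit:
    query_index: int
    subject_index: int
    identity: float  # matches / alignment columns, in [0, 1]
    aligned_columns: int
    query_coverage: float  # fraction of query bases in match/mismatch columns
    strand: str  # '+' or '-'


@dataclass
class AniResult:
    oani: float  # percent
    n_orthologous_pairs: int
    pair_identities: list[float]
    zone: str
    parameters: dict = field(default_factory=dict)


def fragment_genome(genome: Genome, fragment_length: int = 1020) -> list[Fragment]:
    """Consecutive non-overlapping fragments; remainder < fragment_length dropped."""
    if fragment_length < 100:
        raise ValueError("fragment_length must be >= 100")
    if genome.total_length == 0 or len(genome) == 0:
        raise ValueError("cannot fragment an empty genome")
    frags: list[Fragment] = []
    idx = 0
    for chrom, seq in genome.chromosomes.items():
        for start in range(0, len(seq) - fragment_length + 1, fragment_length):
            frags.append(
                Fragment(genome.name, chrom, start, fragment_length,
                         seq[start : start + fragment_length], idx)
            )
            idx += 1
    return frags


def _align_stats(query: str, subject: str, mode: str = "NW") -> tuple[float, int, float]:
    """Alignment of a fragment: (identity, columns, query coverage).

    mode NW is a global fragment-vs-fragment alignment; mode HW aligns the
    full query as an infix of a longer subject (the fragment plus flanking
    genomic context), which keeps identity meaningful when rearrangements
    shift the fragment grid out of phase between the two genomes.
    """
    res = edlib.align(query, subject, mode=mode, task="path")
    matches = columns = paired = 0
    for count, op in _CIGAR_RE.findall(res["cigar"]):
        n = int(count)
        columns += n
        if op == "=":
            matches += n
            paired += n
        elif op == "X":
            paired += n
    identity = matches / columns if columns else 0.0
    coverage = paired / len(query)  # query bases sitting in match/mismatch columns
    return identity, columns, coverage


class KmerIndex:
    """k-mer -> fragment indices, for candidate prefiltering."""

    def __init__(self, fragments: list[Fragment], k: int = 15):
        self.k = k
        self.index: dict[str, list[int]] = {}
        for frag in fragments:
            seq = frag.sequence
            seen: set[str] = set()
            for i in range(0, len(seq) - k + 1):
                kmer = seq[i : i + k]
                if kmer not in seen:
                    seen.add(kmer)
                    self.index.setdefault(kmer, []).append(frag.index)

    def candidates(self, sequence: str) -> set[int]:
        k = self.k
        out: set[int] = set()
        for i in range(0, len(sequence) - k + 1):
            hit = self.index.get(sequence[i : i + k])
            if hit:
                out.update(hit)
        return out


def best_hit(
    fragment: Fragment,
    subject_fragments: list[Fragment],
    min_coverage: float = 0.35,
    min_identity: float = 0.0,
    index: KmerIndex | None = None,
    context_of: dict[int, str] | None = None,
) -> FragmentHit | None:
    """Maximal-identity subject passing the coverage/identity filters.

    Both strands are tried; ties break to the lower subject fragment index.
    With a KmerIndex, only subjects sharing at least one k-mer (either strand)
    are aligned; pass index=None for the brute-force all-vs-all path. When
    context_of supplies flank-padded subject sequences, the query aligns as an
    infix of the padded subject (local-style); otherwise fragment-vs-fragment
    globally.
    """
    if not subject_fragments:
        raise ValueError("subject fragment set is empty")
    by_index = {f.index: f for f in subject_fragments}
    rc = reverse_complement(fragment.sequence)
    if index is not None:
        cand = index.candidates(fragment.sequence) | index.candidates(rc)
        candidates = [by_index[i] for i in sorted(cand) if i in by_index]
    else:
        candidates = subject_fragments
    best: FragmentHit | None = None
    for subj in candidates:
        if context_of is not None:
            target, mode = context_of[subj.index], "HW"
        else:
            target, mode = subj.sequence, "NW"
        for strand, qseq in (("+", fragment.sequence), ("-", rc)):
            identity, columns, coverage = _align_stats(qseq, target, mode)
            if coverage < min_coverage or identity < min_identity:
                continue
            hit = FragmentHit(fragment.index, subj.index, identity, columns, coverage, strand)
            if (
                best is None
                or hit.identity > best.identity
                or (hit.identity == best.identity and hit.subject_index < best.subject_index)
            ):
                best = hit
    return best


def fragment_contexts(genome: Genome, fragments: list[Fragment], pad: int | None = None) -> dict[int, str]:
    """Flank-padded genomic sequence per fragment (default pad = fragment length)."""
    out: dict[int, str] = {}
    for frag in fragments:
        p = pad if pad is not None else frag.length
        seq = genome[frag.chrom]
        out[frag.index] = seq[max(0, frag.start - p) : frag.start + frag.length + p]
    return out


def orthologous_pairs(
    frags_a: list[Fragment],
    frags_b: list[Fragment],
    min_coverage: float = 0.35,
    min_identity: float = 0.0,
    k: int = 15,
    use_prefilter: bool = True,
    contexts_a: dict[int, str] | None = None,
    contexts_b: dict[int, str] | None = None,
) -> list[tuple[FragmentHit, FragmentHit]]:
    """Reciprocal best hits between two fragment sets; each fragment in <=1 pair."""
    if not frags_a or not frags_b:
        raise ValueError("both fragment lists must be non-empty")
    idx_b = KmerIndex(frags_b, k) if use_prefilter else None
    idx_a = KmerIndex(frags_a, k) if use_prefilter else None
    hits_ab: dict[int, FragmentHit] = {}
    for fa in frags_a:
        hit = best_hit(fa, frags_b, min_coverage, min_identity, idx_b, contexts_b)
        if hit is not None:
            hits_ab[fa.index] = hit
    pairs: list[tuple[FragmentHit, FragmentHit]] = []
    # only fragments of B that were somebody's best hit need the reverse check
    needed_b = {h.subject_index for h in hits_ab.values()}
    by_index_b = {f.index: f for f in frags_b}
    hits_ba: dict[int, FragmentHit] = {}
    for jb in sorted(needed_b):
        back = best_hit(by_index_b[jb], frags_a, min_coverage, min_identity, idx_a, contexts_a)
        if back is not None:
            hits_ba[jb] = back
    for ia in sorted(hits_ab):
        fwd = hits_ab[ia]
        back = hits_ba.get(fwd.subject_index)
        if back is not None and back.subject_index == ia:
            pairs.append((fwd, back))
    return pairs


def classify_ani(oani: float, lower: float = 95.0, upper: float = 96.0) -> str:
    """Zone against the species-delineation band: distinct / ambiguous / conspecific."""
    if lower >= upper:
        raise ValueError("lower threshold must be below upper threshold")
    if not 0.0 <= oani <= 100.0:
        raise ValueError("oani must lie in [0, 100]")
    if oani < lower:
        return "distinct"
    if oani > upper:
        return "conspecific"
    return "ambiguous"


def compute_oani(
    genome_a: Genome,
    genome_b: Genome,
    fragment_length: int = 1020,
    min_coverage: float = 0.35,
    min_identity: float = 0.0,
    k: int = 15,
    lower: float = 95.0,
    upper: float = 96.0,
    use_prefilter: bool = True,
) -> AniResult:
    """OANI between two assemblies; raises NoOrthologyError on zero pairs."""
    frags_a = fragment_genome(genome_a, fragment_length)
    frags_b = fragment_genome(genome_b, fragment_length)
    if len(frags_a) < 2 or len(frags_b) < 2:
        raise ValueError("each genome must yield at least 2 fragments")
    pairs = orthologous_pairs(
        frags_a, frags_b, min_coverage, min_identity, k, use_prefilter,
        contexts_a=fragment_contexts(genome_a, frags_a),
        contexts_b=fragment_contexts(genome_b, frags_b),
    )
    if not pairs:
        raise NoOrthologyError(
            f"no orthologous fragment pairs between {genome_a.name} and {genome_b.name}"
        )
    identities = [(fwd.identity + back.identity) / 2.0 for fwd, back in pairs]
    oani = 100.0 * sum(identities) / len(identities)
    return AniResult(
        oani=oani,
        n_orthologous_pairs=len(pairs),
        pair_identities=identities,
        zone=classify_ani(oani, lower, upper),
        parameters={
            "fragment_length": fragment_length,
            "min_coverage": min_coverage,
            "min_identity": min_identity,
            "k": k,
            "lower": lower,
            "upper": upper,
        },
    )
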