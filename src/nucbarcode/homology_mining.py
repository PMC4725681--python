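"""Seed screening against anchor genomes and extension of hits into
candidate conserved regions.

The first pipeline stage takes a collection of candidate seed sequences
(e.g. long identical multispecies elements) and keeps only those with local
homology in two anchor genomes — one dicot, one monocot in the original
application, to avoid clade bias. Surviving seeds' hits are widened by a
flank so the regions comfortably contain a full amplicon design window.

The local search is a k-mer-prescreened Smith-Waterman: pairs of sequences
sharing no word of ``word_size`` exact bases are skipped (BLAST-style seeding
precondition); otherwise the full affine-gap DP is run. Multiple hits per
subject are produced by recursive splitting: after the best local alignment
is recorded, the subject segments strictly left and right of its footprint
are searched independently. This is deterministic and reproducible by an
independent DP oracle, unlike heuristic X-drop extension.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._align import best_local_alignment
from .core_io import SeqRecord, reverse_complement


@dataclass(frozen=True)
class AlignParams:
    """Scoring scheme and thresholds for the local homology search."""

    word_size: int = 11
    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2
    min_score: int = 40


@dataclass
class HomologyHit:
    """A local alignment of a query (seed) against a subject (genome).

    Intervals are 0-based half-open; the subject interval is always on the
    forward strand, with ``strand`` recording which query orientation aligned.
    Identity is computed over alignment columns with gaps as mismatches.
    """

    query_id: str
    subject_id: str
    query_interval: tuple[int, int]
    subject_interval: tuple[int, int]
    strand: str
    score: int
    identity_fraction: float


@dataclass
class ExtendedRegion:
    """A hit widened by a flank, read in the orientation of the seed."""

    source_seed_id: str
    genome_id: str
    interval: tuple[int, int]
    sequence: str


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def _shares_word(query: str, subject: str, k: int) -> bool:
    if len(query) < k or len(subject) < k:
        return False
    words = _kmers(query, k)
    return any(subject[i:i + k] in words for i in range(len(subject) - k + 1))


def _search_one_strand(query: str, subject: str, lo: int, hi: int,
                       params: AlignParams, out: list[tuple]) -> None:
    """Recursively collect non-overlapping local alignments in subject[lo:hi]."""
    if hi - lo < params.word_size:
        return
    res = best_local_alignment(query, subject[lo:hi], params.match,
                               params.mismatch, params.gap_open,
                               params.gap_extend)
    if res is None:
        return
    score, q_iv, s_iv, identity = res
    if score < params.min_score:
        return
    s_start, s_end = s_iv[0] + lo, s_iv[1] + lo
    out.append((score, q_iv, (s_start, s_end), identity))
    _search_one_strand(query, subject, lo, s_start, params, out)
    _search_one_strand(query, subject, s_end, hi, params, out)


def local_align_search(query: SeqRecord, subject: SeqRecord,
                       params: AlignParams | None = None) -> list[HomologyHit]:
    """All non-overlapping local alignments with score >= min_score, both
    strands, sorted by descending score then (subject_id, start)."""
    params = params or AlignParams()
    if not query.sequence or not subject.sequence:
        raise ValueError("query and subject must be non-empty")
    hits: list[HomologyHit] = []
    n_q = len(query.sequence)
    for strand in "+-":
        q = query.sequence if strand == "+" else reverse_complement(query.sequence)
        if not _shares_word(q, subject.sequence, params.word_size):
            continue
        found: list[tuple] = []
        _search_one_strand(q, subject.sequence, 0, len(subject.sequence),
                           params, found)
        for score, q_iv, s_iv, identity in found:
            if strand == "-":  # map back to forward-strand query coordinates
                q_iv = (n_q - q_iv[1], n_q - q_iv[0])
            hits.append(HomologyHit(query.id, subject.id, q_iv, s_iv, strand,
                                    score, identity))
    hits.sort(key=lambda h: (-h.score, h.subject_id, h.subject_interval[0]))
    return hits


def screen_seeds(seeds: list[SeqRecord], anchor_a: SeqRecord,
                 anchor_b: SeqRecord, params: AlignParams | None = None,
                 ) -> list[tuple[SeqRecord, HomologyHit, HomologyHit]]:
    """Keep seeds with at least one hit in BOTH anchor genomes.

    Returns, in input order, ``(seed, best_hit_in_a, best_hit_in_b)`` triples.
    """
    params = params or AlignParams()
    retained = []
    for seed in seeds:
        hits_a = local_align_search(seed, anchor_a, params)
        if not hits_a:
            continue
        hits_b = local_align_search(seed, anchor_b, params)
        if not hits_b:
            continue
        retained.append((seed, hits_a[0], hits_b[0]))
    return retained


def extend_hit(hit: HomologyHit, genome: SeqRecord,
               flank: int = 200) -> ExtendedRegion:
    """Widen a hit's subject footprint by ``flank`` on both sides (clipped to
    the genome) and extract the sequence in seed orientation (minus-strand
    hits are reverse-complemented)."""
    if flank < 0:
        raise ValueError("flank must be non-negative")
    if hit.subject_id != genome.id:
        raise ValueError(f"hit refers to {hit.subject_id!r}, not {genome.id!r}")
    start = max(0, hit.subject_interval[0] - flank)
    end = min(len(genome.sequence), hit.subject_interval[1] + flank)
    seq = genome.sequence[start:end]
    if hit.strand == "-":
        seq = reverse_complement(seq)
    return ExtendedRegion(hit.query_id, genome.id, (start, end), seq)


def mine_regions(seed: SeqRecord, genomes: list[SeqRecord],
                 params: AlignParams | None = None,
                 flank: int = 200) -> list[ExtendedRegion]:
    """Extend the best hit of a seed in every genome where it has one."""
    regions = []
    for genome in genomes:
        hits = local_align_search(seed, genome, params)
        if hits:
            regions.append(extend_hit(hits[0], genome, flank))
    return regions
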