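"""Multiple alignment of homologous regions and per-column conservation.

The built-in aligner is a deterministic center-star progressive alignment:
the center is the sequence with the highest summed pairwise k-mer similarity
(ties broken by input order), every other sequence is aligned to it globally,
and the pairwise alignments are merged under the usual once-a-gap-always-a-gap
rule. It exists so the pipeline is testable hermetically; externally computed
alignments (aligned FASTA or Clustal) are the production path for large jobs
and enter through :func:`load_msa`.

Conservation is the per-column majority-base fraction with gaps counted in
the denominator, so an indel anywhere across species penalises a column —
primer windows must be indel-free to anneal uniformly.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import AlignIO

from ._align import global_alignment
from .core_io import BITS_TO_IUPAC, IUPAC_BITS, FastaFormatError, SeqRecord

PROFILE_SYMBOLS = ("A", "C", "G", "T", "N", "-")


@dataclass
class Alignment:
    """Rows of equal-length gapped sequences."""

    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        lengths = {len(seq) for _, seq in self.rows}
        if len(lengths) > 1:
            raise FastaFormatError("ragged alignment: rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def degapped(self, row: int) -> str:
        return self.rows[row][1].replace("-", "")


@dataclass
class ConservationProfile:
    """Per-column symbol counts plus majority/gap summaries.

    ``counts`` has one row per column in :data:`PROFILE_SYMBOLS` order;
    majority ties are broken by base order A < C < G < T.
    """

    counts: np.ndarray  # (n_columns, 6) ints
    n_rows: int
    majority_base: list[str]
    majority_fraction: np.ndarray
    gap_fraction: np.ndarray

    def __len__(self) -> int:
        return self.counts.shape[0]


def _kmer_profile(seq: str, k: int = 6) -> Counter:
    return Counter(seq[i:i + k] for i in range(len(seq) - k + 1))


def _merge_center_alignments(center: str, others: list[tuple[int, str, str]],
                             ) -> list[str]:
    """Merge pairwise (center vs other) alignments into one master alignment.

    ``others`` holds (row_index, gapped_center, gapped_other). Returns gapped
    strings: element 0 is the center row, then one per entry in input order.
    """
    # inserts[c] = max gap run length before center position c (c == len ->
    # trailing inserts)
    n = len(center)
    inserts = [0] * (n + 1)
    parsed = []
    for _, g_center, g_other in others:
        runs = [0] * (n + 1)
        c = 0
        for ch in g_center:
            if ch == "-":
                runs[c] += 1
            else:
                c += 1
        for c in range(n + 1):
            inserts[c] = max(inserts[c], runs[c])
        parsed.append((runs, g_center, g_other))

    def expand(gapped_center: str, partner: str) -> str:
        out = []
        c = 0
        run = 0
        i = 0
        while i <= len(gapped_center):
            at_gap = i < len(gapped_center) and gapped_center[i] == "-"
            if at_gap:
                run += 1
                out.append(partner[i])
                i += 1
                continue
            out.append("-" * (inserts[c] - run))
            run = 0
            if i < len(gapped_center):
                out.append(partner[i])
                c += 1
            i += 1
        return "".join(out)

    master_center = expand(center, center)
    rows = [expand(g_center, g_other) for _, g_center, g_other in parsed]
    return [master_center] + rows


def build_msa(seqs: list[SeqRecord], match: int = 1, mismatch: int = -1,
              gap_open: int = -4, gap_extend: int = -1) -> Alignment:
    """Center-star progressive multiple alignment (deterministic)."""
    if len(seqs) < 2:
        raise ValueError("build_msa requires at least 2 sequences")
    profiles = [_kmer_profile(r.sequence) for r in seqs]
    sims = []
    for i, pi in enumerate(profiles):
        total = 0
        for j, pj in enumerate(profiles):
            if i != j:
                total += sum((pi & pj).values())
        sims.append(total)
    center_idx = int(np.argmax(sims))  # argmax takes the first on ties
    center = seqs[center_idx].sequence

    pairwise = []
    for i, rec in enumerate(seqs):
        if i == center_idx:
            continue
        _, g_c, g_o = global_alignment(center, rec.sequence, match, mismatch,
                                       gap_open, gap_extend)
        pairwise.append((i, g_c, g_o))
    merged = _merge_center_alignments(center, pairwise)

    gapped = [""] * len(seqs)
    gapped[center_idx] = merged[0]
    for (i, _, _), row in zip(pairwise, merged[1:]):
        gapped[i] = row
    return Alignment([(rec.id, row) for rec, row in zip(seqs, gapped)])


def load_msa(path: str | Path) -> Alignment:
    """Load an aligned FASTA or Clustal file (sniffed from the first line)."""
    with open(path) as fh:
        first = fh.readline()
    fmt = "clustal" if first.upper().startswith("CLUSTAL") else "fasta"
    try:
        aln = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise FastaFormatError(f"cannot parse alignment: {exc}") from exc
    rows = [(rec.id, str(rec.seq).upper().replace("U", "T"))
            for rec in aln]
    for rid, seq in rows:
        for ch in seq:
            if ch != "-" and ch not in IUPAC_BITS:
                raise FastaFormatError(
                    f"non-IUPAC character {ch!r} in alignment row {rid!r}")
    return Alignment(rows)


def conservation_profile(aln: Alignment) -> ConservationProfile:
    """Tally A/C/G/T/N/gap per column; degenerate codes count as N."""
    if aln.n_rows < 1:
        raise ValueError("alignment has no rows")
    n_cols = aln.n_columns
    counts = np.zeros((n_cols, 6), dtype=np.int64)
    idx = {sym: k for k, sym in enumerate(PROFILE_SYMBOLS)}
    for _, row in aln.rows:
        for c, ch in enumerate(row):
            counts[c, idx.get(ch, idx["N"])] += 1
    maj_idx = counts[:, :4].argmax(axis=1)  # ties -> lowest index: A<C<G<T
    majority_base = [PROFILE_SYMBOLS[k] for k in maj_idx]
    maj_counts = counts[np.arange(n_cols), maj_idx] if n_cols else np.zeros(0)
    return ConservationProfile(
        counts=counts,
        n_rows=aln.n_rows,
        majority_base=majority_base,
        majority_fraction=maj_counts / aln.n_rows,
        gap_fraction=counts[:, 5] / aln.n_rows,
    )


def consensus_sequence(profile: ConservationProfile, mode: str = "strict",
                       minor_threshold: float = 0.25,
                       columns: tuple[int, int] | None = None) -> str:
    """Consensus over the profile (or a column slice).

    strict: the majority base per column; columns where gaps hold the
    majority are omitted. iupac: the degenerate code covering every concrete
    base with frequency >= ``minor_threshold`` (falling back to the majority
    base when none reaches the threshold).
    """
    if mode not in ("strict", "iupac"):
        raise ValueError(f"unknown consensus mode {mode!r}")
    lo, hi = columns if columns is not None else (0, len(profile))
    out = []
    for c in range(lo, hi):
        gap_count = profile.counts[c, 5]
        maj_count = profile.counts[c, :4].max()
        if gap_count > maj_count:
            continue
        if mode == "strict":
            out.append(profile.majority_base[c])
        else:
            bits = 0
            for k, base in enumerate("ACGT"):
                if profile.counts[c, k] / profile.n_rows >= minor_threshold:
                    bits |= IUPAC_BITS[base]
            out.append(BITS_TO_IUPAC[bits] if bits else profile.majority_base[c])
    return "".join(out)


def write_profile_tsv(profile: ConservationProfile, path: str | Path) -> None:
    """Per-column logo data: counts, majority base and fractions."""
    with open(path, "w") as fh:
        fh.write("column\tA\tC\tG\tT\tN\tgap\tmajority\t"
                 "majority_fraction\tgap_fraction\n")
        for c in range(len(profile)):
            counts = "\t".join(str(int(v)) for v in profile.counts[c])
            fh.write(f"{c}\t{counts}\t{profile.majority_base[c]}\t"
                     f"{profile.majority_fraction[c]:.6g}\t"
                     f"{profile.gap_fraction[c]:.6g}\n")
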