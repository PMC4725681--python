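"""In-silico PCR: approximate primer-site search, amplicon prediction, and
reference amplicon sets.

A primer anneals wherever a semi-global alignment of the (possibly
degenerate) primer against the subject accumulates at most ``max_errors``
mismatches plus gaps; degenerate IUPAC letters match compatible bases at no
cost. Both strands are searched. Two error presets mirror the two scans the
pipeline performs: whole-genome scans allow 4 errors in total across the two
primers; nucleotide-database scans allow 2 errors per primer. Predicted
amplicons keep their primer-inclusive genomic interval but the reference
record stores only the inner sequence (both primer spans removed), which is
the unit compared against sequenced reads.

Site search is a two-stage exact procedure: a Sellers semi-global DP yields
the minimum error count for every possible site end; surviving ends (local
error minima among overlapping placements, ties to the leftmost) are then
re-aligned with edlib to recover the site start and the mismatch/gap split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import edlib

from ._align import semiglobal_end_distances
from .core_io import (IUPAC_BITS, SeqRecord, reverse_complement,
                      write_fasta, read_fasta)
from .primer_design import PrimerPair
from .taxonomy import Taxonomy, TaxonomyError

logger = logging.getLogger(__name__)

# unordered pairs of distinct IUPAC codes that share a concrete base
_EQUALITIES = [(a, b) for a, b in combinations(IUPAC_BITS, 2)
               if IUPAC_BITS[a] & IUPAC_BITS[b]]

MAIN_DIVISIONS = ("Plants", "Invertebrates", "Vertebrates")


@dataclass(frozen=True)
class ScanConfig:
    """Error budget and product-size bounds for a scan.

    ``error_mode`` "per_primer" caps each primer's errors independently
    (database preset, max 2); "total" caps the sum across both primers
    (genome preset, max 4).
    """

    error_mode: str = "per_primer"
    max_errors_per_primer: int = 2
    max_total_errors: int = 4
    size_min: int = 50
    size_max: int = 1000

    def __post_init__(self):
        if self.error_mode not in ("per_primer", "total"):
            raise ValueError(f"unknown error_mode {self.error_mode!r}")
        if self.size_min > self.size_max:
            raise ValueError("size_min > size_max")

    @property
    def per_primer_budget(self) -> int:
        return (self.max_errors_per_primer if self.error_mode == "per_primer"
                else self.max_total_errors)


GENOME_PRESET = ScanConfig(error_mode="total", max_total_errors=4)
DATABASE_PRESET = ScanConfig(error_mode="per_primer", max_errors_per_primer=2)


@dataclass
class PrimerSite:
    """An approximate annealing site on the forward strand of a subject."""

    subject_id: str
    interval: tuple[int, int]
    strand: str
    n_mismatches: int
    n_gaps: int

    @property
    def total_errors(self) -> int:
        return self.n_mismatches + self.n_gaps

    @property
    def start(self) -> int:
        return self.interval[0]

    @property
    def end(self) -> int:
        return self.interval[1]


@dataclass
class AmpliconPrediction:
    """A predicted PCR product (primer-inclusive interval, forward strand)."""

    subject_id: str
    interval: tuple[int, int]
    strand: str
    inner_sequence: str
    forward_site: PrimerSite
    reverse_site: PrimerSite

    @property
    def length_with_primers(self) -> int:
        return self.interval[1] - self.interval[0]

    @property
    def total_errors(self) -> int:
        return self.forward_site.total_errors + self.reverse_site.total_errors


def _site_details(primer: str, subject: str, end: int, max_errors: int,
                  ) -> tuple[int, int, int]:
    """Recover (start, n_mismatches, n_gaps) for a site ending at ``end``.

    Aligns the reversed primer against the reversed tail of the subject in
    edlib SHW (prefix semi-global) mode, so the alignment is anchored at the
    site end and free at its start.
    """
    m = len(primer)
    lo = max(0, end - m - max_errors)
    rev_window = subject[lo:end][::-1]
    res = edlib.align(primer[::-1], rev_window, mode="SHW", task="path",
                      k=max_errors, additionalEqualities=_EQUALITIES)
    if res["editDistance"] < 0:  # pragma: no cover - ends come from the DP
        raise AssertionError("edlib disagrees with DP site")
    matched = res["locations"][0][1] + 1
    start = end - matched
    n_gaps = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
        else:
            if ch in "ID":
                n_gaps += int(num)
            num = ""
    return start, res["editDistance"] - n_gaps, n_gaps


def find_primer_sites(primer: str, subject: SeqRecord,
                      max_errors: int = 2) -> list[PrimerSite]:
    """All annealing sites of the primer on both strands of the subject.

    Overlapping candidate placements (ends closer than the primer length)
    are collapsed to the one with fewest errors, ties to the leftmost.
    Minus-strand sites are reported on forward-strand coordinates with
    strand '-'. Sorted by start position.
    """
    if len(primer) < 10:
        raise ValueError("primer shorter than 10 bases")
    sites: list[PrimerSite] = []
    m = len(primer)
    for strand in "+-":
        p = primer if strand == "+" else reverse_complement(primer)
        dist = semiglobal_end_distances(p, subject.sequence)
        ends = [j for j in range(1, len(dist)) if dist[j] <= max_errors]
        # group overlapping placements; keep the local error minimum
        groups: list[list[int]] = []
        for j in ends:
            if groups and j - groups[-1][-1] < m:
                groups[-1].append(j)
            else:
                groups.append([j])
        for group in groups:
            best = min(group, key=lambda j: (dist[j], j))
            start, n_mm, n_gap = _site_details(p, subject.sequence, best,
                                               max_errors)
            sites.append(PrimerSite(subject.id, (start, best), strand,
                                    n_mm, n_gap))
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def predict_amplicons(pair: PrimerPair, subject: SeqRecord,
                      cfg: ScanConfig = DATABASE_PRESET,
                      ) -> list[AmpliconPrediction]:
    """Predict all PCR products of the pair on the subject.

    A plus-strand product pairs a forward-primer site on + with a
    reverse-primer site on − downstream; a minus-strand product is the
    mirror image. Inner sequences always read forward-primer-first.
    Deduplicated on the primer-inclusive interval; sorted by start.
    """
    budget = cfg.per_primer_budget
    f_sites = find_primer_sites(pair.forward, subject, budget)
    r_sites = find_primer_sites(pair.reverse, subject, budget)

    def ok(f: PrimerSite, r: PrimerSite) -> bool:
        if cfg.error_mode == "total":
            return f.total_errors + r.total_errors <= cfg.max_total_errors
        return (f.total_errors <= cfg.max_errors_per_primer
                and r.total_errors <= cfg.max_errors_per_primer)

    preds: list[AmpliconPrediction] = []
    seq = subject.sequence
    for f in (s for s in f_sites if s.strand == "+"):
        for r in (s for s in r_sites if s.strand == "-"):
            if r.start < f.end or not ok(f, r):
                continue
            length = r.end - f.start
            if cfg.size_min <= length <= cfg.size_max:
                preds.append(AmpliconPrediction(
                    subject.id, (f.start, r.end), "+",
                    seq[f.end:r.start], f, r))
    for r in (s for s in r_sites if s.strand == "+"):
        for f in (s for s in f_sites if s.strand == "-"):
            if f.start < r.end or not ok(f, r):
                continue
            length = f.end - r.start
            if cfg.size_min <= length <= cfg.size_max:
                preds.append(AmpliconPrediction(
                    subject.id, (r.start, f.end), "-",
                    reverse_complement(seq[r.end:f.start]), f, r))
    preds.sort(key=lambda a: (a.interval, a.strand))
    unique: list[AmpliconPrediction] = []
    seen: set[tuple] = set()
    for a in preds:
        key = (a.subject_id, a.interval)
        if key not in seen:
            seen.add(key)
            unique.append(a)
    return unique


@dataclass
class ReferenceRecord:
    """A primer-trimmed predicted amplicon labelled with its species."""

    inner_sequence: str
    species_taxid: int
    source: str
    source_id: str


class ReferenceSet:
    """Reference amplicons plus an inner-sequence -> species-set index."""

    def __init__(self, records: list[ReferenceRecord] | None = None):
        self.records: list[ReferenceRecord] = []
        self.index: dict[str, set[int]] = {}
        self._keys: set[tuple] = set()
        for rec in records or []:
            self.add(rec)

    def add(self, rec: ReferenceRecord) -> None:
        key = (rec.inner_sequence, rec.species_taxid, rec.source_id)
        if key in self._keys:
            return
        self._keys.add(key)
        self.records.append(rec)
        self.index.setdefault(rec.inner_sequence, set()).add(rec.species_taxid)

    def __len__(self) -> int:
        return len(self.records)

    def rebuild_index(self) -> dict[str, set[int]]:
        index: dict[str, set[int]] = {}
        for rec in self.records:
            index.setdefault(rec.inner_sequence, set()).add(rec.species_taxid)
        return index


def build_reference_set(pair: PrimerPair, records: list[SeqRecord],
                        cfg: ScanConfig = GENOME_PRESET,
                        source: str = "genome") -> ReferenceSet:
    """Predict amplicons across taxon-labelled records and collect their
    inner sequences as the reference set. Records without a species taxid
    are skipped with a warning."""
    refset = ReferenceSet()
    for rec in records:
        if rec.species_taxid is None:
            logger.warning("record %r lacks a species taxid; skipped", rec.id)
            continue
        for amp in predict_amplicons(pair, rec, cfg):
            start, end = amp.interval
            refset.add(ReferenceRecord(
                amp.inner_sequence, rec.species_taxid, source,
                f"{rec.id}:{start}-{end}"))
    return refset


def diagnostic_species_count(refset: ReferenceSet,
                             ) -> tuple[dict[int, int], int]:
    """Per-species count of diagnostic inner sequences (sequences seen in
    exactly one species), and the number of species owning at least one."""
    per_species: dict[int, int] = {}
    for inner, species in refset.index.items():
        if len(species) == 1:
            (taxid,) = species
            per_species[taxid] = per_species.get(taxid, 0) + 1
    return per_species, len(per_species)


def tally_divisions(refset: ReferenceSet, taxonomy: Taxonomy,
                    ) -> dict[str, int]:
    """Count species with >= 1 diagnostic sequence per taxonomy division."""
    per_species, _ = diagnostic_species_count(refset)
    tallies = {d: 0 for d in MAIN_DIVISIONS}
    tallies["other"] = 0
    for taxid in per_species:
        try:
            division = taxonomy.division_of(taxid)
        except TaxonomyError:
            logger.warning("taxid %d not in taxonomy; counted as other", taxid)
            division = ""
        if division not in MAIN_DIVISIONS:
            division = "other"
        tallies[division] += 1
    return tallies


def write_reference_fasta(refset: ReferenceSet, path: str | Path) -> None:
    records = []
    for n, rec in enumerate(refset.records):
        records.append(SeqRecord(f"{rec.source}:{rec.source_id}:{n}",
                                 rec.inner_sequence,
                                 species_taxid=rec.species_taxid))
    write_fasta(records, path)


def read_reference_fasta(path: str | Path) -> ReferenceSet:
    refset = ReferenceSet()
    for rec in read_fasta(path):
        if rec.species_taxid is None:
            logger.warning("reference %r lacks a taxid; skipped", rec.id)
            continue
        source, rest = rec.id.split(":", 1)
        source_id = rest.rsplit(":", 1)[0]
        refset.add(ReferenceRecord(rec.sequence, rec.species_taxid,
                                   source, source_id))
    return refset


def write_amplicon_tsv(preds: list[AmpliconPrediction],
                       path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("subject\tstart\tend\tstrand\tlength\terrors\n")
        for a in preds:
            fh.write(f"{a.subject_id}\t{a.interval[0]}\t{a.interval[1]}\t"
                     f"{a.strand}\t{a.length_with_primers}\t{a.total_errors}\n")
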