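"""Amplicon read assignment: MID demultiplexing, primer orientation and
trimming, exact full-length clustering against references, and cluster-level
taxonomic conclusions.

Reads arrive error-corrected with a fusion-primer structure
``MID + primer + inner + revcomp(other primer)``; sequencing is
bidirectional, so roughly half the reads start with the reverse primer and
are flipped before trimming. Assignment is deliberately strict: a read joins
a reference only when its trimmed inner sequence is identical, character for
character and in length (the cd-hit-est ``-c 1.0 -aL 1 -aS 1`` regime), so
reads with residual errors fall into reads-only clusters and are reported as
unassigned rather than misassigned. A cluster whose references span several
species is concluded at the lowest common ancestor of those species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import edlib

from .core_io import SeqRecord, reverse_complement
from .insilico_pcr import _EQUALITIES, ReferenceRecord, ReferenceSet
from .primer_design import PrimerPair
from .taxonomy import Taxonomy, lowest_common_ancestor

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    pass


@dataclass
class MidScheme:
    """Sample label -> (forward MID, reverse MID), all of one length."""

    samples: dict[str, tuple[str, str]]

    def __post_init__(self) -> None:
        lengths = {len(m) for pair in self.samples.values() for m in pair}
        if len(lengths) > 1:
            raise ConfigurationError("MIDs must share one length")
        owner: dict[str, str] = {}
        for label, pair in self.samples.items():
            for mid in pair:
                if owner.get(mid, label) != label:
                    raise ConfigurationError(
                        f"MID {mid} appears in samples {owner[mid]!r} "
                        f"and {label!r}")
                owner[mid] = label
        mids = sorted(owner)
        for i, a in enumerate(mids):
            for b in mids[i + 1:]:
                if sum(x != y for x, y in zip(a, b)) < 2:
                    raise ConfigurationError(
                        f"MIDs {a} and {b} differ at fewer than 2 positions")

    @property
    def mid_length(self) -> int:
        return len(next(iter(self.samples.values()))[0])

    def mid_owner(self) -> dict[str, str]:
        return {mid: label for label, pair in self.samples.items()
                for mid in pair}


def load_mid_scheme(path) -> MidScheme:
    """TSV: sample <tab> forward_mid <tab> reverse_mid (header optional)."""
    samples: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0].lower() == "sample":  # header row
                continue
            if len(fields) == 2:
                samples[fields[0]] = (fields[1].upper(), fields[1].upper())
            else:
                samples[fields[0]] = (fields[1].upper(), fields[2].upper())
    return MidScheme(samples)


def demultiplex(reads: list[SeqRecord], scheme: MidScheme,
                max_mid_mismatches: int = 0,
                ) -> tuple[dict[str, list[SeqRecord]], list[SeqRecord]]:
    """Route each read by its 5' MID prefix; strip the MID from routed reads.

    A read goes to the unique sample owning a MID within the mismatch budget
    of its prefix; ambiguous or unmatched reads land in the unassigned bin.
    """
    owner = scheme.mid_owner()
    length = scheme.mid_length
    bins: dict[str, list[SeqRecord]] = {label: [] for label in scheme.samples}
    unassigned: list[SeqRecord] = []
    for read in reads:
        prefix = read.sequence[:length]
        labels = set()
        if len(prefix) == length:
            for mid, label in owner.items():
                if sum(a != b for a, b in zip(prefix, mid)) <= max_mid_mismatches:
                    labels.add(label)
        if len(labels) == 1:
            label = labels.pop()
            bins[label].append(SeqRecord(read.id, read.sequence[length:],
                                         read.description, read.species_taxid))
        else:
            unassigned.append(read)
    return bins, unassigned


@dataclass
class TrimmedRead:
    id: str
    inner: str
    orientation: str  # '+' read began with the forward primer, '-' reverse


def _prefix_end(primer: str, seq: str, k: int) -> int | None:
    """End of the best <=k-error match of the primer against a 5' prefix.

    Among equally good end positions (e.g. a substitution at the primer's
    last base can be explained as a mismatch or a deletion) the longest
    span is cut, so no primer base leaks into the inner sequence.
    """
    if not seq:
        return None
    res = edlib.align(primer, seq, mode="SHW", task="locations", k=k,
                      additionalEqualities=_EQUALITIES)
    if res["editDistance"] < 0:
        return None
    return max(loc[1] for loc in res["locations"]) + 1


def _suffix_start(primer_rc: str, seq: str, k: int) -> int | None:
    """Start of the best <=k-error match of primer_rc against a 3' suffix
    (ties resolved to the longest primer span, as for the 5' cut)."""
    if not seq:
        return None
    res = edlib.align(primer_rc[::-1], seq[::-1], mode="SHW",
                      task="locations", k=k,
                      additionalEqualities=_EQUALITIES)
    if res["editDistance"] < 0:
        return None
    return len(seq) - (max(loc[1] for loc in res["locations"]) + 1)


def orient_and_trim(reads: list[SeqRecord], pair: PrimerPair,
                    max_trim_errors: int = 2,
                    ) -> tuple[list[TrimmedRead], list[SeqRecord]]:
    """Orient each read by its 5' primer and strip both primer spans.

    Reads beginning with the forward primer keep their orientation; reads
    beginning with the reverse primer are flipped (their inner is
    reverse-complemented). The 3' primer is trimmed best-effort: its absence
    does not reject the read. Reads starting with neither primer within the
    error budget are rejected.
    """
    trimmed: list[TrimmedRead] = []
    rejected: list[SeqRecord] = []
    for read in reads:
        seq = read.sequence
        end_f = _prefix_end(pair.forward, seq, max_trim_errors)
        if end_f is not None:
            middle = seq[end_f:]
            cut = _suffix_start(reverse_complement(pair.reverse), middle,
                                max_trim_errors)
            inner = middle[:cut] if cut is not None else middle
            trimmed.append(TrimmedRead(read.id, inner, "+"))
            continue
        end_r = _prefix_end(pair.reverse, seq, max_trim_errors)
        if end_r is not None:
            middle = seq[end_r:]
            cut = _suffix_start(reverse_complement(pair.forward), middle,
                                max_trim_errors)
            middle = middle[:cut] if cut is not None else middle
            trimmed.append(TrimmedRead(read.id, reverse_complement(middle), "-"))
            continue
        rejected.append(read)
    return trimmed, rejected


@dataclass
class Cluster:
    """An equivalence class of full-length-identical sequences."""

    representative: str
    read_ids: list[str] = field(default_factory=list)
    reference_records: list[ReferenceRecord] = field(default_factory=list)
    conclusion: int | None = None

    @property
    def n_reads(self) -> int:
        return len(self.read_ids)

    @property
    def n_refs(self) -> int:
        return len(self.reference_records)

    @property
    def category(self) -> str:
        if self.n_reads and self.n_refs:
            return "mixed"
        return "reads_only" if self.n_reads else "refs_only"

    @property
    def species(self) -> set[int]:
        return {r.species_taxid for r in self.reference_records}


def cluster_exact(inner_reads: list[TrimmedRead],
                  refset: ReferenceSet) -> list[Cluster]:
    """Group reads and references by exact full-length sequence identity."""
    clusters: dict[str, Cluster] = {}
    for read in inner_reads:
        clusters.setdefault(read.inner, Cluster(read.inner)).read_ids.append(
            read.id)
    for ref in refset.records:
        clusters.setdefault(ref.inner_sequence,
                            Cluster(ref.inner_sequence)
                            ).reference_records.append(ref)
    return list(clusters.values())


@dataclass
class ClusterReport:
    """Ranked mixed clusters plus the unranked bins and stage totals.

    ``table`` holds mixed clusters ordered by descending read count (ties by
    representative sequence); reference-only clusters are excluded from the
    ranked table but counted in the totals. Totals conserve counts:
    assigned + unassigned == trimmed.
    """

    table: list[Cluster]
    reads_only: list[Cluster]
    refs_only: list[Cluster]
    totals: dict[str, int]


def conclude_clusters(clusters: list[Cluster],
                      taxonomy: Taxonomy) -> ClusterReport:
    """Attach taxonomic conclusions and build the ranked report.

    A mixed cluster with references from one species concludes at that
    species; with several, at their lowest common ancestor. Reads-only
    clusters have no conclusion and their reads count as unassigned.
    """
    mixed, reads_only, refs_only = [], [], []
    for cluster in clusters:
        if cluster.category == "mixed":
            cluster.conclusion = lowest_common_ancestor(taxonomy,
                                                        cluster.species)
            mixed.append(cluster)
        elif cluster.category == "reads_only":
            cluster.conclusion = None
            reads_only.append(cluster)
        else:
            refs_only.append(cluster)
    mixed.sort(key=lambda c: (-c.n_reads, c.representative))
    reads_only.sort(key=lambda c: (-c.n_reads, c.representative))
    assigned = sum(c.n_reads for c in mixed)
    unassigned = sum(c.n_reads for c in reads_only)
    totals = {
        "trimmed": assigned + unassigned,
        "assigned": assigned,
        "unassigned": unassigned,
        "n_mixed_clusters": len(mixed),
        "n_reads_only_clusters": len(reads_only),
        "n_refs_only_clusters": len(refs_only),
    }
    return ClusterReport(mixed, reads_only, refs_only, totals)


def taxonomy_summary(report: ClusterReport, taxonomy: Taxonomy,
                     ) -> dict[int, tuple[int, int]]:
    """Per-conclusion-taxon (n_clusters, n_reads) over the ranked table."""
    summary: dict[int, tuple[int, int]] = {}
    for cluster in report.table:
        n_c, n_r = summary.get(cluster.conclusion, (0, 0))
        summary[cluster.conclusion] = (n_c + 1, n_r + cluster.n_reads)
    return summary


def lineage_summary(report: ClusterReport, taxonomy: Taxonomy,
                    ) -> dict[int, tuple[int, int]]:
    """Cumulative (n_clusters, n_reads) at every node along the lineages of
    the concluded taxa — the numbers drawn beside a taxonomy line plot."""
    cumulative: dict[int, tuple[int, int]] = {}
    for taxid, (n_c, n_r) in taxonomy_summary(report, taxonomy).items():
        for node in taxonomy.lineage(taxid):
            c, r = cumulative.get(node, (0, 0))
            cumulative[node] = (c + n_c, r + n_r)
    return cumulative


def write_report_tsv(report: ClusterReport, taxonomy: Taxonomy, path) -> None:
    """Ranked-cluster table (cluster, reads, refs, species, conclusion) plus
    a totals block as trailing comment lines."""
    with open(path, "w") as fh:
        fh.write("cluster\tn_ngs_reads\tn_reference_reads\t"
                 "reference_species\tconclusion\treference_ids\n")
        for i, c in enumerate(report.table, start=1):
            names = sorted(taxonomy.name_of(t) for t in c.species)
            conclusion = taxonomy.name_of(c.conclusion)
            ids = ",".join(r.source_id for r in c.reference_records)
            fh.write(f"{i}\t{c.n_reads}\t{c.n_refs}\t{', '.join(names)}\t"
                     f"{conclusion}\t{ids}\n")
        for key, value in report.totals.items():
            fh.write(f"#{key}\t{value}\n")


def assign_reads(reads: list[SeqRecord], pair: PrimerPair,
                 refset: ReferenceSet, taxonomy: Taxonomy,
                 scheme: MidScheme | None = None, sample: str | None = None,
                 max_mid_mismatches: int = 0, max_trim_errors: int = 2,
                 ) -> ClusterReport:
    """Full read-assignment chain for one sample.

    With a MID scheme the reads are demultiplexed first and ``sample``
    selects the bin (default: the only sample in the scheme).
    """
    totals = {"reads_in": len(reads)}
    if scheme is not None:
        bins, unrouted = demultiplex(reads, scheme, max_mid_mismatches)
        if sample is None:
            if len(scheme.samples) != 1:
                raise ValueError("sample label required with a multi-sample "
                                 "MID scheme")
            sample = next(iter(scheme.samples))
        reads = bins[sample]
        totals["demux_assigned"] = sum(len(b) for b in bins.values())
    trimmed, rejected = orient_and_trim(reads, pair, max_trim_errors)
    report = conclude_clusters(cluster_exact(trimmed, refset), taxonomy)
    totals["rejected_at_trim"] = len(rejected)
    report.totals = {**totals, **report.totals}
    return report
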