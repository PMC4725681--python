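"""Hermetic ground-truth fixtures for every pipeline stage.

The generator emulates the study system: plant-style genomes carrying a
multi-copy conserved locus (two fixed 20-mer primer sites around a variable
inner region, 194 bp primer-inclusive by default, mirroring the tested
barcode locus), a ranked taxonomy with divisions, and error-bearing amplicon
reads with fusion-primer + MID prefixes drawn from DNA mixtures at known
weight ratios. Everything emitted is recorded in a ledger so tests can check
pipeline output against construction truth.

Read sampling follows template availability: a species contributes reads
with probability proportional to ``weight / C`` (copies per unit mass),
spread uniformly across its locus copies; half the reads are sequenced from
the opposite direction. The error model is substitution-only by default —
homopolymer indels of the original instrument are omitted because full-length
exact clustering turns any indel read into an unassigned read by design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core_io import SeqRecord, reverse_complement, write_fasta
from .primer_design import PrimerPair
from .quantification import CValueTable
from .read_assignment import MidScheme
from .taxonomy import TaxNode, Taxonomy, write_lineage_tsv

BASES = np.array(list("ACGT"))

# the printed barcode primers; the generator's default locus architecture
DEFAULT_FORWARD = "TCCTTCTGGATGTTGTAGTC"
DEFAULT_REVERSE = "AAGATGCAGATCTTCGTGAA"
MID1 = "ACGAGTGCGT"
MID2 = "ACGCTCGACA"


@dataclass
class LocusModel:
    """Architecture of the planted conserved locus."""

    forward: str = DEFAULT_FORWARD
    reverse: str = DEFAULT_REVERSE
    inner_length: int = 154
    inner_divergence: float = 0.05
    copies: int = 1
    copy_divergence: float = 0.0

    @property
    def implied_amplicon(self) -> int:
        return len(self.forward) + self.inner_length + len(self.reverse)


@dataclass
class LocusEntry:
    genome_id: str
    species_taxid: int
    copy_index: int
    start: int
    end: int
    strand: str
    inner: str


@dataclass
class ReadEntry:
    read_id: str
    species_taxid: int
    genome_id: str
    copy_index: int
    orientation: str
    mid: str
    n_errors: int


@dataclass
class SimulationLedger:
    loci: list[LocusEntry] = field(default_factory=list)
    reads: list[ReadEntry] = field(default_factory=list)
    mixture: dict[int, float] = field(default_factory=dict)

    def loci_of(self, taxid: int) -> list[LocusEntry]:
        return [e for e in self.loci if e.species_taxid == taxid]

    def write_loci_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("genome\ttaxid\tcopy\tstart\tend\tstrand\tinner\n")
            for e in self.loci:
                fh.write(f"{e.genome_id}\t{e.species_taxid}\t{e.copy_index}\t"
                         f"{e.start}\t{e.end}\t{e.strand}\t{e.inner}\n")

    def write_reads_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("read\ttaxid\tgenome\tcopy\torientation\tmid\tn_errors\n")
            for e in self.reads:
                fh.write(f"{e.read_id}\t{e.species_taxid}\t{e.genome_id}\t"
                         f"{e.copy_index}\t{e.orientation}\t{e.mid}\t"
                         f"{e.n_errors}\n")


def poaceae_fixture() -> Taxonomy:
    """Fixed taxonomy encoding the standard lineages of the study species:
    grasses (Zea mays, Oryza sativa, Triticum aestivum, Panicum virgatum),
    soybean, strawberry, thale cress, plus a vertebrate and an invertebrate
    out-group for division tallies."""
    rows = [
        # taxid, parent, rank, name, division
        (1, 1, "no rank", "root", ""),
        (33090, 1, "kingdom", "Viridiplantae", "Plants"),
        (35493, 33090, "phylum", "Streptophyta", ""),
        (3398, 35493, "class", "Magnoliopsida", ""),
        (4479, 3398, "family", "Poaceae", ""),
        (4575, 4479, "genus", "Zea", ""),
        (4577, 4575, "species", "Zea mays", ""),
        (4527, 4479, "genus", "Oryza", ""),
        (4530, 4527, "species", "Oryza sativa", ""),
        (4564, 4479, "genus", "Triticum", ""),
        (4565, 4564, "species", "Triticum aestivum", ""),
        (4539, 4479, "genus", "Panicum", ""),
        (38727, 4539, "species", "Panicum virgatum", ""),
        (3803, 3398, "family", "Fabaceae", ""),
        (3846, 3803, "genus", "Glycine", ""),
        (3847, 3846, "species", "Glycine max", ""),
        (3745, 3398, "family", "Rosaceae", ""),
        (3746, 3745, "genus", "Fragaria", ""),
        (3747, 3746, "species", "Fragaria x ananassa", ""),
        (3699, 3398, "family", "Brassicaceae", ""),
        (3701, 3699, "genus", "Arabidopsis", ""),
        (3702, 3701, "species", "Arabidopsis thaliana", ""),
        (33208, 1, "kingdom", "Metazoa", ""),
        (7711, 33208, "phylum", "Chordata", "Vertebrates"),
        (9605, 7711, "genus", "Homo", ""),
        (9606, 9605, "species", "Homo sapiens", ""),
        (6656, 33208, "phylum", "Arthropoda", "Invertebrates"),
        (7215, 6656, "genus", "Drosophila", ""),
        (7227, 7215, "species", "Drosophila melanogaster", ""),
    ]
    return Taxonomy({t: TaxNode(t, p, r, n, d) for t, p, r, n, d in rows})


RANKS = ("kingdom", "phylum", "class", "family", "genus", "species")


def simulate_taxonomy(seed: int, n_species: int,
                      divisions: tuple[str, ...] = ("Plants",),
                      ) -> tuple[Taxonomy, list[int]]:
    """Random ranked taxonomy with the requested number of species leaves.

    Species are attached to random genera, genera to random families, and
    each division gets one kingdom node under the root. Deterministic per
    seed; leaf taxids are returned in creation order.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    rng = np.random.default_rng(seed)
    nodes: dict[int, TaxNode] = {1: TaxNode(1, 1, "no rank", "root", "")}
    next_id = 10
    kingdoms = []
    for division in divisions:
        nodes[next_id] = TaxNode(next_id, 1, "kingdom",
                                 f"kingdom_{division}", division)
        kingdoms.append(next_id)
        next_id += 1
    n_genera = max(1, n_species // 2)
    n_families = max(1, n_genera // 2)
    families = []
    for i in range(n_families):
        parent = kingdoms[int(rng.integers(len(kingdoms)))]
        nodes[next_id] = TaxNode(next_id, parent, "family", f"family_{i}", "")
        families.append(next_id)
        next_id += 1
    genera = []
    for i in range(n_genera):
        parent = families[int(rng.integers(len(families)))]
        nodes[next_id] = TaxNode(next_id, parent, "genus", f"genus_{i}", "")
        genera.append(next_id)
        next_id += 1
    leaves = []
    for i in range(n_species):
        parent = genera[int(rng.integers(len(genera)))]
        nodes[next_id] = TaxNode(next_id, parent, "species", f"species_{i}", "")
        leaves.append(next_id)
        next_id += 1
    return Taxonomy(nodes), leaves


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute each position with probability ``rate`` (always to a
    different base)."""
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return "".join(arr)


def simulate_genomes(leaf_taxids: list[int], locus: LocusModel,
                     genome_length: int = 10_000, seed: int = 0,
                     minus_strand_fraction: float = 0.0,
                     ) -> tuple[list[SeqRecord], SimulationLedger]:
    """Random background genomes with non-overlapping planted locus copies.

    Each species gets one genome. A shared ancestral inner sequence is
    mutated per species at ``inner_divergence``, then per copy at
    ``copy_divergence``; primer sites are planted exactly. Raises when the
    copies cannot be packed into the genome.
    """
    rng = np.random.default_rng(seed)
    cassette_len = locus.implied_amplicon
    if genome_length <= locus.copies * cassette_len:
        raise ValueError("genome_length too small for the requested copies")
    ancestral_inner = _random_dna(rng, locus.inner_length)
    genomes: list[SeqRecord] = []
    ledger = SimulationLedger()
    for taxid in leaf_taxids:
        species_inner = _mutate(rng, ancestral_inner, locus.inner_divergence)
        background = _random_dna(rng, genome_length)
        # place copies by spacing starts at least one cassette apart
        free = genome_length - locus.copies * cassette_len
        offsets = np.sort(rng.integers(0, free + 1, size=locus.copies))
        genome_id = f"g{taxid}"
        pieces = []
        cursor = 0
        for k in range(locus.copies):
            start = int(offsets[k]) + k * cassette_len
            inner = _mutate(rng, species_inner, locus.copy_divergence)
            cassette = (locus.forward + inner
                        + reverse_complement(locus.reverse))
            strand = "+"
            if rng.random() < minus_strand_fraction:
                strand = "-"
                cassette = reverse_complement(cassette)
            pieces.append(background[cursor:start])
            pieces.append(cassette)
            cursor = start + cassette_len
            ledger.loci.append(LocusEntry(genome_id, taxid, k, start,
                                          start + cassette_len, strand, inner))
        pieces.append(background[cursor:])
        genomes.append(SeqRecord(genome_id, "".join(pieces),
                                 species_taxid=taxid))
    return genomes, ledger


def simulate_reads(mixture: dict[int, float], cvalues: CValueTable,
                   ledger: SimulationLedger, pair: PrimerPair,
                   mids: MidScheme, n_reads: int, error_rate: float = 0.002,
                   seed: int = 0, sample: str | None = None,
                   ) -> tuple[list[SeqRecord], SimulationLedger]:
    """Amplicon reads from a DNA mixture specified by weight fractions.

    Reads are ``MID + primer + inner + revcomp(other primer)``; half are
    built from the opposite sequencing direction (reverse primer first).
    Substitution errors hit every position independently at ``error_rate``.
    The returned ledger shares locus entries with the input ledger and
    records the provenance of every read.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    if abs(sum(mixture.values()) - 1.0) > 1e-9:
        raise ValueError("mixture weights must sum to 1")
    for taxid in mixture:
        if not ledger.loci_of(taxid):
            raise ValueError(f"species taxid {taxid} absent from the ledger")
    rng = np.random.default_rng(seed)
    if sample is None:
        sample = next(iter(mids.samples))
    mid_f, mid_r = mids.samples[sample]

    species = list(mixture)
    template = np.array([mixture[t] / cvalues[t] for t in species])
    template /= template.sum()
    loci_by_species = {t: ledger.loci_of(t) for t in species}

    out_ledger = SimulationLedger(loci=ledger.loci, mixture=dict(mixture))
    reads: list[SeqRecord] = []
    picks = rng.choice(len(species), size=n_reads, p=template)
    flips = rng.random(n_reads) < 0.5
    for i in range(n_reads):
        taxid = species[int(picks[i])]
        loci = loci_by_species[taxid]
        entry = loci[int(rng.integers(len(loci)))]
        if flips[i]:
            orientation = "-"
            mid = mid_r
            body = (pair.reverse + reverse_complement(entry.inner)
                    + reverse_complement(pair.forward))
        else:
            orientation = "+"
            mid = mid_f
            body = pair.forward + entry.inner + reverse_complement(pair.reverse)
        seq = mid + body
        mutated = _mutate(rng, seq, error_rate)
        n_errors = sum(a != b for a, b in zip(seq, mutated))
        read_id = f"read{i}"
        reads.append(SeqRecord(read_id, mutated))
        out_ledger.reads.append(ReadEntry(read_id, taxid, entry.genome_id,
                                          entry.copy_index, orientation, mid,
                                          n_errors))
    return reads, out_ledger


def default_mid_scheme(sample: str = "sample1") -> MidScheme:
    """One-sample scheme using the two published 10-base MIDs."""
    return MidScheme({sample: (MID1, MID2)})


@dataclass
class Scenario:
    """Everything a pipeline run needs, with ground truth attached."""

    taxonomy: Taxonomy
    genomes: list[SeqRecord]
    pair: PrimerPair
    mids: MidScheme
    cvalues: CValueTable
    mixture: dict[int, float]
    reads: list[SeqRecord]
    ledger: SimulationLedger


def build_scenario(scenario: str, seed: int, n_reads: int = 2000,
                   error_rate: float = 0.002,
                   mixture: dict[int, float] | None = None,
                   copies: int = 3) -> Scenario:
    """Canned two-species (maize + soybean) study scenarios.

    "pure": all reads from maize. "mixture": reads drawn from a 25:75
    maize:soy weight mixture unless ``mixture`` overrides it. C values are
    the published ones (maize 2.73 pg, soy 1.13 pg); both genomes carry the
    same locus copy number so marker read counts track template input.
    """
    maize, soy = 4577, 3847
    tax = poaceae_fixture()
    locus = LocusModel(copies=copies, inner_divergence=0.05,
                       copy_divergence=0.02)
    genomes, ledger = simulate_genomes([maize, soy], locus,
                                       genome_length=10_000, seed=seed)
    pair = PrimerPair("23579-aaa", locus.forward, locus.reverse)
    mids = default_mid_scheme()
    cvalues = CValueTable({maize: 2.73, soy: 1.13})
    if scenario == "pure":
        weights = {maize: 1.0}
    elif scenario == "mixture":
        weights = mixture or {maize: 0.25, soy: 0.75}
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    reads, ledger = simulate_reads(weights, cvalues, ledger, pair, mids,
                                   n_reads, error_rate, seed=seed + 1)
    return Scenario(tax, genomes, pair, mids, cvalues, weights, reads, ledger)


def write_scenario(sc: Scenario, out_dir: str | Path) -> dict[str, Path]:
    """Emit a scenario as plain-text files; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genomes": out / "genomes.fasta",
        "reads": out / "reads.fasta",
        "taxonomy": out / "lineage.tsv",
        "cvalues": out / "cvalues.tsv",
        "mids": out / "mids.tsv",
        "pair": out / "primer_pair.tsv",
        "loci": out / "ledger_loci.tsv",
        "read_ledger": out / "ledger_reads.tsv",
    }
    write_fasta(sc.genomes, paths["genomes"])
    write_fasta(sc.reads, paths["reads"])
    write_lineage_tsv(sc.taxonomy, paths["taxonomy"])
    with open(paths["cvalues"], "w") as fh:
        fh.write("taxid\tname\tpg\n")
        for taxid, pg in sc.cvalues.values.items():
            fh.write(f"{taxid}\t{sc.taxonomy.name_of(taxid)}\t{pg}\n")
    with open(paths["mids"], "w") as fh:
        fh.write("sample\tforward_mid\treverse_mid\n")
        for label, (f, r) in sc.mids.samples.items():
            fh.write(f"{label}\t{f}\t{r}\n")
    with open(paths["pair"], "w") as fh:
        fh.write("name\tforward\treverse\tamplicon_min\tamplicon_max\t"
                 "upstream_start\tdownstream_start\n")
        fh.write(f"{sc.pair.name}\t{sc.pair.forward}\t{sc.pair.reverse}\t"
                 f"{sc.pair.amplicon_min}\t{sc.pair.amplicon_max}\t\t\n")
    sc.ledger.write_loci_tsv(paths["loci"])
    sc.ledger.write_reads_tsv(paths["read_ledger"])
    return paths
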