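"""Genome-size-corrected relative quantification of species mixtures.

Read counts are not directly comparable between species: locus copy number,
reference specificity and per-locus PCR efficiency all differ. The pipeline
therefore picks, from each species' pure-sample run, one marker reference —
the single-reference cluster with the most reads, taken as the locus closest
to optimal amplification — and, in a mixture, compares only the reads
clustering to those markers. Because a read count is proportional to
template copy number while a DNA mixture is specified by mass, each species'
raw count is multiplied by its 1C genome mass (the C-value, in pg) to move
back to the mass scale before forming percentages. Percentages are rounded
half-up to one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

from .read_assignment import ClusterReport


class QuantificationError(ValueError):
    pass


@dataclass
class CValueTable:
    """Species taxid -> 1C genome mass in picograms (strictly positive)."""

    values: dict[int, float]

    def __post_init__(self) -> None:
        for taxid, pg in self.values.items():
            if pg <= 0:
                raise QuantificationError(
                    f"C value for taxid {taxid} must be positive, got {pg}")

    def __getitem__(self, taxid: int) -> float:
        return self.values[taxid]

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.values


def load_cvalues(path: str | Path) -> CValueTable:
    """TSV: taxid <tab> name <tab> 1C_pg (header optional)."""
    values: dict[int, float] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#") or line.lower().startswith("taxid"):
                continue
            fields = line.split("\t")
            values[int(fields[0])] = float(fields[-1])
    return CValueTable(values)


@dataclass
class QuantRow:
    species_taxid: int
    marker_id: str
    raw_reads: int
    corrected: float
    percent: float


@dataclass
class QuantResult:
    rows: list[QuantRow]

    def percent_of(self, taxid: int) -> float:
        for row in self.rows:
            if row.species_taxid == taxid:
                return row.percent
        raise KeyError(taxid)

    def corrected_of(self, taxid: int) -> float:
        for row in self.rows:
            if row.species_taxid == taxid:
                return row.corrected
        raise KeyError(taxid)


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal rounding with ties away from zero (1.25 -> 1.3 at 1 dp)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def select_marker_reference(pure_report: ClusterReport, species: int) -> str:
    """The source_id of the marker locus for a species.

    Among ranked clusters whose reference set is exactly one record of the
    given species, pick the one with the most reads (ties resolve to the
    first in report order, which is already deterministic).
    """
    for cluster in pure_report.table:
        if cluster.n_refs == 1 and cluster.species == {species}:
            return cluster.reference_records[0].source_id
    raise QuantificationError(
        f"no species-specific marker cluster for taxid {species}")


def quantify_mixture(mix_report: ClusterReport, markers: dict[int, str],
                     cvalues: CValueTable) -> QuantResult:
    """C-value-corrected percentages from marker-cluster read counts.

    ``markers`` maps species taxid -> marker reference source_id (from
    :func:`select_marker_reference` on the pure samples). A species whose
    marker cluster is absent from the mixture report contributes 0 reads.
    """
    raw: dict[int, int] = {}
    for species, marker_id in markers.items():
        if species not in cvalues:
            raise QuantificationError(
                f"species taxid {species} missing from the C-value table")
        raw[species] = 0
        for cluster in mix_report.table:
            if any(r.source_id == marker_id for r in cluster.reference_records):
                raw[species] = cluster.n_reads
                break
    corrected = {s: raw[s] * cvalues[s] for s in markers}
    total = sum(corrected.values())
    rows = []
    for species, marker_id in markers.items():
        percent = (round_half_up(100.0 * corrected[species] / total)
                   if total > 0 else 0.0)
        rows.append(QuantRow(species, marker_id, raw[species],
                             round_half_up(corrected[species], 2), percent))
    return QuantResult(rows)


def quantify_counts(raw: dict[int, int], cvalues: CValueTable) -> QuantResult:
    """Quantification directly from raw marker read counts (no report)."""
    for species in raw:
        if species not in cvalues:
            raise QuantificationError(
                f"species taxid {species} missing from the C-value table")
    corrected = {s: n * cvalues[s] for s, n in raw.items()}
    total = sum(corrected.values())
    rows = [QuantRow(s, "", raw[s], round_half_up(corrected[s], 2),
                     round_half_up(100.0 * corrected[s] / total)
                     if total > 0 else 0.0)
            for s in raw]
    return QuantResult(rows)


def write_quant_tsv(result: QuantResult, path: str | Path,
                    names: dict[int, str] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("species\tmarker\traw_reads\tcorrected\tpercent\n")
        for row in result.rows:
            label = (names or {}).get(row.species_taxid, str(row.species_taxid))
            fh.write(f"{label}\t{row.marker_id}\t{row.raw_reads}\t"
                     f"{row.corrected}\t{row.percent}\n")
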