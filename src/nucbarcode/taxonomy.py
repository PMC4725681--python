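"""Rooted taxonomy: loading, lowest common ancestor, division lookup.

Two on-disk dialects are accepted and produce identical structures on
equivalent content: NCBI-taxdump-style ``nodes.dmp``/``names.dmp`` files
('|'-delimited, optionally with a ``division.dmp`` mapping numeric division
ids to names), and a simplified 5-column lineage TSV
``taxid <tab> parent <tab> rank <tab> name <tab> division`` with a header
line. The root is the single node that is its own parent.

The LCA — the deepest node ancestral-or-equal to every member of a taxid
set, i.e. the most specific taxon common to all of them — is what turns a
multi-species cluster into its taxonomic conclusion. Divisions (Plants,
Vertebrates, Invertebrates, ...) are inherited from the nearest ancestor
carrying one when a node's own division is empty.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path


class TaxonomyError(ValueError):
    """Structural problem in a taxonomy file (cycle, orphan, missing root)."""


@dataclass
class TaxNode:
    taxid: int
    parent: int
    rank: str
    name: str
    division: str = ""


class Taxonomy:
    """Immutable rooted tree of taxa keyed by integer taxid."""

    def __init__(self, nodes: dict[int, TaxNode]):
        self.nodes = nodes
        roots = [t for t, n in nodes.items() if n.parent == t]
        if len(roots) != 1:
            raise TaxonomyError(f"expected exactly one root, found {roots}")
        self.root = roots[0]
        self._depth: dict[int, int] = {}
        for taxid, node in nodes.items():
            if node.parent not in nodes:
                raise TaxonomyError(
                    f"node {taxid} has missing parent {node.parent}")
        for taxid in nodes:
            self._depth[taxid] = len(self.lineage(taxid)) - 1

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def _require(self, taxid: int) -> TaxNode:
        try:
            return self.nodes[taxid]
        except KeyError:
            raise TaxonomyError(f"unknown taxid {taxid}") from None

    def name_of(self, taxid: int) -> str:
        return self._require(taxid).name

    def rank_of(self, taxid: int) -> str:
        return self._require(taxid).rank

    def taxid_of(self, name: str) -> int:
        for taxid, node in self.nodes.items():
            if node.name == name:
                return taxid
        raise TaxonomyError(f"unknown taxon name {name!r}")

    def lineage(self, taxid: int) -> list[int]:
        """Taxids from the root down to (and including) ``taxid``."""
        self._require(taxid)
        path = []
        seen = set()
        cur = taxid
        while True:
            if cur in seen:
                raise TaxonomyError(f"cycle in taxonomy at taxid {cur}")
            seen.add(cur)
            path.append(cur)
            parent = self._require(cur).parent
            if parent == cur:
                break
            cur = parent
        return path[::-1]

    def depth(self, taxid: int) -> int:
        return self._depth[taxid]

    def division_of(self, taxid: int) -> str:
        """The node's division, inherited from the nearest labelled ancestor
        when its own is empty; "" if no ancestor carries one."""
        for tid in reversed(self.lineage(taxid)):
            division = self.nodes[tid].division
            if division:
                return division
        return ""

    def leaves(self) -> list[int]:
        parents = {n.parent for t, n in self.nodes.items() if n.parent != t}
        return sorted(t for t in self.nodes if t not in parents)


def lowest_common_ancestor(tax: Taxonomy, taxids) -> int:
    """Deepest node that is an ancestor-or-self of every input taxid."""
    taxids = list(taxids)
    if not taxids:
        raise ValueError("empty taxid set")
    common = tax.lineage(taxids[0])
    for taxid in taxids[1:]:
        other = tax.lineage(taxid)
        k = 0
        while k < len(common) and k < len(other) and common[k] == other[k]:
            k += 1
        common = common[:k]
        if not common:  # cannot happen with a single root, defensive
            raise TaxonomyError("no common ancestor")
    return common[-1]


def _split_dmp(line: str) -> list[str]:
    # taxdump rows end with "\t|\n"; fields are separated by "\t|\t" and
    # may be empty, so split first and strip each field
    fields = [f.strip() for f in line.rstrip("\n").split("|")]
    if fields and fields[-1] == "":
        fields.pop()
    return fields


def load_taxonomy(nodes_path: str | Path | None = None,
                  names_path: str | Path | None = None,
                  lineage_tsv_path: str | Path | None = None,
                  divisions_path: str | Path | None = None) -> Taxonomy:
    """Load from either a lineage TSV or taxdump nodes.dmp + names.dmp."""
    if lineage_tsv_path is not None:
        return _load_lineage_tsv(lineage_tsv_path)
    if nodes_path is None or names_path is None:
        raise ValueError("provide lineage_tsv_path or nodes_path + names_path")
    return _load_taxdump(nodes_path, names_path, divisions_path)


def _load_lineage_tsv(path: str | Path) -> Taxonomy:
    nodes: dict[int, TaxNode] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.lower().startswith("taxid"):
            raise TaxonomyError("lineage TSV must start with a header line")
        for raw in fh:
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise TaxonomyError(f"short lineage row: {line!r}")
            taxid, parent = int(fields[0]), int(fields[1])
            division = fields[4] if len(fields) > 4 else ""
            nodes[taxid] = TaxNode(taxid, parent, fields[2], fields[3], division)
    return Taxonomy(nodes)


def _load_taxdump(nodes_path, names_path, divisions_path) -> Taxonomy:
    div_names: dict[str, str] = {}
    if divisions_path is not None:
        with open(divisions_path) as fh:
            for line in fh:
                fields = _split_dmp(line)
                if len(fields) >= 3:
                    div_names[fields[0]] = fields[2]

    nodes: dict[int, TaxNode] = {}
    with open(nodes_path) as fh:
        for line in fh:
            fields = _split_dmp(line)
            if len(fields) < 3:
                raise TaxonomyError(f"short nodes.dmp row: {line!r}")
            taxid, parent, rank = int(fields[0]), int(fields[1]), fields[2]
            div_id = fields[4] if len(fields) > 4 else ""
            # with a division.dmp, unmapped ids mean "no division"; without
            # one the raw id is kept as an opaque label
            if divisions_path is not None:
                division = div_names.get(div_id, "")
            else:
                division = div_id
            nodes[taxid] = TaxNode(taxid, parent, rank, "", division)

    with open(names_path) as fh:
        for line in fh:
            fields = _split_dmp(line)
            if len(fields) < 4:
                continue
            taxid, name, name_class = int(fields[0]), fields[1], fields[3]
            if taxid in nodes and name_class == "scientific name":
                nodes[taxid].name = name
    return Taxonomy(nodes)


def write_lineage_tsv(tax: Taxonomy, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("taxid\tparent\trank\tname\tdivision\n")
        for taxid in sorted(tax.nodes):
            n = tax.nodes[taxid]
            fh.write(f"{n.taxid}\t{n.parent}\t{n.rank}\t{n.name}\t{n.division}\n")
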