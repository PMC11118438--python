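"""Rank-filtered taxonomic trees with per-node sample counts.

Lineage records (one per NCBI taxid, carrying the ordered rank path from
kingdom down to the record's own rank) are assembled into a tree restricted
to the canonical ranks kingdom, phylum, class, order, family, genus,
subgenus, species, subspecies and varietas. Non-whitelisted levels (tribe,
section, ...) are dropped with their children re-attached to the nearest
kept ancestor. Duplicate taxids collapse to a single node; if the input
spans multiple kingdoms a synthetic root (taxid 1, rank "no rank") joins
them.

Sample counts attach reference files (never blanks/QCs) to the node of
their taxid — which may be an internal node when a file is only identified
to genus or family — and every node's subtree total equals the sum of its
children's totals plus its own directly attached files.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
import skbio

from .errors import ConsistencyError, ParameterError, UnknownTaxonError
from .spectra import MetadataEntry

__all__ = [
    "RANK_WHITELIST",
    "RANK_ORDER",
    "LineageRecord",
    "TaxonNode",
    "TaxonTree",
    "build_tree",
    "attach_sample_counts",
    "tree_to_newick",
    "tree_from_newick",
    "tree_to_json",
    "tree_from_json",
    "prune_tree_to_results",
    "read_lineage_table",
    "write_lineage_table",
    "inventory_counts",
]

RANK_WHITELIST: tuple[str, ...] = (
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "subgenus",
    "species",
    "subspecies",
    "varietas",
)
RANK_ORDER = {r: i for i, r in enumerate(RANK_WHITELIST)}

ROOT_TAXID = 1
ROOT_RANK = "no rank"

TREE_JSON_FORMAT = "masstree-tree"
TREE_JSON_VERSION = 1


@dataclass(frozen=True)
class LineageRecord:
    """Ordered lineage of one taxid: (rank, name, taxid) from kingdom down
    to and terminating at the record's own rank."""

    taxid: int
    lineage: tuple[tuple[str, str, int], ...]

    def __post_init__(self) -> None:
        if not self.lineage:
            raise ConsistencyError(f"taxid {self.taxid}: empty lineage")
        if self.lineage[-1][2] != self.taxid:
            raise ConsistencyError(
                f"taxid {self.taxid}: lineage must terminate at its own taxid"
            )

    def filtered(self) -> list[tuple[str, str, int]]:
        """Whitelisted levels only, validated to be strictly rank-ordered."""
        kept = [lv for lv in self.lineage if lv[0] in RANK_ORDER]
        orders = [RANK_ORDER[lv[0]] for lv in kept]
        if any(b <= a for a, b in zip(orders, orders[1:])):
            raise ConsistencyError(
                f"taxid {self.taxid}: lineage ranks not strictly ordered: "
                f"{[lv[0] for lv in kept]}"
            )
        return kept


@dataclass
class TaxonNode:
    taxid: int
    name: str
    rank: str
    children: list["TaxonNode"] = field(default_factory=list)
    n_samples: int = 0  # non-blank reference files in subtree
    n_samples_direct: int = 0  # files attached at this very node

    def preorder(self) -> Iterable["TaxonNode"]:
        yield self
        for c in self.children:
            yield from c.preorder()


class TaxonTree:
    """A rooted rank-filtered taxonomy with a taxid -> node lookup."""

    def __init__(self, root: TaxonNode) -> None:
        self.root = root
        self._by_taxid: dict[int, TaxonNode] = {}
        for node in root.preorder():
            if node.taxid in self._by_taxid:
                raise ConsistencyError(f"duplicate taxid {node.taxid} in tree")
            self._by_taxid[node.taxid] = node

    def __contains__(self, taxid: int) -> bool:
        return taxid in self._by_taxid

    def node(self, taxid: int) -> TaxonNode:
        try:
            return self._by_taxid[taxid]
        except KeyError:
            raise UnknownTaxonError(f"taxid {taxid} not in tree") from None

    @property
    def taxids(self) -> set[int]:
        return set(self._by_taxid)

    def preorder(self) -> Iterable[TaxonNode]:
        return self.root.preorder()

    def parent_map(self) -> dict[int, int | None]:
        parents: dict[int, int | None] = {self.root.taxid: None}
        for node in self.preorder():
            for c in node.children:
                parents[c.taxid] = node.taxid
        return parents

    def ancestors(self, taxid: int) -> list[int]:
        """Taxids from the node's parent up to the root."""
        parents = self.parent_map()
        out = []
        cur = parents[self.node(taxid).taxid]
        while cur is not None:
            out.append(cur)
            cur = parents[cur]
        return out


def build_tree(lineages: Sequence[LineageRecord]) -> TaxonTree:
    """Assemble lineage records into one deduplicated, rank-filtered tree.

    Duplicate taxids (same taxon submitted more than once) collapse to one
    node. A taxid observed under two different parents is a consistency
    error. Multiple kingdoms are joined under a synthetic root.
    """
    if not lineages:
        raise ConsistencyError("no lineage records supplied")
    nodes: dict[int, TaxonNode] = {}
    parent_of: dict[int, int | None] = {}
    top_level: dict[int, TaxonNode] = {}
    for rec in lineages:
        path = rec.filtered()
        if not path:
            raise ConsistencyError(
                f"taxid {rec.taxid}: no whitelisted ranks in lineage"
            )
        prev: int | None = None
        for rank, name, taxid in path:
            node = nodes.get(taxid)
            if node is None:
                node = TaxonNode(taxid=taxid, name=name, rank=rank)
                nodes[taxid] = node
                parent_of[taxid] = prev
                if prev is None:
                    top_level[taxid] = node
                else:
                    nodes[prev].children.append(node)
            else:
                if node.rank != rank or parent_of[taxid] != prev:
                    raise ConsistencyError(
                        f"taxid {taxid} appears with conflicting rank/parentage"
                    )
            prev = taxid
    for node in nodes.values():
        node.children.sort(key=lambda n: n.taxid)
    if len(top_level) == 1:
        root = next(iter(top_level.values()))
    else:
        root = TaxonNode(taxid=ROOT_TAXID, name="root", rank=ROOT_RANK)
        root.children = sorted(top_level.values(), key=lambda n: n.taxid)
    return TaxonTree(root)


def attach_sample_counts(
    tree: TaxonTree, metadata: Sequence[MetadataEntry]
) -> TaxonTree:
    """Attach non-blank reference files to their taxid's node and propagate
    subtree totals upward. Blanks/QCs contribute nothing. Modifies the tree
    in place and returns it.

    Raises
    ------
    UnknownTaxonError
        Listing every non-blank file whose taxid has no node.
    """
    for node in tree.preorder():
        node.n_samples = 0
        node.n_samples_direct = 0
    unplaceable = []
    for entry in metadata:
        if entry.is_blank_or_qc:
            continue
        if entry.ncbi_taxid not in tree:
            unplaceable.append(entry.dataset_filename)
            continue
        tree.node(entry.ncbi_taxid).n_samples_direct += 1
    if unplaceable:
        raise UnknownTaxonError(
            "files with taxids absent from tree: " + ", ".join(sorted(unplaceable))
        )

    def accumulate(node: TaxonNode) -> int:
        node.n_samples = node.n_samples_direct + sum(
            accumulate(c) for c in node.children
        )
        return node.n_samples

    accumulate(tree.root)
    return tree


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def tree_to_newick(tree: TaxonTree) -> str:
    """Newick string with taxid node labels (topology only)."""

    def to_skbio(node: TaxonNode) -> skbio.TreeNode:
        t = skbio.TreeNode(name=str(node.taxid))
        for c in node.children:
            t.append(to_skbio(c))
        return t

    buf = io.StringIO()
    to_skbio(tree.root).write(buf, format="newick")
    return buf.getvalue().strip()


def tree_from_newick(newick: str) -> TaxonTree:
    """Topology-only inverse of :func:`tree_to_newick` (names/ranks/counts
    are not stored in Newick; use the JSON form for full round trips)."""
    st = skbio.TreeNode.read(io.StringIO(newick), format="newick")

    def from_skbio(t: skbio.TreeNode) -> TaxonNode:
        node = TaxonNode(taxid=int(t.name), name=str(t.name), rank="")
        for c in t.children:
            node.children.append(from_skbio(c))
        return node

    return TaxonTree(from_skbio(st))


def _node_to_dict(node: TaxonNode) -> dict:
    return {
        "taxid": node.taxid,
        "name": node.name,
        "rank": node.rank,
        "n_samples": node.n_samples,
        "n_samples_direct": node.n_samples_direct,
        "children": [_node_to_dict(c) for c in node.children],
    }


def tree_to_json(tree: TaxonTree) -> str:
    """Versioned JSON document carrying full node annotations."""
    doc = {
        "format": TREE_JSON_FORMAT,
        "version": TREE_JSON_VERSION,
        "tree": _node_to_dict(tree.root),
    }
    return json.dumps(doc, indent=1)


def tree_from_json(document: str) -> TaxonTree:
    doc = json.loads(document)
    if doc.get("format") != TREE_JSON_FORMAT:
        raise ConsistencyError("not a masstree tree JSON document")

    def from_dict(d: dict) -> TaxonNode:
        node = TaxonNode(
            taxid=d["taxid"],
            name=d["name"],
            rank=d["rank"],
            n_samples=d["n_samples"],
            n_samples_direct=d["n_samples_direct"],
        )
        node.children = [from_dict(c) for c in d["children"]]
        return node

    return TaxonTree(from_dict(doc["tree"]))


def prune_tree_to_results(tree: TaxonTree, matched_taxids: set[int]) -> TaxonTree:
    """Subtree containing exactly the matched nodes and their ancestors.

    Counts are carried over untouched (they still describe the full
    library). An empty match set yields a root-only tree.

    Raises
    ------
    UnknownTaxonError
        If a matched taxid is not in the tree.
    """
    unknown = matched_taxids - tree.taxids
    if unknown:
        raise UnknownTaxonError(f"matched taxids not in tree: {sorted(unknown)}")
    keep = set(matched_taxids)
    for t in matched_taxids:
        keep.update(tree.ancestors(t))
    keep.add(tree.root.taxid)

    def copy_kept(node: TaxonNode) -> TaxonNode:
        new = TaxonNode(
            taxid=node.taxid,
            name=node.name,
            rank=node.rank,
            n_samples=node.n_samples,
            n_samples_direct=node.n_samples_direct,
        )
        new.children = [copy_kept(c) for c in node.children if c.taxid in keep]
        return new

    return TaxonTree(copy_kept(tree.root))


# ---------------------------------------------------------------------------
# Lineage table I/O and inventory counts
# ---------------------------------------------------------------------------

_LEVEL_SEP = ";"
_FIELD_SEP = "|"


def write_lineage_table(records: Sequence[LineageRecord], path) -> None:
    """TSV with columns taxid, rank, name, lineage; lineage encodes the full
    path as ``rank|name|taxid`` levels joined by ``;``."""
    rows = []
    for r in records:
        rank, name, _ = r.lineage[-1]
        rows.append(
            {
                "taxid": r.taxid,
                "rank": rank,
                "name": name,
                "lineage": _LEVEL_SEP.join(
                    _FIELD_SEP.join((lv[0], lv[1], str(lv[2]))) for lv in r.lineage
                ),
            }
        )
    pd.DataFrame(rows, columns=["taxid", "rank", "name", "lineage"]).to_csv(
        path, sep="\t", index=False
    )


def read_lineage_table(path) -> list[LineageRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("taxid", "lineage"):
        if col not in df.columns:
            raise ConsistencyError(f"lineage table missing column {col!r}")
    records = []
    for _, row in df.iterrows():
        levels = []
        for lv in row["lineage"].split(_LEVEL_SEP):
            rank, name, taxid = lv.split(_FIELD_SEP)
            levels.append((rank, name, int(taxid)))
        records.append(LineageRecord(taxid=int(row["taxid"]), lineage=tuple(levels)))
    return records


def inventory_counts(
    metadata: Sequence[MetadataEntry], records: Sequence[LineageRecord]
) -> dict[str, int]:
    """Library inventory: distinct taxids among non-blank files, and the
    distinct families, genera, and species their lineages span."""
    by_taxid = {r.taxid: r for r in records}
    taxids = {m.ncbi_taxid for m in metadata if not m.is_blank_or_qc}
    taxids.discard(None)
    per_rank: dict[str, set[int]] = {"family": set(), "genus": set(), "species": set()}
    for t in taxids:
        rec = by_taxid.get(t)
        if rec is None:
            raise UnknownTaxonError(f"taxid {t} has no lineage record")
        for rank, _, taxid in rec.lineage:
            if rank in per_rank:
                per_rank[rank].add(taxid)
    return {
        "distinct_taxids": len(taxids),
        "families": len(per_rank["family"]),
        "genera": len(per_rank["genus"]),
        "species": len(per_rank["species"]),
    }
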