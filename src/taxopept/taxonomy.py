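"""NCBI-taxdump-style taxonomy loading and lineage resolution.

The taxonomy is held entirely in memory as three flat dictionaries so that
resolving an organism ID to any higher rank (genus, superkingdom, ...) is a
constant-time pointer chase, which is what makes per-peptide taxon assignment
cheap downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from os import PathLike
from typing import Iterable, Mapping

ROOT_TAXON_ID = 1

__all__ = [
    "TaxonomyIndex",
    "TaxdumpParseError",
    "UnknownTaxonError",
    "load_taxdump",
    "lineage",
]


class TaxdumpParseError(ValueError):
    """A nodes/names file row that does not follow the taxdump dialect."""


class UnknownTaxonError(KeyError):
    """Lookup of a taxon ID absent from the loaded taxonomy."""


@dataclass
class TaxonomyIndex:
    """In-memory taxonomy: parent links, ranks, and scientific names.

    Invariants: every ID in ``parent_of`` has entries in ``rank_of`` and
    ``name_of`` (possibly an empty name); following parents terminates at the
    root (its own parent) or at a dangling parent ID absent from the index.
    """

    parent_of: dict[int, int] = field(default_factory=dict)
    rank_of: dict[int, str] = field(default_factory=dict)
    name_of: dict[int, str] = field(default_factory=dict)

    def __contains__(self, taxon_id: int) -> bool:
        return taxon_id in self.parent_of

    def __len__(self) -> int:
        return len(self.parent_of)

    def ancestors(self, taxon_id: int) -> Iterable[int]:
        """Yield ``taxon_id`` and its ancestors up to the root.

        Stops at the root (a node that is its own parent) or when a parent ID
        is not present in the index (dangling parent); ranks found up to that
        point are still usable.
        """
        if taxon_id not in self.parent_of:
            raise UnknownTaxonError(taxon_id)
        current = taxon_id
        seen: set[int] = set()
        while current not in seen:
            seen.add(current)
            yield current
            parent = self.parent_of.get(current)
            if parent is None or parent == current:
                return
            if parent not in self.parent_of:
                return  # dangling parent: report what we have
            current = parent

    def lineage(
        self, taxon_id: int, ranks: Iterable[str]
    ) -> dict[str, tuple[int, str]]:
        return lineage(self, taxon_id, ranks)


def _split_taxdump_row(line: str) -> list[str]:
    # Rows look like: "9606\t|\t9605\t|\tspecies\t|\t..." with a trailing "\t|".
    return [f.strip("\t") for f in line.rstrip("\n").rstrip("|\t").split("\t|\t")]


def load_taxdump(
    nodes_path: str | PathLike, names_path: str | PathLike
) -> TaxonomyIndex:
    """Parse ``nodes.dmp`` / ``names.dmp`` files into a :class:`TaxonomyIndex`.

    Only rows of the names file whose name class is ``scientific name`` are
    used; IDs without one map to an empty name. Unknown rank strings are
    preserved verbatim.

    Raises
    ------
    TaxdumpParseError
        If a row cannot be parsed, naming the file and 1-based line number.
    """
    index = TaxonomyIndex()
    with open(nodes_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = _split_taxdump_row(line)
            if len(fields) < 3:
                raise TaxdumpParseError(
                    f"{nodes_path}: line {lineno}: expected at least 3 "
                    f"pipe-delimited fields, got {len(fields)}"
                )
            try:
                tax_id = int(fields[0])
                parent_id = int(fields[1])
            except ValueError as exc:
                raise TaxdumpParseError(
                    f"{nodes_path}: line {lineno}: non-integer taxon/parent ID"
                ) from exc
            index.parent_of[tax_id] = parent_id
            index.rank_of[tax_id] = fields[2]
            index.name_of.setdefault(tax_id, "")
    with open(names_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = _split_taxdump_row(line)
            if len(fields) < 4:
                raise TaxdumpParseError(
                    f"{names_path}: line {lineno}: expected at least 4 "
                    f"pipe-delimited fields, got {len(fields)}"
                )
            try:
                tax_id = int(fields[0])
            except ValueError as exc:
                raise TaxdumpParseError(
                    f"{names_path}: line {lineno}: non-integer taxon ID"
                ) from exc
            if fields[3] == "scientific name" and tax_id in index.parent_of:
                index.name_of[tax_id] = fields[1]
    return index


def lineage(
    index: TaxonomyIndex, taxon_id: int, ranks: Iterable[str]
) -> dict[str, tuple[int, str]]:
    """Resolve ``taxon_id`` to the nearest self-or-ancestor at each rank.

    Returns a mapping ``rank -> (taxon_id, scientific_name)`` containing only
    the ranks that resolve; a rank carried by no ancestor is absent from the
    result (never imputed). Non-canonical ranks such as ``no rank`` match only
    if explicitly requested.

    Raises
    ------
    UnknownTaxonError
        If ``taxon_id`` is not in the index (distinguishable from a merely
        absent rank, which yields a missing key).
    """
    wanted = list(ranks)
    if not wanted:
        raise ValueError("ranks must be non-empty")
    remaining = set(wanted)
    out: dict[str, tuple[int, str]] = {}
    for node in index.ancestors(taxon_id):
        rank = index.rank_of.get(node)
        if rank in remaining:
            out[rank] = (node, index.name_of.get(node, ""))
            remaining.discard(rank)
            if not remaining:
                break
    return out
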