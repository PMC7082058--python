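"""Annotate experimental peptide tables with taxa and genes; filter, roll up,
normalize, and compute peptidome-sharing statistics.

The two filtering semantics mirror the two ways multi-species (e.g. PDX)
experiments are analyzed:

* method 1 (``require_unique=False`` with a ``default_taxon``) — every peptide
  for which the default taxon is a *plausible* assignment is kept and
  attributed to it, simulating a targeted search against a single organism's
  proteome;
* method 2 (``require_unique=True``) — only peptides unique to a single taxon
  at the chosen rank, in the context of the whole combined database, are kept.

Method-2 rows are always a subset of method-1 rows for the same taxon.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .digest import DigestParams, canonicalize, digest_protein
from .pcdb import PCDBHandle, query_peptide
from .proteomes import ProteinRecord
from .taxonomy import TaxonomyIndex, lineage

logger = logging.getLogger(__name__)

#: Bracketed/parenthesized modification tags, e.g. "(+15.99)", "[Oxidation]",
#: MaxQuant-style "(ph)"; underscores and lowercase annotations are dropped too.
_MOD_TAG_RE = re.compile(r"\([^)]*\)|\[[^\]]*\]")
_NON_RESIDUE_RE = re.compile(r"[^A-Z]")

SEQUENCE_COLUMN = "Sequence"

__all__ = [
    "TaxonFilter",
    "strip_modifications",
    "annotate_peptides",
    "apply_taxon_filter",
    "rollup_to_genes",
    "normalize_reference_pool",
    "shared_peptidome_fraction",
    "genus_peptidome_stats",
    "UNRANKED",
]

UNRANKED = "unranked"


def strip_modifications(sequence: str) -> str:
    """Remove PTM annotations: bracketed/parenthesized tags and any
    non-uppercase character (underscores, lowercase shorthand)."""
    return _NON_RESIDUE_RE.sub("", _MOD_TAG_RE.sub("", sequence))


@dataclass(frozen=True)
class TaxonFilter:
    """Taxon-specificity filter applied to an annotated table.

    ``include``/``exclude`` are disjoint lists of taxon names at ``rank``;
    ``default_taxon`` attributes shared peptides in method-1 mode;
    ``require_unique`` switches to method-2 (unique-only) semantics.
    ``require_nonempty_after_exclusion`` additionally demands that some
    non-excluded taxon remains plausible (on by default).
    """

    rank: str
    include: tuple[str, ...] = ()
    exclude: tuple[str, ...] = ()
    default_taxon: str | None = None
    require_unique: bool = False
    require_nonempty_after_exclusion: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "include", tuple(self.include))
        object.__setattr__(self, "exclude", tuple(self.exclude))
        if set(self.include) & set(self.exclude):
            raise ValueError("include and exclude must be disjoint")
        if self.default_taxon and self.require_unique and len(self.include) > 1:
            raise ValueError(
                "default_taxon with require_unique and multiple include "
                "entries is ambiguous"
            )


def _taxon_col(rank: str) -> str:
    return f"Taxa {rank}"


def _unique_col(rank: str) -> str:
    return f"Unique {rank}"


def annotate_peptides(
    table: pd.DataFrame,
    handle: PCDBHandle,
    index: TaxonomyIndex,
    ranks: Sequence[str],
    sequence_col: str = SEQUENCE_COLUMN,
) -> pd.DataFrame:
    """Annotate every row of a peptide table with its database hits.

    Adds: ``Stripped sequence``, ``Matched``, ``Accessions``, ``Genes``, and
    per requested rank ``Taxa <rank>`` (semicolon-joined names) and
    ``Unique <rank>`` (True iff all hits resolve to one taxon at that rank).
    Quantitative columns are carried through untouched; unmatched rows are
    retained with ``Matched=False`` so match-rate QC is possible. A hidden
    ``_hits`` column keeps the raw (accession, taxon_id, gene) tuples for the
    filtering and rollup steps.
    """
    if sequence_col not in table.columns:
        raise KeyError(
            f"peptide table lacks sequence column {sequence_col!r}; "
            f"columns present: {list(table.columns)}"
        )
    out = table.copy()
    stripped = table[sequence_col].astype(str).map(strip_modifications)
    out["Stripped sequence"] = stripped

    # One query per distinct stripped sequence.
    cache: dict[str, frozenset[tuple[str, int, str]]] = {}
    lineage_cache: dict[int, dict[str, tuple[int, str]]] = {}
    for seq in stripped.unique():
        cache[seq] = frozenset(query_peptide(handle, seq)) if seq else frozenset()

    def resolve(taxon_id: int) -> dict[str, tuple[int, str]]:
        if taxon_id not in lineage_cache:
            lineage_cache[taxon_id] = lineage(index, taxon_id, ranks)
        return lineage_cache[taxon_id]

    hits_col = [cache[s] for s in stripped]
    out["_hits"] = hits_col
    out["Matched"] = [bool(h) for h in hits_col]
    out["Accessions"] = [
        ";".join(sorted({a for a, _, _ in h})) for h in hits_col
    ]
    out["Genes"] = [
        ";".join(sorted({g for _, _, g in h if g})) for h in hits_col
    ]
    for rank in ranks:
        names: list[str] = []
        uniq: list[bool] = []
        for h in hits_col:
            resolved = [resolve(t).get(rank) for _, t, _ in h]
            labels = {r[1] if r else None for r in resolved}
            names.append(";".join(sorted(n for n in labels if n is not None)))
            uniq.append(len(labels) == 1 and None not in labels)
        out[_taxon_col(rank)] = names
        out[_unique_col(rank)] = uniq
    return out


def _rank_taxa_of_hits(
    hits: Iterable[tuple[str, int, str]],
    index: TaxonomyIndex,
    rank: str,
) -> dict[str | None, set[str]]:
    """Map resolved taxon name (None = rank absent) -> gene symbols of the
    hits carrying it."""
    by_taxon: dict[str | None, set[str]] = {}
    for _, taxon_id, gene in hits:
        res = lineage(index, taxon_id, [rank]).get(rank)
        name = res[1] if res else None
        by_taxon.setdefault(name, set())
        if gene:
            by_taxon[name].add(gene)
    return by_taxon


def apply_taxon_filter(
    annotated: pd.DataFrame,
    filt: TaxonFilter,
    index: TaxonomyIndex,
) -> pd.DataFrame:
    """Apply method-1/method-2 taxon-specificity semantics.

    Returns the retained rows with two added columns: ``Assigned taxon`` and
    ``Assigned genes`` (gene symbols of the hits belonging to the assigned
    taxon, semicolon-joined). Requires the hidden ``_hits`` column produced by
    :func:`annotate_peptides`.
    """
    if "_hits" not in annotated.columns:
        raise KeyError("table must come from annotate_peptides (missing _hits)")
    include = set(filt.include)
    exclude = set(filt.exclude)
    keep_idx: list = []
    assigned_taxon: list[str] = []
    assigned_genes: list[str] = []
    for idx, hits in annotated["_hits"].items():
        if not hits:
            continue
        by_taxon = _rank_taxa_of_hits(hits, index, filt.rank)
        taxa = set(by_taxon)  # may contain None for rank-absent hits
        named = {t for t in taxa if t is not None}
        effective = named - exclude
        target: str | None = None
        if filt.require_unique:
            # method 2: unique to a single (included, non-excluded) taxon in
            # the context of the whole database.
            if len(taxa) == 1 and None not in taxa:
                (only,) = taxa
                if only not in exclude and (not include or only in include):
                    target = only
        else:
            # method 1: the taxon of interest need only be plausible.
            if filt.require_nonempty_after_exclusion and not effective:
                target = None
            elif filt.default_taxon is not None:
                if filt.default_taxon in named:
                    target = filt.default_taxon
            elif include:
                overlap = sorted(effective & include)
                target = overlap[0] if len(overlap) == 1 else None
            elif len(effective) == 1:
                (target,) = effective
        if target is None:
            continue
        keep_idx.append(idx)
        assigned_taxon.append(target)
        assigned_genes.append(";".join(sorted(by_taxon.get(target, set()))))
    out = annotated.loc[keep_idx].copy()
    out["Assigned taxon"] = assigned_taxon
    out["Assigned genes"] = assigned_genes
    return out


def rollup_to_genes(
    filtered: pd.DataFrame,
    quant_columns: Sequence[str],
    gene_col: str = "Assigned genes",
) -> pd.DataFrame:
    """Sum quantitative columns to gene symbols.

    Rows mapping to zero or multiple gene symbols are dropped (and counted in
    ``result.attrs['n_dropped_ambiguous_gene']``); per-gene contributing
    peptide-row counts are reported in ``Peptide count``. Column sums over the
    output equal column sums over the retained rows (additivity).
    """
    missing = [c for c in quant_columns if c not in filtered.columns]
    if missing:
        raise KeyError(f"quant columns absent from table: {missing}")
    if gene_col not in filtered.columns:
        raise KeyError(f"gene column {gene_col!r} absent; run apply_taxon_filter")
    single = ~filtered[gene_col].astype(str).str.contains(";") & (
        filtered[gene_col].astype(str) != ""
    )
    n_dropped = int((~single).sum())
    if n_dropped:
        logger.warning(
            "rollup_to_genes: dropped %d rows with 0 or >1 gene symbols", n_dropped
        )
    kept = filtered.loc[single]
    grouped = kept.groupby(gene_col, sort=True)
    out = grouped[list(quant_columns)].sum()
    out.insert(0, "Peptide count", grouped.size())
    out.index.name = "Gene"
    out.attrs["n_dropped_ambiguous_gene"] = n_dropped
    return out


def normalize_reference_pool(
    gene_table: pd.DataFrame,
    reference_channel: str,
    channels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Reference-pool normalization for isobaric (e.g. TMT) gene tables.

    In order: (1) ratio of each channel to the internal reference-pool
    channel, per gene; (2) log2; (3) per-channel median centering; (4) per-
    channel scaling by the population standard deviation. Genes whose
    reference value is missing or non-positive are dropped and counted in
    ``result.attrs['n_dropped_no_reference']``. The reference channel itself
    is identically zero after step 3 (SD undefined) and is omitted from the
    output; every output channel has median 0 and SD 1 (tolerance 1e-9).
    """
    if reference_channel not in gene_table.columns:
        raise KeyError(f"reference channel {reference_channel!r} absent")
    if channels is None:
        channels = [
            c
            for c in gene_table.columns
            if c != reference_channel
            and pd.api.types.is_numeric_dtype(gene_table[c])
            and c != "Peptide count"
        ]
    ref = gene_table[reference_channel]
    ok = ref.notna() & (ref > 0)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning(
            "normalize_reference_pool: dropped %d genes without a positive "
            "reference value",
            n_dropped,
        )
    sub = gene_table.loc[ok]
    if len(sub) < 2:
        raise ValueError("need at least 2 genes to normalize (SD undefined)")
    ratios = sub[list(channels)].div(sub[reference_channel], axis=0)
    logged = np.log2(ratios)
    centered = logged - logged.median(axis=0)
    scaled = centered / centered.std(axis=0, ddof=0)
    scaled.attrs["n_dropped_no_reference"] = n_dropped
    return scaled


def _peptides_by_gene(
    records: Iterable[ProteinRecord], params: DigestParams
) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for rec in records:
        if not rec.gene:
            continue
        out.setdefault(rec.gene, set()).update(digest_protein(rec, params))
    return out


def shared_peptidome_fraction(
    proteome_a: Iterable[ProteinRecord],
    proteome_b: Iterable[ProteinRecord],
    params: DigestParams | None = None,
) -> tuple[pd.DataFrame, float]:
    """Per-gene fraction of A's digest peptides also produced by B's homolog.

    Peptides are pooled per gene symbol (the homolog join key) in each
    proteome. Returns a table indexed by A's gene symbols with columns
    ``n_peptides``, ``n_shared``, ``fraction``, ``gene_in_b``; genes absent
    from B score 0 and are flagged. The second return value is the summary
    fraction of A's genes sharing at least one peptide with B.
    """
    params = params or DigestParams()
    pep_a = _peptides_by_gene(proteome_a, params)
    pep_b = _peptides_by_gene(proteome_b, params)
    rows = []
    for gene in sorted(pep_a):
        mine = pep_a[gene]
        theirs = pep_b.get(gene, set())
        if not mine:
            continue
        shared = len(mine & theirs)
        rows.append(
            {
                "Gene": gene,
                "n_peptides": len(mine),
                "n_shared": shared,
                "fraction": shared / len(mine),
                "gene_in_b": gene in pep_b,
            }
        )
    table = pd.DataFrame(rows).set_index("Gene") if rows else pd.DataFrame(
        columns=["n_peptides", "n_shared", "fraction", "gene_in_b"]
    )
    summary = float((table["fraction"] > 0).mean()) if len(table) else 0.0
    return table, summary


def genus_peptidome_stats(
    handle: PCDBHandle, index: TaxonomyIndex
) -> pd.DataFrame:
    """Per-genus unique/shared peptide tallies over a whole database.

    A (distinct) peptide is unique to a genus iff every parent protein
    resolves to that genus; proteins with no genus ancestor fall into the
    ``unranked`` bucket. Returns a table indexed by genus with columns
    ``total``, ``unique``, ``fraction_shared``, sorted by total descending.
    """
    genus_of_taxon: dict[int, str] = {}

    def genus_of(taxon_id: int) -> str:
        if taxon_id not in genus_of_taxon:
            res = lineage(index, taxon_id, ["genus"]).get("genus")
            genus_of_taxon[taxon_id] = res[1] if res else UNRANKED
        return genus_of_taxon[taxon_id]

    taxon_of_protein: dict[int, int] = dict(
        handle.conn.execute("SELECT protein_id, taxon_id FROM MainData")
    )
    totals: dict[str, int] = {}
    uniques: dict[str, int] = {}
    cursor = handle.conn.execute(
        "SELECT hash_peptide, GROUP_CONCAT(DISTINCT protein_id)"
        " FROM Reference GROUP BY hash_peptide"
    )
    for _, protein_ids in cursor:
        genera = {
            genus_of(taxon_of_protein[int(p)]) for p in protein_ids.split(",")
        }
        for g in genera:
            totals[g] = totals.get(g, 0) + 1
        if len(genera) == 1:
            (g,) = genera
            uniques[g] = uniques.get(g, 0) + 1
    rows = [
        {
            "genus": g,
            "total": totals[g],
            "unique": uniques.get(g, 0),
            "fraction_shared": 1.0 - uniques.get(g, 0) / totals[g],
        }
        for g in totals
    ]
    out = pd.DataFrame(rows).set_index("genus") if rows else pd.DataFrame(
        columns=["total", "unique", "fraction_shared"]
    )
    return out.sort_values("total", ascending=False)
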