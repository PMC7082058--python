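"""Protein FASTA I/O with UniProt-style headers, concatenation, decoys, fetch.

Headers are expected to carry the UniProt cross-reference tokens ``OX=<taxid>``
(mandatory — it is the organism link) and ``GN=<symbol>`` (optional gene
symbol). FASTA mechanics are delegated to Biopython; only the header dialect
and the collection-level operations live here.
"""

from __future__ import annotations

import io
import logging
import re
import time
from dataclasses import dataclass
from os import PathLike
from typing import Callable, Iterable, Sequence, TextIO

from Bio import SeqIO

logger = logging.getLogger(__name__)

DECOY_PREFIX = "REV_"

#: Residue alphabet accepted in sequences: the 20 canonical amino acids plus
#: ambiguity/rare codes retained (but never hashed, see the digest module).
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY" + "XUBZ")

_OX_RE = re.compile(r"\bOX=(\d+)\b")
_GN_RE = re.compile(r"\bGN=(\S+)")

__all__ = [
    "ProteinRecord",
    "FastaParseResult",
    "DECOY_PREFIX",
    "parse_fasta",
    "write_fasta",
    "concatenate",
    "reverse_decoy",
    "fetch_proteomes",
    "uniprot_query_url",
]


@dataclass(frozen=True)
class ProteinRecord:
    """One protein entry: accession, gene symbol (may be empty), organism, sequence."""

    accession: str
    gene: str
    taxon_id: int
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        if self.taxon_id <= 0:
            raise ValueError(f"{self.accession}: taxon_id must be positive")


@dataclass
class FastaParseResult:
    """Parsed records plus a tally of rejected entries (no OX token, duplicate
    accession, invalid residues)."""

    records: list[ProteinRecord]
    n_rejected: int = 0

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _accession_from_header(header: str) -> str:
    first = header.split()[0]
    if "|" in first:
        parts = first.split("|")
        if len(parts) >= 2 and parts[1]:
            return parts[1]
    return first


def parse_fasta(source: str | PathLike | TextIO) -> FastaParseResult:
    """Read a UniProt-dialect FASTA into :class:`ProteinRecord` objects.

    Entries without an ``OX=`` token, with a duplicate accession, or with
    residues outside the accepted alphabet are rejected with a logged warning;
    the reject count is returned alongside the records. Sequences are
    uppercased on read; an empty stream yields an empty collection.
    """
    close = False
    if isinstance(source, (str, PathLike)):
        handle: TextIO = open(source, encoding="utf-8")
        close = True
    else:
        handle = source
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    n_rejected = 0
    try:
        for entry in SeqIO.parse(handle, "fasta"):
            header = entry.description
            seq = str(entry.seq).upper()
            ox = _OX_RE.search(header)
            if ox is None:
                logger.warning("rejected FASTA entry without OX= token: %s", header)
                n_rejected += 1
                continue
            accession = _accession_from_header(header)
            if accession in seen:
                logger.warning("rejected duplicate accession: %s", accession)
                n_rejected += 1
                continue
            if not seq or not set(seq) <= VALID_RESIDUES:
                logger.warning("rejected entry with invalid sequence: %s", accession)
                n_rejected += 1
                continue
            gn = _GN_RE.search(header)
            records.append(
                ProteinRecord(
                    accession=accession,
                    gene=gn.group(1) if gn else "",
                    taxon_id=int(ox.group(1)),
                    sequence=seq,
                )
            )
            seen.add(accession)
    finally:
        if close:
            handle.close()
    return FastaParseResult(records=records, n_rejected=n_rejected)


def write_fasta(
    records: Iterable[ProteinRecord], dest: str | PathLike | TextIO, width: int = 60
) -> None:
    """Write records in the same header dialect ``parse_fasta`` reads.

    ``parse_fasta(write_fasta(x))`` is the identity on record collections.
    """
    close = False
    if isinstance(dest, (str, PathLike)):
        handle: TextIO = open(dest, "w", encoding="utf-8")
        close = True
    else:
        handle = dest
    try:
        for rec in records:
            gene_token = f" GN={rec.gene}" if rec.gene else ""
            handle.write(f">{rec.accession}{gene_token} OX={rec.taxon_id}\n")
            for i in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[i : i + width] + "\n")
    finally:
        if close:
            handle.close()


def concatenate(
    collections: Sequence[Iterable[ProteinRecord]],
) -> FastaParseResult:
    """Order-preserving union of collections; duplicate accessions keep the
    first occurrence and are counted in ``n_rejected``."""
    out: list[ProteinRecord] = []
    seen: set[str] = set()
    n_dup = 0
    for coll in collections:
        for rec in coll:
            if rec.accession in seen:
                n_dup += 1
                continue
            out.append(rec)
            seen.add(rec.accession)
    if n_dup:
        logger.warning("concatenate: dropped %d duplicate accessions", n_dup)
    return FastaParseResult(records=out, n_rejected=n_dup)


def reverse_decoy(
    records: Iterable[ProteinRecord], prefix: str = DECOY_PREFIX
) -> list[ProteinRecord]:
    """Whole-protein sequence reversal for decoy (false-discovery) databases.

    Each sequence is reversed end-to-end; the accession gains a decoy marker;
    gene and taxon are preserved so decoy matches are attributed to the same
    taxa as their targets.
    """
    return [
        ProteinRecord(
            accession=prefix + rec.accession,
            gene=rec.gene,
            taxon_id=rec.taxon_id,
            sequence=rec.sequence[::-1],
        )
        for rec in records
    ]


def uniprot_query_url(taxon_id: int, sources: frozenset[str] | set[str]) -> str:
    """The documented REST query template for one organism.

    ``sources`` is a subset of {"curated", "unreviewed", "reference"}:
    curated restricts to reviewed (Swiss-Prot-like) entries, unreviewed to
    TrEMBL-like entries, reference to reference-proteome membership.
    """
    clauses = [f"organism_id:{taxon_id}"]
    if "curated" in sources and "unreviewed" not in sources:
        clauses.append("reviewed:true")
    elif "unreviewed" in sources and "curated" not in sources:
        clauses.append("reviewed:false")
    if "reference" in sources:
        clauses.append("proteome:reference")
    query = "+AND+".join(clauses)
    return (
        "https://rest.uniprot.org/uniprotkb/stream?"
        f"format=fasta&query={query}"
    )


def fetch_proteomes(
    taxon_ids: Sequence[int],
    sources: set[str] | frozenset[str],
    transport: Callable[[int, frozenset[str]], str],
    out_path: str | PathLike,
    retries: int = 3,
    backoff_seconds: float = 1.0,
) -> FastaParseResult:
    """Fetch and concatenate per-taxon FASTA text through an injected transport.

    ``transport(taxon_id, sources)`` returns FASTA text for one organism
    (tests inject a local fixture transport; a live transport would GET
    :func:`uniprot_query_url`). Transport failures are retried with backoff
    and then raised naming the taxon; an empty result for a taxon is a
    warning, not a failure. Malformed FASTA propagates as a parse error with
    taxon context.
    """
    sources = frozenset(sources)
    collections: list[list[ProteinRecord]] = []
    if not taxon_ids:
        logger.warning("fetch_proteomes: empty taxon list, writing empty file")
    for taxon_id in taxon_ids:
        last_exc: Exception | None = None
        text: str | None = None
        for attempt in range(retries):
            try:
                text = transport(taxon_id, sources)
                break
            except Exception as exc:  # pragma: no cover - exercised via fixture
                last_exc = exc
                if attempt < retries - 1:
                    time.sleep(backoff_seconds * (2**attempt))
        if text is None:
            raise RuntimeError(
                f"fetch_proteomes: transport failed for taxon {taxon_id}"
            ) from last_exc
        if text.strip() and not text.lstrip().startswith(">"):
            raise ValueError(
                f"fetch_proteomes: malformed FASTA for taxon {taxon_id}"
            )
        parsed = parse_fasta(io.StringIO(text))
        if not parsed.records:
            logger.warning("fetch_proteomes: no records for taxon %d", taxon_id)
        else:
            logger.info(
                "fetch_proteomes: taxon %d -> %d records", taxon_id, len(parsed)
            )
        collections.append(parsed.records)
    merged = concatenate(collections)
    write_fasta(merged.records, out_path)
    return merged
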