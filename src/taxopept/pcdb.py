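"""Build, index, and query the single-file peptide database (SQLite).

Schema (three relations):

* ``MainData(protein_id, accession, sequence, taxon_id, gene)`` — full protein
  sequences so hash hits can be verified.
* ``Reference(hash_peptide, protein_id)`` — one row per (peptide, protein)
  incidence; stores only the 64-bit peptide hash (compression), indexed after
  build as a separate step.
* ``DBParams(key, value)`` — the exact digestion parameters used at build
  time, a schema version, and the index flag. DBParams is authoritative:
  queries always canonicalize with the stored rules, never the caller's.

Collision safety: a hash hit is confirmed by re-digesting the stored parent
sequence and checking the canonical query peptide is truly among its digest
products, so annotation never reports a protein that could not have produced
the peptide under the stored cleavage rules.
"""

from __future__ import annotations

import json
import logging
import multiprocessing
import os
import sqlite3
from os import PathLike
from typing import Iterable, Sequence

from .digest import (
    CleavageRule,
    DigestParams,
    canonicalize,
    digest_sequence,
    hash_peptide,
)
from .proteomes import ProteinRecord

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"

__all__ = ["PCDBHandle", "create_pcdb", "index_pcdb", "query_peptide", "open_pcdb"]


def _protease_to_str(protease: str | CleavageRule) -> str:
    if isinstance(protease, str):
        return protease
    return json.dumps(
        {
            "residues": "".join(sorted(protease.residues)),
            "blocked_next": "".join(sorted(protease.blocked_next)),
            "side": protease.side,
        }
    )


def _protease_from_str(text: str) -> str | CleavageRule:
    if text.startswith("{"):
        obj = json.loads(text)
        return CleavageRule(
            residues=frozenset(obj["residues"]),
            blocked_next=frozenset(obj["blocked_next"]),
            side=obj["side"],
        )
    return text


class PCDBHandle:
    """An opened peptide database."""

    def __init__(self, path: str | PathLike):
        self.path = os.fspath(path)
        self.conn = sqlite3.connect(self.path)
        self._params: DigestParams | None = None
        self._digest_cache: dict[int, dict[str, int]] = {}

    # -- metadata ----------------------------------------------------------

    def _get_param(self, key: str) -> str | None:
        try:
            row = self.conn.execute(
                "SELECT value FROM DBParams WHERE key = ?", (key,)
            ).fetchone()
        except sqlite3.DatabaseError as exc:
            raise sqlite3.IntegrityError(f"{self.path}: not a valid PCDB") from exc
        return None if row is None else row[0]

    @property
    def params(self) -> DigestParams:
        """The digestion parameters stored at build time (authoritative)."""
        if self._params is None:
            get = self._get_param
            self._params = DigestParams(
                min_len=int(get("min_len")),
                max_len=int(get("max_len")),
                protease=_protease_from_str(get("protease")),
                max_missed_cleavages=int(get("max_missed_cleavages")),
                nterm_met_excision=get("nterm_met_excision") == "1",
                il_equivalence=get("il_equivalence") == "1",
            )
        return self._params

    @property
    def indexed(self) -> bool:
        return self._get_param("indexed") == "1"

    def n_proteins(self) -> int:
        return self.conn.execute("SELECT COUNT(*) FROM MainData").fetchone()[0]

    def n_reference_rows(self) -> int:
        return self.conn.execute("SELECT COUNT(*) FROM Reference").fetchone()[0]

    def close(self) -> None:
        self.conn.close()

    def __enter__(self) -> "PCDBHandle":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- queries -----------------------------------------------------------

    def _digest_of_protein(self, protein_id: int, sequence: str) -> dict[str, int]:
        cached = self._digest_cache.get(protein_id)
        if cached is None:
            cached = digest_sequence(sequence, self.params)
            if len(self._digest_cache) > 50_000:  # bound memory on huge scans
                self._digest_cache.clear()
            self._digest_cache[protein_id] = cached
        return cached

    def query_peptide(self, observed_sequence: str) -> set[tuple[str, int, str]]:
        return query_peptide(self, observed_sequence)


def open_pcdb(path: str | PathLike) -> PCDBHandle:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    return PCDBHandle(path)


# -- build ------------------------------------------------------------------

_WORKER_PARAMS: DigestParams | None = None


def _init_worker(params: DigestParams) -> None:
    global _WORKER_PARAMS
    _WORKER_PARAMS = params


def _digest_chunk(chunk: list[tuple[int, str]]) -> list[tuple[int, int]]:
    """Digest a chunk of (protein_id, sequence); return (hash, protein_id) rows."""
    params = _WORKER_PARAMS
    rows: list[tuple[int, int]] = []
    for protein_id, sequence in chunk:
        for canon in digest_sequence(sequence, params):
            rows.append((hash_peptide(canon), protein_id))
    return rows


def create_pcdb(
    records: Sequence[ProteinRecord],
    params: DigestParams,
    out_path: str | PathLike,
    workers: int = 1,
    overwrite: bool = False,
) -> PCDBHandle:
    """Digest ``records`` and write the peptide database at ``out_path``.

    The Reference row multiset is identical regardless of ``workers`` (the
    build partitions proteins, not peptides). Refuses to clobber an existing
    file unless ``overwrite``; on failure the partial file is removed.
    """
    records = list(records)
    if not records:
        raise ValueError("create_pcdb: empty record collection")
    out_path = os.fspath(out_path)
    if os.path.exists(out_path):
        if not overwrite:
            raise FileExistsError(f"{out_path} exists; pass overwrite=True")
        os.remove(out_path)
    conn = sqlite3.connect(out_path)
    try:
        conn.executescript(
            """
            PRAGMA journal_mode = OFF;
            PRAGMA synchronous = OFF;
            CREATE TABLE MainData (
                protein_id INTEGER PRIMARY KEY,
                accession  TEXT NOT NULL UNIQUE,
                sequence   TEXT NOT NULL,
                taxon_id   INTEGER NOT NULL,
                gene       TEXT NOT NULL
            );
            CREATE TABLE Reference (
                hash_peptide INTEGER NOT NULL,
                protein_id   INTEGER NOT NULL REFERENCES MainData(protein_id)
            );
            CREATE TABLE DBParams (key TEXT PRIMARY KEY, value TEXT NOT NULL);
            """
        )
        conn.executemany(
            "INSERT INTO MainData (protein_id, accession, sequence, taxon_id, gene)"
            " VALUES (?, ?, ?, ?, ?)",
            [
                (i, r.accession, r.sequence, r.taxon_id, r.gene)
                for i, r in enumerate(records, start=1)
            ],
        )
        jobs = [(i, r.sequence) for i, r in enumerate(records, start=1)]
        # chunked inserts bound peak memory; multiset content is unaffected
        if workers > 1:
            chunk_size = max(1, min(2000, len(jobs) // (workers * 4) + 1))
        else:
            chunk_size = 2000
        chunks = [jobs[i : i + chunk_size] for i in range(0, len(jobs), chunk_size)]
        if workers > 1 and len(chunks) > 1:
            ctx = multiprocessing.get_context()
            with ctx.Pool(workers, initializer=_init_worker, initargs=(params,)) as pool:
                for rows in pool.imap(_digest_chunk, chunks):
                    conn.executemany(
                        "INSERT INTO Reference (hash_peptide, protein_id) VALUES (?, ?)",
                        rows,
                    )
        else:
            _init_worker(params)
            for chunk in chunks:
                conn.executemany(
                    "INSERT INTO Reference (hash_peptide, protein_id) VALUES (?, ?)",
                    _digest_chunk(chunk),
                )
        meta = {
            "schema_version": SCHEMA_VERSION,
            "min_len": str(params.min_len),
            "max_len": str(params.max_len),
            "protease": _protease_to_str(params.protease),
            "max_missed_cleavages": str(params.max_missed_cleavages),
            "nterm_met_excision": "1" if params.nterm_met_excision else "0",
            "il_equivalence": "1" if params.il_equivalence else "0",
            "indexed": "0",
        }
        conn.executemany(
            "INSERT INTO DBParams (key, value) VALUES (?, ?)", meta.items()
        )
        conn.commit()
    except BaseException:
        conn.close()
        if os.path.exists(out_path):
            os.remove(out_path)
        raise
    conn.close()
    logger.info("built PCDB at %s (%d proteins)", out_path, len(records))
    return PCDBHandle(out_path)


def index_pcdb(handle: PCDBHandle) -> PCDBHandle:
    """Create the hash-peptide index (idempotent); records the flag in DBParams.

    Kept separate from :func:`create_pcdb` so insertion cost scales linearly
    with protein count and the (one-off) index build is paid at the end.
    """
    if handle.indexed:
        return handle
    try:
        handle.conn.execute(
            "CREATE INDEX IF NOT EXISTS idx_reference_hash"
            " ON Reference (hash_peptide)"
        )
        handle.conn.execute(
            "UPDATE DBParams SET value = '1' WHERE key = 'indexed'"
        )
        handle.conn.commit()
    except sqlite3.DatabaseError as exc:
        raise sqlite3.IntegrityError(f"{handle.path}: cannot index") from exc
    return handle


def query_peptide(
    handle: PCDBHandle, observed_sequence: str
) -> set[tuple[str, int, str]]:
    """Look up an observed peptide; return ``{(accession, taxon_id, gene)}``.

    The sequence is canonicalized with the database's stored parameters,
    hashed, and each hash hit is verified against the parent protein's digest
    products before inclusion (collision safety). A peptide outside the
    stored length bounds simply returns the empty set.
    """
    if not observed_sequence:
        return set()
    params = handle.params
    canon = canonicalize(observed_sequence, params.il_equivalence)
    if not (params.min_len <= len(canon) <= params.max_len):
        return set()
    h = hash_peptide(canon)
    rows = handle.conn.execute(
        "SELECT DISTINCT m.protein_id, m.accession, m.sequence, m.taxon_id, m.gene"
        " FROM Reference r JOIN MainData m ON m.protein_id = r.protein_id"
        " WHERE r.hash_peptide = ?",
        (h,),
    ).fetchall()
    hits: set[tuple[str, int, str]] = set()
    for protein_id, accession, sequence, taxon_id, gene in rows:
        if canon in handle._digest_of_protein(protein_id, sequence):
            hits.add((accession, taxon_id, gene))
    return hits
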