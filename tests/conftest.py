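"""Shared fixtures and the independent brute-force digestion oracle.

The oracle enumerates *all* substrings of a protein and accepts one iff its
boundaries are termini or cleavage sites, its internal cut count is within
the missed-cleavage budget, and it passes the length window — a structurally
different algorithm from the fragment-concatenation implementation, so
agreement is meaningful. Cleavage-site predicates are hand-written per
protease here, independent of the package's rule table.
"""

from __future__ import annotations

import random

import pytest

from taxopept.digest import canonicalize
from taxopept.proteomes import ProteinRecord

AMBIGUOUS = set("XUBZ")

#: Hand-written cut-after predicates (seq, pos) -> bool, one per protease.
ORACLE_RULES = {
    "trypsin/p": lambda s, p: s[p] in "KR",
    "trypsin": lambda s, p: s[p] in "KR" and s[p + 1] != "P",
    "lys-c": lambda s, p: s[p] == "K",
    "glu-c": lambda s, p: s[p] == "E",
    "chymotrypsin": lambda s, p: s[p] in "FWY" and s[p + 1] != "P",
}


def oracle_digest(
    sequence: str,
    protease: str = "trypsin/p",
    min_len: int = 7,
    max_len: int = 55,
    max_missed: int = 2,
    met_excision: bool = True,
    il_equivalence: bool = True,
) -> dict[str, int]:
    """Brute-force reference digest: canonical peptide -> min missed count."""
    seq = sequence.upper()
    n = len(seq)
    rule = ORACLE_RULES[protease]
    sites = {p for p in range(n - 1) if rule(seq, p)}
    valid_start = {0} | {p + 1 for p in sites}
    valid_end = {n} | {p + 1 for p in sites}
    out: dict[str, int] = {}

    def emit(pep: str, missed: int) -> None:
        if not (min_len <= len(pep) <= max_len):
            return
        if AMBIGUOUS & set(pep):
            return
        canon = canonicalize(pep, il_equivalence)
        if canon not in out or missed < out[canon]:
            out[canon] = missed

    for i in valid_start:
        for j in valid_end:
            if j <= i:
                continue
            internal = sum(1 for p in sites if i <= p < j - 1)
            if internal > max_missed:
                continue
            emit(seq[i:j], internal)
            if i == 0 and met_excision and seq[0] == "M":
                emit(seq[1:j], internal)
    return out


def random_protein(rng: random.Random, max_len: int = 200, alphabet: str | None = None) -> str:
    letters = alphabet or "ACDEFGHIKLMNPQRSTVWYM"  # M overweighted for excision
    length = rng.randint(10, max_len)
    return "".join(rng.choice(letters) for _ in range(length))


@pytest.fixture
def rng() -> random.Random:
    return random.Random(42)


@pytest.fixture
def toy_records() -> list[ProteinRecord]:
    """A tiny two-species proteome with planted unique and shared peptides.

    Taxa 9606 ("human-like") and 10090 ("mouse-like"). The peptide
    HAPPYWDAYK is planted only in P_H1, NLCEMEATK only in P_M1, and
    SHAREDPEPTLDEK in one protein of each species (gene SHR in both).
    """
    return [
        ProteinRecord("P_H1", "GH1", 9606, "MHAPPYWDAYKSHAREDPEPTLDEKVVNQAESTR"),
        ProteinRecord("P_H2", "GH2", 9606, "MFEELGNDAWKTTPWQESCVR"),
        ProteinRecord("P_M1", "GM1", 10090, "MNLCEMEATKSHAREDPEPTLDEKGGWNQFESTR"),
        ProteinRecord("P_M2", "GM2", 10090, "MDDAYWGNNVKAAPLQESCFR"),
    ]
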