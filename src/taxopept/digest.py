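"""In-silico proteolysis, peptide canonicalization, and stable 64-bit hashing.

Bottom-up proteomics observes peptides, not proteins, so reference proteomes
are digested in silico under the same rules the experimental protease obeys:
a cleavage-site predicate (trypsin/p by default: cut C-terminal to K or R,
proline allowed), a missed-cleavage budget, a length window, optional
N-terminal methionine excision, and I/L collapse (isoleucine and leucine are
isobaric and indistinguishable by standard MS2).

Canonical peptides are stored as 64-bit integers: the first 8 bytes of the
BLAKE2b digest of the canonical sequence, read little-endian as a signed
integer. This is a documented, platform- and process-stable function, so
databases built on one machine are queryable on another.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

__all__ = [
    "CleavageRule",
    "DigestParams",
    "PeptideKey",
    "PROTEASES",
    "cleavage_sites",
    "digest_protein",
    "digest_sequence",
    "hash_peptide",
    "canonicalize",
]

#: Residues that cannot be matched by an observed sequence; any peptide
#: containing one is excluded from hashing (the protein itself is kept).
AMBIGUOUS_RESIDUES = frozenset("XUBZ")


@dataclass(frozen=True)
class CleavageRule:
    """A deterministic cleavage-site predicate on (residue, next residue).

    ``side='C'`` cuts C-terminal to a residue in ``residues`` unless the next
    residue is in ``blocked_next`` (classic protease notation, e.g. strict
    trypsin blocks proline). ``side='N'`` cuts N-terminal to a residue in
    ``residues`` (e.g. Asp-N), i.e. after position p when residue p+1 matches.
    """

    residues: frozenset[str]
    blocked_next: frozenset[str] = frozenset()
    side: str = "C"

    def __post_init__(self) -> None:
        if self.side not in ("C", "N"):
            raise ValueError("cleavage side must be 'C' or 'N'")

    def cuts_after(self, sequence: str, pos: int) -> bool:
        """Whether a cut occurs after 0-based position ``pos`` (never after
        the final residue)."""
        if pos >= len(sequence) - 1:
            return False
        if self.side == "C":
            return (
                sequence[pos] in self.residues
                and sequence[pos + 1] not in self.blocked_next
            )
        return (
            sequence[pos + 1] in self.residues
            and sequence[pos] not in self.blocked_next
        )


PROTEASES: Mapping[str, CleavageRule] = {
    "trypsin/p": CleavageRule(frozenset("KR")),
    "trypsin": CleavageRule(frozenset("KR"), frozenset("P")),
    "lys-c": CleavageRule(frozenset("K")),
    "chymotrypsin": CleavageRule(frozenset("FWY"), frozenset("P")),
    "glu-c": CleavageRule(frozenset("E")),
    "asp-n": CleavageRule(frozenset("D"), side="N"),
}


def resolve_protease(protease: str | CleavageRule) -> CleavageRule:
    if isinstance(protease, CleavageRule):
        return protease
    try:
        return PROTEASES[protease.lower()]
    except KeyError:
        raise ValueError(
            f"unknown protease {protease!r}; built-ins: {sorted(PROTEASES)}"
        ) from None


@dataclass(frozen=True)
class DigestParams:
    """The full rule set governing in-silico digestion and canonicalization.

    Defaults are the standard bottom-up settings: 7–55 residue peptides,
    trypsin/p, up to 2 missed cleavages, N-terminal Met excision, and I/L
    equivalence.
    """

    min_len: int = 7
    max_len: int = 55
    protease: str | CleavageRule = "trypsin/p"
    max_missed_cleavages: int = 2
    nterm_met_excision: bool = True
    il_equivalence: bool = True

    def __post_init__(self) -> None:
        if not (1 <= self.min_len <= self.max_len):
            raise ValueError("need 1 <= min_len <= max_len")
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages must be >= 0")
        resolve_protease(self.protease)  # fail fast on unknown rule

    @property
    def rule(self) -> CleavageRule:
        return resolve_protease(self.protease)

    def with_protease(self, protease: str | CleavageRule) -> "DigestParams":
        return replace(self, protease=protease)


@dataclass(frozen=True)
class PeptideKey:
    """A canonical peptide and its stable 64-bit hash."""

    canonical_sequence: str
    hash64: int = field(hash=False, compare=False, default=0)

    @classmethod
    def from_sequence(cls, canonical_sequence: str) -> "PeptideKey":
        return cls(canonical_sequence, hash_peptide(canonical_sequence))


def canonicalize(sequence: str, il_equivalence: bool = True) -> str:
    """Uppercase and, when I/L equivalence is on, collapse I onto L."""
    seq = sequence.upper()
    return seq.replace("I", "L") if il_equivalence else seq


def hash_peptide(canonical_sequence: str) -> int:
    """Stable signed 64-bit hash of a canonical peptide sequence.

    First 8 bytes of BLAKE2b(seq), little-endian, signed — identical across
    runs, platforms, and processes.
    """
    if not canonical_sequence:
        raise ValueError("cannot hash an empty peptide")
    digest = hashlib.blake2b(canonical_sequence.encode("ascii"), digest_size=8)
    return int.from_bytes(digest.digest(), "little", signed=True)


def cleavage_sites(sequence: str, protease: str | CleavageRule) -> list[int]:
    """0-based positions AFTER which a cut occurs.

    For trypsin/p this is every K or R position except the final residue.
    """
    if not sequence:
        raise ValueError("empty sequence")
    rule = resolve_protease(protease)
    return [p for p in range(len(sequence) - 1) if rule.cuts_after(sequence, p)]


def digest_sequence(sequence: str, params: DigestParams) -> dict[str, int]:
    """Digest a residue string; return ``{canonical peptide: missed cleavages}``.

    Peptides span whole inter-cut fragments, carry at most
    ``max_missed_cleavages`` internal cut sites, and pass the length window.
    When Met excision is on and the protein starts with M, every peptide
    anchored at position 0 also contributes its Met-less variant
    (length-checked independently; the Met-bearing form is kept too). Peptides
    containing ambiguous residues (X/U/B/Z) are dropped. When the same
    canonical sequence arises more than once the smallest missed-cleavage
    count is kept.
    """
    seq = sequence.upper()
    sites = cleavage_sites(seq, params.rule) if seq else []
    boundaries = [0] + [p + 1 for p in sites] + [len(seq)]
    n_frag = len(boundaries) - 1
    out: dict[str, int] = {}

    def emit(peptide: str, missed: int) -> None:
        if not (params.min_len <= len(peptide) <= params.max_len):
            return
        if AMBIGUOUS_RESIDUES & set(peptide):
            return
        canon = canonicalize(peptide, params.il_equivalence)
        prev = out.get(canon)
        if prev is None or missed < prev:
            out[canon] = missed

    for i in range(n_frag):
        start = boundaries[i]
        for j in range(i, min(i + params.max_missed_cleavages + 1, n_frag)):
            end = boundaries[j + 1]
            missed = j - i
            peptide = seq[start:end]
            emit(peptide, missed)
            if start == 0 and params.nterm_met_excision and seq[0] == "M":
                emit(peptide[1:], missed)
    return out


def digest_protein(record, params: DigestParams) -> dict[str, int]:
    """Digest a :class:`~taxopept.proteomes.ProteinRecord` (or anything with a
    ``sequence`` attribute); see :func:`digest_sequence`."""
    return digest_sequence(record.sequence, params)


def digest_keys(sequence: str, params: DigestParams) -> Iterable[PeptideKey]:
    """Digest and hash in one pass."""
    for canon in digest_sequence(sequence, params):
        yield PeptideKey.from_sequence(canon)
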