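"""Database-constrained annotation of de-novo sequencing candidates with
decoy-based genus-level false-discovery control.

De-novo engines emit several candidate sequences per MS/MS spectrum, ranked
by an average local confidence (ALC) score, but no reference database and no
FDR control. The pipeline here: (1) drop low-confidence candidates;
(2) per spectrum, serially test candidates (best first) against a peptide
database until one matches — biological plausibility constraint; (3) collapse
modified forms, keep genus-unique peptides with enough spectral support and a
taxon allowlist; (4) repeat everything against a reversed-sequence decoy
database and rank genera by Δ = forward − reverse counts, accepting genera
above a Δ threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from os import PathLike
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotate import strip_modifications
from .digest import canonicalize
from .pcdb import PCDBHandle, query_peptide
from .taxonomy import TaxonomyIndex, lineage

logger = logging.getLogger(__name__)

__all__ = [
    "DeNovoParams",
    "DeNovoCandidateSet",
    "AcceptedPeptide",
    "DEFAULT_TAXON_ALLOWLIST",
    "read_candidates",
    "constrain_to_db",
    "genus_unique_counts",
    "decoy_delta",
]

#: Retention rule for the oral-microbiome-style analysis: keep peptides whose
#: taxa fall in the bacterial superkingdom or are the human species. This is
#: study-specific and fully configurable.
DEFAULT_TAXON_ALLOWLIST: tuple[tuple[str, str], ...] = (
    ("superkingdom", "Bacteria"),
    ("species", "Homo sapiens"),
)


@dataclass(frozen=True)
class DeNovoParams:
    """Tunables for the de-novo pipeline (defaults are the published ones)."""

    min_alc: float = 50.0
    min_spectral_counts: int = 2
    rank_for_uniqueness: str = "genus"
    delta_threshold: int = 7
    mode: str = "database_constrained"  # or "top_candidate"
    taxon_allowlist: tuple[tuple[str, str], ...] | None = DEFAULT_TAXON_ALLOWLIST

    def __post_init__(self) -> None:
        if not (0 <= self.min_alc <= 100):
            raise ValueError("min_alc must be in [0, 100]")
        if self.min_spectral_counts < 1:
            raise ValueError("min_spectral_counts must be >= 1")
        if self.delta_threshold < 0:
            raise ValueError("delta_threshold must be >= 0")
        if self.mode not in ("database_constrained", "top_candidate"):
            raise ValueError("mode must be database_constrained or top_candidate")


@dataclass
class DeNovoCandidateSet:
    """Per spectrum: candidates ordered by descending ALC (ties keep the
    engine's emission order)."""

    candidates: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    n_rejected: int = 0

    def __len__(self) -> int:
        return len(self.candidates)

    def spectra(self) -> Iterable[str]:
        return self.candidates.keys()


@dataclass(frozen=True)
class AcceptedPeptide:
    """The peptide accepted for one spectrum, with its database hits."""

    spectrum: str
    sequence: str  # modification-stripped, as observed
    alc: float
    hits: frozenset[tuple[str, int, str]]  # (accession, taxon_id, gene)


def read_candidates(
    csv_path: str | PathLike,
    spectrum_col: str = "Scan",
    peptide_col: str = "Peptide",
    alc_col: str = "ALC (%)",
) -> DeNovoCandidateSet:
    """Read a de-novo candidates CSV, grouped by spectrum and ALC-sorted.

    Rows with an ALC outside [0, 100] are rejected with a warning and counted.
    Column names are configurable to accommodate engine dialects.
    """
    table = pd.read_csv(csv_path)
    missing = [c for c in (spectrum_col, peptide_col, alc_col) if c not in table.columns]
    if missing:
        raise KeyError(
            f"candidates file lacks columns {missing}; present: {list(table.columns)}"
        )
    out = DeNovoCandidateSet()
    for _, row in table.iterrows():
        alc = float(row[alc_col])
        if not (0 <= alc <= 100):
            logger.warning(
                "rejected candidate with out-of-range ALC %.1f (spectrum %s)",
                alc,
                row[spectrum_col],
            )
            out.n_rejected += 1
            continue
        out.candidates.setdefault(str(row[spectrum_col]), []).append(
            (str(row[peptide_col]), alc)
        )
    for spectrum in out.candidates:
        # stable sort: equal-ALC candidates keep input order
        out.candidates[spectrum].sort(key=lambda c: -c[1])
    return out


def constrain_to_db(
    candidates: DeNovoCandidateSet,
    handle: PCDBHandle,
    params: DeNovoParams,
) -> dict[str, AcceptedPeptide]:
    """Accept at most one peptide per spectrum by database matching.

    ``database_constrained``: candidates at or above the ALC floor are tested
    best-first and the first with any database hit wins; ``top_candidate``:
    only the single best candidate is tested. Modification tags are stripped
    before lookup. Spectra with no matching candidate are absent from the
    result.
    """
    accepted: dict[str, AcceptedPeptide] = {}
    query_cache: dict[str, frozenset[tuple[str, int, str]]] = {}
    for spectrum, cand_list in candidates.candidates.items():
        eligible = [(p, a) for p, a in cand_list if a >= params.min_alc]
        if params.mode == "top_candidate":
            eligible = eligible[:1]
        for peptide, alc in eligible:
            stripped = strip_modifications(peptide)
            if not stripped:
                continue
            if stripped not in query_cache:
                query_cache[stripped] = frozenset(query_peptide(handle, stripped))
            hits = query_cache[stripped]
            if hits:
                accepted[spectrum] = AcceptedPeptide(
                    spectrum=spectrum, sequence=stripped, alc=alc, hits=hits
                )
                break
    return accepted


def genus_unique_counts(
    accepted: Mapping[str, AcceptedPeptide],
    index: TaxonomyIndex,
    params: DeNovoParams,
) -> dict[str, int]:
    """Spectral counts per genus over genus-unique, allowlisted peptides.

    Modified and unmodified observations of the same (I/L-canonical) stripped
    sequence are pooled for spectral counting across all spectra in the run.
    A peptide is retained iff (a) all its hits resolve to a single taxon at
    ``params.rank_for_uniqueness``, (b) its pooled spectral count is at least
    ``min_spectral_counts``, and (c) when an allowlist is set, at least one
    (rank, name) entry matches its resolved lineage.
    """
    rank = params.rank_for_uniqueness
    allow = params.taxon_allowlist
    allow_ranks = sorted({r for r, _ in allow}) if allow else []
    # Pool spectra by canonical stripped sequence (PTM + I/L collapse).
    by_peptide: dict[str, list[AcceptedPeptide]] = {}
    for acc in accepted.values():
        key = canonicalize(acc.sequence, il_equivalence=True)
        by_peptide.setdefault(key, []).append(acc)
    counts: dict[str, int] = {}
    lineage_cache: dict[int, dict[str, tuple[int, str]]] = {}

    def resolve(taxon_id: int) -> dict[str, tuple[int, str]]:
        if taxon_id not in lineage_cache:
            lineage_cache[taxon_id] = lineage(
                index, taxon_id, [rank, *allow_ranks]
            )
        return lineage_cache[taxon_id]

    for key, observations in by_peptide.items():
        spectral_count = len(observations)
        if spectral_count < params.min_spectral_counts:
            continue
        hits = observations[0].hits  # same canonical sequence -> same hits
        labels = {
            (res := resolve(t).get(rank)) and res[1] for _, t, _ in hits
        }
        if len(labels) != 1 or None in labels:
            continue  # not genus-unique
        (genus,) = labels
        if allow is not None:
            allowed = any(
                any(
                    (res := resolve(t).get(r)) is not None and res[1] == n
                    for _, t, _ in hits
                )
                for r, n in allow
            )
            if not allowed:
                continue
        counts[genus] = counts.get(genus, 0) + spectral_count
    return counts


def decoy_delta(
    forward_counts: Mapping[str, int],
    reverse_counts: Mapping[str, int],
    params: DeNovoParams,
) -> pd.DataFrame:
    """Rank genera by Δ = forward − reverse spectral counts.

    Genera absent from one map count 0 there. Returns a table indexed by
    genus with columns ``forward``, ``reverse``, ``delta``, ``accepted``
    (Δ strictly above ``params.delta_threshold``), sorted by Δ descending
    (ties: genus name).
    """
    genera = sorted(set(forward_counts) | set(reverse_counts))
    rows = []
    for g in genera:
        fwd = int(forward_counts.get(g, 0))
        rev = int(reverse_counts.get(g, 0))
        rows.append(
            {
                "genus": g,
                "forward": fwd,
                "reverse": rev,
                "delta": fwd - rev,
                "accepted": (fwd - rev) > params.delta_threshold,
            }
        )
    out = pd.DataFrame(
        rows, columns=["genus", "forward", "reverse", "delta", "accepted"]
    )
    if len(out):
        out = out.sort_values(
            ["delta", "genus"], ascending=[False, True]
        ).set_index("genus")
    else:
        out = out.set_index("genus")
    return out
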