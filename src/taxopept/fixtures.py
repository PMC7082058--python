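"""Deterministic synthetic fixtures: toy taxonomies, homolog-bearing
proteomes, search-result tables, and de-novo candidate sets.

Proteins are generated fragment-wise — blocks of non-K/R residues terminated
by K or R — so their tryptic digest is controlled by construction: every
protein's peptide set is exactly its fragments and their adjacent
concatenations (plus N-terminal-Met variants), which the generator enumerates
itself into a ground-truth manifest. Downstream tests read truth only from
manifests, never from the pipeline under test.

Homolog pairs share an engineered number of whole fragments, so the designed
shared-peptide fraction is exact under a 0-missed-cleavage digest (with
missed cleavages, concatenations spanning a shared/unshared boundary dilute
the fraction; the manifest records the exact peptide sets either way).

Every generator is a pure function of its spec: same seed, byte-identical
output.
"""

from __future__ import annotations

import os
import random
from dataclasses import dataclass, field
from os import PathLike
from typing import Iterable, Sequence

import pandas as pd

from .digest import DigestParams, canonicalize, digest_sequence
from .proteomes import ProteinRecord, write_fasta

__all__ = [
    "FixtureSpec",
    "FixtureManifest",
    "make_taxonomy",
    "taxonomy_layout",
    "make_proteomes",
    "make_search_results",
    "make_denovo_candidates",
]

#: Interior fragment alphabet: no K/R (cleavage), no I (so I/L tests can
#: mutate L->I), no ambiguity codes, no M (reserved for protein N-termini).
_FRAGMENT_ALPHABET = "ACDEFGHLNPQSTVWY"

SUPERKINGDOM_NAME = "Bacteria"
ROOT_ID = 1
SUPERKINGDOM_ID = 2


@dataclass(frozen=True)
class FixtureSpec:
    """The stated world of one synthetic data set."""

    seed: int = 0
    n_genera: int = 3
    species_per_genus: int = 2
    proteins_per_species: int = 5
    protein_length: tuple[int, int] = (80, 160)
    homolog_pairs: int = 2
    homolog_shared_fraction: float = 0.4
    homolog_fragments: int = 5
    planted_unique_peptides: int = 2
    quant_channels: int = 4
    noise_rate: float = 0.1


def _genus_id(i: int) -> int:
    return 10 + i


def _species_id(genus_idx: int, species_idx: int) -> int:
    return 100 + genus_idx * 100 + species_idx


def taxonomy_layout(spec: FixtureSpec) -> dict:
    """Deterministic IDs/names for the fixture taxonomy tree."""
    genera = {
        _genus_id(i): f"Genus{i}" for i in range(spec.n_genera)
    }
    species: dict[int, tuple[int, str]] = {}
    for i in range(spec.n_genera):
        for j in range(spec.species_per_genus):
            species[_species_id(i, j)] = (_genus_id(i), f"Genus{i} species{j}")
    return {"genera": genera, "species": species}


def make_taxonomy(spec: FixtureSpec, out_dir: str | PathLike) -> tuple[str, str]:
    """Write taxdump-dialect ``nodes.dmp``/``names.dmp`` for the fixture tree:
    root -> superkingdom -> genera -> species. Returns the two paths."""
    layout = taxonomy_layout(spec)
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    nodes_path = os.path.join(out_dir, "nodes.dmp")
    names_path = os.path.join(out_dir, "names.dmp")
    nodes: list[tuple[int, int, str]] = [
        (ROOT_ID, ROOT_ID, "no rank"),
        (SUPERKINGDOM_ID, ROOT_ID, "superkingdom"),
    ]
    names: list[tuple[int, str]] = [
        (ROOT_ID, "root"),
        (SUPERKINGDOM_ID, SUPERKINGDOM_NAME),
    ]
    for gid, gname in layout["genera"].items():
        nodes.append((gid, SUPERKINGDOM_ID, "genus"))
        names.append((gid, gname))
    for sid, (gid, sname) in layout["species"].items():
        nodes.append((sid, gid, "species"))
        names.append((sid, sname))
    with open(nodes_path, "w", encoding="utf-8") as fh:
        for tax_id, parent, rank in nodes:
            fh.write(f"{tax_id}\t|\t{parent}\t|\t{rank}\t|\n")
    with open(names_path, "w", encoding="utf-8") as fh:
        for tax_id, name in names:
            fh.write(f"{tax_id}\t|\t{name}\t|\t\t|\tscientific name\t|\n")
    return nodes_path, names_path


@dataclass
class FixtureManifest:
    """Ground truth for one generated proteome.

    ``peptides`` enumerates every default-digest product of every protein
    (canonical sequence, protein, gene, taxon, genus, missed-cleavage count)
    computed from the generator's own fragment bookkeeping — an oracle
    independent of the digestion code under test.
    """

    proteins: pd.DataFrame
    peptides: pd.DataFrame
    planted: pd.DataFrame
    homologs: pd.DataFrame
    fragments: dict[str, list[str]] = field(default_factory=dict)

    def peptide_hits(self, canonical: str) -> set[tuple[str, int, str]]:
        """All (accession, taxon_id, gene) truly producing this peptide."""
        sub = self.peptides[self.peptides["peptide"] == canonical]
        return set(
            zip(sub["accession"], sub["taxon_id"].astype(int), sub["gene"])
        )

    def all_peptides(self) -> set[str]:
        return set(self.peptides["peptide"])

    def write(self, out_dir: str | PathLike) -> None:
        out_dir = os.fspath(out_dir)
        os.makedirs(out_dir, exist_ok=True)
        for name in ("proteins", "peptides", "planted", "homologs"):
            getattr(self, name).to_csv(
                os.path.join(out_dir, f"{name}.tsv"), sep="\t", index=False
            )


def _new_fragment(
    rng: random.Random, used: set[str], start_met: bool = False
) -> str:
    """A K/R-terminated fragment, globally unique within the fixture."""
    while True:
        interior = "".join(
            rng.choice(_FRAGMENT_ALPHABET) for _ in range(rng.randint(6, 11))
        )
        frag = ("M" if start_met else "") + interior + rng.choice("KR")
        if frag not in used and (not start_met or frag[1:] not in used):
            used.add(frag)
            if start_met:
                used.add(frag[1:])
            return frag


def _enumerate_truth_peptides(
    fragments: Sequence[str], max_missed: int = 2
) -> dict[str, int]:
    """Independent enumeration of the default digest of a fragment-built
    protein: runs of <= max_missed+1 fragments, plus Met-less variants of
    protein-N-terminal peptides; length window 7-55; I->L canonical."""
    out: dict[str, int] = {}

    def emit(pep: str, missed: int) -> None:
        if 7 <= len(pep) <= 55:
            canon = canonicalize(pep, True)
            if canon not in out or missed < out[canon]:
                out[canon] = missed
    n = len(fragments)
    for i in range(n):
        for j in range(i, min(i + max_missed + 1, n)):
            pep = "".join(fragments[i : j + 1])
            emit(pep, j - i)
            if i == 0 and fragments[0].startswith("M"):
                emit(pep[1:], j - i)
    return out


def make_proteomes(
    spec: FixtureSpec,
    out_fasta: str | PathLike | None = None,
) -> tuple[list[ProteinRecord], FixtureManifest]:
    """Generate the fixture proteome and its ground-truth manifest.

    Each species gets ``proteins_per_species`` Met-initial proteins of
    ~``protein_length`` residues plus ``planted_unique_peptides`` marked
    genus-unique fragments. The first ``homolog_pairs`` genera pairs
    (cyclically) each share a gene whose proteins (non-Met-initial,
    ``homolog_fragments`` fragments) share exactly
    ``round(homolog_shared_fraction * homolog_fragments)`` fragments.
    """
    rng = random.Random(spec.seed)
    layout = taxonomy_layout(spec)
    used: set[str] = set()
    records: list[ProteinRecord] = []
    protein_rows: list[dict] = []
    peptide_rows: list[dict] = []
    planted_rows: list[dict] = []
    homolog_rows: list[dict] = []
    fragments_of: dict[str, list[str]] = {}
    genus_name = dict(layout["genera"])

    def add_protein(
        accession: str,
        gene: str,
        taxon_id: int,
        gid: int,
        fragments: list[str],
        is_homolog: bool = False,
    ) -> None:
        seq = "".join(fragments)
        records.append(ProteinRecord(accession, gene, taxon_id, seq))
        fragments_of[accession] = list(fragments)
        protein_rows.append(
            {
                "accession": accession,
                "gene": gene,
                "taxon_id": taxon_id,
                "genus": genus_name[gid],
                "n_fragments": len(fragments),
                "is_homolog": is_homolog,
            }
        )
        for pep, missed in _enumerate_truth_peptides(fragments).items():
            peptide_rows.append(
                {
                    "peptide": pep,
                    "accession": accession,
                    "gene": gene,
                    "taxon_id": taxon_id,
                    "genus": genus_name[gid],
                    "missed": missed,
                }
            )

    # ordinary species proteins
    for sid, (gid, _sname) in layout["species"].items():
        for p in range(spec.proteins_per_species):
            accession = f"P{sid}_{p}"
            gene = f"G{sid}_{p}"
            target = rng.randint(*spec.protein_length)
            frags = [_new_fragment(rng, used, start_met=True)]
            while sum(map(len, frags)) < target:
                frags.append(_new_fragment(rng, used))
            add_protein(accession, gene, sid, gid, frags)
            if p == 0:
                # planted genus-unique peptides: interior fragments, globally
                # unique by construction
                for k in range(min(spec.planted_unique_peptides, len(frags) - 1)):
                    planted_rows.append(
                        {
                            "peptide": canonicalize(frags[k + 1], True),
                            "accession": accession,
                            "gene": gene,
                            "taxon_id": sid,
                            "genus": genus_name[gid],
                        }
                    )

    # homolog pairs across genera (cyclic over available genera)
    if spec.n_genera >= 2:
        for k in range(spec.homolog_pairs):
            gid_a = _genus_id(k % spec.n_genera)
            gid_b = _genus_id((k + 1) % spec.n_genera)
            sid_a = _species_id(k % spec.n_genera, 0)
            sid_b = _species_id((k + 1) % spec.n_genera, 0)
            n = spec.homolog_fragments
            n_shared = round(spec.homolog_shared_fraction * n)
            frags_a = [_new_fragment(rng, used) for _ in range(n)]
            frags_b = list(frags_a[:n_shared]) + [
                _new_fragment(rng, used) for _ in range(n - n_shared)
            ]
            gene = f"HOM{k}"
            add_protein(f"HA{k}", gene, sid_a, gid_a, frags_a, is_homolog=True)
            add_protein(f"HB{k}", gene, sid_b, gid_b, frags_b, is_homolog=True)
            homolog_rows.append(
                {
                    "gene": gene,
                    "accession_a": f"HA{k}",
                    "accession_b": f"HB{k}",
                    "taxon_a": sid_a,
                    "taxon_b": sid_b,
                    "n_fragments": n,
                    "n_shared": n_shared,
                    "designed_fraction": n_shared / n,
                }
            )

    manifest = FixtureManifest(
        proteins=pd.DataFrame(protein_rows),
        peptides=pd.DataFrame(peptide_rows),
        planted=pd.DataFrame(
            planted_rows,
            columns=["peptide", "accession", "gene", "taxon_id", "genus"],
        ),
        homologs=pd.DataFrame(
            homolog_rows,
            columns=[
                "gene",
                "accession_a",
                "accession_b",
                "taxon_a",
                "taxon_b",
                "n_fragments",
                "n_shared",
                "designed_fraction",
            ],
        ),
        fragments=fragments_of,
    )
    if out_fasta is not None:
        write_fasta(records, out_fasta)
    return records, manifest


def _random_absent_peptide(
    rng: random.Random, manifest_peptides: set[str], length: int = 12
) -> str:
    while True:
        pep = (
            "".join(rng.choice(_FRAGMENT_ALPHABET) for _ in range(length - 1))
            + rng.choice("KR")
        )
        if canonicalize(pep, True) not in manifest_peptides:
            return pep


def make_search_results(
    spec: FixtureSpec,
    manifest: FixtureManifest,
    out_path: str | PathLike | None = None,
    peptides_per_protein: int = 3,
    mod_rate: float = 0.2,
    il_swap_rate: float = 0.2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a peptide-level search-engine table with TMT-style channels.

    Samples true single-fragment peptides from the manifest plus contaminant
    rows (``noise_rate`` of the total) absent from the proteome. Channel
    intensities are log-normal; channel 0 ("Reporter intensity 0") is the
    internal reference pool. Some observed sequences carry modification tags
    and L->I rewrites to exercise canonicalization. Returns (table, truth);
    truth rows carry the canonical peptide and a contaminant flag.
    """
    rng = random.Random(spec.seed + 1)
    truth_pep = manifest.all_peptides()
    rows: list[dict] = []
    truth_rows: list[dict] = []
    channels = [f"Reporter intensity {i}" for i in range(spec.quant_channels)]

    def intensities() -> dict[str, float]:
        return {c: round(rng.lognormvariate(10.0, 1.0), 3) for c in channels}

    singles = manifest.peptides[manifest.peptides["missed"] == 0]
    for accession, sub in singles.groupby("accession", sort=True):
        chosen = sub["peptide"].tolist()[:peptides_per_protein]
        for pep in chosen:
            observed = pep
            if rng.random() < il_swap_rate and "L" in observed:
                i = observed.index("L")
                observed = observed[:i] + "I" + observed[i + 1 :]
            if rng.random() < mod_rate:
                j = rng.randrange(len(observed))
                observed = observed[: j + 1] + "(+15.99)" + observed[j + 1 :]
            rows.append({"Sequence": observed, **intensities()})
            truth_rows.append(
                {
                    "Sequence": observed,
                    "peptide": pep,
                    "is_contaminant": False,
                }
            )
    n_contaminants = int(round(spec.noise_rate * len(rows)))
    for _ in range(n_contaminants):
        pep = _random_absent_peptide(rng, truth_pep)
        rows.append({"Sequence": pep, **intensities()})
        truth_rows.append(
            {"Sequence": pep, "peptide": canonicalize(pep, True), "is_contaminant": True}
        )
    table = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    if out_path is not None:
        table.to_csv(out_path, sep="\t", index=False)
    return table, truth


def make_denovo_candidates(
    spec: FixtureSpec,
    manifest: FixtureManifest,
    records: Sequence[ProteinRecord],
    out_path: str | PathLike | None = None,
    n_planted_genera: int = 6,
    peptides_per_genus: int = 10,
    spectra_per_peptide: int = 2,
    second_rank_fraction: float = 0.3,
    noise_peptides_per_genus: int = 10,
    digest_params: DigestParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a de-novo candidates table with known per-spectrum truth.

    The first ``n_planted_genera`` genera are "present": each contributes
    ``peptides_per_genus`` genus-unique true peptides observed in
    ``spectra_per_peptide`` spectra. In a ``second_rank_fraction`` of those
    spectra the true peptide sits at rank 2 behind a database-absent decoy
    candidate (the database-constrained vs top-candidate contrast). The
    remaining genera are "noise": their candidates are digest products of the
    REVERSED fixture proteins, so they match only a reversed-decoy database.
    Returns (candidates table, truth table with spectrum/genus/kind).
    """
    rng = random.Random(spec.seed + 2)
    params = digest_params or DigestParams()
    truth_pep = manifest.all_peptides()
    genera = sorted(manifest.proteins["genus"].unique())
    planted = genera[:n_planted_genera]
    noise_genera = genera[n_planted_genera:]

    # genus-unique true peptides: fragments seen in exactly one genus
    pep_genera = manifest.peptides.groupby("peptide")["genus"].agg(set)
    unique_map = {p: next(iter(g)) for p, g in pep_genera.items() if len(g) == 1}

    rows: list[dict] = []
    truth_rows: list[dict] = []
    scan = 0

    def add_spectrum(true_pep: str | None, genus: str, kind: str, fillers: list[str]):
        nonlocal scan
        scan += 1
        spectrum = f"F1:{scan}"
        cand: list[tuple[str, float]] = []
        rank_of_truth = 0
        if true_pep is not None:
            at_second = rng.random() < second_rank_fraction
            if at_second and fillers:
                cand.append((fillers.pop(), 99.0))
                cand.append((true_pep, 95.0))
                rank_of_truth = 2
            else:
                cand.append((true_pep, 97.0))
                rank_of_truth = 1
        for _ in range(rng.randint(1, 4)):
            if fillers:
                cand.append((fillers.pop(), round(rng.uniform(60.0, 90.0), 1)))
        for peptide, alc in cand:
            rows.append(
                {
                    "Fraction": 1,
                    "Source File": "sample01.raw",
                    "Scan": spectrum,
                    "Peptide": peptide,
                    "ALC (%)": alc,
                }
            )
        truth_rows.append(
            {
                "Scan": spectrum,
                "genus": genus,
                "kind": kind,
                "true_peptide": true_pep or "",
                "true_rank": rank_of_truth,
            }
        )

    def random_fillers(n: int) -> list[str]:
        return [_random_absent_peptide(rng, truth_pep) for _ in range(n)]

    # planted genera: genus-unique peptides with spectral support
    for genus in planted:
        gen_peps = sorted(
            p
            for p, g in unique_map.items()
            if g == genus and 7 <= len(p) <= 55
        )
        rng.shuffle(gen_peps)
        for pep in gen_peps[:peptides_per_genus]:
            for _ in range(spectra_per_peptide):
                add_spectrum(pep, genus, "planted", random_fillers(4))

    # noise genera: candidates from reversed fixture proteins (match only a
    # reversed-decoy database)
    rev_products: dict[str, list[str]] = {g: [] for g in noise_genera}
    genus_of_taxon = {
        int(r.taxon_id): g
        for r, g in zip(records, manifest.proteins["genus"])
    }
    for rec in records:
        genus = genus_of_taxon[rec.taxon_id]
        if genus not in rev_products:
            continue
        rev_products[genus].extend(
            p for p in digest_sequence(rec.sequence[::-1], params)
            if p not in truth_pep
        )
    for genus in noise_genera:
        peps = sorted(set(rev_products[genus]))
        rng.shuffle(peps)
        for pep in peps[:noise_peptides_per_genus]:
            for _ in range(spectra_per_peptide):
                add_spectrum(pep, genus, "noise", random_fillers(3))

    table = pd.DataFrame(
        rows, columns=["Fraction", "Source File", "Scan", "Peptide", "ALC (%)"]
    )
    truth = pd.DataFrame(
        truth_rows, columns=["Scan", "genus", "kind", "true_peptide", "true_rank"]
    )
    if out_path is not None:
        table.to_csv(out_path, index=False)
    return table, truth
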