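# Methods

## The model

`taxopept` treats taxon assignment of observed peptides as exact set
membership in an in-silico digest of a reference proteome, not as a
statistical inference. A peptide's possible origins are *all* proteins whose
digest, under the same proteolytic rules the experiment used, contains the
canonicalized sequence. Taxonomic claims are then purely set-theoretic:
a peptide is specific to a taxon at rank *r* iff the lineage of every
possible origin resolves to that taxon at *r*. This is conservative by
construction — one shared homolog is enough to disqualify a peptide — which
is the behavior wanted for cross-species quantitation.

### Digestion

A cleavage rule is a deterministic predicate on (residue, next residue)
with a side: C-terminal-side rules (trypsin, Lys-C, chymotrypsin, Glu-C)
cut after a matching residue unless the next residue blocks; N-terminal-side
rules (Asp-N) cut before one. Built-ins are provided and arbitrary custom
rules accepted. Peptides are concatenations of whole inter-cut fragments
with at most `max_missed_cleavages` internal sites. Two combinatorial
expansions mirror biology and search-engine practice:

* **N-terminal Met excision** — when the protein starts with M, every
  peptide anchored at position 0 also contributes its Met-less variant.
  The variant is *additional*, not a replacement, and is length-filtered
  independently; retaining both maximizes matchability of observed
  peptides regardless of whether the mature protein kept its initiator.
* **I/L equivalence** — isoleucine and leucine are isobaric under standard
  MS2 fragmentation. Sequences are canonicalized I→L (that fixed direction,
  applied identically to database peptides and to observed/query
  sequences), so the conflation happens in canonicalization, never in
  hashing or matching.

Peptides containing ambiguity codes (X/U/B/Z) are excluded individually;
the rest of the protein still contributes. Semi-specific and non-specific
digestion are out of scope.

### Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| `min_len` / `max_len` | 7 / 55 | residues | standard detectable tryptic range |
| `protease` | trypsin/p | — | cut after K/R, proline allowed |
| `max_missed_cleavages` | 2 | sites | standard search-engine setting |
| `nterm_met_excision` | on | — | co-translational Met removal |
| `il_equivalence` | on | — | MS2 cannot distinguish I/L |
| `min_alc` (de novo) | 50 | score 0–100 | confidence floor for candidates |
| `min_spectral_counts` | 2 | spectra | single-spectrum calls are unreliable |
| `delta_threshold` | 7 | counts | forward−reverse margin for genus calls |

### The peptide database

Three relations in one SQLite file: `MainData` (full protein sequences,
organism, gene), `Reference` (hashed peptide → protein key; one row per
peptide–protein incidence), `DBParams` (the exact build parameters, a
schema version, and the index flag). Design choices:

* **Hash** — first 8 bytes of BLAKE2b of the canonical sequence, read
  little-endian as a signed 64-bit integer. Chosen because it is
  C-implemented in the standard library, documented, and stable across
  platforms and processes; storing 8-byte integers instead of text is the
  compression that lets the design scale.
* **Collision safety** — `Reference` stores no plaintext, so a hash hit is
  confirmed by re-digesting the stored parent sequence (memoized per
  handle) and requiring the canonical query to be among its products. A
  query therefore never reports a protein that could not have produced the
  peptide under the stored cleavage rules, whatever the hash does.
* **DBParams is authoritative** — queries canonicalize with the stored
  build parameters and ignore caller-side settings, preventing silent
  build/query rule mismatch. A query outside the stored length window
  returns empty rather than erroring.
* **Separate indexing** — insertion scales linearly in protein count;
  the one-off hash index is created afterwards and flagged in `DBParams`
  (idempotent).
* **Parallelism** — the build partitions *proteins* across workers, so the
  Reference row multiset is identical for any worker count.

### Filtering semantics

`TaxonFilter` implements both analysis perspectives for multi-organism
quantitation. With `require_unique` (method 2), a row is kept iff all hits
resolve to a single, included, non-excluded taxon at the rank. Without it
(method 1), the `default_taxon` need only be *plausible* (among the
resolved taxa); excluded taxa are removed from consideration and, by
default, some non-excluded taxon must remain (`require_nonempty_after_
exclusion`, exposed because the plausible-assignment convention is
ambiguous on peptides explained only by excluded taxa). Hits whose lineage
lacks the rank resolve to an "absent" category that never satisfies
uniqueness and is never imputed. Method-2 output is a subset of method-1
output for the same taxon, by construction.

Rollup drops rows mapping to zero or several gene symbols (counted, never
fractionally shared — razor allocation is explicitly not modeled) and sums
each quantitative column per gene, so column totals are conserved over
retained rows.

### Normalization

Reference-pool normalization is, in order: per-gene ratio to the reference
channel; log2; per-channel median centering; per-channel division by the
*population* standard deviation (ddof = 0). Genes without a positive
reference value are dropped and counted. The reference channel itself is
identically zero after centering (its SD is 0), so it is omitted from the
output; all output channels have median 0 and SD 1 to 1e-9.

### De-novo pipeline

Candidates are ALC-filtered first, then ordered by descending score (ties
keep the engine's emission order, which is documented because acceptance
can depend on it). In `database_constrained` mode the candidates of each
spectrum are tested serially until one has a database hit; `top_candidate`
mode tests only the best. Modified and unmodified observations of the same
stripped, I/L-canonical sequence pool for spectral counting across all
input spectra. Retention requires genus uniqueness, the spectral-count
floor, and membership in a configurable (rank, name) allowlist defaulting
to bacterial-superkingdom-or-human-species. The decoy run repeats the
identical procedure against a database of whole-protein-reversed sequences
with the same digestion parameters, and genera are ranked by
Δ = forward − reverse with strict-inequality acceptance.

**A structural note on decoy symmetry.** Digestion does not commute with
sequence reversal for a single-sided cleavage rule: reversing a protein
moves each K/R from fragment ends to fragment starts, so the decoy's
peptide set is a frame-shifted mirror, not the reversed forward peptide
set. Consequently "reverse the candidates and search the reversed database"
does *not* reproduce forward results — and that same asymmetry is exactly
why a reversed database works as a null model for tryptic matching. A
cleavage-site-aware (mirrored-rule) decoy would restore the symmetry but
was deliberately not used: whole-protein reversal with forward parameters
is the standard construction this package follows.

## The synthetic fixture generator

Fixtures emulate the *structure* that the pipeline's correctness depends
on, not mass-spectral physics. Proteins are built fragment-wise from
K/R-terminated blocks over an alphabet excluding K/R (cleavage), I (so
tests can probe I/L spelling), M (reserved for N-termini) and ambiguity
codes; each block is globally unique within a fixture, so cross-taxon
sharing exists only where engineered. The generator enumerates every
digest product from its own fragment bookkeeping into a manifest — an
oracle independent of the digestion engine — and homolog pairs share an
exact number of whole fragments, making the designed shared fraction exact
under a 0-missed-cleavage digest (with missed cleavages, boundary-spanning
concatenations dilute it; the manifest records the realized sets either
way). De-novo fixtures plant genus-unique peptides with controlled
spectral support and draw noise candidates from digests of the *reversed*
fixture proteins, so noise matches only a decoy database. Everything is a
pure function of the seed.

What a green test therefore establishes: exact digestion, storage,
retrieval, filtering, rollup, and decoy arithmetic on data whose truth is
known by construction. What it does not: search-engine error modeling,
realistic peptide detectability, retention/fragmentation behavior, or the
sequence-bias structure of real repositories.

## Numerical and degenerate-input choices

* Hash: signed 64-bit; collisions are possible in principle and harmless
  (verification); an empty peptide is an error.
* Normalization tolerance: median/SD contracts hold to 1e-9; fewer than
  two genes is an error (SD undefined).
* Dangling taxonomy parents end the lineage walk with ranks found so far;
  unknown taxon IDs raise a distinct error from "rank absent".
* Duplicate FASTA accessions keep the first occurrence; entries without an
  organism token are rejected and counted, never silently dropped.
* Equal-Δ genera sort by name for deterministic reports.

## Known limitations

* Databases are not interchangeable with other tools' files (different
  hash function, same schema idea).
* No protein-level FDR, isoform inference, razor allocation, or
  differential-expression statistics.
* Merged/deleted taxon IDs are not remapped; live UniProt/NCBI retrieval
  is specified via an injectable transport and exercised only against
  local fixtures.
* Gene-less proteins are carried through annotation but excluded from
  gene rollup (counted).
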