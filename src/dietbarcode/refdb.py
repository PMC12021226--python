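"""Local barcode reference database: construction, curation, resolution.

The reference database maps each unique trimmed barcode-region sequence to
the set of flora species it has been attributed to.  Because the ~262 bp
rbcL region evolves slowly, one sequence frequently belongs to several
congeners or confamilials; the *resolution class* of an entry records how
specifically a perfect match to it can be interpreted:

* ``species_specific`` — one source species;
* ``genus_shared``     — several species, one genus;
* ``family_shared``    — several genera, one family;
* ``unassignable``     — source species span families.

Curation applies two exclusions.  A user-supplied blacklist drops
accessions known to be misidentified.  The bait-confound rule removes trap
bait species together with any in-area species that shares *every* one of
its sequences with bait — a match to such a sequence can never be told
apart from the animal eating the bait.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from ._util import percent
from .taxonomy import Flora

#: Synthetic anchor primers flanking the barcode region in raw reference
#: sequences.  Deposited reference sequences are longer than the amplified
#: region; the region is located by these anchors and cut out.
DEFAULT_ANCHOR_F = "ATGTCACCACAAACAGAGAC"
DEFAULT_ANCHOR_R = "GTAAAATCAAGTCCACCACG"

RESOLUTION_CLASSES = (
    "species_specific",
    "genus_shared",
    "family_shared",
    "unassignable",
)


class UntrimmableError(ValueError):
    """Raised when a raw sequence does not contain both anchor primers."""


class ReferenceDatabaseError(ValueError):
    pass


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _find_anchor(raw: str, anchor: str, max_mismatch: int, start: int = 0) -> int | None:
    """Leftmost best occurrence of ``anchor`` in ``raw`` with <= max_mismatch."""
    best_pos, best_mm = None, max_mismatch + 1
    for i in range(start, len(raw) - len(anchor) + 1):
        mm = _hamming(raw[i : i + len(anchor)], anchor)
        if mm < best_mm:
            best_pos, best_mm = i, mm
            if mm == 0:
                break
    return best_pos if best_mm <= max_mismatch else None


def trim_to_region(
    raw_seq: str,
    anchor_primers: tuple[str, str] = (DEFAULT_ANCHOR_F, DEFAULT_ANCHOR_R),
    max_mismatch: int = 2,
) -> str:
    """Extract the barcode region between two anchor primers.

    Each anchor may carry up to ``max_mismatch`` substitutions.  Returns
    the inter-anchor region uppercased; raises :class:`UntrimmableError`
    if either anchor is absent.
    """
    raw = raw_seq.upper()
    fwd, rev = anchor_primers[0].upper(), anchor_primers[1].upper()
    fpos = _find_anchor(raw, fwd, max_mismatch)
    if fpos is None:
        raise UntrimmableError("forward anchor not found")
    region_start = fpos + len(fwd)
    rpos = _find_anchor(raw, rev, max_mismatch, start=region_start)
    if rpos is None:
        raise UntrimmableError("reverse anchor not found")
    region = raw[region_start:rpos]
    bad = set(region) - set("ACGTN")
    if bad:
        raise UntrimmableError(f"non-nucleotide characters in region: {sorted(bad)}")
    return region


@dataclass
class DBEntry:
    """One unique trimmed sequence with its provenance."""

    sequence: str
    species: set[str] = field(default_factory=set)
    accessions: set[str] = field(default_factory=set)
    tier: str = "external_pool"  # becomes local_survey if any accession is local
    resolution_class: str | None = None


@dataclass
class ReferenceDatabase:
    entries: dict[str, DBEntry]
    region_length: int
    uncovered_species: list[str] = field(default_factory=list)
    skipped: list[tuple[str, str]] = field(default_factory=list)  # (accession, reason)
    blacklisted: dict[str, str] = field(default_factory=dict)  # accession -> reason
    bait_excluded: dict[str, str] = field(default_factory=dict)  # species -> reason

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def sequences(self) -> list[str]:
        return list(self.entries)

    def species_sequences(self) -> dict[str, set[str]]:
        """Map each source species to the set of sequences attributed to it."""
        out: dict[str, set[str]] = {}
        for seq, entry in self.entries.items():
            for sp in entry.species:
                out.setdefault(sp, set()).add(seq)
        return out

    # -- serialization -----------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {
                "sequence": e.sequence,
                "source_species": ";".join(sorted(e.species)),
                "accessions": ";".join(sorted(e.accessions)),
                "tier": e.tier,
                "resolution_class": e.resolution_class or "",
            }
            for e in self.entries.values()
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, region_length: int | None = None) -> "ReferenceDatabase":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        entries: dict[str, DBEntry] = {}
        for row in df.itertuples():
            entries[row.sequence] = DBEntry(
                sequence=row.sequence,
                species=set(row.source_species.split(";")) if row.source_species else set(),
                accessions=set(row.accessions.split(";")) if row.accessions else set(),
                tier=row.tier,
                resolution_class=row.resolution_class or None,
            )
        if region_length is None:
            region_length = len(next(iter(entries))) if entries else 0
        return cls(entries=entries, region_length=region_length)


def read_pool_fasta(path: str | Path) -> list[tuple[str, str, str]]:
    """Read a reference pool FASTA with ``>accession|species_name`` headers.

    Returns (accession, species, raw sequence) triples.
    """
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description
        if "|" not in header:
            raise ReferenceDatabaseError(
                f"pool FASTA header lacks 'accession|species' format: {header!r}"
            )
        accession, species = header.split("|", 1)
        out.append((accession.strip(), species.strip(), str(rec.seq)))
    return out


def read_blacklist(path: str | Path) -> dict[str, str]:
    """Read a blacklist TSV with columns ``accession`` and ``reason``."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "accession" not in df.columns:
        raise ReferenceDatabaseError("blacklist TSV needs an 'accession' column")
    reasons = df["reason"] if "reason" in df.columns else [""] * len(df)
    return dict(zip(df["accession"], reasons))


def build_database(
    flora: Flora,
    pool: Iterable[tuple[str, str, str]] | str | Path,
    blacklist: Mapping[str, str] | str | Path | None = None,
    anchor_primers: tuple[str, str] = (DEFAULT_ANCHOR_F, DEFAULT_ANCHOR_R),
    local_accessions: set[str] | None = None,
) -> ReferenceDatabase:
    """Trim, deduplicate and index a reference sequence pool.

    ``pool`` is either a FASTA path (headers ``>accession|species``) or an
    iterable of (accession, species, raw_sequence).  Accessions on the
    blacklist are dropped with their reason recorded; raw sequences in
    which the anchors cannot be found are skipped and logged.  Species
    attributed in the pool but absent from the flora are an error.  Flora
    species that end up with no usable sequence are reported as uncovered,
    never silently dropped.
    """
    if isinstance(pool, (str, Path)):
        pool = read_pool_fasta(pool)
    if isinstance(blacklist, (str, Path)):
        blacklist = read_blacklist(blacklist)
    blacklist = dict(blacklist or {})
    local_accessions = local_accessions or set()

    unknown = sorted({sp for _, sp, _ in pool if sp not in flora})
    if unknown:
        raise ReferenceDatabaseError(f"pool species absent from flora: {unknown}")

    entries: dict[str, DBEntry] = {}
    skipped: list[tuple[str, str]] = []
    used_blacklist: dict[str, str] = {}
    lengths: set[int] = set()
    for accession, species, raw in pool:
        if accession in blacklist:
            used_blacklist[accession] = blacklist[accession] or "blacklisted"
            continue
        try:
            region = trim_to_region(raw, anchor_primers)
        except UntrimmableError as exc:
            skipped.append((accession, str(exc)))
            continue
        lengths.add(len(region))
        entry = entries.setdefault(region, DBEntry(sequence=region))
        entry.species.add(species)
        entry.accessions.add(accession)
        if accession in local_accessions:
            entry.tier = "local_survey"

    covered = {sp for e in entries.values() for sp in e.species}
    uncovered = sorted(sp for sp in flora.species if sp not in covered)
    region_length = max(lengths) if lengths else 0
    # stable ordering: by sequence, so rebuilds are byte-identical
    entries = {seq: entries[seq] for seq in sorted(entries)}
    db = ReferenceDatabase(
        entries=entries,
        region_length=region_length,
        uncovered_species=uncovered,
        skipped=skipped,
        blacklisted=used_blacklist,
    )
    classify_resolution(db, flora)
    return db


def classify_species_set(species: set[str], flora: Flora) -> str:
    """Resolution class of a source-species set under the flora taxonomy."""
    if len(species) == 1:
        return "species_specific"
    genera = {flora.genus_of(sp) for sp in species}
    if len(genera) == 1:
        return "genus_shared"
    families = {flora.family_of(sp) for sp in species}
    if len(families) == 1:
        return "family_shared"
    return "unassignable"


def classify_resolution(db: ReferenceDatabase, flora: Flora) -> dict:
    """Class every unique entry and summarize counts and percentages.

    Percentages are over the unique-entry count, half-up rounded to one
    decimal, the way database papers print them.
    """
    counts = dict.fromkeys(RESOLUTION_CLASSES, 0)
    for entry in db.entries.values():
        entry.resolution_class = classify_species_set(entry.species, flora)
        counts[entry.resolution_class] += 1
    return resolution_percentages(counts)


def resolution_percentages(counts: Mapping[str, int]) -> dict:
    """Counts + percentages (1 decimal, half-up) for resolution classes."""
    total = sum(counts.values())
    summary = {"n_entries": total, "counts": dict(counts)}
    summary["percent"] = {
        cls: percent(n, total) if total else 0.0 for cls, n in counts.items()
    }
    return summary


def flag_bait_confounded(db: ReferenceDatabase, flora: Flora) -> dict[str, str]:
    """Species that cannot be told apart from trap bait.

    Bait species are always excluded.  An in-area species is excluded iff
    *every* sequence attributed to it is also attributed to some bait
    species — then no match could ever be credited to the wild plant.  A
    species with at least one distinguishing sequence is retained.
    """
    bait = flora.bait_species
    per_species = db.species_sequences()
    bait_seqs: set[str] = set()
    for sp in bait:
        bait_seqs |= per_species.get(sp, set())

    excluded: dict[str, str] = {sp: "trap bait species" for sp in bait if sp in per_species}
    for sp, seqs in per_species.items():
        if sp in bait or not seqs:
            continue
        if seqs <= bait_seqs:
            excluded[sp] = "bait-confounded: every sequence shared with bait"
    return excluded


def curate_database(db: ReferenceDatabase, flora: Flora) -> ReferenceDatabase:
    """Apply the bait-confound exclusion.

    Every entry carried by a bait species is dropped outright — a read
    matching such a sequence can never be told apart from the bait — and
    excluded species are removed everywhere.  A distinguishable in-area
    species keeps its bait-free sequences only.
    """
    excluded = flag_bait_confounded(db, flora)
    bait = flora.bait_species
    entries: dict[str, DBEntry] = {}
    for seq, entry in db.entries.items():
        if entry.species & bait:
            continue
        remaining = entry.species - set(excluded)
        if not remaining:
            continue
        entries[seq] = DBEntry(
            sequence=seq,
            species=remaining,
            accessions=set(entry.accessions),
            tier=entry.tier,
        )
    out = ReferenceDatabase(
        entries=entries,
        region_length=db.region_length,
        uncovered_species=list(db.uncovered_species),
        skipped=list(db.skipped),
        blacklisted=dict(db.blacklisted),
        bait_excluded=dict(db.bait_excluded or {}) | excluded,
    )
    classify_resolution(out, flora)
    return out


def database_summary(db: ReferenceDatabase, flora: Flora) -> dict:
    """JSON-ready coverage and resolution accounting."""
    counts = dict.fromkeys(RESOLUTION_CLASSES, 0)
    for entry in db.entries.values():
        cls = entry.resolution_class or classify_species_set(entry.species, flora)
        counts[cls] += 1
    covered = {sp for e in db.entries.values() for sp in e.species}
    return {
        "n_unique_sequences": len(db),
        "n_species_covered": len(covered),
        "n_species_uncovered": len(db.uncovered_species),
        "n_blacklisted_accessions": len(db.blacklisted),
        "n_untrimmable": len(db.skipped),
        "bait_excluded": dict(db.bait_excluded),
        "resolution": resolution_percentages(counts),
    }


def write_summary(db: ReferenceDatabase, flora: Flora, path: str | Path) -> None:
    Path(path).write_text(json.dumps(database_summary(db, flora), indent=2) + "\n")
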