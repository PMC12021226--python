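"""Tiered identity search with LCA tie resolution and exclusion filters.

Each ASV is compared against the curated local reference database first.
If its best identity there reaches the gate (default 98%), all entries
tying with the best hit contribute their source species, and the union is
resolved to the lowest common rank (species / genus / family).  Below the
gate, the search is repeated against a fallback database standing in for
a public-repository search; fallback hits additionally pass an
ecological-plausibility filter (the species must grow in the study area
or be on a user allow-list of planted taxa).  Matches attributable only
to trap bait are excluded at either tier.  ASVs below the gate in both
databases stay unassigned.  Every outcome is an explicit status with a
reason — nothing is silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import Align

from ._util import percent
from .refdb import ReferenceDatabase
from .taxonomy import Flora

STATUSES = ("assigned", "excluded_bait", "excluded_implausible", "unassigned")


@dataclass
class PipelineConfig:
    """Numeric constants of the analysis, in one place.

    ``identity_gate`` is in percent; exactly at the gate counts as a pass.
    ``tie_tolerance`` is the identity margin within which hits tie with
    the best hit (exact ties only, by default).
    """

    identity_gate: float = 98.0
    rarefaction_depth: int = 1000
    lowfreq_threshold: float = 0.01
    permutations: int = 10000
    bootstrap_reps: int = 1000
    nmds_dims: int = 3
    stress_ceiling: float = 0.2
    alpha: float = 0.05
    tie_tolerance: float = 1e-9
    allow_list: set[str] = field(default_factory=set)  # planted out-of-area taxa
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.identity_gate <= 100.0:
            raise ValueError("identity_gate must be in (0, 100]")
        for name in ("rarefaction_depth", "permutations", "bootstrap_reps", "nmds_dims"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class Assignment:
    """Per-ASV outcome with provenance."""

    asv_id: str
    sequence: str
    tier: str  # local | fallback | none
    best_identity: float
    matched_species: set[str] = field(default_factory=set)
    rank: str | None = None  # species | genus | family
    name: str | None = None
    status: str = "unassigned"
    reason: str = ""


_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1
_aligner.mismatch_score = -1
_aligner.open_gap_score = -2
_aligner.extend_gap_score = -2
# end gaps penalized: default global mode scores end gaps with the same
# open/extend penalties, which is what we want.


def percent_identity(query: str, reference: str) -> float:
    """Global-alignment identity in percent.

    Scores: match +1, mismatch -1, gap -2, end gaps penalized.  Identity
    is matches over alignment columns.  For equal-length sequences with at
    most two mismatches the gapless alignment is provably optimal (any
    gapped alignment loses at least 5 score points), so identity reduces
    to the Hamming fraction; that fast path covers the exact and near-exact
    hits that dominate real searches.
    """
    if not query or not reference:
        raise ValueError("sequences must be non-empty")
    query, reference = query.upper(), reference.upper()
    if len(query) == len(reference):
        mismatches = sum(a != b for a, b in zip(query, reference))
        if mismatches <= 2:
            return 100.0 * (len(query) - mismatches) / len(query)
    alignment = _aligner.align(query, reference)[0]
    counts = alignment.counts()
    columns = alignment.length
    return 100.0 * counts.identities / columns


def _best_hits(
    seq: str, db: ReferenceDatabase, tie_tolerance: float
) -> tuple[float, set[str]]:
    """Best identity over db entries and the source-species union of ties."""
    best = -1.0
    identities: list[tuple[str, float]] = []
    for ref_seq in db.entries:
        ident = percent_identity(seq, ref_seq)
        identities.append((ref_seq, ident))
        best = max(best, ident)
    tied_species: set[str] = set()
    for ref_seq, ident in identities:
        if best - ident <= tie_tolerance:
            tied_species |= db.entries[ref_seq].species
    return best, tied_species


def assign_asv(
    sequence: str,
    local_db: ReferenceDatabase,
    fallback_db: ReferenceDatabase | None,
    flora: Flora,
    cfg: PipelineConfig,
    asv_id: str = "",
) -> Assignment:
    """Run the tiered decision flow for one ASV."""
    cfg.validate()
    best_local, local_species = _best_hits(sequence, local_db, cfg.tie_tolerance)
    if best_local >= cfg.identity_gate:
        return _resolve(
            asv_id, sequence, "local", best_local, local_species, flora, cfg,
            plausibility=False,
        )
    if fallback_db is not None and len(fallback_db) > 0:
        best_fb, fb_species = _best_hits(sequence, fallback_db, cfg.tie_tolerance)
        if best_fb >= cfg.identity_gate:
            return _resolve(
                asv_id, sequence, "fallback", best_fb, fb_species, flora, cfg,
                plausibility=True,
            )
        best_any = max(best_local, best_fb)
    else:
        best_any = best_local
    return Assignment(
        asv_id=asv_id,
        sequence=sequence,
        tier="none",
        best_identity=best_any,
        status="unassigned",
        reason=f"best identity {best_any:.2f}% below gate in both databases",
    )


def _resolve(
    asv_id: str,
    sequence: str,
    tier: str,
    identity: float,
    species: set[str],
    flora: Flora,
    cfg: PipelineConfig,
    plausibility: bool,
) -> Assignment:
    bait = flora.bait_species
    if species and species <= bait:
        return Assignment(
            asv_id=asv_id, sequence=sequence, tier=tier, best_identity=identity,
            matched_species=species, status="excluded_bait",
            reason="matched only trap-bait taxa",
        )
    if plausibility:
        plausible = {
            sp for sp in species
            if flora.record(sp).in_area or sp in cfg.allow_list
        }
        if not plausible:
            return Assignment(
                asv_id=asv_id, sequence=sequence, tier=tier, best_identity=identity,
                matched_species=species, status="excluded_implausible",
                reason="matched taxa do not grow in the study area",
            )
        species = plausible
    lcr = flora.lowest_common_rank(species)
    if lcr is None:
        return Assignment(
            asv_id=asv_id, sequence=sequence, tier=tier, best_identity=identity,
            matched_species=species, status="unassigned",
            reason="tied matches span multiple families",
        )
    rank, name = lcr
    return Assignment(
        asv_id=asv_id, sequence=sequence, tier=tier, best_identity=identity,
        matched_species=species, rank=rank, name=name, status="assigned",
        reason="",
    )


def assign_table(
    asv_sequences: Sequence[str] | Iterable[str],
    local_db: ReferenceDatabase,
    fallback_db: ReferenceDatabase | None,
    flora: Flora,
    cfg: PipelineConfig,
) -> tuple[list[Assignment], dict]:
    """Assign every ASV and summarize tier/status counts.

    Percentages are over the ASV count, half-up rounded to 1 decimal.
    """
    sequences = list(asv_sequences)
    ids = {seq: f"ASV{i + 1:04d}" for i, seq in enumerate(sequences)}
    assignments = [
        assign_asv(seq, local_db, fallback_db, flora, cfg, asv_id=ids[seq])
        for seq in sequences
    ]
    summary = identification_summary(assignments)
    return assignments, summary


def identification_summary(assignments: Sequence[Assignment]) -> dict:
    n = len(assignments)
    tier_counts = {t: 0 for t in ("local", "fallback", "none")}
    status_counts = {s: 0 for s in STATUSES}
    rank_counts = {r: 0 for r in ("species", "genus", "family")}
    for a in assignments:
        tier_counts[a.tier] += 1
        status_counts[a.status] += 1
        if a.status == "assigned" and a.rank:
            rank_counts[a.rank] += 1
    summary = {
        "n_asvs": n,
        "tier_counts": tier_counts,
        "status_counts": status_counts,
        "assigned_rank_counts": rank_counts,
    }
    if n:
        summary["tier_percent"] = {t: percent(c, n) for t, c in tier_counts.items()}
        summary["status_percent"] = {s: percent(c, n) for s, c in status_counts.items()}
    return summary


def assignments_to_tsv(assignments: Sequence[Assignment], path: str | Path) -> None:
    rows = [
        {
            "asv_id": a.asv_id,
            "tier": a.tier,
            "identity": round(a.best_identity, 2),
            "rank": a.rank or "",
            "name": a.name or "",
            "status": a.status,
            "reason": a.reason,
            "matched_species": ";".join(sorted(a.matched_species)),
            "sequence": a.sequence,
        }
        for a in assignments
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
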