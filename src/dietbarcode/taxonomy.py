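"""Flora list and taxonomic backbone.

A flora is the list of plant species known (or allowed) for a study area,
each carried with its genus, family, growth form, and two curation flags:
whether the species actually grows in the area and whether it was used as
trap bait.  The species -> genus -> family hierarchy is the backbone for
lowest-common-ancestor resolution of ambiguous barcode matches and for the
ecological-plausibility filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

GROWTH_FORMS = ("woody", "herbaceous")

#: Ranks at which an assignment can be resolved, most to least specific.
RANKS = ("species", "genus", "family")


class TaxonomyError(ValueError):
    """Raised for inconsistent or unknown taxa."""


@dataclass(frozen=True)
class FloraRecord:
    """One species in the flora list.

    Parameters
    ----------
    species:
        Full species name, unique within the flora.
    genus, family:
        Parent taxa.  A genus must belong to exactly one family.
    growth_form:
        ``"woody"`` or ``"herbaceous"``.
    in_area:
        Whether the species grows in the study area.  Out-of-area species
        (e.g. likely lab contaminants) may still appear in the fallback
        reference pool but are excluded by the plausibility filter.
    is_bait:
        Whether the species was used as trap bait.
    """

    species: str
    genus: str
    family: str
    growth_form: str = "woody"
    in_area: bool = True
    is_bait: bool = False

    def __post_init__(self) -> None:
        if self.growth_form not in GROWTH_FORMS:
            raise TaxonomyError(
                f"growth_form must be one of {GROWTH_FORMS}, got {self.growth_form!r}"
            )


class Flora:
    """An indexed flora list.

    Validates that species names are unique and that each genus maps to a
    single family, then offers O(1) lookups and LCA-style rank resolution.
    """

    def __init__(self, records: Iterable[FloraRecord]):
        self._records: dict[str, FloraRecord] = {}
        genus_family: dict[str, str] = {}
        for rec in records:
            if rec.species in self._records:
                raise TaxonomyError(f"duplicate species in flora: {rec.species}")
            if rec.genus in genus_family and genus_family[rec.genus] != rec.family:
                raise TaxonomyError(
                    f"genus {rec.genus} assigned to two families: "
                    f"{genus_family[rec.genus]} and {rec.family}"
                )
            genus_family[rec.genus] = rec.family
            self._records[rec.species] = rec
        if not self._records:
            raise TaxonomyError("flora is empty")

    # -- basic access ------------------------------------------------------

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, species: str) -> bool:
        return species in self._records

    def __iter__(self):
        return iter(self._records.values())

    @property
    def species(self) -> list[str]:
        return list(self._records)

    def record(self, species: str) -> FloraRecord:
        try:
            return self._records[species]
        except KeyError:
            raise TaxonomyError(f"species not in flora: {species}") from None

    def genus_of(self, species: str) -> str:
        return self.record(species).genus

    def family_of(self, species: str) -> str:
        return self.record(species).family

    @property
    def bait_species(self) -> set[str]:
        return {r.species for r in self if r.is_bait}

    @property
    def in_area_species(self) -> set[str]:
        return {r.species for r in self if r.in_area}

    # -- LCA resolution ----------------------------------------------------

    def lowest_common_rank(self, species_set: Sequence[str] | set[str]) -> tuple[str, str] | None:
        """Resolve a set of species to the most specific shared rank.

        A single species resolves to itself; congeners resolve to their
        genus; confamilials to their family.  If the set spans more than
        one family there is no usable rank and ``None`` is returned.
        """
        species = set(species_set)
        if not species:
            raise TaxonomyError("cannot resolve an empty species set")
        for sp in species:
            self.record(sp)  # raises on unknown species
        if len(species) == 1:
            return ("species", next(iter(species)))
        genera = {self.genus_of(sp) for sp in species}
        if len(genera) == 1:
            return ("genus", next(iter(genera)))
        families = {self.family_of(sp) for sp in species}
        if len(families) == 1:
            return ("family", next(iter(families)))
        return None

    # -- serialization -----------------------------------------------------

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Flora":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"species", "genus", "family", "growth_form", "in_area", "is_bait"}
        missing = required - set(df.columns)
        if missing:
            raise TaxonomyError(f"flora TSV missing columns: {sorted(missing)}")
        records = [
            FloraRecord(
                species=row.species,
                genus=row.genus,
                family=row.family,
                growth_form=row.growth_form,
                in_area=str(row.in_area).lower() in ("true", "1", "yes"),
                is_bait=str(row.is_bait).lower() in ("true", "1", "yes"),
            )
            for row in df.itertuples()
        ]
        return cls(records)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            [
                {
                    "species": r.species,
                    "genus": r.genus,
                    "family": r.family,
                    "growth_form": r.growth_form,
                    "in_area": r.in_area,
                    "is_bait": r.is_bait,
                }
                for r in self
            ]
        )
        df.to_csv(path, sep="\t", index=False)
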