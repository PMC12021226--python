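"""Diet table construction and occurrence/resolution summaries.

The diet table is the sample x taxon presence matrix that all downstream
statistics consume.  A *taxon* here is an assignment outcome: the resolved
rank and name together with the exact set of reference species behind the
tie.  Two distinct tie-sets resolving to the same genus or family name are
distinct taxa; their display names get ``-1``/``-2`` suffixes ordered by
overall frequency (the convention diet tables use for e.g. "Fagaceae-1").

Also ships a machine-readable transcription of the published Table-1 style
diet summary used as a validation fixture: 72 taxa in 43 families scored
over 100 fecal samples (22 spring / 35 summer / 32 autumn / 11 winter).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import percent, round_half_up
from .assign import Assignment
from .asv import ASVTable
from .taxonomy import Flora

SEASONS = ("spring", "summer", "autumn", "winter")
#: Month -> season bins (Mar-May, Jun-Aug, Sep-Nov, Dec-Feb).
MONTH_SEASON = {
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "autumn", 10: "autumn", 11: "autumn",
    12: "winter", 1: "winter", 2: "winter",
}

#: Seasonal sample sizes of the packaged fixture.
TABLE1_SEASON_N = {"spring": 22, "summer": 35, "autumn": 32, "winter": 11}
TABLE1_N = 100


class SummaryError(ValueError):
    pass


@dataclass
class DietTable:
    """Sample x taxon presence matrix with taxon metadata.

    ``presence`` is boolean, indexed by sample id with taxon display-name
    columns; ``abundance`` holds the rarefied read counts behind it (the
    substrate for relative-read-abundance dissimilarity).  ``taxa``
    carries one row per taxon: display name, rank, resolved name, family,
    growth form and the member species behind it.  ``seasons`` maps each
    sample to its season bin.
    """

    presence: pd.DataFrame
    taxa: pd.DataFrame
    seasons: dict[str, str]
    abundance: pd.DataFrame | None = None

    @property
    def samples(self) -> list[str]:
        return list(self.presence.index)

    @property
    def n_samples(self) -> int:
        return len(self.presence)

    def season_n(self) -> dict[str, int]:
        out = dict.fromkeys(SEASONS, 0)
        for s in self.seasons.values():
            out[s] += 1
        return out

    def to_tsv(self, path: str | Path) -> None:
        out = self.presence.astype(int).copy()
        out.insert(0, "season", [self.seasons[s] for s in out.index])
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")


def season_of_month(month: int) -> str:
    try:
        return MONTH_SEASON[int(month)]
    except KeyError:
        raise SummaryError(f"month out of range: {month}") from None


def _growth_form_of(members: set[str], flora: Flora) -> str:
    forms = [flora.record(sp).growth_form for sp in sorted(members)]
    # tie-set members almost always agree; on disagreement take majority,
    # ties going to woody (the commoner form in diet tables)
    woody = sum(f == "woody" for f in forms)
    return "woody" if woody * 2 >= len(forms) else "herbaceous"


def build_diet_table(
    assignments: Sequence[Assignment],
    asv_table: ASVTable,
    metadata: pd.DataFrame,
    flora: Flora,
) -> DietTable:
    """Collapse ASV-level assignments to per-sample taxon presence.

    A taxon is present in a sample iff at least one ASV with ``assigned``
    status and a nonzero rarefied count resolves to it.  Excluded and
    unassigned ASVs contribute nothing.  Samples must all carry a season
    (either a ``season`` column or a ``collection_month`` to bin).
    """
    meta = metadata.set_index("sample_id")
    seasons: dict[str, str] = {}
    for sid in asv_table.samples:
        if sid not in meta.index:
            raise SummaryError(f"sample {sid} missing from metadata")
        row = meta.loc[sid]
        if "season" in meta.columns and isinstance(row["season"], str) and row["season"]:
            season = row["season"]
            if season not in SEASONS:
                raise SummaryError(f"unknown season {season!r} for sample {sid}")
        elif "collection_month" in meta.columns:
            season = season_of_month(row["collection_month"])
        else:
            raise SummaryError("metadata needs a 'season' or 'collection_month' column")
        seasons[sid] = season

    # taxon identity: (rank, name, member set)
    by_key: dict[tuple[str, str, frozenset[str]], list[Assignment]] = {}
    for a in assignments:
        if a.status != "assigned":
            continue
        key = (a.rank, a.name, frozenset(a.matched_species))
        by_key.setdefault(key, []).append(a)

    counts = asv_table.counts
    presence_sets: dict[tuple[str, str, frozenset[str]], set[str]] = {}
    abundance_by_key: dict[tuple[str, str, frozenset[str]], pd.Series] = {}
    for key, members in by_key.items():
        present: set[str] = set()
        reads = pd.Series(0, index=counts.columns, dtype=np.int64)
        for a in members:
            if a.sequence in counts.index:
                row = counts.loc[a.sequence]
                present |= set(row.index[row > 0])
                reads = reads + row
        presence_sets[key] = present
        abundance_by_key[key] = reads

    # display names: disambiguate same (rank, name) by overall frequency
    freq = {key: len(samples) for key, samples in presence_sets.items()}
    names: dict[tuple[str, str, frozenset[str]], str] = {}
    by_name: dict[tuple[str, str], list] = {}
    for key in presence_sets:
        by_name.setdefault((key[0], key[1]), []).append(key)
    for (rank, name), keys in by_name.items():
        if len(keys) == 1:
            names[keys[0]] = name
        else:
            ordered = sorted(keys, key=lambda k: (-freq[k], sorted(k[2])))
            for i, k in enumerate(ordered):
                names[k] = f"{name}-{i + 1}"

    taxa_rows = []
    data = {}
    abundance_data = {}
    sample_ids = asv_table.samples
    for key, display in sorted(names.items(), key=lambda kv: kv[1]):
        rank, name, member_set = key
        members = set(member_set)
        family = (
            name if rank == "family" else flora.family_of(next(iter(members)))
        )
        taxa_rows.append(
            {
                "taxon": display,
                "rank": rank,
                "name": name,
                "family": family,
                "growth_form": _growth_form_of(members, flora),
                "members": ";".join(sorted(members)),
            }
        )
        data[display] = [sid in presence_sets[key] for sid in sample_ids]
        abundance_data[display] = abundance_by_key[key].reindex(sample_ids)

    presence = pd.DataFrame(data, index=sample_ids, dtype=bool)
    abundance = pd.DataFrame(abundance_data, index=sample_ids).fillna(0).astype(np.int64)
    taxa = pd.DataFrame(
        taxa_rows, columns=["taxon", "rank", "name", "family", "growth_form", "members"]
    )
    return DietTable(presence=presence, taxa=taxa, seasons=seasons, abundance=abundance)


# -- summaries -------------------------------------------------------------


def frequency_of_occurrence(diet: DietTable) -> pd.DataFrame:
    """Per-taxon occurrence counts and percents, per season and overall.

    The frequency of occurrence of a taxon is the number of samples where
    it is present divided by the number of samples; seasonal columns use
    the seasonal sample counts.  Percents are half-up rounded to one
    decimal.  Rows are sorted by overall count (desc), then taxon name.
    """
    if diet.presence.empty:
        raise SummaryError("diet table has no taxa")
    season_n = diet.season_n()
    season_of = diet.seasons
    rows = []
    for _, trow in diet.taxa.iterrows():
        taxon = trow["taxon"]
        col = diet.presence[taxon]
        seasonal = dict.fromkeys(SEASONS, 0)
        for sid, present in col.items():
            if present:
                seasonal[season_of[sid]] += 1
        overall = int(col.sum())
        row = {
            "taxon": taxon,
            "family": trow["family"],
            "rank": trow["rank"],
            "growth_form": trow["growth_form"],
        }
        for season in SEASONS:
            row[f"{season}_count"] = seasonal[season]
            row[f"{season}_pct"] = (
                percent(seasonal[season], season_n[season]) if season_n[season] else 0.0
            )
        row["overall_count"] = overall
        row["overall_pct"] = percent(overall, diet.n_samples)
        rows.append(row)
    df = pd.DataFrame(rows).sort_values(
        ["overall_count", "taxon"], ascending=[False, True], ignore_index=True
    )
    return df


def resolution_summary(diet: DietTable) -> dict:
    """Counts and percents of taxa resolved at species / genus / family."""
    counts = {r: int((diet.taxa["rank"] == r).sum()) for r in ("species", "genus", "family")}
    total = sum(counts.values())
    return {
        "n_taxa": total,
        "counts": counts,
        "percent": {r: percent(c, total) if total else 0.0 for r, c in counts.items()},
    }


def growth_form_summary(diet: DietTable) -> dict:
    counts = {
        f: int((diet.taxa["growth_form"] == f).sum()) for f in ("woody", "herbaceous")
    }
    return {"n_taxa": int(len(diet.taxa)), "counts": counts}


def taxa_per_sample(diet: DietTable) -> tuple[pd.Series, dict]:
    """Per-sample taxon richness plus overall and seasonal location stats."""
    per_sample = diet.presence.sum(axis=1).astype(int)

    def stats(values: pd.Series) -> dict:
        if len(values) == 0:
            return {"n": 0}
        return {
            "n": int(len(values)),
            "mean": float(values.mean()),
            "median": float(values.median()),
            "min": int(values.min()),
            "max": int(values.max()),
        }

    out = {"overall": stats(per_sample)}
    for season in SEASONS:
        ids = [sid for sid, s in diet.seasons.items() if s == season]
        out[season] = stats(per_sample.loc[ids]) if ids else {"n": 0}
    return per_sample, out


# -- packaged diet-summary fixture ----------------------------------------


@dataclass
class Table1Fixture:
    """The packaged 72-taxon diet summary with its seasonal sample sizes."""

    df: pd.DataFrame
    season_n: dict[str, int]
    n_samples: int

    def resolution_summary(self) -> dict:
        counts = {
            r: int((self.df["rank"] == r).sum()) for r in ("species", "genus", "family")
        }
        total = sum(counts.values())
        return {
            "n_taxa": total,
            "counts": counts,
            "percent": {r: percent(c, total) for r, c in counts.items()},
        }

    def growth_form_summary(self) -> dict:
        counts = {
            f: int((self.df["growth_form"] == f).sum()) for f in ("woody", "herbaceous")
        }
        return {"n_taxa": int(len(self.df)), "counts": counts}

    def occurrence_percent(self, taxon: str) -> float:
        row = self.df[self.df["taxon"] == taxon]
        if row.empty:
            raise SummaryError(f"taxon not in fixture: {taxon}")
        return percent(int(row["overall_count"].iloc[0]), self.n_samples)

    def family_occurrence_counts(self) -> pd.Series:
        """Samples per family cannot be derived from taxon rows (presences
        overlap within a sample), so this reports the per-family max taxon
        count as a lower bound and is mainly useful for ordering."""
        return self.df.groupby("family")["overall_count"].max().sort_values(ascending=False)


def load_table1_fixture(validate: bool = True) -> Table1Fixture:
    """Load and validate the packaged diet-summary transcription.

    Validation checks: 72 rows; 43 distinct families; every overall count
    equals the sum of its four seasonal counts; every printed percent
    matches the count recomputed against its seasonal sample size to one
    decimal (half-up).
    """
    with resources.files("dietbarcode.data").joinpath("table1.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    fixture = Table1Fixture(df=df, season_n=dict(TABLE1_SEASON_N), n_samples=TABLE1_N)
    if validate:
        errors = validate_table1(fixture)
        if errors:
            raise SummaryError("fixture validation failed: " + "; ".join(errors))
    return fixture


def validate_table1(fixture: Table1Fixture) -> list[str]:
    df, errors = fixture.df, []
    if len(df) != 72:
        errors.append(f"expected 72 rows, found {len(df)}")
    n_fam = df["family"].nunique()
    if n_fam != 43:
        errors.append(f"expected 43 families, found {n_fam}")
    for _, row in df.iterrows():
        seasonal = [int(row[f"{s}_count"]) for s in SEASONS]
        if int(row["overall_count"]) != sum(seasonal):
            errors.append(f"{row['taxon']}: overall != sum of seasons")
        for season in SEASONS:
            expect = percent(int(row[f"{season}_count"]), fixture.season_n[season])
            got = round_half_up(float(row[f"{season}_pct"]), 1)
            if abs(expect - got) > 0.05:
                errors.append(
                    f"{row['taxon']}: {season} percent {got} != recomputed {expect}"
                )
        expect = percent(int(row["overall_count"]), fixture.n_samples)
        if abs(expect - round_half_up(float(row["overall_pct"]), 1)) > 0.05:
            errors.append(f"{row['taxon']}: overall percent mismatch")
    return errors
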