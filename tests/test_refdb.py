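"""Reference database construction, curation and resolution classes."""

import numpy as np
import pytest

from dietbarcode.refdb import (
    DEFAULT_ANCHOR_F,
    DEFAULT_ANCHOR_R,
    ReferenceDatabaseError,
    UntrimmableError,
    build_database,
    classify_resolution,
    classify_species_set,
    curate_database,
    flag_bait_confounded,
    resolution_percentages,
    trim_to_region,
)

from conftest import make_seq, wrap_with_anchors


class TestTrimToRegion:
    def test_exact_anchors(self):
        rng = np.random.default_rng(0)
        region = make_seq(rng, 262)
        assert trim_to_region(wrap_with_anchors(region, rng)) == region

    def test_missing_reverse_anchor(self):
        rng = np.random.default_rng(1)
        raw = make_seq(rng, 6) + DEFAULT_ANCHOR_F + make_seq(rng, 262)
        with pytest.raises(UntrimmableError, match="reverse"):
            trim_to_region(raw)

    def test_one_mismatch_in_forward_anchor_still_extracts(self):
        rng = np.random.default_rng(2)
        region = make_seq(rng, 100)
        fwd = list(DEFAULT_ANCHOR_F)
        fwd[5] = "A" if fwd[5] != "A" else "C"
        raw = "".join(fwd) + region + DEFAULT_ANCHOR_R
        assert trim_to_region(raw) == region

    def test_three_mismatches_rejected(self):
        rng = np.random.default_rng(3)
        region = make_seq(rng, 100)
        fwd = list(DEFAULT_ANCHOR_F)
        for i in (0, 5, 9):
            fwd[i] = "A" if fwd[i] != "A" else "C"
        with pytest.raises(UntrimmableError):
            trim_to_region("".join(fwd) + region + DEFAULT_ANCHOR_R)

    def test_brute_force_anchor_scan_oracle(self):
        """Anchor located anywhere in the raw sequence, <=2 mismatches."""
        rng = np.random.default_rng(4)
        for trial in range(20):
            region = make_seq(rng, 80)
            fwd = list(DEFAULT_ANCHOR_F)
            n_mm = int(rng.integers(0, 3))
            for pos in rng.choice(len(fwd), size=n_mm, replace=False):
                fwd[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[fwd[pos]]
            raw = make_seq(rng, int(rng.integers(0, 30))) + "".join(fwd) + region + DEFAULT_ANCHOR_R
            assert trim_to_region(raw) == region


class TestBuildDatabase:
    def _pool(self, entries):
        rng = np.random.default_rng(9)
        return [(acc, sp, wrap_with_anchors(seq, rng)) for acc, sp, seq in entries]

    def test_same_species_duplicates_merge(self, toy_flora):
        rng = np.random.default_rng(5)
        seq = make_seq(rng, 120)
        db = build_database(
            toy_flora,
            self._pool([("A1", "Quercus acuta", seq), ("A2", "Quercus acuta", seq)]),
        )
        assert len(db) == 1
        entry = next(iter(db.entries.values()))
        assert entry.species == {"Quercus acuta"}
        assert entry.accessions == {"A1", "A2"}

    def test_congeners_sharing_sequence_merge_sources(self, toy_flora):
        rng = np.random.default_rng(6)
        seq = make_seq(rng, 120)
        db = build_database(
            toy_flora,
            self._pool([("A1", "Quercus acuta", seq), ("A2", "Quercus glauca", seq)]),
        )
        assert len(db) == 1
        assert next(iter(db.entries.values())).species == {
            "Quercus acuta", "Quercus glauca"
        }

    def test_blacklisted_accession_dropped(self, toy_flora):
        """A misidentified accession is excluded before dedup."""
        rng = np.random.default_rng(7)
        good, bad = make_seq(rng, 120), make_seq(rng, 120)
        db = build_database(
            toy_flora,
            self._pool(
                [("A1", "Cinnamomum camphora", good), ("HE963559", "Cinnamomum camphora", bad)]
            ),
            blacklist={"HE963559": "misidentified (clusters elsewhere)"},
        )
        assert len(db) == 1
        assert "HE963559" in db.blacklisted
        assert next(iter(db.entries.values())).sequence == good

    def test_unknown_species_is_error(self, toy_flora):
        rng = np.random.default_rng(8)
        with pytest.raises(ReferenceDatabaseError, match="Fagus crenata"):
            build_database(toy_flora, self._pool([("A1", "Fagus crenata", make_seq(rng, 99))]))

    def test_uncovered_species_reported(self, toy_flora):
        rng = np.random.default_rng(9)
        db = build_database(
            toy_flora, self._pool([("A1", "Quercus acuta", make_seq(rng, 99))])
        )
        assert "Machilus thunbergii" in db.uncovered_species
        assert "Quercus acuta" not in db.uncovered_species

    def test_rebuild_is_byte_identical(self, toy_flora, tmp_path):
        rng = np.random.default_rng(10)
        pool = self._pool(
            [("A1", "Quercus acuta", make_seq(rng, 90)),
             ("A2", "Quercus glauca", make_seq(rng, 90))]
        )
        paths = []
        for name in ("x", "y"):
            db = build_database(toy_flora, list(pool))
            p = tmp_path / f"{name}.tsv"
            db.to_tsv(p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()


class TestResolutionClasses:
    def test_published_worked_percentages(self):
        """Counts (631, 96, 44, 11) of 782 give 80.7 / 12.3 / 5.6 / 1.4."""
        summary = resolution_percentages(
            {
                "species_specific": 631,
                "genus_shared": 96,
                "family_shared": 44,
                "unassignable": 11,
            }
        )
        assert summary["percent"] == {
            "species_specific": 80.7,
            "genus_shared": 12.3,
            "family_shared": 5.6,
            "unassignable": 1.4,
        }

    def test_single_entry_single_species(self, toy_flora):
        rng = np.random.default_rng(11)
        db = build_database(
            toy_flora,
            [("A1", "Quercus acuta", wrap_with_anchors(make_seq(rng, 99), rng))],
        )
        summary = classify_resolution(db, toy_flora)
        assert summary["percent"]["species_specific"] == 100.0

    def test_cross_genus_entry_is_family_shared(self, toy_flora):
        assert (
            classify_species_set({"Quercus acuta", "Lithocarpus edulis"}, toy_flora)
            == "family_shared"
        )

    def test_agrees_with_pairwise_oracle_on_random_dbs(self, flora20):
        """Class from pairwise genus/family comparisons matches, <=50 entries."""
        rng = np.random.default_rng(12)
        species = flora20.species
        for _ in range(30):
            size = int(rng.integers(1, 5))
            subset = set(rng.choice(species, size=size, replace=False))
            got = classify_species_set(subset, flora20)
            pairs = [(a, b) for i, a in enumerate(sorted(subset)) for b in sorted(subset)[i + 1:]]
            if not pairs:
                expected = "species_specific"
            elif all(flora20.genus_of(a) == flora20.genus_of(b) for a, b in pairs):
                expected = "genus_shared"
            elif all(flora20.family_of(a) == flora20.family_of(b) for a, b in pairs):
                expected = "family_shared"
            else:
                expected = "unassignable"
            assert got == expected

    def test_percentages_partition(self, flora20):
        rng = np.random.default_rng(13)
        pool = []
        for i, sp in enumerate(flora20.species):
            pool.append((f"A{i}", sp, wrap_with_anchors(make_seq(rng, 70), rng)))
        db = build_database(flora20, pool)
        summary = classify_resolution(db, flora20)
        assert sum(summary["counts"].values()) == len(db)
        assert sum(summary["percent"].values()) == pytest.approx(100.0, abs=0.1)


class TestBaitConfound:
    def _db(self, toy_flora, entries):
        rng = np.random.default_rng(14)
        pool = [(f"A{i}", sp, wrap_with_anchors(seq, rng)) for i, (sp, seq) in enumerate(entries)]
        return build_database(toy_flora, pool)

    def test_shared_sequence_excludes_both(self, toy_flora):
        """An in-area species identical to bait is excluded with the bait."""
        rng = np.random.default_rng(15)
        shared = make_seq(rng, 100)
        db = self._db(toy_flora, [("Hordeum vulgare", shared), ("Quercus acuta", shared)])
        excluded = flag_bait_confounded(db, toy_flora)
        assert set(excluded) == {"Hordeum vulgare", "Quercus acuta"}

    def test_bait_with_unique_sequence_excluded_alone(self, toy_flora):
        rng = np.random.default_rng(16)
        db = self._db(
            toy_flora,
            [("Hordeum vulgare", make_seq(rng, 100)), ("Quercus acuta", make_seq(rng, 100))],
        )
        excluded = flag_bait_confounded(db, toy_flora)
        assert set(excluded) == {"Hordeum vulgare"}

    def test_species_with_distinguishing_sequence_retained(self, toy_flora):
        """One of two sequences shared with bait: the species survives."""
        rng = np.random.default_rng(17)
        shared, own = make_seq(rng, 100), make_seq(rng, 100)
        db = self._db(
            toy_flora,
            [("Hordeum vulgare", shared), ("Quercus acuta", shared), ("Quercus acuta", own)],
        )
        excluded = flag_bait_confounded(db, toy_flora)
        assert set(excluded) == {"Hordeum vulgare"}
        curated = curate_database(db, toy_flora)
        # the bait-shared sequence is dropped outright (ambiguous), but the
        # species survives through its distinguishing sequence
        assert shared not in curated.entries
        assert all("Hordeum vulgare" not in e.species for e in curated.entries.values())
        assert any("Quercus acuta" in e.species for e in curated.entries.values())
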