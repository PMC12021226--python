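"""Synthetic flora, reference pool and fecal read sets with known truth.

The generator emulates the data a plant diet-metabarcoding study works
from: a study-area flora with a species/genus/family hierarchy, a pool of
reference barcode sequences (deposited accessions), and per-sample merged
amplicon reads drawn from seasonal diet profiles.  Sequence structure is
built top-down — one random root per family, genera diverged from the root
by a fixed number of substitutions, species diverged from their genus
backbone likewise — so within-genus and within-family identity is under
direct control and genus- or family-ambiguous sequences can be created by
construction (divergence 0 makes congeners identical).

Reads carry four origins, all recorded in the ground truth: diet reads
(multinomial draws from the sample's seasonal profile, with i.i.d.
substitution errors), two-parent chimeras joining a prefix and suffix of
two diet reads from the same sample, bait reads copied from trap-bait
species, and rare contaminant reads copied from out-of-area species.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import child_rng
from .refdb import DEFAULT_ANCHOR_F, DEFAULT_ANCHOR_R
from .taxonomy import Flora, FloraRecord

SEASONS = ("spring", "summer", "autumn", "winter")
#: Representative collection month per season (northern-hemisphere bins
#: Mar-May / Jun-Aug / Sep-Nov / Dec-Feb).
SEASON_MONTH = {"spring": 4, "summer": 7, "autumn": 10, "winter": 1}

_BASES = np.array(list("ACGT"))


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study-design constants for a synthetic run.

    Defaults describe the standing synthetic study: a small flora (6
    families x 2 genera x 2 species), the 262 bp barcode region, 24
    samples spread evenly over four seasons, 2000 merged reads per sample,
    a 1e-3 per-base substitution error rate, 2% chimeric reads, 5% bait
    reads and 1% contaminant reads.
    """

    n_families: int = 6
    genera_per_family: int = 2
    species_per_genus: int = 2
    region_length: int = 262
    within_genus_div: int = 8  # substitutions per congeneric sequence pair
    within_family_div: int = 25  # substitutions between genus backbones
    n_samples: int = 24
    season_assignment: dict[str, str] | None = None  # sample -> season
    diet_profile: dict[str, dict[str, float]] | None = None  # season -> taxon -> p
    read_depth: int = 2000
    error_rate: float = 1e-3
    chimera_rate: float = 0.02
    bait_fraction: float = 0.05
    contaminant_fraction: float = 0.01
    n_bait_species: int = 1
    n_contaminant_species: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.region_length < 50:
            raise SimulationError("region_length must be >= 50")
        for name in ("error_rate", "chimera_rate", "bait_fraction", "contaminant_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name} must be in [0, 1]")
        if self.chimera_rate + self.bait_fraction + self.contaminant_fraction > 0.5:
            raise SimulationError("chimera + bait + contaminant fractions exceed 0.5")
        if (self.species_per_genus - 1) * self.within_genus_div > self.region_length:
            raise SimulationError("within-genus divergence exceeds region length")
        if (self.genera_per_family - 1) * self.within_family_div > self.region_length:
            raise SimulationError("within-family divergence exceeds region length")
        if self.diet_profile is not None:
            for season, profile in self.diet_profile.items():
                if not profile:
                    raise SimulationError(f"empty diet profile for {season}")
                total = sum(profile.values())
                if abs(total - 1.0) > 1e-9:
                    raise SimulationError(
                        f"diet profile for {season} sums to {total}, expected 1"
                    )

    def sample_ids(self) -> list[str]:
        return [f"S{i + 1:03d}" for i in range(self.n_samples)]

    def seasons(self) -> dict[str, str]:
        """Sample -> season map; default is a round-robin over the bins."""
        if self.season_assignment is not None:
            return dict(self.season_assignment)
        return {sid: SEASONS[i % 4] for i, sid in enumerate(self.sample_ids())}


@dataclass
class GroundTruth:
    """What was actually put into each synthetic sample."""

    true_taxa: dict[str, list[str]]  # sample -> sorted diet species present
    read_origins: dict[str, list[str]]  # sample -> per-read origin labels
    diet_read_species: dict[str, list[str]]  # sample -> species behind diet reads

    def occurrence_counts(self) -> dict[str, int]:
        """Per-species number of samples in which it truly occurs."""
        counts: dict[str, int] = {}
        for taxa in self.true_taxa.values():
            for sp in taxa:
                counts[sp] = counts.get(sp, 0) + 1
        return dict(sorted(counts.items()))

    def frequency_of_occurrence(self) -> dict[str, float]:
        n = len(self.true_taxa)
        return {sp: c / n for sp, c in self.occurrence_counts().items()}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "true_taxa": self.true_taxa,
            "read_origins": self.read_origins,
            "diet_read_species": self.diet_read_species,
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")


@dataclass
class Simulation:
    flora: Flora
    pool: list[tuple[str, str, str]]  # (accession, species, raw sequence)
    species_sequences: dict[str, str]  # species -> true region sequence
    reads: dict[str, list[str]] = field(default_factory=dict)
    metadata: pd.DataFrame | None = None
    ground_truth: GroundTruth | None = None

    def local_pool(self) -> list[tuple[str, str, str]]:
        """Accessions for the local database: in-area plus bait species."""
        return [
            (acc, sp, raw)
            for acc, sp, raw in self.pool
            if self.flora.record(sp).in_area or self.flora.record(sp).is_bait
        ]

    def fallback_pool(self) -> list[tuple[str, str, str]]:
        """The full pool, standing in for a public-repository search."""
        return list(self.pool)


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length)


def _codes_to_str(codes: np.ndarray) -> str:
    return "".join(_BASES[codes])


def _mutate_at(codes: np.ndarray, positions: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Substitute each listed position with a uniformly different base."""
    out = codes.copy()
    shifts = rng.integers(1, 4, size=len(positions))
    out[positions] = (out[positions] + shifts) % 4
    return out


def generate_flora(cfg: SimConfig) -> Simulation:
    """Build the toy flora and its reference sequence pool.

    Within a genus, species 1 carries the genus backbone sequence and each
    further species is substituted at its own disjoint block of
    ``within_genus_div`` positions, so a congeneric pair involving species
    1 differs by exactly that many substitutions.  Genera diverge from the
    family root the same way.  Bait and contaminant species get their own
    families with independent root sequences.  Deterministic given
    ``cfg.seed``.
    """
    cfg.validate()
    rng = child_rng(cfg.seed, 1)
    L = cfg.region_length

    records: list[FloraRecord] = []
    seqs: dict[str, str] = {}

    def add_family(fam: str, n_genera: int, n_species: int, *, in_area: bool, is_bait: bool,
                   growth_forms: Sequence[str]) -> None:
        root = _random_seq(rng, L)
        genus_positions = rng.permutation(L)
        for j in range(n_genera):
            genus = f"{fam}_genus{j + 1}"
            if j == 0:
                gcodes = root
            else:
                block = genus_positions[(j - 1) * cfg.within_family_div : j * cfg.within_family_div]
                gcodes = _mutate_at(root, block, rng)
            species_positions = rng.permutation(L)
            for k in range(n_species):
                species = f"{genus} sp{k + 1}"
                if k == 0:
                    scodes = gcodes
                else:
                    block = species_positions[
                        (k - 1) * cfg.within_genus_div : k * cfg.within_genus_div
                    ]
                    scodes = _mutate_at(gcodes, block, rng)
                records.append(
                    FloraRecord(
                        species=species,
                        genus=genus,
                        family=fam,
                        growth_form=growth_forms[(j * n_species + k) % len(growth_forms)],
                        in_area=in_area,
                        is_bait=is_bait,
                    )
                )
                seqs[species] = _codes_to_str(scodes)

    for i in range(cfg.n_families):
        add_family(
            f"Family{i + 1}",
            cfg.genera_per_family,
            cfg.species_per_genus,
            in_area=True,
            is_bait=False,
            growth_forms=("woody", "herbaceous") if i % 2 else ("woody",),
        )
    for i in range(cfg.n_bait_species):
        add_family(f"Baitfamily{i + 1}", 1, 1, in_area=False, is_bait=True,
                   growth_forms=("herbaceous",))
    for i in range(cfg.n_contaminant_species):
        add_family(f"Alpinefamily{i + 1}", 1, 1, in_area=False, is_bait=False,
                   growth_forms=("herbaceous",))

    flora = Flora(records)
    pool: list[tuple[str, str, str]] = []
    for idx, rec in enumerate(records):
        accession = f"SIM{idx + 1:05d}"
        flank5 = _codes_to_str(_random_seq(rng, 8))
        flank3 = _codes_to_str(_random_seq(rng, 8))
        raw = flank5 + DEFAULT_ANCHOR_F + seqs[rec.species] + DEFAULT_ANCHOR_R + flank3
        pool.append((accession, rec.species, raw))
    return Simulation(flora=flora, pool=pool, species_sequences=seqs)


def default_diet_profiles(flora: Flora, cfg: SimConfig) -> dict[str, dict[str, float]]:
    """Seasonal diet profiles over the in-area flora.

    Spring/summer/autumn eat six species each (a rotating window over the
    species list, so seasons overlap but differ) with relative abundances
    0.35/0.20/0.15/0.10/0.10/0.10; winter eats a narrower set of four
    (0.40/0.30/0.20/0.10), emulating the poorer cold-season diet a field
    study sees.  Every dietary taxon is common enough (>= 10% of winter
    diet reads, >= 5% otherwise) to survive the 1% low-frequency filter.
    """
    diet_species = [r.species for r in flora if r.in_area]
    if len(diet_species) < 2:
        raise SimulationError("need at least two in-area species for diet profiles")
    season_weights = {
        "spring": [0.35, 0.20, 0.15, 0.10, 0.10, 0.10],
        "summer": [0.35, 0.20, 0.15, 0.10, 0.10, 0.10],
        "autumn": [0.35, 0.20, 0.15, 0.10, 0.10, 0.10],
        "winter": [0.40, 0.30, 0.20, 0.10],
    }
    profiles: dict[str, dict[str, float]] = {}
    for s_idx, season in enumerate(SEASONS):
        weights = season_weights[season]
        k = min(len(weights), len(diet_species))
        w = np.array(weights[:k])
        w = w / w.sum()
        start = (3 * s_idx) % len(diet_species)
        chosen = [(start + j) % len(diet_species) for j in range(k)]
        profiles[season] = {diet_species[i]: float(w[j]) for j, i in enumerate(chosen)}
    return profiles


def _apply_errors(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), error_rate)
    if n_err == 0:
        return seq
    codes = np.searchsorted(_BASES, np.frombuffer(seq.encode(), dtype="S1").astype("U1"))
    positions = rng.choice(len(seq), size=n_err, replace=False)
    return _codes_to_str(_mutate_at(codes, positions, rng))


def generate_samples(sim: Simulation, cfg: SimConfig) -> Simulation:
    """Draw per-sample reads and record the ground truth.

    Per sample: the read count is exactly ``cfg.read_depth``; category
    counts (chimera / bait / contaminant / diet) are multinomial at the
    configured fractions; diet reads are multinomial over the season's
    profile with substitution errors applied i.i.d.; chimeras join a
    prefix of one diet read of the sample with the suffix of another at a
    uniform breakpoint.  The read order within a sample is shuffled.
    """
    cfg.validate()
    flora = sim.flora
    profiles = cfg.diet_profile or default_diet_profiles(flora, cfg)
    for season, profile in profiles.items():
        if not profile:
            raise SimulationError(f"empty diet profile for {season}")
        for sp in profile:
            rec = flora.record(sp)  # raises if unknown
            if not rec.in_area:
                raise SimulationError(f"diet profile references out-of-area species {sp}")

    bait_species = sorted(flora.bait_species)
    contaminant_species = sorted(
        r.species for r in flora if not r.in_area and not r.is_bait
    )
    if cfg.bait_fraction > 0 and not bait_species:
        raise SimulationError("bait_fraction > 0 but flora has no bait species")
    if cfg.contaminant_fraction > 0 and not contaminant_species:
        raise SimulationError("contaminant_fraction > 0 but no out-of-area species")

    seasons = cfg.seasons()
    reads: dict[str, list[str]] = {}
    origins: dict[str, list[str]] = {}
    true_taxa: dict[str, list[str]] = {}
    diet_species_log: dict[str, list[str]] = {}
    meta_rows = []

    for s_idx, sid in enumerate(cfg.sample_ids()):
        season = seasons[sid]
        profile = profiles[season]
        rng = child_rng(cfg.seed, 2, s_idx)
        meta_rows.append(
            {"sample_id": sid, "season": season, "collection_month": SEASON_MONTH[season]}
        )

        fracs = [cfg.chimera_rate, cfg.bait_fraction, cfg.contaminant_fraction]
        fracs.append(1.0 - sum(fracs))
        n_chim, n_bait, n_contam, n_diet = rng.multinomial(cfg.read_depth, fracs)
        if n_diet < 2 and n_chim > 0:  # chimeras need two parents
            n_diet += n_chim
            n_chim = 0

        taxa = sorted(profile)
        taxon_counts = rng.multinomial(n_diet, [profile[t] for t in taxa])
        diet_reads: list[str] = []
        diet_sources: list[str] = []
        for taxon, count in zip(taxa, taxon_counts):
            base = sim.species_sequences[taxon]
            for _ in range(count):
                diet_reads.append(_apply_errors(base, rng, cfg.error_rate))
                diet_sources.append(taxon)

        sample_reads = list(diet_reads)
        sample_origins = ["diet"] * len(diet_reads)

        for _ in range(n_chim):
            i, j = rng.choice(len(diet_reads), size=2, replace=False)
            k = int(rng.integers(1, cfg.region_length))
            sample_reads.append(diet_reads[i][:k] + diet_reads[j][k:])
            sample_origins.append("chimera")
        for b in range(n_bait):
            sp = bait_species[b % len(bait_species)]
            sample_reads.append(_apply_errors(sim.species_sequences[sp], rng, cfg.error_rate))
            sample_origins.append("bait")
        if n_contam:
            # one contaminant source per sample (rotating), as a stray
            # pollen/lab contamination event typically is
            sp = contaminant_species[s_idx % len(contaminant_species)]
            for _ in range(n_contam):
                sample_reads.append(_apply_errors(sim.species_sequences[sp], rng, cfg.error_rate))
                sample_origins.append("contaminant")

        order = rng.permutation(len(sample_reads))
        reads[sid] = [sample_reads[i] for i in order]
        origins[sid] = [sample_origins[i] for i in order]
        present = sorted({sp for sp, c in zip(taxa, taxon_counts) if c > 0})
        true_taxa[sid] = present
        diet_species_log[sid] = diet_sources

    sim.reads = reads
    sim.metadata = pd.DataFrame(meta_rows)
    sim.ground_truth = GroundTruth(
        true_taxa=true_taxa, read_origins=origins, diet_read_species=diet_species_log
    )
    return sim


# -- on-disk interfaces ----------------------------------------------------


def write_pool_fasta(pool: list[tuple[str, str, str]], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(raw), id=f"{acc}|{sp}", description="") for acc, sp, raw in pool
    ]
    SeqIO.write(records, str(path), "fasta")


def write_fastq_dir(sim: Simulation, outdir: str | Path) -> None:
    """One ``<sample_id>.fastq`` per sample; constant Q37 placeholder quality."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sid, seqs in sim.reads.items():
        records = []
        for i, seq in enumerate(seqs):
            rec = SeqRecord(Seq(seq), id=f"{sid}_read{i + 1}", description="")
            rec.letter_annotations["phred_quality"] = [37] * len(seq)
            records.append(rec)
        SeqIO.write(records, str(outdir / f"{sid}.fastq"), "fastq")


def read_fastq_dir(indir: str | Path) -> dict[str, list[str]]:
    """Read ``<sample_id>.fastq`` files back into per-sample read lists."""
    out: dict[str, list[str]] = {}
    for path in sorted(Path(indir).glob("*.fastq")):
        out[path.stem] = [str(rec.seq) for rec in SeqIO.parse(str(path), "fastq")]
    return out


def write_metadata(sim: Simulation, path: str | Path) -> None:
    sim.metadata.to_csv(path, sep="\t", index=False)
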