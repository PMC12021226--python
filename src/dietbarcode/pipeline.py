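"""End-to-end orchestration: reads -> ASV table -> assignments -> diet table.

Convenience layer tying the modules together in the fixed order the
analysis defines: build and curate the local database, dereplicate and
filter the reads, rarefy, assign every surviving ASV through the tiered
search, and collapse to the sample x taxon diet table.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import asv as asv_mod
from .assign import Assignment, PipelineConfig, assign_table
from .refdb import ReferenceDatabase, build_database, curate_database
from .simulate import SimConfig, Simulation, generate_flora, generate_samples
from .summarize import DietTable, build_diet_table, frequency_of_occurrence
from .taxonomy import Flora


@dataclass
class PipelineResult:
    flora: Flora
    local_db: ReferenceDatabase
    fallback_db: ReferenceDatabase
    stages: dict[str, asv_mod.ASVTable]
    assignments: list[Assignment]
    identification: dict
    diet: DietTable
    occurrence: pd.DataFrame


def run_reads_pipeline(
    flora: Flora,
    local_db: ReferenceDatabase,
    fallback_db: ReferenceDatabase | None,
    reads: dict[str, list[str]],
    metadata: pd.DataFrame,
    cfg: PipelineConfig,
) -> PipelineResult:
    """Run the read-processing and identification chain on prepared inputs."""
    cfg.validate()
    stages = asv_mod.run_chain(
        reads,
        depth=cfg.rarefaction_depth,
        lowfreq_threshold=cfg.lowfreq_threshold,
        seed=cfg.seed,
    )
    rarefied = stages["rarefied"]
    assignments, identification = assign_table(
        rarefied.asvs, local_db, fallback_db, flora, cfg
    )
    diet = build_diet_table(assignments, rarefied, metadata, flora)
    occurrence = frequency_of_occurrence(diet)
    return PipelineResult(
        flora=flora,
        local_db=local_db,
        fallback_db=fallback_db,
        stages=stages,
        assignments=assignments,
        identification=identification,
        diet=diet,
        occurrence=occurrence,
    )


def run_synthetic_pipeline(
    sim_cfg: SimConfig | None = None,
    pipe_cfg: PipelineConfig | None = None,
) -> tuple[Simulation, PipelineResult]:
    """Simulate a study and run the full pipeline on it.

    The local database is built from in-area and bait accessions and
    curated (bait-confound exclusion); the fallback database is built
    from the full pool, emulating a public-repository search.
    """
    sim_cfg = sim_cfg or SimConfig()
    pipe_cfg = pipe_cfg or PipelineConfig(seed=sim_cfg.seed)
    sim = generate_flora(sim_cfg)
    generate_samples(sim, sim_cfg)
    local_db = curate_database(build_database(sim.flora, sim.local_pool()), sim.flora)
    fallback_db = build_database(sim.flora, sim.fallback_pool())
    result = run_reads_pipeline(
        sim.flora, local_db, fallback_db, sim.reads, sim.metadata, pipe_cfg
    )
    return sim, result
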