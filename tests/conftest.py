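"""Shared fixtures: a small hand-built flora and helpers."""

from __future__ import annotations

import numpy as np
import pytest

from dietbarcode.refdb import DEFAULT_ANCHOR_F, DEFAULT_ANCHOR_R
from dietbarcode.taxonomy import Flora, FloraRecord


def make_seq(rng: np.random.Generator, length: int = 262) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture
def toy_flora() -> Flora:
    """Two families, mixed genera, a bait species and an out-of-area one."""
    return Flora(
        [
            FloraRecord("Quercus acuta", "Quercus", "Fagaceae"),
            FloraRecord("Quercus glauca", "Quercus", "Fagaceae"),
            FloraRecord("Quercus serrata", "Quercus", "Fagaceae"),
            FloraRecord("Lithocarpus edulis", "Lithocarpus", "Fagaceae"),
            FloraRecord("Cinnamomum camphora", "Cinnamomum", "Lauraceae"),
            FloraRecord("Machilus thunbergii", "Machilus", "Lauraceae"),
            FloraRecord(
                "Hordeum vulgare", "Hordeum", "Poaceae",
                growth_form="herbaceous", in_area=False, is_bait=True,
            ),
            FloraRecord(
                "Gentiana nipponica", "Gentiana", "Gentianaceae",
                growth_form="herbaceous", in_area=False,
            ),
        ]
    )


@pytest.fixture
def flora20() -> Flora:
    """20 species across 4 families / 8 genera for oracle comparisons."""
    records = []
    n = 0
    for f in range(4):
        for g in range(2):
            genus = f"Genus{f}{g}"
            for s in range(2 if f < 2 else 3):
                records.append(
                    FloraRecord(f"{genus} sp{s}", genus, f"Family{f}")
                )
                n += 1
    return Flora(records)


def wrap_with_anchors(region: str, rng: np.random.Generator | None = None) -> str:
    """Embed a region between the default anchors with small random flanks."""
    rng = rng or np.random.default_rng(0)
    return make_seq(rng, 6) + DEFAULT_ANCHOR_F + region + DEFAULT_ANCHOR_R + make_seq(rng, 6)
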