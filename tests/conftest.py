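"""Shared fixtures: all data is generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

from veinfuse.synthetic_leaf import (
    SpeciesArchetype,
    appearance_trio_archetypes,
    generate_dataset,
    generate_leaf,
    venation_trio_archetypes,
)


@pytest.fixture(scope="session")
def vein_archetype() -> SpeciesArchetype:
    """Reference archetype for vein-recovery checks: 3 px veins, 25 px spacing."""
    return SpeciesArchetype(name="ref", blade_shape="ovate", vein_order_count=2,
                            secondary_vein_angle_deg=45.0,
                            secondary_vein_spacing_px=25.0, vein_width_px=3,
                            vein_contrast=0.15)


@pytest.fixture(scope="session")
def sample_leaf(vein_archetype):
    return generate_leaf(vein_archetype, (224, 224), rng_seed=0)


def _assign_splits(records, n_train, n_val):
    by = {}
    for r in records:
        by.setdefault(r.label, []).append(r)
    for rs in by.values():
        for i, r in enumerate(rs):
            r.split = "train" if i < n_train else ("val" if i < n_train + n_val else "test")
    return records


@pytest.fixture(scope="session")
def color_trio_records():
    """3 classes separable by appearance (color/shape); 50/10/10 per class."""
    records = generate_dataset(appearance_trio_archetypes(),
                               {"A": 70, "B": 70, "C": 70}, rng_seed=7)
    return _assign_splits(records, 50, 10)


@pytest.fixture(scope="session")
def venation_trio_records():
    """3 classes distinguishable by venation only; 50/10/10 per class."""
    records = generate_dataset(venation_trio_archetypes(),
                               {"V1": 70, "V2": 70, "V3": 70}, rng_seed=11)
    return _assign_splits(records, 50, 10)


@pytest.fixture(scope="session")
def feature_cache() -> dict:
    """Session-wide branch-feature cache (backbones are frozen, so sharing is safe)."""
    return {}


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
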