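import numpy as np
import pytest

import nichelegacy as nl


@pytest.fixture(scope="session")
def landscape():
    """One shared synthetic landscape (19 variables, 2 latent factors)."""
    return nl.generate_climate_landscape(nl.LandscapeSpec(seed=0))


@pytest.fixture(scope="session")
def background(landscape):
    return nl.apply_background_mask(landscape.grid, landscape.mask)


@pytest.fixture(scope="session")
def space(background):
    return nl.fit_environmental_pca(background)


@pytest.fixture(scope="session")
def bg_scores(space, background):
    return nl.project(space, background.X)


@pytest.fixture(scope="session")
def availability(bg_scores):
    return nl.build_availability_density(bg_scores)


def cell_occurrences(df, landscape, background, taxon="t"):
    """Downscale a synthetic occurrence table to occupied background cells."""
    records, _ = nl.records_from_frame(df)
    return nl.assign_to_cells(records, landscape.grid, background, taxon=taxon)


def occupancy_of(df, landscape, background, space, availability, taxon="t"):
    """Full chain from a synthetic occurrence table to an occupancy surface."""
    co = cell_occurrences(df, landscape, background, taxon=taxon)
    scores = nl.project(space, co.climate_values(landscape.grid))
    return nl.build_occupancy(scores, availability)
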