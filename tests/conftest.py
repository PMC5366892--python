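import numpy as np
import pytest

from microstab.domain_model import CommunityTimeSeries, Origin, Treatment, TrophicGroup
from microstab.synthetic_data import default_config, simulate_experiment


def make_series(
    density,
    species=None,
    days=None,
    trophic=None,
    origin=None,
    treatment=Treatment.CONTROL,
    microcosm_id="m1",
):
    """Build a small CommunityTimeSeries with sensible defaults."""
    density = np.asarray(density, dtype=float)
    n_sp, n_days = density.shape
    if species is None:
        species = [f"sp{i}" for i in range(n_sp)]
    if days is None:
        days = list(range(7, 7 * (n_days + 1), 7))
    if trophic is None:
        trophic = {s: TrophicGroup.ALGA for s in species}
    if origin is None:
        origin = {s: Origin.RESIDENT for s in species}
    return CommunityTimeSeries(
        microcosm_id=microcosm_id,
        treatment=treatment,
        sampling_days=tuple(days),
        species_names=tuple(species),
        trophic_group=trophic,
        origin=origin,
        density=density,
    )


@pytest.fixture(scope="session")
def shipped_config():
    return default_config(seed=0)


@pytest.fixture(scope="session")
def shipped_experiment(shipped_config):
    """One full simulated experiment at the shipped defaults (seed 0)."""
    return simulate_experiment(shipped_config)
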