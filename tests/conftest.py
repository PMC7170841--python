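import numpy as np
import pytest

from bescreen.guide_design import build_library
from bescreen.synthetic_screen import SimTruth, generate_reference, simulate_screen

from helpers import build_filter_toy


@pytest.fixture(scope="session")
def toy_reference():
    """Hand-planted three-gene genome exercising every design rule."""
    return build_filter_toy()


@pytest.fixture(scope="session")
def random_reference():
    return generate_reference(n_genes=3, length_range=(300, 600), gc=0.4, seed=1)


@pytest.fixture(scope="session")
def random_library(random_reference):
    library, report = build_library(random_reference)
    assert len(library) > 5
    return library


def simulate_planted(
    n_guides=2000,
    n_lethal=100,
    n_se=100,
    depth_per_guide=300,
    editing_range=(0.5, 0.9),
    seed=0,
):
    """Count-level screen with planted lethal guides; returns
    (CountTable, is_se, truth, planted ids)."""
    ids = [f"g{i:05d}" for i in range(n_guides)]
    rng = np.random.default_rng(seed)
    rates = {g: float(rng.uniform(*editing_range)) for g in ids}
    s = {g: 0.0 for g in ids}
    planted = [ids[i] for i in rng.choice(n_guides, size=n_lethal, replace=False)]
    for g in planted:
        s[g] = 1.0
    truth = SimTruth(
        editing_rate=rates,
        fitness_s=s,
        se_fraction=n_se / n_guides,
        depth_per_guide=depth_per_guide,
        generations=10.0,
        seed=seed + 1,
    )
    table, is_se = simulate_screen(ids, truth)
    return table, is_se, truth, set(planted)
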