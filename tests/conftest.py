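"""Shared fixtures.

The three expensive study runs (permuted-label null control, three-regime
recovery, mixed-world association) are session-scoped: several tests read
different aspects of the same run, and each run regenerates its world from
a fixed seed so results are identical across test orderings.
"""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from gesbench import experiments, synthgen
from gesbench.synthgen import ScenarioConfig, TargetSpec

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")

STUDY_SEED = 1


@pytest.fixture(scope="session")
def null_control_df():
    """Permuted-label control: 10 seeds × 10 pipeline repeats × 2 descriptor kinds."""
    return experiments.null_control(n_seeds=10, seed=STUDY_SEED)


@pytest.fixture(scope="session")
def regime_run():
    """Three-regime recovery at the study conditions (2000 compounds, 10 repeats, 3 seeds)."""
    return experiments.regime_recovery(seed=STUDY_SEED)


@pytest.fixture(scope="session")
def mixed_run():
    """Mixed 20-target world: benchmark + quadrant summaries + association."""
    return experiments.mixed_association(seed=STUDY_SEED)


@pytest.fixture(scope="session")
def small_world():
    """A fast single-target world with a responsive cell line, for plumbing tests."""
    cfg = ScenarioConfig(
        n_compounds=500,
        n_genes=150,
        bit_length=256,
        cell_lines=("A549", "MCF7"),
        n_scaffolds=12,
        observed_fraction=0.30,
        targets=(
            TargetSpec(
                target_id="T1",
                active_fraction=0.12,
                chem_coherent=True,
                responsive_cell_lines=("A549",),
                active_cosine_target=0.65,
            ),
        ),
        seed=7,
    )
    return synthgen.make_world(cfg)
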