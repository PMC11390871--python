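import numpy as np
import pandas as pd
import pytest

from twinprox import (
    DomainSpec,
    LifestyleSpec,
    SimulationConfig,
    simulate_cohort,
)


def small_config(
    seed: int = 0,
    n_pairs: int = 40,
    a2: float = 0.5,
    c2: float = 0.2,
    co_residence_prob: float = 0.3,
    couplings: dict | None = None,
) -> SimulationConfig:
    """Scaled-down two-domain cohort for fast tests: one omics-like domain
    with an additive-genetic component and one exposome-like domain that
    is shared exactly by co-resident pairs."""
    e2 = 1.0 - a2 - c2
    couplings = couplings or {}
    return SimulationConfig(
        n_pairs=n_pairs,
        prop_mz=0.54,
        domain_specs=(
            DomainSpec("proteome", 24, 4, a2, c2, e2, feature_noise=0.2),
            DomainSpec(
                "exposome", 16, 3, 0.0, 0.6, 0.4,
                feature_noise=0.05, shared_when_coresident=True,
            ),
        ),
        lifestyle_specs=(
            LifestyleSpec("smoking", 0.25, couplings.get("smoking", {})),
            LifestyleSpec("going_out", 0.3, couplings.get("going_out", {})),
            LifestyleSpec("reading", 0.3, couplings.get("reading", {}), missing_prob=0.1),
        ),
        co_residence_prob=co_residence_prob,
        seed=seed,
    )


@pytest.fixture(scope="session")
def demo_cohort():
    return simulate_cohort(small_config(seed=11, n_pairs=60))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_pairs_table(n_pairs: int, rng: np.random.Generator) -> pd.DataFrame:
    """Minimal pair-metadata table over twins t{i}_1 / t{i}_2."""
    pid = [f"p{i}" for i in range(n_pairs)]
    return pd.DataFrame(
        {
            "pair_id": pid,
            "twin1_id": [f"t{i}_1" for i in range(n_pairs)],
            "twin2_id": [f"t{i}_2" for i in range(n_pairs)],
            "zygosity": rng.choice(["MZ", "DZ"], n_pairs),
            "sex": rng.choice(["F", "M"], n_pairs),
            "age_blood_twin1": rng.normal(22.3, 0.6, n_pairs),
            "age_blood_twin2": rng.normal(22.3, 0.6, n_pairs),
            "age_left_home": rng.normal(19, 2, n_pairs),
            "co_resident": rng.random(n_pairs) < 0.3,
        }
    )
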