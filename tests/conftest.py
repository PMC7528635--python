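import numpy as np
import pandas as pd
import pytest

from cptdetect.cohort import ClassFractionRule, CohortConfig, simulate_cohort


def make_records(
    n_per_cell: dict[tuple[int, int, int, int], tuple[int, int]],
    z_shift_adhd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Hand-built cohort table: cell (age, gender, dow, tod) -> (n_adhd, n_control).

    Index z-scores are standard normal, shifted by ``z_shift_adhd`` on every
    index for the ADHD class.
    """
    rng = np.random.default_rng(seed)
    rows = []
    cid = 0
    for (age, gender, dow, tod), (n_a, n_c) in n_per_cell.items():
        for diagnosis, count in (("ADHD", n_a), ("control", n_c)):
            for _ in range(count):
                z = rng.standard_normal(4)
                if diagnosis == "ADHD":
                    z += z_shift_adhd
                rows.append(
                    dict(
                        child_id=cid, age=age, gender=gender, dow=dow, tod=tod,
                        z_attention=z[0], z_timeliness=z[1],
                        z_hyperactivity=z[2], z_impulsiveness=z[3],
                        diagnosis=diagnosis,
                    )
                )
                cid += 1
    return pd.DataFrame(rows)


#: confounded, globally class-imbalanced study cohort used by the evaluation
#: properties: weekend testing only among controls, afternoon/evening almost
#: only controls, a higher ADHD rate in boys than girls, ADHD index effects
#: in the 0.5-0.8 SD range and a negative ToD trend on hyperactivity
CONFOUNDED_RULES = (
    ClassFractionRule({"dow": frozenset({6, 7})}, 0.0),
    ClassFractionRule({"tod": frozenset({2, 3})}, 0.02),
    ClassFractionRule({"gender": frozenset({0})}, 0.55),
    ClassFractionRule({"gender": frozenset({1})}, 0.30),
)


def confounded_config(seed: int = 11, n: int = 458) -> CohortConfig:
    return CohortConfig(
        n_children=n,
        class_fraction_map=CONFOUNDED_RULES,
        index_effect_sizes=(-0.8, -0.7, 0.6, 0.5),
        tod_hyperactivity_slope=-0.35,
        seed=seed,
    )


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    return simulate_cohort(CohortConfig(seed=0))


@pytest.fixture(scope="session")
def confounded_cohort() -> pd.DataFrame:
    return simulate_cohort(confounded_config())
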