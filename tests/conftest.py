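import numpy as np
import pandas as pd
import pytest

from clonesel.simulate import default_scenario, simulate_phenotypes


def make_table(rows):
    """Long-format phenotype frame from (trial, plot, block, entry, family,
    is_check, value) tuples, single trait 'y'."""
    recs = [
        {
            "trial": tr,
            "plot": pl,
            "block": bl,
            "entry": en,
            "family": fa,
            "is_check": ic,
            "trait": "y",
            "value": v,
        }
        for tr, pl, bl, en, fa, ic, v in rows
    ]
    return pd.DataFrame(recs)


def one_way_table(n_groups, n_per_group, sigma2_g, sigma2_e, seed, mean=10.0):
    """Balanced one-way layout: groups as unrelated clones, no blocks."""
    rng = np.random.default_rng(seed)
    eff = rng.normal(0.0, np.sqrt(sigma2_g), n_groups)
    rows = []
    for i in range(n_groups):
        for j in range(n_per_group):
            rows.append(
                (
                    "T1",
                    f"p{i}_{j}",
                    "B1",
                    f"G{i:03d}",
                    f"F{i:03d}",
                    0,
                    mean + eff[i] + rng.normal(0.0, np.sqrt(sigma2_e)),
                )
            )
    return make_table(rows)


@pytest.fixture(scope="session")
def small_study():
    """A small three-season ABD study (8 families x 6 clones, one trait)."""
    designs, params = default_scenario(
        seed=11, n_families=8, clones_per_family=6, n_blocks=6, traits=("TTY",)
    )
    table, truth = simulate_phenotypes(designs, params)
    return designs, params, table, truth
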