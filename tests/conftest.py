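import numpy as np
import pandas as pd
import pytest

from coralnet import SimulationConfig, fixture_small, normalize_median_of_ratios, simulate


@pytest.fixture(scope="session")
def small_fixture():
    """Deterministic 12-sample / 20-OTU miniature with planted structure."""
    return fixture_small(seed=0)


@pytest.fixture(scope="session")
def small_normalized(small_fixture):
    counts, _, _, _ = small_fixture
    return normalize_median_of_ratios(counts, "pseudo-geomean")


@pytest.fixture(scope="session")
def sim_survey():
    """A reduced synthetic survey (144 samples, 120 OTUs) with the default
    planted effect ordering (genus >> site > time)."""
    cfg = SimulationConfig(seed=7, colonies_per_cell=2, n_otus=120)
    return simulate(cfg)


def survey_design(reps: int = 2) -> pd.DataFrame:
    """Fully crossed survey design: 3 genera / 6 nested species x 4 sites x
    3 times, ``reps`` colonies per cell."""
    rows = []
    genera = {
        "Porites": ["P_ast", "P_fur"],
        "Acropora": ["A_cer", "A_pal"],
        "Diploria": ["D_lab", "D_str"],
    }
    i = 0
    for g, sps in genera.items():
        for sp in sps:
            for s in ["PC", "CB", "C14", "C4"]:
                for t in ["December", "April", "October"]:
                    for _ in range(reps):
                        rows.append(
                            {"sample": f"s{i:04d}", "genus": g, "species": sp, "site": s, "time": t}
                        )
                        i += 1
    return pd.DataFrame(rows).set_index("sample")
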