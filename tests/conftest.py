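import numpy as np
import pandas as pd
import pytest

from methylrad.pipeline import run_all
from methylrad.simulate import SimulationConfig, simulate_all

STANDARD_SEED = 1


@pytest.fixture(scope="session")
def groups6() -> pd.Series:
    return pd.Series(
        {
            "T1": "treated",
            "T2": "treated",
            "T3": "treated",
            "C1": "control",
            "C2": "control",
            "C3": "control",
        }
    )


@pytest.fixture(scope="session")
def standard_sim(tmp_path_factory):
    """The standard synthetic study (3 treated vs 3 control), zero Ct noise."""
    out = tmp_path_factory.mktemp("sim_standard")
    cfg = SimulationConfig(seed=STANDARD_SEED, ct_noise_sd=0.0)
    res = simulate_all(cfg, out)
    res["config"] = cfg
    return res


@pytest.fixture(scope="session")
def standard_run(standard_sim, tmp_path_factory):
    """Full pipeline executed on the standard synthetic study."""
    out = tmp_path_factory.mktemp("run_standard")
    paths = standard_sim["paths"]
    config = {
        "genome": str(paths["genome"]),
        "gff": str(paths["gff"]),
        "ctcf": str(paths["ctcf"]),
        "samples": str(paths["samples"]),
        "ct": str(paths["ct"]),
        "terms": str(paths["terms"]),
        "pathway_genes": str(paths["pathway_genes"]),
        "seed": STANDARD_SEED,
    }
    return run_all(config, out)


def nb_counts(
    rng: np.random.Generator, mu: np.ndarray, phi: float, n_cols: int
) -> np.ndarray:
    """NB(mu, phi) count matrix with one column per replicate (Poisson at phi=0)."""
    mu = np.asarray(mu, dtype=float)
    cols = []
    for _ in range(n_cols):
        if phi > 0:
            r = 1.0 / phi
            cols.append(rng.negative_binomial(r, r / (r + mu)))
        else:
            cols.append(rng.poisson(mu))
    return np.column_stack(cols)
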