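import numpy as np
import pandas as pd
import pytest

import forestqg as fq
from forestqg.simulate import TraitConfig


@pytest.fixture()
def rng():
    return np.random.default_rng(20250901)


@pytest.fixture(scope="session")
def halfsib_pedigree():
    """3 dams x 4 progeny, sires unknown: the canonical OP family layout."""
    ids, dams = [], []
    for d in range(3):
        for k in range(4):
            ids.append(f"P{d}{k}")
            dams.append(f"D{d}")
    ped = fq.Pedigree(
        ids=ids, sires=[fq.UNKNOWN] * len(ids), dams=dams
    )
    return fq.validate_and_order(ped)


@pytest.fixture(scope="session")
def op_truth():
    """Mid-sized OP simulation shared by several modules (read-only)."""
    return fq.simulate_pedigree(
        n_dams=40, progeny_per_dam=6, pollen_pool_size=60, seed=101
    )


@pytest.fixture(scope="session")
def op_genotypes(op_truth):
    return fq.simulate_genotypes(op_truth, n_snps=2000, seed=102)


@pytest.fixture(scope="session")
def single_site_phenotypes(op_truth):
    """Single-site two-trait phenotypes with known genetic correlation 0.6."""
    A = fq.compute_A(op_truth.true_pedigree)
    site_of = {t: "S1" for t in op_truth.progeny}
    rep_of = {t: "R1" for t in op_truth.progeny}
    cfg = TraitConfig(
        traits=["T1", "T2"],
        sites=["S1"],
        heritability={("T1", "S1"): 0.5, ("T2", "S1"): 0.5},
        genetic_correlation=np.array([[1.0, 0.6], [0.6, 1.0]]),
        replication_sd=0.0,
    )
    table = fq.simulate_phenotypes(op_truth, A, cfg, site_of, rep_of, seed=103)
    return table, A


def make_phenotype_table(ids, values, site="S1", rep="R1", group="g"):
    return pd.DataFrame(
        {
            "tree": ids,
            "site": site,
            "replication": rep,
            "group": group,
            "y": values,
        }
    )
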