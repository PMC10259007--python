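import numpy as np
import pandas as pd
import pytest

from thermoqtl import pheno, relmat, syndata
from thermoqtl.containers import Pedigree


@pytest.fixture(scope="session")
def small_study():
    """One compact synthetic study shared across tests: 10-block factorial
    matings, 300 offspring x 800 SNPs, default variance ratios."""
    ped = syndata.make_pedigree(seed=11, n_offspring=300)
    snp_map = syndata.default_snp_map(n_snps=800, n_chrom=8, seed=11)
    rng = np.random.default_rng(12)
    geno = syndata.gene_drop(ped, snp_map, rng.uniform(0.1, 0.9, 800), seed=13)
    truth = syndata.challenge_truth(h2=0.29, dam_ratio=0.06)
    challenge = syndata.simulate_challenge(ped, geno, truth, seed=14)
    challenge = pheno.standardize_rtle(challenge)
    return {"ped": ped, "geno": geno, "truth": truth, "challenge": challenge}


@pytest.fixture(scope="session")
def small_grm(small_study):
    off = small_study["geno"].subset_individuals(
        small_study["challenge"]["id"].tolist()
    )
    a = relmat.a_matrix(small_study["ped"])
    return relmat.g_matrix(off, blend_weight=0.95, a=a)


@pytest.fixture
def trio_pedigree():
    """Two founders and one offspring."""
    return Pedigree(
        pd.DataFrame(
            {
                "id": ["S1", "D1", "K1"],
                "sire": ["0", "0", "S1"],
                "dam": ["0", "0", "D1"],
                "generation": [0, 0, 1],
            }
        )
    )
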