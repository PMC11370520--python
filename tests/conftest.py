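import numpy as np
import pandas as pd
import pytest

from metaprs.scoring import GenotypeMatrix, VariantWeightTable
from metaprs.simulate import (
    SimConfig,
    simulate_architecture,
    simulate_candidate_weights,
    simulate_genotypes,
    simulate_phenotypes,
)


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(
        n_samples=800,
        n_variants=300,
        n_causal=40,
        n_sources=3,
        n_risk_factor_sources=1,
        n_candidates_per_source=4,
        n_pcs=2,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    geno = simulate_genotypes(small_cfg)
    arch = simulate_architecture(small_cfg, geno)
    sources = simulate_candidate_weights(small_cfg, arch, geno)
    cohort = simulate_phenotypes(geno, arch, small_cfg)
    return geno, arch, sources, cohort


@pytest.fixture()
def tiny_geno():
    """4 samples x 3 variants with fixed dosages and unambiguous alleles."""
    variants = pd.DataFrame(
        {
            "variant_id": ["rs1", "rs2", "rs3"],
            "chr": "1",
            "pos": [100, 200, 300],
            "allele1": ["A", "C", "G"],
            "allele2": ["G", "T", "A"],  # counted allele
            "af": [0.25, 0.5, 0.1],
        }
    )
    dosages = np.array(
        [
            [0.0, 2.0, 1.0],
            [1.0, 1.0, 0.0],
            [2.0, 0.0, 2.0],
            [1.0, 2.0, 1.0],
        ]
    )
    return GenotypeMatrix(
        sample_ids=np.array(["a", "b", "c", "d"]),
        variants=variants,
        dosages=dosages,
    )


def make_table(variant_ids, chrs, poss, ea, oa, weights, **meta):
    return VariantWeightTable(
        df=pd.DataFrame(
            {
                "variant_id": variant_ids,
                "chr": chrs,
                "pos": poss,
                "effect_allele": ea,
                "other_allele": oa,
                "weight": weights,
            }
        ),
        metadata=meta,
    )
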