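import numpy as np
import pandas as pd
import pytest

from bxlink.genotypes import GeneticMap, GenotypeMatrix
from bxlink import simdata


@pytest.fixture(scope="session")
def default_map():
    return simdata.simulate_map()


@pytest.fixture(scope="session")
def small_cohort():
    """374-individual cohort with one planted BMI QTL on chr4 (r2 ~ 0.055)."""
    cfg = simdata.SimConfig(
        qtl_effects=[simdata.QTLEffect("4", 60.0, "bmi", 0.4826)],
        module_spec=None, n_genes=0, rng_seed=2)
    ss = np.random.SeedSequence(cfg.rng_seed)  # representative draw
    rngs = [np.random.default_rng(c) for c in ss.spawn(3)]
    gmap = simdata.simulate_map(cfg.map_spec)
    sex = simdata.simulate_sexes(cfg.n_individuals, 0.5, rngs[0])
    gm = simdata.simulate_genotypes(gmap, cfg.n_individuals, sex, rng=rngs[1])
    pheno = simdata.simulate_phenotypes(gm, cfg.qtl_effects, rng=rngs[2])
    return gm, pheno


def toy_map(markers, chrom="1"):
    """GeneticMap from [(name, cm)] on one chromosome, 2 Mb/cM."""
    return GeneticMap(pd.DataFrame(
        {"marker": [m for m, _ in markers], "chrom": chrom,
         "cm": [c for _, c in markers], "mb": [2.0 * c for _, c in markers]}))


def toy_genotypes(geno_rows, markers, sex=None, chrom="1"):
    geno = np.asarray(geno_rows, dtype=np.int8)
    n = geno.shape[0]
    sex = sex if sex is not None else ["F"] * n
    return GenotypeMatrix([f"i{k}" for k in range(n)], sex, geno,
                          toy_map(markers, chrom))
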