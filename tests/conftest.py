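import numpy as np
import pytest

from boagwas.containers import MISSING, GenotypeMatrix, make_marker_map, make_sample_table


def random_genotypes(rng, n, m, missing_rate=0.0, n_chrom=1) -> GenotypeMatrix:
    """Random dosage matrix with a valid marker map, for format round-trips."""
    d = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    if missing_rate > 0:
        d[rng.random((n, m)) < missing_rate] = MISSING
    chrom = np.sort(rng.integers(1, n_chrom + 1, size=m))
    pos = np.empty(m, dtype=np.int64)
    for c in np.unique(chrom):
        k = (chrom == c).sum()
        pos[chrom == c] = np.sort(rng.choice(np.arange(1, 10 * k + 1), size=k, replace=False))
    markers = make_marker_map(
        [f"snp{i}" for i in range(m)],
        chrom,
        pos,
        rng.choice(list("ACGT"), size=m),
        rng.choice(list("ACGT"), size=m),
    )
    samples = make_sample_table(
        [f"ind{i}" for i in range(n)], [f"G{g}" for g in rng.integers(1, 4, size=n)]
    )
    return GenotypeMatrix(dosage=d, markers=markers, samples=samples)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest simulated cohort reused across read-only tests."""
    from boagwas.synthetic import SimulationConfig, sim_admixed_cohort, sim_phenotypes

    cfg = SimulationConfig(n_individuals=150, n_markers=400, n_chromosomes=5, seed=11)
    geno, ancestry, truth = sim_admixed_cohort(cfg)
    pheno, truth = sim_phenotypes(geno, ancestry, cfg, truth)
    return cfg, geno, ancestry, truth, pheno
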