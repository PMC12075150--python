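"""Synthetic two-breed admixed cohorts with known ground truth.

The generator emulates a Brangus-like Angus x Brahman population.  Founder
allele frequencies for the two breeds are drawn from the Balding-Nichols
model at a chosen divergence FST.  Each individual carries two haplotypes
per chromosome whose breed-of-origin follows a two-state Markov chain along
the marker map: stationary distribution (1 - pi_B, pi_B) where pi_B is the
Brahman admixture proportion, and between adjacent markers at genetic
distance d Morgans the chain resamples its state from the stationary
distribution with probability 1 - exp(-g d), g being the number of
generations since admixture.  This is distributionally identical to dropping
ancestry-switch events as a Poisson process of rate g per Morgan and drawing
each tract's ancestry independently, which is what window-based local
ancestry callers assume.

Alleles are drawn Bernoulli(p_breed) given the tract ancestry, so the true
breed-of-origin (BOA) dosage at every marker is the Brahman haplotype count.
Phenotypes follow the association model used downstream:

    y = mu + group + sum_q a_q * snp_dosage_q + sum_q c_q * boa_dosage_q
        + polygenic + residual

with the polygenic term realized through per-marker infinitesimal effects
u_m ~ N(0, sigma_g^2 / (2 sum p(1-p))) on centered dosages, so that the
breeding values have covariance sigma_g^2 G with G the VanRaden relationship
matrix — exactly the structure the mixed model assumes.

Defaults mimic the study conditions: pi_B = 0.375 (Brangus), 8 generations
since admixture, founder FST 0.2, polygenic variance 0.4 against residual
variance 0.6.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

from .containers import MISSING, AncestryMatrix, GenotypeMatrix, make_marker_map, make_sample_table
from .thermo import compute_thi

#: Genetic-to-physical scale used for the default uniform map: 1 cM ~ 1 Mb.
BP_PER_MORGAN = 100_000_000


@dataclass
class QtlSpec:
    """A planted causal locus: allele-substitution effect on the genotype
    dosage and/or on the Brahman-origin dosage, in trait units per copy."""

    marker_index: int
    snp_effect: float = 0.0
    boa_effect: float = 0.0


@dataclass
class SimulationConfig:
    n_individuals: int = 500
    n_markers: int = 2000
    n_chromosomes: int = 29
    chromosome_length_morgans: float = 1.0
    founder_divergence_fst: float = 0.2
    admixture_proportion_brahman: float = 0.375
    generations_since_admixture: int = 8
    qtl_specs: list[QtlSpec] = field(default_factory=list)
    polygenic_variance: float = 0.4
    residual_variance: float = 0.6
    n_groups: int = 4
    group_effect_sd: float = 0.5
    mean: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.founder_divergence_fst < 1:
            raise ValueError("founder_divergence_fst must be in (0, 1)")
        if not 0 < self.admixture_proportion_brahman < 1:
            raise ValueError("admixture_proportion_brahman must be in (0, 1)")
        if self.generations_since_admixture < 1:
            raise ValueError("generations_since_admixture must be >= 1")
        if self.polygenic_variance < 0 or self.residual_variance <= 0:
            raise ValueError("variances must be non-negative (residual positive)")
        for q in self.qtl_specs:
            if not 0 <= q.marker_index < self.n_markers:
                raise ValueError(f"QTL marker index {q.marker_index} out of range")


@dataclass
class TruthSet:
    """Ground truth recorded alongside a simulated cohort."""

    p_angus: np.ndarray
    p_brahman: np.ndarray
    hap_ancestry: np.ndarray  # (n, 2, m) int8, 1 = Brahman origin
    boa: np.ndarray  # (n, m) = hap_ancestry.sum(axis=1)
    positions_morgans: np.ndarray
    groups: np.ndarray | None = None
    group_effects: np.ndarray | None = None
    breeding_value: np.ndarray | None = None
    components: pd.DataFrame | None = None
    y: np.ndarray | None = None


def sim_founder_freqs(n_markers: int, fst: float, seed) -> tuple[np.ndarray, np.ndarray]:
    """Balding-Nichols founder frequencies for the two breeds.

    Ancestral frequencies are Uniform(0.05, 0.95); each daughter population
    draws Beta(p(1-F)/F, (1-p)(1-F)/F) independently.  Frequencies are
    clipped to [0.01, 0.99] to keep every marker segregating.
    """
    if not 0 < fst < 1:
        raise ValueError("fst must be in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = rng.uniform(0.05, 0.95, size=n_markers)
    a = p * (1 - fst) / fst
    b = (1 - p) * (1 - fst) / fst
    p_angus = np.clip(rng.beta(a, b), 0.01, 0.99)
    p_brahman = np.clip(rng.beta(a, b), 0.01, 0.99)
    return p_angus, p_brahman


def default_marker_map(
    n_markers: int, n_chromosomes: int, chromosome_length_morgans: float
) -> tuple[pd.DataFrame, np.ndarray]:
    """Uniformly spaced markers over equal-length chromosomes.

    Markers are split as evenly as possible across chromosomes; within a
    chromosome they sit at (i + 1/2) * L / m_c Morgans.  Physical positions
    use 1 cM ~ 1 Mb.  Returns (MarkerMap, positions_morgans).
    """
    counts = np.full(n_chromosomes, n_markers // n_chromosomes)
    counts[: n_markers % n_chromosomes] += 1
    chroms, pos_m = [], []
    for c, m_c in enumerate(counts, start=1):
        if m_c == 0:
            continue
        pos = (np.arange(m_c) + 0.5) * chromosome_length_morgans / m_c
        chroms.append(np.full(m_c, c))
        pos_m.append(pos)
    chrom = np.concatenate(chroms)
    pos_m = np.concatenate(pos_m)
    markers = make_marker_map(
        [f"snp{i + 1}" for i in range(n_markers)],
        chrom,
        np.round(pos_m * BP_PER_MORGAN).astype(np.int64) + 1,
        ["A"] * n_markers,
        ["B"] * n_markers,
    )
    return markers, pos_m


def _sim_hap_ancestry(
    chrom: np.ndarray, pos_m: np.ndarray, n_haplotypes: int, pi_b: float, g: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Markov-chain breed-of-origin states for n haplotypes over all markers."""
    m = len(chrom)
    states = np.empty((n_haplotypes, m), dtype=np.int8)
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        cur = (rng.random(n_haplotypes) < pi_b).astype(np.int8)
        states[:, idx[0]] = cur
        d = np.diff(pos_m[idx])
        switch_p = 1.0 - np.exp(-g * d)
        for k, j in enumerate(idx[1:]):
            resample = rng.random(n_haplotypes) < switch_p[k]
            if resample.any():
                cur = cur.copy()
                cur[resample] = (rng.random(resample.sum()) < pi_b).astype(np.int8)
            states[:, j] = cur
    return states


def sim_admixed_cohort(config: SimulationConfig):
    """Simulate a crossbred cohort: genotypes, true BOA, and the truth set.

    Returns ``(GenotypeMatrix, AncestryMatrix, TruthSet)``.  The ancestry
    matrix holds the *true* BOA dosages (what a perfect local-ancestry caller
    would report).
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_individuals, config.n_markers
    p_a, p_b = sim_founder_freqs(m, config.founder_divergence_fst, rng)
    markers, pos_m = default_marker_map(
        m, config.n_chromosomes, config.chromosome_length_morgans
    )
    chrom = markers["chromosome"].to_numpy()

    hap = _sim_hap_ancestry(
        chrom, pos_m, 2 * n, config.admixture_proportion_brahman,
        config.generations_since_admixture, rng,
    ).reshape(n, 2, m)

    freq = np.where(hap == 1, p_b, p_a)  # (n, 2, m)
    alleles = (rng.random((n, 2, m)) < freq).astype(np.int8)
    dosage = alleles.sum(axis=1, dtype=np.int8)
    boa = hap.sum(axis=1, dtype=np.int8)

    if config.missing_rate > 0:
        miss = rng.random((n, m)) < config.missing_rate
        dosage = np.where(miss, np.int8(MISSING), dosage)

    groups = rng.integers(config.n_groups, size=n)
    samples = make_sample_table(
        [f"ind{i + 1}" for i in range(n)], [f"G{g + 1}" for g in groups]
    )
    geno = GenotypeMatrix(dosage=dosage, markers=markers, samples=samples)
    ancestry = AncestryMatrix(boa_dosage=boa, markers=markers, samples=samples)
    truth = TruthSet(
        p_angus=p_a, p_brahman=p_b, hap_ancestry=hap, boa=boa,
        positions_morgans=pos_m, groups=groups,
    )
    return geno, ancestry, truth


def sim_reference_panels(
    p_angus: np.ndarray,
    p_brahman: np.ndarray,
    markers: pd.DataFrame,
    n_angus: int = 123,
    n_brahman: int = 406,
    seed=0,
) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Purebred reference panels drawn at the founder frequencies.

    Panel sizes default to the study's reference population (123 Angus,
    406 Brahman).  Genotypes are Hardy-Weinberg draws Binomial(2, p)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def panel(p, n_ref, prefix):
        d = rng.binomial(2, p, size=(n_ref, len(p))).astype(np.int8)
        samples = make_sample_table([f"{prefix}{i + 1}" for i in range(n_ref)], [prefix] * n_ref)
        return GenotypeMatrix(dosage=d, markers=markers.copy(), samples=samples)

    return panel(p_angus, n_angus, "angus"), panel(p_brahman, n_brahman, "brahman")


def sim_phenotypes(
    genotypes: GenotypeMatrix,
    true_boa: AncestryMatrix,
    config: SimulationConfig,
    truth: TruthSet | None = None,
    trait: str = "sim_trait",
    seed=None,
):
    """Simulate phenotypes on top of a cohort; returns (PhenotypeTable, TruthSet).

    The stored decomposition (mu, group, qtl_snp, qtl_boa, polygenic,
    residual) sums exactly to y.  The phenotype seed is derived from the
    config seed so a cohort + phenotype simulation is reproducible end to end.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    n, m = genotypes.n_individuals, genotypes.n_markers
    d = genotypes.imputed_dosage()
    boa = true_boa.boa_dosage.astype(float)

    if truth is not None and truth.groups is not None:
        groups = truth.groups
    else:
        groups = (
            genotypes.samples["collection_group"].astype("category").cat.codes.to_numpy()
        )
    group_effects = rng.normal(0.0, config.group_effect_sd, size=config.n_groups)

    qtl_snp = np.zeros(n)
    qtl_boa = np.zeros(n)
    for q in config.qtl_specs:
        qtl_snp += q.snp_effect * d[:, q.marker_index]
        qtl_boa += q.boa_effect * boa[:, q.marker_index]

    p = d.mean(axis=0) / 2.0
    denom = 2.0 * np.sum(p * (1 - p))
    if config.polygenic_variance > 0 and denom > 0:
        u = rng.normal(0.0, np.sqrt(config.polygenic_variance / denom), size=m)
        polygenic = (d - 2 * p) @ u
    else:
        polygenic = np.zeros(n)
    residual = rng.normal(0.0, np.sqrt(config.residual_variance), size=n)

    comp = pd.DataFrame(
        {
            "mu": np.full(n, config.mean),
            "group": group_effects[groups],
            "qtl_snp": qtl_snp,
            "qtl_boa": qtl_boa,
            "polygenic": polygenic,
            "residual": residual,
        }
    )
    y = comp.sum(axis=1).to_numpy()
    pheno = pd.DataFrame(
        {
            "animal_id": genotypes.samples["animal_id"],
            "trait": trait,
            "value": y,
            "collection_group": genotypes.samples["collection_group"],
        }
    )
    out_truth = truth or TruthSet(
        p_angus=np.array([]), p_brahman=np.array([]),
        hap_ancestry=np.empty((n, 2, 0), dtype=np.int8),
        boa=true_boa.boa_dosage, positions_morgans=np.array([]), groups=groups,
    )
    out_truth.groups = groups
    out_truth.group_effects = group_effects
    out_truth.breeding_value = qtl_snp + qtl_boa + polygenic
    out_truth.components = comp
    out_truth.y = y
    return pheno, out_truth


@dataclass
class EnvProfile:
    """Sinusoidal daily weather profile for the environment logger.

    Air temperature peaks at ``peak_hour``; relative humidity runs in
    antiphase (moist nights, drier afternoons).  Defaults give a Florida
    summer day whose hourly THI stays above 70 around the clock."""

    t_mean: float = 29.0
    t_amplitude: float = 7.0
    rh_mean: float = 70.0
    rh_amplitude: float = 15.0
    peak_hour: float = 16.0
    rain_days: tuple[int, ...] = ()


def sim_temperature_logs(
    amplitudes,
    env: EnvProfile | None = None,
    n_days: int = 5,
    seed: int = 0,
    noise_sd: float = 0.05,
    baseline_vt: float = 38.6,
    start: str = "2023-07-10",
    animal_ids=None,
):
    """Simulate 15-minute body-temperature and environment logger series.

    Vaginal temperature for animal i is ``baseline_vt + A_i * s(t) + eps``
    with s(t) a daily sinusoid of unit amplitude peaking at the profile's
    peak hour (diurnal range 2 A_i) and eps ~ N(0, noise_sd^2).  Returns
    ``(TemperatureSeries, EnvironmentSeries)`` DataFrames.
    """
    env = env or EnvProfile()
    amplitudes = np.asarray(amplitudes, dtype=float)
    n_animals = len(amplitudes)
    if animal_ids is None:
        animal_ids = [f"ind{i + 1}" for i in range(n_animals)]
    rng = np.random.default_rng(seed)

    t0 = datetime.fromisoformat(start)
    n_steps = n_days * 96
    times = np.array([t0 + timedelta(minutes=15 * k) for k in range(n_steps)])
    hours = np.array([t.hour + t.minute / 60.0 for t in times])
    s = np.cos(2 * np.pi * (hours - env.peak_hour) / 24.0)

    vt = baseline_vt + amplitudes[:, None] * s[None, :]
    if noise_sd > 0:
        vt = vt + rng.normal(0.0, noise_sd, size=vt.shape)
    temp = pd.DataFrame(
        {
            "animal_id": np.repeat(animal_ids, n_steps),
            "timestamp": np.tile(times, n_animals),
            "vaginal_temperature": vt.ravel(),
        }
    )

    air = env.t_mean + env.t_amplitude * s
    rh = np.clip(env.rh_mean - env.rh_amplitude * s, 0.0, 100.0)
    day_index = np.array([(t.date() - t0.date()).days for t in times])
    rain = np.isin(day_index, np.asarray(env.rain_days, dtype=int))
    env_df = pd.DataFrame(
        {"timestamp": times, "air_temperature": air, "relative_humidity": rh, "rain": rain}
    )
    env_df["thi"] = compute_thi(env_df["air_temperature"], env_df["relative_humidity"])
    return temp, env_df
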