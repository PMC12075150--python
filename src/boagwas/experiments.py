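"""Simulation studies that validate the association machinery.

These reusable experiments exercise the pipeline on synthetic cohorts with
known ground truth:

* ``null_calibration`` — empirical type-I error of the three models on a
  cohort with a polygenic background and no marker effects.  The phenotype's
  genetic covariance equals sigma_g^2 G for the genome-wide VanRaden G, so
  the scan is run against that same matrix; under LOCO kinship a tested
  marker tags real (deliberately unmodelled) local polygenic variance, which
  is power, not size error.
* ``h2_recovery`` — repeated-cohort recovery of the simulated heritability.
  REML is used here because variance-component estimation is its natural
  setting; ML carries the usual downward residual bias from estimated fixed
  effects, which tilts h2 upward by about p/n.
* ``power_contrast`` — the admixture-mapping detectability contrast: a QTL
  whose effect rides on local ancestry (with no effect attached to any
  genotyped allele) is visible to the BOA and joint models but nearly
  invisible to the SNP model when the marker is barely ancestry-informative;
  a pure allele-substitution QTL at the same low-AFD marker shows the
  reverse.  Detection is judged at the planted marker against the
  genome-wide Bonferroni cutoff (alpha = 0.1 over the panel size).

Planted effect sizes (0.4 per Brahman-origin allele, 0.45 per minor allele)
come from a power calculation at the default cohort size: both give a
non-centrality around 5-6 SE at n = 500, comfortably above the Bonferroni
boundary for the model that sees the effect and far below it for the model
that does not.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .lmm import assoc_test, association_scan, fit_null_lmm, group_design, vanraden_grm
from .synthetic import QtlSpec, SimulationConfig, sim_admixed_cohort, sim_phenotypes

BOA_QTL_EFFECT = 0.4
SNP_QTL_EFFECT = 0.45
MODELS = ("SNP", "BOA", "SNP+BOA")


def null_calibration(seed: int, config: SimulationConfig | None = None,
                     nominal=(0.05, 0.01)) -> dict:
    """Empirical size of the three Wald tests under the global null.

    Simulates one cohort at the default study conditions (or ``config``),
    scans every marker under all three models with the genome-wide GRM, and
    returns the fraction of p-values below each nominal level.
    """
    cfg = config or SimulationConfig(seed=seed)
    if config is None:
        cfg = replace(cfg, seed=seed)
    geno, ancestry, truth = sim_admixed_cohort(cfg)
    pheno, truth = sim_phenotypes(geno, ancestry, cfg, truth)
    y = pheno["value"].to_numpy()
    X = group_design(geno.samples)
    grm = vanraden_grm(geno)
    res = association_scan(y, X, geno, ancestry, grm)
    out = {}
    for model in MODELS:
        p = res.loc[res["model"] == model, "p"].to_numpy(dtype=float)
        p = p[np.isfinite(p)]
        out[model] = {f"size_at_{lvl}": float((p < lvl).mean()) for lvl in nominal}
        out[model]["n_tests"] = int(len(p))
    return out


def h2_recovery(seed: int, n_replicates: int = 20,
                config: SimulationConfig | None = None,
                method: str = "reml") -> dict:
    """Mean estimated heritability over replicate cohorts (true value from
    the simulation's variance parameters)."""
    base = config or SimulationConfig()
    estimates = []
    for rep in range(n_replicates):
        cfg = replace(base, seed=seed + 1000 * rep)
        geno, ancestry, truth = sim_admixed_cohort(cfg)
        pheno, truth = sim_phenotypes(geno, ancestry, cfg, truth)
        grm = vanraden_grm(geno)
        vc = fit_null_lmm(
            pheno["value"].to_numpy(), group_design(geno.samples), grm, method=method
        )
        estimates.append(vc.h2)
    true_h2 = base.polygenic_variance / (base.polygenic_variance + base.residual_variance)
    return {
        "true_h2": true_h2,
        "mean_h2": float(np.mean(estimates)),
        "sd_h2": float(np.std(estimates, ddof=1)),
        "estimates": estimates,
    }


def _least_informative_passing_marker(truth, pi_b: float, threshold: float = 0.05,
                                      min_maf: float = 0.2) -> int:
    """Marker with the smallest founder allele-frequency difference among
    AFD-passing markers that segregate commonly in the admixed cohort.

    The common-variant condition (expected cohort MAF >= 0.2) mirrors the
    marker QC every tested SNP passes; without it the planted QTL could sit
    on a near-monomorphic dosage where no allele-effect test has power."""
    afd = np.abs(truth.p_angus - truth.p_brahman)
    p_cohort = pi_b * truth.p_brahman + (1 - pi_b) * truth.p_angus
    maf = np.minimum(p_cohort, 1 - p_cohort)
    passing = np.flatnonzero((afd >= threshold) & (maf >= min_maf))
    return int(passing[np.argmin(afd[passing])])


def power_contrast(seed: int, n_replicates: int = 20,
                   config: SimulationConfig | None = None,
                   alpha: float = 0.1) -> dict:
    """Detectability contrast between ancestry-driven and allele-driven QTLs.

    For each replicate and each scenario the QTL sits at the least
    ancestry-informative AFD-passing marker; the three models are evaluated
    at that marker with the LOCO kinship for its chromosome, against the
    Bonferroni cutoff alpha / n_markers.  Returns per-scenario, per-model
    detection rates and median -log10 p at the QTL.
    """
    base = config or SimulationConfig()
    bonferroni = alpha / base.n_markers
    out = {}
    for scenario in ("boa_driven", "snp_driven"):
        pvals = {m: [] for m in MODELS}
        for rep in range(n_replicates):
            cfg = replace(base, seed=seed + 1000 * rep)
            geno, ancestry, truth = sim_admixed_cohort(cfg)
            qtl = _least_informative_passing_marker(truth, cfg.admixture_proportion_brahman)
            spec = (
                QtlSpec(qtl, boa_effect=BOA_QTL_EFFECT)
                if scenario == "boa_driven"
                else QtlSpec(qtl, snp_effect=SNP_QTL_EFFECT)
            )
            cfg_q = replace(cfg, qtl_specs=[spec])
            pheno, truth = sim_phenotypes(geno, ancestry, cfg_q, truth)
            y = pheno["value"].to_numpy()
            X = group_design(geno.samples)
            chrom_q = geno.markers["chromosome"].iloc[qtl]
            loco_mask = (geno.markers["chromosome"] != chrom_q).to_numpy()
            grm = vanraden_grm(geno, loco_mask)
            snp = geno.imputed_dosage()[:, qtl]
            boa = ancestry.boa_dosage[:, qtl].astype(float)
            pvals["SNP"].append(assoc_test(y, X, snp, grm, "snp").p)
            pvals["BOA"].append(assoc_test(y, X, boa, grm, "boa").p)
            pvals["SNP+BOA"].append(
                assoc_test(y, X, np.column_stack([snp, boa]), grm, "joint").p
            )
        out[scenario] = {
            "bonferroni_p": bonferroni,
            "detection_rate": {
                m: float(np.mean(np.asarray(v) < bonferroni)) for m, v in pvals.items()
            },
            "median_neglog10p": {
                m: float(np.median(-np.log10(np.asarray(v)))) for m, v in pvals.items()
            },
        }
    return out
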