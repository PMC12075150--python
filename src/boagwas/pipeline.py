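"""End-to-end orchestration: simulate or load a cohort, derive phenotypes,
QC and encode BOA, run the three association models per trait, apply
multiple-testing thresholds, and call QTL intervals.

Thresholds follow the family-wise / suggestive convention: with M tests per
trait and model, the genome-wide Bonferroni cutoff is alpha / M at
alpha = 0.1, and the suggestive cutoff is 1 / M.  M is the number of
markers actually tested (post-QC, post-AFD, non-aliased), not the array
size.  QTL intervals are greedy clusters of suggestive markers: successive
passing markers on one chromosome within ``gap_bp`` (default 1 Mb) join one
interval; an interval is classified significant when at least one member
passes its model's Bonferroni cutoff.  The clustering rule and its gap
parameter are this pipeline's own convention — association studies report
intervals without standardizing how nearby hits are merged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import GenotypeMatrix
from .io_formats import (
    read_ancestry_table,
    read_phenotypes,
    read_plink,
    write_ancestry_table,
    write_phenotypes,
    write_plink,
    write_results,
)
from .lmm import MODEL_LABELS, association_scan, group_design, loco_grms
from .prep import afd_filter, qc_filter, recode_minor
from .synthetic import (
    QtlSpec,
    SimulationConfig,
    sim_admixed_cohort,
    sim_phenotypes,
    sim_reference_panels,
)
from .thermo import derive_tss

DEFAULT_ALPHA = 0.1
DEFAULT_GAP_BP = 1_000_000


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class ThresholdSet:
    """Per-trait, per-model multiple-testing cutoffs."""

    n_tests: int
    alpha: float
    bonferroni_p: float
    suggestive_p: float


def make_thresholds(n_tests: int, alpha: float = DEFAULT_ALPHA) -> ThresholdSet:
    if n_tests < 1:
        raise ValueError("need at least one test")
    return ThresholdSet(
        n_tests=n_tests,
        alpha=alpha,
        bonferroni_p=alpha / n_tests,
        suggestive_p=1.0 / n_tests,
    )


def thresholds_by_model(results: pd.DataFrame, alpha: float = DEFAULT_ALPHA) -> dict[str, ThresholdSet]:
    """One ThresholdSet per model, with M = non-aliased markers tested."""
    out = {}
    for model, g in results.groupby("model"):
        tested = g[np.isfinite(g["p"]) & ~g["aliased"].astype(bool)]
        out[model] = make_thresholds(len(tested), alpha)
    return out


def call_qtls(
    results: pd.DataFrame,
    thresholds: dict[str, ThresholdSet],
    gap_bp: int = DEFAULT_GAP_BP,
) -> pd.DataFrame:
    """Cluster suggestive markers into QTL intervals.

    Markers passing their model's suggestive threshold are pooled across
    models, sorted, and merged greedily within ``gap_bp`` on a chromosome.
    Interval bounds are the min/max member positions (1-based inclusive);
    the lead marker is the smallest p across member rows; supporting models
    are every model with a passing member; classification is ``significant``
    when any member row beats its model's Bonferroni cutoff, else
    ``suggestive``.
    """
    res = results[np.isfinite(results["p"].astype(float))].copy()
    res["suggestive_p"] = res["model"].map(lambda m: thresholds[m].suggestive_p)
    res["bonferroni_p"] = res["model"].map(lambda m: thresholds[m].bonferroni_p)
    passing = res[res["p"] < res["suggestive_p"]]
    if len(passing) == 0:
        return pd.DataFrame(
            columns=[
                "chromosome", "start_bp", "end_bp", "n_markers", "lead_marker",
                "lead_model", "lead_p", "models", "classification",
            ]
        )
    passing = passing.sort_values(
        ["chromosome", "position_bp", "model"], kind="mergesort"
    ).reset_index(drop=True)

    intervals = []
    for c, g in passing.groupby("chromosome", sort=True):
        positions = np.sort(g["position_bp"].unique())
        breaks = np.flatnonzero(np.diff(positions) > gap_bp)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(positions) - 1]])
        for s, e in zip(starts, ends):
            lo, hi = positions[s], positions[e]
            members = g[(g["position_bp"] >= lo) & (g["position_bp"] <= hi)]
            lead = members.sort_values(
                ["p", "position_bp", "model"], kind="mergesort"
            ).iloc[0]
            significant = bool((members["p"] < members["bonferroni_p"]).any())
            intervals.append(
                {
                    "chromosome": int(c),
                    "start_bp": int(lo),
                    "end_bp": int(hi),
                    "n_markers": int(members["marker_id"].nunique()),
                    "lead_marker": lead["marker_id"],
                    "lead_model": lead["model"],
                    "lead_p": float(lead["p"]),
                    "models": ",".join(sorted(members["model"].unique())),
                    "classification": "significant" if significant else "suggestive",
                }
            )
    return pd.DataFrame(intervals)


def manhattan_table(results: pd.DataFrame, thresholds: dict[str, ThresholdSet]):
    """Plot-ready table: cumulative genome coordinate and -log10 p per model.

    Returns ``(table, lines)`` where ``lines[model]`` holds the -log10
    heights of the suggestive and Bonferroni threshold lines.
    """
    if len(results) == 0:
        raise ValueError("results table is empty")
    res = results.copy()
    span = res.groupby("chromosome")["position_bp"].max().sort_index()
    offsets = span.cumsum().shift(fill_value=0)
    res["cum_bp"] = res["chromosome"].map(offsets) + res["position_bp"]
    with np.errstate(divide="ignore"):
        res["neglog10p"] = -np.log10(res["p"].astype(float))
    table = res[
        ["marker_id", "chromosome", "position_bp", "cum_bp", "model", "neglog10p"]
    ].sort_values(["model", "cum_bp"], kind="mergesort").reset_index(drop=True)
    lines = {
        model: {
            "suggestive": -np.log10(t.suggestive_p),
            "bonferroni": -np.log10(t.bonferroni_p),
        }
        for model, t in thresholds.items()
    }
    return table, lines


def manhattan_plot(table: pd.DataFrame, lines: dict, path, trait: str = "") -> None:
    """Advisory Manhattan plot, one panel per model."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    models = sorted(table["model"].unique())
    fig, axes = plt.subplots(len(models), 1, figsize=(10, 3 * len(models)), squeeze=False)
    for ax, model in zip(axes[:, 0], models):
        g = table[table["model"] == model]
        colors = g["chromosome"] % 2
        ax.scatter(g["cum_bp"], g["neglog10p"], c=colors, cmap="tab10", s=4)
        ax.axhline(lines[model]["suggestive"], color="green", ls="--", lw=1)
        ax.axhline(lines[model]["bonferroni"], color="red", ls="--", lw=1)
        ax.set_ylabel("-log10 p")
        ax.set_title(f"{trait} {model}".strip())
    axes[-1, 0].set_xlabel("cumulative position (bp)")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def simulation_config_from_block(block: dict, seed: int | None = None) -> SimulationConfig:
    block = dict(block)
    qtls = [QtlSpec(q["marker"], q.get("snp_effect", 0.0), q.get("boa_effect", 0.0))
            for q in block.pop("qtls", [])]
    if seed is not None:
        block["seed"] = seed
    return SimulationConfig(qtl_specs=qtls, **block)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="")


def run_pipeline(config: dict | str, out_dir, seed: int | None = None) -> dict:
    """Run the full pipeline and write all artifacts into ``out_dir``.

    ``config`` is a mapping (or a YAML path) with either a ``simulate`` block
    or an ``input`` block (``plink`` prefix, ``ancestry`` TSV, ``phenotypes``
    CSV, optional ``temperature_log``/``environment_log`` CSVs from which a
    TSS trait is derived).  The run is deterministic given the seed: result
    tables are byte-identical across reruns.  Returns a summary dict (also
    written as ``run_log.json``).
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    models = tuple(config.get("models", ["snp", "boa", "joint"]))
    unknown = set(models) - set(MODEL_LABELS)
    if unknown:
        raise StageError("config", ValueError(f"unknown models: {sorted(unknown)}"))
    alpha = float(config.get("alpha", DEFAULT_ALPHA))
    gap_bp = int(config.get("gap_bp", DEFAULT_GAP_BP))
    use_loco = bool(config.get("loco", True))
    variance_estimation = config.get("variance_estimation", "marker")
    method = config.get("criterion", "ml")
    make_plots = bool(config.get("plots", True))
    log: dict = {"version": __version__, "seed": seed, "stages": {}}

    # ------------------------------------------------------------------ input
    try:
        if "simulate" in config:
            sim_cfg = simulation_config_from_block(config["simulate"], seed=seed)
            geno, ancestry, truth = sim_admixed_cohort(sim_cfg)
            ref_a, ref_b = sim_reference_panels(
                truth.p_angus, truth.p_brahman, geno.markers, seed=sim_cfg.seed + 1000
            )
            pheno, truth = sim_phenotypes(geno, ancestry, sim_cfg, truth)
            write_plink(geno, out / "cohort")
            write_ancestry_table(ancestry, out / "ancestry.tsv")
            write_phenotypes(pheno, out / "phenotypes.csv")
            log["stages"]["simulate"] = {
                "n_individuals": geno.n_individuals,
                "n_markers": geno.n_markers,
                "seed": sim_cfg.seed,
            }
        elif "input" in config:
            inp = config["input"]
            geno, markers, samples = read_plink(inp["plink"])
            ancestry = read_ancestry_table(inp["ancestry"], markers, samples)
            pheno = read_phenotypes(inp["phenotypes"])
            ref_a = ref_b = None
            if "reference_angus" in inp:
                ref_a, _, _ = read_plink(inp["reference_angus"])
                ref_b, _, _ = read_plink(inp["reference_brahman"])
            if "temperature_log" in inp:
                temp = pd.read_csv(inp["temperature_log"], parse_dates=["timestamp"])
                env = pd.read_csv(inp["environment_log"], parse_dates=["timestamp"])
                tss = derive_tss(temp, env)
                groups = geno.samples.set_index("animal_id")["collection_group"]
                extra = pd.DataFrame(
                    {
                        "animal_id": tss["animal_id"],
                        "trait": "TSS",
                        "value": tss["tss"],
                        "collection_group": tss["animal_id"].map(groups),
                    }
                )
                pheno = pd.concat([pheno, extra], ignore_index=True)
            write_phenotypes(pheno, out / "phenotypes.csv")
        else:
            raise ValueError("config needs a 'simulate' or 'input' block")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("input", exc) from exc

    # --------------------------------------------------------------- prep/QC
    try:
        geno_qc, qc_report = qc_filter(geno)
        geno_qc = recode_minor(geno_qc)
        _write_tsv(qc_report, out / "qc_report.tsv")
        if ref_a is not None:
            keep = afd_filter(ref_a, ref_b, geno_qc.markers)
        else:
            keep = np.ones(geno_qc.n_markers, dtype=bool)
        geno_final = geno_qc.subset(markers=keep)
        marker_pos = pd.Index(ancestry.markers["marker_id"]).get_indexer(
            geno_final.markers["marker_id"]
        )
        animal_pos = pd.Index(ancestry.samples["animal_id"]).get_indexer(
            geno_final.samples["animal_id"]
        )
        ancestry_final = ancestry.subset(animals=animal_pos, markers=marker_pos)
        log["stages"]["prep"] = {
            "markers_post_qc": geno_qc.n_markers,
            "markers_post_afd": geno_final.n_markers,
            "animals": geno_final.n_individuals,
            "qc_removed": len(qc_report),
        }
    except StageError:
        raise
    except Exception as exc:
        raise StageError("prep", exc) from exc

    # ------------------------------------------------------------------ gwas
    try:
        if use_loco:
            grms = loco_grms(geno_final)
        else:
            from .lmm import vanraden_grm

            grms = vanraden_grm(geno_final)
        traits = config.get("traits") or sorted(pheno["trait"].unique())
        summary_traits = {}
        for trait in traits:
            sub = pheno[(pheno["trait"] == trait) & pheno["value"].notna()]
            order = pd.Index(geno_final.samples["animal_id"])
            sub = sub[sub["animal_id"].isin(order)]
            pos = order.get_indexer(sub["animal_id"])
            if (pos < 0).any() or len(sub) < 10:
                raise ValueError(f"trait {trait!r}: too few phenotyped genotyped animals")
            # restrict cohort to phenotyped animals, preserving genotype order
            keep_animals = np.sort(pos)
            g_t = geno_final.subset(animals=keep_animals)
            a_t = ancestry_final.subset(animals=keep_animals)
            y = (
                sub.set_index("animal_id")["value"]
                .loc[g_t.samples["animal_id"]]
                .to_numpy(dtype=float)
            )
            X = group_design(g_t.samples)
            grms_t = grms if len(keep_animals) == geno_final.n_individuals else (
                loco_grms(g_t) if use_loco else vanraden_grm(g_t)
            )
            results = association_scan(
                y, X, g_t, a_t, grms_t, models=models, method=method,
                variance_estimation=variance_estimation,
            )
            write_results(results, out / f"results_{trait}.tsv")
            th = thresholds_by_model(results, alpha)
            qtls = call_qtls(results, th, gap_bp)
            qtls.insert(0, "trait", trait)
            _write_tsv(qtls, out / f"qtls_{trait}.tsv")
            table, lines = manhattan_table(results, th)
            _write_tsv(table, out / f"manhattan_{trait}.tsv")
            if make_plots:
                manhattan_plot(table, lines, out / f"manhattan_{trait}.png", trait)
            summary_traits[trait] = {
                "n_animals": int(len(y)),
                "thresholds": {
                    m: {"n_tests": t.n_tests, "bonferroni_p": t.bonferroni_p,
                        "suggestive_p": t.suggestive_p}
                    for m, t in th.items()
                },
                "n_qtls": int(len(qtls)),
                "n_significant": int((qtls["classification"] == "significant").sum())
                if len(qtls) else 0,
            }
        log["stages"]["gwas"] = summary_traits
    except StageError:
        raise
    except Exception as exc:
        raise StageError("gwas", exc) from exc

    import pandas as _pd
    import scipy as _sp

    log["versions"] = {"numpy": np.__version__, "scipy": _sp.__version__,
                       "pandas": _pd.__version__}
    log["config"] = _jsonable(config)
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
    return log


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
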