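"""Genotype QC, ancestry-informative marker filtering, and BOA encoding.

QC mirrors the usual PLINK workflow on an admixed beef-cattle cohort: drop
animals with a genotype completion rate below 90%, then drop markers with a
minor allele frequency below 5% or a call rate below 99% (both computed on
the retained animals).  Inequalities are strict "below"; a marker at exactly
MAF 0.05 survives.

Markers informative about breed of origin are selected by the allele
frequency difference (AFD) between the purebred Angus and Brahman reference
panels: markers with |p_Angus - p_Brahman| >= 5% are retained.  Local
ancestry diplotypes (breed of origin of each allele copy) are encoded as
pseudo-genotypes: AA -> 0, AB/BA -> 1, BB -> 2 Brahman-origin alleles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import MISSING, AncestryMatrix, GenotypeMatrix

#: Diplotype token -> Brahman-origin allele count.
BOA_CODES = {"AA": 0, "AB": 1, "BA": 1, "BB": 2}


class UnknownDiplotypeError(ValueError):
    """A diplotype token outside {AA, AB, BA, BB} (or dosage outside 0/1/2)."""


class EmptyCohortError(ValueError):
    """QC removed every animal or every marker."""


class UnalignedPanelError(ValueError):
    """Reference panels do not cover the requested markers."""


@dataclass
class QcThresholds:
    min_animal_call_rate: float = 0.90
    min_maf: float = 0.05
    min_marker_call_rate: float = 0.99


def qc_filter(
    genotypes: GenotypeMatrix, thresholds: QcThresholds | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply animal-then-marker QC; return the filtered matrix and a report.

    Animals are filtered first (call rate below the animal threshold);
    marker MAF and call rate are then computed on the surviving animals.
    The report has one row per removed entity: (stage, entity, reason).
    """
    th = thresholds or QcThresholds()
    rows: list[tuple[str, str, str]] = []

    acr = genotypes.call_rate_per_animal()
    keep_a = acr >= th.min_animal_call_rate
    for aid, rate in zip(genotypes.samples["animal_id"][~keep_a], acr[~keep_a]):
        rows.append(("animal", aid, f"call_rate {rate:.4f} < {th.min_animal_call_rate}"))
    if not keep_a.any():
        raise EmptyCohortError("animal call-rate filter removed every animal")
    kept = genotypes.subset(animals=keep_a)

    freq = kept.allele_freq()
    maf = np.minimum(freq, 1.0 - freq)
    maf = np.where(np.isnan(maf), 0.0, maf)
    mcr = kept.call_rate_per_marker()
    low_maf = maf < th.min_maf
    low_call = mcr < th.min_marker_call_rate
    keep_m = ~(low_maf | low_call)
    for mid, is_maf, is_call, f, c in zip(
        kept.markers["marker_id"], low_maf, low_call, maf, mcr
    ):
        if is_maf:
            rows.append(("marker", mid, f"maf {f:.4f} < {th.min_maf}"))
        elif is_call:
            rows.append(("marker", mid, f"call_rate {c:.4f} < {th.min_marker_call_rate}"))
    if not keep_m.any():
        raise EmptyCohortError("marker filters removed every marker")
    kept = kept.subset(markers=keep_m)

    report = pd.DataFrame(rows, columns=["stage", "entity", "reason"])
    return kept, report


def recode_minor(genotypes: GenotypeMatrix) -> GenotypeMatrix:
    """Recode dosages so the counted allele is the minor allele (freq <= 0.5).

    Cohort frequencies use non-missing calls.  Ties (frequency exactly 0.5)
    keep the current counted allele, which makes the operation an involution.
    """
    out = genotypes.copy()
    freq = out.allele_freq()
    flip = freq > 0.5
    if flip.any():
        sub = out.dosage[:, flip]
        nonmiss = sub != MISSING
        sub[nonmiss] = 2 - sub[nonmiss]
        out.dosage[:, flip] = sub
        a1 = out.markers["allele1"].to_numpy(dtype=object)
        a2 = out.markers["allele2"].to_numpy(dtype=object)
        was_a1 = out.counted_allele == a1
        out.counted_allele[flip & was_a1] = a2[flip & was_a1]
        out.counted_allele[flip & ~was_a1] = a1[flip & ~was_a1]
    return out


def reference_allele_freq(panel: GenotypeMatrix, marker_ids) -> np.ndarray:
    """Counted-allele frequency in a purebred reference panel, by simple
    allele counting ignoring missing calls, aligned to ``marker_ids``."""
    idx = pd.Index(panel.markers["marker_id"])
    pos = idx.get_indexer(pd.Index(marker_ids))
    if (pos < 0).any():
        absent = list(pd.Index(marker_ids)[pos < 0][:5])
        raise UnalignedPanelError(f"markers absent from reference panel: {absent}")
    return panel.allele_freq()[pos]


def afd_filter(
    ref_angus: GenotypeMatrix,
    ref_brahman: GenotypeMatrix,
    markers: pd.DataFrame,
    threshold: float = 0.05,
) -> np.ndarray:
    """Boolean mask of markers with allele frequency difference >= threshold.

    AFD = |p_Angus - p_Brahman| estimated from the purebred panels; retention
    uses ">=" so a difference of exactly the threshold is kept.
    """
    ids = markers["marker_id"]
    p_a = reference_allele_freq(ref_angus, ids)
    p_b = reference_allele_freq(ref_brahman, ids)
    return np.abs(p_a - p_b) >= threshold


def encode_boa(diplotypes: np.ndarray, markers: pd.DataFrame, samples: pd.DataFrame) -> AncestryMatrix:
    """Encode an (n x m) array of diplotype tokens as BOA pseudo-genotypes."""
    dip = np.asarray(diplotypes, dtype=object)
    flat = pd.Series(dip.ravel())
    bad = ~flat.isin(BOA_CODES)
    if bad.any():
        raise UnknownDiplotypeError(f"unknown diplotype token(s): {sorted(flat[bad].unique())}")
    boa = flat.map(BOA_CODES).to_numpy(dtype=np.int8).reshape(dip.shape)
    return AncestryMatrix(boa_dosage=boa, markers=markers, samples=samples)
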