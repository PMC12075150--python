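"""Core in-memory containers shared across the pipeline.

Genotypes are stored as counted-allele dosages (0/1/2) in an ``int8`` matrix
of shape ``(n_individuals, n_markers)``; missing calls use the out-of-band
sentinel :data:`MISSING`.  Marker metadata (``MarkerMap``) and sample
metadata (``SampleTable``) travel with the dosage matrix as plain pandas
DataFrames so that downstream filtering keeps everything aligned.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call.  Never a valid dosage; imputation
#: (mean dosage 2p) happens only where a model requires complete data.
MISSING: int = -1

MARKER_COLUMNS = ["marker_id", "chromosome", "position_bp", "allele1", "allele2"]
SAMPLE_COLUMNS = ["animal_id", "collection_group"]

#: Autosomes of the ARS-UCD1.2 cattle assembly.
MAX_CHROMOSOME = 29


class ValidationError(ValueError):
    """Container contents violate a structural invariant."""


def make_marker_map(
    marker_id,
    chromosome,
    position_bp,
    allele1=None,
    allele2=None,
) -> pd.DataFrame:
    """Assemble and validate a MarkerMap DataFrame.

    Coordinates are 1-based inclusive, matching PLINK ``.bim``.  Only
    autosomes 1..29 are accepted.
    """
    m = len(marker_id)
    df = pd.DataFrame(
        {
            "marker_id": np.asarray(marker_id, dtype=object),
            "chromosome": np.asarray(chromosome, dtype=np.int64),
            "position_bp": np.asarray(position_bp, dtype=np.int64),
            "allele1": np.asarray(allele1 if allele1 is not None else ["A"] * m, dtype=object),
            "allele2": np.asarray(allele2 if allele2 is not None else ["B"] * m, dtype=object),
        }
    )
    validate_marker_map(df)
    return df


def validate_marker_map(df: pd.DataFrame) -> None:
    missing = set(MARKER_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"MarkerMap missing columns: {sorted(missing)}")
    if df["marker_id"].duplicated().any():
        raise ValidationError("marker_ids must be unique")
    chrom = df["chromosome"].to_numpy()
    if ((chrom < 1) | (chrom > MAX_CHROMOSOME)).any():
        raise ValidationError(f"chromosome must be in 1..{MAX_CHROMOSOME} (autosomes)")
    if (df["position_bp"].to_numpy() < 1).any():
        raise ValidationError("position_bp must be >= 1 (1-based)")


def make_sample_table(animal_id, collection_group=None) -> pd.DataFrame:
    n = len(animal_id)
    df = pd.DataFrame(
        {
            "animal_id": np.asarray(animal_id, dtype=object),
            "collection_group": np.asarray(
                collection_group if collection_group is not None else ["G1"] * n, dtype=object
            ),
        }
    )
    if df["animal_id"].duplicated().any():
        raise ValidationError("animal_ids must be unique")
    return df


@dataclass
class GenotypeMatrix:
    """Counted-allele dosages for n individuals x m autosomal markers.

    ``dosage[i, j]`` counts copies of ``counted_allele[j]`` carried by
    individual ``i`` at marker ``j`` (0/1/2, or :data:`MISSING`).  On read
    from PLINK the counted allele is allele1 of the ``.bim`` line; after
    :func:`boagwas.prep.recode_minor` it is the minor allele in the analyzed
    cohort.
    """

    dosage: np.ndarray
    markers: pd.DataFrame
    samples: pd.DataFrame
    counted_allele: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.ndim != 2:
            raise ValidationError("dosage must be 2-D (individuals x markers)")
        n, m = self.dosage.shape
        if len(self.samples) != n:
            raise ValidationError(f"sample table has {len(self.samples)} rows, dosage has {n}")
        if len(self.markers) != m:
            raise ValidationError(f"marker map has {len(self.markers)} rows, dosage has {m}")
        validate_marker_map(self.markers)
        valid = (self.dosage >= 0) & (self.dosage <= 2)
        if not (valid | (self.dosage == MISSING)).all():
            raise ValidationError("dosages must be 0/1/2 or the MISSING sentinel")
        if self.counted_allele is None:
            self.counted_allele = self.markers["allele1"].to_numpy(dtype=object).copy()
        else:
            self.counted_allele = np.asarray(self.counted_allele, dtype=object)
            if self.counted_allele.shape != (m,):
                raise ValidationError("counted_allele must have one entry per marker")

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Frequency of the counted allele per marker, ignoring missing calls.

        Monomorphic-with-all-missing markers yield NaN.
        """
        d = self.dosage.astype(float)
        d[self.dosage == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=0) / 2.0

    def call_rate_per_animal(self) -> np.ndarray:
        return (self.dosage != MISSING).mean(axis=1)

    def call_rate_per_marker(self) -> np.ndarray:
        return (self.dosage != MISSING).mean(axis=0)

    def imputed_dosage(self) -> np.ndarray:
        """Float dosage with missing cells replaced by the marker mean 2p."""
        d = self.dosage.astype(np.float64)
        miss = self.dosage == MISSING
        if miss.any():
            p = self.allele_freq()
            fill = np.broadcast_to(2.0 * p, d.shape)
            d[miss] = fill[miss]
        return d

    def subset(self, animals=None, markers=None) -> "GenotypeMatrix":
        """Return a copy restricted to boolean/index selections."""
        a = np.arange(self.n_individuals) if animals is None else np.asarray(animals)
        m = np.arange(self.n_markers) if markers is None else np.asarray(markers)
        if a.dtype == bool:
            a = np.flatnonzero(a)
        if m.dtype == bool:
            m = np.flatnonzero(m)
        return GenotypeMatrix(
            dosage=self.dosage[np.ix_(a, m)].copy(),
            markers=self.markers.iloc[m].reset_index(drop=True),
            samples=self.samples.iloc[a].reset_index(drop=True),
            counted_allele=self.counted_allele[m].copy(),
        )

    def copy(self) -> "GenotypeMatrix":
        return replace(
            self,
            dosage=self.dosage.copy(),
            markers=self.markers.copy(),
            samples=self.samples.copy(),
            counted_allele=self.counted_allele.copy(),
        )


@dataclass
class AncestryMatrix:
    """Brahman-origin allele count (0/1/2) per individual x marker.

    The "pseudo-genotype" encoding: 0 = homozygous Angus origin (AA),
    1 = heterozygous origin (AB/BA), 2 = homozygous Brahman origin (BB).
    """

    boa_dosage: np.ndarray
    markers: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.boa_dosage = np.asarray(self.boa_dosage, dtype=np.int8)
        if self.boa_dosage.ndim != 2:
            raise ValidationError("boa_dosage must be 2-D")
        n, m = self.boa_dosage.shape
        if len(self.samples) != n or len(self.markers) != m:
            raise ValidationError("ancestry matrix shape inconsistent with metadata")
        if not ((self.boa_dosage >= 0) & (self.boa_dosage <= 2)).all():
            raise ValidationError("BOA dosages must be 0, 1 or 2")

    @property
    def n_individuals(self) -> int:
        return self.boa_dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.boa_dosage.shape[1]

    def brahman_fraction(self) -> np.ndarray:
        """Per-individual genome-wide Brahman fraction implied by BOA calls."""
        return self.boa_dosage.mean(axis=1) / 2.0

    def subset(self, animals=None, markers=None) -> "AncestryMatrix":
        a = np.arange(self.n_individuals) if animals is None else np.asarray(animals)
        m = np.arange(self.n_markers) if markers is None else np.asarray(markers)
        if a.dtype == bool:
            a = np.flatnonzero(a)
        if m.dtype == bool:
            m = np.flatnonzero(m)
        return AncestryMatrix(
            boa_dosage=self.boa_dosage[np.ix_(a, m)].copy(),
            markers=self.markers.iloc[m].reset_index(drop=True),
            samples=self.samples.iloc[a].reset_index(drop=True),
        )
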