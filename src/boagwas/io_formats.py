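"""Readers and writers for the on-disk formats the pipeline touches.

PLINK 1 binary (.bed/.bim/.fam) carries genotypes; local-ancestry calls come
in as a long-format TSV of diplotypes; phenotypes as CSV; association results
as TSV.  Round-trips are bit-faithful: what :func:`write_plink` emits,
:func:`read_plink` reads back identically, including missing cells.

The .bed codec follows the SNP-major PLINK 1 layout: 3 magic bytes
(0x6c 0x1b 0x01) then, per marker, ceil(n/4) bytes of 2-bit genotype codes
with sample 0 in the lowest bits.  Code 0b00 = homozygous allele1,
0b01 = missing, 0b10 = heterozygous, 0b11 = homozygous allele2; dosage counts
allele1 of the .bim line.
"""

from __future__ import annotations

import io
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    MISSING,
    AncestryMatrix,
    GenotypeMatrix,
    make_marker_map,
    make_sample_table,
)
from .prep import BOA_CODES, UnknownDiplotypeError

BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

RESULT_COLUMNS = [
    "marker_id",
    "chromosome",
    "position_bp",
    "model",
    "beta_snp",
    "se_snp",
    "beta_boa",
    "se_boa",
    "wald",
    "df",
    "p",
    "neglog10p",
]


class PlinkFormatError(ValueError):
    """Base class for malformed PLINK file sets."""


class MissingFileMemberError(PlinkFormatError):
    """One of .bed/.bim/.fam is absent."""


class BedMagicError(PlinkFormatError):
    """.bed does not start with the PLINK 1 magic bytes."""


class BedSizeError(PlinkFormatError):
    """.bed payload size disagrees with the .bim/.fam dimensions."""


class UnmatchedIdError(ValueError):
    """Ancestry table refers to a marker or animal absent from the metadata."""


# 2-bit PLINK genotype code -> dosage of allele1 (bim column 5).
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


def read_plink(prefix: str | os.PathLike):
    """Read a PLINK 1 .bed/.bim/.fam triplet.

    Returns ``(GenotypeMatrix, MarkerMap, SampleTable)``; the marker map and
    sample table are also attached to the genotype matrix.  Dosage counts
    allele1 per marker, recorded in ``counted_allele``.
    """
    prefix = Path(prefix)
    for ext in (".bed", ".bim", ".fam"):
        if not prefix.with_suffix(ext).exists():
            raise MissingFileMemberError(f"missing {prefix.with_suffix(ext)}")

    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chromosome", "marker_id", "cm", "position_bp", "allele1", "allele2"],
        dtype={"marker_id": str, "allele1": str, "allele2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "phenotype"],
        dtype={"fid": str, "iid": str},
    )
    n, m = len(fam), len(bim)

    raw = prefix.with_suffix(".bed").read_bytes()
    if raw[:3] != BED_MAGIC:
        raise BedMagicError(f"{prefix.with_suffix('.bed')}: bad magic bytes {raw[:3]!r}")
    bytes_per_marker = (n + 3) // 4
    if len(raw) - 3 != bytes_per_marker * m:
        raise BedSizeError(
            f"bed payload is {len(raw) - 3} bytes, expected {bytes_per_marker * m} "
            f"for {n} samples x {m} markers (bim/fam length inconsistency?)"
        )

    payload = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, bytes_per_marker)
    # Unpack 2-bit codes, sample 0 in the low bits of each byte.
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (payload[:, :, None] >> shifts) & 0b11  # (m, bytes, 4)
    codes = codes.reshape(m, bytes_per_marker * 4)[:, :n]
    dosage = _CODE_TO_DOSAGE[codes].T  # (n, m)

    markers = make_marker_map(
        bim["marker_id"], bim["chromosome"], bim["position_bp"], bim["allele1"], bim["allele2"]
    )
    samples = make_sample_table(fam["iid"], fam["fid"])
    geno = GenotypeMatrix(
        dosage=dosage.copy(),
        markers=markers,
        samples=samples,
        counted_allele=markers["allele1"].to_numpy(dtype=object).copy(),
    )
    return geno, markers, samples


def write_plink(genotypes: GenotypeMatrix, prefix: str | os.PathLike) -> None:
    """Write a GenotypeMatrix as a PLINK 1 .bed/.bim/.fam triplet.

    The collection group is stored in the .fam family-ID column.  Dosages are
    written relative to allele1; if the matrix currently counts allele2 at a
    marker (after minor-allele recoding) the cell codes are flipped so the
    file is a faithful PLINK representation.
    """
    if genotypes.n_markers == 0:
        raise ValueError("cannot write a PLINK set with zero markers")
    if genotypes.n_individuals == 0:
        raise ValueError("cannot write a PLINK set with zero samples")
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)

    mk = genotypes.markers
    counts_a1 = genotypes.counted_allele == mk["allele1"].to_numpy(dtype=object)
    dos = genotypes.dosage.copy()
    flip = ~counts_a1
    if flip.any():
        sub = dos[:, flip]
        nonmiss = sub != MISSING
        sub[nonmiss] = 2 - sub[nonmiss]
        dos[:, flip] = sub

    with prefix.with_suffix(".bim").open("w") as fh:
        for row in mk.itertuples(index=False):
            fh.write(
                f"{row.chromosome}\t{row.marker_id}\t0\t{row.position_bp}"
                f"\t{row.allele1}\t{row.allele2}\n"
            )
    with prefix.with_suffix(".fam").open("w") as fh:
        for row in genotypes.samples.itertuples(index=False):
            fh.write(f"{row.collection_group}\t{row.animal_id}\t0\t0\t0\t-9\n")

    n, m = dos.shape
    code = np.empty((m, n), dtype=np.uint8)
    for dval, cval in _DOSAGE_TO_CODE.items():
        code[dos.T == dval] = cval
    bytes_per_marker = (n + 3) // 4
    padded = np.zeros((m, bytes_per_marker * 4), dtype=np.uint8)
    padded[:, :n] = code
    padded = padded.reshape(m, bytes_per_marker, 4)
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    packed = (padded << shifts).sum(axis=2).astype(np.uint8)
    with prefix.with_suffix(".bed").open("wb") as fh:
        fh.write(BED_MAGIC)
        fh.write(packed.tobytes())


def read_ancestry_table(
    path: str | os.PathLike, markers: pd.DataFrame, samples: pd.DataFrame
) -> AncestryMatrix:
    """Read long-format local-ancestry calls into an AncestryMatrix.

    Expects a TSV with columns ``animal_id``, ``marker_id`` and either
    ``diplotype`` (AA/AB/BA/BB, breed-of-origin of the two allele copies) or
    ``boa`` (Brahman allele count 0/1/2).  Every (animal, marker) pair must
    be present; markers are aligned to the MarkerMap order.
    """
    tab = pd.read_csv(path, sep="\t", dtype={"animal_id": str, "marker_id": str})
    if "diplotype" in tab.columns:
        dip = tab["diplotype"].astype(str)
        bad = ~dip.isin(BOA_CODES)
        if bad.any():
            raise UnknownDiplotypeError(
                f"unknown diplotype token(s): {sorted(dip[bad].unique())}"
            )
        tab = tab.assign(boa=dip.map(BOA_CODES))
    elif "boa" in tab.columns:
        if not tab["boa"].isin([0, 1, 2]).all():
            raise UnknownDiplotypeError("boa dosages must be 0, 1 or 2")
    else:
        raise ValueError("ancestry table needs a 'diplotype' or 'boa' column")

    unknown_m = set(tab["marker_id"]) - set(markers["marker_id"])
    unknown_a = set(tab["animal_id"]) - set(samples["animal_id"])
    if unknown_m or unknown_a:
        raise UnmatchedIdError(
            f"unmatched ids: markers {sorted(unknown_m)[:5]}, animals {sorted(unknown_a)[:5]}"
        )

    wide = tab.pivot(index="animal_id", columns="marker_id", values="boa")
    try:
        wide = wide.loc[samples["animal_id"], markers["marker_id"]]
    except KeyError as exc:
        raise UnmatchedIdError(f"ancestry table incomplete: {exc}") from exc
    if wide.isna().any().any():
        raise UnmatchedIdError("ancestry table has missing (animal, marker) cells")
    return AncestryMatrix(
        boa_dosage=wide.to_numpy(dtype=np.int8),
        markers=markers.reset_index(drop=True),
        samples=samples.reset_index(drop=True),
    )


def write_ancestry_table(ancestry: AncestryMatrix, path: str | os.PathLike) -> None:
    """Write an AncestryMatrix as long-format diplotype TSV (AA/AB/BB)."""
    rev = {0: "AA", 1: "AB", 2: "BB"}
    animal = np.repeat(ancestry.samples["animal_id"].to_numpy(), ancestry.n_markers)
    marker = np.tile(ancestry.markers["marker_id"].to_numpy(), ancestry.n_individuals)
    dip = np.vectorize(rev.get)(ancestry.boa_dosage.ravel())
    pd.DataFrame({"animal_id": animal, "marker_id": marker, "diplotype": dip}).to_csv(
        path, sep="\t", index=False
    )


def read_phenotypes(path: str | os.PathLike) -> pd.DataFrame:
    """Read a long-format phenotype CSV (animal_id, trait, value, collection_group)."""
    df = pd.read_csv(path, dtype={"animal_id": str, "trait": str, "collection_group": str})
    required = {"animal_id", "trait", "value", "collection_group"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phenotype CSV missing columns: {sorted(missing)}")
    return df


def write_phenotypes(df: pd.DataFrame, path: str | os.PathLike) -> None:
    cols = ["animal_id", "trait", "value", "collection_group"]
    df[cols].to_csv(path, index=False)


def write_results(results: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write per-marker association results as a TSV.

    One row per marker x model, sorted by (chromosome, position, model).
    Aliased or unavailable effects are written as empty fields, never as
    "nan" text.  ``neglog10p`` is derived as -log10(p).
    """
    if len(results) == 0:
        raise ValueError("results table is empty")
    out = results.copy()
    with np.errstate(divide="ignore"):
        out["neglog10p"] = -np.log10(out["p"].to_numpy(dtype=float))
    out = out.sort_values(
        ["chromosome", "position_bp", "model"], kind="mergesort"
    ).reset_index(drop=True)
    buf = io.StringIO()
    out[RESULT_COLUMNS].to_csv(buf, sep="\t", index=False, na_rep="")
    Path(path).write_text(buf.getvalue())


def read_results(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"marker_id": str, "model": str})
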