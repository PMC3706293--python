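"""Readers and writers for genotype, phenotype and kernel files.

Delimited text is the canonical interchange format: genotype matrices are
individual-major with a header row of marker IDs and the individual ID in
the first column; phenotypes are two-column ID/value tables; kernels are
square labelled matrices preceded by a provenance header (family, bandwidth,
block, shrink weight) so that train and cross kernels can be checked for
compatibility at prediction time.  The PLINK ``.raw`` additive-coding
dialect is also read (FID/IID/PAT/MAT/SEX/PHENOTYPE columns skipped).

Individuals are always joined by ID across files, never by position.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .kernels import MISSING_CODE, GenotypeMatrix, KernelMatrix

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "read_kernel",
    "write_kernel",
]

_PLINK_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def _sniff_sep(path: Path) -> str:
    first = path.open().readline()
    if "\t" in first:
        return "\t"
    if "," in first:
        return ","
    return r"\s+"


def read_genotypes(
    path,
    dialect: str = "auto",
    missing_token: str | None = None,
    coding: str | None = None,
) -> GenotypeMatrix:
    """Read a genotype matrix from delimited text or PLINK .raw.

    Coding is auto-detected from the observed codes ({0,1,2} with
    heterozygotes -> snp012; a two-symbol alphabet -> binary) unless
    overridden.  A cell that is not an integer code is an error naming its
    row and column -- unless ``missing_token`` declares it as missing, in
    which case the result carries missing values for
    :func:`diffkrr.simulate.impute_missing`.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    header = pd.read_csv(path, sep=sep, nrows=0)
    if dialect == "auto":
        dialect = "plink_raw" if list(header.columns[:6]) == _PLINK_META else "delimited"
    if dialect == "plink_raw":
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
        ids = df["IID"].tolist()
        body = df.drop(columns=_PLINK_META)
    elif dialect == "delimited":
        df = pd.read_csv(path, sep=sep, dtype=str, index_col=0, keep_default_na=False)
        ids = [str(i) for i in df.index.tolist()]
        body = df
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    marker_ids = [str(c) for c in body.columns]
    raw = body.to_numpy()
    codes = np.empty(raw.shape, dtype=np.int64)
    has_missing = False
    for (i, j), cell in np.ndenumerate(raw):
        text = str(cell).strip()
        if missing_token is not None and text == missing_token:
            codes[i, j] = MISSING_CODE
            has_missing = True
            continue
        try:
            codes[i, j] = int(text)
        except ValueError:
            raise ValueError(
                f"unparseable genotype {text!r} at individual {ids[i]!r}, marker {marker_ids[j]!r}"
                + ("" if missing_token else " (no missing_token declared)")
            ) from None

    if coding is None:
        observed = set(np.unique(codes[codes != MISSING_CODE]).tolist())
        coding = "snp012" if 1 in observed and observed <= {0, 1, 2} else "binary"
        if observed <= {0, 2} or observed <= {-1, 1}:
            coding = "binary"
        elif observed <= {0, 1, 2}:
            coding = "snp012"
    return GenotypeMatrix(
        codes=codes,
        coding=coding,
        marker_ids=marker_ids,
        individual_ids=ids,
        allow_missing=has_missing,
    )


def write_genotypes(g: GenotypeMatrix, path, missing_token: str = "NA"):
    path = Path(path)
    df = pd.DataFrame(g.codes, index=g.individual_ids, columns=g.marker_ids)
    df = df.astype(object).mask(df == MISSING_CODE, missing_token)
    df.to_csv(path, sep="\t", index_label="id")


def read_phenotypes(path) -> pd.Series:
    """Two-column ID/value table -> Series indexed by individual ID."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype={0: str})
    if df.shape[1] != 2:
        raise ValueError("phenotype file must have exactly two columns: id, value")
    s = pd.Series(df.iloc[:, 1].astype(float).to_numpy(), index=df.iloc[:, 0].astype(str))
    return s


def write_phenotypes(y, ids, path):
    pd.DataFrame({"id": ids, "value": np.asarray(y, dtype=float)}).to_csv(
        Path(path), sep="\t", index=False
    )


def write_kernel(k: KernelMatrix, path):
    """Kernel matrix with individual IDs and a provenance header.

    Header lines start with ``#`` and record family, bandwidth, marker block
    and shrink weight; they survive a round-trip losslessly.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# family: {k.family}\n")
        if k.theta is not None:
            fh.write(f"# theta: {k.theta!r}\n")
        if k.block_id is not None:
            fh.write(f"# block: {k.block_id}\n")
        if k.shrink_weight is not None:
            fh.write(f"# shrink: {k.shrink_weight!r}\n")
        df = pd.DataFrame(k.values, index=k.row_ids, columns=k.col_ids)
        df.to_csv(fh, sep="\t", index_label="id", float_format="%.17g")


def read_kernel(path) -> KernelMatrix:
    """Inverse of :func:`write_kernel`; a missing provenance header yields a
    warning and family 'unknown'."""
    path = Path(path)
    meta: dict[str, str] = {}
    skip = 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            key, _, value = line.lstrip("#").partition(":")
            meta[key.strip()] = value.strip()
    if "family" not in meta:
        warnings.warn(f"kernel file {path} has no provenance header; family set to 'unknown'")
    df = pd.read_csv(path, sep="\t", skiprows=skip, index_col=0)
    values = df.to_numpy(dtype=float)
    if values.shape[0] == values.shape[1]:
        asym = np.max(np.abs(values - values.T)) if values.size else 0.0
        if asym > 1e-12:
            warnings.warn(f"kernel read from {path} is asymmetric by {asym:.2e}; symmetrizing")
            values = (values + values.T) / 2.0
    return KernelMatrix(
        values=values,
        family=meta.get("family", "unknown"),
        theta=float(meta["theta"]) if "theta" in meta else None,
        block_id=meta.get("block"),
        shrink_weight=float(meta["shrink"]) if "shrink" in meta else None,
        row_ids=[str(i) for i in df.index.tolist()],
        col_ids=[str(c) for c in df.columns.tolist()],
    )
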