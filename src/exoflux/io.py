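"""Readers and writers for the delimited-text and spectral formats.

Feature tables and design sheets are TSV by default (comma accepted by
sniffing); spectral libraries are MSP or MGF handled through matchms.
MSI scenes are dense per-channel CSV grids (imzML accepted when the
optional pyimzml reader is installed).
"""

from __future__ import annotations

import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    Adduct,
    ChemClass,
    CompoundRecord,
    FeatureTable,
    FormatError,
    Polarity,
    SpectralLibrary,
    default_adducts,
    validate_design,
    DESIGN_COLUMNS,
    FEATURE_META_COLUMNS,
)

logger = logging.getLogger("exoflux")


def _read_delimited(path: str | os.PathLike) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t"
    with open(path) as fh:
        header = fh.readline()
    if "\t" not in header and "," in header:
        sep = ","
    return pd.read_csv(path, sep=sep)


def read_design(path: str | os.PathLike) -> pd.DataFrame:
    return validate_design(_read_delimited(path))


def read_feature_table(path: str | os.PathLike, design_path: str | os.PathLike) -> FeatureTable:
    """Read a feature table (feature_id, mz, rt, polarity, <sample...>) + design.

    Missing intensities are read as 0; the number replaced is logged.
    """
    design = read_design(design_path)
    table = _read_delimited(path)
    missing_cols = [c for c in FEATURE_META_COLUMNS if c not in table.columns]
    if missing_cols:
        raise FormatError(
            f"{path}: malformed header, missing column(s) {', '.join(missing_cols)}"
        )
    sample_cols = [c for c in table.columns if c not in FEATURE_META_COLUMNS]
    n_missing = int(table[sample_cols].isna().sum().sum())
    if n_missing:
        logger.warning("%s: %d missing intensities read as 0", path, n_missing)
        table[sample_cols] = table[sample_cols].fillna(0.0)
    return FeatureTable(features=table, design=design)


def write_feature_table(
    table: FeatureTable, path: str | os.PathLike, design_path: str | os.PathLike | None = None
) -> None:
    df = table.features.copy()
    float_cols = ["mz", "rt"] + table.sample_ids
    df[float_cols] = df[float_cols].map(lambda v: float(f"{v:.6g}"))
    df.to_csv(path, sep="\t", index=False)
    if design_path is not None:
        table.design.to_csv(design_path, sep="\t", index=False)


# --- spectral libraries ----------------------------------------------------

_MSP_EXT = {".msp"}
_MGF_EXT = {".mgf"}


def read_spectral_library(path: str | os.PathLike) -> SpectralLibrary:
    """Read an MSP or MGF library of authentic standards.

    Each entry needs a name and a neutral monoisotopic mass (MSP
    ``PARENT_MASS``/``EXACTMASS``, MGF ``PEPMASS`` treated as neutral
    mass). [M+H]+ and [M-H]- adduct m/z are derived from the neutral
    mass. Optional keys: RETENTION_TIME (min), CHEM_CLASS.
    """
    from matchms.importing import load_from_mgf, load_from_msp

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ext = path.suffix.lower()
    if ext in _MSP_EXT:
        spectra = list(load_from_msp(str(path), metadata_harmonization=True))
    elif ext in _MGF_EXT:
        spectra = list(load_from_mgf(str(path), metadata_harmonization=True))
    else:
        raise FormatError(f"{path}: unsupported library format {ext!r} (use .msp or .mgf)")
    records = []
    for i, sp in enumerate(spectra):
        md = sp.metadata
        name = md.get("compound_name") or md.get("name") or md.get("title")
        if not name:
            raise FormatError(f"{path}: library entry {i} has no name")
        mass = None
        for key in ("parent_mass", "exactmass", "exact_mass", "neutral_mass",
                    "pepmass", "precursor_mz"):
            if md.get(key) not in (None, ""):
                raw = md[key]
                mass = float(raw[0] if isinstance(raw, (tuple, list)) else raw)
                break
        if mass is None:
            raise FormatError(f"{path}: library entry {name!r} has no neutral mass")
        rt = float(md.get("retention_time", 0.0) or 0.0)
        cls_raw = str(md.get("chem_class", "other") or "other")
        try:
            chem_class = ChemClass(cls_raw)
        except ValueError:
            chem_class = ChemClass.other
        msms = [
            (float(mz), float(inten))
            for mz, inten in zip(sp.peaks.mz, sp.peaks.intensities)
        ]
        if msms:
            top = max(i for _, i in msms)
            msms = [(mz, i / top) for mz, i in msms]
        records.append(
            CompoundRecord(
                name=str(name),
                neutral_mass=mass,
                adducts=default_adducts(mass),
                reference_rt=rt,
                msms=msms,
                chem_class=chem_class,
            )
        )
    if not records:
        logger.warning("%s: empty spectral library", path)
    return SpectralLibrary(records=records)


def write_spectral_library(library: SpectralLibrary, path: str | os.PathLike) -> None:
    """Write a library as MSP via matchms (lossless for the fields we use)."""
    from matchms import Spectrum
    from matchms.exporting import save_as_msp

    path = Path(path)
    if path.exists():
        path.unlink()  # save_as_msp appends
    spectra = []
    for rec in library:
        msms = rec.msms or [(rec.neutral_mass, 1.0)]  # placeholder peak; mass carries identity
        mz = np.array([m for m, _ in msms], dtype=float)
        inten = np.array([i for _, i in msms], dtype=float)
        order = np.argsort(mz)
        spectra.append(
            Spectrum(
                mz=mz[order],
                intensities=inten[order],
                metadata={
                    "compound_name": rec.name,
                    "parent_mass": rec.neutral_mass,
                    "retention_time": rec.reference_rt,
                    "chem_class": rec.chem_class.value,
                    "num_peaks_real": len(rec.msms),
                },
                metadata_harmonization=True,
            )
        )
    save_as_msp(spectra, str(path))


# --- MSI grids -------------------------------------------------------------

def read_grid_csv(path: str | os.PathLike) -> np.ndarray:
    """Dense rows x cols intensity (or 0/1 mask) grid, no header."""
    arr = np.loadtxt(path, delimiter=",", ndmin=2, dtype=float)
    if not np.isfinite(arr).all():
        raise FormatError(f"{path}: non-finite values in grid")
    return arr


def write_grid_csv(grid: np.ndarray, path: str | os.PathLike) -> None:
    np.savetxt(path, np.asarray(grid, dtype=float), delimiter=",", fmt="%.6g")


def read_imzml_channel(path: str | os.PathLike, target_mz: float, tol: float = 0.01) -> np.ndarray:
    """Extract one ion image (summed intensity within ``tol`` of ``target_mz``)
    from an imzML file into a dense grid. Requires pyimzml."""
    from pyimzml.ImzMLParser import ImzMLParser

    parser = ImzMLParser(str(path))
    xs = [c[0] for c in parser.coordinates]
    ys = [c[1] for c in parser.coordinates]
    grid = np.zeros((max(ys), max(xs)), dtype=float)
    for idx, (x, y, *_rest) in enumerate(parser.coordinates):
        mzs, intens = parser.getspectrum(idx)
        mzs = np.asarray(mzs)
        sel = np.abs(mzs - target_mz) <= tol
        grid[y - 1, x - 1] = float(np.asarray(intens)[sel].sum())
    return grid


# --- expression matrices ---------------------------------------------------

def read_expression(path: str | os.PathLike, meta_path: str | os.PathLike):
    """Gene x sample expression TSV (first column gene id) + sample metadata."""
    expr = _read_delimited(path)
    expr = expr.set_index(expr.columns[0])
    expr.index = expr.index.astype(str)
    if expr.index.duplicated().any():
        raise FormatError(f"{path}: duplicate gene ids")
    expr = expr.astype(float)
    if (expr.values < 0).any():
        raise FormatError(f"{path}: negative expression values")
    meta = _read_delimited(meta_path)
    for col in ("sample_id", "condition"):
        if col not in meta.columns:
            raise FormatError(f"{meta_path}: missing column {col!r}")
    meta["sample_id"] = meta["sample_id"].astype(str)
    unknown = set(expr.columns) - set(meta["sample_id"])
    if unknown:
        raise FormatError(f"{path}: sample(s) absent from metadata: {sorted(unknown)}")
    return expr, meta


def read_gene_sets(path: str | os.PathLike) -> dict[str, list[str]]:
    """Annotation TSV with columns gene_id, set_name (one row per membership)."""
    df = _read_delimited(path)
    for col in ("gene_id", "set_name"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    sets: dict[str, list[str]] = {}
    for set_name, grp in df.groupby("set_name", sort=True):
        sets[str(set_name)] = [str(g) for g in grp["gene_id"]]
    return sets
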