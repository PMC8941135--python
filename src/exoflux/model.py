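"""Shared data model for the cross-feeding exometabolomics pipeline.

The containers here are deliberately thin wrappers around pandas objects:
a :class:`FeatureTable` couples an LC-MS feature matrix (one row per
feature, one intensity column per sample) with its sample design sheet,
and a :class:`SpectralLibrary` holds authentic-standard references
(neutral mass, adducts, retention time, MS/MS spectrum, chemical class)
used for identification.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PROTON_MASS = 1.007276  # Da, mass of a proton; used for [M+H]+ / [M-H]-


class Organism(str, enum.Enum):
    A_host = "A_host"
    B_symbiont = "B_symbiont"

    def partner(self) -> "Organism":
        return Organism.B_symbiont if self is Organism.A_host else Organism.A_host


class Condition(str, enum.Enum):
    blank = "blank"
    start = "start"
    end = "end"
    cell_extract = "cell_extract"
    alone = "alone"
    cross_fed = "cross_fed"
    direct_contact = "direct_contact"


class Polarity(str, enum.Enum):
    positive = "positive"
    negative = "negative"


class ChemClass(str, enum.Enum):
    amino_acid = "amino_acid"
    carbohydrate = "carbohydrate"
    fatty_acid_conjugate = "fatty_acid_conjugate"
    lipid = "lipid"
    nucleotide_nucleoside = "nucleotide_nucleoside"
    organic_acid = "organic_acid"
    other = "other"


class Direction(str, enum.Enum):
    """Feeding direction: spent medium of the donor fed to the recipient."""

    A_fed_to_B = "A_fed_to_B"
    B_fed_to_A = "B_fed_to_A"

    @property
    def donor(self) -> Organism:
        return Organism.A_host if self is Direction.A_fed_to_B else Organism.B_symbiont

    @property
    def recipient(self) -> Organism:
        return self.donor.partner()


class Call(str, enum.Enum):
    depleted = "depleted"
    exuded = "exuded"
    unchanged = "unchanged"


class MsiLevel(str, enum.Enum):
    """Metabolomics Standards Initiative confidence tier of an identification."""

    level1_plus_msms = "level1_plus_msms"
    level1 = "level1"
    unidentified = "unidentified"


DESIGN_COLUMNS = ["sample_id", "organism", "condition", "replicate", "polarity"]
FEATURE_META_COLUMNS = ["feature_id", "mz", "rt", "polarity"]


class FormatError(ValueError):
    """Malformed input file (header, column, or value contract violated)."""


class DesignMismatchError(ValueError):
    """Feature table and design sheet disagree on the sample set."""


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a sample design sheet.

    Required columns: sample_id, organism, condition, replicate, polarity.
    sample_id must be unique; replicate indices must be distinct within
    each (organism, condition) group.
    """
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise FormatError(f"design sheet missing column(s): {', '.join(missing)}")
    design = design[DESIGN_COLUMNS].copy()
    design["sample_id"] = design["sample_id"].astype(str)
    if design["sample_id"].duplicated().any():
        dup = design.loc[design["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"duplicate sample_id in design: {dup!r}")
    for col, enum_cls in (("organism", Organism), ("condition", Condition), ("polarity", Polarity)):
        bad = set(design[col].astype(str)) - {e.value for e in enum_cls}
        if bad:
            raise FormatError(f"invalid {col} value(s) in design: {sorted(bad)}")
    design["replicate"] = design["replicate"].astype(int)
    if (design["replicate"] < 1).any():
        raise FormatError("replicate indices must be positive integers")
    dup_rep = design.duplicated(subset=["organism", "condition", "replicate"])
    if dup_rep.any():
        row = design.loc[dup_rep].iloc[0]
        raise FormatError(
            f"duplicate replicate index {row['replicate']} in group "
            f"({row['organism']}, {row['condition']})"
        )
    return design.reset_index(drop=True)


@dataclass
class FeatureTable:
    """LC-MS feature matrix plus its sample design.

    ``features`` has columns feature_id, mz, rt, polarity followed by one
    intensity column per sample_id in ``design``. Intensities are total
    ion counts (arbitrary units, >= 0); no normalization is applied.
    """

    features: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        self.design = validate_design(self.design)
        f = self.features
        missing = [c for c in FEATURE_META_COLUMNS if c not in f.columns]
        if missing:
            raise FormatError(f"feature table missing column(s): {', '.join(missing)}")
        f = f.copy()
        f["feature_id"] = f["feature_id"].astype(str)
        if f["feature_id"].duplicated().any():
            dup = f.loc[f["feature_id"].duplicated(), "feature_id"].iloc[0]
            raise FormatError(f"duplicate feature_id: {dup!r}")
        sample_cols = [c for c in f.columns if c not in FEATURE_META_COLUMNS]
        unknown = set(sample_cols) - set(self.design["sample_id"])
        if unknown:
            raise DesignMismatchError(
                f"sample column(s) absent from design: {sorted(unknown)}"
            )
        for col in ("mz", "rt"):
            vals = pd.to_numeric(f[col], errors="coerce")
            if vals.isna().any() or not np.isfinite(vals).all():
                raise FormatError(f"non-finite {col} in feature table")
            f[col] = vals.astype(float)
        if (f["mz"] <= 0).any():
            raise FormatError("m/z values must be > 0")
        if (f["rt"] < 0).any():
            raise FormatError("retention times must be >= 0")
        inten = f[sample_cols].apply(pd.to_numeric, errors="coerce")
        if inten.isna().any().any():
            r, c = next(zip(*np.where(inten.isna().values)))
            raise FormatError(
                f"non-numeric intensity for feature {f['feature_id'].iloc[r]!r}, "
                f"sample {sample_cols[c]!r}"
            )
        neg = inten.values < 0
        if neg.any():
            r, c = next(zip(*np.where(neg)))
            raise FormatError(
                f"negative intensity for feature {f['feature_id'].iloc[r]!r}, "
                f"sample {sample_cols[c]!r}"
            )
        f[sample_cols] = inten.astype(float)
        self.features = f.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return [c for c in self.features.columns if c not in FEATURE_META_COLUMNS]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.features["feature_id"])

    def samples_for(
        self,
        organism: Organism | str | None = None,
        condition: Condition | str | None = None,
    ) -> list[str]:
        """Sample ids matching an (organism, condition) selection."""
        d = self.design
        mask = d["sample_id"].isin(self.sample_ids)
        if organism is not None:
            mask &= d["organism"] == str(getattr(organism, "value", organism))
        if condition is not None:
            mask &= d["condition"] == str(getattr(condition, "value", condition))
        return list(d.loc[mask, "sample_id"])

    def intensities(self, feature_id: str, sample_ids: list[str] | None = None) -> np.ndarray:
        row = self.features.loc[self.features["feature_id"] == feature_id]
        if row.empty:
            raise KeyError(f"no feature {feature_id!r}")
        cols = sample_ids if sample_ids is not None else self.sample_ids
        return row[cols].to_numpy(dtype=float).ravel()

    def require_conditions(self, *conditions: Condition | str) -> None:
        """Raise if any required condition has fewer than 2 replicate samples."""
        for cond in conditions:
            n = len(self.samples_for(condition=cond))
            if n < 2:
                raise DesignMismatchError(
                    f"condition {getattr(cond, 'value', cond)!r} has {n} sample(s); "
                    "statistical operations require >= 2 replicates"
                )


@dataclass
class Adduct:
    label: str
    mz: float
    polarity: Polarity


@dataclass
class CompoundRecord:
    """Authentic-standard reference compound.

    ``msms`` is a list of (fragment m/z, relative intensity in (0, 1])
    pairs and may be empty when no reference spectrum was acquired.
    """

    name: str
    neutral_mass: float
    adducts: list[Adduct] = field(default_factory=list)
    reference_rt: float = 0.0
    msms: list[tuple[float, float]] = field(default_factory=list)
    chem_class: ChemClass = ChemClass.other

    def __post_init__(self) -> None:
        if self.neutral_mass <= 0:
            raise ValueError(f"{self.name}: neutral mass must be > 0")
        if not self.adducts:
            self.adducts = default_adducts(self.neutral_mass)
        for a in self.adducts:
            expected = {
                Polarity.positive: self.neutral_mass + PROTON_MASS,
                Polarity.negative: self.neutral_mass - PROTON_MASS,
            }[a.polarity]
            if a.label in ("[M+H]+", "[M-H]-") and abs(a.mz - expected) > 0.01:
                raise ValueError(
                    f"{self.name}: adduct {a.label} m/z {a.mz:.4f} inconsistent "
                    f"with neutral mass (expected {expected:.4f})"
                )
        limit = max(a.mz for a in self.adducts) + 1.0
        for frag_mz, rel in self.msms:
            if frag_mz >= limit:
                raise ValueError(
                    f"{self.name}: fragment m/z {frag_mz:.4f} exceeds precursor + 1 Da"
                )
            if not (0 < rel <= 1):
                raise ValueError(f"{self.name}: fragment relative intensity must be in (0, 1]")

    def adducts_for(self, polarity: Polarity) -> list[Adduct]:
        return [a for a in self.adducts if a.polarity == polarity]


def default_adducts(neutral_mass: float) -> list[Adduct]:
    """Protonated/deprotonated adducts for a neutral monoisotopic mass."""
    return [
        Adduct("[M+H]+", neutral_mass + PROTON_MASS, Polarity.positive),
        Adduct("[M-H]-", neutral_mass - PROTON_MASS, Polarity.negative),
    ]


@dataclass
class SpectralLibrary:
    records: list[CompoundRecord]

    def __post_init__(self) -> None:
        names = [r.name for r in self.records]
        if len(names) != len(set(names)):
            dup = next(n for n in names if names.count(n) > 1)
            raise ValueError(f"duplicate compound name in library: {dup!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, name: str) -> CompoundRecord:
        for r in self.records:
            if r.name == name:
                return r
        raise KeyError(name)
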