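"""Synthetic data with planted, recoverable ground truth.

Every pipeline stage can be exercised without external downloads: this
module generates cross-feeding feature tables (log-normally noisy ion
counts with planted depletion fractions and exudation folds), spectral
libraries with decoy entries at controlled m/z and RT offsets, MSI
scenes with interaction-zone gradients, and expression matrices with
planted per-set log2 fold-change shifts. Ground truth is emitted
alongside every dataset so downstream calls can be scored for
sensitivity and false-discovery proportion.

The default cross-feeding panel emulates a two-organism symbiosis study:
two partners (a host plant and a cyanobacterial symbiont), four
replicates per condition, six chemical classes, ~53% of each donor's
exometabolites depleted by the partner (fractions 0.85-0.98), a smaller
set exuded at 4-fold, and the remainder null.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    Adduct,
    ChemClass,
    CompoundRecord,
    Direction,
    FeatureTable,
    Organism,
    Polarity,
    SpectralLibrary,
    default_adducts,
)
from .msi import IonImage

logger = logging.getLogger("exoflux")


# --- cross-feeding experiment ----------------------------------------------

@dataclass
class MetaboliteSpec:
    """One planted metabolite: at most one of depleted (d > 0, f = 1),
    exuded (f > 1, d = 0) or null (d = 0, f = 1)."""

    name: str
    chem_class: ChemClass
    donor: Organism
    base_intensity: float
    depletion_fraction: float = 0.0  # d in [0, 1]
    exudation_fold: float = 1.0  # f >= 1
    has_msms: bool = True
    neutral_mass: float | None = None  # assigned deterministically if None
    rt: float | None = None
    polarity: Polarity | None = None

    def __post_init__(self) -> None:
        if self.base_intensity <= 0:
            raise ValueError(f"{self.name}: base_intensity must be > 0")
        if not (0 <= self.depletion_fraction <= 1):
            raise ValueError(f"{self.name}: depletion_fraction must be in [0, 1]")
        if self.exudation_fold < 1:
            raise ValueError(f"{self.name}: exudation_fold must be >= 1")
        if self.depletion_fraction > 0 and self.exudation_fold > 1:
            raise ValueError(
                f"{self.name}: a metabolite is planted as depleted or exuded, not both"
            )

    @property
    def planted_call(self) -> str:
        if self.depletion_fraction > 0:
            return "depleted"
        if self.exudation_fold > 1:
            return "exuded"
        return "unchanged"


@dataclass
class TruthSpec:
    metabolites: list[MetaboliteSpec]
    n_replicates: int = 4
    noise_cv: float = 0.3
    blank_level: float = 1e3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        names = [m.name for m in self.metabolites]
        if len(names) != len(set(names)):
            raise ValueError("metabolite names must be unique")
        for m in self.metabolites:
            if m.planted_call == "exuded" and m.base_intensity <= self.blank_level:
                raise ValueError(
                    f"{m.name}: base_intensity must exceed blank_level for exuded metabolites"
                )

    def truth_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metabolite": [m.name for m in self.metabolites],
                "chem_class": [m.chem_class.value for m in self.metabolites],
                "donor": [m.donor.value for m in self.metabolites],
                "base_intensity": [m.base_intensity for m in self.metabolites],
                "depletion_fraction": [m.depletion_fraction for m in self.metabolites],
                "exudation_fold": [m.exudation_fold for m in self.metabolites],
                "planted_call": [m.planted_call for m in self.metabolites],
            }
        )


def assign_masses(spec: TruthSpec) -> None:
    """Deterministically assign neutral mass, RT and polarity where unset."""
    rng = np.random.default_rng(spec.seed + 101)
    for i, m in enumerate(spec.metabolites):
        draw_mass = rng.uniform(120.0, 600.0)
        draw_rt = rng.uniform(1.0, 14.0)
        if m.neutral_mass is None:
            m.neutral_mass = round(float(draw_mass), 4)
        if m.rt is None:
            m.rt = round(float(draw_rt), 2)
        if m.polarity is None:
            m.polarity = Polarity.positive if i % 2 == 0 else Polarity.negative


def _lognormal(rng: np.random.Generator, mean: float, cv: float, n: int) -> np.ndarray:
    """Log-normal draws with the requested arithmetic mean and CV; exact at cv=0."""
    if mean <= 0:
        return np.zeros(n)
    if cv == 0:
        return np.full(n, mean)
    sigma2 = math.log(1.0 + cv**2)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=n)


def generate_crossfeed_experiment(
    spec: TruthSpec,
) -> tuple[FeatureTable, FeatureTable, FeatureTable, pd.DataFrame]:
    """Full-factorial cross-feeding dataset: (start, end, blank, truth).

    The start and end tables carry samples for both feeding directions;
    the design's ``organism`` column names the recipient. For a
    metabolite with donor D, the spent-medium start mean in the D->
    partner direction is its base intensity and the end mean is
    base x (1 - d) x f; in the opposite direction both means sit at the
    blank level. With noise_cv = 0 the draws equal the means exactly.
    """
    assign_masses(spec)
    rng = np.random.default_rng(spec.seed)
    n = spec.n_replicates

    def sample_ids(tag: str) -> list[str]:
        return [f"{tag}_{r}" for r in range(1, n + 1)]

    directions = [Direction.A_fed_to_B, Direction.B_fed_to_A]
    design_rows = {"start": [], "end": [], "blank": []}
    columns: dict[str, dict[str, np.ndarray]] = {"start": {}, "end": {}, "blank": {}}
    for d in directions:
        for cond in ("start", "end"):
            for r, sid in enumerate(sample_ids(f"{d.value}_{cond}"), start=1):
                design_rows[cond].append(
                    {
                        "sample_id": sid,
                        "organism": d.recipient.value,
                        "condition": cond,
                        "replicate": r,
                        "polarity": Polarity.positive.value,
                    }
                )
    for r, sid in enumerate(sample_ids("blank"), start=1):
        design_rows["blank"].append(
            {
                "sample_id": sid,
                "organism": Organism.A_host.value,
                "condition": "blank",
                "replicate": r,
                "polarity": Polarity.positive.value,
            }
        )

    values: dict[str, dict[str, np.ndarray]] = {"start": {}, "end": {}, "blank": {}}
    for m in spec.metabolites:
        for d in directions:
            in_direction = m.donor == d.donor
            start_mean = m.base_intensity if in_direction else spec.blank_level
            end_mean = (
                m.base_intensity * (1.0 - m.depletion_fraction) * m.exudation_fold
                if in_direction
                else spec.blank_level
            )
            for cond, mean in (("start", start_mean), ("end", end_mean)):
                for r, sid in enumerate(sample_ids(f"{d.value}_{cond}")):
                    values[cond].setdefault(sid, {})
                draws = _lognormal(rng, mean, spec.noise_cv, n)
                for sid, v in zip(sample_ids(f"{d.value}_{cond}"), draws):
                    values[cond][sid][m.name] = v
        blank_draws = _lognormal(rng, spec.blank_level, spec.noise_cv, n)
        for sid, v in zip(sample_ids("blank"), blank_draws):
            values["blank"].setdefault(sid, {})
            values["blank"][sid][m.name] = v

    tables = {}
    for cond in ("start", "end", "blank"):
        meta = pd.DataFrame(
            {
                "feature_id": [m.name for m in spec.metabolites],
                "mz": [
                    m.neutral_mass + (1.007276 if m.polarity == Polarity.positive else -1.007276)
                    for m in spec.metabolites
                ],
                "rt": [m.rt for m in spec.metabolites],
                "polarity": [m.polarity.value for m in spec.metabolites],
            }
        )
        for row in design_rows[cond]:
            sid = row["sample_id"]
            meta[sid] = [values[cond][sid][m.name] for m in spec.metabolites]
        tables[cond] = FeatureTable(features=meta, design=pd.DataFrame(design_rows[cond]))
    return tables["start"], tables["end"], tables["blank"], spec.truth_table()


_PANEL_A = [  # host-donated exometabolites (8 depleted, 3 exuded, 4 null)
    ("trehalose", ChemClass.carbohydrate, 0.85, 1.0),
    ("choline-O-sulfate", ChemClass.organic_acid, 0.98, 1.0),
    ("UDP-galactose", ChemClass.nucleotide_nucleoside, 0.98, 1.0),
    ("arginine_host", ChemClass.amino_acid, 0.98, 1.0),
    ("asparagine", ChemClass.amino_acid, 0.85, 1.0),
    ("taurine", ChemClass.organic_acid, 0.85, 1.0),
    ("glycerophosphocholine", ChemClass.lipid, 0.85, 1.0),
    ("palmitoyl-glycine", ChemClass.fatty_acid_conjugate, 0.85, 1.0),
    ("sulfoacetate", ChemClass.organic_acid, 0.0, 4.0),
    ("glucose", ChemClass.carbohydrate, 0.0, 4.0),
    ("malate", ChemClass.organic_acid, 0.0, 4.0),
    ("xylose", ChemClass.carbohydrate, 0.0, 1.0),
    ("proline", ChemClass.amino_acid, 0.0, 1.0),
    ("citrate", ChemClass.organic_acid, 0.0, 1.0),
    ("uracil", ChemClass.nucleotide_nucleoside, 0.0, 1.0),
]

_PANEL_B = [  # symbiont-donated exometabolites
    ("cytidine", ChemClass.nucleotide_nucleoside, 0.98, 1.0),
    ("xanthosine", ChemClass.nucleotide_nucleoside, 0.98, 1.0),
    ("adenine", ChemClass.nucleotide_nucleoside, 0.85, 1.0),
    ("aspartate", ChemClass.amino_acid, 0.98, 1.0),
    ("acetyl-methionine", ChemClass.amino_acid, 0.85, 1.0),
    ("gluconate", ChemClass.carbohydrate, 0.85, 1.0),
    ("phosphoglycerate", ChemClass.carbohydrate, 0.98, 1.0),
    ("linoleoyl-ethanolamide", ChemClass.fatty_acid_conjugate, 0.85, 1.0),
    ("alanine", ChemClass.amino_acid, 0.0, 4.0),
    ("glutamine", ChemClass.amino_acid, 0.0, 4.0),
    ("guanosine", ChemClass.nucleotide_nucleoside, 0.0, 4.0),
    ("serine", ChemClass.amino_acid, 0.0, 1.0),
    ("fructose", ChemClass.carbohydrate, 0.0, 1.0),
    ("fumarate", ChemClass.organic_acid, 0.0, 1.0),
    ("monoolein", ChemClass.lipid, 0.0, 1.0),
]


def default_truth(
    seed: int = 0, n_replicates: int = 4, noise_cv: float = 0.3, blank_level: float = 1e3
) -> TruthSpec:
    """The default two-organism study conditions (see module docstring)."""
    rng = np.random.default_rng(seed + 7)
    metabolites = []
    for donor, panel in ((Organism.A_host, _PANEL_A), (Organism.B_symbiont, _PANEL_B)):
        for name, cls, d, f in panel:
            base = float(10 ** rng.uniform(5.0, 8.0))
            metabolites.append(
                MetaboliteSpec(
                    name=name,
                    chem_class=cls,
                    donor=donor,
                    base_intensity=base,
                    depletion_fraction=d,
                    exudation_fold=f,
                )
            )
    return TruthSpec(
        metabolites=metabolites,
        n_replicates=n_replicates,
        noise_cv=noise_cv,
        blank_level=blank_level,
        seed=seed,
    )


# --- spectral libraries ----------------------------------------------------

def _fragments_for(rng: np.random.Generator, precursor_mz: float) -> list[tuple[float, float]]:
    n_frag = int(rng.integers(3, 7))
    mzs = np.sort(rng.uniform(50.0, max(60.0, precursor_mz - 1.0), n_frag))
    intens = rng.uniform(0.1, 1.0, n_frag)
    intens[int(rng.integers(n_frag))] = 1.0  # base peak
    return [(round(float(m), 4), round(float(i), 3)) for m, i in zip(mzs, intens)]


def library_from_truth(spec: TruthSpec, with_msms: bool = True) -> SpectralLibrary:
    """Authentic-standard library matching the planted metabolite panel."""
    assign_masses(spec)
    rng = np.random.default_rng(spec.seed + 211)
    records = []
    for m in spec.metabolites:
        precursor = m.neutral_mass + 1.007276
        msms = _fragments_for(rng, precursor) if (with_msms and m.has_msms) else []
        records.append(
            CompoundRecord(
                name=m.name,
                neutral_mass=m.neutral_mass,
                adducts=default_adducts(m.neutral_mass),
                reference_rt=m.rt,
                msms=msms,
                chem_class=m.chem_class,
            )
        )
    return SpectralLibrary(records=records)


def generate_library_with_decoys(
    n_true: int,
    n_decoys: int,
    decoy_mz_offset: float,
    decoy_rt_offset: float,
    seed: int = 0,
) -> SpectralLibrary:
    """True compounds plus DECOY_ entries at controlled m/z and RT offsets.

    Each decoy's neutral mass sits ``decoy_mz_offset`` Da above a true
    compound's (so every adduct m/z is offset identically) and its RT
    ``decoy_rt_offset`` min later, letting each identification gate be
    probed independently.
    """
    if decoy_mz_offset <= 0 or decoy_rt_offset <= 0:
        raise ValueError("decoy offsets must be > 0")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_true):
        mass = round(float(rng.uniform(120.0, 600.0)), 4)
        rt = round(float(rng.uniform(1.0, 14.0)), 2)
        records.append(
            CompoundRecord(
                name=f"compound_{i:03d}",
                neutral_mass=mass,
                reference_rt=rt,
                msms=_fragments_for(rng, mass + 1.007276),
                chem_class=list(ChemClass)[i % len(ChemClass)],
            )
        )
    for j in range(n_decoys):
        target = records[j % n_true]
        records.append(
            CompoundRecord(
                name=f"DECOY_{j:03d}_{target.name}",
                neutral_mass=target.neutral_mass + decoy_mz_offset,
                reference_rt=target.reference_rt + decoy_rt_offset,
                msms=_fragments_for(rng, target.neutral_mass + decoy_mz_offset + 1.007276),
                chem_class=target.chem_class,
            )
        )
    return SpectralLibrary(records=records)


# --- MSI scenes ------------------------------------------------------------

@dataclass
class ChannelSpec:
    name: str
    source_region: str
    base_level: float
    induction_ratio: float = 1.0  # co-culture source-mean multiplier
    decay_length: float = 10.0  # pixels; inf -> flat field

    def __post_init__(self) -> None:
        if self.base_level < 0 or self.induction_ratio < 0:
            raise ValueError(f"{self.name}: levels and ratios must be >= 0")


@dataclass
class MsiSceneSpec:
    grid: tuple[int, int] = (40, 80)
    pixel_size: float = 200.0  # micrometres per pixel
    regions: dict[str, np.ndarray] = field(default_factory=dict)
    channels: list[ChannelSpec] = field(default_factory=list)
    noise_cv: float = 0.1  # additive Gaussian sd as a fraction of base level
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.regions:
            self.regions = default_region_layout(self.grid)
        rows, cols = self.grid
        stack = np.zeros(self.grid, dtype=int)
        for name, mask in self.regions.items():
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != (rows, cols):
                raise ValueError(f"region {name!r} shape mismatch")
            self.regions[name] = mask
            stack += mask.astype(int)
        if (stack > 1).any():
            raise ValueError("region masks must be disjoint")
        for ch in self.channels:
            if ch.source_region not in self.regions:
                raise ValueError(f"channel {ch.name!r}: unknown source region")
            if not self.regions[ch.source_region].any():
                raise ValueError(f"channel {ch.name!r}: empty source region")


def default_region_layout(grid: tuple[int, int]) -> dict[str, np.ndarray]:
    """Two colonies at left and right, interaction zone between, agar control
    strip along the top edge."""
    rows, cols = grid
    a = np.zeros(grid, dtype=bool)
    b = np.zeros(grid, dtype=bool)
    zone = np.zeros(grid, dtype=bool)
    agar = np.zeros(grid, dtype=bool)
    body = slice(rows // 4, rows)
    a[body, : cols // 5] = True
    b[body, -(cols // 5):] = True
    third = cols // 3
    zone[body, third: 2 * third] = True
    agar[: rows // 8, :] = True
    return {"organism_A": a, "organism_B": b, "interaction_zone": zone, "agar_control": agar}


def generate_msi_scene(spec: MsiSceneSpec, co_culture: bool) -> IonImage:
    """Render a scene: each channel is its base level inside the source
    region, decaying exponentially with distance from it; in co-culture
    the source mean is multiplied by the channel's induction ratio.
    Additive Gaussian noise (sd = noise_cv x base) is clipped at zero."""
    from scipy import ndimage

    rng = np.random.default_rng(spec.seed)
    channels = {}
    for ch in spec.channels:
        mask = spec.regions[ch.source_region]
        level = ch.base_level * (ch.induction_ratio if co_culture else 1.0)
        if math.isinf(ch.decay_length):
            field_ = np.full(spec.grid, level)
        else:
            dist = ndimage.distance_transform_edt(~mask)
            field_ = level * np.exp(-dist / ch.decay_length)
        if spec.noise_cv > 0:
            field_ = field_ + rng.normal(0.0, spec.noise_cv * max(level, 1e-12), spec.grid)
        channels[ch.name] = np.clip(field_, 0.0, None)
    return IonImage(channels=channels, pixel_size=spec.pixel_size, masks=dict(spec.regions))


# --- expression matrices ---------------------------------------------------

def generate_expression(
    n_genes: int,
    sets: list[tuple[str, int, float]],
    n_reps: int = 4,
    dispersion: float = 0.2,
    seed: int = 0,
    condition_a: str = "alone",
    condition_b: str = "direct_contact",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Expression matrix with planted per-set LFC shifts.

    ``sets`` is a list of (name, size, planted_lfc); member genes'
    log2 means are shifted by planted_lfc in condition B. Returns
    (expression genes x samples, sample metadata, set annotation,
    truth). Overlapping sets are permitted but flagged with a warning.
    """
    if sum(s for _, s, _ in sets) > 0 and max(s for _, s, _ in sets) > n_genes:
        raise ValueError("set sizes must be <= n_genes")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    base_log2 = rng.uniform(6.0, 12.0, n_genes)
    shift = np.zeros(n_genes)
    annot_rows = []
    assigned: set[int] = set()
    cursor = 0
    overlap = False
    for name, size, lfc in sets:
        idx = list(range(cursor, cursor + size))
        if cursor + size > n_genes:  # wrap -> overlapping membership
            idx = [i % n_genes for i in idx]
        if assigned & set(idx):
            overlap = True
        assigned |= set(idx)
        cursor += size
        for i in idx:
            annot_rows.append({"gene_id": genes[i], "set_name": name})
        shift[idx] += lfc
    if overlap:
        logger.warning("overlapping gene sets in planted annotation")
    samples, meta_rows = [], []
    data = {}
    for cond, delta in ((condition_a, 0.0), (condition_b, 1.0)):
        for r in range(1, n_reps + 1):
            sid = f"{cond}_{r}"
            samples.append(sid)
            meta_rows.append({"sample_id": sid, "condition": cond, "replicate": r})
            mu = base_log2 + shift * delta
            noise = rng.normal(0.0, dispersion, n_genes) if dispersion > 0 else 0.0
            data[sid] = 2.0 ** (mu + noise)
    expr = pd.DataFrame(data, index=pd.Index(genes, name="gene_id"))
    meta = pd.DataFrame(meta_rows)
    annotation = pd.DataFrame(annot_rows)
    truth = pd.DataFrame(
        {"set_name": [n for n, _, _ in sets],
         "size": [s for _, s, _ in sets],
         "planted_lfc": [l for _, _, l in sets]}
    )
    return expr, meta, annotation, truth
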