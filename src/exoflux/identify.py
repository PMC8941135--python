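"""Compound identification of LC-MS features against an authentic-standard library.

A feature is assigned to a library compound when its m/z lies within 5 ppm
OR 0.001 Da of a theoretical adduct m/z AND its retention time lies within
0.5 min of the standard's (all tolerances inclusive and configurable).
Passing both gates yields an MSI (Metabolomics Standards Initiative)
level-1 identification; an additional matching MS/MS spectrum raises the
confidence score to 3, while a mismatching MS/MS spectrum vetoes the
identification outright.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .model import (
    Adduct,
    CompoundRecord,
    FeatureTable,
    MsiLevel,
    Polarity,
    SpectralLibrary,
)

Spectrum = list[tuple[float, float]]  # (fragment m/z, relative intensity)


@dataclass
class IdentificationParams:
    """Tolerances of the identification gates.

    ppm_tol/da_tol form the OR'd mass gate; rt_tol is the retention-time
    gate; msms_similarity_threshold decides match vs veto when both an
    observed and a reference MS/MS spectrum exist.
    """

    ppm_tol: float = 5.0
    da_tol: float = 0.001
    rt_tol: float = 0.5
    msms_similarity_threshold: float = 0.7
    fragment_tol: float = 0.01

    def __post_init__(self) -> None:
        for name in ("ppm_tol", "da_tol", "rt_tol", "fragment_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0 <= self.msms_similarity_threshold <= 1):
            raise ValueError("msms_similarity_threshold must be in [0, 1]")


@dataclass
class Identification:
    feature_id: str
    compound: str | None
    adduct: str | None
    ppm_error: float | None
    da_error: float | None
    rt_delta: float | None
    msms_similarity: float | None
    score: int
    msi_level: MsiLevel
    reason: str = ""


def ppm_error(observed_mz: float, theoretical_mz: float) -> float:
    """Absolute mass error in parts per million."""
    if observed_mz <= 0 or theoretical_mz <= 0:
        raise ValueError("m/z values must be > 0")
    return abs(observed_mz - theoretical_mz) / theoretical_mz * 1e6


def mass_rt_gate(
    observed_mz: float,
    observed_rt: float,
    feature_polarity: Polarity,
    adduct: Adduct,
    reference_rt: float,
    params: IdentificationParams,
) -> tuple[bool, float, float, float, str]:
    """Apply the (ppm OR Da) mass gate and the RT gate; boundaries pass.

    Returns (passed, ppm_error, da_error, rt_delta, reason). A polarity
    mismatch fails the gate with a recorded reason rather than raising.
    """
    if feature_polarity != adduct.polarity:
        return False, math.inf, math.inf, math.inf, "polarity_mismatch"
    ppm = ppm_error(observed_mz, adduct.mz)
    da = abs(observed_mz - adduct.mz)
    rt_delta = abs(observed_rt - reference_rt)
    mass_ok = ppm <= params.ppm_tol or da <= params.da_tol
    rt_ok = rt_delta <= params.rt_tol
    if mass_ok and rt_ok:
        return True, ppm, da, rt_delta, "pass"
    reason = "mass_gate_fail" if not mass_ok else "rt_gate_fail"
    return False, ppm, da, rt_delta, reason


def msms_similarity(
    spectrum_a: Spectrum, spectrum_b: Spectrum, fragment_tol: float = 0.01
) -> float | None:
    """Greedy cosine similarity between two fragment spectra.

    Fragments are matched greedily (closest m/z pairs first) within
    ``fragment_tol``; intensities enter with square-root weighting. The
    score is symmetric, 1 for identical spectra, and ``None`` (absent,
    not 0) when either spectrum is empty.
    """
    if not spectrum_a or not spectrum_b:
        return None
    # all candidate pairs within tolerance, closest first
    pairs = [
        (abs(ma - mb), ia, ib_idx, inten_a, inten_b)
        for ia, (ma, inten_a) in enumerate(spectrum_a)
        for ib_idx, (mb, inten_b) in enumerate(spectrum_b)
        if abs(ma - mb) <= fragment_tol
    ]
    pairs.sort(key=lambda t: (t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    dot = 0.0
    for _, ia, ib, inten_a, inten_b in pairs:
        if ia in used_a or ib in used_b:
            continue
        used_a.add(ia)
        used_b.add(ib)
        dot += math.sqrt(inten_a) * math.sqrt(inten_b)
    norm_a = math.sqrt(sum(i for _, i in spectrum_a))
    norm_b = math.sqrt(sum(i for _, i in spectrum_b))
    if norm_a == 0 or norm_b == 0:
        return None
    return dot / (norm_a * norm_b)


def assign_identification(
    feature_id: str,
    observed_mz: float,
    observed_rt: float,
    polarity: Polarity,
    library: SpectralLibrary,
    params: IdentificationParams | None = None,
    observed_msms: Spectrum | None = None,
) -> Identification:
    """Identify one feature against the library.

    Among gate-passing (compound, adduct) candidates the best is the one
    with the lowest ppm error, ties broken by RT delta then name. If both
    the feature and the best candidate carry MS/MS spectra, similarity >=
    threshold raises the score to 3 (MSI level 1 plus MS/MS); similarity
    below threshold vetoes the identification (MS/MS mismatch invalidates).
    """
    params = params or IdentificationParams()
    if len(library) == 0:
        raise ValueError("spectral library is empty")
    candidates = []
    best_partial = None  # mass gate passed but RT failed -> score 1 evidence
    for rec in library:
        for adduct in rec.adducts_for(polarity):
            passed, ppm, da, rt_d, reason = mass_rt_gate(
                observed_mz, observed_rt, polarity, adduct, rec.reference_rt, params
            )
            if passed:
                candidates.append((ppm, rt_d, rec.name, da, adduct.label, rec))
            elif reason == "rt_gate_fail":
                key = (ppm, rt_d, rec.name)
                if best_partial is None or key < best_partial[:3]:
                    best_partial = (ppm, rt_d, rec.name, da, adduct.label)
    if not candidates:
        if best_partial is not None:
            ppm, rt_d, name, da, label = best_partial
            return Identification(
                feature_id, None, None, ppm, da, rt_d, None,
                score=1, msi_level=MsiLevel.unidentified, reason="rt_gate_fail",
            )
        return Identification(
            feature_id, None, None, None, None, None, None,
            score=0, msi_level=MsiLevel.unidentified, reason="no_gate_pass",
        )
    candidates.sort(key=lambda t: (t[0], t[1], t[2]))
    ppm, rt_d, name, da, label, rec = candidates[0]
    similarity = None
    if observed_msms and rec.msms:
        similarity = msms_similarity(observed_msms, rec.msms, params.fragment_tol)
    if similarity is not None:
        if similarity >= params.msms_similarity_threshold:
            return Identification(
                feature_id, name, label, ppm, da, rt_d, similarity,
                score=3, msi_level=MsiLevel.level1_plus_msms, reason="msms_match",
            )
        # a mismatching reference spectrum invalidates the identification
        return Identification(
            feature_id, None, None, ppm, da, rt_d, similarity,
            score=0, msi_level=MsiLevel.unidentified, reason="msms_mismatch",
        )
    return Identification(
        feature_id, name, label, ppm, da, rt_d, None,
        score=2, msi_level=MsiLevel.level1, reason="mass_rt_match",
    )


def identify_table(
    table: FeatureTable,
    library: SpectralLibrary,
    params: IdentificationParams | None = None,
    msms_by_feature: dict[str, Spectrum] | None = None,
) -> pd.DataFrame:
    """Identify every feature in a table; returns the identifications TSV frame."""
    msms_by_feature = msms_by_feature or {}
    rows = []
    for _, feat in table.features.iterrows():
        ident = assign_identification(
            feat["feature_id"],
            float(feat["mz"]),
            float(feat["rt"]),
            Polarity(feat["polarity"]),
            library,
            params,
            observed_msms=msms_by_feature.get(feat["feature_id"]),
        )
        rows.append(
            {
                "feature_id": ident.feature_id,
                "compound": ident.compound or "",
                "adduct": ident.adduct or "",
                "ppm_error": ident.ppm_error,
                "da_error": ident.da_error,
                "rt_delta": ident.rt_delta,
                "msms_similarity": ident.msms_similarity,
                "score": ident.score,
                "msi_level": ident.msi_level.value,
                "reason": ident.reason,
            }
        )
    return pd.DataFrame(rows)
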