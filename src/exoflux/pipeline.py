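"""End-to-end orchestration of the cross-feeding analysis.

A single declarative :class:`RunConfig` drives every stage: input (real
files or the seeded synthetic study), compound identification,
per-direction differential abundance, exudation calls, exchange-map
construction, and the optional MSI and gene-set reports. Identical
config + inputs + seed produce byte-identical result tables; every
parameter is recorded in the run log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import exchange as exchange_mod
from . import genesets as genesets_mod
from . import msi as msi_mod
from . import stats as stats_mod
from . import synthetic
from .identify import IdentificationParams, identify_table
from .io import read_feature_table, read_spectral_library, write_feature_table
from .model import ChemClass, Condition, Direction, FeatureTable, Organism

logger = logging.getLogger("exoflux")


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str | None = None
    # input: either paths to real tables or the seeded synthetic study
    start_path: str | None = None
    end_path: str | None = None
    blank_path: str | None = None
    design_path: str | None = None
    library_path: str | None = None
    simulate: bool = True
    noise_cv: float = 0.3
    n_replicates: int = 4
    # stages
    with_identify: bool = True
    with_msi: bool = True
    with_genesets: bool = True
    # parameters
    alpha: float = 0.05
    pseudocount: float = 1.0
    test_mode: str = "asymptotic"
    ppm_tol: float = 5.0
    da_tol: float = 0.001
    rt_tol: float = 0.5
    msms_similarity_threshold: float = 0.7
    fragment_tol: float = 0.01
    exudation_fold_threshold: float = 3.0
    min_reps_detected: int = 3
    msi_ratio_threshold: float = 2.0
    msi_noise_cv: float | None = None  # None -> noise_cv is reused
    geneset_dispersion: float = 0.2

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if not self.simulate:
            needed = ["start_path", "end_path", "blank_path", "design_path"]
            missing = [k for k in needed if getattr(self, k) is None]
            if missing:
                raise ConfigError(f"config missing input path(s): {', '.join(missing)}")
            if self.with_identify and self.library_path is None:
                raise ConfigError("identify stage enabled but no library_path configured")
        if self.test_mode not in ("asymptotic", "exact"):
            raise ConfigError(f"unknown test_mode {self.test_mode!r}")
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha must be in (0, 1)")


@dataclass
class RunResult:
    identifications: pd.DataFrame | None
    exchange_results: pd.DataFrame
    class_summaries: pd.DataFrame
    exudations: pd.DataFrame
    exchange_map: pd.DataFrame
    exchange_summary: dict
    msi_induction: pd.DataFrame | None
    geneset_response: pd.DataFrame | None
    truth: pd.DataFrame | None = None
    geneset_truth: pd.DataFrame | None = None
    out_dir: Path | None = None


def pairs_from_tables(
    start: FeatureTable,
    end: FeatureTable,
    direction: Direction,
    class_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Assemble per-metabolite (start, end) replicate vectors for one direction."""
    start_samples = start.samples_for(organism=direction.recipient, condition=Condition.start)
    end_samples = end.samples_for(organism=direction.recipient, condition=Condition.end)
    if len(start_samples) < 2 or len(end_samples) < 2:
        raise ValueError(
            f"direction {direction.value}: need >= 2 start and end replicates"
        )
    class_map = class_map or {}
    rows = []
    shared = [f for f in start.feature_ids if f in set(end.feature_ids)]
    for fid in shared:
        rows.append(
            {
                "metabolite": fid,
                "chem_class": class_map.get(fid, ChemClass.other.value),
                "start": start.intensities(fid, start_samples),
                "end": end.intensities(fid, end_samples),
            }
        )
    return pd.DataFrame(rows)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # annotate with the stage name
                raise StageError(f"[{name}] {exc}") from exc
        return wrapper
    return deco


def run_full_pipeline(config: RunConfig) -> RunResult:
    """Run every configured stage; see module docstring for the contract."""
    config.validate()
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    truth_df = None
    if config.simulate:
        spec = synthetic.default_truth(
            seed=config.seed, n_replicates=config.n_replicates, noise_cv=config.noise_cv
        )
        start, end, blank, truth_df = synthetic.generate_crossfeed_experiment(spec)
        library = synthetic.library_from_truth(spec) if config.with_identify else None
        class_map = dict(zip(truth_df["metabolite"], truth_df["chem_class"]))
        msms_by_feature = (
            {r.name: r.msms for r in library} if library is not None else None
        )
    else:
        start = read_feature_table(config.start_path, config.design_path)
        end = read_feature_table(config.end_path, config.design_path)
        blank = read_feature_table(config.blank_path, config.design_path)
        library = (
            read_spectral_library(config.library_path) if config.with_identify else None
        )
        class_map = (
            {r.name: r.chem_class.value for r in library} if library is not None else {}
        )
        msms_by_feature = None

    identifications = None
    if config.with_identify:
        params = IdentificationParams(
            ppm_tol=config.ppm_tol,
            da_tol=config.da_tol,
            rt_tol=config.rt_tol,
            msms_similarity_threshold=config.msms_similarity_threshold,
            fragment_tol=config.fragment_tol,
        )
        identifications = _stage("identify")(identify_table)(
            start, library, params, msms_by_feature=msms_by_feature
        )

    ex_params = exchange_mod.ExudationParams(
        fold_threshold=config.exudation_fold_threshold,
        min_reps_detected=config.min_reps_detected,
    )
    exudations = {
        org: _stage("exchange")(exchange_mod.define_exuded)(start, blank, org, ex_params)
        for org in Organism
    }
    exudation_df = pd.concat(exudations.values(), ignore_index=True)

    results = {}
    summaries = []
    for direction in Direction:
        pairs = _stage("crossfeed")(pairs_from_tables)(start, end, direction, class_map)
        # the tested family is the donor's exometabolome: only metabolites
        # established as exuded into the spent medium enter the BH family
        donor_exuded = set(
            exudations[direction.donor].loc[
                exudations[direction.donor]["exuded"], "metabolite"
            ]
        )
        pairs = pairs[pairs["metabolite"].isin(donor_exuded)].reset_index(drop=True)
        res = _stage("crossfeed")(stats_mod.differential_abundance)(
            pairs,
            direction,
            alpha=config.alpha,
            pseudocount=config.pseudocount,
            mode=config.test_mode,
        )
        results[direction] = res
        summ = _stage("crossfeed")(stats_mod.class_summary)(res)
        summ.insert(0, "direction", direction.value)
        summaries.append(summ)
    exchange_results = pd.concat(results.values(), ignore_index=True)
    class_summaries = pd.concat(summaries, ignore_index=True)

    msi_induction = None
    if config.with_msi:
        msi_induction = _stage("msi")(_run_msi_stage)(config)

    exchange_map = _stage("exchange")(exchange_mod.build_exchange_map)(
        exudations, results, msi_calls=msi_induction
    )
    exchange_summary = exchange_mod.summarize_exchange(exchange_map)

    geneset_df = geneset_truth = None
    if config.with_genesets:
        geneset_df, geneset_truth = _stage("genesets")(_run_geneset_stage)(config)

    result = RunResult(
        identifications=identifications,
        exchange_results=exchange_results,
        class_summaries=class_summaries,
        exudations=exudation_df,
        exchange_map=exchange_map,
        exchange_summary=exchange_summary,
        msi_induction=msi_induction,
        geneset_response=geneset_df,
        truth=truth_df,
        geneset_truth=geneset_truth,
        out_dir=out_dir,
    )
    if out_dir:
        _write_outputs(result, config, out_dir)
    return result


def _run_msi_stage(config: RunConfig) -> pd.DataFrame:
    """Synthetic MSI scene pair (mono vs co-culture) and induction calls.

    Channels mirror the interaction-zone candidates of the default
    panel: two induced channels (ratio 3) and one uninduced (ratio 1).
    """
    noise = config.noise_cv if config.msi_noise_cv is None else config.msi_noise_cv
    channels = [
        synthetic.ChannelSpec("xanthosine", "organism_B", 100.0, induction_ratio=3.0),
        synthetic.ChannelSpec("sulfoacetate", "interaction_zone", 80.0, induction_ratio=3.0),
        synthetic.ChannelSpec("choline-O-sulfate", "organism_A", 120.0, induction_ratio=1.0),
    ]
    spec = synthetic.MsiSceneSpec(channels=channels, noise_cv=noise, seed=config.seed)
    mono = synthetic.generate_msi_scene(spec, co_culture=False)
    co = synthetic.generate_msi_scene(
        dataclasses.replace(spec, seed=spec.seed + 1), co_culture=True
    )
    frames = []
    for ch in channels:
        call = msi_mod.induction_call(
            co, mono, ch.name, ch.source_region, config.msi_ratio_threshold
        )
        frames.append(
            {
                "metabolite": call.channel,
                "region": call.region,
                "mean_co": call.mean_co,
                "mean_mono": call.mean_mono,
                "ratio": call.ratio,
                "induced": call.induced,
                "planted_ratio": ch.induction_ratio,
            }
        )
    return pd.DataFrame(frames)


def _run_geneset_stage(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic expression study with planted set shifts, then the report."""
    sets = [
        ("photosystem", 40, -1.2),
        ("nitrogen_fixation", 30, -0.8),
        ("host_defense", 40, -1.5),
        ("carbon_fixation", 30, 0.0),
        ("ribosome", 40, 0.0),
    ]
    # competitive set-vs-background testing assumes a predominantly
    # unshifted background: annotated shifts stay under ~3% of genes
    expr, meta, annotation, truth = synthetic.generate_expression(
        n_genes=4000,
        sets=sets,
        n_reps=config.n_replicates,
        dispersion=config.geneset_dispersion,
        seed=config.seed,
    )
    set_map = {
        name: list(annotation.loc[annotation["set_name"] == name, "gene_id"])
        for name in truth["set_name"]
    }
    report = genesets_mod.geneset_response_table(
        expr, meta, set_map, "alone", "direct_contact",
        pseudocount=config.pseudocount, alpha=config.alpha, mode=config.test_mode,
    )
    return report, truth


def _write_outputs(result: RunResult, config: RunConfig, out_dir: Path) -> None:
    def write(df: pd.DataFrame | None, name: str) -> None:
        if df is not None:
            df.to_csv(out_dir / name, sep="\t", index=False)

    write(result.identifications, "identifications.tsv")
    write(result.exchange_results, "exchange_results.tsv")
    write(result.class_summaries, "class_summary.tsv")
    write(result.exudations, "exudation_calls.tsv")
    write(result.exchange_map, "exchange_map.tsv")
    write(result.msi_induction, "msi_induction.tsv")
    write(result.geneset_response, "geneset_response.tsv")
    write(result.truth, "planted_truth.tsv")
    write(result.geneset_truth, "planted_geneset_truth.tsv")
    log = dataclasses.asdict(config)
    log["per_class_summary_rows"] = int(len(result.class_summaries))
    log["n_exchange_edges"] = result.exchange_summary["n_edges"]
    with open(out_dir / "run_log.yaml", "w") as fh:
        yaml.safe_dump(log, fh, sort_keys=True)
    summary = dict(result.exchange_summary)
    summary["per_class"] = summary["per_class"].to_dict(orient="records")
    with open(out_dir / "exchange_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
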