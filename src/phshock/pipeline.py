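"""End-to-end orchestration of the recovery and regulon analyses.

``run_recovery_pipeline`` chains calibration -> gating -> per-cell pH ->
induction kinetics -> subpopulation calls on one stress-recovery experiment;
``run_regulon_pipeline`` chains replicate averaging -> fold changes ->
regulon scoring on one expression experiment.  Either consumes files on disk
or, given only a seed, generates its inputs with the synthetic module — the
route used by the test suite, where every estimate has a known truth.

Every run writes a ``manifest.json`` recording the package version, the
seed, a hash of the configuration, and input-file hashes, with no
wall-clock content, so identical runs produce byte-identical bundles.
Excluded-event counts (debris, BV421-bright, ambiguous strain or class,
out-of-range ratios) are first-class outputs: the fractions themselves carry
biology (e.g. the BV421-bright fraction varies with handling).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, calibration, gating, io, kinetics, simulate, subpop
from . import regulon as regulon_mod
from .subpop import RestingRange


class PipelineConfigError(ValueError):
    """Configuration invalid before any computation ran."""


@dataclass
class RunConfig:
    out_dir: str = "phshock_out"
    seed: int = 0
    # input paths; None means "generate synthetically from the seed"
    events_dir: str | None = None
    calibration_fit: str | None = None
    tpm_path: str | None = None
    samples_path: str | None = None
    gene_sets: str | None = None
    # analysis parameters
    scatter_coverage: float = 0.98
    bv421_quantile: float = 0.999
    fitc_threshold: float = 300.0
    strain_margin: float = 0.0
    posterior_cutoff: float = 0.90
    resting_range: tuple = (7.3, 7.8)
    fitness_window: float = 160.0
    min_regulon_size: int = 4
    pseudocount: float = 1.0
    min_cells: int = 1000
    sim_config: simulate.SimConfig = field(default_factory=simulate.SimConfig)
    sim_truth: simulate.SimTruth | None = None

    def validate(self, need: tuple[str, ...] = ()) -> None:
        for name in need:
            value = getattr(self, name)
            if value is None:
                raise PipelineConfigError(f"config field {name!r} is required but unset")
            if isinstance(value, str) and not Path(value).exists():
                raise PipelineConfigError(f"config field {name!r}: path {value} does not exist")

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            return str(o)
        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)  # analysis parameters only
        blob = json.dumps(payload, sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_manifest(out: Path, config: RunConfig, stage_info: dict, inputs: dict) -> None:
    manifest = {
        "package": "phshock",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "input_hashes": inputs,
        "stages": stage_info,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))


def run_recovery_pipeline(config: RunConfig) -> dict:
    """Full single-cell recovery analysis; returns the result bundle paths.

    Stages (each error is re-raised tagged with its stage):
      calibrate -> gate -> ph -> induction -> subpopulations
    """
    if config.events_dir and not config.calibration_fit:
        raise PipelineConfigError(
            "config field 'calibration_fit' is required when events_dir is set"
        )
    if config.calibration_fit:
        config.validate(("calibration_fit",))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = config.sim_truth or simulate.SimTruth(seed=config.seed)
    inputs: dict[str, str] = {}
    stage_info: dict[str, dict] = {}

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:  # tag the failing stage
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        return deco

    # --- calibration ------------------------------------------------------
    @stage("calibrate")
    def fit():
        if config.calibration_fit:
            inputs["calibration_fit"] = io.file_sha256(config.calibration_fit)
            return calibration.CalibrationFit.from_json(Path(config.calibration_fit).read_text())
        tables = simulate.simulate_calibration(config.sim_config, truth)
        corrected = {
            ph: calibration.subtract_background(tbl, truth.background_405, truth.background_488)
            for ph, tbl in tables.items()
        }
        points = calibration.calibration_points(corrected)
        fit = calibration.fit_calibration(
            points, background_405=truth.background_405, background_488=truth.background_488
        )
        (out / "calibration_fit.json").write_text(fit.to_json())
        return fit

    # --- events -----------------------------------------------------------
    @stage("load-events")
    def events():
        if config.events_dir:
            frames = []
            for path in sorted(Path(config.events_dir).glob("*.csv")):
                inputs[path.name] = io.file_sha256(path)
                frames.append(io.read_events(path))
            if not frames:
                raise PipelineConfigError(f"no event CSVs under {config.events_dir}")
            return pd.concat(frames, ignore_index=True)
        return simulate.simulate_recovery(config.sim_config, truth)

    # --- gating -----------------------------------------------------------
    @stage("gate")
    def gated():
        t0 = events["timepoint_min"] == events["timepoint_min"].min()
        reference = events[t0]
        g = gating.gate_scatter(events, reference, coverage=config.scatter_coverage)
        threshold = gating.bv421_threshold_from_control(
            reference[reference["ch_bv421"] < reference["ch_bv421"].quantile(0.95)],
            q=config.bv421_quantile,
        )
        g = gating.exclude_bv421(g, threshold)
        return g[(g["gate"] == "cell") & (g["bv421"] == "ok")].copy()

    @stage("split-strains")
    def strains():
        return gating.split_strains(gated, config.fitc_threshold, margin=config.strain_margin)

    labeled, spike = strains
    stage_info["gate"] = {
        "n_total": int(len(events)),
        "n_cell": int(len(gated)),
        "n_labeled": int(len(labeled)),
        "n_spike": int(len(spike)),
        "bv421_bright_fraction": gated.attrs.get("bv421_bright_fraction"),
    }

    # --- per-cell pH ------------------------------------------------------
    @stage("ph")
    def ph_table():
        corrected = calibration.subtract_background(
            labeled, fit.background_405, fit.background_488
        )
        ph, n_out = calibration.ratio_to_ph(fit, corrected["ratio405_488"])
        corrected["ph"] = ph
        stage_info["ph"] = {"n_out_of_range": n_out,
                            "n_ratio_excluded": corrected.attrs.get("n_ratio_excluded")}
        return corrected

    resting = RestingRange(*config.resting_range)
    ph_summary = (
        ph_table.groupby("timepoint_min")["ph"]
        .agg(median_ph="median", n="count")
        .reset_index()
    )
    ph_summary["fraction_in_resting_range"] = [
        subpop.fraction_in_range(group["ph"].dropna(), resting)
        for _, group in ph_table.groupby("timepoint_min")
    ]
    ph_summary.to_csv(out / "ph_summary.tsv", sep="\t", index=False)

    # --- induction kinetics ----------------------------------------------
    @stage("induction")
    def induction():
        baseline = ph_table[ph_table["timepoint_min"] == ph_table["timepoint_min"].min()]
        curve = kinetics.fold_change_curve(
            ph_table, baseline, min_cells=min(config.min_cells, len(baseline))
        )
        ind_fit = kinetics.fit_induction(curve)
        pd.DataFrame({
            "timepoint_min": curve.timepoints,
            "fold_change": curve.fold_change,
            "n_cells": curve.n_cells,
        }).to_csv(out / "induction_curve.tsv", sep="\t", index=False)
        return curve, ind_fit

    curve, ind_fit = induction
    stage_info["induction"] = {
        "a": ind_fit.a, "b": ind_fit.b, "c": ind_fit.c, "d": ind_fit.d,
        "delay_min": kinetics.induction_delay(ind_fit),
        "no_induction": ind_fit.no_induction,
    }

    # --- subpopulations ---------------------------------------------------
    @stage("subpopulations")
    def subpops():
        baseline_stat = np.median(
            ph_table.loc[ph_table["timepoint_min"] == ph_table["timepoint_min"].min(),
                         "ch_red"].to_numpy()
            / ph_table.loc[ph_table["timepoint_min"] == ph_table["timepoint_min"].min(),
                           "fsc_area"].to_numpy()
        )
        red_fold = (ph_table["ch_red"] / ph_table["fsc_area"]) / baseline_stat
        expr_fit = subpop.fit_two_component(red_fold, domain="log")
        expr_labels = subpop.classify(expr_fit, config.posterior_cutoff, names=("low", "high"))
        bud_fit = subpop.fit_two_component(ph_table["fsc_width"], domain="linear")
        bud_labels = subpop.classify(bud_fit, config.posterior_cutoff,
                                     names=("unbudded", "budded"))
        table = ph_table.copy()
        table["expression_class"] = expr_labels
        table["budding_class"] = bud_labels
        table["red_fold"] = red_fold.to_numpy()
        series, window_mean = subpop.budded_fraction(
            table["timepoint_min"].to_numpy(), bud_labels
        )
        series.to_csv(out / "budded_fraction.tsv", sep="\t", index=False)
        keep = [c for c in table.columns if not c.startswith("true_")]
        table[keep].to_csv(out / "events_labeled.csv", index=False)
        high = table.loc[table["expression_class"] == "high", "ph"].dropna()
        low = table.loc[table["expression_class"] == "low", "ph"].dropna()
        if len(high) >= 3 and len(low) >= 3:
            _, p_ph = subpop.compare_class_ph(high, low)
        else:
            p_ph = float("nan")
        return {
            "expression_means": expr_fit.means.tolist(),
            "budding_means": bud_fit.means.tolist(),
            "ambiguous_expression_fraction": float(np.mean(expr_labels == "ambiguous")),
            "budded_window_mean": window_mean,
            "high_vs_low_ph_p": p_ph,
            "high_median_ph": float(high.median()) if len(high) else float("nan"),
            "low_median_ph": float(low.median()) if len(low) else float("nan"),
        }

    stage_info["subpopulations"] = subpops
    _write_manifest(out, config, stage_info, inputs)
    return {"out_dir": str(out), "stages": stage_info, "fit": fit,
            "induction_fit": ind_fit, "curve": curve}


def run_regulon_pipeline(config: RunConfig) -> dict:
    """Expression-side analysis: fold changes, regulon scores, adjusted p."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = config.sim_truth or simulate.SimTruth(seed=config.seed)
    inputs: dict[str, str] = {}

    if config.gene_sets:
        config.validate(("gene_sets",))
        regulons = regulon_mod.read_gmt(config.gene_sets)
        inputs["gene_sets"] = io.file_sha256(config.gene_sets)
    else:
        rng = np.random.default_rng(config.seed + 10)
        regulons = _default_synthetic_regulons(rng)
    if config.tpm_path:
        config.validate(("tpm_path", "samples_path"))
        tpm, samples = io.read_tpm(config.tpm_path, config.samples_path)
        inputs["tpm"] = io.file_sha256(config.tpm_path)
    else:
        tpm, samples = simulate.simulate_expression(regulons, config.sim_config, truth)

    try:
        cond = regulon_mod.combine_replicates(tpm, samples)
        induction = regulon_mod.induction_fold_change(
            cond, acidification="allowed", translation="cycloheximide",
            pseudo=config.pseudocount,
        )
        acid = regulon_mod.acidification_fold_change(
            cond, translation="cycloheximide", pseudo=config.pseudocount
        )
        scores = regulon_mod.score_regulons(
            induction, acid, regulons, min_size=config.min_regulon_size
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'regulon-score' failed: {exc}") from exc

    from statsmodels.stats.multitest import multipletests
    if len(scores):
        scores = scores.sort_values("tf", kind="stable").reset_index(drop=True)
        scores["p_adj_bh"] = multipletests(scores["p_vs_background"], method="fdr_bh")[1]
        scores = scores.sort_values("median_acid_fold", ascending=False,
                                    kind="stable").reset_index(drop=True)
    scores.to_csv(out / "regulon_scores.tsv", sep="\t", index=False)
    _write_manifest(out, config, {"regulon": {"n_scored": int(len(scores))}}, inputs)
    return {"out_dir": str(out), "scores": scores}


def _default_synthetic_regulons(rng: np.random.Generator):
    """Hsf1/Msn2-4-style sets plus null regulons over the synthetic universe."""
    background = [f"bg{i:04d}" for i in range(2000)]
    hsf1 = [f"HSF1_{i:02d}" for i in range(40)]
    msn = [f"MSN24_{i:02d}" for i in range(60)]
    sets = [
        regulon_mod.RegulonSet("Hsf1", tuple(hsf1)),
        regulon_mod.RegulonSet("Msn2/4", tuple(msn)),
    ]
    pool = np.array(background)
    offset = 0
    for k in range(20):
        size = int(rng.integers(8, 40))
        members = pool[offset:offset + size]
        offset += size
        sets.append(regulon_mod.RegulonSet(f"TF{k:02d}", tuple(members),
                                           annotation="non-stress-annotated"))
    return sets
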