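"""End-to-end orchestration: simulate -> train -> evaluate -> calibrate ->
quantify -> report.

Each stage reads its inputs from and writes its outputs to the run output
directory, so any stage can be re-run from serialized intermediates.  All
randomness derives from the master seed in the config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np

from . import runio
from .config import DrugConfig, RunConfig
from .metrics import evaluate_segmentation
from .quantify import back_calculate, fit_calibration, pair_ratio
from .simulate import (
    generate_calibration_run,
    generate_dataset,
    simulate_window_pair,
)
from .unet import UNet1D, build_unet, predict_masks, train_model
from .valstats import bland_altman, precision_accuracy

log = logging.getLogger("msquant")

STAGES = ("simulate", "train", "evaluate", "calibrate", "quantify", "report")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _model_path(out: Path) -> Path:
    return out / "model.npz"


def _load_model(out: Path) -> UNet1D:
    path = _model_path(out)
    if not path.exists():
        raise StageError(f"no trained model at {path}; run the train stage first")
    return UNet1D.load(path)


def _drug_qc_levels(drug: DrugConfig) -> list[float]:
    levels = [c for c in (drug.qc_high, drug.qc_low) if c is not None]
    return levels or [float(np.sqrt(drug.low * drug.high))]


def stage_simulate(cfg: RunConfig, out: Path) -> None:
    design = cfg.drugs[0].design()
    train = generate_dataset(cfg.n_train, design, cfg.shape_dist, cfg.noise,
                             seed=cfg.stage_seed("simulate/train"), mode=cfg.mode)
    test = generate_dataset(cfg.n_test, design, cfg.shape_dist, cfg.noise,
                            seed=cfg.stage_seed("simulate/test"), mode=cfg.mode)
    runio.write_run(train, out / "data" / "train", config=cfg.to_dict())
    runio.write_run(test, out / "data" / "test", config=cfg.to_dict())
    cfg.to_yaml(out / "config.yaml")
    log.info("simulate: %d train / %d test window pairs", train.n_samples, test.n_samples)


def stage_train(cfg: RunConfig, out: Path) -> None:
    train, _ = runio.read_run(out / "data" / "train")
    model = build_unet(cfg.unet)
    result = train_model(model, train.flat_windows(), train.flat_labels(), cfg.unet)
    model.save(_model_path(out))
    (out / "loss_trace.json").write_text(json.dumps(result.loss_trace))
    log.info("train: %d epochs, loss %.4g -> %.4g", len(result.loss_trace),
             result.loss_trace[0], result.loss_trace[-1])


def stage_evaluate(cfg: RunConfig, out: Path) -> None:
    test, _ = runio.read_run(out / "data" / "test")
    model = _load_model(out)
    preds = predict_masks(model, test.flat_windows())
    metrics = evaluate_segmentation(preds, test.flat_labels(), test.flat_windows())
    (out / "segmentation_metrics.json").write_text(
        json.dumps(dataclasses.asdict(metrics), indent=2)
    )
    log.info("evaluate: accuracy %.4f, area deviation %.4g",
             metrics.accuracy, metrics.area_ratio_deviation)


def stage_calibrate(cfg: RunConfig, out: Path) -> None:
    model = _load_model(out)
    curves = {}
    for drug in cfg.drugs:
        design = drug.design(replicates=cfg.calibration_replicates)
        shape = cfg.shape_dist.draw(
            np.random.default_rng(cfg.stage_seed(f"calibrate/shape/{drug.name}"))
        )
        run = generate_calibration_run(
            design, shape, cfg.noise, cfg.mode,
            seed=cfg.stage_seed(f"calibrate/{drug.name}"),
        )
        concs, ratios = [], []
        for conc, pair, _truth in run:
            masks = predict_masks(
                model,
                np.stack([pair.analyte.intensities, pair.internal_standard.intensities]),
            )
            concs.append(conc)
            ratios.append(pair_ratio(pair, (masks[0], masks[1])))
        curve = fit_calibration(concs, ratios, drug_id=drug.name)
        curves[drug.name] = {
            **dataclasses.asdict(curve), "concs": concs, "ratios": ratios,
        }
        log.info("calibrate %s: slope %.4g, R^2 %.5f", drug.name,
                 curve.slope, curve.r_squared)
    (out / "calibration.json").write_text(json.dumps(curves, indent=2))


def stage_quantify(cfg: RunConfig, out: Path) -> None:
    model = _load_model(out)
    curves = json.loads((out / "calibration.json").read_text())
    records = []
    for drug in cfg.drugs:
        curve_d = curves[drug.name]
        from .quantify import CalibrationCurve

        curve = CalibrationCurve(
            slope=curve_d["slope"], intercept=curve_d["intercept"],
            r_squared=curve_d["r_squared"], levels=tuple(curve_d["levels"]),
            drug_id=drug.name,
        )
        design = drug.design()
        qc_levels = _drug_qc_levels(drug)
        rng = np.random.default_rng(cfg.stage_seed(f"quantify/{drug.name}"))
        for i in range(cfg.n_unknowns):
            nominal = qc_levels[i % len(qc_levels)]
            shape = cfg.shape_dist.draw(rng)
            pair, _truth = simulate_window_pair(
                nominal, design, shape, cfg.noise, cfg.mode,
                seed=int(rng.integers(0, 2**63 - 1)),
            )
            masks = predict_masks(
                model,
                np.stack([pair.analyte.intensities, pair.internal_standard.intensities]),
            )
            from .quantify import peak_area

            a_area = peak_area(pair.analyte.intensities, masks[0]).area
            i_area = peak_area(pair.internal_standard.intensities, masks[1]).area
            result = back_calculate(a_area / i_area, curve, nominal=nominal)
            records.append({
                "sample": i, "drug": drug.name, "analyte_area": a_area,
                "is_area": i_area, "ratio": result.ratio,
                "conc": result.back_calc_conc, "bias_percent": result.bias_percent,
            })
    runio.write_results(out / "quant_results.tsv", records)
    log.info("quantify: %d unknowns across %d drugs", len(records), len(cfg.drugs))


def _measure_chain(cfg: RunConfig, model: UNet1D, drug: DrugConfig,
                   truths: np.ndarray, chain: str):
    """One independent measurement chain: own calibration + own acquisitions."""
    from .quantify import peak_area

    design = drug.design()
    rng = np.random.default_rng(cfg.stage_seed(f"report/{chain}/{drug.name}"))
    shape = cfg.shape_dist.draw(rng)
    run = generate_calibration_run(design, shape, cfg.noise, cfg.mode,
                                   seed=int(rng.integers(0, 2**63 - 1)))
    concs, ratios = [], []
    for conc, pair, _truth in run:
        masks = predict_masks(
            model,
            np.stack([pair.analyte.intensities, pair.internal_standard.intensities]),
        )
        concs.append(conc)
        ratios.append(pair_ratio(pair, (masks[0], masks[1])))
    curve = fit_calibration(concs, ratios, drug_id=drug.name)
    measured = []
    for conc in truths:
        shape_i = cfg.shape_dist.draw(rng)
        pair, _t = simulate_window_pair(
            float(conc), design, shape_i, cfg.noise, cfg.mode,
            seed=int(rng.integers(0, 2**63 - 1)),
        )
        masks = predict_masks(
            model,
            np.stack([pair.analyte.intensities, pair.internal_standard.intensities]),
        )
        a = peak_area(pair.analyte.intensities, masks[0]).area
        i = peak_area(pair.internal_standard.intensities, masks[1]).area
        measured.append(back_calculate(a / i, curve).back_calc_conc)
    return np.array(measured)


def stage_report(cfg: RunConfig, out: Path) -> None:
    results = runio.read_results(out / "quant_results.tsv")
    precision = {}
    for drug in cfg.drugs:
        sub = results[results["drug"] == drug.name]
        per_level = {}
        qc_levels = _drug_qc_levels(drug)
        for li, nominal in enumerate(qc_levels):
            # unknowns cycle through QC levels by sample index
            values = sub[sub["sample"] % len(qc_levels) == li]["conc"].to_numpy()
            if values.size >= 2:
                rep = precision_accuracy(values, nominal)
                per_level[str(nominal)] = dataclasses.asdict(rep)
        precision[drug.name] = per_level
    # simulated clinical comparison: two independent chains measure the same truths
    model = _load_model(out)
    drug = cfg.drugs[0]
    rng = np.random.default_rng(cfg.stage_seed("report/truths"))
    truths = np.exp(rng.uniform(np.log(drug.low), np.log(drug.high),
                                size=cfg.n_clinical))
    chain_a = _measure_chain(cfg, model, drug, truths, "chain_a")
    chain_b = _measure_chain(cfg, model, drug, truths, "chain_b")
    agreement = bland_altman(chain_a, chain_b)
    agreement_d = {
        "drug": drug.name,
        "mean_difference": agreement.mean_difference,
        "loa_low": agreement.loa_low,
        "loa_high": agreement.loa_high,
        "pearson_r": agreement.pearson_r,
        "pairs": [
            {"mean": float(m), "difference": float(d)}
            for m, d in zip(agreement.means, agreement.differences)
        ],
    }
    seg = json.loads((out / "segmentation_metrics.json").read_text()) \
        if (out / "segmentation_metrics.json").exists() else None
    curves = json.loads((out / "calibration.json").read_text())
    summary = {
        "seed": cfg.seed,
        "segmentation": seg,
        "calibration": {k: {kk: v[kk] for kk in ("slope", "intercept", "r_squared")}
                        for k, v in curves.items()},
        "precision": precision,
        "agreement": agreement_d,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    lines = [f"msquant run summary (seed {cfg.seed})", ""]
    if seg:
        lines += [
            f"segmentation accuracy:      {seg['accuracy']:.4%}",
            f"segmentation sensitivity:   {seg['sensitivity']:.4%}",
            f"segmentation specificity:   {seg['specificity']:.4%}",
            f"mean area-ratio deviation:  {seg['area_ratio_deviation']:.4%}", "",
        ]
    for name, c in summary["calibration"].items():
        lines.append(f"{name}: slope {c['slope']:.4g}  R^2 {c['r_squared']:.5f}")
    lines.append("")
    for name, levels in precision.items():
        for nominal, rep in levels.items():
            lines.append(
                f"{name} @ {nominal} ng/mL: bias {rep['bias_percent']:+.2f}%  "
                f"RSD {rep['rsd_percent']:.2f}%  (n={rep['n']})"
            )
    lines += [
        "",
        f"clinical comparison ({drug.name}, n={cfg.n_clinical}): "
        f"r = {agreement_d['pearson_r']:.4f}, "
        f"mean diff = {agreement_d['mean_difference']:.3g} ng/mL, "
        f"LoA [{agreement_d['loa_low']:.3g}, {agreement_d['loa_high']:.3g}]",
    ]
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    log.info("report: summary written to %s", out / "summary.txt")


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "train": stage_train,
    "evaluate": stage_evaluate,
    "calibrate": stage_calibrate,
    "quantify": stage_quantify,
    "report": stage_report,
}


def run_pipeline(cfg: RunConfig, out_dir, stage: str = "all") -> Path:
    """Run one stage or the full workflow; returns the output directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = STAGES if stage == "all" else (stage,)
    for name in stages:
        if name not in _STAGE_FUNCS:
            raise StageError(f"unknown stage {name!r}; choose from {STAGES}")
        log.info("stage %s starting", name)
        try:
            _STAGE_FUNCS[name](cfg, out)
        except Exception as exc:
            raise StageError(f"stage {name!r} failed: {exc}") from exc
    return out
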