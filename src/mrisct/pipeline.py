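"""End-to-end experiment orchestration.

Runs the full comparison on a phantom cohort: per case, build synthetic
CTs with the requested methods, recompute dose on CT and sCT with frozen
beam weights, and collect ICRU-point and DVH percentage dose
differences, 3D gamma results at the standard criteria ladder, and HU
error reports, then summarize over the cohort.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import atlas as atlas_mod
from . import cgan as cgan_mod
from .density import DensityCalibration, hu_to_red, override_bowel_gas
from .dose import BeamConfig, calculate_dose, dose_report, percent_dose_difference
from .evaluation import gamma_3d, hu_error_by_region, summarize_cohort
from .gamma import STANDARD_CRITERIA
from .grid import ImageVolume
from .phantom import BONE_CORTICAL, BONE_MARROW, PhantomCase
from .sct_classic import (
    BulkDensityValues,
    TissueClassValues,
    assign_bulk_density,
    assign_tissue_class,
    segment_body,
    segment_fat,
)

log = logging.getLogger("mrisct")

ALL_METHODS = ("bulk", "tissue_class", "atlas", "cgan", "identity")


@dataclass
class ExperimentConfig:
    methods: tuple[str, ...] = ("bulk", "tissue_class")
    beams: BeamConfig = field(default_factory=BeamConfig)
    criteria: tuple = STANDARD_CRITERIA
    calibration: DensityCalibration = field(default_factory=DensityCalibration)
    gas_override: bool = True
    exclusion_mm: float = 30.0
    dvh_structures: tuple[str, ...] = ("ptv", "oar_bladder", "oar_femur")
    atlas_params: atlas_mod.LWVParams = field(default_factory=atlas_mod.LWVParams)
    cgan_config: cgan_mod.CganConfig | None = None  # None -> desk profile
    seed: int = 0

    def hash(self) -> str:
        def default(o):
            if hasattr(o, "__dataclass_fields__"):
                return asdict(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            return str(o)

        payload = json.dumps(asdict(self), default=default, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def ground_truth_masks(case: PhantomCase) -> dict[str, np.ndarray]:
    masks = dict(case.masks)
    labels = np.asarray(case.labels.data)
    masks.setdefault("bone", (labels == BONE_CORTICAL) | (labels == BONE_MARROW))
    return masks


def build_sct(
    case: PhantomCase,
    method: str,
    cfg: ExperimentConfig,
    cohort: list[PhantomCase] | None = None,
    case_index: int | None = None,
    cgan_model=None,
) -> ImageVolume:
    """Synthetic CT for one case by the named method.

    ``atlas`` needs the cohort for leave-one-out fusion; ``cgan`` needs a
    trained (generator, metadata) pair from :func:`train_cgan_folds`.
    """
    masks = ground_truth_masks(case)
    bone = masks["bone"]
    body = segment_body(case.mri.in_phase)
    if method == "identity":
        return case.ct.copy()
    if method == "bulk":
        return assign_bulk_density(
            body, bone & body, BulkDensityValues(), cfg.calibration, like=case.ct
        )
    if method == "tissue_class":
        fat = segment_fat(case.mri, body)
        return assign_tissue_class(
            body, bone & body, fat & ~bone, TissueClassValues(), cfg.calibration, like=case.ct
        )
    if method == "atlas":
        if cohort is None or case_index is None:
            raise ValueError("atlas method needs the cohort and the target index")
        pairs = [
            atlas_mod.AtlasPair(
                mri=other.mri.in_phase,
                ct=other.ct,
                masks=ground_truth_masks(other),
            )
            for j, other in enumerate(cohort)
            if j != case_index
        ]
        sct, _ = atlas_mod.multi_atlas_sct(
            case.mri.in_phase,
            {"body": body, "bone": bone, "bladder": masks["bladder"]},
            atlas_mod.AtlasSet(pairs),
            cfg.atlas_params,
        )
        return sct
    if method == "cgan":
        if cgan_model is None:
            raise ValueError("cgan method needs a trained model")
        gen, meta = cgan_model
        return cgan_mod.predict_sct(gen, case.mri.in_phase, body, meta)
    raise ValueError(f"unknown sCT method {method!r}; expected one of {ALL_METHODS}")


def train_cgan_folds(
    cases: list[PhantomCase], cfg: ExperimentConfig, n_folds: int = 2
) -> dict[int, tuple]:
    """Cross-validated training: case index -> (generator, metadata).

    Cases are split into ``n_folds`` groups; the model predicting a case
    was trained only on the other folds.
    """
    ccfg = cfg.cgan_config or cgan_mod.CganConfig.desk(seed=cfg.seed)
    folds = [list(range(i, len(cases), n_folds)) for i in range(n_folds)]
    models: dict[int, tuple] = {}
    for k, fold in enumerate(folds):
        train_idx = [i for i in range(len(cases)) if i not in fold]
        xs, ys = [], []
        meta = None
        for i in train_idx:
            body = segment_body(cases[i].mri.in_phase)
            x, y, meta, _ = cgan_mod.preprocess_pair(
                cases[i].ct, cases[i].mri.in_phase, body, ccfg
            )
            xs.append(x)
            ys.append(y)
        gen, _, history = cgan_mod.train_cgan(np.concatenate(xs), np.concatenate(ys), ccfg)
        log.info("cgan fold %d: final L1 %.4f", k, history[-1]["g_l1"])
        for i in fold:
            models[i] = (gen, meta)
    return models


def evaluate_case(
    case: PhantomCase, sct: ImageVolume, cfg: ExperimentConfig
) -> dict[str, float]:
    """All per-case metrics of one sCT against the ground-truth CT."""
    masks = ground_truth_masks(case)
    body, bone = masks["body"], masks["bone"]

    ct = case.ct
    sct_eval = sct
    if cfg.gas_override:
        ct, _ = override_bowel_gas(ct, body)
        sct_eval, _ = override_bowel_gas(sct, body)

    red_ct = hu_to_red(ct, cfg.calibration)
    red_sct = hu_to_red(sct_eval, cfg.calibration)
    d_ct, scale = calculate_dose(
        red_ct, body, masks["ptv"], cfg.beams, reference_point=case.reference_point
    )
    d_sct, _ = calculate_dose(
        red_sct, body, masks["ptv"], cfg.beams,
        reference_point=case.reference_point, scale=scale,
    )

    structures = {name: masks[name] for name in cfg.dvh_structures if name in masks}
    rep_ct = dose_report(d_ct, structures, case.reference_point, case.prescription_dose)
    rep_sct = dose_report(d_sct, structures, case.reference_point, case.prescription_dose)

    metrics: dict[str, float] = {}
    metrics["icru_pdd"] = percent_dose_difference(
        rep_sct.icru_point_dose, rep_ct.icru_point_dose
    )
    # skip DVH parameters of essentially unirradiated structures (ratio meaningless)
    min_ref = 0.01 * case.prescription_dose
    dvh_pdds = []
    for name in structures:
        pdd = percent_dose_difference(rep_sct.dvh[name], rep_ct.dvh[name], min_reference=min_ref)
        if np.isfinite(pdd["combined_avg"]):
            dvh_pdds.append(pdd["combined_avg"])
    metrics["dvh_pdd"] = float(np.mean(dvh_pdds))

    for crit in cfg.criteria:
        res = gamma_3d(d_ct, d_sct, body, crit)
        tag = f"{crit.dose_diff_pct:g}_{crit.dta_mm:g}"
        metrics[f"gamma_pass_{tag}"] = res.pass_rate
        metrics[f"gamma_mean_{tag}"] = res.mean_gamma

    for region, rep in hu_error_by_region(
        sct, case.ct, body, bone, cfg.exclusion_mm
    ).items():
        metrics[f"me_{region}"] = rep.me
        metrics[f"mae_{region}"] = rep.mae
    return metrics


def run_experiment(
    cases: list[PhantomCase],
    cfg: ExperimentConfig,
    groups: list[str] | None = None,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort experiment: per-case tidy metrics and the cohort summary.

    Per-case failures are recorded (metric ``failed`` = 1) and the run
    continues.  With ``out_dir`` set, per-case metrics, the summary and
    a manifest (config hash, seeds, timings) are written to disk.
    """
    groups = groups or ["all"] * len(cases)
    cgan_models = (
        train_cgan_folds(cases, cfg) if "cgan" in cfg.methods else {}
    )

    rows = []
    failures = 0
    for i, case in enumerate(cases):
        for method in cfg.methods:
            t0 = time.perf_counter()
            try:
                sct = build_sct(
                    case, method, cfg, cohort=cases, case_index=i,
                    cgan_model=cgan_models.get(i),
                )
                metrics = evaluate_case(case, sct, cfg)
            except Exception:  # noqa: BLE001 - per-case isolation is the contract
                log.exception("case %d method %s failed", i, method)
                failures += 1
                rows.append(
                    dict(case=i, group=groups[i], method=method, metric="failed", value=1.0)
                )
                continue
            log.info(
                "case %d method %s done in %.1fs", i, method, time.perf_counter() - t0
            )
            for name, value in metrics.items():
                rows.append(
                    dict(case=i, group=groups[i], method=method, metric=name, value=value)
                )

    per_case = pd.DataFrame(rows)
    summary = summarize_cohort(per_case, grouping="all")
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        per_case.to_csv(out / "per_case_metrics.csv", index=False)
        summary.to_csv(out / "cohort_summary.csv", index=False)
        manifest = {
            "config_hash": cfg.hash(),
            "seed": cfg.seed,
            "n_cases": len(cases),
            "groups": groups,
            "methods": list(cfg.methods),
            "failures": failures,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    if failures:
        log.warning("%d case/method combinations failed", failures)
    per_case.attrs["failures"] = failures
    return per_case, summary
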