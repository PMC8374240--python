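"""End-to-end study orchestration from one configuration.

``run_study`` wires the stages together: generate -> preprocess -> extract ->
univariate exploration -> stratified 80/20 split -> stability selection ->
model training/evaluation (RF/SVM/LR per ROI x image type, including the
pooled-qMRI combination) -> DeLong model comparison -> model-type selection
-> permutation audit -> external validation of the T1w models -> saliency
maps.  Every random draw derives deterministically from ``global_seed`` via
stage-name hashing, so two runs of the same config are bitwise-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import io as msio
from .core import ROIS
from .explore import screen_summary, univariate_screen
from .features.extract import extract_all, feature_column
from .features.registry import FEATURE_NAMES
from .maps import saliency_map
from .model import (
    MODEL_TYPES,
    ModelConfig,
    RadiomicClassifier,
    delong_compare,
    evaluate_bootstrap,
    external_validate,
    permutation_audit,
    select_model_type,
)
from .preprocess import preprocess_subject
from .select import SelectionConfig, stability_select
from .synthetic import CohortSpec, generate_cohort, validation_spec

log = logging.getLogger(__name__)

QMRI_CHANNELS = ("PD", "MT", "R1", "R2*")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: inserting a stage never shifts others."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


@dataclass
class StudyConfig:
    cohort: CohortSpec = field(default_factory=CohortSpec)
    validation_cohort: CohortSpec | None = field(default_factory=validation_spec)
    split_fraction: float = 0.80
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    output_dir: Path | None = None
    global_seed: int = 0
    n_bins: int = 50
    run_permutation: bool = True

    def __post_init__(self) -> None:
        if not 0.5 < self.split_fraction < 0.95:
            raise ValueError("split_fraction must lie in (0.5, 0.95)")


def split_cohort(subjects, fraction: float = 0.8, seed: int = 0):
    """Stratified (outcome x scanner) train/test split of subject ids.

    Each stratum contributes round(fraction * n) subjects to training,
    clipped so both sides stay nonempty; age (Mann-Whitney) and gender
    (Fisher) balance p-values are logged.
    """
    rng = np.random.default_rng(seed)
    by_stratum: dict[tuple, list] = {}
    for s in subjects:
        by_stratum.setdefault((s.status, s.scanner), []).append(s)
    strata = sorted(by_stratum)
    for stratum in strata:
        if len(by_stratum[stratum]) < 2:
            raise ValueError(f"stratum {stratum} too small to split")

    # largest-remainder allocation: global train count = round(fraction * n),
    # each stratum within +-1 of its exact share, both sides nonempty
    sizes = np.array([len(by_stratum[st]) for st in strata])
    exact = fraction * sizes
    base = np.clip(np.floor(exact).astype(int), 1, sizes - 1)
    target = int(round(fraction * sizes.sum()))
    leftover = target - base.sum()
    order_by_remainder = np.argsort(-(exact - np.floor(exact)), kind="stable")
    for k in order_by_remainder:
        if leftover <= 0:
            break
        if base[k] < sizes[k] - 1:
            base[k] += 1
            leftover -= 1

    train_ids, test_ids = [], []
    for stratum, n_train in zip(strata, base):
        members = sorted(by_stratum[stratum], key=lambda s: s.id)
        order = rng.permutation(len(members))
        for k, pos in enumerate(order):
            (train_ids if k < n_train else test_ids).append(members[pos].id)

    by_id = {s.id: s for s in subjects}
    age = {side: [by_id[i].age for i in ids] for side, ids in
           (("train", train_ids), ("test", test_ids))}
    p_age = float(stats.mannwhitneyu(age["train"], age["test"]).pvalue)
    gender = {
        side: [sum(by_id[i].gender == g for i in ids) for g in ("M", "F")]
        for side, ids in (("train", train_ids), ("test", test_ids))
    }
    p_gender = float(stats.fisher_exact([gender["train"], gender["test"]])[1])
    log.info("split balance: age p=%.3f, gender p=%.3f", p_age, p_gender)
    return sorted(train_ids), sorted(test_ids), {"p_age": p_age, "p_gender": p_gender}


def image_type_columns(image_type: str, roi: str, channels) -> list[str]:
    """Feature columns for one (image type, ROI) combination; ``qMRIcomb``
    pools the features of every available quantitative channel."""
    if image_type == "qMRIcomb":
        members = [c for c in QMRI_CHANNELS if c in channels]
        return [feature_column(c, roi, f) for c in members for f in FEATURE_NAMES]
    return [feature_column(image_type, roi, f) for f in FEATURE_NAMES]


def run_single_combination(
    cohort_spec: CohortSpec,
    channel: str = "MT",
    roi: str = "WM",
    selection: SelectionConfig | None = None,
    model: ModelConfig | None = None,
    split_fraction: float = 0.80,
    seed: int = 0,
) -> dict:
    """Generate -> preprocess -> extract -> split -> select -> fit -> evaluate
    for one (channel, ROI) combination; the minimal full-pipeline closure.

    Returns the selection result, the held-out bootstrap evaluation fragment,
    and the train/test feature tables (for permutation reruns).
    """
    selection = selection or SelectionConfig(seed=stage_seed(seed, "select"))
    model = model or ModelConfig(model_type="LR", seed=stage_seed(seed, "model"))
    spec = replace(cohort_spec, seed=stage_seed(seed, "generate"))
    cohort = [preprocess_subject(s) for s in generate_cohort(spec)]
    table = extract_all(cohort, (channel,), (roi,))
    train_ids, test_ids, _ = split_cohort(cohort, split_fraction, stage_seed(seed, "split"))
    train_table, test_table = table.loc[train_ids], table.loc[test_ids]
    cols = [c for c in table.columns if c.startswith(f"{channel}__{roi}__")]
    sel = stability_select(train_table, cols, selection)
    results = RadiomicClassifier(train_table, sel.final_signature, model).fit()
    fragment = results.evaluate_bootstrap(test_table)
    return {
        "selection": sel,
        "results": results,
        "fragment": fragment,
        "train_table": train_table,
        "test_table": test_table,
        "feature_columns": cols,
    }


def run_study(cfg: StudyConfig) -> dict:
    """Run the complete study; returns the report bundle (and writes it to
    ``cfg.output_dir`` when set)."""
    t_start = time.time()
    timings: dict[str, float] = {}
    out = Path(cfg.output_dir) if cfg.output_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
        for sub in ("explore", "selection", "eval", "tables", "maps"):
            (out / sub).mkdir(exist_ok=True)
        logging.basicConfig(filename=out / "study.log", level=logging.INFO, force=False)

    def tick(stage, t0):
        timings[stage] = round(time.time() - t0, 3)
        log.info("stage %s done in %.1fs", stage, timings[stage])

    # --- generate ---------------------------------------------------------
    t0 = time.time()
    dev_spec = replace(cfg.cohort, seed=stage_seed(cfg.global_seed, "generate-dev"))
    subjects = generate_cohort(dev_spec)
    val_subjects = None
    if cfg.validation_cohort is not None:
        val_spec = replace(
            cfg.validation_cohort, seed=stage_seed(cfg.global_seed, "generate-val")
        )
        val_subjects = generate_cohort(val_spec)
    tick("generate", t0)

    # --- preprocess -------------------------------------------------------
    t0 = time.time()
    subjects = [preprocess_subject(s) for s in subjects]
    if val_subjects is not None:
        val_subjects = [preprocess_subject(s) for s in val_subjects]
    tick("preprocess", t0)

    # --- extract ----------------------------------------------------------
    t0 = time.time()
    channels = list(cfg.cohort.channels)
    table = extract_all(subjects, channels, ROIS, n_bins=cfg.n_bins)
    val_table = None
    if val_subjects is not None:
        val_channels = list(cfg.validation_cohort.channels)
        val_table = extract_all(val_subjects, val_channels, ROIS, n_bins=cfg.n_bins)
        val_table["source"] = np.where(val_table["status"] == 0, "DS2-like", "DS3-like")
    tick("extract", t0)

    # --- explore ----------------------------------------------------------
    t0 = time.time()
    screen = univariate_screen(table)
    summary = screen_summary(screen)
    tick("explore", t0)

    # --- split ------------------------------------------------------------
    train_ids, test_ids, balance = split_cohort(
        subjects, cfg.split_fraction, stage_seed(cfg.global_seed, "split")
    )
    train_table = table.loc[train_ids]
    test_table = table.loc[test_ids]

    # --- select + model every combination --------------------------------
    image_types = channels + (
        ["qMRIcomb"] if sum(c in QMRI_CHANNELS for c in channels) >= 2 else []
    )
    selections: dict[tuple, object] = {}
    fragments: dict[tuple, object] = {}
    frozen_models: dict[tuple, object] = {}
    median_aucs: dict[tuple, float] = {}
    delong: dict[str, dict] = {}

    t0 = time.time()
    for roi in ROIS:
        for image_type in image_types:
            combo = (roi, image_type)
            cols = image_type_columns(image_type, roi, channels)
            sel_cfg = replace(
                cfg.selection,
                seed=stage_seed(cfg.global_seed, f"select-{roi}-{image_type}"),
            )
            sel = stability_select(train_table, cols, sel_cfg)
            selections[combo] = sel

            preds = {}
            for mtype in MODEL_TYPES:
                mcfg = replace(
                    cfg.model,
                    model_type=mtype,
                    seed=stage_seed(cfg.global_seed, f"model-{roi}-{image_type}-{mtype}"),
                )
                res = RadiomicClassifier(train_table, sel.final_signature, mcfg).fit()
                frag = res.evaluate_bootstrap(test_table)
                fragments[(roi, image_type, mtype)] = frag
                frozen_models[(roi, image_type, mtype)] = res.frozen
                median_aucs[(combo, mtype)] = float(frag.median["auc"])
                preds[mtype] = res.frozen.decision_scores(test_table)
            delong[f"{roi}__{image_type}"] = {
                f"{a}|{b}": p
                for (a, b), p in delong_compare(
                    preds, test_table["status"].to_numpy()
                ).items()
            }
    tick("select+model", t0)

    chosen_type = select_model_type(median_aucs, cfg.model.auc_floor)
    log.info("selected model type: %s", chosen_type)

    # --- permutation audit (chosen type, every combination) --------------
    t0 = time.time()
    permutation: dict[str, dict] = {}
    audit_combos = [(r, i) for r in ROIS for i in image_types] if cfg.run_permutation else []
    for roi, image_type in audit_combos:
        cols = image_type_columns(image_type, roi, channels)

        def pipeline(tr, te, _cols=cols, _roi=roi, _img=image_type):
            scfg = replace(
                cfg.selection,
                seed=stage_seed(cfg.global_seed, f"permsel-{_roi}-{_img}"),
            )
            sel = stability_select(tr, _cols, scfg)
            mcfg = replace(
                cfg.model,
                model_type=chosen_type,
                seed=stage_seed(cfg.global_seed, f"permmodel-{_roi}-{_img}"),
            )
            frozen = RadiomicClassifier(tr, sel.final_signature, mcfg).fit().frozen
            return evaluate_bootstrap(frozen, te, mcfg)

        audit = permutation_audit(
            pipeline, train_table, test_table,
            seed=stage_seed(cfg.global_seed, f"permute-{roi}-{image_type}"),
            original=fragments[(roi, image_type, chosen_type)],
        )
        permutation[f"{roi}__{image_type}"] = {
            "original_median_auc": audit["original_median_auc"],
            "permuted_median_auc": audit["permuted_median_auc"],
            "drop_p": audit["drop_p"],
            "significant": audit["significant"],
        }
    tick("permute", t0)

    # --- external validation of T1w models -------------------------------
    t0 = time.time()
    validation: dict[str, dict] = {}
    if val_table is not None and "T1w" in channels:
        for roi in ROIS:
            frozen = frozen_models[(roi, "T1w", chosen_type)]
            vcfg = replace(
                cfg.model,
                model_type=chosen_type,
                seed=stage_seed(cfg.global_seed, f"validate-{roi}"),
            )
            res = external_validate(frozen, val_table, vcfg)
            validation[roi] = {
                "metrics": res["fragment"].to_dict(),
                "per_source_accuracy": res.get("per_source_accuracy", {}),
            }
    tick("validate", t0)

    # --- saliency maps (top feature of the chosen model per ROI) ----------
    t0 = time.time()
    maps_written = []
    map_subject = subjects[-1]  # an MSP subject
    for roi in ROIS:
        best_img = max(image_types, key=lambda it: median_aucs[((roi, it), chosen_type)])
        top_feature = selections[(roi, best_img)].final_signature[0]
        channel, _, feature = top_feature.split("__")
        smap = saliency_map(
            map_subject.volumes[channel], map_subject.masks.roi(roi), feature,
            n_bins=cfg.n_bins,
        )
        maps_written.append((roi, top_feature))
        if out:
            msio.save_map(
                smap.data,
                map_subject.volumes[channel].voxel_size_mm,
                out / "maps" / f"{roi}__{top_feature}.nii.gz",
            )
    tick("saliency", t0)

    # --- reports ----------------------------------------------------------
    table5 = _metric_table(fragments, chosen_type, ROIS, image_types)
    report = {
        "chosen_model_type": chosen_type,
        "train_ids": train_ids,
        "test_ids": test_ids,
        "balance": balance,
        "median_aucs": {f"{c[0]}__{c[1]}|{t}": v for (c, t), v in median_aucs.items()},
        "delong": delong,
        "permutation": permutation,
        "validation": validation,
        "saliency_maps": [f"{r}:{f}" for r, f in maps_written],
        "timings_s": timings,
        "n_feature_columns": len(
            [c for c in table.columns if c.count("__") == 2 and not c.startswith("roi_volume")]
        ),
    }

    if out:
        table.to_csv(out / "features.csv")
        if val_table is not None:
            val_table.to_csv(out / "validation_features.csv")
        screen.to_csv(out / "explore" / "univariate.csv")
        summary.to_csv(out / "explore" / "summary.csv")
        for (roi, image_type), sel in selections.items():
            with open(out / "selection" / f"{roi}__{image_type}.json", "w") as fh:
                json.dump(sel.to_dict(), fh, indent=1, sort_keys=True)
        for (roi, image_type, mtype), frag in fragments.items():
            with open(out / "eval" / f"{roi}__{image_type}__{mtype}.json", "w") as fh:
                json.dump(frag.to_dict(), fh, indent=1, sort_keys=True)
        with open(out / "eval" / "delong.json", "w") as fh:
            json.dump(delong, fh, indent=1, sort_keys=True)
        with open(out / "eval" / "permutation.json", "w") as fh:
            json.dump(permutation, fh, indent=1, sort_keys=True)
        table5.to_csv(out / "tables" / "table_test_metrics.csv")
        if validation:
            _validation_table(validation).to_csv(out / "tables" / "table_validation_metrics.csv")
        manifest = _manifest(cfg, report, out)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        report["manifest"] = manifest

    report["fragments"] = fragments
    report["selections"] = selections
    report["frozen_models"] = frozen_models
    report["feature_table"] = table
    report["validation_table"] = val_table
    log.info("study complete in %.1fs", time.time() - t_start)
    return report


def _metric_table(fragments, model_type, rois, image_types) -> pd.DataFrame:
    rows = []
    for roi in rois:
        for image_type in image_types:
            frag = fragments[(roi, image_type, model_type)]
            s = frag.summary()
            row = {"roi": roi, "image": image_type}
            for m in s.index:
                row[m] = (
                    f"{s.loc[m, 'median']:.2f} "
                    f"({s.loc[m, 'ci_low']:.2f}, {s.loc[m, 'ci_high']:.2f})"
                )
            rows.append(row)
    return pd.DataFrame(rows).set_index(["roi", "image"])


def _validation_table(validation: dict) -> pd.DataFrame:
    rows = []
    for roi, rep in validation.items():
        row = {"roi": roi}
        for m, v in rep["metrics"].items():
            row[m] = f"{v['median']:.2f} ({v['ci'][0]:.2f}, {v['ci'][1]:.2f})"
        rows.append(row)
    return pd.DataFrame(rows).set_index("roi")


def _manifest(cfg: StudyConfig, report: dict, out: Path) -> dict:
    hashes = {}
    for path in sorted(out.rglob("*")):
        if path.suffix in (".csv", ".json") and path.name != "manifest.json":
            hashes[str(path.relative_to(out))] = hashlib.sha256(
                path.read_bytes()
            ).hexdigest()
    return {
        "global_seed": cfg.global_seed,
        "chosen_model_type": report["chosen_model_type"],
        "n_feature_columns": report["n_feature_columns"],
        "file_hashes": hashes,
    }
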