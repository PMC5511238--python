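"""Stage orchestration: the end-to-end radiomics pipeline.

Stages run in order: ``simulate`` -> ``train-seg`` -> ``segment`` ->
``extract`` -> ``encode`` -> ``classify`` (plus ``evaluate`` to re-score
stored predictions).  Each stage reads its prerequisites from the working
directory, writes its artifacts back, and logs one line with stage name,
config hash, seed and wall time.  The in-memory helpers used by the
stages are exported too, so the whole chain can be driven from Python
without touching disk.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from .config import PipelineConfig
from .features import FilterResponseSet, extract_filter_responses, multiscale_rois
from .fisher import GmmModel, encode_case, fit_gmm
from .network import ConvNet, NetworkSpec, SgdConfig, build_network, train_network
from .phantom import LabeledVolume, PhantomConfig, generate_cohort
from .preprocessing import sample_patches
from .segmentation import segment_volume, segmentation_metrics
from .selection import loocv_predict, time_split_predict

logger = logging.getLogger("dlradiomics")

__all__ = [
    "PipelineError",
    "run_stage",
    "STAGES",
    "network_spec_from_config",
    "phantom_config_from_config",
    "extract_cohort_responses",
    "fit_encoder",
    "encode_cohort",
]


class PipelineError(RuntimeError):
    pass


STAGES = ("simulate", "train-seg", "segment", "extract", "encode", "classify", "evaluate")

#: artifact each stage produces, and the stage that must have run before it
_PREREQ = {
    "train-seg": ("cohort/manifest.csv", "simulate"),
    "segment": ("network.npz", "train-seg"),
    "extract": ("network.npz", "train-seg"),
    "encode": ("responses", "extract"),
    "classify": ("features.csv", "encode"),
    "evaluate": ("predictions.csv", "classify"),
}


def network_spec_from_config(config: PipelineConfig) -> NetworkSpec:
    return NetworkSpec(
        n_conv_layers=config.n_conv_layers,
        conv_filters=config.resolved_conv_filters(),
        fc_neurons=config.fc_neurons,
        dropout_rate=config.dropout_rate,
        n_input_channels=config.n_channels,
        patch_size=config.patch_size,
    )


def phantom_config_from_config(config: PipelineConfig) -> PhantomConfig:
    return PhantomConfig(
        volume_shape=config.volume_shape,
        n_channels=config.n_channels,
        tumor_radius_range=config.tumor_radius_range,
        tumor_contrast=config.tumor_contrast,
        texture_corr_length=config.texture_corr_length,
        texture_sd=config.texture_sd,
        noise_sd=config.noise_sd,
        background_level=config.background_level,
        seed=config.seed,
    )


# ---------------------------------------------------------------------------
# in-memory pipeline helpers


def extract_cohort_responses(
    net: ConvNet,
    cohort: list[LabeledVolume],
    config: PipelineConfig,
    masks: dict[str, np.ndarray] | None = None,
) -> list[FilterResponseSet]:
    """Multi-scale ROI pooling of last-conv responses for every case.

    ``masks`` overrides the ground-truth masks with predicted ones
    (fully automatic mode).
    """
    out = []
    for vol in cohort:
        mask = None if masks is None else masks[vol.case_id]
        rois = multiscale_rois(
            vol, mask=mask, n_scales=config.n_scales, scale_range=config.scale_range
        )
        out.append(extract_filter_responses(net, rois))
    return out


def fit_encoder(
    responses: list[FilterResponseSet],
    config: PipelineConfig,
    seed: int,
    max_pool: int = 200_000,
) -> GmmModel:
    """Fit the shared GMM on responses pooled over filters from the
    encoder-fit subset (first ``encoder_fit_cases`` cases by default).

    The pooled sample is subsampled to at most ``max_pool`` values with a
    seeded generator to bound EM cost.
    """
    subset = responses[: min(config.encoder_fit_cases, len(responses))]
    pool = np.concatenate([r.responses.ravel() for r in subset])
    if pool.size > max_pool:
        rng = np.random.default_rng(seed)
        pool = rng.choice(pool, size=max_pool, replace=False)
    return fit_gmm(pool, K=config.gmm_components, seed=seed)


def encode_cohort(
    responses: list[FilterResponseSet], gmm: GmmModel
) -> tuple[np.ndarray, list[str]]:
    """Stack per-case Fisher descriptors into a cases x (2KF) matrix."""
    rows, ids = [], []
    for r in responses:
        rows.append(encode_case(r, gmm).values)
        ids.append(r.case_id)
    return np.stack(rows), ids


# ---------------------------------------------------------------------------
# disk stages


def _require(workdir: Path, stage: str) -> None:
    if stage in _PREREQ:
        artifact, producer = _PREREQ[stage]
        if not (workdir / artifact).exists():
            raise PipelineError(
                f"stage '{stage}' is missing prerequisite '{artifact}': "
                f"run stage {producer} first"
            )


def run_stage(stage: str, config: PipelineConfig, workdir, seed: int | None = None):
    """Run one named stage in ``workdir``; returns the stage's main artifact path."""
    if stage not in STAGES:
        raise PipelineError(f"unknown stage '{stage}'; choose from {STAGES}")
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else seed
    _require(workdir, stage)
    t0 = time.perf_counter()
    result = _STAGE_FNS[stage](config, workdir, seed)
    logger.info(
        "stage=%s config=%s seed=%d wall=%.2fs",
        stage,
        config.digest(),
        seed,
        time.perf_counter() - t0,
    )
    return result


def _stage_simulate(config, workdir, seed):
    cohort = generate_cohort(config.n_per_class, phantom_config_from_config(config), seed=seed)
    return dio.write_cohort(cohort, workdir / "cohort")


def _stage_train_seg(config, workdir, seed):
    cohort = dio.load_cohort(workdir / "cohort" / "manifest.csv")
    patches = sample_patches(
        cohort,
        n_total=config.n_patches,
        tumor_fraction=config.tumor_patch_fraction,
        patch_size=config.patch_size,
        seed=seed,
    )
    net = build_network(network_spec_from_config(config), seed=seed)
    sgd = SgdConfig(
        learning_rate=config.learning_rate,
        momentum=config.momentum,
        batch_size=config.batch_size,
        n_epochs=config.n_epochs,
    )
    train_network(net, patches, sgd, seed=seed)
    path = workdir / "network.npz"
    net.save(path)
    pd.DataFrame(net.training_log).to_csv(workdir / "training_log.csv", index=False)
    return path


def _stage_segment(config, workdir, seed):
    net = ConvNet.load(workdir / "network.npz")
    cohort = dio.load_cohort(workdir / "cohort" / "manifest.csv")
    seg_dir = workdir / "segmentation"
    seg_dir.mkdir(exist_ok=True)
    rows = []
    for vol in cohort:
        res = segment_volume(net, vol, threshold=config.mask_threshold)
        dio.write_volume(res.probability_map, seg_dir / f"{vol.case_id}_prob.nii.gz")
        dio.write_volume(res.mask.astype(np.float64), seg_dir / f"{vol.case_id}_mask.nii.gz")
        dsc, ppv, sens = segmentation_metrics(res.mask, vol.mask)
        rows.append({"case_id": vol.case_id, "DSC": dsc, "PPV": ppv, "SENS": sens})
    out = seg_dir / "seg_metrics.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    return out


def _stage_extract(config, workdir, seed):
    net = ConvNet.load(workdir / "network.npz")
    cohort = dio.load_cohort(workdir / "cohort" / "manifest.csv")
    masks = None
    if config.roi_mask == "predicted":
        seg_dir = workdir / "segmentation"
        if not seg_dir.exists():
            raise PipelineError(
                "roi_mask='predicted' needs predicted masks: run stage segment first"
            )
        masks = {
            v.case_id: (dio.read_volume(seg_dir / f"{v.case_id}_mask.nii.gz") != 0)
            for v in cohort
        }
    responses = extract_cohort_responses(net, cohort, config, masks=masks)
    resp_dir = workdir / "responses"
    resp_dir.mkdir(exist_ok=True)
    for r in responses:
        dio.save_responses(r, resp_dir / r.case_id)
    return resp_dir


def _stage_encode(config, workdir, seed):
    manifest = pd.read_csv(workdir / "cohort" / "manifest.csv")
    responses = [
        dio.load_responses(workdir / "responses" / cid) for cid in manifest["case_id"]
    ]
    gmm = fit_encoder(responses, config, seed)
    (workdir / "gmm.json").write_text(gmm.to_json())
    values, ids = encode_cohort(responses, gmm)
    out = workdir / "features.csv"
    dio.save_feature_matrix(values, ids, out)
    return out


def _stage_classify(config, workdir, seed):
    manifest = pd.read_csv(workdir / "cohort" / "manifest.csv")
    values, ids = dio.load_feature_matrix(workdir / "features.csv")
    labels = manifest.set_index("case_id").loc[ids, "label"].to_numpy()
    if config.classify_mode == "loocv":
        report = loocv_predict(
            values,
            labels,
            alpha=config.ttest_alpha,
            m=config.m_features,
            svm_c=config.svm_c,
            case_ids=ids,
        )
    else:
        times = manifest.set_index("case_id").loc[ids, "diagnosis_time"].to_numpy()
        cutoff = config.time_cutoff
        if cutoff is None:
            cutoff = float(np.median(times))
        report = time_split_predict(
            values,
            labels,
            times,
            cutoff,
            alpha=config.ttest_alpha,
            m=config.m_features,
            svm_c=config.svm_c,
            case_ids=ids,
        )
    pd.DataFrame(
        {
            "case_id": report.case_ids,
            "label": report.labels,
            "score": report.scores,
            "predicted": report.predicted,
        }
    ).to_csv(workdir / "predictions.csv", index=False)
    pd.DataFrame([report.metrics()]).to_csv(workdir / "metrics.csv", index=False)
    pd.DataFrame(report.roc_points, columns=["FPR", "TPR"]).to_csv(
        workdir / "roc.csv", index=False
    )
    return workdir / "metrics.csv"


def _stage_evaluate(config, workdir, seed):
    from .selection import confusion_metrics, roc_auc

    preds = pd.read_csv(workdir / "predictions.csv")
    auc, _ = roc_auc(preds["score"].to_numpy(), preds["label"].to_numpy())
    acc, sens, spec, ppv, npv, mcc = confusion_metrics(
        preds["predicted"].to_numpy(), preds["label"].to_numpy()
    )
    out = workdir / "metrics.csv"
    pd.DataFrame(
        [{"AUC": auc, "ACC": acc, "SENS": sens, "SPEC": spec, "PPV": ppv, "NPV": npv, "MCC": mcc}]
    ).to_csv(out, index=False)
    return out


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "train-seg": _stage_train_seg,
    "segment": _stage_segment,
    "extract": _stage_extract,
    "encode": _stage_encode,
    "classify": _stage_classify,
    "evaluate": _stage_evaluate,
}
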