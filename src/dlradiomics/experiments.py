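"""Self-contained phantom experiments exercising the whole pipeline.

These are the package's benchmark runs: each builds its own phantom
cohort, trains (or builds) a network, runs the stages in memory and
returns the resulting numbers.  Problem sizes are reduced relative to
the reference operating point (small cohorts, a 2-conv network) so a
full run stays in the minutes range on one CPU; the methods note
discusses what that does and does not demonstrate.
"""

from __future__ import annotations

import warnings

import numpy as np

from .config import PipelineConfig
from .fisher import encode_case
from .network import NetworkSpec, SgdConfig, build_network, train_network
from .phantom import PhantomConfig, generate_cohort, generate_phantom
from .pipeline import encode_cohort, extract_cohort_responses, fit_encoder
from .preprocessing import sample_patches
from .segmentation import segment_volume, segmentation_metrics
from .selection import PredictionReport, loocv_predict

__all__ = [
    "reduced_spec",
    "segmentation_experiment",
    "phenotype_experiment",
    "null_phenotype_auc",
    "descriptor_dimensionality",
    "depth_ablation",
]


def reduced_spec(n_channels: int = 2, conv_filters=(8, 16), fc_neurons: int = 64) -> NetworkSpec:
    """Two-conv reduced architecture used by the scaled-down experiments."""
    return NetworkSpec(
        n_conv_layers=len(conv_filters),
        conv_filters=tuple(conv_filters),
        fc_neurons=fc_neurons,
        n_input_channels=n_channels,
    )


def segmentation_experiment(
    seed: int = 0,
    n_train: int = 8,
    n_patches: int = 5000,
    n_epochs: int = 10,
) -> dict:
    """Train the reduced network on high-contrast phantoms; score a held-out one.

    Returns the held-out DSC/PPV/sensitivity after post-processing, plus
    the final training accuracy.
    """
    config = PhantomConfig()
    cohort = generate_cohort((n_train + 2) // 2, config, seed=seed)
    train, held_out = cohort[:n_train], cohort[n_train]
    patches = sample_patches(train, n_patches, tumor_fraction=0.4, seed=seed)
    net = build_network(reduced_spec(config.n_channels), seed=seed)
    train_network(net, patches, SgdConfig(n_epochs=n_epochs), seed=seed)
    result = segment_volume(net, held_out)
    dsc, ppv, sens = segmentation_metrics(result.mask, held_out.mask)
    return {
        "dsc": dsc,
        "ppv": ppv,
        "sens": sens,
        "train_accuracy": net.training_log[-1]["accuracy"],
        "n_train": n_train,
    }


def phenotype_experiment(
    seed: int = 0,
    texture_corr_length: tuple[float, float] = (3.0, 1.0),
    n_per_class: int = 20,
    gmm_components: int = 8,
    m_features: int = 50,
    n_patches: int = 2000,
    n_epochs: int = 5,
) -> PredictionReport:
    """Full pipeline under LOOCV on a phantom cohort with ground-truth masks.

    With the default (well separated) correlation lengths the texture
    contrast should be recovered far above chance; with identical
    lengths (``(c, c)``) the features carry no phenotype signal and the
    AUC should wander around 0.5.
    """
    config = PhantomConfig(texture_corr_length=texture_corr_length)
    cohort = generate_cohort(n_per_class, config, seed=seed)
    labels = np.array([v.label for v in cohort])

    patches = sample_patches(cohort[:8], n_patches, tumor_fraction=0.4, seed=seed)
    net = build_network(reduced_spec(config.n_channels), seed=seed)
    train_network(net, patches, SgdConfig(n_epochs=n_epochs), seed=seed)

    pcfg = PipelineConfig(gmm_components=gmm_components, n_channels=config.n_channels)
    responses = extract_cohort_responses(net, cohort, pcfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gmm = fit_encoder(responses, pcfg, seed=seed, max_pool=100_000)
        features, _ = encode_cohort(responses, gmm)
        report = loocv_predict(
            features, labels, alpha=pcfg.ttest_alpha, m=m_features, svm_c=pcfg.svm_c
        )
    return report


def null_phenotype_auc(
    seed: int = 0,
    corr_length: float = 2.0,
    n_repeats: int = 3,
    **kwargs,
) -> dict:
    """Mean LOOCV AUC over independent null cohorts (identical texture classes).

    A single leave-one-out AUC under in-fold feature selection at n = 40 is
    very noisy (its null distribution has a standard deviation near 0.2 and
    a mild pessimistic bias, the familiar LOOCV anti-learning effect), so
    the chance-level check averages ``n_repeats`` cohorts generated from
    consecutive seeds.  Returns the mean and the per-cohort AUCs.
    """
    aucs = [
        phenotype_experiment(
            seed=seed + r, texture_corr_length=(corr_length, corr_length), **kwargs
        ).auc
        for r in range(n_repeats)
    ]
    return {"mean_auc": float(np.mean(aucs)), "aucs": aucs}


def descriptor_dimensionality(seed: int = 0) -> int:
    """Length of one case's descriptor at the reference defaults F=128, K=64.

    Uses an untrained two-conv network whose last layer has the full 128
    deep filters; only the dimensionality is meaningful here.
    """
    config = PhantomConfig()
    volume = generate_phantom(config, label=1, seed=seed)
    net = build_network(
        reduced_spec(config.n_channels, conv_filters=(8, 128)), seed=seed
    )
    pcfg = PipelineConfig(gmm_components=64, n_channels=config.n_channels)
    responses = extract_cohort_responses(net, [volume], pcfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gmm = fit_encoder(responses, pcfg, seed=seed, max_pool=20_000)
        descriptor = encode_case(responses[0], gmm)
    return len(descriptor)


def depth_ablation(
    n_conv_grid=(1, 2),
    fc_grid=(16, 64),
    seed: int = 0,
    n_patches: int = 500,
    n_epochs: int = 2,
):
    """Segmentation metrics over a {depth x fc width} grid (ablation axis).

    Returns a pandas DataFrame with one row per configuration; values are
    data-dependent and deliberately not asserted anywhere.
    """
    import pandas as pd

    config = PhantomConfig()
    cohort = generate_cohort(3, config, seed=seed)
    train, held_out = cohort[:4], cohort[4]
    patches = sample_patches(train, n_patches, tumor_fraction=0.4, seed=seed)
    rows = []
    for n_conv in n_conv_grid:
        for fc in fc_grid:
            spec = NetworkSpec(
                n_conv_layers=n_conv,
                conv_filters=(8,) * (n_conv - 1) + (16,),
                fc_neurons=fc,
                n_input_channels=config.n_channels,
            )
            net = build_network(spec, seed=seed)
            train_network(net, patches, SgdConfig(n_epochs=n_epochs), seed=seed)
            dsc, ppv, sens = segmentation_metrics(
                segment_volume(net, held_out).mask, held_out.mask
            )
            rows.append(
                {"n_conv_layers": n_conv, "fc_neurons": fc, "DSC": dsc, "PPV": ppv, "SENS": sens}
            )
    return pd.DataFrame(rows)
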