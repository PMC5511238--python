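"""Train the patch classifier on phantoms and segment a held-out case.

A reduced architecture (2 conv layers, 64 fc neurons) is trained on
33x33 patches sampled with the unbalanced ~40% tumor-center scheme, then
applied fully convolutionally to a held-out phantom.  Prints per-epoch
training accuracy and the held-out overlap metrics.
"""

from dlradiomics import (
    NetworkSpec,
    PhantomConfig,
    SgdConfig,
    build_network,
    generate_cohort,
    sample_patches,
    segment_volume,
    segmentation_metrics,
    train_network,
)

cohort = generate_cohort(5, PhantomConfig(), seed=11)
train, held_out = cohort[:8], cohort[8]

patches = sample_patches(train, n_total=2000, tumor_fraction=0.4, seed=2)
print(f"sampled {len(patches)} patches, tumor fraction "
      f"{patches.labels.mean():.2f}")

spec = NetworkSpec(n_conv_layers=2, conv_filters=(8, 16), fc_neurons=64,
                   n_input_channels=2)
net = build_network(spec, seed=0)
train_network(net, patches, SgdConfig(n_epochs=5), seed=0)
for row in net.training_log:
    print(f"epoch {row['epoch']}: loss {row['loss']:.3f} "
          f"accuracy {row['accuracy']:.3f}")

result = segment_volume(net, held_out)
dsc, ppv, sens = segmentation_metrics(result.mask, held_out.mask)
print(f"held-out case {held_out.case_id}: DSC {dsc:.3f}, PPV {ppv:.3f}, "
      f"sensitivity {sens:.3f}")
print("DSC is the voxel overlap with the ground-truth tumor mask (1 = perfect).")
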