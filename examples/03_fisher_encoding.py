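"""Encode a case's deep filter responses into a Fisher vector.

Responses of every last-conv filter are pooled over all tumor slices at
10 scales (ratios 0.5-2), a shared Gaussian mixture is fitted on the
pooled values, and each case becomes a fixed-length descriptor holding
the first- and second-order Fisher statistics of every (filter,
component) pair — 2*K*F dimensions.
"""

import numpy as np

from dlradiomics import (
    NetworkSpec,
    PhantomConfig,
    build_network,
    descriptor_unindex,
    encode_case,
    extract_filter_responses,
    fit_gmm,
    generate_phantom,
    multiscale_rois,
)

volume = generate_phantom(PhantomConfig(), label=1, seed=3)
net = build_network(
    NetworkSpec(n_conv_layers=2, conv_filters=(8, 16), fc_neurons=64,
                n_input_channels=2),
    seed=0,
)

rois = multiscale_rois(volume, n_scales=10, scale_range=(0.5, 2.0))
responses = extract_filter_responses(net, rois)
print(f"{len(rois)} scaled ROIs -> responses {responses.responses.shape} "
      f"(filters x pooled positions)")

K = 8
gmm = fit_gmm(responses.responses.ravel(), K=K, seed=0)
print(f"GMM: {K} components, means in [{gmm.means.min():.3f}, {gmm.means.max():.3f}]")

descriptor = encode_case(responses, gmm)
print(f"descriptor length {len(descriptor)} = 2 x {K} x {responses.n_filters}; "
      f"L2 norm {np.linalg.norm(descriptor.values):.3f}")
top = int(np.argmax(np.abs(descriptor.values)))
f, k, order = descriptor_unindex(top, K=K, F=responses.n_filters)
kind = "first" if order == 0 else "second"
print(f"strongest entry: filter {f}, component {k}, {kind}-order statistic —")
print("each entry measures how the case's responses pull on one Gaussian.")
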