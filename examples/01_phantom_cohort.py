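"""Generate a phantom cohort and inspect the class texture contrast.

Each phantom carries an ellipsoidal tumor; the two phenotype classes
differ only in the spatial correlation length of the intratumoral
texture.  The high-frequency energy statistic printed below is the
contrast every downstream stage must detect.
"""

import numpy as np

from dlradiomics import PhantomConfig, generate_cohort
from dlradiomics.phantom import highfreq_energy

config = PhantomConfig()
cohort = generate_cohort(n_per_class=5, config=config, seed=0)

print(f"cohort: {len(cohort)} cases, shape {config.volume_shape}, "
      f"{config.n_channels} channels")
for label in (0, 1):
    energies = [highfreq_energy(v) for v in cohort if v.label == label]
    corr = config.texture_corr_length[label]
    print(f"class {label} (corr length {corr}): "
          f"in-mask high-freq energy {np.mean(energies):.3f} ± {np.std(energies):.3f}")
print("The short-correlation class (1) shows higher high-frequency energy —")
print("that texture difference is the phenotype signal.")
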