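"""Simulate a dehydration campaign and write it to CSV.

Generates the default 229-sample labeled set: vegetation-shaped 176-band
spectra whose NIR plateau rises as leaves dry, with a right-skewed leaf
water potential distribution (most samples mildly stressed). Runs in
seconds.
"""

import numpy as np

from leafwp import SimulationConfig, generate_dataset, write_spectra_csv

cfg = SimulationConfig(seed=0)
dataset = generate_dataset(cfg)

psi = dataset.psi
print(f"samples: {dataset.n_samples}, bands: {dataset.grid.n_bands}")
print(f"Psi range: [{psi.min():.2f}, {psi.max():.2f}] MPa, mean {psi.mean():.2f} MPa")
print(f"mildly stressed (> -1 MPa): {np.mean(psi > -1):.0%}; "
      f"severely stressed (< -2 MPa): {np.mean(psi < -2):.0%}")

nir = dataset.grid.values >= 900
r = np.corrcoef(-psi, dataset.spectra[:, nir].mean(axis=1))[0, 1]
print(f"correlation of stress (-Psi) with mean NIR reflectance: {r:.2f}")
# the positive correlation is the physical signal the regressor exploits:
# drier leaves reflect more in the near infrared

write_spectra_csv(dataset, "campaign.csv")
print("wrote campaign.csv (columns: sample_id, psi_mpa, r393.7 ... r1001.4)")
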