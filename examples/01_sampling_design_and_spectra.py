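"""Build the greenhouse sampling design and draw a synthetic spectra dataset.

The design is 5 CBD hemp cultivars x 5 sampling dates (growth stages, 2-10
weeks after flower initiation) x 4 replicate plants, with 16 leaves and 16-24
flowers sampled per cultivar and date.  The generator draws one relative
reflectance spectrum per sampled organ around its class mean curve.
"""

import numpy as np

from hempspec import default_wavelengths, generate_spectra_dataset, study_sampling_design

design = study_sampling_design()
print(f"plants per cultivar : {design.plants_per_cultivar}")   # 5 dates x 4 reps = 20
print(f"total plants        : {design.total_plants}")           # 5 cultivars x 20 = 100
print(f"total organ samples : {design.total_samples}")
print(f"CW flowers at first date: {design.cell_count('CW', 'wk02', 'flower')}")  # 24

wavelengths = default_wavelengths(462)  # 400-1000 nm, ~1.3 nm steps
table, labels = generate_spectra_dataset(design, seed=0, wavelengths=wavelengths)
print(f"\nspectra table: {table.values.shape[0]} samples x {table.values.shape[1]} wavelengths")
print(table.metadata.groupby(['organ']).size().rename('samples').to_string())

# Vegetation shape sanity: low visible reflectance, chlorophyll dip near
# 670 nm, NIR plateau beyond the red edge.
leaf = table.values[(table.metadata['organ'] == 'leaf').to_numpy()].mean(axis=0)
for nm in (550, 670, 900):
    print(f"mean leaf reflectance @ {nm} nm: {leaf[np.argmin(np.abs(wavelengths - nm))]:.3f}")
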