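"""Generate a synthetic trichome Raman dataset.

Five cannabis classes (four Sativa varieties + one Indica), three trichome
heads per class, twenty spectra per trichome: 300 spectra on a
200-1800 cm^-1 grid, with cannabinoid bands, a random fluorescence
baseline, wavenumber jitter and planted class effects (x1.5 amplitude at
each class's discriminating bands).
"""

import trichospec as ts

design = ts.default_design(seed=1)
dataset = ts.generate_dataset(design)

print(f"spectra:    {dataset.n_spectra} ({design.trichomes_per_class} trichomes "
      f"x {design.points_per_trichome} points per class)")
print(f"grid:       {dataset.grid[0]:.0f}-{dataset.grid[-1]:.0f} cm^-1, "
      f"{dataset.grid.size} points")
print("per class:  ", dict(dataset.labels.groupby("class").size()))

lib = ts.make_band_library()
strongest = max(lib, key=lambda b: b.amplitude)
print(f"strongest band: {strongest.center:.0f} cm^-1 ({strongest.assignment})")

ts.write_matrix_csv(dataset, "scratch_dataset.csv")
print("wrote scratch_dataset.csv (one row per spectrum, header = metadata + grid)")
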