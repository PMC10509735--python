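"""Generate a small synthetic z-stack cohort and summarize its labels.

Each specimen is a bag of 256-like (here 32 px) H&E tiles imaged at several
focal planes; positive specimens carry larger, more irregular nuclei.
"""

from stackmil import SynthConfig, generate_cohort, summarize_labels

config = SynthConfig(tile_size=32, n_slices=5, nuclei_density=10.0,
                     nucleus_radius_px=3.0, morphology_effect=2.5,
                     tiles_per_specimen_range=(3, 6), seed=0)
bags, table = generate_cohort(config, n_specimens=12, positive_fraction=0.5,
                              seed=0)

print(f"{len(bags)} specimens, {sum(b.n_tiles for b in bags)} tiles, "
      f"stack shape {bags[0].tiles[0].pixels.shape}")
for marker, s in summarize_labels(table).items():
    print(f"  {marker}: {s['n_positive']}/{s['n_total']} "
          f"({s['percent_positive']}%) positive")
# The tile arrays are (height, width, RGB, focal plane); the label table has
# one row per specimen with binary status for each of the five markers.
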