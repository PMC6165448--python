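#!/usr/bin/env python
"""Generate the synthetic five-class ham study.

Writes a full bundle (surface images, colorimeter table, band-amplitude
table, manifest) under results/bundle/.  Five classes x 30 replicates,
sampled every 3 days for three weeks; one image per replicate.
"""

from pathlib import Path

from hamqa import synthetic

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    design = synthetic.SimulationDesign(n_per_class=30, seed=20180915)
    bundle = synthetic.gen_study(design)
    out = synthetic.write_bundle(bundle, OUT / "bundle")
    n_img = len(bundle.images)
    n_rows = len(bundle.colors)
    print(f"bundle written to {out}")
    print(f"  {n_img} surface images ({design.image_size[0]}x{design.image_size[1]})")
    print(f"  {n_rows} colorimeter readings across days {list(design.days)}")
    print(f"  band amplitudes for {bundle.band_amplitudes.shape[1] - 3} bands")


if __name__ == "__main__":
    main()
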