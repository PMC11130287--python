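#!/usr/bin/env python
"""Generate every synthetic input for both membrane contexts.

Bilayer fixtures encode the deep-V hairpin state (kink 2 nm below the
phosphate plane, ~80 deg tilt, 20 A arm-tip distance, embedded core
W94-R122 at ~5% relative PEGylation); monolayer fixtures encode the
open-shallow state (kink at the surface, ~30 deg tilt, 36 A tips, core
partially exposed with 3.6-residue helical periodicity). Outputs land in
results/fixtures/ with a ground-truth sidecar per dataset.
"""

from pathlib import Path

from ldhairpin import pipeline

OUT = Path("results/fixtures")


def main() -> None:
    cfg = pipeline.RunConfig(seed=1, outdir=str(OUT), stages=("simulate",),
                             noise_sd_fraction=0.0)
    _, manifest = pipeline.run_pipeline(cfg)
    print(f"wrote {len(manifest['outputs'])} fixture files to {OUT}/:")
    for name in sorted(manifest["outputs"]):
        print(f"  {name}")


if __name__ == "__main__":
    main()
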