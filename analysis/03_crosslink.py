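#!/usr/bin/env python
"""Intramolecular crosslinking quantification (L91C/L118C, BMH vs DMSO).

The 0-PEG band enrichment under crosslinker measures how often the two
arm-tip cysteines are close enough to bridge (13 A spacer). Expected
outcome on the fixtures: efficient crosslinking in the bilayer (closed V,
normalized 100%) and roughly half of it on the monolayer (open V).
"""

from pathlib import Path

import pandas as pd

from ldhairpin import accessibility as acc

FIXTURES = Path("results/fixtures")
OUT = Path("results/crosslink")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    lanes = pd.read_csv(FIXTURES / "crosslink_lanes.csv")
    quant = acc.crosslink_efficiency(lanes)
    quant.to_csv(OUT / "quantification.csv", index=False)
    print(quant.to_string(index=False))


if __name__ == "__main__":
    main()
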