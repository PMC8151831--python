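#!/usr/bin/env python
"""Simulate the study-condition series every later step consumes.

Writes the flagship NDVI-like record (18 years of 8-day composites:
seasonality, slow trend, one abrupt shift, persistent noise, sparse gaps)
under results/series/, with a sidecar metadata file echoing the
generating specification. The longer ground-truth references — fGn at
three Hurst exponents, Brownian motion, the p=0.3 binomial cascade — go
under scratch/series/ (they are bulky and fully regenerable from their
specs; the validation step regenerates them in memory anyway).
"""

from pathlib import Path

import yaml

from ndviscaling.series import write_series
from ndviscaling.synthetic import SimSpec, generate

ROOT = Path(__file__).resolve().parents[1]

SPECS = {
    "results/series/ndvi_like": SimSpec(seed=11),
    "scratch/series/fgn_h03": SimSpec(generator="fgn", n_points=4096, hurst=0.3, seed=1),
    "scratch/series/fgn_h05": SimSpec(generator="fgn", n_points=4096, hurst=0.5, seed=1),
    "scratch/series/fgn_h07": SimSpec(generator="fgn", n_points=4096, hurst=0.7, seed=1),
    "scratch/series/brownian": SimSpec(generator="brownian", n_points=8192, seed=1),
    "scratch/series/cascade_p03": SimSpec(generator="binomial_cascade", cascade_p=0.3,
                                          cascade_levels=13, seed=0),
}


def main() -> None:
    for name, spec in SPECS.items():
        path = ROOT / f"{name}.csv"
        path.parent.mkdir(parents=True, exist_ok=True)
        series = generate(spec)
        write_series(series, path)
        path.with_suffix(".meta.yaml").write_text(yaml.safe_dump(spec.to_dict(), sort_keys=False))
        print(f"{name}: n={len(series)}, missing={series.n_missing} -> {path}")


if __name__ == "__main__":
    main()
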