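#!/usr/bin/env python
"""Simulate one paired structural/angiographic OCT phantom with ground truth.

Writes the two volumes (multi-page TIFF + JSON sidecars) and the layer model
under scratch/phantom/, and the ground-truth object table under results/.
"""

import argparse
from pathlib import Path

from hrdot import phantom
from hrdot.io_core import write_stack

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    cfg = phantom.PhantomConfig(seed=args.seed)
    pair = phantom.generate_pair(cfg)

    out = ROOT / "scratch" / "phantom"
    out.mkdir(parents=True, exist_ok=True)
    write_stack(pair.structural, out / f"structural_seed{args.seed}.tif")
    write_stack(pair.angiographic, out / f"angio_seed{args.seed}.tif")
    pair.layers.to_json(out / f"layers_seed{args.seed}.json")
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    phantom.export_truth(pair.objects, results / f"phantom_truth_seed{args.seed}.csv")

    caps = [o for o in pair.objects if o.kind == "capillary"]
    print(f"phantom seed {args.seed}: {len(pair.objects)} objects "
          f"({len(caps)} capillaries, {sum(not c.perfused for c in caps)} non-perfused), "
          f"structural {pair.structural.shape}, angiographic {pair.angiographic.shape}")
    print(f"volumes -> {out}, truth -> results/phantom_truth_seed{args.seed}.csv")


if __name__ == "__main__":
    main()
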