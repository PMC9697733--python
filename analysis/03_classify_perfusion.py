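#!/usr/bin/env python
"""Align the phantom's two stacks, assign perfusion classes, score recovery.

Estimates the rigid en-face misregistration between the structural and
angiographic stacks, maps every traced element into the angiographic frame,
assigns the final class (granule / perfused filiform / non-perfused filiform /
unclassifiable), and compares everything against planted ground truth.
"""

import argparse
from pathlib import Path

import pandas as pd

from hrdot import phantom, pipeline

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    pair = phantom.generate_pair(phantom.PhantomConfig(seed=args.seed))
    classified, transform = pipeline.run_inl_pipeline(pair)

    dx, dy, rot = pair.true_transform
    print(f"alignment: estimated ({transform.lateral_shift:.1f} µm, "
          f"{transform.scanaxis_shift:.1f} µm, {transform.rotation:.2f}°) "
          f"vs planted ({dx:.1f} µm, {dy:.1f} µm, {rot:.2f}°)")

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    pd.DataFrame([{
        "id": c.element.id, "first_scan": c.element.first_scan,
        "n_scans": c.element.n_scans, "extent_um": c.element.conservative_extent,
        "shape_class": c.element.shape_class, "location": c.element.location,
        "final_class": c.final_class, "overlap_fraction": c.motion_overlap_fraction,
        "adjacent_signal": c.adjacent_signal, "projection_risk": c.projection_risk,
        "retrievable": c.retrievable,
    } for c in classified]).to_csv(results / f"classified_seed{args.seed}.csv", index=False)

    rec = pipeline.evaluate_recovery(pair, classified)
    rec.to_csv(results / f"recovery_seed{args.seed}.csv", index=False)
    counts = pd.Series([c.final_class for c in classified]).value_counts()
    print("final classes:", dict(counts))
    print(f"recovery: {rec.recovered.sum()}/{len(rec)} planted INL objects "
          f"({100 * rec.recovered.mean():.0f}%) with matching shape, perfusion "
          f"and location")


if __name__ == "__main__":
    main()
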