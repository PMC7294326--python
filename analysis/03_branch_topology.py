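"""Skeletonize the vessel network and analyse branch points vs radius.

For ten simulated lobules: segment the noisy render, skeletonize the vessel
mask, detect and classify junctions (triple vs four-plus), bin them by
normalized radius, fit the pooled counts (R <= 0.8) to a line with the
nested-model F-test, and compare branch-type proportions by unpaired
t-test — the image-analysis route to "vessel number rises towards the
periphery, mostly by triple branching".
"""

import argparse
import json
from collections import Counter
from pathlib import Path

import numpy as np
import pandas as pd

from lobulemorph import morphometry as M
from lobulemorph import segmentation as S
from lobulemorph import stats as ST
from lobulemorph import synthetic as Y
from lobulemorph import topology as T


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seeds", type=int, default=10)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    pooled = np.zeros(11)
    triple_props, quad_props, rows = [], [], []
    for seed in range(args.seeds):
        lob, img, _ = Y.simulate_lobule(seed=seed)
        masks = S.segment_classes(img, "auto", scale=lob.scale)
        skel = T.skeletonize_vessels(masks.vessel, scale=lob.scale)
        detected = T.detect_branch_points(skel, merge_radius=5.0)
        frame = M.LobuleFrame(cv_centroid=lob.cv_centroid,
                              boundary=lob.lobule_radius)
        counts, edges = T.branch_counts_by_ring(detected, frame, 10)
        pooled += counts
        c = Counter(bp.type for bp in detected)
        total = sum(c.values())
        triple_props.append(c.get(T.TRIPLE, 0) / total)
        quad_props.append(c.get(T.QUAD_PLUS, 0) / total)
        rows.append({"seed": seed, "n_branch_points": total,
                     "triple": c.get(T.TRIPLE, 0),
                     "quad_plus": c.get(T.QUAD_PLUS, 0)})

    centers = 0.5 * (edges[:-1] + edges[1:])
    keep = centers <= 0.8
    fit = ST.fit_linear_ftest(centers[keep], pooled[:10][keep])
    t, p_t = ST.branch_type_test(triple_props, quad_props)

    pd.DataFrame(rows).to_csv(args.out / "branch_points_per_lobule.csv",
                              index=False)
    pd.DataFrame({"bin_center": centers, "pooled_count": pooled[:10]}).to_csv(
        args.out / "branch_counts_by_ring.csv", index=False)
    summary = {
        "n_lobules": args.seeds,
        "slope": fit.slope, "r_squared": fit.r_squared,
        "f_statistic": fit.f_statistic, "p_value": fit.p_value,
        "mean_triple_fraction": float(np.mean(triple_props)),
        "mean_quad_plus_fraction": float(np.mean(quad_props)),
        "branch_type_t": t, "branch_type_p": p_t,
    }
    (args.out / "branch_topology_summary.json").write_text(
        json.dumps(summary, indent=2))

    print(f"pooled branch counts per ring: {pooled[:10].astype(int)}")
    print(f"linear fit (R <= 0.8): slope {fit.slope:.1f}, "
          f"R² {fit.r_squared:.2f}, F-test p = {fit.p_value:.2e} "
          "(vs intercept-only model)")
    print(f"triple fraction {np.mean(triple_props):.2f} vs quad-plus "
          f"{np.mean(quad_props):.2f}; unpaired t-test p = {p_t:.2e}")


if __name__ == "__main__":
    main()
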