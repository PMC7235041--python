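#!/usr/bin/env python
"""Visualize item-level structure in the peak mechanical network.

Embeds the expert group's peak mechanical-network average DM in 3-D with
nonmetric MDS and fits a 95% concentration ellipsoid per mechanical
category.  Writes:

* ``results/item_embedding.csv``   — item coordinates, category, stress,
* ``results/category_ellipsoids.csv`` — ellipsoid centers and semi-axes,
* ``results/item_embedding.png``   — a 2-D projection of the embedding
  (categories should separate for the mechanical peak, not for the visual
  model DM).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
sys.path.insert(0, str(Path(__file__).resolve().parent))

import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

import infonets as inf  # noqa: E402
from infonets.rsa import network_average_dm  # noqa: E402
from _common import ensure_results_dir, get_result, get_study  # noqa: E402


def main() -> None:
    results = ensure_results_dir()
    res = get_result()
    study = get_study()

    peak = res.peaks[("expert", "mechanical_category")]
    nets = {n.network_id: n for n in res.group_networks("expert")}
    net = nets[peak.network_id]
    # group-average DM over the peak network
    dms = np.mean(
        [network_average_dm(m, net).condensed for m in res.subject_maps["expert"]],
        axis=0,
    )
    dm = inf.ItemDM(condensed=dms, item_ids=study.labels.item_ids)
    emb = inf.nmds_embed(dm, dims=3, n_starts=8, seed=0)
    print(f"embedded peak network {net.network_id}: stress-1 = {emb.stress:.4f}")

    cats = dict(zip(study.labels.item_ids, study.labels.categories))
    df = pd.DataFrame(emb.coords, columns=["x", "y", "z"])
    df.insert(0, "item_id", list(emb.item_ids))
    df["category"] = [cats[i] for i in emb.item_ids]
    df["stress"] = emb.stress
    df.to_csv(results / "item_embedding.csv", index=False)

    erows = []
    for cat in study.labels.category_names:
        pts = emb.coords[[c == cat for c in df["category"]]]
        ell = inf.concentration_ellipsoid(pts, probability=0.95, category=cat)
        inside = ell.contains(pts).mean()
        erows.append(dict(category=cat, cx=ell.center[0], cy=ell.center[1],
                          cz=ell.center[2],
                          semi_axis_1=ell.semi_axis_lengths[0],
                          semi_axis_2=ell.semi_axis_lengths[1],
                          semi_axis_3=ell.semi_axis_lengths[2],
                          fraction_of_points_inside=inside))
        print(f"  {cat}: ellipsoid semi-axes "
              f"{np.round(ell.semi_axis_lengths, 3).tolist()}, "
              f"{100 * inside:.0f}% of its items inside")
    pd.DataFrame(erows).to_csv(results / "category_ellipsoids.csv", index=False)

    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 5))
        for cat, color in zip(study.labels.category_names, ("tab:green", "tab:blue", "tab:red")):
            sel = df["category"] == cat
            ax.scatter(df.loc[sel, "x"], df.loc[sel, "y"], label=cat, color=color)
        ax.set_xlabel("NMDS dim 1")
        ax.set_ylabel("NMDS dim 2")
        ax.set_title(f"peak mechanical network item space (stress {emb.stress:.3f})")
        ax.legend()
        fig.tight_layout()
        fig.savefig(results / "item_embedding.png", dpi=100)
    except Exception as exc:  # plotting is best-effort
        print(f"figure skipped: {exc}")
    print(f"wrote item embedding and ellipsoids under {results}")


if __name__ == "__main__":
    main()
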