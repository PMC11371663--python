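#!/usr/bin/env python
"""Summarize niche volumes and per-variable climate gradients from the
study report: group medians and the paired t-test for both volume
estimators, the extinct-vs-extant volume regression, and the variables
with the lowest kernel-density overlap for each non-similar pair.

Run after 03:  python analysis/04_volumes_and_gradients.py
"""

import json
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    report = json.loads((ROOT / "results" / "study" / "report.json").read_text())

    rows = []
    for pair in report["pairs"]:
        if pair["skipped"]:
            continue
        for role in ("extinct", "extant"):
            rows.append({"pair_id": pair["pair_id"], "status": role,
                         "taxon": pair[f"taxon_{role}"],
                         "schoener_volume": pair["volumes"][role]["schoener"],
                         "hdr_volume": pair["volumes"][role]["hdr"]})
    volumes = pd.DataFrame(rows)
    volumes.to_csv(ROOT / "results" / "niche_volumes.csv", index=False)

    print("Niche volume by status group:")
    for metric in ("schoener", "hdr"):
        cmp = report["volume_comparison"][metric]
        print(f"  {metric}: median extinct {cmp['median_extinct']:.2f}, "
              f"extant {cmp['median_extant']:.2f}; paired t-test p = "
              f"{cmp['p_paired']:.2f}; pair regression r^2 = {cmp['r_squared']:.2f} "
              f"(slope p = {cmp['slope_p']:.2f})")

    print("\nLowest-overlap climate variables for non-similar pairs:")
    grads = []
    for pair in report["pairs"]:
        if pair["skipped"] or pair["sim_category"] != "non_similar":
            continue
        vo = pd.DataFrame(pair["variable_overlaps"]).dropna(subset=["overlap_percent"])
        worst = vo.nsmallest(3, "overlap_percent")
        for row in worst.itertuples():
            grads.append({"pair_id": pair["pair_id"], "variable": row.variable,
                          "overlap_percent": row.overlap_percent,
                          "mean_extinct": row.mean_extinct,
                          "mean_extant": row.mean_extant})
            print(f"  {pair['pair_id']}: {row.variable} overlap "
                  f"{row.overlap_percent:.0f}%, means {row.mean_extinct:.1f} vs "
                  f"{row.mean_extant:.1f}")
    if grads:
        pd.DataFrame(grads).to_csv(ROOT / "results" / "legacy_gradients.csv", index=False)
    else:
        print("  (no non-similar pairs in this run)")


if __name__ == "__main__":
    main()
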