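#!/usr/bin/env python
"""Read the climate rasters back from disk, restrict to the background,
and fit the environmental PCA defining the two-axis niche space.

Reports how much variation the first two axes explain (on real
WorldClim-over-Australia inputs this is the familiar ~64%/~20% split;
the synthetic landscape concentrates nearly everything on two axes by
construction) and stores the fitted space as JSON for the later stages.

Run after 01:  python analysis/02_fit_climate_space.py
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

import nichelegacy as nl
from nichelegacy.grids import read_ascii_grid

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    inputs = json.loads((ROOT / "scratch" / "synthetic" / "inputs.json").read_text())
    rasters = {k: Path(v) for k, v in inputs["rasters"].items()}
    mask_layer, *_ = read_ascii_grid(rasters.pop("background_mask"))
    grid = nl.read_climate_grid(rasters)
    background = nl.apply_background_mask(grid, mask_layer.astype(bool))
    print(f"background: {background.n_cells} of {grid.n_rows * grid.n_cols} cells")

    space = nl.fit_environmental_pca(background)
    space.to_json(ROOT / "results" / "environmental_space.json")
    vf = space.var_fraction
    print(f"PC1 explains {100 * vf[0]:.1f}% of the variation, "
          f"PC2 {100 * vf[1]:.1f}% (two axes: {100 * vf[:2].sum():.1f}%)")

    loadings = pd.DataFrame(space.loadings[:, :2], index=space.var_names,
                            columns=["pc1", "pc2"])
    loadings["communality_2axis"] = (space.loadings[:, :2] ** 2).sum(axis=1)
    loadings.to_csv(ROOT / "results" / "pca_loadings.csv")
    scores = nl.project(space, background.X)
    print(f"background score ranges: PC1 [{scores[:, 0].min():.2f}, "
          f"{scores[:, 0].max():.2f}], PC2 [{scores[:, 1].min():.2f}, "
          f"{scores[:, 1].max():.2f}]")


if __name__ == "__main__":
    main()
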