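#!/usr/bin/env python
"""Spatial varicosity analyses of the synthetic cohort.

Builds the 100-μm voxel density map per cell (plus one VTK export for 3-D
viewing), a varicosity Sholl profile in 100-μm shells around the soma, and
the 100-μm path-distance histogram measured along the axon from its origin.
"""

from pathlib import Path

import pandas as pd

from lcnmorph.io import write_voxels
from lcnmorph.morphometrics import path_distance_histogram, sholl
from lcnmorph.synthetic import SyntheticSpec, generate_lcn
from lcnmorph.voxelmap import compute_voxel_grid, grid_summary

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"
SEEDS = range(10)


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
    vox_rows, profile_rows = [], []
    for seed in SEEDS:
        recon, truth = generate_lcn(SyntheticSpec(seed=seed))
        grid = compute_voxel_grid(recon, edge=100.0)
        max_count, occupied, com = grid_summary(grid)
        vox_rows.append(
            {
                "seed": seed,
                "n_varicosities": truth.n_varicosities,
                "max_voxel_count": max_count,
                "occupied_voxels": occupied,
                "centroid_rc_um": com[0],
                "centroid_dv_um": com[1],
                "centroid_ml_um": com[2],
            }
        )
        if seed == 0:
            write_voxels(grid, SCRATCH / "lcn_00.voxels.vtk")
        for profile, kind in (
            (sholl(recon, "varicosities", shell_width=100.0), "sholl_100um"),
            (path_distance_histogram(recon, bin_width=100.0), "path_distance_100um"),
        ):
            frame = profile.to_frame()
            frame.insert(0, "seed", seed)
            frame.insert(1, "profile", kind)
            frame.columns = ["seed", "profile", "bin_lower_um", "count"]
            profile_rows.append(frame)

    vox = pd.DataFrame(vox_rows)
    vox.to_csv(RESULTS / "voxel_map_summary.csv", index=False, float_format="%.6g")
    profiles = pd.concat(profile_rows, ignore_index=True)
    profiles.to_csv(RESULTS / "varicosity_profiles.csv", index=False, float_format="%.6g")

    print("per-cell voxel maps (100-μm voxels):")
    print(vox.to_string(index=False))
    print(
        f"\nmax per-voxel counts span {vox.max_voxel_count.min()}-{vox.max_voxel_count.max()} "
        "(published range for reconstructed cells: 79-273)"
    )
    peak = profiles[profiles.profile == "path_distance_100um"].groupby("seed").apply(
        lambda g: g.loc[g["count"].idxmax(), "bin_lower_um"], include_groups=False
    )
    print(f"path-distance histogram peaks at {peak.min():.0f}-{peak.max():.0f} μm from the origin")
    print(f"\ntables: {RESULTS}/voxel_map_summary.csv, {RESULTS}/varicosity_profiles.csv")


if __name__ == "__main__":
    main()
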