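#!/usr/bin/env python
"""Action-potential propagation-time maps of the synthetic cohort.

Computes per-cell cumulative conduction times under the diameter-threshold
myelination model and under the all-unmyelinated assumption, the per-cell
maximum-time ratio, and 1-ms histograms of per-varicosity propagation times
for both models.
"""

from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from lcnmorph.propagation import (
    PropagationParams,
    compare_models,
    propagation_map,
    varicosity_time_histogram,
)
from lcnmorph.synthetic import SyntheticSpec, generate_lcn

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SEEDS = range(10)


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    params = PropagationParams()
    rows, hist_rows = [], []
    for seed in SEEDS:
        recon, truth = generate_lcn(SyntheticSpec(seed=seed))
        max_u, max_t, ratio = compare_models(recon, params)
        rows.append(
            {
                "seed": seed,
                "has_solitary_branch": truth.has_solitary_branch,
                "max_time_all_unmyelinated_ms": max_u,
                "max_time_thresholded_ms": max_t,
                "ratio_percent": ratio,
            }
        )
        for label, p in (
            ("thresholded", params),
            ("all_unmyelinated", replace(params, force_all_unmyelinated=True)),
        ):
            counts = varicosity_time_histogram(propagation_map(recon, p), bin_width=1.0)
            hist_rows.append(
                pd.DataFrame(
                    {
                        "seed": seed,
                        "model": label,
                        "bin_lower_ms": np.arange(len(counts), dtype=float),
                        "count": counts,
                    }
                )
            )

    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "propagation_comparison.csv", index=False, float_format="%.6g")
    pd.concat(hist_rows, ignore_index=True).to_csv(
        RESULTS / "varicosity_time_histograms.csv", index=False, float_format="%.6g"
    )

    print("myelination-aware vs all-unmyelinated propagation (per cell):")
    print(df.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
    sol = df[df.has_solitary_branch].ratio_percent.mean()
    compact = df[~df.has_solitary_branch].ratio_percent.mean()
    print(
        f"\nmean max-time ratio: {sol:.1f}% with a solitary branch vs "
        f"{compact:.1f}% without — myelinated thick pieces shorten delays most "
        "in cells with remote varicose fields"
    )
    print(f"\ntables: {RESULTS}/propagation_comparison.csv, "
          f"{RESULTS}/varicosity_time_histograms.csv")


if __name__ == "__main__":
    main()
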