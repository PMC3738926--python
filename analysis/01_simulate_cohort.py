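#!/usr/bin/env python
"""Generate the synthetic LCN cohort used by the downstream analyses.

Writes ten default-preset cells (seeds 0-9) as SWC + varicosity-marker CSV +
ground-truth JSON under scratch/cohort/, and a cohort overview table under
results/.  All downstream scripts regenerate cells deterministically from the
same seeds, so this step is about inspectable artifacts, not state.
"""

import json
from pathlib import Path

import pandas as pd

from lcnmorph.io import write_markers, write_swc
from lcnmorph.synthetic import SyntheticSpec, generate_lcn

ROOT = Path(__file__).resolve().parents[1]
COHORT_DIR = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"
SEEDS = range(10)


def main() -> None:
    COHORT_DIR.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for seed in SEEDS:
        recon, truth = generate_lcn(SyntheticSpec(seed=seed))
        base = COHORT_DIR / f"lcn_{seed:02d}"
        write_swc(recon, base.with_suffix(".swc"))
        write_markers(recon.varicosities, base.with_suffix(".markers.csv"))
        base.with_suffix(".groundtruth.json").write_text(
            json.dumps(truth.to_dict(), indent=2, sort_keys=True) + "\n"
        )
        rows.append(
            {
                "seed": seed,
                "n_nodes": len(recon.nodes),
                "n_varicosities": truth.n_varicosities,
                "n_primary_branches": truth.n_primary_branches,
                "axon_origin": truth.axon_origin,
                "has_solitary_branch": truth.has_solitary_branch,
            }
        )
    df = pd.DataFrame(rows)
    out = RESULTS / "cohort_overview.csv"
    df.to_csv(out, index=False)
    print(f"wrote {len(rows)} cells to {COHORT_DIR}")
    print(df.to_string(index=False))
    print(f"\noverview table: {out}")


if __name__ == "__main__":
    main()
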