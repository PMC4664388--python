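#!/usr/bin/env python
"""Simulate the three-arm cohort from the published group parameters.

Draws eye-level values for healthy (29 eyes / 24 subjects), MSON- (31/25)
and MSON+ (36/26) groups for every across-all-regions metric × layer cell,
with inter-eye correlation rho = 0.5 and printed dispersions treated as
standard errors (rescaled to eye-level SDs).  Writes
results/cohort_features.csv and prints a per-group summary for the
ganglion-cell-family thickness cells.
"""

from pathlib import Path

import retinotex as rt

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 20260922


def main() -> None:
    spec = rt.CohortSpec(seed=SEED)
    table, truth = rt.generate_cohort_features(spec)
    RESULTS.mkdir(exist_ok=True)
    rt.write_feature_table(table, RESULTS / "cohort_features.csv")
    print(f"wrote {RESULTS / 'cohort_features.csv'} ({len(table)} rows, "
          f"rho={truth['rho']}, dispersions treated as SE: "
          f"{truth['dispersion_is_se']})")

    summary = rt.summarize_groups(table)
    wanted = summary[
        (summary.metric == "thickness_um")
        & summary.layer.isin(["RNFL", "GCL+IPL", "GCC"])
    ]
    print("\nsimulated thickness summaries (um, across all macular regions):")
    for _, row in wanted.sort_values(["layer", "group"]).iterrows():
        print(f"  {row.layer:8s} {row.group:5s} n={row.n:2d} "
              f"mean={row['mean']:7.2f}  sd={row.sd:5.2f}  se={row.se:4.2f}")


if __name__ == "__main__":
    main()
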