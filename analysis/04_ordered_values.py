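#!/usr/bin/env python
"""Rank location-independent ordered values of 2-year thickness change.

For every analysis knee the 16 subregional changes are sorted ascending
(OV1 = greatest thinning ... OV16 = greatest thickening) and the source
subregions of the extreme ranks are tabulated per group.
"""

import shutil
from pathlib import Path

import pandas as pd

from kneeqmri.ordered_values import rank_ov, tabulate_ov_occurrences
from kneeqmri.pipeline import _participants_from_csv
from kneeqmri.regions import SUBREGIONS
from kneeqmri.report_io import read_report, write_report
from kneeqmri.stats import (build_analysis_table, compute_change,
                            select_control_knee)

ROOT = Path(__file__).resolve().parents[1]
RUN_DIR = ROOT / "scratch" / "pipeline_run"
RESULTS = ROOT / "results"


def main() -> None:
    measures = read_report(RUN_DIR / "measures.csv")
    participants = _participants_from_csv(RUN_DIR / "cohort.csv")
    change = compute_change(measures)
    table = build_analysis_table(change, select_control_knee(participants, 2026))

    sub = table[(table.measure == "thickness") & table.location.isin(SUBREGIONS)]
    ovs, groups = {}, {}
    for knee, grp in sub.groupby("knee_id"):
        ovs[knee] = rank_ov(dict(zip(grp.location, grp.change)))
        groups[knee] = grp.knee_group.iloc[0]
    occ = tabulate_ov_occurrences(ovs, groups)
    write_report(occ.table, RESULTS / "ov_occurrences.csv",
                 {"seed": 2026, "groups": occ.group_sizes})

    ov1 = pd.Series({k: v.value(1) for k, v in ovs.items()})
    grp = pd.Series(groups)
    print("group sizes:", occ.group_sizes)
    for g in ("ACL_in", "ACL_unin", "HEA"):
        vals = ov1[grp == g]
        print(f"OV1 mean change, {g}: {vals.mean():.0f} um")
    top = (occ.table[occ.table["rank"] == "OV1"]
           .sort_values("count", ascending=False).groupby("group").head(1))
    for _, r in top.iterrows():
        print(f"most frequent OV1 source in {r.group}: {r.subregion} "
              f"({r['count']} knees, {r.percent:.1f} %)")


if __name__ == "__main__":
    main()
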