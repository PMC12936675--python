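"""Pipeline stages tying the modules into one reproducible run.

Stage outputs are plain CSV (with a provenance header), YAML config and
NIfTI volumes under a single output directory:

    out/
      config.yaml                resolved configuration
      cohort.csv                 participant records
      measures.csv               per knee-visit regional means (truth level)
      images/<knee>_<visit>/     rendered echo/mask volumes (subset)
      manifest.csv               index of rendered images
      morphometry_measures.csv   image-derived thickness means vs truth
      t2_measures.csv            image-derived laminar T2 means vs truth
      reports/table1..table4 ... statistical outputs

The cohort statistics run on the truth-level measure tables; the rendered
images validate the imaging chain (thickness, atlas, T2, laminae) on a
subset of knees.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (ParticipantRecord, generate_cohort, read_knee_image,
                     render_knee_image, truth_regional_measures,
                     write_knee_image)
from .config import PipelineConfig
from .morphometry import build_subregion_atlas, compute_thickness_map, \
    summarize_thickness
from .ordered_values import rank_ov, tabulate_ov_occurrences
from .regions import (LAYERS, SUBREGIONS, T2_LOCATIONS, THICKNESS_LOCATIONS)
from .report_io import write_report
from .stats import (build_analysis_table, characteristics_table,
                    compute_change, paired_bilateral_test, run_models,
                    screen_covariates, select_control_knee)
from .t2_mapping import estimate_t2_map, summarize_t2

log = logging.getLogger(__name__)


def _meta(cfg: PipelineConfig, **extra) -> dict:
    return {"generator": f"kneeqmri {__version__}",
            "config_hash": cfg.config_hash(),
            "simulation_seed": cfg.simulation.seed,
            "analysis_seed": cfg.analysis.seed, **extra}


# ---------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig, out_dir: str | Path) -> Path:
    """Generate the cohort, write measure tables, render an image subset."""
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")

    participants, truths = generate_cohort(cfg.simulation)
    pdf = pd.DataFrame([{**vars(p),
                         "followup_months": p.visit_months[1]}
                        for p in participants]).drop(columns=["visit_months"])
    write_report(pdf, out / "cohort.csv", _meta(cfg))
    measures = truth_regional_measures(participants, truths)
    write_report(measures, out / "measures.csv", _meta(cfg))

    manifest_rows = []
    for idx, kt in enumerate(truths[:cfg.n_rendered_knees]):
        for v_i, visit in enumerate(("baseline", "followup")):
            rng = np.random.default_rng([cfg.simulation.seed, idx, v_i])
            img = render_knee_image(kt, cfg.simulation, visit=visit,
                                    spacing=cfg.render_spacing, rng=rng)
            d = write_knee_image(img, out / "images" / f"{kt.knee_id}_{visit}")
            manifest_rows.append({"knee_id": kt.knee_id, "visit": visit,
                                  "role": kt.role, "path": str(d.relative_to(out))})
    write_report(pd.DataFrame(manifest_rows,
                              columns=["knee_id", "visit", "role", "path"]),
                 out / "manifest.csv", _meta(cfg))
    log.info("simulated %d participants, %d knees, %d rendered images",
             len(participants), len(truths), len(manifest_rows))
    return out


def _load_manifest(out: Path) -> pd.DataFrame:
    manifest = out / "manifest.csv"
    if not manifest.exists():
        raise FileNotFoundError(f"missing manifest {manifest}")
    return pd.read_csv(manifest, comment="#")


def stage_morphometry(out_dir: str | Path) -> Path:
    """Thickness maps and subregional means for every rendered image."""
    out = Path(out_dir)
    cfg = PipelineConfig.from_yaml(out / "config.yaml")
    rows = []
    for _, rec in _load_manifest(out).iterrows():
        echo1, echo2, mask, meta = read_knee_image(out / rec.path)
        tmap = compute_thickness_map(mask)
        atlas = build_subregion_atlas(mask)
        regional = summarize_thickness(tmap, atlas)
        truth = meta["true_voxelized_thickness_mm"]
        for loc, val in regional.values.items():
            truth_val = np.nan
            if loc in SUBREGIONS:
                for plate, subs in truth.items():
                    if loc in subs:
                        truth_val = subs[loc]
            rows.append({"knee_id": rec.knee_id, "visit": rec.visit,
                         "location": loc, "mean_thickness_mm": val,
                         "n_positions": regional.n_positions[loc],
                         "voxelized_truth_mm": truth_val})
    path = write_report(pd.DataFrame(rows), out / "morphometry_measures.csv",
                        _meta(cfg))
    return path


def stage_t2map(out_dir: str | Path) -> Path:
    """Voxel-wise T2 and laminar summaries for every rendered image."""
    out = Path(out_dir)
    cfg = PipelineConfig.from_yaml(out / "config.yaml")
    sim = cfg.simulation
    rows = []
    for _, rec in _load_manifest(out).iterrows():
        echo1, echo2, mask, meta = read_knee_image(out / rec.path)
        t2map = estimate_t2_map(echo1, echo2, mask, sim.tr_ms, sim.te_ms)
        summary = summarize_t2(t2map)
        for _, r in summary.table.iterrows():
            truth_val = np.nan
            t = meta["true_t2_ms"].get(r.location)
            if t is not None:
                truth_val = (0.5 * (t["deep"] + t["superficial"])
                             if r.layer == "total" else t[r.layer])
            rows.append({"knee_id": rec.knee_id, "visit": rec.visit,
                         "location": r.location, "layer": r.layer,
                         "mean_t2_ms": r.mean_t2_ms, "n_valid": r.n_valid,
                         "true_t2_ms": truth_val})
    path = write_report(pd.DataFrame(rows), out / "t2_measures.csv", _meta(cfg))
    return path


# ---------------------------------------------------------------------------

def _participants_from_csv(path: Path) -> list[ParticipantRecord]:
    df = pd.read_csv(path, comment="#")
    out = []
    for _, r in df.iterrows():
        out.append(ParticipantRecord(
            id=r.id, group=r.group, age_group=r.age_group, age=r.age,
            sex=r.sex, body_mass_kg=r.body_mass_kg, height_cm=r.height_cm,
            bmi=r.bmi, injured_side=r.injured_side,
            visit_months=(0.0, float(r.followup_months))))
    return out


def stage_analyze(out_dir: str | Path) -> Path:
    """The statistical layer: bilateral tests, screening, EMM models,
    ordered values, characteristics."""
    out = Path(out_dir)
    cfg = PipelineConfig.from_yaml(out / "config.yaml")
    acfg = cfg.analysis
    measures_path = out / "measures.csv"
    if not measures_path.exists():
        raise FileNotFoundError(f"missing measures table {measures_path}")
    measures = pd.read_csv(measures_path, comment="#")
    participants = _participants_from_csv(out / "cohort.csv")
    rep = out / "reports"
    rep.mkdir(exist_ok=True)
    meta = _meta(cfg)

    change = compute_change(measures)

    # characteristics (Table-1 style)
    write_report(characteristics_table(participants),
                 rep / "table1_characteristics.csv", meta)

    # bilateral left/right agreement in healthy knees (paired t-tests)
    hea = change[change.role.str.startswith("HEA")]
    bil_rows = []
    for (measure, loc, layer), grp in hea.groupby(["measure", "location", "layer"]):
        wide = grp.pivot_table(index="participant_id", columns="side",
                               values="change").dropna()
        if len(wide) < 3:
            continue
        res = paired_bilateral_test(wide["left"], wide["right"])
        bil_rows.append({"measure": measure, "location": loc, "layer": layer,
                         "t": res.t, "p": res.p, "n": res.n,
                         "zero_variance": res.zero_variance})
    write_report(pd.DataFrame(bil_rows), rep / "bilateral_paired_tests.csv", meta)

    # control-knee selection and the analysis table (with OV rows)
    control = select_control_knee(participants, acfg.seed)
    table = build_analysis_table(change, control)
    write_report(pd.DataFrame(sorted(control.items()),
                              columns=["participant_id", "selected_side"]),
                 rep / "control_knee_selection.csv", meta)

    # covariate screening on joint/region level
    scr_rows = []
    screen_locs = [("thickness", loc, "total") for loc in
                   ("FTJ", "MT", "cMF", "LT", "cLF")] + \
                  [("t2", "FTJ", l) for l in LAYERS]
    for measure, loc, layer in screen_locs:
        sub = table[(table.measure == measure) & (table.location == loc)
                    & (table.layer == layer)]
        for cov in ("age", "daytime_diff_h", "baseline"):
            s = screen_covariates(sub.change, sub[cov])
            scr_rows.append({"measure": measure, "location": loc, "layer": layer,
                             "covariate": cov, "slope": s.slope, "p": s.p,
                             "se": s.se})
    write_report(pd.DataFrame(scr_rows), rep / "covariate_screening.csv", meta)

    # thickness EMMs (compartments, regions, subregions, ordered values)
    locs = list(THICKNESS_LOCATIONS) + list(acfg.ov_ranks)
    emm_t, con_t = run_models(table, "thickness", locs, ("total",), acfg)
    write_report(emm_t, rep / "table2_thickness_emms.csv", meta)
    write_report(con_t, rep / "table2_thickness_contrasts.csv", meta)

    # ordered-value occurrences (Table-3 style)
    sub = table[(table.measure == "thickness") & table.location.isin(SUBREGIONS)]
    ovs, groups = {}, {}
    for knee, grp in sub.groupby("knee_id"):
        if len(grp) == len(SUBREGIONS):
            ovs[knee] = rank_ov(dict(zip(grp.location, grp.change)))
            groups[knee] = grp.knee_group.iloc[0]
    occ = tabulate_ov_occurrences(ovs, groups, acfg.ov_ranks)
    write_report(occ.table, rep / "table3_ov_occurrences.csv", meta)

    # T2 EMMs per region/compartment and layer (Table-4 style)
    emm_q, con_q = run_models(table, "t2", list(T2_LOCATIONS), LAYERS, acfg)
    write_report(emm_q, rep / "table4_t2_emms.csv", meta)
    write_report(con_q, rep / "table4_t2_contrasts.csv", meta)
    log.info("analysis reports written to %s", rep)
    return rep


def run_all(cfg: PipelineConfig, out_dir: str | Path) -> Path:
    out = stage_simulate(cfg, out_dir)
    stage_morphometry(out)
    stage_t2map(out)
    return stage_analyze(out)
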