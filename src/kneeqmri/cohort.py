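"""Synthetic cohort: participants, ground-truth trajectories, rendered images.

The generator emulates a four-cell longitudinal study (ACL-injured and
healthy participants in two age bands, both knees imaged at baseline and
~24-month follow-up).  Ground truth is injected at the level the analysis
operates on: per-subregion cartilage thickness at both visits (2-year
change = configured group truth + covariate terms + participant random
intercept + residual noise, all in um) and per-region laminar T2 (ms).

Rendered images are deliberately idealized: each cartilage plate is an
axis-aligned voxel slab whose per-column height is the subregional truth
thickness (plus a smooth within-plate modulation) rounded to whole
voxels, with the bone-cartilage interface on a flat face and echo volumes
filled by the two-echo steady-state forward model.  Slab geometry gives
exact oracles for thickness, subregion areas and laminar assignment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .config import GROUP_CELLS, STUDY_CHARACTERISTICS, SimulationConfig
from .morphometry import (PLATE_CODES, SegmentationMask, partition_plate)
from .regions import PLATES, SUBREGIONS, SUBREGIONS_OF_PLATE, TIBIAL_PLATES

VISITS = ("baseline", "followup")
T2_LAYERS = ("deep", "superficial")


# ---------------------------------------------------------------------------
# forward signal model
# ---------------------------------------------------------------------------

def qdess_forward(t2_ms, tr_ms: float, te_ms: float, amplitude=1.0):
    """Two-echo steady-state signal pair for a voxel with relaxation T2.

    s1 = amplitude, s2 = amplitude * exp(-2 (TR - TE) / T2); the second
    echo is always the smaller.  Accepts scalar or array T2.
    """
    t2 = np.asarray(t2_ms, dtype=float)
    if np.any(t2 <= 0):
        raise ValueError("t2_ms must be > 0")
    if not 0 < te_ms < tr_ms:
        raise ValueError("need 0 < te_ms < tr_ms")
    if np.any(np.asarray(amplitude) <= 0):
        raise ValueError("amplitude must be > 0")
    s1 = np.broadcast_to(np.asarray(amplitude, dtype=float), t2.shape).copy()
    s2 = s1 * np.exp(-2.0 * (tr_ms - te_ms) / t2)
    if s1.ndim == 0:
        return float(s1), float(s2)
    return s1, s2


# ---------------------------------------------------------------------------
# cohort records
# ---------------------------------------------------------------------------

@dataclass
class ParticipantRecord:
    id: str
    group: str                    # "ACL" | "HEA"
    age_group: str                # "20-30" | "40-60"
    age: float
    sex: str                      # "F" | "M"
    body_mass_kg: float
    height_cm: float
    bmi: float
    injured_side: str             # "left" | "right" | "none"
    visit_months: tuple[float, float]  # baseline = 0, follow-up


@dataclass
class KneeTruth:
    participant_id: str
    role: str                     # ACL_in | ACL_unin | HEA_l | HEA_r
    side: str                     # left | right
    thickness_baseline_mm: dict[str, float]
    thickness_followup_mm: dict[str, float]
    t2_baseline_ms: dict[tuple[str, str], float]   # (region, layer) -> ms
    t2_followup_ms: dict[tuple[str, str], float]
    u_intercept_um: float
    daytime_h: tuple[float, float]

    @property
    def knee_id(self) -> str:
        return f"{self.participant_id}_{self.side[0].upper()}"

    @property
    def analysis_group(self) -> str:
        return "HEA" if self.role.startswith("HEA") else self.role


def _split_counts(n: int, frac_first: float) -> int:
    return int(round(n * frac_first))


def generate_cohort(config: SimulationConfig,
                    ) -> tuple[list[ParticipantRecord], list[KneeTruth]]:
    """Draw a full cohort: demographics plus per-knee truth trajectories.

    Deterministic under ``config.seed``; per-cell counts exactly as
    configured; every ACL participant contributes an ACL_in and an
    ACL_unin knee, every healthy participant an HEA_l and an HEA_r knee.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    age_center = config.expected_age()
    participants: list[ParticipantRecord] = []
    truths: list[KneeTruth] = []
    pid_counter = 0

    for group, age_group in GROUP_CELLS:
        n = config.n_per_group[group][age_group]
        chars = STUDY_CHARACTERISTICS[(group, age_group)]
        f, m = chars["sex_fm"]
        sexes = np.array(["F"] * _split_counts(n, f / (f + m)) + ["M"] * n)[:n]
        sexes = rng.permutation(sexes)
        if group == "ACL":
            l, r = chars["injured_lr"]
            n_l = _split_counts(n, l / (l + r))
            inj = rng.permutation(np.array(["left"] * n_l + ["right"] * (n - n_l)))
        else:
            inj = np.array(["none"] * n)
        lo, hi = config.age_ranges[age_group]
        ages = rng.uniform(lo, hi, n)
        heights = np.clip(rng.normal(*chars["height"], n), 140.0, 210.0)
        masses = np.clip(rng.normal(*chars["body_mass"], n), 40.0, 140.0)
        fu = np.clip(rng.normal(*config.follow_up_months, n), 12.0, 40.0)

        for i in range(n):
            pid_counter += 1
            pid = f"P{pid_counter:03d}"
            rec = ParticipantRecord(
                id=pid, group=group, age_group=age_group, age=float(ages[i]),
                sex=str(sexes[i]), body_mass_kg=float(masses[i]),
                height_cm=float(heights[i]),
                bmi=float(masses[i] / (heights[i] / 100.0) ** 2),
                injured_side=str(inj[i]), visit_months=(0.0, float(fu[i])))
            participants.append(rec)
            truths.extend(_knee_truths(rec, config, rng, age_center))
    return participants, truths


def _knee_truths(rec: ParticipantRecord, cfg: SimulationConfig,
                 rng: np.random.Generator, age_center: float) -> list[KneeTruth]:
    day_bl, day_fu = rng.uniform(*cfg.daytime_window_h, size=2)
    u = rng.normal(0.0, cfg.sd_random_intercept) if cfg.sd_random_intercept else 0.0
    u_t2 = rng.normal(0.0, cfg.sd_t2_intercept_ms) if cfg.sd_t2_intercept_ms else 0.0

    if rec.group == "ACL":
        other = "left" if rec.injured_side == "right" else "right"
        knees = [("ACL_in", rec.injured_side), ("ACL_unin", other)]
    else:
        knees = [("HEA_l", "left"), ("HEA_r", "right")]

    out = []
    for role, side in knees:
        gkey = "HEA" if role.startswith("HEA") else role
        base = {}
        follow = {}
        for sub in SUBREGIONS:
            b_mm = cfg.baseline_thickness_by_subregion[sub]
            if cfg.sd_baseline_mm:
                b_mm = b_mm + rng.normal(0.0, cfg.sd_baseline_mm)
            b_mm = max(b_mm, 0.3)
            eps = rng.normal(0.0, cfg.sd_residual) if cfg.sd_residual else 0.0
            change_um = (
                cfg.true_change_by_group_and_subregion[gkey][sub]
                + cfg.beta_age * (rec.age - age_center)
                + cfg.beta_daytime * (day_fu - day_bl)
                + cfg.beta_baseline * (b_mm - cfg.baseline_thickness_by_subregion[sub]) * 1000.0
                + u + eps)
            base[sub] = b_mm
            follow[sub] = max(b_mm + change_um / 1000.0, 0.05)
        t2b = {}
        t2f = {}
        for region in PLATES:
            for layer in T2_LAYERS:
                b_ms = cfg.t2_baseline_ms[region][layer]
                if cfg.sd_t2_baseline_ms:
                    b_ms = b_ms + rng.normal(0.0, cfg.sd_t2_baseline_ms)
                b_ms = max(b_ms, 5.0)
                sd = cfg.sd_t2_residual_ms[layer]
                eps = rng.normal(0.0, sd) if sd else 0.0
                change = (cfg.t2_change_by_group_region_layer[region][layer][gkey]
                          + u_t2 + eps)
                t2b[(region, layer)] = b_ms
                t2f[(region, layer)] = max(b_ms + change, 1.0)
        out.append(KneeTruth(
            participant_id=rec.id, role=role, side=side,
            thickness_baseline_mm=base, thickness_followup_mm=follow,
            t2_baseline_ms=t2b, t2_followup_ms=t2f,
            u_intercept_um=float(u), daytime_h=(float(day_bl), float(day_fu))))
    return out


# ---------------------------------------------------------------------------
# truth-level regional measures (the generator's "measurement" output)
# ---------------------------------------------------------------------------

def truth_regional_measures(participants: list[ParticipantRecord],
                            truths: list[KneeTruth]) -> pd.DataFrame:
    """Long table of per knee-visit regional means from the truth tables.

    Thickness: subregional truths, region means (equal-area subregions by
    construction), MFTC = MT + cMF, LFTC = LT + cLF, FTJ = (MFTC+LFTC)/2.
    T2: per region deep/superficial truths, total = mean of the two
    laminae, compartments = unweighted means of member regions.
    """
    pmap = {p.id: p for p in participants}
    rows = []
    for kt in truths:
        p = pmap[kt.participant_id]
        meta = dict(participant_id=p.id, knee_id=kt.knee_id, role=kt.role,
                    group=p.group, age_group=p.age_group, sex=p.sex,
                    side=kt.side, age=p.age)
        for visit, thick, t2 in (("baseline", kt.thickness_baseline_mm,
                                  kt.t2_baseline_ms),
                                 ("followup", kt.thickness_followup_mm,
                                  kt.t2_followup_ms)):
            daytime = kt.daytime_h[0] if visit == "baseline" else kt.daytime_h[1]
            vals = dict(thick)
            for plate in PLATES:
                vals[plate] = float(np.mean([thick[s]
                                             for s in SUBREGIONS_OF_PLATE[plate]]))
            vals["MFTC"] = vals["MT"] + vals["cMF"]
            vals["LFTC"] = vals["LT"] + vals["cLF"]
            vals["FTJ"] = 0.5 * (vals["MFTC"] + vals["LFTC"])
            for loc, v in vals.items():
                rows.append({**meta, "visit": visit, "daytime_h": daytime,
                             "measure": "thickness", "location": loc,
                             "layer": "total", "value": v, "units": "mm"})
            t2vals: dict[tuple[str, str], float] = {}
            for region in PLATES:
                d, s = t2[(region, "deep")], t2[(region, "superficial")]
                t2vals[(region, "deep")] = d
                t2vals[(region, "superficial")] = s
                t2vals[(region, "total")] = 0.5 * (d + s)
            for comp, members in (("MFTC", ("MT", "cMF")),
                                  ("LFTC", ("LT", "cLF")),
                                  ("FTJ", PLATES)):
                for layer in ("total", "deep", "superficial"):
                    t2vals[(comp, layer)] = float(
                        np.mean([t2vals[(m, layer)] for m in members]))
            for (loc, layer), v in t2vals.items():
                rows.append({**meta, "visit": visit, "daytime_h": daytime,
                             "measure": "t2", "location": loc,
                             "layer": layer, "value": v, "units": "ms"})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# image rendering
# ---------------------------------------------------------------------------

# plate footprints for a right knee, mm: (x0, x1, y0, y1); the grid is
# mirrored along x for left knees.  Tibial cartilage grows upward from the
# tibial interface plane, femoral cartilage downward from the femoral one.
_LAYOUT_RIGHT = {
    "MT": (2.0, 30.0, 3.0, 27.0),
    "LT": (36.0, 64.0, 3.0, 27.0),
    "cMF": (2.0, 30.0, 6.0, 24.0),
    "cLF": (36.0, 64.0, 6.0, 24.0),
}
_GRID_MM = (66.0, 30.0, 14.0)
_TIBIA_INTERFACE_MM = 2.0
_FEMUR_INTERFACE_MM = 12.0


@dataclass
class SegmentedKneeImage:
    """Two echo volumes plus per-plate masks and rendering ground truth."""

    knee_id: str
    visit: str
    laterality: str
    spacing: tuple[float, float, float]
    echo1: np.ndarray
    echo2: np.ndarray
    plate_masks: dict[str, np.ndarray]
    interface_side: dict[str, str]
    # auxiliary truth recorded at render time (exact oracles for tests)
    voxel_thickness_mm: dict[str, np.ndarray] = field(default_factory=dict)
    target_thickness_mm: dict[str, np.ndarray] = field(default_factory=dict)
    atlas_labels: dict[str, np.ndarray] = field(default_factory=dict)
    true_t2_ms: dict[str, dict[str, float]] = field(default_factory=dict)

    @property
    def mask(self) -> SegmentationMask:
        return SegmentationMask(self.plate_masks, self.interface_side,
                                self.spacing, self.laterality).validate()

    def label_volume(self) -> np.ndarray:
        labels = np.zeros(self.echo1.shape, dtype=np.uint8)
        for plate, occ in self.plate_masks.items():
            labels[occ] = PLATE_CODES[plate]
        return labels


def render_knee_image(truth: KneeTruth, config: SimulationConfig,
                      visit: str = "baseline",
                      spacing: tuple[float, float, float] | None = None,
                      rng: np.random.Generator | None = None,
                      ) -> SegmentedKneeImage:
    """Voxelize one knee visit into echo volumes plus segmentation masks."""
    if visit not in VISITS:
        raise ValueError(f"visit must be one of {VISITS}")
    sp = tuple(spacing) if spacing is not None else tuple(config.voxel_spacing)
    dx, dy, dz = sp
    if rng is None:
        rng = np.random.default_rng(config.seed)
    thick = (truth.thickness_baseline_mm if visit == "baseline"
             else truth.thickness_followup_mm)
    t2 = truth.t2_baseline_ms if visit == "baseline" else truth.t2_followup_ms

    shape = (int(round(_GRID_MM[0] / dx)), int(round(_GRID_MM[1] / dy)),
             int(round(_GRID_MM[2] / dz)))
    echo1 = np.zeros(shape, dtype=np.float64)
    echo2 = np.zeros(shape, dtype=np.float64)
    plate_masks: dict[str, np.ndarray] = {}
    interface_side: dict[str, str] = {}
    voxel_thick: dict[str, np.ndarray] = {}
    target_thick: dict[str, np.ndarray] = {}
    atlas_labels: dict[str, np.ndarray] = {}

    amp_mod = config.thickness_modulation_mm
    lx, ly = config.modulation_wavelength_mm

    for plate in PLATES:
        x0, x1, y0, y1 = _LAYOUT_RIGHT[plate]
        if truth.side == "left":
            x0, x1 = _GRID_MM[0] - x1, _GRID_MM[0] - x0
        i0, i1 = int(round(x0 / dx)), int(round(x1 / dx))
        j0, j1 = int(round(y0 / dy)), int(round(y1 / dy))
        support = np.zeros(shape[:2], dtype=bool)
        support[i0:i1, j0:j1] = True
        labels2d = partition_plate(support, (dx, dy), plate, truth.side)
        atlas_labels[plate] = labels2d

        ii, jj = np.nonzero(support)
        x = (ii + 0.5) * dx
        y = (jj + 0.5) * dy
        base = np.array([thick[labels2d[a, b]] for a, b in zip(ii, jj)])
        tcol = base + amp_mod * np.sin(2 * np.pi * x / lx) * np.cos(2 * np.pi * y / ly)
        if config.thickness_smoothing_mm > 0:
            # blend the subregional plateaus into a continuous surface
            field = np.zeros((i1 - i0, j1 - j0))
            field[ii - i0, jj - j0] = tcol
            field = gaussian_filter(
                field, sigma=(config.thickness_smoothing_mm / dx,
                              config.thickness_smoothing_mm / dy),
                mode="nearest")
            tcol = field[ii - i0, jj - j0]
        if np.any(tcol < dz):
            raise ValueError(
                f"plate {plate}: column thickness below one voxel "
                f"({tcol.min():.2f} mm < {dz} mm slice spacing); "
                "use finer depth spacing")
        nvox = np.rint(tcol / dz).astype(int)

        occ = np.zeros(shape, dtype=bool)
        vt = np.full(shape[:2], np.nan)
        vt[ii, jj] = nvox * dz
        tt = np.full(shape[:2], np.nan)
        tt[ii, jj] = tcol
        target_thick[plate] = tt
        if plate in TIBIAL_PLATES:
            k0 = int(round(_TIBIA_INTERFACE_MM / dz))
            interface_side[plate] = "low"
            for a, b, n in zip(ii, jj, nvox):
                occ[a, b, k0:k0 + n] = True
        else:
            k1 = int(round(_FEMUR_INTERFACE_MM / dz))
            interface_side[plate] = "high"
            for a, b, n in zip(ii, jj, nvox):
                occ[a, b, k1 - n:k1] = True
        plate_masks[plate] = occ
        voxel_thick[plate] = vt

        # two-layer T2 field along each column
        vox = occ.nonzero()
        if plate in TIBIAL_PLATES:
            order = vox[2] - int(round(_TIBIA_INTERFACE_MM / dz))
        else:
            order = int(round(_FEMUR_INTERFACE_MM / dz)) - 1 - vox[2]
        ncol = occ.sum(axis=2)[vox[0], vox[1]]
        frac = (order + 0.5) / ncol
        t2vox = np.where(frac < 0.5, t2[(plate, "deep")],
                         t2[(plate, "superficial")])
        s1, s2 = qdess_forward(t2vox, config.tr_ms, config.te_ms,
                               config.amplitude)
        echo1[vox] = s1
        echo2[vox] = s2

    if config.noise_sd_signal:
        sd = config.noise_sd_signal * config.amplitude
        cart = np.zeros(shape, dtype=bool)
        for occ in plate_masks.values():
            cart |= occ
        echo1[cart] += rng.normal(0.0, sd, int(cart.sum()))
        echo2[cart] += rng.normal(0.0, sd, int(cart.sum()))

    return SegmentedKneeImage(
        knee_id=truth.knee_id, visit=visit, laterality=truth.side, spacing=sp,
        echo1=echo1, echo2=echo2, plate_masks=plate_masks,
        interface_side=interface_side, voxel_thickness_mm=voxel_thick,
        target_thickness_mm=target_thick, atlas_labels=atlas_labels,
        true_t2_ms={p: {"deep": t2[(p, "deep")],
                        "superficial": t2[(p, "superficial")]} for p in PLATES})


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def write_knee_image(img: SegmentedKneeImage, out_dir: str | Path) -> Path:
    """Write echo volumes, plate-label mask and a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = np.diag([*img.spacing, 1.0])
    nib.save(nib.Nifti1Image(img.echo1.astype(np.float32), affine),
             out / "echo1.nii.gz")
    nib.save(nib.Nifti1Image(img.echo2.astype(np.float32), affine),
             out / "echo2.nii.gz")
    nib.save(nib.Nifti1Image(img.label_volume(), affine), out / "mask.nii.gz")
    meta = {
        "knee_id": img.knee_id, "visit": img.visit,
        "laterality": img.laterality, "spacing": list(img.spacing),
        "interface_side": img.interface_side,
        "true_t2_ms": img.true_t2_ms,
        "true_voxelized_thickness_mm": {
            plate: {sub: float(np.nanmean(
                np.where(img.atlas_labels[plate] == sub,
                         img.voxel_thickness_mm[plate], np.nan)))
                for sub in SUBREGIONS_OF_PLATE[plate]}
            for plate in img.plate_masks},
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=1))
    return out


def read_knee_image(in_dir: str | Path
                    ) -> tuple[np.ndarray, np.ndarray, SegmentationMask, dict]:
    """Load a rendered knee: echoes, segmentation mask, sidecar metadata."""
    p = Path(in_dir)
    for fname in ("echo1.nii.gz", "echo2.nii.gz", "mask.nii.gz", "meta.json"):
        if not (p / fname).exists():
            raise FileNotFoundError(f"missing {p / fname}")
    meta = json.loads((p / "meta.json").read_text())
    echo1 = np.asarray(nib.load(p / "echo1.nii.gz").dataobj, dtype=np.float64)
    echo2 = np.asarray(nib.load(p / "echo2.nii.gz").dataobj, dtype=np.float64)
    labels = np.asarray(nib.load(p / "mask.nii.gz").dataobj).astype(np.uint8)
    mask = SegmentationMask.from_label_volume(
        labels, tuple(meta["spacing"]), meta["laterality"],
        meta["interface_side"])
    return echo1, echo2, mask, meta
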