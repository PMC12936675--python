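"""Simulation and pipeline configuration.

The defaults encode the study conditions the synthetic cohort emulates:
four demographic cells (ACL-injured and healthy, 20-30 and 40-60 years),
two knees per participant, two visits ~24 months apart, subregional
baseline cartilage thickness in the 1.5-3 mm range, 2-year thickness
changes of order -180..+90 um, and laminar T2 around 20-45 ms with a
deep < superficial gradient.  Group-level 2-year change targets are the
published estimated marginal means for each subregion (thickness, um) and
each region x layer (T2, ms).

Variance components are calibrated once so that, at the default group
sizes (34 ACL-injured / 34 contralateral / 44 healthy knees), the EMM
95 % CI half-widths are approximately 24 um (ACL groups) and 21 um
(healthy), matching the reported subregional precision:
t * sqrt((tau^2 + sigma^2)/n) with tau = 40 um, sigma = 58 um.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .regions import PLATES, SUBREGIONS


class ConfigError(ValueError):
    """Invalid configuration; the message names the offending field."""


GROUPS = ("ACL", "HEA")
AGE_GROUPS = ("20-30", "40-60")
GROUP_CELLS = (("ACL", "20-30"), ("HEA", "20-30"), ("ACL", "40-60"), ("HEA", "40-60"))

# Published cohort characteristics per cell: mean +/- SD summaries used both
# as generator parameters and as the reference for characteristic-table
# checks (SMDs).  Sex and injured-side are counts (female/male, left/right).
STUDY_CHARACTERISTICS: dict[tuple[str, str], dict[str, Any]] = {
    ("ACL", "20-30"): {
        "n": 20, "sex_fm": (11, 9), "age": (28.2, 3.0), "body_mass": (72.0, 12.8),
        "height": (172.8, 11.3), "bmi": (24.0, 2.6), "followup_months": (24.2, 1.0),
        "injured_lr": (10, 10),
    },
    ("HEA", "20-30"): {
        "n": 23, "sex_fm": (11, 12), "age": (28.6, 3.1), "body_mass": (69.3, 10.8),
        "height": (173.0, 8.7), "bmi": (23.1, 2.4), "followup_months": (24.9, 2.4),
        "injured_lr": None,
    },
    ("ACL", "40-60"): {
        "n": 14, "sex_fm": (10, 4), "age": (53.5, 5.5), "body_mass": (68.2, 12.5),
        "height": (167.1, 10.6), "bmi": (24.3, 2.6), "followup_months": (23.9, 1.6),
        "injured_lr": (9, 5),
    },
    ("HEA", "40-60"): {
        "n": 21, "sex_fm": (12, 9), "age": (51.3, 6.5), "body_mass": (70.2, 11.4),
        "height": (172.6, 9.5), "bmi": (23.7, 4.3), "followup_months": (24.3, 0.7),
        "injured_lr": None,
    },
}

# Baseline subregional thickness (mm).  Values anchored where the published
# relative changes fix them (change_um / relative_fraction), remaining
# subregions set once to plausible values in the 1.5-3.0 mm range (tibial
# central subregions thickest, exterior thinnest; femoral bands ~1.6-2.1).
DEFAULT_BASELINE_THICKNESS_MM: dict[str, float] = {
    "cMT": 2.39, "eMT": 1.60, "iMT": 1.90, "aMT": 1.80, "pMT": 1.90,
    "ccMF": 2.10, "ecMF": 1.80, "icMF": 1.90,
    "cLT": 2.60, "eLT": 1.62, "iLT": 2.19, "aLT": 1.70, "pLT": 2.00,
    "ccLF": 1.96, "ecLF": 1.44, "icLF": 1.63,
}

# True 2-year subregional thickness change (um) per analysis group.
DEFAULT_TRUE_CHANGE_UM: dict[str, dict[str, float]] = {
    "ACL_in": {
        "cMT": -12, "eMT": -13, "iMT": -39, "aMT": -34, "pMT": -19,
        "ccMF": -2, "ecMF": 21, "icMF": -32,
        "cLT": -75, "eLT": -47, "iLT": -46, "aLT": -56, "pLT": -40,
        "ccLF": -33, "ecLF": -19, "icLF": -37,
    },
    "ACL_unin": {
        "cMT": -43, "eMT": -28, "iMT": -37, "aMT": -32, "pMT": -38,
        "ccMF": -15, "ecMF": -6, "icMF": -39,
        "cLT": -35, "eLT": -18, "iLT": -46, "aLT": -21, "pLT": -35,
        "ccLF": -29, "ecLF": -17, "icLF": -49,
    },
    "HEA": {
        "cMT": -29, "eMT": -20, "iMT": -24, "aMT": -25, "pMT": -14,
        "ccMF": -36, "ecMF": -23, "icMF": -28,
        "cLT": -33, "eLT": -39, "iLT": -13, "aLT": -27, "pLT": -38,
        "ccLF": -45, "ecLF": -49, "icLF": -38,
    },
}

# Baseline laminar T2 (ms) per plate region: deep < superficial.
DEFAULT_T2_BASELINE_MS: dict[str, dict[str, float]] = {
    "MT": {"deep": 20.0, "superficial": 38.0},
    "cMF": {"deep": 22.0, "superficial": 41.0},
    "LT": {"deep": 21.5, "superficial": 38.5},
    "cLF": {"deep": 22.5, "superficial": 40.0},
}

# True 2-year laminar T2 change (ms) per region x layer x group.
DEFAULT_T2_CHANGE_MS: dict[str, dict[str, dict[str, float]]] = {
    "MT": {"deep": {"ACL_in": 0.7, "ACL_unin": 0.5, "HEA": 0.2},
           "superficial": {"ACL_in": 0.4, "ACL_unin": 0.3, "HEA": 0.0}},
    "cMF": {"deep": {"ACL_in": 0.6, "ACL_unin": 0.3, "HEA": 0.1},
            "superficial": {"ACL_in": 0.0, "ACL_unin": 0.3, "HEA": 1.6}},
    "LT": {"deep": {"ACL_in": 0.8, "ACL_unin": 0.6, "HEA": 0.3},
           "superficial": {"ACL_in": 0.3, "ACL_unin": 1.5, "HEA": 0.8}},
    "cLF": {"deep": {"ACL_in": 0.7, "ACL_unin": 0.1, "HEA": -0.1},
            "superficial": {"ACL_in": 0.3, "ACL_unin": 1.1, "HEA": 1.5}},
}


def _as_plain(obj: Any) -> Any:
    """Recursively convert dataclass / tuple structures to YAML-safe types."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _as_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _as_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_plain(v) for v in obj]
    return obj


@dataclass
class SimulationConfig:
    """All tunable parameters of the synthetic cohort.

    Units: thickness in mm where named *_mm, changes and variance components
    for thickness change in um, T2 in ms, sequence timing in ms, voxel
    spacing in mm, acquisition daytime in hours since midnight.
    """

    # cohort composition
    n_per_group: dict[str, dict[str, int]] = field(default_factory=lambda: {
        "ACL": {"20-30": 20, "40-60": 14},
        "HEA": {"20-30": 23, "40-60": 21},
    })
    age_ranges: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "20-30": (20.0, 30.0), "40-60": (40.0, 60.0),
    })
    follow_up_months: tuple[float, float] = (24.0, 1.5)  # mean, SD

    # imaging geometry / sequence (placeholder TR/TE exposed here; the
    # published protocol states only the voxel size)
    voxel_spacing: tuple[float, float, float] = (0.31, 0.31, 1.5)
    tr_ms: float = 20.0
    te_ms: float = 6.0
    amplitude: float = 1000.0
    noise_sd_signal: float = 0.01  # fraction of echo-1 amplitude

    # thickness truth
    baseline_thickness_by_subregion: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_THICKNESS_MM))
    true_change_by_group_and_subregion: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_TRUE_CHANGE_UM.items()})
    sd_baseline_mm: float = 0.25          # between-knee baseline variation
    sd_random_intercept: float = 40.0     # participant intercept, um
    sd_residual: float = 58.0             # knee x subregion residual, um

    # T2 truth
    t2_baseline_ms: dict[str, dict[str, float]] = field(
        default_factory=lambda: {r: dict(v) for r, v in DEFAULT_T2_BASELINE_MS.items()})
    t2_change_by_group_region_layer: dict[str, dict[str, dict[str, float]]] = field(
        default_factory=lambda: {r: {l: dict(g) for l, g in v.items()}
                                 for r, v in DEFAULT_T2_CHANGE_MS.items()})
    sd_t2_baseline_ms: float = 1.5
    sd_t2_intercept_ms: float = 0.5
    sd_t2_residual_ms: dict[str, float] = field(
        default_factory=lambda: {"deep": 1.3, "superficial": 3.5})

    # covariate effects on the 2-year thickness change (um scale)
    beta_age: float = -1.0        # um per year of age
    beta_daytime: float = -3.0    # um per hour of acquisition-daytime difference
    beta_baseline: float = -0.02  # um per um of baseline thickness
    daytime_window_h: tuple[float, float] = (8.0, 17.0)

    # rendered-image texture: smooth within-plate thickness modulation that
    # dithers the whole-voxel quantization of column heights
    thickness_modulation_mm: float = 0.25
    modulation_wavelength_mm: tuple[float, float] = (11.0, 7.0)
    # in-plane Gaussian smoothing of the rendered thickness field, blending
    # the subregional plateaus into a continuous surface (real cartilage has
    # no thickness steps); 0 disables
    thickness_smoothing_mm: float = 1.2

    seed: int = 0

    # ------------------------------------------------------------------
    def validate(self) -> "SimulationConfig":
        for g in GROUPS:
            if g not in self.n_per_group:
                raise ConfigError(f"n_per_group missing group {g!r}")
            for a in AGE_GROUPS:
                n = self.n_per_group[g].get(a)
                if not isinstance(n, int) or n < 0:
                    raise ConfigError(f"n_per_group[{g!r}][{a!r}] must be a count >= 0")
        for a in AGE_GROUPS:
            lo, hi = self.age_ranges[a]
            if not lo < hi:
                raise ConfigError(f"age_ranges[{a!r}] must be an increasing (lo, hi)")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ConfigError("voxel_spacing entries must be > 0")
        if not self.te_ms < self.tr_ms:
            raise ConfigError("te_ms must be smaller than tr_ms")
        if self.te_ms <= 0:
            raise ConfigError("te_ms must be > 0")
        if self.amplitude <= 0:
            raise ConfigError("amplitude must be > 0")
        for name in ("noise_sd_signal", "sd_baseline_mm", "sd_random_intercept",
                     "sd_residual", "sd_t2_baseline_ms", "sd_t2_intercept_ms",
                     "follow_up_months", "thickness_modulation_mm",
                     "thickness_smoothing_mm"):
            val = getattr(self, name)
            sd = val[1] if name == "follow_up_months" else val
            if sd < 0:
                raise ConfigError(f"{name} must be >= 0")
        for layer, sd in self.sd_t2_residual_ms.items():
            if sd < 0:
                raise ConfigError(f"sd_t2_residual_ms[{layer!r}] must be >= 0")
        missing = set(SUBREGIONS) - set(self.baseline_thickness_by_subregion)
        if missing:
            raise ConfigError(
                f"baseline_thickness_by_subregion missing labels {sorted(missing)}")
        for sub, v in self.baseline_thickness_by_subregion.items():
            if v <= 0:
                raise ConfigError(f"baseline_thickness_by_subregion[{sub!r}] must be > 0")
        for grp in ("ACL_in", "ACL_unin", "HEA"):
            table = self.true_change_by_group_and_subregion.get(grp)
            if table is None:
                raise ConfigError(f"true_change_by_group_and_subregion missing {grp!r}")
            missing = set(SUBREGIONS) - set(table)
            if missing:
                raise ConfigError(
                    f"true_change_by_group_and_subregion[{grp!r}] missing {sorted(missing)}")
        for region in PLATES:
            for layer in ("deep", "superficial"):
                if self.t2_baseline_ms[region][layer] <= 0:
                    raise ConfigError(f"t2_baseline_ms[{region!r}][{layer!r}] must be > 0")
        return self

    # ------------------------------------------------------------------
    def expected_age(self) -> float:
        """Population mean age implied by the cell sizes and age ranges
        (the centering point for the age effect)."""
        tot = n = 0.0
        for g, a in GROUP_CELLS:
            mid = 0.5 * (self.age_ranges[a][0] + self.age_ranges[a][1])
            tot += self.n_per_group[g][a] * mid
            n += self.n_per_group[g][a]
        return tot / n if n else 0.0

    def n_participants(self) -> int:
        return sum(self.n_per_group[g][a] for g, a in GROUP_CELLS)

    # ------------------------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return _as_plain(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "SimulationConfig":
        kwargs: dict[str, Any] = {}
        for f in dataclasses.fields(cls):
            if f.name in data:
                val = data[f.name]
                if f.name in ("follow_up_months", "voxel_spacing", "daytime_window_h",
                              "modulation_wavelength_mm"):
                    val = tuple(val)
                if f.name == "age_ranges":
                    val = {k: tuple(v) for k, v in val.items()}
                kwargs[f.name] = val
        return cls(**kwargs).validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class AnalysisConfig:
    """Statistical-layer settings."""

    seed: int = 0
    ci_level: float = 0.95
    sidak_k: int = 3
    bootstrap_reps: int = 200
    ov_ranks: tuple[str, ...] = ("OV1", "OV2", "OV15", "OV16")
    adjust_age: bool = True
    adjust_daytime: bool = True
    adjust_baseline: bool = True

    def validate(self) -> "AnalysisConfig":
        if not 0 < self.ci_level < 1:
            raise ConfigError("ci_level must be in (0, 1)")
        if self.sidak_k < 1:
            raise ConfigError("sidak_k must be >= 1")
        if self.bootstrap_reps < 0:
            raise ConfigError("bootstrap_reps must be >= 0")
        return self


@dataclass
class PipelineConfig:
    """End-to-end pipeline: simulation block, analysis block, and how many
    knees receive rendered image volumes (image rendering is for validating
    the imaging chain; the cohort statistics run on the measure tables)."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    n_rendered_knees: int = 4
    render_spacing: tuple[float, float, float] = (0.6, 0.6, 0.2)

    def validate(self) -> "PipelineConfig":
        self.simulation.validate()
        self.analysis.validate()
        if self.n_rendered_knees < 0:
            raise ConfigError("n_rendered_knees must be >= 0")
        if any(s <= 0 for s in self.render_spacing):
            raise ConfigError("render_spacing entries must be > 0")
        return self

    def to_dict(self) -> dict[str, Any]:
        return _as_plain(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        sim = SimulationConfig.from_dict(data.get("simulation", {}))
        ana = AnalysisConfig(**{k: tuple(v) if k == "ov_ranks" else v
                                for k, v in data.get("analysis", {}).items()})
        out = cls(simulation=sim, analysis=ana)
        if "n_rendered_knees" in data:
            out.n_rendered_knees = int(data["n_rendered_knees"])
        if "render_spacing" in data:
            out.render_spacing = tuple(data["render_spacing"])
        return out.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
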