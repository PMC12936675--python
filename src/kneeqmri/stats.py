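"""Longitudinal statistics: change scores, control-knee selection, mixed
models, estimated marginal means, Sidak-adjusted contrasts and effect sizes.

Per location (compartment, region, subregion or OV rank) the 2-year change
(follow-up mean minus baseline mean; thickness in um, T2 in ms) is modeled
with a linear mixed model

    change ~ knee_group + age + daytime_difference + baseline + (1 | participant)

fit by REML.  The random participant intercept links the injured and
contralateral knee of each ACL participant; healthy participants
contribute the one knee selected by the balanced control-knee draw.
Estimated marginal means (EMMs) are model predictions at the grand means
of the covariates over the analysis sample; their 95 % CIs and the three
pairwise contrasts use a t reference with residual degrees of freedom
(n - rank(X)), and the contrasts are Sidak-adjusted with k = 3 per
location.  A location's EMM is flagged significant iff its CI excludes 0.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .cohort import KneeTruth, ParticipantRecord
from .config import AGE_GROUPS, AnalysisConfig
from .ordered_values import rank_ov
from .regions import ANALYSIS_GROUPS, OV_LABELS, SUBREGIONS

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------

def smd(m1: float, s1: float, n1: int, m2: float, s2: float, n2: int) -> float:
    """Standardized mean difference (m1 - m2) / pooled SD.

    Pooled SD = sqrt(((n1-1) s1^2 + (n2-1) s2^2) / (n1 + n2 - 2)).
    """
    if s1 < 0 or s2 < 0:
        raise ValueError("SDs must be >= 0")
    if n1 < 2 or n2 < 2:
        raise ValueError("need n1, n2 >= 2")
    pooled = np.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2))
    if pooled == 0:
        raise ValueError("pooled SD is zero; SMD undefined")
    return float((m1 - m2) / pooled)


def sidak_adjust(p, k: int = 3):
    """Sidak multiple-comparison adjustment p_adj = 1 - (1 - p)^k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    adj = 1.0 - (1.0 - p) ** k
    return float(adj) if adj.ndim == 0 else adj


@dataclass
class PairedTestResult:
    t: float
    p: float
    n: int
    qq: pd.DataFrame          # theoretical vs sample quantiles of differences
    zero_variance: bool = False


def paired_bilateral_test(changes_left, changes_right) -> PairedTestResult:
    """Paired t-test of left vs right 2-year changes, with QQ export."""
    a = np.asarray(changes_left, dtype=float)
    b = np.asarray(changes_right, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors must be 1-D and equal length")
    if a.size < 3:
        raise ValueError("need n >= 3 pairs")
    d = a - b
    (osm, osr), _ = sps.probplot(d)
    qq = pd.DataFrame({"theoretical": osm, "sample": osr})
    if np.allclose(d, d[0]) and np.isclose(d[0], 0):
        return PairedTestResult(t=0.0, p=1.0, n=a.size, qq=qq, zero_variance=True)
    if np.allclose(d, d.mean()):
        log.warning("paired differences have zero variance")
        return PairedTestResult(t=float("nan"), p=1.0, n=a.size, qq=qq,
                                zero_variance=True)
    t, p = sps.ttest_rel(a, b)
    return PairedTestResult(t=float(t), p=float(p), n=a.size, qq=qq)


@dataclass
class CovariateScreen:
    slope: float
    intercept: float
    p: float
    se: float
    scatter: pd.DataFrame
    constant_covariate: bool = False


def screen_covariates(change, covariate) -> CovariateScreen:
    """Univariate OLS of change on one candidate covariate + scatter export."""
    y = np.asarray(change, dtype=float)
    x = np.asarray(covariate, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("change and covariate must be equal-length vectors")
    if y.size < 3:
        raise ValueError("need n >= 3")
    scatter = pd.DataFrame({"covariate": x, "change": y})
    if np.allclose(x, x[0]):
        log.warning("constant covariate; slope undefined")
        return CovariateScreen(float("nan"), float("nan"), float("nan"),
                               float("nan"), scatter, constant_covariate=True)
    res = sps.linregress(x, y)
    return CovariateScreen(slope=float(res.slope), intercept=float(res.intercept),
                           p=float(res.pvalue), se=float(res.stderr),
                           scatter=scatter)


# ---------------------------------------------------------------------------
# control-knee selection and change tables
# ---------------------------------------------------------------------------

def select_control_knee(participants: list[ParticipantRecord], seed: int
                        ) -> dict[str, str]:
    """Pick one knee per healthy participant, balancing left/right counts
    within every age-group x sex stratum.  Deterministic under ``seed``."""
    rng = np.random.default_rng(seed)
    selection: dict[str, str] = {}
    hea = sorted((p for p in participants if p.group == "HEA"), key=lambda p: p.id)
    for age_group in AGE_GROUPS:
        for sex in ("F", "M"):
            ids = [p.id for p in hea if p.age_group == age_group and p.sex == sex]
            if not ids:
                continue
            n = len(ids)
            n_left = n // 2 + (int(rng.integers(0, 2)) if n % 2 else 0)
            if n % 2:
                log.info("odd stratum (%s, %s): %d left of %d",
                         age_group, sex, n_left, n)
            order = rng.permutation(n)
            for pos, idx in enumerate(order):
                selection[ids[idx]] = "left" if pos < n_left else "right"
    return selection


def compute_change(measures: pd.DataFrame) -> pd.DataFrame:
    """Per knee x location (x layer) change table from the long measures.

    change = follow-up mean - baseline mean; thickness converted mm -> um
    (both change and the baseline covariate), T2 kept in ms.  Knees
    missing either visit are excluded with a log entry.
    """
    keys = ["participant_id", "knee_id", "role", "group", "age_group", "sex",
            "side", "age", "measure", "location", "layer"]
    piv = measures.pivot_table(index=keys, columns="visit", values="value",
                               aggfunc="first")
    if "baseline" not in piv or "followup" not in piv:
        raise ValueError("measures must contain both visits")
    incomplete = piv[piv.baseline.isna() | piv.followup.isna()]
    if len(incomplete):
        for knee in incomplete.index.get_level_values("knee_id").unique():
            log.warning("knee %s missing a visit; excluded", knee)
        piv = piv.dropna()
    day = (measures[["knee_id", "visit", "daytime_h"]].drop_duplicates()
           .pivot(index="knee_id", columns="visit", values="daytime_h"))
    daytime_diff = (day["followup"] - day["baseline"]).rename("daytime_diff_h")

    out = piv.reset_index()
    out["baseline"] = out["baseline"].astype(float)
    out["change"] = out["followup"] - out["baseline"]
    thick = out["measure"] == "thickness"
    out.loc[thick, "change"] *= 1000.0
    out.loc[thick, "baseline"] *= 1000.0
    out["units"] = np.where(thick, "um", "ms")
    out = out.merge(daytime_diff, on="knee_id", how="left")
    return out.drop(columns=["followup"])


def subregion_change_table(participants: list[ParticipantRecord],
                           truths: list[KneeTruth], subregion: str,
                           control_sides: dict[str, str]) -> pd.DataFrame:
    """One-location analysis table straight from the truth trajectories.

    Equivalent to the measures -> compute_change -> build_analysis_table
    route restricted to a single subregion; used by simulation studies
    that fit one location per replicate.
    """
    ages = {p.id: p.age for p in participants}
    rows = []
    for kt in truths:
        if kt.role.startswith("HEA") and \
                control_sides.get(kt.participant_id) != kt.side:
            continue
        rows.append({
            "participant_id": kt.participant_id,
            "knee_group": kt.analysis_group,
            "change": (kt.thickness_followup_mm[subregion]
                       - kt.thickness_baseline_mm[subregion]) * 1000.0,
            "baseline": kt.thickness_baseline_mm[subregion] * 1000.0,
            "age": ages[kt.participant_id],
            "daytime_diff_h": kt.daytime_h[1] - kt.daytime_h[0],
        })
    return pd.DataFrame(rows)


def build_analysis_table(change: pd.DataFrame,
                         control_sides: dict[str, str],
                         include_ov: bool = True) -> pd.DataFrame:
    """Restrict to the three analysis groups: both ACL knees plus the one
    selected healthy knee per participant; adds the ``knee_group`` column
    and per-knee OV rows for thickness."""
    df = change.copy()
    keep_hea = df.apply(
        lambda r: r.role.startswith("ACL")
        or control_sides.get(r.participant_id) == r.side, axis=1)
    df = df[keep_hea].copy()
    df["knee_group"] = np.where(df.role.str.startswith("HEA"), "HEA", df.role)
    if not include_ov:
        return df

    # OV rows: rank each knee's 16 subregional thickness changes
    sub = df[(df.measure == "thickness") & df.location.isin(SUBREGIONS)]
    n_incomplete = 0
    ov_rows = []
    for knee, grp in sub.groupby("knee_id"):
        if len(grp) != len(SUBREGIONS):
            n_incomplete += 1
            continue
        changes = dict(zip(grp.location, grp.change))
        baselines = dict(zip(grp.location, grp.baseline))
        ov = rank_ov(changes)
        proto = grp.iloc[0]
        for r, lab in enumerate(OV_LABELS, start=1):
            row = proto.to_dict()
            row.update(location=lab, change=ov.value(r),
                       baseline=baselines[ov.label(r)])
            ov_rows.append(row)
    if n_incomplete:
        log.info("%d knees lacked complete subregional changes; no OV rows "
                 "for them", n_incomplete)
    if ov_rows:
        df = pd.concat([df, pd.DataFrame(ov_rows)], ignore_index=True)
    return df


# ---------------------------------------------------------------------------
# mixed model, EMMs, contrasts
# ---------------------------------------------------------------------------

@dataclass
class FittedChangeModel:
    params: pd.Series
    cov: pd.DataFrame
    df_resid: int
    n_obs: int
    groups_present: tuple[str, ...]
    reference: str
    tau2: float
    sigma2: float
    converged: bool
    model_type: str               # "mixed" | "ols_fallback"
    covariate_cols: tuple[str, ...]
    df_method: str = "residual"


def fit_change_model(table: pd.DataFrame,
                     adjust_age: bool = True,
                     adjust_daytime: bool = True,
                     adjust_baseline: bool = True) -> FittedChangeModel:
    """REML linear mixed model for one location's change values.

    ``table`` needs columns change, knee_group, participant_id and the
    requested covariates (age, daytime_diff_h, baseline).  Covariates are
    centered at their sample grand means, so the intercept and group
    dummies directly give the EMMs.  Singular/non-converging fits fall
    back to an ordinary linear model (tau^2 = 0) with a warning.
    """
    df = table.copy()
    present = tuple(g for g in ANALYSIS_GROUPS if (df.knee_group == g).any())
    if len(present) < 2:
        raise ValueError("need at least two knee groups")
    if df.change.isna().any() or len(df) < len(present) + 2:
        raise ValueError("incomplete change data")
    ref = present[0]
    X = pd.DataFrame({"const": np.ones(len(df))}, index=df.index)
    for g in present[1:]:
        X[f"g_{g}"] = (df.knee_group == g).astype(float)
    cov_cols = []
    for use, col, name in ((adjust_age, "age", "age_c"),
                           (adjust_daytime, "daytime_diff_h", "dt_c"),
                           (adjust_baseline, "baseline", "base_c")):
        if use:
            if df[col].isna().any():
                raise ValueError(f"covariate {col!r} incomplete")
            X[name] = df[col] - df[col].mean()
            cov_cols.append(name)

    y = df.change.to_numpy(dtype=float)
    n, p = X.shape
    df_resid = n - p
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, X.to_numpy(), groups=df.participant_id.to_numpy())
            res = model.fit(reml=True, method=["bfgs", "powell"])
        tau2 = float(np.atleast_2d(res.cov_re)[0, 0])
        cov_fe = np.asarray(res.cov_params())[:p, :p]
        fitted = FittedChangeModel(
            params=pd.Series(np.asarray(res.fe_params), index=X.columns),
            cov=pd.DataFrame(cov_fe, index=X.columns, columns=X.columns),
            df_resid=df_resid, n_obs=n, groups_present=present, reference=ref,
            tau2=tau2, sigma2=float(res.scale), converged=bool(res.converged),
            model_type="mixed", covariate_cols=tuple(cov_cols))
        if not np.all(np.isfinite(cov_fe)) or not res.converged \
                or np.linalg.eigvalsh(cov_fe).min() <= 0:
            raise np.linalg.LinAlgError("mixed fit did not converge")
        return fitted
    except Exception as exc:  # singular fit: plain linear model, tau^2 = 0
        log.warning("mixed model fell back to OLS (%s)", exc)
        ols = sm.OLS(y, X.to_numpy()).fit()
        return FittedChangeModel(
            params=pd.Series(ols.params, index=X.columns),
            cov=pd.DataFrame(np.asarray(ols.cov_params()),
                             index=X.columns, columns=X.columns),
            df_resid=df_resid, n_obs=n, groups_present=present, reference=ref,
            tau2=0.0, sigma2=float(ols.scale), converged=True,
            model_type="ols_fallback", covariate_cols=tuple(cov_cols))


def _emm_design(fit: FittedChangeModel, group: str) -> np.ndarray:
    """Design row for a group's EMM: covariates at their grand means, which
    are exactly 0 after the centering done at fit time."""
    x = pd.Series(0.0, index=fit.params.index)
    x["const"] = 1.0
    if group != fit.reference:
        x[f"g_{group}"] = 1.0
    return x.to_numpy()


@dataclass
class EmmResult:
    """Group EMMs with CIs plus the scaffolding for contrasts."""

    frame: pd.DataFrame           # group, emm, se, lo, hi, significant, n
    fit: FittedChangeModel
    ci_level: float

    def emm(self, group: str) -> float:
        return float(self.frame.set_index("group").loc[group, "emm"])


def estimate_emms(fit: FittedChangeModel, group_ns: dict[str, int] | None = None,
                  ci_level: float = 0.95) -> EmmResult:
    """EMM per group = model prediction at grand-mean covariates; 95 % CI
    from the fixed-effect covariance with residual-df t quantiles."""
    tq = sps.t.ppf(0.5 + ci_level / 2.0, fit.df_resid)
    rows = []
    for g in fit.groups_present:
        x = _emm_design(fit, g)
        emm = float(x @ fit.params.to_numpy())
        se = float(np.sqrt(x @ fit.cov.to_numpy() @ x))
        lo, hi = emm - tq * se, emm + tq * se
        rows.append({"group": g, "emm": emm, "se": se, "lo": lo, "hi": hi,
                     "significant": bool(lo > 0 or hi < 0),
                     "n": (group_ns or {}).get(g, np.nan)})
    return EmmResult(frame=pd.DataFrame(rows), fit=fit, ci_level=ci_level)


#: the three pairwise group comparisons reported per location
CONTRAST_PAIRS = (("ACL_in", "ACL_unin"), ("ACL_in", "HEA"), ("ACL_unin", "HEA"))


def pairwise_contrasts_sidak(emms: EmmResult, k: int | None = None,
                             alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise EMM differences with Sidak-adjusted p-values.

    k defaults to the number of contrasts among the groups present
    (3 for the full design)."""
    fit = emms.fit
    pairs = [(a, b) for a, b in CONTRAST_PAIRS
             if a in fit.groups_present and b in fit.groups_present]
    if k is None:
        k = len(pairs)
    tq = sps.t.ppf(0.5 + emms.ci_level / 2.0, fit.df_resid)
    rows = []
    for a, b in pairs:
        L = _emm_design(fit, a) - _emm_design(fit, b)
        est = float(L @ fit.params.to_numpy())
        se = float(np.sqrt(L @ fit.cov.to_numpy() @ L))
        t = est / se if se > 0 else float("nan")
        p = float(2.0 * sps.t.sf(abs(t), fit.df_resid)) if se > 0 else float("nan")
        p_adj = float(sidak_adjust(p, k)) if np.isfinite(p) else float("nan")
        rows.append({"contrast": f"{a}-{b}", "estimate": est, "se": se,
                     "lo": est - tq * se, "hi": est + tq * se,
                     "t": t, "p": p, "p_sidak": p_adj,
                     "significant": bool(np.isfinite(p_adj) and p_adj < alpha)})
    return pd.DataFrame(rows)


def effect_size_d(emm_difference: float, table: pd.DataFrame,
                  group_a: str, group_b: str, n_boot: int = 200,
                  seed: int = 0) -> tuple[float, float, float]:
    """Change-score Cohen's d for one contrast with bootstrap CI.

    d = EMM difference / pooled SD of the observed changes in the two
    groups.  The CI bootstraps participants within each group and
    recomputes the raw mean-difference / pooled-SD ratio (an
    approximation that avoids refitting the mixed model per replicate).
    """
    sub = {g: table[table.knee_group == g] for g in (group_a, group_b)}
    vals = {g: s.change.to_numpy(dtype=float) for g, s in sub.items()}
    n1, n2 = len(vals[group_a]), len(vals[group_b])
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 changes per group")
    s1, s2 = vals[group_a].std(ddof=1), vals[group_b].std(ddof=1)
    pooled = np.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2))
    if pooled == 0:
        raise ValueError("degenerate (zero) pooled change SD")
    d = float(emm_difference / pooled)
    if n_boot == 0:
        return d, float("nan"), float("nan")
    rng = np.random.default_rng(seed)
    # resample at the participant level
    parts = {g: s.groupby("participant_id").change.mean() for g, s in sub.items()}
    reps = np.empty(n_boot)
    for i in range(n_boot):
        xa = parts[group_a].sample(frac=1, replace=True,
                                   random_state=rng.integers(2**31)).to_numpy()
        xb = parts[group_b].sample(frac=1, replace=True,
                                   random_state=rng.integers(2**31)).to_numpy()
        sa, sb = xa.std(ddof=1), xb.std(ddof=1)
        sp = np.sqrt(((len(xa) - 1) * sa**2 + (len(xb) - 1) * sb**2)
                     / (len(xa) + len(xb) - 2))
        reps[i] = (xa.mean() - xb.mean()) / sp if sp > 0 else np.nan
    lo, hi = np.nanpercentile(reps, [2.5, 97.5])
    return d, float(lo), float(hi)


# ---------------------------------------------------------------------------
# per-location drivers
# ---------------------------------------------------------------------------

def run_models(analysis_table: pd.DataFrame, measure: str,
               locations: list[str], layers: tuple[str, ...] = ("total",),
               cfg: AnalysisConfig | None = None,
               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit the change model at every location (x layer); tidy EMM and
    contrast frames out."""
    cfg = (cfg or AnalysisConfig()).validate()
    emm_rows, con_rows = [], []
    for loc in locations:
        for layer in layers:
            sub = analysis_table[(analysis_table.measure == measure)
                                 & (analysis_table.location == loc)
                                 & (analysis_table.layer == layer)]
            if sub.empty:
                continue
            fit = fit_change_model(sub, cfg.adjust_age, cfg.adjust_daytime,
                                   cfg.adjust_baseline)
            ns = sub.groupby("knee_group").size().to_dict()
            emms = estimate_emms(fit, group_ns=ns, ci_level=cfg.ci_level)
            ef = emms.frame.assign(location=loc, layer=layer,
                                   model=fit.model_type,
                                   df_method=fit.df_method)
            emm_rows.append(ef)
            cons = pairwise_contrasts_sidak(emms, k=cfg.sidak_k)
            ds, dlo, dhi = [], [], []
            for _, row in cons.iterrows():
                a, b = row.contrast.split("-")
                try:
                    d, lo, hi = effect_size_d(
                        row.estimate, sub, a, b, n_boot=cfg.bootstrap_reps,
                        seed=cfg.seed
                        + zlib.crc32(f"{loc}|{layer}|{row.contrast}".encode())
                        % 10_000)
                except ValueError:
                    d = lo = hi = float("nan")
                ds.append(d), dlo.append(lo), dhi.append(hi)
            cons = cons.assign(location=loc, layer=layer, d=ds, d_lo=dlo, d_hi=dhi)
            con_rows.append(cons)
    emm_df = pd.concat(emm_rows, ignore_index=True) if emm_rows else pd.DataFrame()
    con_df = pd.concat(con_rows, ignore_index=True) if con_rows else pd.DataFrame()
    return emm_df, con_df


def characteristics_table(participants: list[ParticipantRecord]) -> pd.DataFrame:
    """Cohort characteristics per cell with ACL-vs-healthy SMDs per age band."""
    df = pd.DataFrame([vars(p) for p in participants])
    df["followup_months"] = [p.visit_months[1] for p in participants]
    rows = []
    for age_group in AGE_GROUPS:
        cell = df[df.age_group == age_group]
        for var in ("age", "body_mass_kg", "height_cm", "bmi", "followup_months"):
            a = cell[cell.group == "ACL"][var]
            h = cell[cell.group == "HEA"][var]
            row = {"age_group": age_group, "variable": var,
                   "acl_mean": a.mean(), "acl_sd": a.std(ddof=1), "acl_n": len(a),
                   "hea_mean": h.mean(), "hea_sd": h.std(ddof=1), "hea_n": len(h)}
            row["smd"] = (smd(row["acl_mean"], row["acl_sd"], len(a),
                              row["hea_mean"], row["hea_sd"], len(h))
                          if len(a) >= 2 and len(h) >= 2 else float("nan"))
            rows.append(row)
    return pd.DataFrame(rows)
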