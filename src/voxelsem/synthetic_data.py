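"""Synthetic cohorts, behavior, and FA/MD volumes with known causal truth.

The generator realises the competing aging diagrams as data-generating
processes so that every downstream stage (per-voxel fitting, filtering, AIC
selection, cluster thresholding, overlap statistics) can be validated against
a known ground truth without any real data.

Construction
------------
* **Cohort** — an age-stratified sample (default three strata of 36/27/25
  subjects spanning 18-89 years) with per-stratum sex splits; ages are drawn
  uniformly within each stratum interval (a truncated-normal mode matching
  the strata's published mean/SD is available).
* **Behavior** — a latent slowing factor ``BEH_i = beta_age * age_i + e_i``
  drives task-level subject means through loadings; trial-level RTs add
  within-subject noise.  Defaults give an age-BEH correlation of about 0.6
  and between-task RT correlations around 0.7, typical magnitudes for
  speeded tasks in adult-lifespan samples.
* **Volumes** — each labelled region realises one causal diagram.  The
  target covariance of (age, BEH, WMI) under that diagram is computed in
  closed form, and the per-voxel latent ``WMI_iv`` is drawn from its exact
  conditional distribution given the subject's (age, BEH); sign-flipped FA
  and MD indicators then load on WMI with residual noise calibrated so the
  per-voxel (-FA, MD) correlation is about 0.55.  NULL regions carry pure
  noise.  By construction the population covariance in each region equals
  the model-implied covariance of the matching SEM specification.

The defaults are chosen for testability of the recovery pipeline, not as
estimates of real effect sizes (none are published for these paths).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .aging_models import ModelKind, make_aging_model
from .sem_core import SemModelSpec, implied_covariance

__all__ = [
    "AgeStratum",
    "COHORT_STRATA",
    "pooled_summary",
    "generate_cohort",
    "BehaviorParams",
    "BehaviorResult",
    "generate_behavior",
    "attach_indicators",
    "RegionParams",
    "GroundTruthSpec",
    "default_ground_truth",
    "VolumeSet",
    "generate_volumes",
    "latent_target_covariance",
    "population_covariance",
    "true_theta",
    "recovery_score",
    "RecoveryScore",
]


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AgeStratum:
    """One age band of the sampling frame.

    ``mean_age``/``sd_age`` are the band's published moments; they drive the
    truncated-normal sampling mode and the pooled-summary arithmetic.
    """

    age_min: float
    age_max: float
    n: int
    n_male: int
    n_female: int
    mean_age: float
    sd_age: float

    def __post_init__(self):
        if self.n_male + self.n_female != self.n:
            raise ValueError(
                f"stratum {self.age_min}-{self.age_max}: sex counts "
                f"{self.n_male}+{self.n_female} != n={self.n}"
            )


#: Default sampling frame: 88 adults in three age bands (36/27/25; 54 women).
COHORT_STRATA: tuple[AgeStratum, ...] = (
    AgeStratum(18, 39, 36, 17, 19, 26.69, 5.34),
    AgeStratum(40, 59, 27, 8, 19, 49.04, 6.31),
    AgeStratum(60, 89, 25, 9, 16, 68.64, 5.96),
)


def pooled_summary(strata: tuple[AgeStratum, ...] = COHORT_STRATA) -> dict:
    """Pooled cohort summary recomputed from per-stratum moments.

    Combines the strata's means and SDs exactly (law of total variance with
    N-1 denominators throughout), returning the pooled mean age, pooled SD,
    total n and total number of women.
    """
    n_total = sum(s.n for s in strata)
    mean = sum(s.n * s.mean_age for s in strata) / n_total
    ss = sum(
        (s.n - 1) * s.sd_age ** 2 + s.n * (s.mean_age - mean) ** 2 for s in strata
    )
    sd = float(np.sqrt(ss / (n_total - 1)))
    return {
        "mean_age": float(mean),
        "sd_age": sd,
        "n": int(n_total),
        "n_women": int(sum(s.n_female for s in strata)),
    }


def age_population_moments(strata: tuple[AgeStratum, ...] = COHORT_STRATA,
                           distribution: str = "uniform") -> tuple[float, float]:
    """Population mean and variance of age under the sampling scheme."""
    n_total = sum(s.n for s in strata)
    w = np.array([s.n / n_total for s in strata])
    if distribution == "uniform":
        means = np.array([(s.age_min + s.age_max) / 2 for s in strata])
        variances = np.array([(s.age_max - s.age_min) ** 2 / 12 for s in strata])
    elif distribution == "truncnorm":
        means, variances = [], []
        for s in strata:
            mu, sig = _truncnorm_params(s.age_min, s.age_max, s.mean_age,
                                        s.sd_age)
            a = (s.age_min - mu) / sig
            b = (s.age_max - mu) / sig
            m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sig,
                                         moments="mv")
            means.append(float(m))
            variances.append(float(v))
        means, variances = np.array(means), np.array(variances)
    else:
        raise ValueError(f"unknown age distribution {distribution!r}")
    mean = float(w @ means)
    var = float(w @ variances + w @ (means - mean) ** 2)
    return mean, var


def _truncnorm_params(lo: float, hi: float, mean: float, sd: float):
    """Underlying (mu, sigma) whose [lo, hi]-truncated moments match mean/sd.

    Solved by bounded least squares; when the requested sd exceeds the
    interval's uniform-limit sd of (hi - lo)/sqrt(12) no truncated normal can
    reach it and the closest attainable (near-uniform) shape is returned.
    """
    from scipy import optimize

    def resid(p):
        mu, log_sig = p
        sig = np.exp(log_sig)
        a, b = (lo - mu) / sig, (hi - mu) / sig
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sig, moments="mv")
        return [float(m) - mean, float(np.sqrt(v)) - sd]

    sol = optimize.least_squares(resid, [mean, np.log(sd)],
                                 bounds=([lo - 50, -3], [hi + 50, 5]))
    mu, log_sig = sol.x
    return float(mu), float(np.exp(log_sig))


def generate_cohort(n: int = 88,
                    strata: tuple[AgeStratum, ...] = COHORT_STRATA,
                    seed: int = 0,
                    age_distribution: str = "uniform") -> pd.DataFrame:
    """Draw a cohort with subject_id, age and sex columns.

    Ages are uniform within each stratum interval by default;
    ``age_distribution="truncnorm"`` instead matches each stratum's published
    mean/SD with a truncated normal.  ``n=0`` yields an empty cohort.
    """
    if n == 0:
        return pd.DataFrame(columns=["subject_id", "age", "sex"])
    if sum(s.n for s in strata) != n:
        raise ValueError(
            f"strata counts sum to {sum(s.n for s in strata)}, expected n={n}"
        )
    rng = np.random.default_rng(seed)
    ages, sexes = [], []
    for s in strata:
        if age_distribution == "uniform":
            a = rng.uniform(s.age_min, s.age_max, s.n)
        elif age_distribution == "truncnorm":
            mu, sig = _truncnorm_params(s.age_min, s.age_max, s.mean_age,
                                        s.sd_age)
            lo = (s.age_min - mu) / sig
            hi = (s.age_max - mu) / sig
            a = stats.truncnorm.rvs(lo, hi, loc=mu, scale=sig,
                                    size=s.n, random_state=rng)
        else:
            raise ValueError(f"unknown age distribution {age_distribution!r}")
        ages.append(a)
        sx = np.array(["M"] * s.n_male + ["F"] * s.n_female)
        rng.shuffle(sx)
        sexes.append(sx)
    cohort = pd.DataFrame({
        "subject_id": [f"sub-{i + 1:03d}" for i in range(n)],
        "age": np.concatenate(ages),
        "sex": np.concatenate(sexes),
    })
    return cohort


# ---------------------------------------------------------------------------
# Behavior
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BehaviorParams:
    """Parameters of the latent-slowing behavioral generator (units: ms).

    With the default cohort (age SD about 20 years) ``age_slope=3`` and
    ``latent_sd=80`` give cor(age, BEH) of about 0.6; loadings near 1 and
    ``unique_sd=40`` give between-task correlations around 0.7.
    """

    age_slope: float = 3.0          # ms of latent slowing per year of age
    latent_sd: float = 80.0         # residual SD of the latent factor
    loadings: dict = field(default_factory=lambda: {
        "verbal": 1.0, "spatial": 0.9, "stroop": 0.8})
    intercepts: dict = field(default_factory=lambda: {
        "verbal": 650.0, "spatial": 700.0, "stroop": 600.0})
    unique_sd: dict = field(default_factory=lambda: {
        "verbal": 40.0, "spatial": 40.0, "stroop": 40.0})
    trial_sd: float = 150.0         # within-subject trial-to-trial SD

    def __post_init__(self):
        if self.latent_sd < 0 or self.trial_sd < 0 or any(
            v < 0 for v in self.unique_sd.values()
        ):
            raise ValueError("variances must be non-negative")


@dataclass
class BehaviorResult:
    """Trial table plus the latent factor scores that generated it."""

    trials: pd.DataFrame
    latents: np.ndarray          # BEH_i, aligned with the cohort rows
    subject_means: pd.DataFrame  # per subject x task true means (pre-trial-noise)
    params: BehaviorParams


def generate_behavior(cohort: pd.DataFrame,
                      params: BehaviorParams = BehaviorParams(),
                      seed: int = 0,
                      tasks: tuple[str, ...] = ("verbal", "spatial", "stroop"),
                      ) -> BehaviorResult:
    """Generate trial-level RTs driven by a latent age-related slowing factor.

    ``BEH_i = age_slope * age_i + e_i``; each task's subject-level mean is
    ``intercept + loading * BEH_i + u_i``; trials add N(0, trial_sd) noise and
    are split over two sessions (24+24 trials for the working-memory tasks,
    48+48 for Stroop, matching the task protocol).
    """
    from .behavioral_prep import TRIALS_PER_SESSION

    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    rng = np.random.default_rng(seed)
    age = cohort["age"].to_numpy(dtype=float)
    n = age.size
    beh = params.age_slope * age + rng.normal(0.0, params.latent_sd, n)

    rows_subject, rows_trials = [], []
    for task in tasks:
        lam = params.loadings[task]
        mu = params.intercepts[task]
        u = rng.normal(0.0, params.unique_sd[task], n)
        task_mean = mu + lam * beh + u
        rows_subject.append(pd.DataFrame({
            "subject_id": cohort["subject_id"], "task": task,
            "true_mean": task_mean,
        }))
        n_per_sess = TRIALS_PER_SESSION[task]
        for sess in (1, 2):
            noise = rng.normal(0.0, params.trial_sd, (n, n_per_sess))
            rts = task_mean[:, None] + noise
            rows_trials.append(pd.DataFrame({
                "subject_id": np.repeat(cohort["subject_id"].to_numpy(), n_per_sess),
                "task": task,
                "session": sess,
                "trial_index": np.tile(np.arange(1, n_per_sess + 1), n),
                "rt": rts.ravel(),
            }))
    trials = pd.concat(rows_trials, ignore_index=True)
    if (trials["rt"] <= 0).any():
        # keep the trial table valid; with default parameters this clips
        # essentially nothing (means are ~500-1000 ms, trial SD 150 ms)
        n_bad = int((trials["rt"] <= 0).sum())
        if n_bad / len(trials) > 1e-3:
            warnings.warn(f"{n_bad} non-positive RTs clipped to 1 ms")
        trials.loc[trials["rt"] <= 0, "rt"] = 1.0
    return BehaviorResult(trials=trials, latents=beh,
                          subject_means=pd.concat(rows_subject, ignore_index=True),
                          params=params)


def attach_indicators(cohort: pd.DataFrame, trials: pd.DataFrame) -> pd.DataFrame:
    """Merge per-task mean RTs (over all trials) into the cohort table."""
    from .behavioral_prep import subject_indicator

    wide = subject_indicator(trials)
    merged = cohort.merge(wide, on="subject_id", how="left", validate="1:1")
    if merged[[c for c in wide.columns if c != "subject_id"]].isna().any().any():
        raise ValueError("trial table does not cover every cohort subject")
    return merged


# ---------------------------------------------------------------------------
# Ground truth and volumes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionParams:
    """True parameters of one region's data-generating process.

    The structural effect sizes are expressed as target correlations, which
    fixes the latent path coefficients given the cohort's age variance and
    the behavioral parameters:

    * ``age_wmi_corr`` — cor(age, WMI); used by the independent-factor and
      brain-mediation diagrams.
    * ``beh_wmi_corr`` — cor(BEH, WMI); used by cognitive mediation.
    * ``partial_corr`` — cor(BEH, WMI | age); used by the common-factor
      diagram (its age links are inherited from the behavior generator and
      ``age_wmi_corr``).

    Indicator residual SDs of 0.905 against a unit-variance WMI give each
    indicator a reliability of 0.55 and hence a (-FA, MD) correlation of
    0.55, the generator's target.
    """

    age_wmi_corr: float = 0.5
    beh_wmi_corr: float = 0.5
    partial_corr: float = 0.4
    wmi_sd: float = 1.0
    fa_loading: float = 1.0
    md_loading: float = 1.0
    fa_resid_sd: float = 0.905
    md_resid_sd: float = 0.905
    fa_baseline: float = 0.55
    fa_scale: float = 0.03
    md_baseline: float = 0.80
    md_scale: float = 0.05


@dataclass(frozen=True)
class GroundTruthSpec:
    """Region labels plus the generating model and parameters per region."""

    region_labels: np.ndarray                       # 3-D int volume
    region_model: dict                              # label -> ModelKind | None
    region_params: dict                             # label -> RegionParams

    def __post_init__(self):
        labels = set(np.unique(self.region_labels).tolist())
        for lab in labels:
            if lab not in self.region_model:
                raise ValueError(f"region label {lab} has no model assigned")
            if lab not in self.region_params:
                raise ValueError(f"region label {lab} has no parameters")


def default_ground_truth(shape: tuple[int, int, int] = (24, 24, 12),
                         params: RegionParams = RegionParams()) -> GroundTruthSpec:
    """Three equal axial slabs: NULL, independent factor, cognitive mediation.

    The slab geometry gives every region a few thousand voxels — enough for
    stable recovery rates and for cluster-extent thresholding tests while
    staying minutes-scale on one CPU.
    """
    labels = np.zeros(shape, dtype=np.int32)
    z = shape[2]
    thirds = [0, z // 3, 2 * z // 3, z]
    for lab, (z0, z1) in enumerate(zip(thirds[:-1], thirds[1:]), start=1):
        labels[:, :, z0:z1] = lab
    return GroundTruthSpec(
        region_labels=labels,
        region_model={1: None, 2: ModelKind.INDEPENDENT_FACTOR,
                      3: ModelKind.COGNITIVE_MEDIATION},
        region_params={1: params, 2: params, 3: params},
    )


@dataclass
class VolumeSet:
    """Per-subject FA and MD stacks on a common grid (subject axis last)."""

    fa: np.ndarray
    md: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        if self.fa.shape != self.md.shape:
            raise ValueError("FA and MD stacks must share one shape")

    @property
    def voxel_volume(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def n_subjects(self) -> int:
        return self.fa.shape[-1]


def latent_target_covariance(kind: ModelKind | None,
                             params: RegionParams,
                             behavior: BehaviorParams,
                             age_var: float) -> np.ndarray:
    """Population covariance of (age, BEH, WMI) under one causal diagram.

    The age-BEH block is fixed by the behavior generator; the diagram then
    determines cov(age, WMI) and cov(BEH, WMI):

    * NULL — both zero.
    * independent factor — WMI tracks age only, so cov(BEH, WMI) is purely
      age-shared: c_bw = c_ab * c_aw / var(age).
    * cognitive mediation — WMI = b*BEH + w, so c_bw = b*var(BEH) and
      c_aw = b*c_ab.
    * brain mediation — BEH is independent of age given WMI, so
      c_ab = c_aw * c_bw / var(WMI); c_aw is set by ``age_wmi_corr`` and
      c_bw follows (feasibility requires age_wmi_corr >= cor(age, BEH)).
    * common factor — age links as under independence plus a positive
      residual association cor(BEH, WMI | age) = ``partial_corr``.
    """
    va = age_var
    c_ab = behavior.age_slope * va
    var_b = behavior.age_slope ** 2 * va + behavior.latent_sd ** 2
    var_w = params.wmi_sd ** 2
    sd_a, sd_b, sd_w = np.sqrt(va), np.sqrt(var_b), np.sqrt(var_w)

    if kind is None:
        c_aw = c_bw = 0.0
    elif kind is ModelKind.INDEPENDENT_FACTOR:
        c_aw = params.age_wmi_corr * sd_a * sd_w
        c_bw = c_ab * c_aw / va
    elif kind is ModelKind.COGNITIVE_MEDIATION:
        b = params.beh_wmi_corr * sd_w / sd_b
        c_bw = b * var_b
        c_aw = b * c_ab
    elif kind is ModelKind.BRAIN_MEDIATION:
        r_ab = c_ab / (sd_a * sd_b)
        if params.age_wmi_corr <= r_ab:
            raise ValueError(
                f"full brain mediation needs cor(age, WMI) > cor(age, BEH)="
                f"{r_ab:.3f}; got {params.age_wmi_corr}"
            )
        c_aw = params.age_wmi_corr * sd_a * sd_w
        c_bw = c_ab * var_w / c_aw
    elif kind is ModelKind.COMMON_FACTOR:
        c_aw = params.age_wmi_corr * sd_a * sd_w
        resid_b = np.sqrt(var_b - c_ab ** 2 / va)
        resid_w = np.sqrt(var_w - c_aw ** 2 / va)
        c_bw = c_ab * c_aw / va + params.partial_corr * resid_b * resid_w
    else:
        raise ValueError(f"{kind} is not a generating model")

    sigma = np.array([
        [va, c_ab, c_aw],
        [c_ab, var_b, c_bw],
        [c_aw, c_bw, var_w],
    ])
    if np.linalg.eigvalsh(sigma)[0] <= 0:
        raise ValueError(f"infeasible parameter combination for {kind}: "
                         "latent covariance not positive definite")
    return sigma


def generate_volumes(cohort: pd.DataFrame,
                     behavior: BehaviorResult,
                     ground_truth: GroundTruthSpec,
                     seed: int = 0,
                     affine: np.ndarray | None = None,
                     age_var: float | None = None) -> VolumeSet:
    """Generate 4-D FA and MD stacks whose voxels obey the region's diagram.

    Per voxel the latent WMI is drawn from its exact conditional distribution
    given the subject's (age, BEH) under the region's target covariance, so
    the population covariance per voxel equals the diagram's.  FA is written
    as ``clip(fa_baseline - fa_scale * negFA, 0, 1)`` (so that raw FA
    anti-correlates with MD) and MD as ``md_baseline + md_scale * MD``.
    """
    if affine is None:
        affine = np.eye(4)
    rng = np.random.default_rng(seed)
    labels = ground_truth.region_labels
    shape = labels.shape
    n = len(cohort)
    if n != behavior.latents.size:
        raise ValueError("behavior latents do not match cohort size")
    age = cohort["age"].to_numpy(dtype=float)
    beh = behavior.latents
    x = np.column_stack([age - age.mean(), beh - beh.mean()])

    fa = np.empty(shape + (n,))
    md = np.empty(shape + (n,))
    if age_var is None:  # default sampling frame; pass age_var for custom strata
        _, age_var = age_population_moments()
    clipped = 0
    for lab in np.unique(labels):
        kind = ground_truth.region_model[lab]
        par = ground_truth.region_params[lab]
        sigma = latent_target_covariance(kind, par, behavior.params, age_var)
        # conditional law of WMI given (age, BEH)
        sxx = sigma[:2, :2]
        sxw = sigma[:2, 2]
        coef = np.linalg.solve(sxx, sxw)
        cond_var = sigma[2, 2] - sxw @ coef
        cond_sd = np.sqrt(max(cond_var, 0.0))
        mean_w = x @ coef                     # per subject, shared in region
        mask = labels == lab
        n_vox = int(mask.sum())
        wmi = mean_w[None, :] + rng.normal(0.0, cond_sd, (n_vox, n))
        neg_fa = par.fa_loading * wmi + rng.normal(0.0, par.fa_resid_sd, (n_vox, n))
        md_raw = par.md_loading * wmi + rng.normal(0.0, par.md_resid_sd, (n_vox, n))
        fa_vals = par.fa_baseline - par.fa_scale * neg_fa
        clipped += int(np.sum((fa_vals < 0) | (fa_vals > 1)))
        fa[mask] = np.clip(fa_vals, 0.0, 1.0)
        md[mask] = par.md_baseline + par.md_scale * md_raw
    frac = clipped / fa.size
    if frac > 1e-3:
        warnings.warn(f"FA clipping affected {frac:.2%} of values; "
                      "reconsider fa_baseline/fa_scale")
    return VolumeSet(fa=fa, md=md, affine=affine)


# ---------------------------------------------------------------------------
# Generator <-> engine shared algebra
# ---------------------------------------------------------------------------

def true_theta(kind: ModelKind, params: RegionParams,
               behavior: BehaviorParams, age_var: float,
               n_behavior_indicators: int = 2) -> tuple[SemModelSpec, np.ndarray]:
    """The SEM spec matching one generating diagram and its true parameters.

    The returned theta reproduces, through the engine's RAM algebra, the
    generator's population covariance of (age, RTs..., negFA, MD) on the raw
    measurement scale (RT task means including trial-mean noise; indicator
    units of the WMI scale).  Intercepts drop out of covariances.
    """
    from .behavioral_prep import TRIALS_PER_SESSION

    sigma_l = latent_target_covariance(kind, params, behavior, age_var)
    va, c_ab, c_aw = sigma_l[0]
    var_b, c_bw, var_w = sigma_l[1, 1], sigma_l[1, 2], sigma_l[2, 2]

    spec = make_aging_model(kind, n_behavior_indicators)
    tasks = ["verbal", "spatial", "stroop"][:n_behavior_indicators]
    # RT indicators: loading lam on BEH; unique variance + trial-mean noise.
    lam1 = behavior.loadings[tasks[0]]
    theta = {}
    for task, rt_name in zip(tasks, ["rt_verbal", "rt_visuospatial", "rt_stroop"]):
        lam = behavior.loadings[task]
        trial_var = behavior.trial_sd ** 2 / (2 * TRIALS_PER_SESSION[task])
        if rt_name != "rt_verbal":
            theta[f"l_{rt_name}"] = lam / lam1
        theta[f"e_{rt_name}"] = behavior.unique_sd[task] ** 2 + trial_var
    # the model's BEH latent is lam1 * (generator BEH): rescale its moments
    var_b_m = lam1 ** 2 * var_b
    c_ab_m = lam1 * c_ab
    c_bw_m = lam1 * c_bw
    theta["l_md"] = params.md_loading / params.fa_loading
    theta["e_neg_fa"] = params.fa_resid_sd ** 2
    theta["e_md"] = params.md_resid_sd ** 2
    # likewise WMI latent is fa_loading * WMI
    var_w_m = params.fa_loading ** 2 * var_w
    c_aw_m = params.fa_loading * c_aw
    c_bw_m = c_bw_m * params.fa_loading
    theta["v_age"] = va

    if kind is ModelKind.INDEPENDENT_FACTOR:
        theta["age_to_beh"] = c_ab_m / va
        theta["age_to_wmi"] = c_aw_m / va
        theta["v_beh"] = var_b_m - c_ab_m ** 2 / va
        theta["v_wmi"] = var_w_m - c_aw_m ** 2 / va
    elif kind is ModelKind.COGNITIVE_MEDIATION:
        b = c_bw_m / var_b_m
        theta["age_to_beh"] = c_ab_m / va
        theta["beh_to_wmi"] = b
        theta["v_beh"] = var_b_m - c_ab_m ** 2 / va
        theta["v_wmi"] = var_w_m - b ** 2 * var_b_m
    elif kind is ModelKind.BRAIN_MEDIATION:
        b = c_bw_m / var_w_m
        theta["age_to_wmi"] = c_aw_m / va
        theta["wmi_to_beh"] = b
        theta["v_wmi"] = var_w_m - c_aw_m ** 2 / va
        theta["v_beh"] = var_b_m - b ** 2 * var_w_m
    elif kind is ModelKind.COMMON_FACTOR:
        # g has unit residual variance; solve the three paths
        pi = c_bw_m - c_ab_m * c_aw_m / va   # residual (partial) covariance
        if pi <= 0:
            raise ValueError("common-factor diagram needs a positive "
                             "residual BEH-WMI association")
        g1 = np.sqrt(pi * c_ab_m / c_aw_m)
        g2 = pi / g1
        gamma = c_ab_m / (g1 * va)
        var_g = gamma ** 2 * va + 1.0
        theta["age_to_g"] = gamma
        theta["g_to_beh"] = g1
        theta["g_to_wmi"] = g2
        theta["v_beh"] = var_b_m - g1 ** 2 * var_g
        theta["v_wmi"] = var_w_m - g2 ** 2 * var_g
    else:
        raise ValueError(f"{kind} has no aging-model counterpart")
    vec = np.array([theta[p] for p in spec.param_ids])
    return spec, vec


def population_covariance(kind: ModelKind, params: RegionParams,
                          behavior: BehaviorParams, age_var: float,
                          n_behavior_indicators: int = 2) -> tuple[np.ndarray, tuple]:
    """Observed-variable population covariance implied by generator settings."""
    spec, theta = true_theta(kind, params, behavior, age_var,
                             n_behavior_indicators)
    return implied_covariance(spec, theta), spec.observed


# ---------------------------------------------------------------------------
# Recovery scoring
# ---------------------------------------------------------------------------

@dataclass
class RecoveryScore:
    """Confusion table of selected model codes against generating regions."""

    confusion: pd.DataFrame      # rows: true region model, cols: selected label
    accuracy: dict               # ModelKind -> fraction of its voxels recovered

    def false_assignment_rate(self, kinds, regions) -> float:
        """Fraction of voxels in the given true regions assigned to ``kinds``.

        ``regions`` are row labels of the confusion table ("null" or a model
        value name); ``kinds`` are ModelKinds counted as false assignments.
        """
        from .aging_models import MODEL_CODES, CODE_LABELS

        rows = self.confusion.loc[list(regions)]
        bad_cols = [CODE_LABELS[MODEL_CODES[k]] for k in kinds]
        return float(rows[bad_cols].to_numpy().sum() / rows.to_numpy().sum())


def recovery_score(selection_map: np.ndarray,
                   ground_truth: GroundTruthSpec) -> RecoveryScore:
    """Score a selection map against the generating ground truth.

    Rows of the confusion table are generating regions (by model, "null" for
    noise regions); columns are the selected-model labels including
    "unclassified".  Accuracy per generating model is the fraction of its
    voxels whose winner matches.
    """
    from .aging_models import CODE_LABELS, MODEL_CODES

    labels = ground_truth.region_labels
    if selection_map.shape != labels.shape:
        raise ValueError(
            f"selection map shape {selection_map.shape} does not match "
            f"ground truth {labels.shape}"
        )
    col_names = [CODE_LABELS[c] for c in sorted(CODE_LABELS)]
    rows = {}
    for lab in np.unique(labels):
        kind = ground_truth.region_model[lab]
        row_name = "null" if kind is None else kind.value
        sel = selection_map[labels == lab]
        counts = np.array([(sel == c).sum() for c in sorted(CODE_LABELS)])
        if row_name in rows:
            rows[row_name] += counts
        else:
            rows[row_name] = counts
    confusion = pd.DataFrame.from_dict(rows, orient="index", columns=col_names)
    accuracy = {}
    for kind, code in MODEL_CODES.items():
        if kind.value in confusion.index:
            row = confusion.loc[kind.value]
            accuracy[kind] = float(row[CODE_LABELS[code]] / row.sum())
    return RecoveryScore(confusion=confusion, accuracy=accuracy)
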