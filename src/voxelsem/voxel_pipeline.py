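"""End-to-end per-voxel procedure: mask, transform, fit, filter, select, map.

The pipeline mirrors the voxel-wise SEM workflow for DTI aging data:

1. keep only voxels with FA > 0.2 in *every* subject (the white-matter
   "skeleton" in the strict conjunction sense — no projection);
2. per voxel, assemble (age, RT indicators, -FA, MD), min-max scale each
   column to [0, 10] (the sign flip makes FA co-vary positively with MD, and
   the scaling puts every variable in a predictable range for the fixed
   starting values; the chi-square itself is scale-invariant);
3. fit the requested aging models on one shared sample covariance;
4. keep a model only when its fit converged cleanly (GREEN), its chi-square
   fit p-value exceeds 0.05, and its latent correlations lie inside [-1, 1]
   (Heywood screen);
5. assign the voxel to the eligible model with the lowest AIC (chi2 - 2 df;
   exact ties: larger df, then a fixed preference order), 0 if none;
6. optionally cluster-threshold maps by physical extent (mm^3) and summarise
   as overlap percentages and atlas-label conjunctions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from . import sem_core
from .aging_models import (
    CODE_LABELS,
    MODEL_CODES,
    TIE_ORDER,
    ModelKind,
    behavior_indicators,
    make_aging_model,
    make_simple_model,
    restrict_path,
)
from .sem_core import (
    DegenerateInputError,
    FitStatus,
    SemFitResult,
    build_covariance,
    chi_square_difference,
    fit_sem,
)

__all__ = [
    "SkeletonMask",
    "VoxelSelectionMap",
    "skeleton_mask",
    "prepare_voxel",
    "fit_voxel",
    "select_model",
    "run_selection",
    "path_significance_map",
    "cluster_threshold",
    "overlap_statistic",
    "overlap_table",
    "conjunction_with_labels",
    "fa_md_correlation_map",
]

FA_SKELETON_THRESHOLD = 0.2
FIT_P_THRESHOLD = 0.05
DEFAULT_MODEL_SET = (
    ModelKind.BRAIN_MEDIATION,
    ModelKind.COGNITIVE_MEDIATION,
    ModelKind.INDEPENDENT_FACTOR,
    ModelKind.COMMON_FACTOR,
)

_STATUS_CODE = {FitStatus.GREEN: 1, FitStatus.BLUE: 2, FitStatus.RED: 3}


@dataclass(frozen=True)
class SkeletonMask:
    """Voxels with FA above threshold in every subject."""

    mask: np.ndarray
    threshold: float

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class VoxelSelectionMap:
    """Winning-model labels plus the winner's fit diagnostics per voxel.

    ``selected`` holds the model codes (0 = unclassified); the diagnostic
    volumes describe the winning fit (NaN where unclassified).  ``per_model``
    maps each fitted kind to its own chi2/p/aic/latent-corr/status volumes,
    supporting per-model map export and the suspect-voxel histograms.
    """

    selected: np.ndarray
    aic: np.ndarray
    chi_square: np.ndarray
    p_value: np.ndarray
    latent_corr: np.ndarray
    status: np.ndarray
    skeleton: SkeletonMask
    per_model: dict = field(default_factory=dict)
    n_indicators: int = 2


def skeleton_mask(fa_stack: np.ndarray,
                  threshold: float = FA_SKELETON_THRESHOLD) -> SkeletonMask:
    """Strict conjunction mask: FA > threshold for all subjects at a voxel."""
    fa = np.asarray(fa_stack)
    if fa.ndim != 4:
        raise ValueError(f"FA stack must be 4-D (x, y, z, subject), got {fa.ndim}-D")
    mask = (fa > threshold).all(axis=-1)
    if not mask.any():
        warnings.warn("skeleton mask is empty: no voxel exceeds the FA "
                      f"threshold {threshold} in all subjects")
    return SkeletonMask(mask=mask, threshold=threshold)


def _minmax_scale(x: np.ndarray, name: str) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise DegenerateInputError(f"constant column {name!r} at this voxel")
    return (x - lo) / (hi - lo) * 10.0


def prepare_voxel(fa_values: np.ndarray, md_values: np.ndarray,
                  cohort: pd.DataFrame,
                  n_indicators: int = 2) -> tuple[np.ndarray, list[str]]:
    """Per-voxel data matrix: (age, RTs, -FA, MD), each scaled to [0, 10].

    The FA sign flip precedes the scaling, so a positive scaled age-FA
    correlation reads as diffusivity increasing with age.  A constant column
    marks the voxel unfittable (degenerate-input error).
    """
    rts = behavior_indicators(n_indicators)
    names = ["age"] + rts + ["neg_fa", "md"]
    cols = [cohort["age"].to_numpy(dtype=float)]
    cols += [cohort[rt].to_numpy(dtype=float) for rt in rts]
    cols += [-np.asarray(fa_values, dtype=float), np.asarray(md_values, dtype=float)]
    n = len(cohort)
    if any(c.shape != (n,) for c in cols):
        raise ValueError("per-voxel values do not match the cohort size")
    data = np.column_stack([_minmax_scale(c, nm) for c, nm in zip(cols, names)])
    return data, names


def _red_placeholder(spec, n_subjects: int, message: str) -> SemFitResult:
    """Ineligible stand-in for a voxel/model combination that failed hard."""
    return SemFitResult(
        spec=spec, theta_hat=np.full(spec.n_free, np.nan), f_ml=np.nan,
        chi_square=np.nan, df=spec.df, p_value=0.0, aic=np.inf,
        status=FitStatus.RED, latent_corr={}, n_subjects=n_subjects,
        message=message,
    )


def fit_voxel(data_matrix: np.ndarray, specs: dict,
              names: list[str] | None = None) -> dict:
    """Fit every requested model on one shared sample covariance.

    Engine failures are captured as RED placeholder results so a voxel loop
    tallies problems instead of aborting.
    """
    n = data_matrix.shape[0]
    try:
        cov = build_covariance(
            data_matrix,
            list(names) if names is not None else None,
        )
    except sem_core.SemError as exc:
        return {k: _red_placeholder(s, n, str(exc)) for k, s in specs.items()}
    out = {}
    for key, spec in specs.items():
        try:
            out[key] = fit_sem(spec, cov)
        except sem_core.SemError as exc:
            out[key] = _red_placeholder(spec, n, str(exc))
    return out


def select_model(fits: dict, p_threshold: float = FIT_P_THRESHOLD,
                 ) -> tuple[int, dict]:
    """AIC selection among eligible fits.

    Eligibility: GREEN convergence, fit p > p_threshold, and all latent
    correlations finite within [-1, 1].  The winner is the eligible model
    with the lowest AIC; exact AIC ties go to the larger-df (more
    parsimonious) model, then to a fixed preference order.  Returns
    (0, diagnostics) when no model is eligible.
    """
    eligible = {}
    for kind, fit in fits.items():
        ok = (
            fit.status is FitStatus.GREEN
            and fit.p_value > p_threshold
            and fit.max_abs_latent_corr <= 1.0
        )
        if ok:
            eligible[kind] = fit
    diagnostics = {
        "eligible": sorted(k.value for k in eligible),
        "n_red": sum(f.status is FitStatus.RED for f in fits.values()),
        "n_blue": sum(f.status is FitStatus.BLUE for f in fits.values()),
    }
    if not eligible:
        return 0, diagnostics
    order = {k: i for i, k in enumerate(TIE_ORDER)}
    winner = min(
        eligible,
        key=lambda k: (eligible[k].aic, -eligible[k].df, order.get(k, 99)),
    )
    ties = [k for k in eligible
            if eligible[k].aic == eligible[winner].aic and k is not winner]
    if ties:
        diagnostics["tie_broken_against"] = sorted(k.value for k in ties)
    return MODEL_CODES[winner], diagnostics


def run_selection(volumes, cohort: pd.DataFrame,
                  kinds: tuple = DEFAULT_MODEL_SET,
                  n_indicators: int = 2,
                  p_threshold: float = FIT_P_THRESHOLD,
                  fa_threshold: float = FA_SKELETON_THRESHOLD,
                  ) -> VoxelSelectionMap:
    """Full per-voxel model comparison over the skeleton.

    ``volumes`` provides 4-D ``fa`` and ``md`` stacks (subject axis last)
    aligned with the cohort rows.  Voxels outside the skeleton, or whose
    every model fails the filters, carry 0 in the selection map.
    """
    fa, md = volumes.fa, volumes.md
    if fa.shape[-1] != len(cohort):
        raise ValueError(
            f"{fa.shape[-1]} volume frames vs {len(cohort)} cohort rows"
        )
    skel = skeleton_mask(fa, fa_threshold)
    shape = skel.mask.shape
    specs = {k: make_aging_model(k, n_indicators) for k in kinds}

    selected = np.zeros(shape, dtype=np.int16)
    nanvol = lambda: np.full(shape, np.nan)
    win_aic, win_chi2, win_p, win_corr = nanvol(), nanvol(), nanvol(), nanvol()
    win_status = np.zeros(shape, dtype=np.int8)
    per_model = {
        k: {"chi_square": nanvol(), "p_value": nanvol(), "aic": nanvol(),
            "latent_corr": nanvol(),
            "status": np.zeros(shape, dtype=np.int8)}
        for k in kinds
    }

    for idx in np.argwhere(skel.mask):
        i, j, k = idx
        try:
            data, names = prepare_voxel(fa[i, j, k], md[i, j, k], cohort,
                                        n_indicators)
        except DegenerateInputError:
            continue  # unfittable voxel stays 0, like a RED voxel
        fits = fit_voxel(data, specs, names)
        for kind, fit in fits.items():
            maps = per_model[kind]
            maps["chi_square"][i, j, k] = fit.chi_square
            maps["p_value"][i, j, k] = fit.p_value
            maps["aic"][i, j, k] = fit.aic
            maps["latent_corr"][i, j, k] = fit.max_abs_latent_corr
            maps["status"][i, j, k] = _STATUS_CODE[fit.status]
        code, _ = select_model(fits, p_threshold)
        if code:
            win = fits[[k for k, c in MODEL_CODES.items() if c == code][0]]
            selected[i, j, k] = code
            win_aic[i, j, k] = win.aic
            win_chi2[i, j, k] = win.chi_square
            win_p[i, j, k] = win.p_value
            win_corr[i, j, k] = win.max_abs_latent_corr
            win_status[i, j, k] = _STATUS_CODE[win.status]

    return VoxelSelectionMap(
        selected=selected, aic=win_aic, chi_square=win_chi2, p_value=win_p,
        latent_corr=win_corr, status=win_status, skeleton=skel,
        per_model=per_model, n_indicators=n_indicators,
    )


def path_significance_map(volumes, cohort: pd.DataFrame,
                          kind: ModelKind | str,
                          n_indicators: int = 2,
                          fa_threshold: float = FA_SKELETON_THRESHOLD,
                          ) -> tuple[np.ndarray, SkeletonMask]:
    """Voxel-wise chi-square difference map for the latent path "a".

    Fits the simple model (age->WMI or BEH->WMI) with the path free and with
    it fixed to zero, and maps the 1-df chi-square difference.  Voxels whose
    full-model fit is RED (or unfittable) carry 0.
    """
    if isinstance(kind, str):
        kind = ModelKind.from_name(kind)
    full = make_simple_model(kind, n_indicators)
    restricted = restrict_path(full, "a")
    skel = skeleton_mask(volumes.fa, fa_threshold)
    delta = np.zeros(skel.mask.shape)

    use_cols = list(full.observed)
    rts = behavior_indicators(n_indicators)
    for idx in np.argwhere(skel.mask):
        i, j, k = idx
        try:
            data, names = prepare_voxel(volumes.fa[i, j, k], volumes.md[i, j, k],
                                        cohort, n_indicators)
        except DegenerateInputError:
            continue
        sub = [names.index(c) for c in use_cols]
        fits = fit_voxel(data[:, sub], {"full": full, "restricted": restricted},
                         use_cols)
        if any(f.status is FitStatus.RED for f in fits.values()):
            continue
        d, _, _ = chi_square_difference(fits["full"], fits["restricted"])
        delta[i, j, k] = d
    return delta, skel


_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


def cluster_threshold(label_map: np.ndarray, min_volume_mm3: float,
                      voxel_volume: float = 1.0,
                      connectivity: int = 26) -> np.ndarray:
    """Remove connected components smaller than a physical extent.

    Components are computed per model label separately (26-connectivity by
    default; 6 and 18 available) and zeroed when their volume in mm^3 falls
    below ``min_volume_mm3`` (strictly; an exactly threshold-sized cluster
    survives).
    """
    if min_volume_mm3 <= 0:
        raise ValueError("cluster threshold must be positive")
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError(f"connectivity must be one of {sorted(_CONNECTIVITY_RANK)}")
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    out = np.asarray(label_map).copy()
    for lab in np.unique(out):
        if lab == 0:
            continue
        comp, n_comp = ndimage.label(out == lab, structure=structure)
        sizes = np.bincount(comp.ravel())
        kill = np.nonzero(sizes * voxel_volume < min_volume_mm3)[0]
        kill = kill[kill > 0]
        if len(kill):
            out[np.isin(comp, kill)] = 0
    return out


def overlap_statistic(selection_map: np.ndarray, skeleton: SkeletonMask,
                      model_code: int) -> float:
    """Percentage of skeleton voxels detected by one model.

    ``overlap = (number of detected voxels / number of skeleton voxels) * 100``.
    """
    n_skel = skeleton.n_voxels
    if n_skel == 0:
        raise ValueError("empty skeleton: overlap undefined")
    detected = int(((selection_map == model_code) & skeleton.mask).sum())
    return 100.0 * detected / n_skel


def overlap_table(selection_map: np.ndarray, skeleton: SkeletonMask) -> pd.DataFrame:
    """Overlap percentages for every model code plus unclassified.

    The rows partition the skeleton, so the percentages sum to 100.
    """
    rows = [
        {"code": code, "model": CODE_LABELS[code],
         "overlap_pct": overlap_statistic(selection_map, skeleton, code)}
        for code in sorted(CODE_LABELS)
    ]
    return pd.DataFrame(rows)


def conjunction_with_labels(selection_map: np.ndarray, label_volume: np.ndarray,
                            model_code: int) -> pd.DataFrame:
    """Per-atlas-label counts of voxels selected by one model.

    Returns a frame (label, n_voxels) sorted descending, supporting
    "top structures" reports against a tract atlas.
    """
    labels = np.asarray(label_volume)
    if labels.shape != selection_map.shape:
        raise ValueError(
            f"label volume shape {labels.shape} does not match map "
            f"{selection_map.shape}"
        )
    hit = selection_map == model_code
    present = np.unique(labels[(labels != 0)])
    rows = [
        {"label": int(lab), "n_voxels": int((hit & (labels == lab)).sum())}
        for lab in present
    ]
    frame = pd.DataFrame(rows, columns=["label", "n_voxels"])
    return frame.sort_values(["n_voxels", "label"],
                             ascending=[False, True]).reset_index(drop=True)


def fa_md_correlation_map(fa_stack: np.ndarray, md_stack: np.ndarray,
                          skeleton: SkeletonMask,
                          ) -> tuple[np.ndarray, float, np.ndarray, np.ndarray]:
    """Per-voxel Pearson r between -FA and MD across subjects.

    Returns (r volume with NaN outside the skeleton or where undefined,
    median r over defined voxels, histogram counts, bin edges).
    """
    fa = np.asarray(fa_stack, dtype=float)
    md = np.asarray(md_stack, dtype=float)
    if fa.shape != md.shape or fa.ndim != 4:
        raise ValueError("FA and MD stacks must be 4-D with identical shapes")
    x = -fa
    xc = x - x.mean(axis=-1, keepdims=True)
    yc = md - md.mean(axis=-1, keepdims=True)
    sx = np.sqrt((xc ** 2).sum(axis=-1))
    sy = np.sqrt((yc ** 2).sum(axis=-1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc * yc).sum(axis=-1) / (sx * sy)
    r[~skeleton.mask] = np.nan
    defined = r[np.isfinite(r)]
    median = float(np.median(defined)) if defined.size else np.nan
    counts, edges = np.histogram(defined, bins=40, range=(-1.0, 1.0))
    return r, median, counts, edges
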