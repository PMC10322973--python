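"""Constructors for the competing white-matter aging models.

Four causal hypotheses link age, latent white-matter integrity (WMI, indicated
by sign-flipped FA and by MD) and latent cognition (BEH, indicated by task
reaction times):

* **brain mediation** — age -> WMI -> BEH: white matter decline drives
  cognitive slowing.
* **cognitive mediation** — age -> BEH -> WMI: cognitive decline drives
  white matter deterioration.
* **independent factor** — age -> WMI and age -> BEH with no WMI-BEH link:
  both systems age, but independently.
* **common factor** — age -> G, G -> WMI, G -> BEH: a single neurocognitive
  factor mediates both declines.

The three single-mediator models share S and measurement structure and differ
only in the directed-path matrix A.  Two *simple* path models support the
path-significance maps: AGE_WM (age -> WMI, saturated) and BEH_WM
(BEH -> WMI).  Every model comes in a 2-indicator (verbal + visuospatial RT)
or 3-indicator (+ number-Stroop RT) behavioral variant.
"""

from __future__ import annotations

import enum

from .sem_core import ModelBuilder, SemModelSpec, SemError, restrict_parameter

__all__ = [
    "ModelKind",
    "MODEL_CODES",
    "CODE_LABELS",
    "make_aging_model",
    "make_simple_model",
    "restrict_path",
    "behavior_indicators",
]


class ModelKind(enum.Enum):
    BRAIN_MEDIATION = "brainmed"
    COGNITIVE_MEDIATION = "cogmed"
    INDEPENDENT_FACTOR = "independent"
    COMMON_FACTOR = "common"
    AGE_WM = "age-wm"
    BEH_WM = "beh-wm"

    @classmethod
    def from_name(cls, name: str) -> "ModelKind":
        for kind in cls:
            if name in (kind.value, kind.name, kind.name.lower()):
                return kind
        raise SemError(f"unknown model kind {name!r}")


#: integer codes used in selection maps (0 = unclassified)
MODEL_CODES: dict[ModelKind, int] = {
    ModelKind.BRAIN_MEDIATION: 1,
    ModelKind.COGNITIVE_MEDIATION: 2,
    ModelKind.INDEPENDENT_FACTOR: 3,
    ModelKind.COMMON_FACTOR: 4,
}
CODE_LABELS: dict[int, str] = {0: "unclassified"} | {
    code: kind.value for kind, code in MODEL_CODES.items()
}

#: AIC tie-break preference (after the larger-df rule): earlier wins
TIE_ORDER = [
    ModelKind.INDEPENDENT_FACTOR,
    ModelKind.COGNITIVE_MEDIATION,
    ModelKind.BRAIN_MEDIATION,
    ModelKind.COMMON_FACTOR,
]


def behavior_indicators(n: int) -> list[str]:
    if n == 2:
        return ["rt_verbal", "rt_visuospatial"]
    if n == 3:
        return ["rt_verbal", "rt_visuospatial", "rt_stroop"]
    raise SemError(f"n_behavior_indicators must be 2 or 3, got {n}")


def _measurement(b: ModelBuilder, rts: list[str]) -> None:
    """Shared measurement model: BEH on the RTs, WMI on negFA and MD.

    Scale identification fixes the first loading of each latent to 1; the
    remaining loadings and all indicator residual variances are free.
    """
    b.path("beh", rts[0], value=1.0)
    for rt in rts[1:]:
        b.path("beh", rt, free=f"l_{rt}")
    b.path("wmi", "neg_fa", value=1.0)
    b.path("wmi", "md", free="l_md")
    for v in rts + ["neg_fa", "md"]:
        b.variance(v, free=f"e_{v}")


def make_aging_model(kind: ModelKind | str,
                     n_behavior_indicators: int = 2) -> SemModelSpec:
    """Build one of the four competing aging models.

    Observed order is (age, RTs..., neg_fa, md); latents are BEH and WMI
    (plus G for the common-factor model, whose residual variance is fixed to
    1 for scale identification).  Mediation is full: the mediated models carry
    no direct age path.
    """
    if isinstance(kind, str):
        kind = ModelKind.from_name(kind)
    rts = behavior_indicators(n_behavior_indicators)
    observed = ["age"] + rts + ["neg_fa", "md"]
    latent = ["beh", "wmi"]
    if kind is ModelKind.COMMON_FACTOR:
        latent = latent + ["g"]
    elif kind not in (ModelKind.BRAIN_MEDIATION, ModelKind.COGNITIVE_MEDIATION,
                      ModelKind.INDEPENDENT_FACTOR):
        raise SemError(f"{kind} is a simple path model; use make_simple_model")

    b = ModelBuilder(observed=observed, latent=latent)
    _measurement(b, rts)
    b.variance("age", free="v_age")
    b.variance("beh", free="v_beh")
    b.variance("wmi", free="v_wmi")

    if kind is ModelKind.BRAIN_MEDIATION:
        b.path("age", "wmi", free="age_to_wmi")
        b.path("wmi", "beh", free="wmi_to_beh")
    elif kind is ModelKind.COGNITIVE_MEDIATION:
        b.path("age", "beh", free="age_to_beh")
        b.path("beh", "wmi", free="beh_to_wmi")
    elif kind is ModelKind.INDEPENDENT_FACTOR:
        b.path("age", "beh", free="age_to_beh")
        b.path("age", "wmi", free="age_to_wmi")
    else:  # common factor
        b.variance("g", value=1.0)
        b.path("age", "g", free="age_to_g")
        b.path("g", "beh", free="g_to_beh")
        b.path("g", "wmi", free="g_to_wmi")
    return b.build(f"{kind.value}_{n_behavior_indicators}ind")


def make_simple_model(kind: ModelKind | str,
                      n_behavior_indicators: int = 2) -> SemModelSpec:
    """Build one of the two simple path models whose latent path "a" is
    tested by chi-square difference.

    AGE_WM regresses latent WMI on observed age (6 moments, 6 free
    parameters: saturated, df = 0).  BEH_WM regresses latent WMI on latent
    BEH built from the RT indicators (df = 1 with two indicators, from the
    single vanishing-tetrad constraint the two-factor structure imposes).
    """
    if isinstance(kind, str):
        kind = ModelKind.from_name(kind)
    if kind is ModelKind.AGE_WM:
        b = ModelBuilder(observed=["age", "neg_fa", "md"], latent=["wmi"])
        b.path("wmi", "neg_fa", value=1.0)
        b.path("wmi", "md", free="l_md")
        b.variance("neg_fa", free="e_neg_fa")
        b.variance("md", free="e_md")
        b.variance("age", free="v_age")
        b.variance("wmi", free="v_wmi")
        b.path("age", "wmi", free="a")
        return b.build("age_wm")
    if kind is ModelKind.BEH_WM:
        rts = behavior_indicators(n_behavior_indicators)
        b = ModelBuilder(observed=rts + ["neg_fa", "md"], latent=["beh", "wmi"])
        _measurement(b, rts)
        b.variance("beh", free="v_beh")
        b.variance("wmi", free="v_wmi")
        b.path("beh", "wmi", free="a")
        return b.build("beh_wm")
    raise SemError(f"{kind} is not a simple path model")


def restrict_path(spec: SemModelSpec, path_id: str) -> SemModelSpec:
    """Copy of ``spec`` with directed path ``path_id`` fixed to zero.

    Fitting the pair (full, restricted) and differencing their chi-squares
    tests the path's significance on 1 df.
    """
    return restrict_parameter(spec, path_id, 0.0)
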