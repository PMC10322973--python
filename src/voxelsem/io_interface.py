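"""Readers, writers and run configuration for a reproducible pipeline.

Volumes travel as NIfTI (4-D stacks with the subject axis fourth), tabular
data as headered CSV, and a whole run is captured by a YAML config that
round-trips losslessly; every run directory embeds the config and library
version so any output can be regenerated bit-for-bit.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "VolumeIOError",
    "CohortError",
    "read_volume_stack",
    "read_volume_pair",
    "write_volume",
    "read_cohort",
    "write_cohort",
    "RunConfig",
    "make_run_dir",
]


class VolumeIOError(ValueError):
    """Raised for malformed or inconsistent volume files."""


class CohortError(ValueError):
    """Raised for malformed cohort tables."""


def voxel_volume_of(affine: np.ndarray) -> float:
    """Physical voxel volume in mm^3 from a NIfTI affine (|det| of the 3x3)."""
    return float(abs(np.linalg.det(np.asarray(affine)[:3, :3])))


def read_volume_stack(path, expect_4d: bool = True):
    """Load a NIfTI volume; returns (data, affine, voxel_volume_mm3).

    4-D stacks carry the subject axis fourth.  Non-finite voxel values are a
    hard error (their indices are reported) because downstream covariance
    computation silently propagates them.
    """
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    if expect_4d and data.ndim != 4:
        raise VolumeIOError(f"{path}: expected a 4-D stack, got {data.ndim}-D")
    if not expect_4d and data.ndim not in (3, 4):
        raise VolumeIOError(f"{path}: expected a 3-D or 4-D volume")
    bad = np.argwhere(~np.isfinite(data))
    if len(bad):
        head = ", ".join(str(tuple(int(v) for v in row)) for row in bad[:5])
        raise VolumeIOError(
            f"{path}: {len(bad)} non-finite voxel value(s), first at {head}"
        )
    affine = img.affine
    return data, affine, voxel_volume_of(affine)


def read_volume_pair(fa_path, md_path):
    """Load aligned FA and MD stacks; mismatched grids or affines are fatal."""
    fa, fa_aff, vv = read_volume_stack(fa_path)
    md, md_aff, _ = read_volume_stack(md_path)
    if fa.shape != md.shape:
        raise VolumeIOError(
            f"FA {fa.shape} and MD {md.shape} stacks differ in shape"
        )
    if not np.allclose(fa_aff, md_aff, atol=1e-6):
        raise VolumeIOError("FA and MD affines differ; volumes are not aligned")
    from .synthetic_data import VolumeSet

    return VolumeSet(fa=fa, md=md, affine=fa_aff)


def write_volume(path, data: np.ndarray, affine: np.ndarray | None = None) -> None:
    """Write an array as NIfTI-1 (float64 for stats, native ints for labels)."""
    if affine is None:
        affine = np.eye(4)
    arr = np.asarray(data)
    if arr.dtype.kind in "ui":
        arr = arr.astype(np.int32)
    img = nib.Nifti1Image(arr, np.asarray(affine, dtype=float))
    img.to_filename(str(path))


def read_cohort(path, n_expected: int | None = None,
                order_column: str | None = None) -> pd.DataFrame:
    """Load a cohort CSV (subject_id, age, indicator columns).

    Row order defines the subject axis of the volume stacks; pass
    ``order_column`` to sort by an explicit ordering column instead.  A
    mismatch with ``n_expected`` (the stack's 4th dimension) is fatal.
    """
    cohort = pd.read_csv(path)
    for col in ("subject_id", "age"):
        if col not in cohort.columns:
            raise CohortError(f"{path}: missing required column {col!r}")
    if cohort["subject_id"].duplicated().any():
        dup = cohort.loc[cohort["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise CohortError(f"{path}: duplicate subject_id {dup!r}")
    if order_column is not None:
        if order_column not in cohort.columns:
            raise CohortError(f"{path}: no order column {order_column!r}")
        cohort = cohort.sort_values(order_column).reset_index(drop=True)
    if n_expected is not None and len(cohort) != n_expected:
        raise CohortError(
            f"{path}: {len(cohort)} subjects vs {n_expected} volume frames"
        )
    return cohort


def write_cohort(path, cohort: pd.DataFrame) -> None:
    cohort.to_csv(path, index=False)


@dataclass
class RunConfig:
    """Complete description of one pipeline run (YAML round-trippable)."""

    fa_path: str = ""
    md_path: str = ""
    cohort_path: str = ""
    labels_path: str = ""
    models: list = field(default_factory=lambda: [
        "brainmed", "cogmed", "independent", "common"])
    n_indicators: int = 2
    fa_threshold: float = 0.2
    fit_p_threshold: float = 0.05
    cluster_mm3: float = 300.0
    connectivity: int = 26
    seed: int = 0
    workers: int = 1

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        known = {f for f in cls.__dataclass_fields__}
        extra = set(raw) - known
        if extra:
            raise ValueError(f"unknown config keys: {sorted(extra)}")
        return cls(**raw)


def make_run_dir(root, config: RunConfig, stamp: str | None = None) -> Path:
    """Create a timestamped run directory embedding config and version."""
    from . import __version__

    if stamp is None:
        stamp = _dt.datetime.now().strftime("%Y%m%d-%H%M%S")
    run_dir = Path(root) / f"run-{stamp}"
    run_dir.mkdir(parents=True, exist_ok=False)
    config.to_yaml(run_dir / "config.yaml")
    (run_dir / "VERSION").write_text(f"voxelsem {__version__}\n")
    return run_dir
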