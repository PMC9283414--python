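"""Tissue-volume containers and volumetric operations.

A :class:`TissueMapSet` holds one tissue class for one sequence: a stack of
3-D voxel-wise volume maps (one per participant), each voxel value being the
tissue volume in mm^3 contained in that voxel. Global volumes are obtained by
summing voxels; voxel-wise analyses are restricted to an inclusion mask of
voxels reliably inside the rapid sequence's field of view.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import AlignmentError, DataError, ParameterError


@dataclass
class TissueMapSet:
    """Per-participant 3-D voxel-wise tissue-volume maps for one sequence.

    Attributes
    ----------
    values : ndarray, shape (n_participants, nx, ny, nz)
        Voxel tissue volume in mm^3; finite and non-negative.
    participant_ids : list of str
    tissue_class : {"GM", "WM", "CSF"}
    sequence_label : str
    voxel_dims : (3,) voxel edge lengths in mm (metadata only; values are
        already volumes, not densities).
    fov_mask : optional boolean array, shape (nx, ny, nz)
        Validity mask of the acquisition's field of view.
    """

    values: np.ndarray
    participant_ids: list[str]
    tissue_class: str
    sequence_label: str
    voxel_dims: tuple[float, float, float]
    fov_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 4:
            raise DataError(
                f"values must be 4-D (participants, x, y, z), got shape "
                f"{self.values.shape}"
            )
        if len(self.participant_ids) != self.values.shape[0]:
            raise DataError(
                f"{len(self.participant_ids)} participant ids for "
                f"{self.values.shape[0]} maps"
            )
        self.voxel_dims = tuple(float(v) for v in self.voxel_dims)
        if self.fov_mask is not None:
            self.fov_mask = np.asarray(self.fov_mask, dtype=bool)
            if self.fov_mask.shape != self.grid_shape:
                raise DataError(
                    f"fov_mask shape {self.fov_mask.shape} does not match grid "
                    f"{self.grid_shape}"
                )

    @property
    def n_participants(self) -> int:
        return self.values.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.values.shape[1:]

    def subset(self, participant_ids: Sequence[str]) -> "TissueMapSet":
        """Return the maps of the given participants, in the given order."""
        index = {pid: i for i, pid in enumerate(self.participant_ids)}
        missing = [p for p in participant_ids if p not in index]
        if missing:
            raise AlignmentError(f"participants not in map set: {missing}")
        rows = [index[p] for p in participant_ids]
        return replace(
            self, values=self.values[rows], participant_ids=list(participant_ids)
        )


@dataclass
class InclusionMask:
    """Voxels covered by (nearly) all participants' acquisitions."""

    mask: np.ndarray
    threshold: float
    participant_fraction: float
    required_count: int = 0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class DistributionSummary:
    """Median and quartiles of a set of values (missing values dropped)."""

    median: float
    q1: float
    q3: float
    n: int

    def to_dict(self) -> dict:
        return {"median": self.median, "q1": self.q1, "q3": self.q3, "n": self.n}


def global_volumes(maps: TissueMapSet) -> pd.DataFrame:
    """Total tissue volume per participant, by summing across voxels.

    Returns a DataFrame with columns ``participant_id`` and ``volume_mm3``,
    one row per participant, in map order.
    """
    bad = ~np.isfinite(maps.values)
    if bad.any():
        p, x, y, z = (int(v[0]) for v in np.nonzero(bad))
        raise DataError(
            f"non-finite voxel for participant {maps.participant_ids[p]!r} at "
            f"voxel index ({x}, {y}, {z})"
        )
    totals = maps.values.reshape(maps.n_participants, -1).sum(axis=1)
    return pd.DataFrame(
        {"participant_id": list(maps.participant_ids), "volume_mm3": totals}
    )


def inclusion_mask(
    maps: TissueMapSet, threshold: float = 0.001, fraction: float = 0.95
) -> InclusionMask:
    """Voxels with at least ``threshold`` mm^3 of tissue in at least
    ``fraction`` of participants.

    The participant count is compared against ``ceil(fraction * n)``, the
    conservative reading of "at least 95% of participants".
    """
    if not (0.0 < fraction <= 1.0):
        raise ParameterError(f"fraction must lie in (0, 1], got {fraction}")
    n = maps.n_participants
    if n < 2:
        raise DataError("inclusion mask requires at least 2 participants")
    required = math.ceil(fraction * n)
    counts = (maps.values >= threshold).sum(axis=0)
    return InclusionMask(
        mask=counts >= required,
        threshold=threshold,
        participant_fraction=fraction,
        required_count=required,
    )


def _as_mask_array(mask) -> np.ndarray:
    if isinstance(mask, InclusionMask):
        return mask.mask
    return np.asarray(mask, dtype=bool)


def voxelwise_correlation(
    maps_a: TissueMapSet,
    maps_b: TissueMapSet,
    mask,
    method: str = "spearman",
) -> np.ndarray:
    """Per-voxel cross-participant correlation between two map sets.

    Returns a 3-D array with the correlation at voxels inside ``mask`` and
    NaN elsewhere. Voxels where either set is constant across participants
    (zero variance, correlation undefined) are NaN as well.
    """
    if maps_a.participant_ids != maps_b.participant_ids:
        raise AlignmentError(
            "map sets must hold the same participants in the same order"
        )
    if maps_a.grid_shape != maps_b.grid_shape:
        raise AlignmentError(
            f"grid shapes differ: {maps_a.grid_shape} vs {maps_b.grid_shape}"
        )
    if method not in ("spearman", "pearson"):
        raise ParameterError(f"unknown correlation method {method!r}")
    m = _as_mask_array(mask)
    a = maps_a.values[:, m]  # (n, V)
    b = maps_b.values[:, m]
    if method == "spearman":
        a = sps.rankdata(a, axis=0)
        b = sps.rankdata(b, axis=0)
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    sa = np.einsum("ij,ij->j", a, a)
    sb = np.einsum("ij,ij->j", b, b)
    cov = np.einsum("ij,ij->j", a, b)
    denom = np.sqrt(sa * sb)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), np.nan)
    r = np.clip(r, -1.0, 1.0)
    out = np.full(maps_a.grid_shape, np.nan)
    out[m] = r
    return out


def reduce_fov(maps: TissueMapSet, fov_mask) -> TissueMapSet:
    """Zero all voxels outside ``fov_mask``, emulating a truncated
    field of view; the mask is recorded on the result."""
    m = _as_mask_array(fov_mask)
    if m.shape != maps.grid_shape:
        raise ParameterError(
            f"mask shape {m.shape} does not match grid {maps.grid_shape}"
        )
    if not m.any():
        raise ParameterError("field-of-view mask is empty")
    values = np.where(m[None, :, :, :], maps.values, 0.0)
    return replace(
        maps,
        values=values,
        fov_mask=m.copy(),
        sequence_label=f"{maps.sequence_label}_fovreduced"
        if not maps.sequence_label.endswith("_fovreduced")
        else maps.sequence_label,
    )


def summarize_distribution(values) -> DistributionSummary:
    """Median and quartiles (linear interpolation); NaNs are dropped."""
    arr = np.asarray(values, dtype=float).ravel()
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise DataError("no finite values to summarize")
    q1, md, q3 = np.percentile(arr, [25.0, 50.0, 75.0])
    return DistributionSummary(median=float(md), q1=float(q1), q3=float(q3), n=arr.size)
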