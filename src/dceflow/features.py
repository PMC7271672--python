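"""Per-lesion histogram features of the IFP and IFV maps.

Each lesion at each timepoint is reduced to eight numbers: mean, SD,
skewness and kurtosis of the interstitial pressure (reported in kPa) and of
the interstitial speed (m/s) over the tumor voxels.  Moments are the
population (n-denominator) versions; skewness is Fisher-Pearson g1 and
kurtosis the Pearson non-excess m4/m2^2 (normal distribution -> 3).  The
default reduction computes the statistics slice by slice along the axial
axis and averages them across slices; pooling all tumor voxels first is
available as ``whole_voi``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "histogram_stats",
    "lesion_features",
    "LesionFeatures",
    "delta_features",
    "FEATURE_COLUMNS",
]

STAT_NAMES = ("mean", "sd", "skew", "kurt")
FEATURE_COLUMNS = [
    "ifp_mean_kpa", "ifp_sd_kpa", "ifp_skew", "ifp_kurt",
    "ifv_mean_mps", "ifv_sd_mps", "ifv_skew", "ifv_kurt",
]


def histogram_stats(values, excess_kurtosis: bool = False) -> dict:
    """Mean, population SD, skewness g1 and Pearson kurtosis of a sample.

    A constant sample has undefined shape moments: skewness and kurtosis are
    returned as NaN ("missing") rather than raising.  ``excess_kurtosis``
    subtracts 3 (normal -> 0).
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("empty sample")
    mean = float(values.mean())
    sd = float(values.std())
    if sd == 0.0:
        return {"mean": mean, "sd": sd, "skew": np.nan, "kurt": np.nan}
    skew = float(sps.skew(values, bias=True))
    kurt = float(sps.kurtosis(values, fisher=excess_kurtosis, bias=True))
    return {"mean": mean, "sd": sd, "skew": skew, "kurt": kurt}


def _masked_slice_stats(volume, mask, slice_axis, min_slice_voxels, excess):
    out = []
    for k in range(mask.shape[slice_axis]):
        m = np.take(mask, k, axis=slice_axis)
        if m.sum() >= min_slice_voxels:
            out.append(histogram_stats(np.take(volume, k, axis=slice_axis)[m],
                                       excess_kurtosis=excess))
    return out


def lesion_features(
    volume: np.ndarray,
    mask: np.ndarray,
    mode: str = "per_slice_mean",
    slice_axis: int = 2,
    min_slice_voxels: int = 8,
    excess_kurtosis: bool = False,
) -> dict:
    """Histogram statistics of one scalar map over the tumor voxels.

    ``per_slice_mean`` computes each statistic on every axial slice holding
    at least ``min_slice_voxels`` tumor voxels and averages the statistics
    across slices; if no slice qualifies it falls back to ``whole_voi``
    with a warning.  ``whole_voi`` pools all tumor voxels.
    """
    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if volume.shape != mask.shape:
        raise ValueError("volume and mask shapes differ")
    if not mask.any():
        raise ValueError("mask is empty")
    if mode == "whole_voi":
        return histogram_stats(volume[mask], excess_kurtosis=excess_kurtosis)
    if mode != "per_slice_mean":
        raise ValueError(f"unknown mode {mode!r}")
    per_slice = _masked_slice_stats(volume, mask, slice_axis, min_slice_voxels,
                                    excess_kurtosis)
    if not per_slice:
        warnings.warn(
            "no slice reaches the voxel minimum; falling back to whole_voi",
            stacklevel=2,
        )
        return histogram_stats(volume[mask], excess_kurtosis=excess_kurtosis)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slice stats
        return {
            name: float(np.nanmean([s[name] for s in per_slice]))
            for name in STAT_NAMES
        }


@dataclass(frozen=True)
class LesionFeatures:
    """The eight-feature row for one lesion at one timepoint.

    IFP statistics are in kPa, IFV statistics in m/s (computed on the Darcy
    speed).  ``timepoint`` is "pre" or "post".
    """

    lesion_id: str
    timepoint: str
    values: dict  # keys = FEATURE_COLUMNS

    def __post_init__(self) -> None:
        if self.timepoint not in ("pre", "post"):
            raise ValueError("timepoint must be 'pre' or 'post'")
        missing = [c for c in FEATURE_COLUMNS if c not in self.values]
        if missing:
            raise ValueError(f"missing feature values: {missing}")

    @classmethod
    def from_maps(
        cls,
        lesion_id: str,
        timepoint: str,
        ifp_pa: np.ndarray,
        ifv_mps: np.ndarray,
        mask: np.ndarray,
        **kwargs,
    ) -> "LesionFeatures":
        """Compute the feature row from pressure (Pa) and speed (m/s) maps."""
        s_p = lesion_features(ifp_pa / 1000.0, mask, **kwargs)  # kPa
        s_v = lesion_features(ifv_mps, mask, **kwargs)
        vals = {
            "ifp_mean_kpa": s_p["mean"], "ifp_sd_kpa": s_p["sd"],
            "ifp_skew": s_p["skew"], "ifp_kurt": s_p["kurt"],
            "ifv_mean_mps": s_v["mean"], "ifv_sd_mps": s_v["sd"],
            "ifv_skew": s_v["skew"], "ifv_kurt": s_v["kurt"],
        }
        return cls(lesion_id=lesion_id, timepoint=timepoint, values=vals)


def delta_features(pre: LesionFeatures, post: LesionFeatures) -> dict:
    """Post-minus-pre change of every feature; NaN propagates."""
    if pre.timepoint != "pre" or post.timepoint != "post":
        raise ValueError("expected a (pre, post) pair in that order")
    if pre.lesion_id != post.lesion_id:
        raise ValueError("pre and post rows belong to different lesions")
    return {c: post.values[c] - pre.values[c] for c in FEATURE_COLUMNS}
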