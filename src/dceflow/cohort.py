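"""Paired pre/post synthetic lesion cohorts with a designed response effect.

Emulates the two-arm study design: every lesion is imaged before and after
treatment, and lesions are labeled OR (objective response) or non-OR.  The
default effect structure models response as perfusion homogenization:

* pre-treatment lesions are rim-enhancing — a spatially correlated Ktrans
  field with a poorly perfused central core (the classic appearance of an
  untreated brain metastasis);
* OR lesions lose the core contrast and half of the Ktrans spatial SD after
  treatment (devascularization makes the lesion uniformly hypoperfused);
* non-OR lesions keep the pre-treatment structure.

Pre and post scans of the same lesion share the random-field seed (the
underlying vasculature is the same lesion) while measurement noise is drawn
fresh per scan.  Every lesion is reproducible from (cohort seed, lesion
index) alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .phantom import Phantom, PhantomSpec, TumorGeometry, generate_phantom

__all__ = ["CohortSpec", "LesionRecord", "generate_cohort", "cohort_manifest"]

# acquisition grid border of background tissue around the lesion, mm
_GRID_MARGIN_MM = 10.0


def _default_pre() -> PhantomSpec:
    # rim-enhancing metastasis: correlated Ktrans with a hypoperfused core
    return PhantomSpec(
        grid_shape=(12, 12, 12),
        voxel_size_mm=(2.5, 2.5, 2.5),
        tumor=TumorGeometry.sphere((15.0, 15.0, 15.0), 5.0),
        ktrans_mean=0.3,
        ktrans_spatial_sd=0.12,
        ktrans_correlation_length=3.0,
        necrotic_core_fraction=0.6,
        necrotic_core_level=0.1,
        noise_sd=1.0,
    )


def _default_post_or() -> PhantomSpec:
    # response homogenizes perfusion: core contrast gone, SD halved
    return _default_pre().replace(
        necrotic_core_fraction=0.0,
        necrotic_core_level=1.0,
        ktrans_spatial_sd=0.06,
    )


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a paired two-arm lesion cohort.

    ``pre_spec``, ``post_or_spec`` and ``post_non_or_spec`` are templates:
    their field/noise/protocol settings are used while geometry, grid and
    seeds are assigned per lesion (radius drawn uniformly from
    ``radius_range_mm``).  Group sizes default to the study's 31 OR / 22
    non-OR split.
    """

    n_or: int = 31
    n_non_or: int = 22
    pre_spec: PhantomSpec = field(default_factory=_default_pre)
    post_or_spec: PhantomSpec = field(default_factory=_default_post_or)
    post_non_or_spec: PhantomSpec = field(default_factory=_default_pre)
    radius_range_mm: tuple[float, float] = (5.5, 8.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_or < 1 or self.n_non_or < 1:
            raise ValueError("need at least one lesion per group")
        lo, hi = self.radius_range_mm
        if not (0 < lo <= hi):
            raise ValueError("invalid radius range")

    @property
    def n_lesions(self) -> int:
        return self.n_or + self.n_non_or

    def replace(self, **kwargs) -> "CohortSpec":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class LesionRecord:
    """One lesion: its group label and the concrete pre/post phantom specs."""

    lesion_id: str
    group: str  # "OR" / "non-OR"
    radius_mm: float
    pre: PhantomSpec
    post: PhantomSpec

    def generate(self) -> tuple[Phantom, Phantom]:
        return generate_phantom(self.pre), generate_phantom(self.post)


def _concrete_spec(template: PhantomSpec, radius: float,
                   field_seed: int, noise_seed: int) -> PhantomSpec:
    vox = np.asarray(template.voxel_size_mm, dtype=float)
    shape = tuple(int(np.ceil((2 * radius + _GRID_MARGIN_MM) / v)) + 2 for v in vox)
    extent = np.array(shape) * vox
    geom = TumorGeometry.sphere(tuple(extent / 2.0), radius)
    return template.replace(
        grid_shape=shape, tumor=geom, seed=noise_seed, field_seed=field_seed
    )


def generate_cohort(spec: CohortSpec) -> list[LesionRecord]:
    """Materialize the per-lesion specs of a cohort (phantoms stay lazy).

    Each lesion derives its radius and seeds from an independent
    ``SeedSequence([cohort_seed, index])`` stream, so any lesion can be
    regenerated bit-identically without generating the others.
    """
    records = []
    for i in range(spec.n_lesions):
        is_or = i < spec.n_or
        ss = np.random.SeedSequence(entropy=[int(spec.seed), i])
        rng = np.random.default_rng(ss)
        radius = float(rng.uniform(*spec.radius_range_mm))
        field_seed, pre_seed, post_seed = (int(s) for s in rng.integers(0, 2**31, 3))
        template_post = spec.post_or_spec if is_or else spec.post_non_or_spec
        records.append(
            LesionRecord(
                lesion_id=f"L{i:03d}",
                group="OR" if is_or else "non-OR",
                radius_mm=radius,
                pre=_concrete_spec(spec.pre_spec, radius, field_seed, pre_seed),
                post=_concrete_spec(template_post, radius, field_seed, post_seed),
            )
        )
    return records


def cohort_manifest(records: list[LesionRecord], path_map: dict | None = None) -> pd.DataFrame:
    """Manifest table: one row per lesion with group, geometry and seeds.

    ``path_map`` optionally maps (lesion_id, timepoint) to written file
    paths, filled in by the pipeline's simulate stage.
    """
    rows = []
    for rec in records:
        row = {
            "lesion_id": rec.lesion_id,
            "group": rec.group,
            "radius_mm": rec.radius_mm,
            "pre_seed": rec.pre.seed,
            "post_seed": rec.post.seed,
            "field_seed": rec.pre.field_seed,
        }
        if path_map is not None:
            row["pre_path"] = path_map.get((rec.lesion_id, "pre"), "")
            row["post_path"] = path_map.get((rec.lesion_id, "post"), "")
        rows.append(row)
    return pd.DataFrame(rows)
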