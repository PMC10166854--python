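"""Seeded generators for every input the pipeline consumes.

Real inputs to the analysis — tractograms of the dentatorubrothalamic
tract, ablation-core masks, thalamic-nuclei segmentations, per-element
transducer skull parameters and longitudinal tremor scores — come from a
treated patient cohort and are not redistributable. These generators
emulate their statistical structure so every stage is testable without
any download:

* bundles are smooth arcs with anterior-axis sub-bundle offsets and
  Gaussian jitter, carrying generative sub-bundle labels for oracle tests;
* ablation masks are voxelised spheres, nuclei segmentations are Voronoi
  partitions (hard segmentation by construction);
* skull parameters are 1,024-element Gaussian arrays;
* cohort outcome tables follow a linear model on standardized posterior
  overlap, age and SDR variability with configurable noise, returning the
  generative coefficients for recovery tests.

Geometric realism is explicitly not a goal; geometric separability and
the assumed statistical structure are. All generators are pure functions
of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .clinical import (N_TRANSDUCER_ELEMENTS, SKULL_PARAMETERS,
                       TreatmentParams)
from .errors import ValidationError
from .spatial import LabelVolume, Tractogram

__all__ = [
    "BundleSpec",
    "CohortSpec",
    "gen_bundle",
    "gen_ablation_mask",
    "gen_nuclei_segmentation",
    "gen_treatment_params",
    "gen_cohort",
    "DEFAULT_CENTERLINE",
]

#: Default centerline control points (mm): a C-shaped arc in the x-z plane
#: (y = 0 throughout) evoking a dentate -> red nucleus -> thalamus course,
#: so that sub-bundle offsets along the anterior (+y) axis translate
#: directly into mean anterior-coordinate differences.
DEFAULT_CENTERLINE = np.array([
    [12.0, 0.0, -35.0],
    [20.0, 0.0, -18.0],
    [16.0, 0.0, -2.0],
    [8.0, 0.0, 12.0],
    [4.0, 0.0, 28.0],
])

SUB_BUNDLE_ROLES = ("posterior", "middle", "anterior")


@dataclass
class BundleSpec:
    """Generative description of a multi-sub-bundle streamline set.

    ``offsets`` shift each sub-bundle along the anterior (+y) axis;
    ``weights`` are the mixing probabilities of the sub-bundles.
    ``jitter_sd`` controls the per-streamline lateral offset and the
    (three times smaller) per-point jitter.
    """

    control_points: np.ndarray = None
    n_streamlines: int = 900
    jitter_sd: float = 1.0
    offsets: tuple = (-6.0, 0.0, 6.0)
    weights: tuple = None
    n_points: int = 40
    seed: int = 0

    def __post_init__(self):
        if self.control_points is None:
            self.control_points = DEFAULT_CENTERLINE.copy()
        self.control_points = np.asarray(self.control_points, dtype=np.float64)
        if self.control_points.ndim != 2 or self.control_points.shape[0] < 2 \
                or self.control_points.shape[1] != 3:
            raise ValidationError("control_points must be (m >= 2, 3)")
        if self.jitter_sd < 0:
            raise ValidationError("jitter_sd must be >= 0")
        if self.n_streamlines < 1:
            raise ValidationError("n_streamlines must be >= 1")
        if self.weights is None:
            self.weights = tuple(1.0 / len(self.offsets)
                                 for _ in self.offsets)
        if len(self.weights) != len(self.offsets):
            raise ValidationError("weights and offsets length mismatch")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValidationError("weights must sum to 1")


def gen_bundle(spec: BundleSpec):
    """Generate a synthetic bundle; returns ``(Tractogram, labels)``.

    ``labels[i]`` is the generative sub-bundle index of streamline ``i``
    (ordered as ``spec.offsets``). Streamlines are the cubic-spline
    centerline shifted by the sub-bundle offset along +y, by a
    per-streamline Gaussian lateral offset in (x, z), and by per-point
    Gaussian jitter.
    """
    rng = np.random.default_rng(spec.seed)
    u = np.linspace(0.0, 1.0, spec.control_points.shape[0])
    spline = CubicSpline(u, spec.control_points, axis=0)
    base = spline(np.linspace(0.0, 1.0, spec.n_points))

    labels = rng.choice(len(spec.offsets), size=spec.n_streamlines,
                        p=np.asarray(spec.weights))
    streamlines = []
    point_sd = spec.jitter_sd / 3.0
    for lab in labels:
        s = base.copy()
        s[:, 1] += spec.offsets[lab]
        lateral = rng.normal(0.0, spec.jitter_sd, size=2)
        s[:, 0] += lateral[0]
        s[:, 2] += lateral[1]
        s += rng.normal(0.0, point_sd, size=s.shape)
        streamlines.append(s)
    return Tractogram(streamlines, space_id="synthetic"), labels


def gen_ablation_mask(center, radius: float, shape, affine,
                      space_id: str = "synthetic") -> LabelVolume:
    """Binary spherical mask: voxels whose centres lie within ``radius`` of
    ``center`` (mm). The centre must fall inside the grid field of view."""
    if radius < 0:
        raise ValidationError("radius must be >= 0")
    affine = np.asarray(affine, dtype=np.float64)
    center = np.asarray(center, dtype=np.float64)
    inv = np.linalg.inv(affine)
    cvox = center @ inv[:3, :3].T + inv[:3, 3]
    if np.any(cvox < -0.5) or np.any(cvox > np.array(shape) - 0.5):
        raise ValidationError(f"center {center} is outside the grid FOV")
    idx = np.indices(shape).reshape(3, -1).T
    centres = idx @ affine[:3, :3].T + affine[:3, 3]
    inside = np.linalg.norm(centres - center, axis=1) <= radius
    grid = inside.reshape(shape).astype(np.int32)
    return LabelVolume(grid=grid, affine=affine, space_id=space_id)


def gen_nuclei_segmentation(shape, affine, n_labels: int = 5,
                            seed: int = 0,
                            space_id: str = "synthetic") -> LabelVolume:
    """Hard segmentation: Voronoi regions of ``n_labels`` random sites.

    Every voxel receives exactly one label in ``1..n_labels``.
    """
    if n_labels < 2:
        raise ValidationError("need n_labels >= 2")
    rng = np.random.default_rng(seed)
    sites = rng.uniform(0, np.array(shape) - 1, size=(n_labels, 3))
    idx = np.indices(shape).reshape(3, -1).T.astype(np.float64)
    d2 = ((idx[:, None, :] - sites[None, :, :]) ** 2).sum(axis=2)
    grid = (np.argmin(d2, axis=1) + 1).reshape(shape).astype(np.int32)
    names = {i: f"nucleus_{i}" for i in range(1, n_labels + 1)}
    return LabelVolume(grid=grid, affine=np.asarray(affine, dtype=np.float64),
                       label_names=names, space_id=space_id)


#: (mean, SD) of each per-element skull parameter draw. SDR is unitless;
#: thickness in mm; angles in degrees.
DEFAULT_PARAM_DISTRIBUTIONS = {
    "sdr": (0.45, 0.10),
    "skull_thickness": (6.5, 1.5),
    "inner_angle": (12.0, 4.0),
    "outer_angle": (15.0, 5.0),
}


def gen_treatment_params(seed: int = 0, subject_id: str = "synthetic",
                         distributions: dict | None = None) -> TreatmentParams:
    """Draw 1,024-element Gaussian arrays for each skull parameter, plus
    treatment scalars (max temperature, active elements, sonication count,
    summed temperature)."""
    dists = dict(DEFAULT_PARAM_DISTRIBUTIONS)
    if distributions:
        dists.update(distributions)
    rng = np.random.default_rng(seed)
    arrays = {name: rng.normal(dists[name][0], dists[name][1],
                               size=N_TRANSDUCER_ELEMENTS)
              for name in SKULL_PARAMETERS}
    n_son = int(np.clip(np.round(rng.normal(9, 2)), 2, 25))
    return TreatmentParams(
        subject_id=subject_id,
        arrays=arrays,
        max_temperature=float(rng.normal(58.0, 2.0)),
        active_elements=int(np.clip(np.round(rng.normal(1000, 15)), 1, 1024)),
        total_sonications=n_son,
        summed_temperature=float(n_son * rng.normal(54.0, 2.0)),
    )


@dataclass
class CohortSpec:
    """Generative description of an outcome cohort.

    The response is a linear model on the sample-standardized posterior
    tract overlap, age and SDR element-array standard deviation, with
    standardized effect sizes ``effects`` and Gaussian noise set either
    directly (``residual_sd``, standardized units) or via the target
    coefficient of determination ``target_r2`` of the true three-predictor
    model. The standardized response is then rescaled to a percent-change
    scale (``response_mean`` +/- ``response_sd``) and clipped to
    [-100, 100].
    """

    n_subjects: int = 31
    effects: dict = field(default_factory=lambda: {
        "pdrtt_overlap": 0.533, "age": -0.375, "sdr_sd": -0.324})
    target_r2: float = 0.548
    residual_sd: float | None = None
    response: str = "crst_t_change"
    response_mean: float = 44.77
    response_sd: float = 16.6
    age_mean: float = 75.72
    age_sd: float = 7.20
    n_secondary_lesions: int = 9
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 5:
            raise ValidationError("need n_subjects >= 5")
        if self.residual_sd is None and not (0 < self.target_r2 < 1):
            raise ValidationError("target_r2 must lie in (0, 1)")
        if self.residual_sd is not None and self.residual_sd < 0:
            raise ValidationError("residual_sd must be >= 0")
        if all(b == 0 for b in self.effects.values()) and \
                self.residual_sd is None and self.target_r2 > 0:
            raise ValidationError(
                "target_r2 > 0 is infeasible with all effects zero")


#: Pools offered to the two-stage selection on synthetic cohorts.
PATIENT_POOL = [
    "age", "sex", "brain_volume", "sdr_mean", "sdr_sd",
    "skull_thickness_mean", "skull_thickness_sd",
    "inner_angle_mean", "inner_angle_sd",
    "outer_angle_mean", "outer_angle_sd", "pre_crst_t",
]
TREATMENT_POOL = [
    "ablation_volume", "native_overlap", "adrtt_overlap", "mdrtt_overlap",
    "pdrtt_overlap", "vlp_overlap_volume", "max_temperature",
    "active_elements", "total_sonications", "summed_temperature",
]


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=1)


def gen_cohort(spec: CohortSpec):
    """Generate an outcome cohort table; returns ``(DataFrame, truth)``.

    Skull-parameter summaries are computed from full per-subject
    1,024-element arrays (same distributions as `gen_treatment_params`),
    so the cohort table is consistent with the treatment-parameter
    pathway.

    ``truth`` carries the generative coefficients: ``std_effects`` (the
    standardized effect sizes of the linear model), ``raw_coefficients``
    (the exact raw-scale coefficients of the signal part of the response,
    recoverable to machine precision when ``residual_sd`` is zero),
    ``intercept`` and the realized ``residual_sd``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    m = N_TRANSDUCER_ELEMENTS

    table = pd.DataFrame({"subject_id": [f"S{i + 1:03d}" for i in range(n)]})
    # per-element arrays per subject, summarised as in treatment_summary;
    # the per-element SDR spread varies between subjects so sdr_sd carries
    # between-subject signal
    spread = rng.uniform(0.6, 1.6, size=n)
    sdr = 0.45 + rng.normal(0.0, 1.0, size=(n, m)) * (0.10 * spread[:, None])
    table["sdr_mean"] = sdr.mean(axis=1)
    table["sdr_sd"] = sdr.std(ddof=1, axis=1)
    for param, (mu, sd) in list(DEFAULT_PARAM_DISTRIBUTIONS.items())[1:]:
        arr = rng.normal(mu, sd, size=(n, m))
        table[f"{param}_mean"] = arr.mean(axis=1)
        table[f"{param}_sd"] = arr.std(ddof=1, axis=1)
    n_son = np.clip(np.round(rng.normal(9, 2, size=n)), 2, 25)
    table["max_temperature"] = rng.normal(58.0, 2.0, size=n)
    table["active_elements"] = np.clip(
        np.round(rng.normal(1000, 15, size=n)), 1, 1024).astype(int)
    table["total_sonications"] = n_son.astype(int)
    table["summed_temperature"] = n_son * rng.normal(54.0, 2.0, size=n)

    table["age"] = rng.normal(spec.age_mean, spec.age_sd, size=n)
    table["sex"] = (rng.uniform(size=n) < 0.74).astype(int)
    table["brain_volume"] = rng.normal(1.15e6, 9e4, size=n)
    table["pre_crst_t"] = np.clip(rng.normal(60.0, 17.3, size=n), 10, 160)
    table["ablation_volume"] = np.clip(rng.normal(11.61, 4.82, size=n), 1, None)
    table["native_overlap"] = np.clip(rng.normal(20.86, 11.33, size=n), 0, 100)
    table["adrtt_overlap"] = np.clip(rng.normal(21.79, 10.56, size=n), 0, 100)
    table["mdrtt_overlap"] = np.clip(rng.normal(28.35, 11.66, size=n), 0, 100)
    table["pdrtt_overlap"] = np.clip(rng.normal(25.28, 12.14, size=n), 0, 100)
    table["vlp_overlap_volume"] = np.clip(rng.normal(5.13, 3.64, size=n), 0, None)

    secondary = np.zeros(n, dtype=bool)
    secondary[rng.choice(n, size=min(spec.n_secondary_lesions, n),
                         replace=False)] = True
    table["secondary_lesion"] = secondary

    Z = np.column_stack([_zscore(table[c].to_numpy(dtype=np.float64))
                         for c in spec.effects])
    beta = np.array(list(spec.effects.values()))
    signal = Z @ beta
    s2 = signal.var(ddof=1)
    if spec.residual_sd is not None:
        sigma = spec.residual_sd
    else:
        sigma = float(np.sqrt(s2 * (1.0 / spec.target_r2 - 1.0)))
    y = signal + rng.normal(0.0, sigma, size=n) if sigma > 0 else signal
    y_sd = y.std(ddof=1)
    scaled = spec.response_mean + spec.response_sd * (y - y.mean()) / y_sd
    table[spec.response] = np.clip(scaled, -100.0, 100.0)

    # exact raw-scale coefficients of the signal part of the response
    gain = spec.response_sd / y_sd
    raw = {}
    intercept = spec.response_mean - spec.response_sd * y.mean() / y_sd
    for c, b in spec.effects.items():
        x = table[c].to_numpy(dtype=np.float64)
        raw[c] = gain * b / x.std(ddof=1)
        intercept -= raw[c] * x.mean()
    truth = {"std_effects": dict(spec.effects), "raw_coefficients": raw,
             "intercept": intercept, "residual_sd": sigma}
    return table, truth
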