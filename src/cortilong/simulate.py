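"""Synthetic longitudinal cohort and thickness-map generation.

Emulates the design of a multi-site accelerated-longitudinal study of youth
at clinical high risk (CHR) for psychosis: three clinical groups (healthy
controls HC, non-converters CHR-NC, converters CHR-C), up to five structural
scans targeted at 0/2/4/6/8 months with per-visit jitter and dropout,
scanner (site) offsets, subject-specific baseline thickness, and
group-specific thinning slopes concentrated in spatially smooth cortical
patches. A separate travelling-subjects generator produces the crossed
subject x site x day design used for scanner-reliability ICCs.

Default parameters encode the reference study conditions: group sizes
62/338/42, mean scans per subject ~3.7 (HC) and ~2.7 (CHR), conversion times
N(8.8, 7.6) months truncated at 0.5, and CHR-C thinning steepest with CHR-NC
intermediate.

The generated data model per scan i at vertex v is

    thickness = baseline_field(v) + subject_intercept + age/sex effects
                + [background_slope + group_patch_slope(v)] * months
                + scanner_offset + residual noise,

i.e. exactly the fixed/random structure the downstream mixed model assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .surface import SurfaceMesh, geodesic_patch, smooth_surface

__all__ = [
    "CohortConfig",
    "EffectSpec",
    "TravellingConfig",
    "generate_cohort",
    "generate_thickness",
    "generate_travelling",
    "default_dropout",
]

#: Per-visit dropout probabilities calibrated so that the expected number of
#: scans per subject (1 baseline + 4 follow-ups) matches the reference
#: design: HC 1 + 4*(1-0.325) = 3.7, CHR 1 + 4*(1-0.575) = 2.7.
default_dropout = {"HC": 0.325, "CHR-NC": 0.575, "CHR-C": 0.575}


@dataclass
class CohortConfig:
    """Cohort composition and visit-schedule parameters."""

    n_hc: int = 62
    n_chrnc: int = 338
    n_chrc: int = 42
    scan_schedule_months: tuple[float, ...] = (0.0, 2.0, 4.0, 6.0, 8.0)
    visit_jitter_sd: float = 0.75          # months, follow-up visits only
    dropout_prob_per_visit: float | dict = dc_field(
        default_factory=lambda: dict(default_dropout))
    age_mean: float = 19.3                 # years at first scan
    age_sd: float = 4.2
    age_range: tuple[float, float] = (12.0, 30.0)
    n_scanners: int = 7
    scanner_offset_sd: float = 0.05        # mm
    conversion_time_mean: float = 8.8      # months from first scan
    conversion_time_sd: float = 7.6
    seed: int = 0

    def __post_init__(self):
        if min(self.n_hc, self.n_chrnc, self.n_chrc) < 0:
            raise ValueError("group counts must be >= 0")
        if self.n_hc + self.n_chrnc + self.n_chrc == 0:
            raise ValueError("at least one subject required across groups")
        sched = tuple(self.scan_schedule_months)
        if sched[0] != 0 or any(b <= a for a, b in zip(sched, sched[1:])):
            raise ValueError("scan schedule must be strictly increasing from 0")
        probs = self.dropout_prob_per_visit
        vals = probs.values() if isinstance(probs, dict) else [probs]
        if any(not (0.0 <= p <= 1.0) for p in vals):
            raise ValueError("dropout probabilities must lie in [0, 1]")
        if self.visit_jitter_sd < 0 or self.age_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.n_scanners < 1:
            raise ValueError("need at least one scanner")

    def dropout_for(self, group: str) -> float:
        p = self.dropout_prob_per_visit
        return p[group] if isinstance(p, dict) else float(p)


@dataclass
class EffectSpec:
    """Spatial and covariate effect structure of the thickness model.

    Slopes are mm/month; the group-specific patch slopes apply inside the
    geodesic patch around ``patch_center_vertices``, on top of the global
    ``background_slope``. Defaults encode steepest thinning for converters,
    intermediate for non-converters, flat controls.
    """

    patch_center_vertices: tuple[int, ...] = (0,)
    patch_radius_mm: float = 10.0
    slope_hc: float = 0.0
    slope_chrnc: float = -0.005
    slope_chrc: float = -0.02
    background_slope: float = -0.002
    baseline_mean: float = 2.5             # mm
    baseline_spatial_sd: float = 0.3       # mm, across vertices
    baseline_smooth_fwhm: float = 25.0     # mm, spatial correlation scale
    subject_intercept_sd: float = 0.25     # mm
    residual_sd: float = 0.12              # mm, per scan x vertex
    age_coef: float = -0.01                # mm/year
    sex_coef: float = 0.02                 # mm, male minus female
    clip_floor: float = 0.5                # mm

    def __post_init__(self):
        if self.patch_radius_mm <= 0:
            raise ValueError("patch_radius_mm must be > 0")
        if self.residual_sd < 0 or self.subject_intercept_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be > 0")

    def slope_for(self, group: str) -> float:
        return {"HC": self.slope_hc, "CHR-NC": self.slope_chrnc,
                "CHR-C": self.slope_chrc}[group]


@dataclass
class TravellingConfig:
    """Travelling-subjects reliability study: every subject scanned at every
    site on ``n_days`` successive days."""

    n_subjects: int = 9
    n_sites: int = 9
    n_days: int = 2
    n_parcels: int = 68
    subject_sd: float = 0.12               # mm, between-subject per parcel
    site_bias_sd: float = 0.04             # mm, per site x parcel
    day_noise_sd: float = 0.03             # mm, per measurement
    unreliable_sites: tuple[int, ...] = ()
    unreliable_noise_factor: float = 3.0
    parcel_mean_range: tuple[float, float] = (2.0, 3.0)
    seed: int = 0

    def __post_init__(self):
        if min(self.n_subjects, self.n_sites, self.n_parcels) < 1:
            raise ValueError("counts must be >= 1")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.n_days < 2:
            raise ValueError("n_days must be >= 2 for test-retest reliability")


COHORT_COLUMNS = [
    "subject_id", "group", "sex", "age_first_scan", "scanner",
    "months_from_baseline", "converted", "post_conversion", "cpz_dose",
]


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate the long-format scan table for a synthetic cohort.

    One row per retained scan; every subject keeps the baseline scan.
    Follow-up visits are independently missed with the per-group dropout
    probability and jittered around their scheduled month (Gaussian,
    truncated below at 0.1 months so follow-ups stay after baseline).
    CHR-C subjects receive a conversion time (Gaussian, truncated at 0.5
    months); scans after conversion are flagged, not removed. Deterministic
    given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    groups = (["HC"] * config.n_hc + ["CHR-NC"] * config.n_chrnc
              + ["CHR-C"] * config.n_chrc)
    rows = []
    for i, group in enumerate(groups):
        sid = f"sub-{i:04d}"
        age = float(np.clip(rng.normal(config.age_mean, config.age_sd),
                            *config.age_range))
        sex = "M" if rng.random() < 0.5 else "F"
        scanner = f"site{rng.integers(config.n_scanners):02d}"
        converted = group == "CHR-C"
        conv_time = np.nan
        if converted:
            conv_time = max(0.5, rng.normal(config.conversion_time_mean,
                                            config.conversion_time_sd))
        dropout = config.dropout_for(group)
        for j, target in enumerate(config.scan_schedule_months):
            if j == 0:
                month = 0.0
            else:
                if rng.random() < dropout:
                    continue
                month = max(0.1, rng.normal(target, config.visit_jitter_sd))
            rows.append({
                "subject_id": sid,
                "group": group,
                "sex": sex,
                "age_first_scan": age,
                "scanner": scanner,
                "months_from_baseline": month,
                "converted": int(converted),
                "post_conversion": int(converted and month > conv_time),
                "cpz_dose": np.nan,
                "conversion_time": conv_time,
            })
    cohort = pd.DataFrame(rows)
    return cohort.sort_values(["subject_id", "months_from_baseline"],
                              kind="stable").reset_index(drop=True)


def generate_thickness(
    mesh: SurfaceMesh,
    cohort: pd.DataFrame,
    effects: EffectSpec,
    seed: int = 0,
    scanner_offset_sd: float | None = None,
) -> np.ndarray:
    """Per-scan x per-vertex thickness matrix aligned to the cohort rows.

    The baseline spatial field is smoothed white noise (via the package's
    own surface smoother) rescaled to ``baseline_spatial_sd`` around
    ``baseline_mean``. Values are clipped below at ``clip_floor``.
    Deterministic given ``seed``.

    ``scanner_offset_sd`` defaults to the EffectSpec-independent value 0.05
    mm; pass 0 to disable scanner offsets.
    """
    centers = np.asarray(effects.patch_center_vertices, dtype=int)
    if centers.min(initial=0) < 0 or centers.max(initial=0) >= mesh.n_vertices:
        raise ValueError("patch center vertices must lie on the mesh")
    # reject patches wider than the mesh itself
    extent = np.linalg.norm(
        mesh.vertices.max(axis=0) - mesh.vertices.min(axis=0))
    if effects.patch_radius_mm > np.pi * extent:
        raise ValueError("patch radius exceeds the mesh extent")
    if scanner_offset_sd is None:
        scanner_offset_sd = 0.05

    rng = np.random.default_rng(seed)
    V = mesh.n_vertices

    raw = rng.standard_normal(V)
    base = smooth_surface(mesh, raw, effects.baseline_smooth_fwhm)
    sd = base.std()
    if sd > 0 and effects.baseline_spatial_sd > 0:
        base = (base - base.mean()) / sd * effects.baseline_spatial_sd
    else:
        base = np.zeros(V)
    base = effects.baseline_mean + base

    patch = geodesic_patch(mesh, centers, effects.patch_radius_mm)
    in_patch = np.zeros(V)
    in_patch[patch] = 1.0

    subject_ids, codes = np.unique(cohort["subject_id"].to_numpy(),
                                   return_inverse=True)
    b = rng.normal(0.0, effects.subject_intercept_sd, size=subject_ids.size)
    scanners, scodes = np.unique(cohort["scanner"].astype(str).to_numpy(),
                                 return_inverse=True)
    offs = rng.normal(0.0, scanner_offset_sd, size=scanners.size)

    months = cohort["months_from_baseline"].to_numpy(dtype=float)
    age = cohort["age_first_scan"].to_numpy(dtype=float)
    male = (cohort["sex"].astype(str) == "M").to_numpy(dtype=float)
    gslope = np.array([effects.slope_for(g) for g in cohort["group"]])

    Y = np.tile(base, (len(cohort), 1))
    Y += (b[codes] + offs[scodes]
          + effects.age_coef * (age - age.mean())
          + effects.sex_coef * male
          + effects.background_slope * months)[:, None]
    Y += np.outer(months * gslope, in_patch)
    if effects.residual_sd > 0:
        Y += rng.normal(0.0, effects.residual_sd, size=Y.shape)
    np.maximum(Y, effects.clip_floor, out=Y)
    return Y


def true_patch(mesh: SurfaceMesh, effects: EffectSpec) -> np.ndarray:
    """Vertex ids of the generated effect patch (for recovery checks)."""
    return geodesic_patch(mesh, np.asarray(effects.patch_center_vertices, int),
                          effects.patch_radius_mm)


def generate_travelling(config: TravellingConfig) -> pd.DataFrame:
    """Complete crossed subject x site x day table of per-parcel values.

    Columns: subject, site, day, parcel, value. Sites listed in
    ``unreliable_sites`` receive ``unreliable_noise_factor`` times larger
    site bias and day-to-day noise. Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    c = config
    lo, hi = c.parcel_mean_range
    parcel_mean = rng.uniform(lo, hi, size=c.n_parcels)
    subj_eff = rng.normal(0.0, c.subject_sd, size=(c.n_subjects, c.n_parcels))
    factor = np.ones(c.n_sites)
    for s in c.unreliable_sites:
        factor[s] = c.unreliable_noise_factor
    site_bias = rng.normal(0.0, c.site_bias_sd,
                           size=(c.n_sites, c.n_parcels)) * factor[:, None]
    noise = rng.normal(0.0, c.day_noise_sd,
                       size=(c.n_subjects, c.n_sites, c.n_days, c.n_parcels))
    noise *= factor[None, :, None, None]
    vals = (parcel_mean[None, None, None, :] + subj_eff[:, None, None, :]
            + site_bias[None, :, None, :] + noise)
    subj, site, day, parcel = np.meshgrid(
        np.arange(c.n_subjects), np.arange(c.n_sites), np.arange(c.n_days),
        np.arange(c.n_parcels), indexing="ij")
    return pd.DataFrame({
        "subject": [f"trav{int(i):02d}" for i in subj.ravel()],
        "site": [f"site{int(s):02d}" for s in site.ravel()],
        "day": day.ravel() + 1,
        "parcel": [f"parcel{int(p):03d}" for p in parcel.ravel()],
        "value": vals.ravel(),
    })
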