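"""Synthetic phantoms and cohorts with known ground truth.

Two generators make every pipeline stage testable without patient data:

* Geometric phantoms — pairs of ellipsoidal tumor / ice-ball masks voxelized
  on a shared lattice.  For sphere pairs the true minimal treatment margin
  has the closed form ``r_ice - |center offset| - r_tumor``; for general
  ellipsoid pairs it is computed by dense direction sampling of the signed
  distance from tumor-surface points to the ice surface.

* Cohorts — per-case records whose marginal structure mirrors a small
  renal-tumor cryoablation series: tumor diameters truncated-normal around
  31.3 mm (SD 9.4, bounds 16-51 mm), a margin that shrinks with tumor size
  (``mtm = a - b * diameter_cm + noise``, defaults a = 9 mm, b = 2 mm/cm,
  noise SD 2.5 mm, so negative margins arise predominantly above 3 cm),
  local-progression events from a proportional-hazards model whose
  log-hazard is linear in the margin (default true beta = -0.26 per mm),
  administrative censoring uniform on 1-58 months, and categorical
  covariate frequencies matching the published cohort.  The generator's
  true parameters are returned alongside the records for oracle tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import SpecError
from .imaging_io import BinaryMask, ImageGeometry
from .margin_analysis import round_half_away_from_zero
from .outcome_stats import CaseRecord
from .registration import LandmarkSet, RigidTransform


# ---------------------------------------------------------------------------
# geometric phantoms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid in world mm: center and positive semi-axes."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes):
            raise SpecError(f"semi-axes must be positive, got {self.semi_axes}")

    @property
    def is_sphere(self) -> bool:
        a = self.semi_axes
        return abs(a[0] - a[1]) < 1e-12 and abs(a[1] - a[2]) < 1e-12

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = (np.atleast_2d(points) - np.asarray(self.center)) / np.asarray(self.semi_axes)
        return (p**2).sum(axis=1) <= 1.0

    def surface_points(self, directions: np.ndarray) -> np.ndarray:
        """Surface point along each unit direction from the center."""
        d = directions / np.linalg.norm(directions, axis=1, keepdims=True)
        scale = 1.0 / np.sqrt(((d / np.asarray(self.semi_axes)) ** 2).sum(axis=1))
        return np.asarray(self.center) + d * scale[:, None]

    def signed_distance(self, points: np.ndarray, n_directions: int = 20000,
                        seed: int = 0) -> np.ndarray:
        """Signed distance to the ellipsoid surface, positive inside.

        Exact for spheres; for general ellipsoids the surface is sampled
        densely and the nearest sampled surface point is used.
        """
        pts = np.atleast_2d(points)
        if self.is_sphere:
            r = self.semi_axes[0]
            return r - np.linalg.norm(pts - np.asarray(self.center), axis=1)
        dirs = _fibonacci_sphere(n_directions)
        surf = self.surface_points(dirs)
        from scipy.spatial import cKDTree

        dist, _ = cKDTree(surf).query(pts, workers=-1)
        sign = np.where(self.contains(pts), 1.0, -1.0)
        return sign * dist


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Near-uniform unit directions (golden-angle spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack([
        np.sin(phi) * np.cos(theta),
        np.sin(phi) * np.sin(theta),
        np.cos(phi),
    ])


@dataclass(frozen=True)
class PhantomSpec:
    """A tumor/ice ellipsoid pair on a shared voxel lattice."""

    shape: tuple[int, int, int] = (72, 72, 72)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tumor: Ellipsoid = Ellipsoid((36.0, 36.0, 36.0), (10.0, 10.0, 10.0))
    ice: Ellipsoid = Ellipsoid((36.0, 36.0, 36.0), (15.0, 15.0, 15.0))
    seed: int = 0

    def geometry(self) -> ImageGeometry:
        return ImageGeometry.from_spacing(self.shape, self.spacing)

    def validate(self) -> None:
        extent = np.asarray(self.shape) * np.asarray(self.spacing)
        clearance = 2.0 * np.asarray(self.spacing)
        for name, ell in (("tumor", self.tumor), ("ice", self.ice)):
            lo = np.asarray(ell.center) - np.asarray(ell.semi_axes)
            hi = np.asarray(ell.center) + np.asarray(ell.semi_axes)
            if np.any(lo < clearance) or np.any(hi > extent - clearance):
                raise SpecError(
                    f"{name} ellipsoid must fit inside the grid with >= 2 voxels clearance"
                )


@dataclass(frozen=True)
class PhantomTruth:
    """Analytic / brute-force ground truth for a phantom pair."""

    analytic_mtm_mm: float
    tumor_volume_ml: float
    ice_volume_ml: float
    max_diameter_mm: float


def sphere_pair_mtm(r_tumor: float, r_ice: float, center_offset: float) -> float:
    """Closed-form minimal margin for a sphere pair (fully disjoint included)."""
    return r_ice - abs(center_offset) - r_tumor


def _ellipsoid_pair_mtm(tumor: Ellipsoid, ice: Ellipsoid,
                        n_directions: int = 100_000) -> float:
    """Brute-force minimal signed margin over densely sampled tumor-surface points."""
    dirs = _fibonacci_sphere(n_directions)
    surf = tumor.surface_points(dirs)
    return float(ice.signed_distance(surf, n_directions=n_directions).min())


def phantom_truth(spec: PhantomSpec, n_directions: int = 100_000) -> PhantomTruth:
    t, i = spec.tumor, spec.ice
    if t.is_sphere and i.is_sphere:
        offset = float(np.linalg.norm(np.asarray(i.center) - np.asarray(t.center)))
        mtm = sphere_pair_mtm(t.semi_axes[0], i.semi_axes[0], offset)
    else:
        mtm = _ellipsoid_pair_mtm(t, i, n_directions)
    vol = lambda e: 4.0 / 3.0 * np.pi * np.prod(e.semi_axes) / 1000.0
    return PhantomTruth(
        analytic_mtm_mm=mtm,
        tumor_volume_ml=float(vol(t)),
        ice_volume_ml=float(vol(i)),
        max_diameter_mm=2.0 * float(max(t.semi_axes)),
    )


def make_phantom(spec: PhantomSpec) -> tuple[BinaryMask, BinaryMask, PhantomTruth]:
    """Voxelize a phantom spec: a voxel is foreground iff its center is inside."""
    spec.validate()
    geom = spec.geometry()
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in spec.shape), indexing="ij")
    centers = geom.voxel_to_world(
        np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
    )
    tumor = spec.tumor.contains(centers).reshape(spec.shape).astype(np.uint8)
    ice = spec.ice.contains(centers).reshape(spec.shape).astype(np.uint8)
    return (
        BinaryMask(geom, tumor),
        BinaryMask(geom, ice),
        phantom_truth(spec),
    )


def sweep_sphere_phantoms(
    n: int = 50,
    seed: int = 42,
    mtm_range_mm: tuple[float, float] = (-11.0, 6.0),
    shape: tuple[int, int, int] = (96, 96, 96),
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
):
    """Yield ``n`` sphere-pair specs whose analytic margins span ``mtm_range_mm``.

    Target margins are spaced evenly over the range (the clinically observed
    span of minimal margins); tumor radius, ice radius and the offset
    direction are drawn from the seeded stream, and the center offset is
    solved so the closed-form margin hits each target exactly.
    """
    rng = np.random.default_rng(seed)
    lo, hi = mtm_range_mm
    ctr = 0.5 * (np.asarray(shape) - 1) * np.asarray(spacing)
    for s in range(n):
        target = lo + (hi - lo) * s / (n - 1)
        r_t = rng.uniform(8.0, 13.0)
        r_i = r_t + rng.uniform(6.0, 8.0)
        offset = r_i - r_t - target
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        yield PhantomSpec(
            shape=shape, spacing=spacing,
            tumor=Ellipsoid(tuple(ctr), (r_t,) * 3),
            ice=Ellipsoid(tuple(ctr + offset * d), (r_i,) * 3),
            seed=s,
        )


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Parametric model of a renal-cryoablation cohort.

    Defaults encode the study conditions the generator emulates; they are a
    qualitative stand-in for the real series, not estimates of it.
    """

    n_cases: int = 32
    diameter_mean_mm: float = 31.3
    diameter_sd_mm: float = 9.4
    diameter_bounds_mm: tuple[float, float] = (16.0, 51.0)
    margin_intercept_mm: float = 9.0
    margin_slope_mm_per_cm: float = 2.0
    margin_noise_sd_mm: float = 2.5
    true_beta_per_mm: float = -0.26
    baseline_hazard_per_month: float = 0.008
    censor_bounds_months: tuple[float, float] = (1.0, 58.0)
    p_male: float = 0.666
    p_asa_ii: float = 0.566
    p_renal: tuple[float, float, float] = (0.625, 0.344, 0.031)

    def validate(self) -> None:
        if self.n_cases < 2:
            raise SpecError("n_cases must be >= 2")
        if self.diameter_sd_mm <= 0 or self.margin_noise_sd_mm < 0:
            raise SpecError("scale parameters must be positive")
        if self.diameter_bounds_mm[0] >= self.diameter_bounds_mm[1]:
            raise SpecError("diameter bounds must be increasing")
        if self.baseline_hazard_per_month <= 0:
            raise SpecError("baseline hazard must be positive")
        if abs(sum(self.p_renal) - 1.0) > 1e-9:
            raise SpecError("renal category probabilities must sum to 1")
        for p in (self.p_male, self.p_asa_ii, *self.p_renal):
            if not 0.0 <= p <= 1.0:
                raise SpecError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class CohortTruth:
    """The generator's true parameters, for parameter-recovery oracles."""

    beta_per_mm: float
    baseline_hazard_per_month: float
    margin_intercept_mm: float
    margin_slope_mm_per_cm: float
    seed: int

    def true_event_free(self, t_months: float, mtm_raw_mm: float) -> float:
        """True survival of the event-time model at t for a given margin."""
        rate = self.baseline_hazard_per_month * np.exp(self.beta_per_mm * mtm_raw_mm)
        return float(np.exp(-rate * t_months))


def simulate_cohort(spec: CohortSpec, seed: int) -> tuple[list[CaseRecord], CohortTruth]:
    """Draw a reproducible synthetic cohort from a :class:`CohortSpec` model."""
    spec.validate()
    rng = np.random.default_rng(seed)
    n = spec.n_cases

    lo, hi = spec.diameter_bounds_mm
    a = (lo - spec.diameter_mean_mm) / spec.diameter_sd_mm
    b = (hi - spec.diameter_mean_mm) / spec.diameter_sd_mm
    diam = stats.truncnorm.rvs(
        a, b, loc=spec.diameter_mean_mm, scale=spec.diameter_sd_mm,
        size=n, random_state=rng,
    )

    mtm = (
        spec.margin_intercept_mm
        - spec.margin_slope_mm_per_cm * diam / 10.0
        + rng.normal(0.0, spec.margin_noise_sd_mm, size=n)
    )

    # proportional-hazards event model: exponential with log-hazard linear in mtm
    rate = spec.baseline_hazard_per_month * np.exp(spec.true_beta_per_mm * mtm)
    t_event = rng.exponential(1.0 / rate)
    t_censor = rng.uniform(*spec.censor_bounds_months, size=n)
    event = t_event <= t_censor
    time = np.minimum(t_event, t_censor)

    sex = rng.random(n) < spec.p_male
    asa = rng.random(n) < spec.p_asa_ii
    renal = rng.choice(3, size=n, p=list(spec.p_renal))

    # plausible morphometry consistent with the diameters (prolate-ish tumors)
    tumor_vol = 4.0 / 3.0 * np.pi * (diam / 2.0) ** 3 * rng.uniform(0.55, 0.85, n) / 1000.0
    ice_vol = tumor_vol * rng.uniform(3.0, 7.0, n) + rng.uniform(5.0, 15.0, n)
    n_probes = rng.integers(2, 5, size=n)

    records = []
    for i in range(n):
        records.append(CaseRecord(
            case_id=f"case-{i + 1:03d}",
            tumor_diameter_mm=float(diam[i]),
            tumor_volume_ml=float(tumor_vol[i]),
            iceball_volume_ml=float(ice_vol[i]),
            n_probes=int(n_probes[i]),
            mtm_raw_mm=float(mtm[i]),
            mtm_mm=round_half_away_from_zero(float(mtm[i])),
            sex="male" if sex[i] else "female",
            asa="II" if asa[i] else "III",
            renal_category=("low", "moderate", "high")[renal[i]],
            ltp=bool(event[i]),
            time_months=float(time[i]),
            event=bool(event[i]),
        ))
    truth = CohortTruth(
        beta_per_mm=spec.true_beta_per_mm,
        baseline_hazard_per_month=spec.baseline_hazard_per_month,
        margin_intercept_mm=spec.margin_intercept_mm,
        margin_slope_mm_per_cm=spec.margin_slope_mm_per_cm,
        seed=seed,
    )
    return records, truth


# ---------------------------------------------------------------------------
# registration fixtures
# ---------------------------------------------------------------------------

def jittered_landmarks(
    n: int,
    transform: RigidTransform,
    sigma_mm: float,
    seed: int,
    box_mm: float = 100.0,
) -> tuple[LandmarkSet, LandmarkSet]:
    """Paired landmark sets: source uniform in an origin-centered box,
    target = transform(source) + isotropic Gaussian jitter."""
    if n < 3:
        raise SpecError("need >= 3 landmarks")
    rng = np.random.default_rng(seed)
    src = rng.uniform(-box_mm / 2.0, box_mm / 2.0, size=(n, 3))
    tgt = transform.apply(src) + rng.normal(0.0, sigma_mm, size=(n, 3))
    return LandmarkSet(src), LandmarkSet(tgt)


def random_rigid_transform(seed: int, max_translation_mm: float = 10.0) -> RigidTransform:
    """Uniformly random rotation with a bounded random translation."""
    rng = np.random.default_rng(seed)
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.uniform(-max_translation_mm, max_translation_mm, size=3)
    return RigidTransform(R, t)
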