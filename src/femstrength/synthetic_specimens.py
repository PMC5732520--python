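"""Synthetic CT phantoms, force-displacement curves and specimen cohorts.

No cadaver data ships with this package, so every pipeline input can be
generated here with known ground truth: calibrated CT volumes of femur-like
objects (cortical shell, trabecular interior, hydroxyapatite calibration
rods, additive Gaussian imaging noise, partial volume via supersampled
voxel averaging), bilinear force-displacement curves with a programmed
fracture knee, and cohorts whose age/strength/stiffness structure follows
the regression lines reported for elderly cadaveric femora (fracture load
declining 142.6 N per year of age). All generators are bit-reproducible
under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .ct_calibration import CTVolume, PhantomSpec, RodCylinder
from .femur_meshing import Surface
from .fracture_metrics import ForceDisplacementCurve

# cohort defaults: the fitted lines and spreads reported for the cadaver
# cohort (ages 74-101); configuration, not ground truth about new data
MECH_AGE_SLOPE = -142.6  # N per year
MECH_AGE_INTERCEPT = 15856.0  # N
FEA_AGE_SLOPE = -153.8
FEA_AGE_INTERCEPT = 17915.0


@dataclass
class PhantomDesign:
    """Parametric CT phantom: geometry, density fields, rods, noise.

    ``geometry`` is ``bar`` (box), ``cylinder``, or ``femur`` (shaft
    cylinder + angled neck cylinder + spherical head). ``trabecular_density``
    is a constant (g/cm^3) or ``("radial", centre, edge)`` for a radial
    gradient. The calibration implied by the generator is
    density[mg/cm^3] = cal_slope * HU + cal_intercept.
    """

    geometry: str = "femur"
    dimensions: dict = field(default_factory=dict)
    cortical_thickness: float = 0.0
    trabecular_density: float | tuple = 0.3
    cortical_density: float = 1.2
    rod_densities: tuple[float, ...] = (0.0, 100.0, 200.0)
    rod_hu_means: tuple[float, ...] | None = None
    cal_slope: float = 1.0  # (mg/cm^3) per HU
    cal_intercept: float = 0.0  # mg/cm^3
    noise_sigma: float = 0.0  # HU
    spacing: tuple[float, float, float] = (0.3, 0.3, 0.5)
    supersample: int = 8
    rod_radius: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        defaults = {
            "bar": {"lx": 20.0, "ly": 20.0, "lz": 40.0},
            "cylinder": {"radius": 12.0, "length": 160.0},
            "femur": {
                "shaft_radius": 14.0,
                "shaft_length": 140.0,
                "neck_radius": 10.0,
                "neck_length": 35.0,
                "neck_angle_deg": 20.0,
                "head_radius": 22.0,
            },
        }
        if self.geometry not in defaults:
            raise ValueError(f"unknown geometry {self.geometry!r}")
        d = dict(defaults[self.geometry])
        d.update(self.dimensions)
        self.dimensions = d
        if any(v <= 0 for k, v in d.items() if k != "neck_angle_deg"):
            raise ValueError(f"phantom dimensions must be positive: {d}")

    def hu_of_density(self, rho_g_cc):
        """Inverse calibration: HU producing the given density (g/cm^3)."""
        return (np.asarray(rho_g_cc) * 1000.0 - self.cal_intercept) / self.cal_slope


@dataclass
class PhantomTruth:
    """Everything the generator knows exactly about a phantom."""

    surface: Surface | None
    density_fn: Callable[[np.ndarray], np.ndarray]
    landmark_gt_tip: np.ndarray
    shaft_axis: np.ndarray  # unit vector pointing distally
    head_center: np.ndarray | None
    head_radius: float | None
    phantom_spec: PhantomSpec
    cal_slope: float
    cal_intercept: float
    design: PhantomDesign


# ---------------------------------------------------------------------------
# signed distance fields (negative inside)


def _sdf_box(pts, lx, ly, lz):
    center = np.array([0.0, 0.0, lz / 2.0])
    half = np.array([lx / 2.0, ly / 2.0, lz / 2.0])
    q = np.abs(pts - center) - half
    outside = np.linalg.norm(np.maximum(q, 0.0), axis=1)
    inside = np.minimum(q.max(axis=1), 0.0)
    return outside + inside


def _sdf_cylinder(pts, base, axis, radius, length):
    axis = axis / np.linalg.norm(axis)
    rel = pts - base
    t = rel @ axis
    radial = np.linalg.norm(rel - np.outer(t, axis), axis=1)
    dr = radial - radius
    dt = np.maximum(-t, t - length)
    outside = np.hypot(np.maximum(dr, 0.0), np.maximum(dt, 0.0))
    inside = np.minimum(np.maximum(dr, dt), 0.0)
    return outside + inside


def _sdf_sphere(pts, center, radius):
    return np.linalg.norm(pts - center, axis=1) - radius


def _specimen_sdf(design: PhantomDesign) -> tuple[Callable, dict]:
    """Signed distance of the specimen and its landmark geometry."""
    d = design.dimensions
    if design.geometry == "bar":
        lz = d["lz"]
        info = {
            "landmark": np.array([0.0, 0.0, lz]),
            "shaft_axis": np.array([0.0, 0.0, -1.0]),
            "head_center": None,
            "head_radius": None,
            "bounds": (np.array([-d["lx"] / 2, -d["ly"] / 2, 0.0]),
                       np.array([d["lx"] / 2, d["ly"] / 2, lz])),
        }
        return (lambda p: _sdf_box(p, d["lx"], d["ly"], d["lz"])), info
    if design.geometry == "cylinder":
        r, length = d["radius"], d["length"]
        info = {
            "landmark": np.array([0.0, 0.0, length]),
            "shaft_axis": np.array([0.0, 0.0, -1.0]),
            "head_center": None,
            "head_radius": None,
            "bounds": (np.array([-r, -r, 0.0]), np.array([r, r, length])),
        }
        return (
            lambda p: _sdf_cylinder(p, np.array([0.0, 0.0, 0.0]), np.array([0.0, 0.0, 1.0]), r, length)
        ), info
    # femur-like: shaft along +z, neck tilted in the x-z (coronal) plane, head sphere
    rs, ls = d["shaft_radius"], d["shaft_length"]
    rn, ln = d["neck_radius"], d["neck_length"]
    ang = np.deg2rad(d["neck_angle_deg"])
    rh = d["head_radius"]
    neck_base = np.array([0.0, 0.0, ls - rs])
    neck_dir = np.array([np.sin(ang), 0.0, np.cos(ang)])
    head_center = neck_base + neck_dir * (ln + 0.6 * rh)
    shaft_base = np.array([0.0, 0.0, 0.0])

    def sdf(p):
        return np.minimum.reduce(
            [
                _sdf_cylinder(p, shaft_base, np.array([0.0, 0.0, 1.0]), rs, ls),
                _sdf_cylinder(p, neck_base, neck_dir, rn, ln + 0.6 * rh),
                _sdf_sphere(p, head_center, rh),
            ]
        )

    ext = max(rs, rn, rh)
    hi = np.maximum(head_center + rh, [rs, rs, ls])
    info = {
        "landmark": np.array([0.0, 0.0, ls]),  # greater-trochanter-tip analogue
        "shaft_axis": np.array([0.0, 0.0, -1.0]),
        "head_center": head_center,
        "head_radius": rh,
        "bounds": (np.array([-ext, -ext, 0.0]), hi + 0.0),
    }
    return sdf, info


# ---------------------------------------------------------------------------
# phantom synthesis


def make_phantom(design: PhantomDesign) -> tuple[CTVolume, PhantomTruth]:
    """Voxelize a calibrated CT phantom with rods, noise and partial volume.

    Each voxel averages ``supersample**3`` sub-samples of the analytic HU
    field (partial-volume emulation); seeded Gaussian HU noise is added on
    top. Ground truth carries the exact density field, landmarks, and the
    rod regions as a :class:`PhantomSpec`.
    """
    sdf, info = _specimen_sdf(design)
    lo, hi = info["bounds"]
    d = design.dimensions

    # rods sit in a slab on the -y side of the specimen, parallel to z
    rod_r = design.rod_radius
    z_mid = 0.5 * (lo[2] + hi[2])
    rod_len = max(0.5 * (hi[2] - lo[2]), 4 * rod_r)
    rod_y = lo[1] - 2.5 * rod_r
    rod_xs = np.linspace(-1, 1, len(design.rod_densities)) * 3.0 * rod_r
    rods = [
        RodCylinder(
            center=(float(x), float(rod_y), float(z_mid)),
            axis=(0.0, 0.0, 1.0),
            radius=rod_r,
            half_length=rod_len / 2.0,
        )
        for x in rod_xs
    ]
    # measurement ROIs are inset from the physical rods so the mean HU is
    # never diluted by partial-volume voxels at the rod rim
    inset = 1.5 * float(max(design.spacing))
    rois = [
        RodCylinder(
            center=r.center,
            axis=r.axis,
            radius=max(r.radius - inset, 0.25 * r.radius),
            half_length=max(r.half_length - inset, 0.25 * r.half_length),
        )
        for r in rods
    ]
    rod_hu = (
        np.asarray(design.rod_hu_means, float)
        if design.rod_hu_means is not None
        else design.hu_of_density(np.asarray(design.rod_densities) / 1000.0)
    )
    if len(rod_hu) != len(design.rod_densities):
        raise ValueError("rod_hu_means must match rod_densities in length")

    margin = 3.0 * np.asarray(design.spacing)
    vol_lo = np.minimum(lo, [rod_xs.min() - 2 * rod_r, rod_y - 2 * rod_r, lo[2]]) - margin
    vol_hi = np.maximum(hi, [rod_xs.max() + 2 * rod_r, lo[1], hi[2]]) + margin
    spacing = np.asarray(design.spacing, float)
    shape = np.ceil((vol_hi - vol_lo) / spacing).astype(int)
    origin = vol_lo + 0.5 * spacing

    def density_fn(pts: np.ndarray) -> np.ndarray:
        s = sdf(pts)
        rho = np.zeros(len(pts))
        inside = s <= 0
        if isinstance(design.trabecular_density, tuple):
            kind, centre, edge = design.trabecular_density
            if kind != "radial":
                raise ValueError(f"unknown trabecular density spec {design.trabecular_density}")
            r_char = 0.5 * min(v for k, v in d.items() if k != "neck_angle_deg")
            frac = np.clip(-s / r_char, 0.0, 1.0)
            rho[inside] = (edge + (centre - edge) * frac)[inside]
        else:
            rho[inside] = design.trabecular_density
        if design.cortical_thickness > 0:
            cortex = inside & (s > -design.cortical_thickness)
            rho[cortex] = design.cortical_density
        return rho

    def hu_fn(pts: np.ndarray) -> np.ndarray:
        hu = np.zeros(len(pts))
        inside = sdf(pts) <= 0
        hu[inside] = design.hu_of_density(density_fn(pts[inside]))
        for rod, value in zip(rods, rod_hu):
            hu[rod.contains(pts)] = value
        return hu

    ss = max(1, int(design.supersample))
    offs = (np.arange(ss) + 0.5) / ss - 0.5
    ox, oy, oz = np.meshgrid(offs * spacing[0], offs * spacing[1], offs * spacing[2], indexing="ij")
    offsets = np.column_stack([ox.ravel(), oy.ravel(), oz.ravel()])

    xs = origin[0] + np.arange(shape[0]) * spacing[0]
    ys = origin[1] + np.arange(shape[1]) * spacing[1]
    zs = origin[2] + np.arange(shape[2]) * spacing[2]
    values = np.empty(shape, dtype=np.float64)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    base_xy = np.column_stack([gx.ravel(), gy.ravel()])
    for kz, z in enumerate(zs):  # slab by slab to bound memory
        centers = np.column_stack([base_xy, np.full(len(base_xy), z)])
        acc = np.zeros(len(centers))
        for off in offsets:
            acc += hu_fn(centers + off)
        values[:, :, kz] = (acc / len(offsets)).reshape(shape[0], shape[1])

    if design.noise_sigma > 0:
        rng = np.random.default_rng(design.seed)
        values = values + rng.normal(0.0, design.noise_sigma, size=values.shape)

    volume = CTVolume(values=values, spacing=tuple(spacing), origin=tuple(origin))
    truth = PhantomTruth(
        surface=_analytic_surface(design),
        density_fn=density_fn,
        landmark_gt_tip=info["landmark"],
        shaft_axis=info["shaft_axis"],
        head_center=info["head_center"],
        head_radius=info["head_radius"],
        phantom_spec=PhantomSpec(
            rod_densities=tuple(design.rod_densities), rod_regions=tuple(rois)
        ),
        cal_slope=design.cal_slope,
        cal_intercept=design.cal_intercept,
        design=design,
    )
    return volume, truth


def _analytic_surface(design: PhantomDesign) -> Surface | None:
    """Exact boundary surface for the primitive geometries (None for femur)."""
    import trimesh

    d = design.dimensions
    if design.geometry == "bar":
        tm = trimesh.creation.box(extents=[d["lx"], d["ly"], d["lz"]])
        tm.apply_translation([0, 0, d["lz"] / 2.0])
    elif design.geometry == "cylinder":
        tm = trimesh.creation.cylinder(radius=d["radius"], height=d["length"], sections=64)
        tm.apply_translation([0, 0, d["length"] / 2.0])
    else:
        return None  # union of primitives; segment from the volume instead
    return Surface(np.asarray(tm.vertices), np.asarray(tm.faces))


# ---------------------------------------------------------------------------
# synthetic force-displacement curves


def make_curve(
    stiffness: float,
    fracture_load: float,
    post_knee_stiffness_fraction: float = 0.1,
    increment: float = 0.05,
    noise_sigma: float = 0.0,
    seed: int = 0,
    max_displacement: float | None = None,
    source: str = "mechanical",
) -> ForceDisplacementCurve:
    """Bilinear curve with a programmed knee at the fracture load.

    The curve rises at ``stiffness`` N/mm to the knee, then continues at
    ``post_knee_stiffness_fraction`` of it; seeded Gaussian force noise is
    added pointwise. ``post_knee_stiffness_fraction = 1`` degenerates to a
    straight line (no fracture).
    """
    if stiffness <= 0 or fracture_load <= 0:
        raise ValueError("stiffness and fracture_load must be positive")
    d_knee = fracture_load / stiffness
    if max_displacement is None:
        max_displacement = 1.8 * d_knee
    disp = np.arange(0.0, max_displacement + 0.5 * increment, increment)
    force = np.where(
        disp <= d_knee,
        stiffness * disp,
        fracture_load + post_knee_stiffness_fraction * stiffness * (disp - d_knee),
    )
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        force = force + rng.normal(0.0, noise_sigma, size=force.shape)
    return ForceDisplacementCurve(displacement=disp, force=force, source=source)


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class CohortDesign:
    """Statistical model of a paired left/right specimen cohort.

    Per femur: mech fracture load = b0 + b1*age + latent + noise, the FE
    prediction shares the latent strength deviation with its own line and
    noise (making the mech-vs-FE correlation tunable), and each stiffness is
    fracture load / divisor + noise. Defaults emulate an elderly cadaver
    cohort (ages 74-101, load falling 142.6 N/yr). ``laterality_effect`` is
    added to right-side mech loads.
    """

    n_specimens: int = 20
    age_range: tuple[float, float] = (74.0, 101.0)
    b0: float = MECH_AGE_INTERCEPT
    b1: float = MECH_AGE_SLOPE
    fea_b0: float = FEA_AGE_INTERCEPT
    fea_b1: float = FEA_AGE_SLOPE
    latent_sd: float = 1141.0
    mech_noise_sd: float = 844.0
    fea_noise_sd: float = 844.0
    stiffness_divisor_mech: float = 2.684
    stiffness_divisor_fea: float = 2.886
    stiffness_noise_mech: float = 517.0
    stiffness_noise_fea: float = 130.0
    laterality_effect: float = 0.0
    with_curves: bool = False
    curve_increment: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_specimens < 2:
            raise ValueError("cohort needs at least 2 specimens")
        for name in ("latent_sd", "mech_noise_sd", "fea_noise_sd",
                     "stiffness_noise_mech", "stiffness_noise_fea"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def make_cohort(design: CohortDesign) -> list[dict]:
    """Generate per-specimen records (and optionally bilinear curves)."""
    rng = np.random.default_rng(design.seed)
    n = design.n_specimens
    n_cadavers = (n + 1) // 2
    ages = rng.uniform(*design.age_range, size=n_cadavers)
    sexes = np.where(np.arange(n_cadavers) % 2 == 0, "M", "F")
    records = []
    for i in range(n):
        cad = i // 2
        side = "right" if i % 2 == 0 else "left"
        age = float(ages[cad])
        latent = rng.normal(0.0, design.latent_sd)
        mech_fl = (
            design.b0
            + design.b1 * age
            + latent
            + rng.normal(0.0, design.mech_noise_sd)
            + (design.laterality_effect if side == "right" else 0.0)
        )
        fea_fl = (
            design.fea_b0 + design.fea_b1 * age + latent + rng.normal(0.0, design.fea_noise_sd)
        )
        mech_k = mech_fl / design.stiffness_divisor_mech + rng.normal(
            0.0, design.stiffness_noise_mech
        )
        fea_k = fea_fl / design.stiffness_divisor_fea + rng.normal(
            0.0, design.stiffness_noise_fea
        )
        rec = {
            "specimen_id": f"S{i:03d}",
            "cadaver_id": f"C{cad:02d}",
            "side": side,
            "age": age,
            "sex": str(sexes[cad]),
            "mech_fracture_load": float(mech_fl),
            "mech_stiffness": float(mech_k),
            "fea_fracture_load": float(fea_fl),
            "fea_stiffness": float(fea_k),
        }
        if design.with_curves:
            rec["mech_curve"] = make_curve(
                stiffness=max(mech_k, 50.0),
                fracture_load=max(mech_fl, 100.0),
                increment=design.curve_increment,
                seed=design.seed * 100003 + 2 * i,
                source="mechanical",
            )
            rec["fea_curve"] = make_curve(
                stiffness=max(fea_k, 50.0),
                fracture_load=max(fea_fl, 100.0),
                increment=design.curve_increment,
                seed=design.seed * 100003 + 2 * i + 1,
                source="fea",
            )
        records.append(rec)
    return records
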