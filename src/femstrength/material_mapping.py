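"""Density-based material mapping and Drucker-Prager calibration.

Each tetrahedron receives the mean HU of the CT voxels it contains, the
calibration turns HU into equivalent mineral density rho (g/cm^3), and a
density-property power law turns rho into Young's modulus and compressive
yield stress. The normative law is Keller's vertebral relations

    E     = 1890 rho^1.92  MPa   (rho > 0),   E = 0.001 MPa at rho <= 0
    sigma = 284  rho^2.27  MPa   (rho > 0.2), sigma = 1e20 MPa at rho <= 0.2

with the modulus clamped to [0.01 MPa, 20 GPa] during assignment, Poisson's
ratio fixed at 0.3, and tensile yield taken as 0.8x compressive. The 1e20
sentinel marks low-density elements as effectively never yielding. Yield is
governed by the pressure-sensitive Drucker-Prager surface

    f(sigma) = alpha I1 + sqrt(J2) - k

whose constants are calibrated so uniaxial compression at sigma_c and
uniaxial tension at 0.8 sigma_c both sit exactly on the surface.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np

from .ct_calibration import CTVolume, DensityCalibration, hu_to_density
from .femur_meshing import TetMesh

MODULUS_FLOOR_MPA = 0.01
MODULUS_CEILING_MPA = 20000.0
YIELD_SENTINEL_MPA = 1.0e20
POISSON_RATIO = 0.3
TENSILE_RATIO = 0.8
SHELL_HU = 1000.0


@dataclass(frozen=True)
class MaterialLaw:
    """A density-property law pair: rho (g/cm^3) -> E (MPa), sigma_c (MPa)."""

    name: str
    modulus_fn: Callable[[np.ndarray], np.ndarray]
    yield_fn: Callable[[np.ndarray], np.ndarray]
    citation: str = ""


@dataclass
class ElementMaterial:
    """Isotropic elastoplastic material record for one element."""

    E: float
    nu: float
    sigma_c: float
    sigma_t: float
    rho: float
    hu: float


@dataclass(frozen=True)
class DruckerPragerParams:
    """Constants of f = alpha*I1 + sqrt(J2) - k."""

    alpha: float
    k: float

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.k <= 0:
            raise ValueError(f"invalid Drucker-Prager constants alpha={self.alpha}, k={self.k}")


# ---------------------------------------------------------------------------
# the normative law and the registry


def keller_modulus(rho) -> np.ndarray | float:
    """Vertebral density-modulus power law, before clamping (MPa)."""
    rho = np.asarray(rho, dtype=float)
    with np.errstate(invalid="ignore"):
        e = np.where(rho > 0, 1890.0 * np.power(np.maximum(rho, 0.0), 1.92), 0.001)
    return float(e) if e.ndim == 0 else e


def keller_yield(rho) -> np.ndarray | float:
    """Vertebral density-yield power law (MPa); sentinel below 0.2 g/cm^3."""
    rho = np.asarray(rho, dtype=float)
    s = np.where(
        rho > 0.2, 284.0 * np.power(np.maximum(rho, 1e-300), 2.27), YIELD_SENTINEL_MPA
    )
    return float(s) if s.ndim == 0 else s


def make_power_law(
    name: str,
    modulus_coef: float,
    modulus_exp: float,
    yield_coef: float,
    yield_exp: float,
    modulus_floor_rho: float = 0.0,
    yield_floor_rho: float = 0.0,
    citation: str = "",
) -> MaterialLaw:
    """Build a configuration-supplied power law E = a*rho^b, sigma = c*rho^d.

    Below the respective density floors the modulus falls back to 0.001 MPa
    and the yield to the never-yield sentinel, mirroring the normative law's
    structure. Coefficients for alternative published laws (e.g. Keyak,
    Carter) are supplied by the caller with their citation.
    """

    def e_fn(rho):
        rho = np.asarray(rho, dtype=float)
        out = np.where(
            rho > modulus_floor_rho,
            modulus_coef * np.power(np.maximum(rho, 1e-300), modulus_exp),
            0.001,
        )
        return float(out) if out.ndim == 0 else out

    def y_fn(rho):
        rho = np.asarray(rho, dtype=float)
        out = np.where(
            rho > yield_floor_rho,
            yield_coef * np.power(np.maximum(rho, 1e-300), yield_exp),
            YIELD_SENTINEL_MPA,
        )
        return float(out) if out.ndim == 0 else out

    return MaterialLaw(name=name, modulus_fn=e_fn, yield_fn=y_fn, citation=citation)


LAW_REGISTRY: dict[str, MaterialLaw] = {
    "keller_vertebra": MaterialLaw(
        name="keller_vertebra",
        modulus_fn=keller_modulus,
        yield_fn=keller_yield,
        citation="Keller TS, J Biomech 1994 (vertebral relations)",
    )
}


def get_law(name: str) -> MaterialLaw:
    try:
        return LAW_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown material law {name!r}; registered: {sorted(LAW_REGISTRY)}"
        ) from None


def clamp_modulus(e_raw) -> np.ndarray | float:
    """Clamp modulus to [0.01 MPa, 20 GPa]."""
    out = np.clip(np.asarray(e_raw, dtype=float), MODULUS_FLOOR_MPA, MODULUS_CEILING_MPA)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# element HU averaging


def element_average_hu(volume: CTVolume, mesh: TetMesh) -> np.ndarray:
    """Mean HU of voxel centers inside each tet; centroid interpolation fallback.

    A tetrahedron that contains no voxel center gets the HU trilinearly
    interpolated at its centroid. A tet entirely outside the scanned volume
    is an error. Meshes carrying a CT transform (cut and oriented into the
    stance frame) are mapped back into the volume's frame first.
    """
    from scipy.ndimage import map_coordinates

    spacing = np.asarray(volume.spacing)
    origin = np.asarray(volume.origin)
    shape = np.asarray(volume.shape)
    nodes = mesh.nodes_in_ct_frame()
    out = np.full(mesh.n_tets, np.nan)

    vals = volume.values
    centroids = nodes[mesh.tets].mean(axis=1)
    idx_c = (centroids - origin) / spacing
    outside = (idx_c < -0.5).any(axis=1) | (idx_c > shape - 0.5).any(axis=1)
    if outside.any():
        raise ValueError(
            f"element {int(np.where(outside)[0][0])} lies outside the CT volume"
        )

    for t in range(mesh.n_tets):
        p = nodes[mesh.tets[t]]
        lo = np.ceil((p.min(axis=0) - origin) / spacing).astype(int)
        hi = np.floor((p.max(axis=0) - origin) / spacing).astype(int)
        lo = np.maximum(lo, 0)
        hi = np.minimum(hi, shape - 1)
        if np.any(hi < lo):
            continue
        ax = [origin[d] + np.arange(lo[d], hi[d] + 1) * spacing[d] for d in range(3)]
        gx, gy, gz = np.meshgrid(*ax, indexing="ij")
        pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        inside = _points_in_tet(pts, p)
        if inside.any():
            sub = vals[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1].ravel()
            out[t] = sub[inside].mean()

    empty = np.isnan(out)
    if empty.any():
        coords = idx_c[empty].T
        out[empty] = map_coordinates(vals, coords, order=1, mode="nearest")
    return out


def _points_in_tet(pts: np.ndarray, tet: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    m = np.column_stack([tet[1] - tet[0], tet[2] - tet[0], tet[3] - tet[0]])
    try:
        bary = np.linalg.solve(m, (pts - tet[0]).T).T
    except np.linalg.LinAlgError:
        return np.zeros(len(pts), dtype=bool)
    w = 1.0 - bary.sum(axis=1)
    return (bary >= -tol).all(axis=1) & (w >= -tol)


# ---------------------------------------------------------------------------
# assignment


@dataclass
class MaterialField:
    """Per-element materials for the tets plus the single shell material."""

    hu: np.ndarray
    rho: np.ndarray
    E: np.ndarray
    nu: float
    sigma_c: np.ndarray
    sigma_t: np.ndarray
    shell: ElementMaterial | None = None
    law_name: str = "keller_vertebra"

    def __len__(self) -> int:
        return len(self.E)

    def __getitem__(self, i: int) -> ElementMaterial:
        return ElementMaterial(
            E=float(self.E[i]),
            nu=self.nu,
            sigma_c=float(self.sigma_c[i]),
            sigma_t=float(self.sigma_t[i]),
            rho=float(self.rho[i]),
            hu=float(self.hu[i]),
        )

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        df = pd.DataFrame(
            {
                "element_id": np.arange(len(self)),
                "hu": self.hu,
                "rho": self.rho,
                "E": self.E,
                "nu": self.nu,
                "sigma_c": self.sigma_c,
                "sigma_t": self.sigma_t,
            }
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "MaterialField":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(
            hu=df["hu"].to_numpy(),
            rho=df["rho"].to_numpy(),
            E=df["E"].to_numpy(),
            nu=float(df["nu"].iloc[0]),
            sigma_c=df["sigma_c"].to_numpy(),
            sigma_t=df["sigma_t"].to_numpy(),
        )


def _materials_from_hu(hu: np.ndarray, cal: DensityCalibration, law: MaterialLaw):
    rho = hu_to_density(cal, hu)
    e = clamp_modulus(law.modulus_fn(rho))
    sc = law.yield_fn(rho)
    return rho, e, sc


def assign_materials(
    mesh: TetMesh,
    volume: CTVolume,
    cal: DensityCalibration,
    law: MaterialLaw | str = "keller_vertebra",
    shell_hu: float = SHELL_HU,
    tensile_ratio: float = TENSILE_RATIO,
) -> MaterialField:
    """HU -> density -> (clamped) modulus and yield for tets and shells.

    Shell elements are assigned assuming a CT value of ``shell_hu`` (1000 HU
    by default) through the same calibration and law.
    """
    if isinstance(law, str):
        law = get_law(law)
    hu = element_average_hu(volume, mesh)
    rho, e, sc = _materials_from_hu(hu, cal, law)
    shell = None
    if mesh.shell:
        s_rho, s_e, s_sc = _materials_from_hu(np.asarray(shell_hu, float), cal, law)
        shell = ElementMaterial(
            E=float(s_e),
            nu=POISSON_RATIO,
            sigma_c=float(s_sc),
            sigma_t=float(tensile_ratio * s_sc),
            rho=float(s_rho),
            hu=float(shell_hu),
        )
    return MaterialField(
        hu=hu,
        rho=np.asarray(rho, float),
        E=np.asarray(e, float),
        nu=POISSON_RATIO,
        sigma_c=np.asarray(sc, float),
        sigma_t=tensile_ratio * np.asarray(sc, float),
        shell=shell,
        law_name=law.name,
    )


def uniform_materials(
    mesh: TetMesh, E: float, sigma_c: float = YIELD_SENTINEL_MPA, nu: float = POISSON_RATIO,
    tensile_ratio: float = TENSILE_RATIO,
) -> MaterialField:
    """Homogeneous material field, mainly for verification problems."""
    n = mesh.n_tets
    sc = np.full(n, float(sigma_c))
    return MaterialField(
        hu=np.full(n, np.nan),
        rho=np.full(n, np.nan),
        E=np.full(n, float(E)),
        nu=float(nu),
        sigma_c=sc,
        sigma_t=tensile_ratio * sc,
        shell=None,
    )


# ---------------------------------------------------------------------------
# Drucker-Prager calibration


def dp_params(sigma_c: float, tensile_ratio: float = TENSILE_RATIO) -> DruckerPragerParams:
    """Constants matching uniaxial strengths sigma_c and tensile_ratio*sigma_c.

    Closed form: alpha = (1 - r) / (sqrt(3) (1 + r)),
    k = r sigma_c (alpha + 1/sqrt(3)). r = 1 recovers von Mises
    (alpha = 0, k = sigma_c / sqrt(3)).
    """
    if sigma_c <= 0:
        raise ValueError("sigma_c must be positive")
    if not 0 < tensile_ratio <= 1:
        raise ValueError("tensile_ratio must be in (0, 1]")
    r = tensile_ratio
    alpha = (1.0 - r) / (np.sqrt(3.0) * (1.0 + r))
    k = r * sigma_c * (alpha + 1.0 / np.sqrt(3.0))
    return DruckerPragerParams(alpha=float(alpha), k=float(k))
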