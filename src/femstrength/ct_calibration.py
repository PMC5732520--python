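"""Quantitative CT calibration against a hydroxyapatite phantom.

A calibration phantom with rods of known equivalent mineral density
(typically 0, 100 and 200 mg/cm^3 hydroxyapatite) is scanned together with
the specimen. The mean attenuation (HU) inside each rod is regressed on the
nominal rod density, giving an affine HU -> density map that the material
laws consume downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


class LoadError(RuntimeError):
    """Raised when a CT volume cannot be read."""


class GeometryError(RuntimeError):
    """Raised when series geometry is inconsistent."""


@dataclass
class CTVolume:
    """A CT attenuation volume on a regular grid.

    ``values[i, j, k]`` sits at world position ``origin + (i, j, k) * spacing``
    (array axes aligned with world x, y, z). Spacing and origin are in mm,
    values in Hounsfield units.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_labels: tuple[str, str, str] = ("x", "y", "z")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3 or self.values.size == 0:
            raise ValueError("CT volume must be a non-empty 3-D array")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("CT volume contains non-finite HU")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def affine(self) -> np.ndarray:
        a = np.eye(4)
        a[:3, :3] = np.diag(self.spacing)
        a[:3, 3] = self.origin
        return a

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of voxel centers along each axis."""
        return tuple(
            self.origin[d] + np.arange(self.shape[d]) * self.spacing[d] for d in range(3)
        )


@dataclass(frozen=True)
class RodCylinder:
    """World-space cylinder delimiting one calibration rod."""

    center: tuple[float, float, float]
    axis: tuple[float, float, float]
    radius: float
    half_length: float

    def contains(self, pts: np.ndarray) -> np.ndarray:
        c = np.asarray(self.center, float)
        a = np.asarray(self.axis, float)
        a = a / np.linalg.norm(a)
        rel = pts - c
        t = rel @ a
        radial = rel - np.outer(t, a)
        return (np.abs(t) <= self.half_length) & (
            np.einsum("ij,ij->i", radial, radial) <= self.radius**2
        )


@dataclass
class PhantomSpec:
    """Nominal rod densities (mg/cm^3) and their regions.

    Regions are either :class:`RodCylinder` objects or boolean voxel masks
    matching the volume shape. Densities must be strictly increasing and
    regions disjoint.
    """

    rod_densities: tuple[float, ...]
    rod_regions: tuple

    def __post_init__(self) -> None:
        if len(self.rod_densities) < 2:
            raise ValueError("need at least two calibration rods")
        if len(self.rod_densities) != len(self.rod_regions):
            raise ValueError("one region per rod density required")
        d = np.asarray(self.rod_densities, float)
        if not np.all(np.diff(d) > 0):
            raise ValueError("rod densities must be strictly increasing")


@dataclass
class DensityCalibration:
    """Affine HU -> equivalent mineral density map.

    slope is (mg/cm^3)/HU, intercept mg/cm^3. ``fit_r2`` is the R^2 of the
    rod regression; ``warnings`` records anomalies such as a negative slope.
    """

    slope: float
    intercept: float
    fit_r2: float = 1.0
    rod_hu: tuple[float, ...] = ()
    rod_density: tuple[float, ...] = ()
    warnings: tuple[str, ...] = field(default_factory=tuple)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "slope": self.slope,
                    "intercept": self.intercept,
                    "fit_r2": self.fit_r2,
                    "rod_hu": list(self.rod_hu),
                    "rod_density": list(self.rod_density),
                    "warnings": list(self.warnings),
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "DensityCalibration":
        d = json.loads(Path(path).read_text())
        return cls(
            slope=d["slope"],
            intercept=d["intercept"],
            fit_r2=d.get("fit_r2", 1.0),
            rod_hu=tuple(d.get("rod_hu", ())),
            rod_density=tuple(d.get("rod_density", ())),
            warnings=tuple(d.get("warnings", ())),
        )


# ---------------------------------------------------------------------------
# volume I/O


def load_volume(path: str | Path, format: str | None = None) -> CTVolume:
    """Load a CT volume from NIfTI, a DICOM directory, or raw + JSON sidecar.

    ``format`` is one of ``nifti``, ``dicom_dir``, ``raw`` and is guessed from
    the path when omitted. DICOM rescale slope/intercept are applied so the
    returned values are HU.
    """
    path = Path(path)
    if not path.exists():
        raise LoadError(f"no such file or directory: {path}")
    if format is None:
        if path.is_dir():
            format = "dicom_dir"
        elif path.suffix in (".nii", ".gz") or str(path).endswith(".nii.gz"):
            format = "nifti"
        elif path.suffix == ".raw":
            format = "raw"
        else:
            format = "nifti"
    if format == "nifti":
        return _load_nifti(path)
    if format == "dicom_dir":
        return _load_dicom_dir(path)
    if format == "raw":
        return _load_raw(path)
    raise LoadError(f"unsupported format {format!r}")


def _load_nifti(path: Path) -> CTVolume:
    import nibabel as nib

    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - corrupt-file path
        raise LoadError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    aff = img.affine
    spacing = tuple(float(np.linalg.norm(aff[:3, d])) for d in range(3))
    origin = tuple(float(v) for v in aff[:3, 3])
    return CTVolume(values=data, spacing=spacing, origin=origin)


def _load_dicom_dir(path: Path) -> CTVolume:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".dcm", ".ima", ""))
    slices = []
    for f in files:
        if not f.is_file():
            continue
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        if hasattr(ds, "pixel_array") and hasattr(ds, "ImagePositionPatient"):
            slices.append(ds)
    if not slices:
        raise LoadError(f"no readable DICOM slices in {path}")
    slices.sort(key=lambda d: float(d.ImagePositionPatient[2]))
    zs = np.array([float(d.ImagePositionPatient[2]) for d in slices])
    dz = np.diff(zs)
    if len(dz) and not np.allclose(dz, dz[0], atol=1e-3):
        raise GeometryError(f"inconsistent slice spacing in {path}: {sorted(set(np.round(dz, 4)))}")
    first = slices[0]
    px = [float(v) for v in first.PixelSpacing]
    spacing = (px[1], px[0], float(dz[0]) if len(dz) else 1.0)
    stack = []
    for ds in slices:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        inter = float(getattr(ds, "RescaleIntercept", 0.0))
        stack.append(arr * slope + inter)
    # DICOM pixel_array is (row, col) = (y, x); reorder to (x, y, z)
    vol = np.stack(stack, axis=-1).transpose(1, 0, 2)
    ipp = [float(v) for v in first.ImagePositionPatient]
    return CTVolume(values=vol, spacing=spacing, origin=(ipp[0], ipp[1], float(zs[0])))


def _load_raw(path: Path) -> CTVolume:
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise LoadError(f"raw volume {path} needs a JSON sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    data = np.fromfile(path, dtype=np.dtype(meta["dtype"]))
    shape = tuple(meta["shape"])
    if data.size != int(np.prod(shape)):
        raise LoadError(f"raw file {path} has {data.size} values, sidecar shape {shape}")
    return CTVolume(
        values=data.reshape(shape).astype(np.float64),
        spacing=tuple(meta["spacing"]),
        origin=tuple(meta.get("origin", (0.0, 0.0, 0.0))),
    )


def save_volume(volume: CTVolume, path: str | Path) -> None:
    """Write a volume as NIfTI (.nii/.nii.gz)."""
    import nibabel as nib

    img = nib.Nifti1Image(volume.values.astype(np.float32), volume.affine)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# calibration


def rod_mean_hu(volume: CTVolume, spec: PhantomSpec) -> list[float]:
    """Mean HU over the voxels whose centers fall inside each rod region."""
    xs, ys, zs = volume.voxel_centers()
    means = []
    for i, region in enumerate(spec.rod_regions):
        if isinstance(region, np.ndarray):
            mask = region.astype(bool)
            if mask.shape != volume.shape:
                raise ValueError(f"rod {i}: mask shape {mask.shape} != volume {volume.shape}")
            if not mask.any():
                raise ValueError(f"rod {i}: region contains no voxel centers")
            means.append(float(volume.values[mask].mean()))
        else:
            # restrict to the cylinder's bounding box before the exact test
            c = np.asarray(region.center)
            r = region.radius + region.half_length
            sel = [
                (ax >= c[d] - r) & (ax <= c[d] + r) for d, ax in enumerate((xs, ys, zs))
            ]
            ii, jj, kk = (np.where(s)[0] for s in sel)
            if ii.size == 0 or jj.size == 0 or kk.size == 0:
                raise ValueError(f"rod {i}: region contains no voxel centers")
            gx, gy, gz = np.meshgrid(xs[ii], ys[jj], zs[kk], indexing="ij")
            pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
            inside = region.contains(pts)
            if not inside.any():
                raise ValueError(f"rod {i}: region contains no voxel centers")
            sub = volume.values[np.ix_(ii, jj, kk)].ravel()
            means.append(float(sub[inside].mean()))
    return means


def fit_calibration(rod_hu, rod_density) -> DensityCalibration:
    """Ordinary least-squares line density = slope * HU + intercept."""
    hu = np.asarray(rod_hu, dtype=float)
    rho = np.asarray(rod_density, dtype=float)
    if hu.shape != rho.shape or hu.size < 2:
        raise ValueError("need matching HU/density lists with at least two rods")
    if np.ptp(hu) == 0:
        raise ValueError("degenerate calibration: all rod HU values are equal")
    slope, intercept = np.polyfit(hu, rho, 1)
    pred = slope * hu + intercept
    ss_res = float(np.sum((rho - pred) ** 2))
    ss_tot = float(np.sum((rho - rho.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    warnings = ()
    if slope <= 0:
        warnings = (f"non-positive calibration slope {slope:.4g} (mg/cm^3)/HU",)
    return DensityCalibration(
        slope=float(slope),
        intercept=float(intercept),
        fit_r2=float(min(r2, 1.0)),
        rod_hu=tuple(map(float, hu)),
        rod_density=tuple(map(float, rho)),
        warnings=warnings,
    )


def hu_to_density(cal: DensityCalibration, hu) -> np.ndarray | float:
    """Equivalent mineral density in g/cm^3 for HU values (may be negative)."""
    rho = (cal.slope * np.asarray(hu, dtype=float) + cal.intercept) / 1000.0
    return float(rho) if np.isscalar(hu) or rho.ndim == 0 else rho


def calibrate_from_phantom(volume: CTVolume, spec: PhantomSpec) -> DensityCalibration:
    """Convenience: rod means + OLS fit in one call."""
    return fit_calibration(rod_mean_hu(volume, spec), spec.rod_densities)
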