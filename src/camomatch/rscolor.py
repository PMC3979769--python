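"""Environmental coloration from calibrated satellite scenes.

Implements the two-step radiometric chain used to put landscape color on
the same 8-bit RGB scale as specimen photographs:

1. digital numbers (DN) -> at-sensor spectral radiance, using the per-band
   linear gain/bias (Lmin/Lmax over Qcalmin/Qcalmax);
2. radiance -> surface reflectance with a dark-object-subtraction (DOS/COST)
   style atmospheric correction,
   rho = pi * (L - Lp) * d^2 / (Tv * (ESUN * cos(theta_s) * Tz + Edown));

followed by BT.601 luminosity composition and circular-buffer zonal means
around specimen locations (default radius 10 km, the nightly movement range
of the study animal).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import tifffile
import yaml

__all__ = [
    "CalibrationMeta",
    "RasterScene",
    "BufferColor",
    "BT601_WEIGHTS",
    "dn_to_radiance",
    "radiance_to_reflectance",
    "estimate_dark_object",
    "rgb_luminosity",
    "reflectance_to_rgb255",
    "calibrate_scene",
    "scene_rgb255",
    "buffer_extract",
    "check_scene_quality",
    "write_scene",
    "read_scene",
]

#: ITU-R BT.601 luma weights for (R, G, B).
BT601_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclass
class CalibrationMeta:
    """Per-band radiometric calibration plus scene atmospheric terms.

    Radiances are W·m⁻²·sr⁻¹·µm⁻¹, irradiances W·m⁻²·µm⁻¹, angles degrees,
    Earth–Sun distance astronomical units. ``tv``/``tz`` are the surface–
    sensor and sun–surface atmospheric transmittances; with ``path_radiance
    = 0``, ``tv = tz = 1`` and ``edown = 0`` the chain reduces to
    top-of-atmosphere reflectance.
    """

    lmin: np.ndarray
    lmax: np.ndarray
    qcalmin: np.ndarray
    qcalmax: np.ndarray
    esun: np.ndarray
    solar_zenith_deg: float
    earth_sun_distance_au: float = 1.0
    path_radiance: np.ndarray | None = None
    edown: np.ndarray | None = None
    tv: float = 1.0
    tz: float = 1.0

    def __post_init__(self) -> None:
        for name in ("lmin", "lmax", "qcalmin", "qcalmax", "esun"):
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name), float)))
        nb = self.n_bands
        if self.path_radiance is None:
            self.path_radiance = np.zeros(nb)
        if self.edown is None:
            self.edown = np.zeros(nb)
        self.path_radiance = np.atleast_1d(np.asarray(self.path_radiance, float))
        self.edown = np.atleast_1d(np.asarray(self.edown, float))
        self.validate()

    @property
    def n_bands(self) -> int:
        return len(self.lmin)

    def validate(self) -> None:
        if np.any(self.qcalmax <= self.qcalmin):
            raise ValueError("Qcalmax must exceed Qcalmin")
        if self.earth_sun_distance_au <= 0:
            raise ValueError("Earth-Sun distance must be positive")
        if not (0.0 < self.tv <= 1.0 and 0.0 < self.tz <= 1.0):
            raise ValueError("transmittances must lie in (0, 1]")
        if not (0.0 <= self.solar_zenith_deg < 90.0):
            raise ValueError("solar zenith angle must lie in [0, 90)")

    @property
    def cos_solar_zenith(self) -> float:
        return float(np.cos(np.deg2rad(self.solar_zenith_deg)))

    def irradiance_term(self, band: int) -> float:
        """ESUN·cosθs·Tz + Edown for one band (denominator of the correction)."""
        return float(self.esun[band] * self.cos_solar_zenith * self.tz + self.edown[band])

    def to_dict(self) -> dict:
        d = asdict(self)
        return {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in d.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationMeta":
        return cls(**d)


@dataclass
class RasterScene:
    """Multi-band 8-bit scene on a planar meter grid.

    ``dn`` has shape (bands, rows, cols); ``mask`` is True where pixels are
    invalid (cloud, water, urban). Band order is red, green, blue, matching
    the Landsat TM/ETM+ 3-2-1 natural-color convention. Pixel (i, j) has
    its center at ``origin + ((j + 0.5) px, (i + 0.5) px)`` with y growing
    down-row, so coordinates are plain scene-local meters.
    """

    dn: np.ndarray
    mask: np.ndarray
    pixel_size: float
    meta: CalibrationMeta
    origin: tuple[float, float] = (0.0, 0.0)
    band_order: tuple[int, int, int] = (0, 1, 2)

    def __post_init__(self) -> None:
        self.dn = np.asarray(self.dn)
        if self.dn.ndim != 3:
            raise ValueError("dn must be (bands, rows, cols)")
        self.mask = np.asarray(self.mask, bool)
        if self.mask.shape != self.dn.shape[1:]:
            raise ValueError("mask shape must match raster grid")
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.dn.shape[1:]

    @property
    def masked_fraction(self) -> float:
        return float(self.mask.mean())

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate arrays of pixel centers, each shaped like the grid."""
        nr, nc = self.shape
        x = self.origin[0] + (np.arange(nc) + 0.5) * self.pixel_size
        y = self.origin[1] + (np.arange(nr) + 0.5) * self.pixel_size
        return np.meshgrid(x, y)

    def contains(self, point: tuple[float, float]) -> bool:
        nr, nc = self.shape
        x, y = point[0] - self.origin[0], point[1] - self.origin[1]
        return 0 <= x <= nc * self.pixel_size and 0 <= y <= nr * self.pixel_size


@dataclass
class BufferColor:
    """Zonal color statistics of a circular buffer around one location."""

    r: float
    g: float
    b: float
    luminosity: float
    pixels_used: int
    pixels_masked: int
    radius_m: float


def dn_to_radiance(dn, meta: CalibrationMeta, band: int, out_of_range: str = "raise"):
    """Linear DN -> at-sensor radiance for one band.

    L = (Lmax − Lmin)/(Qcalmax − Qcalmin) · (DN − Qcalmin) + Lmin.

    DN outside the calibrated range is an acquisition error, not data;
    ``out_of_range`` is ``"raise"`` or ``"flag"`` (returns ``(L, flags)``
    with the offending values converted but marked, never clamped).
    """
    dn = np.asarray(dn, float)
    lo, hi = meta.qcalmin[band], meta.qcalmax[band]
    flags = (dn < lo) | (dn > hi)
    if flags.any() and out_of_range == "raise":
        raise ValueError(
            f"{int(flags.sum())} DN value(s) outside calibrated range [{lo}, {hi}]"
        )
    gain = (meta.lmax[band] - meta.lmin[band]) / (hi - lo)
    radiance = gain * (dn - lo) + meta.lmin[band]
    if out_of_range == "flag":
        return radiance, flags
    return radiance


def radiance_to_reflectance(radiance, meta: CalibrationMeta, band: int):
    """Atmospherically corrected surface reflectance for one band.

    Negative output means the path radiance was over-subtracted (a known
    failure mode of dark-object corrections); such values are preserved
    and warned about, never silently clipped.
    """
    if meta.cos_solar_zenith <= 0:
        raise ValueError("sun below horizon: cos(theta_s) <= 0")
    radiance = np.asarray(radiance, float)
    lp = meta.path_radiance[band]
    d = meta.earth_sun_distance_au
    rho = np.pi * (radiance - lp) * d * d / (meta.tv * meta.irradiance_term(band))
    if np.any(rho < 0):
        warnings.warn(
            f"band {band}: {int(np.sum(rho < 0))} pixel(s) with negative reflectance "
            "(dark-object over-subtraction)",
            stacklevel=2,
        )
    return rho


def estimate_dark_object(
    scene: RasterScene,
    band: int,
    percentile: float = 0.01,
    dark_reflectance: float = 0.01,
) -> float:
    """Path-radiance estimate from the scene's darkest unmasked pixels.

    COST-style convention: the radiance at the given low quantile of the
    unmasked pixels is assumed to come from a target of ``dark_reflectance``
    (1% by default); everything above that is attributed to the atmosphere:

    Lp = L_dark − dark_reflectance · Tv · (ESUN·cosθs·Tz + Edown) / (π·d²).

    ``percentile=0`` uses the scene minimum.
    """
    valid = ~scene.mask
    if not valid.any():
        raise ValueError("no unmasked pixels to estimate the dark object from")
    dn = scene.dn[band][valid]
    radiance = dn_to_radiance(dn, scene.meta, band)
    l_dark = float(np.quantile(radiance, percentile))
    d = scene.meta.earth_sun_distance_au
    dark_term = dark_reflectance * scene.meta.tv * scene.meta.irradiance_term(band) / (
        np.pi * d * d
    )
    return l_dark - dark_term


def rgb_luminosity(r, g, b):
    """BT.601 luminosity Y = 0.299·R + 0.587·G + 0.114·B on the 0–255 scale."""
    r, g, b = (np.asarray(c, float) for c in (r, g, b))
    for name, c in (("R", r), ("G", g), ("B", b)):
        if np.any((c < 0) | (c > 255)):
            raise ValueError(f"{name} channel outside [0, 255]")
    return BT601_WEIGHTS[0] * r + BT601_WEIGHTS[1] * g + BT601_WEIGHTS[2] * b


def reflectance_to_rgb255(rho):
    """Linear 0–1 reflectance -> 0–255 channel value, clipped at the ends."""
    return np.clip(255.0 * np.asarray(rho, float), 0.0, 255.0)


def calibrate_scene(
    scene: RasterScene,
    correction: str = "toa",
    dark_percentile: float = 0.01,
) -> np.ndarray:
    """Full DN -> surface reflectance chain for every band.

    ``correction="toa"`` uses the metadata as-is (typically no atmosphere);
    ``correction="dos"`` additionally estimates per-band path radiance from
    the scene's dark objects, overriding ``meta.path_radiance``.
    """
    if correction not in ("toa", "dos"):
        raise ValueError("correction must be 'toa' or 'dos'")
    out = np.empty(scene.dn.shape, float)
    for band in range(scene.dn.shape[0]):
        radiance = dn_to_radiance(scene.dn[band], scene.meta, band)
        if correction == "dos":
            lp = estimate_dark_object(scene, band, percentile=dark_percentile)
            meta = CalibrationMeta.from_dict(scene.meta.to_dict())
            meta.path_radiance[band] = lp
        else:
            meta = scene.meta
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # negatives handled downstream by clipping
            out[band] = radiance_to_reflectance(radiance, meta, band)
    return out


def scene_rgb255(scene: RasterScene, correction: str = "toa") -> np.ndarray:
    """(3, rows, cols) array of calibrated R, G, B channels on 0–255."""
    rho = calibrate_scene(scene, correction=correction)
    return reflectance_to_rgb255(rho[list(scene.band_order)])


def buffer_extract(
    scene: RasterScene,
    point: tuple[float, float],
    radius: float = 10_000.0,
    rgb: np.ndarray | None = None,
    correction: str = "toa",
) -> BufferColor:
    """Mean R, G, B and luminosity in a circular buffer around ``point``.

    A pixel belongs to the buffer iff its center lies within ``radius``
    meters of the point; masked pixels are excluded from the mean and
    counted. Luminosity is the BT.601 combination of the channel means
    (equivalently the mean of per-pixel luminosities — the weights are
    linear). Pass a precomputed ``rgb`` (from :func:`scene_rgb255`) when
    extracting many points from one scene.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if not scene.contains(point):
        raise ValueError(f"point {point} outside scene")
    if rgb is None:
        rgb = scene_rgb255(scene, correction=correction)
    x, y = scene.pixel_centers()
    inside = (x - point[0]) ** 2 + (y - point[1]) ** 2 < radius**2
    used = inside & ~scene.mask
    n_used = int(used.sum())
    if n_used == 0:
        raise ValueError("no unmasked pixels within the buffer")
    means = [float(rgb[c][used].mean()) for c in range(3)]
    return BufferColor(
        r=means[0],
        g=means[1],
        b=means[2],
        luminosity=float(rgb_luminosity(*means)),
        pixels_used=n_used,
        pixels_masked=int((inside & scene.mask).sum()),
        radius_m=float(radius),
    )


def check_scene_quality(scene: RasterScene, max_masked_fraction: float = 0.10) -> None:
    """Reject scenes with too much invalid cover (default threshold 10%)."""
    if scene.masked_fraction > max_masked_fraction:
        raise ValueError(
            f"scene masked fraction {scene.masked_fraction:.3f} exceeds "
            f"{max_masked_fraction:.2f}"
        )


def write_scene(scene: RasterScene, path: str | Path) -> Path:
    """Write a scene as multi-band uint8 GeoTIFF (mask as an extra band)
    with calibration metadata in a ``.meta.yaml`` sidecar."""
    path = Path(path)
    stack = np.concatenate(
        [scene.dn.astype(np.uint8), scene.mask[None].astype(np.uint8) * 255]
    )
    tifffile.imwrite(path, stack, photometric="minisblack")
    sidecar = {
        "pixel_size": scene.pixel_size,
        "origin": list(scene.origin),
        "band_order": list(scene.band_order),
        "calibration": scene.meta.to_dict(),
    }
    path.with_suffix(path.suffix + ".meta.yaml").write_text(
        yaml.safe_dump(sidecar, sort_keys=False)
    )
    return path


def read_scene(path: str | Path) -> RasterScene:
    path = Path(path)
    stack = tifffile.imread(path)
    sidecar = yaml.safe_load(path.with_suffix(path.suffix + ".meta.yaml").read_text())
    return RasterScene(
        dn=stack[:-1],
        mask=stack[-1] > 0,
        pixel_size=float(sidecar["pixel_size"]),
        meta=CalibrationMeta.from_dict(sidecar["calibration"]),
        origin=tuple(sidecar["origin"]),
        band_order=tuple(sidecar["band_order"]),
    )
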