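"""Wavelength grids, endmember emission spectra and the spectral-cube container.

The imaging model is the standard linear mixing model of multispectral
fluorescence microscopy: each pixel's 21-band emission spectrum (450-650 nm,
10-nm steps) is a non-negative combination of three endmembers -- the
green-emitting quantum dot labelling cytokeratin (CK, QD-525), the
red-emitting quantum dot labelling Ki67 (QD-605), and broad tissue
autofluorescence.  Endmember lineshapes are modelled as Gaussians because
quantum-dot emission is narrow and symmetric; only the peak wavelengths are
known from the instrument, so widths are parametric.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile

from .errors import FormatError, InvalidParameterError, ValidationError

__all__ = [
    "WavelengthGrid",
    "Spectrum",
    "EndmemberLibrary",
    "SpectralCube",
    "gaussian_emission",
    "build_default_library",
    "read_cube",
    "write_cube",
]

DEFAULT_EXPOSURE_MS = 800.0


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform emission-wavelength sampling grid.

    The default grid (450-650 nm in 10-nm steps, 21 bands) matches the
    acquisition protocol of liquid-crystal tunable-filter multispectral
    systems used for quantum-dot tissue imaging.
    """

    start_nm: float = 450.0
    stop_nm: float = 650.0
    step_nm: float = 10.0

    def __post_init__(self) -> None:
        if not (self.start_nm < self.stop_nm):
            raise InvalidParameterError("start_nm must be < stop_nm")
        if self.step_nm <= 0:
            raise InvalidParameterError("step_nm must be positive")
        span = self.stop_nm - self.start_nm
        n = span / self.step_nm
        if abs(n - round(n)) > 1e-9:
            raise InvalidParameterError(
                f"grid span {span} nm is not a multiple of step {self.step_nm} nm"
            )

    @property
    def n_bands(self) -> int:
        return int(round((self.stop_nm - self.start_nm) / self.step_nm)) + 1

    @property
    def wavelengths(self) -> np.ndarray:
        """Band-centre wavelengths in nm, ascending."""
        return self.start_nm + self.step_nm * np.arange(self.n_bands)

    def index_of(self, wavelength_nm: float) -> int:
        """Index of the band whose centre is nearest ``wavelength_nm``."""
        return int(np.argmin(np.abs(self.wavelengths - wavelength_nm)))


@dataclass(frozen=True)
class Spectrum:
    """Non-negative emission intensities (a.u.) sampled on a wavelength grid."""

    grid: WavelengthGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (self.grid.n_bands,):
            raise ValidationError(
                f"spectrum has {values.shape} values for a {self.grid.n_bands}-band grid"
            )
        if np.any(values < 0):
            raise ValidationError("spectrum values must be non-negative")
        object.__setattr__(self, "values", values)


def gaussian_emission(
    peak_nm: float, fwhm_nm: float, grid: WavelengthGrid | None = None
) -> Spectrum:
    """Gaussian emission lineshape sampled on a wavelength grid.

    ``values[i] = exp(-4 ln2 (lambda_i - peak)^2 / fwhm^2)``, so the analytic
    peak is 1 and the curve reaches 0.5 exactly ``fwhm/2`` either side of it.
    The sampled maximum equals 1 exactly when the peak lies on a grid point.
    """
    grid = grid if grid is not None else WavelengthGrid()
    if fwhm_nm <= 0:
        raise InvalidParameterError("fwhm_nm must be positive")
    if not (grid.start_nm - 100.0 <= peak_nm <= grid.stop_nm + 100.0):
        raise InvalidParameterError(
            f"peak {peak_nm} nm lies too far outside the grid {grid.start_nm}-{grid.stop_nm} nm"
        )
    lam = grid.wavelengths
    values = np.exp(-4.0 * np.log(2.0) * (lam - peak_nm) ** 2 / fwhm_nm**2)
    return Spectrum(grid, values)


@dataclass(frozen=True)
class EndmemberLibrary:
    """Reference spectra for the three unmixing components.

    Column order is fixed as (CK, Ki67, AF) throughout the package.
    """

    ck_525: Spectrum
    ki67_605: Spectrum
    autofluorescence: Spectrum

    COMPONENTS = ("ck", "ki67", "af")

    def __post_init__(self) -> None:
        if not (self.ck_525.grid == self.ki67_605.grid == self.autofluorescence.grid):
            raise ValidationError("endmember spectra must share one wavelength grid")

    @property
    def grid(self) -> WavelengthGrid:
        return self.ck_525.grid

    @property
    def as_matrix(self) -> np.ndarray:
        """bands x 3 endmember matrix, columns (CK, Ki67, AF)."""
        return np.column_stack(
            [self.ck_525.values, self.ki67_605.values, self.autofluorescence.values]
        )

    def condition_number(self) -> float:
        return float(np.linalg.cond(self.as_matrix))


def build_default_library(grid: WavelengthGrid | None = None) -> EndmemberLibrary:
    """Default three-component library: QD-525 (CK), QD-605 (Ki67), autofluorescence.

    Quantum-dot endmembers are Gaussians of FWHM 30 nm (typical QD emission
    width) at the nominal peaks; the autofluorescence endmember is a broad
    Gaussian (peak 500 nm, FWHM 150 nm) standing in for the smooth tissue
    background a spectral imager estimates from unstained regions.
    """
    grid = grid if grid is not None else WavelengthGrid()

    def sampled_peak_normalized(peak_nm: float, fwhm_nm: float) -> Spectrum:
        # QD peaks (525, 605 nm) fall between 10-nm band centres, so the
        # sampled maximum is slightly below the analytic peak of 1;
        # renormalizing makes a pure pixel's abundance equal its intensity.
        raw = gaussian_emission(peak_nm, fwhm_nm, grid)
        return Spectrum(grid, raw.values / raw.values.max())

    return EndmemberLibrary(
        ck_525=sampled_peak_normalized(525.0, 30.0),
        ki67_605=sampled_peak_normalized(605.0, 30.0),
        autofluorescence=sampled_peak_normalized(500.0, 150.0),
    )


@dataclass
class SpectralCube:
    """A multispectral image: ``intensities[row, col, band]`` in a.u.

    ``exposure_ms`` records the acquisition exposure; quantification is only
    comparable across cores imaged at one exposure (default 800 ms).
    """

    intensities: np.ndarray
    grid: WavelengthGrid = field(default_factory=WavelengthGrid)
    exposure_ms: float = DEFAULT_EXPOSURE_MS

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=np.float64)
        if arr.ndim != 3:
            raise ValidationError("intensities must be a (height, width, bands) array")
        if arr.shape[2] != self.grid.n_bands:
            raise FormatError(
                f"cube has {arr.shape[2]} bands but the grid declares {self.grid.n_bands}"
            )
        if np.any(arr < 0):
            raise ValidationError("cube intensities must be non-negative")
        self.intensities = arr

    @property
    def height(self) -> int:
        return self.intensities.shape[0]

    @property
    def width(self) -> int:
        return self.intensities.shape[1]

    def band(self, wavelength_nm: float) -> np.ndarray:
        """The image plane of the band nearest ``wavelength_nm``."""
        return self.intensities[:, :, self.grid.index_of(wavelength_nm)]


def _grid_from_wavelengths(wavelengths: np.ndarray) -> WavelengthGrid:
    wavelengths = np.asarray(wavelengths, dtype=float)
    if wavelengths.size < 2:
        raise FormatError("need at least two wavelengths to define a grid")
    steps = np.diff(wavelengths)
    if not np.allclose(steps, steps[0]):
        raise FormatError("wavelengths are not uniformly spaced")
    return WavelengthGrid(float(wavelengths[0]), float(wavelengths[-1]), float(steps[0]))


def write_cube(cube: SpectralCube, path) -> None:
    """Write a cube to disk; the format follows the file extension.

    ``.tif``/``.tiff``: multi-page TIFF, one page per band in ascending
    wavelength, with ``wavelengths_nm`` and ``exposure_ms`` stored as JSON in
    the image description.  ``.npz``: compressed NumPy archive with the same
    keys.  Both round-trip intensities bit-exactly at float32 precision for
    TIFF and float64 for npz.
    """
    path = str(path)
    meta = {
        "wavelengths_nm": [float(w) for w in cube.grid.wavelengths],
        "exposure_ms": float(cube.exposure_ms),
    }
    if path.endswith((".tif", ".tiff")):
        pages = np.ascontiguousarray(np.moveaxis(cube.intensities, 2, 0))
        tifffile.imwrite(path, pages.astype(np.float32), description=json.dumps(meta))
    elif path.endswith(".npz"):
        np.savez_compressed(
            path,
            intensities=cube.intensities,
            wavelengths_nm=cube.grid.wavelengths,
            exposure_ms=cube.exposure_ms,
        )
    else:
        raise FormatError(f"unsupported cube extension: {path!r} (use .tif/.tiff/.npz)")


def read_cube(path) -> SpectralCube:
    """Read a cube written by :func:`write_cube` (multi-page TIFF or npz)."""
    path = str(path)
    if path.endswith((".tif", ".tiff")):
        with tifffile.TiffFile(path) as tif:
            pages = tif.asarray()
            desc = tif.pages[0].description
        try:
            meta = json.loads(desc)
            wavelengths = meta["wavelengths_nm"]
            exposure = float(meta["exposure_ms"])
        except (json.JSONDecodeError, KeyError, TypeError) as exc:
            raise FormatError(f"missing or malformed cube metadata in {path}") from exc
        if pages.ndim == 2:
            pages = pages[None]
        grid = _grid_from_wavelengths(np.asarray(wavelengths))
        if pages.shape[0] != grid.n_bands:
            raise FormatError(
                f"{path}: {pages.shape[0]} pages but metadata declares {grid.n_bands} bands"
            )
        intensities = np.moveaxis(pages, 0, 2).astype(np.float64)
    elif path.endswith(".npz"):
        with np.load(path) as data:
            try:
                intensities = data["intensities"]
                wavelengths = data["wavelengths_nm"]
                exposure = float(data["exposure_ms"])
            except KeyError as exc:
                raise FormatError(f"missing cube array in {path}") from exc
        grid = _grid_from_wavelengths(wavelengths)
    else:
        raise FormatError(f"unsupported cube extension: {path!r} (use .tif/.tiff/.npz)")
    return SpectralCube(intensities=intensities, grid=grid, exposure_ms=exposure)
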