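"""Reading and writing hyperspectral datacubes (ENVI layout) and spectra tables.

A line-scan hyperspectral camera stores a datacube as a flat binary file plus a
small text header describing its geometry (``samples`` = pixels per scan line,
``lines`` = number of scan lines, ``bands``), the numeric type, the byte
interleave (BIL/BIP/BSQ), and the wavelength (nm) of every band.  In memory a
cube is always held in ``(line, pixel, band)`` order as float, whatever the
stored interleave or integer type, so downstream code never has to care.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "HyperspectralCube",
    "SpectraTable",
    "EnviFormatError",
    "read_cube",
    "write_cube",
    "read_spectra_table",
    "write_spectra_table",
    "read_label_image",
    "write_label_image",
    "METADATA_COLUMNS",
]

#: Fixed metadata prefix of a spectra table, in canonical order.
METADATA_COLUMNS = ["sample_id", "scan_id", "cultivar", "stage", "organ", "replicate"]

# ENVI numeric type codes <-> numpy dtypes (the subset in common camera use).
_ENVI_DTYPES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
    13: np.uint32,
}
_DTYPE_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


class EnviFormatError(ValueError):
    """Malformed, inconsistent, or truncated ENVI header/binary pair."""


@dataclass
class HyperspectralCube:
    """A reflectance datacube in ``(line, pixel, band)`` order.

    Parameters
    ----------
    values : ndarray, shape (lines, pixels, bands)
        Non-negative, finite reflectance intensities (arbitrary units).
    wavelengths : ndarray, shape (bands,)
        Band-center wavelengths in nm, strictly ascending.
    scan_id : str
        Opaque identifier tying the cube to its sample metadata.
    pixel_area_mm2 : float, optional
        Ground area covered by one pixel (the study's system: ~0.5 mm^2).
    """

    values: np.ndarray
    wavelengths: np.ndarray
    scan_id: str = ""
    pixel_area_mm2: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("cube values must be 3-D (line, pixel, band)")
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != self.values.shape[2]:
            raise ValueError(
                f"wavelength count {len(self.wavelengths)} != band count "
                f"{self.values.shape[2]}"
            )
        if len(self.wavelengths) > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly ascending")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("cube contains NaN/Inf values")
        if np.any(self.values < 0):
            raise ValueError("cube contains negative reflectance values")

    @property
    def n_lines(self) -> int:
        return self.values.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.values.shape[1]

    @property
    def n_bands(self) -> int:
        return self.values.shape[2]

    def band_index(self, wavelength_nm: float) -> int:
        """Index of the band nearest ``wavelength_nm``.

        Raises ``KeyError`` if the requested wavelength is farther from the
        nearest band center than one full band spacing (i.e. clearly outside
        the sampled grid).
        """
        idx = int(np.argmin(np.abs(self.wavelengths - wavelength_nm)))
        spacing = (
            float(np.max(np.diff(self.wavelengths))) if self.n_bands > 1 else np.inf
        )
        if abs(self.wavelengths[idx] - wavelength_nm) > spacing:
            raise KeyError(
                f"wavelength {wavelength_nm} nm not on the cube's grid "
                f"({self.wavelengths[0]:.1f}-{self.wavelengths[-1]:.1f} nm)"
            )
        return idx

    def band_image(self, wavelength_nm: float) -> np.ndarray:
        """The 2-D reflectance image at the band nearest ``wavelength_nm``."""
        return self.values[:, :, self.band_index(wavelength_nm)]


# ---------------------------------------------------------------------------
# ENVI cube I/O
# ---------------------------------------------------------------------------


def _header_path(path: Path) -> Path:
    return path if path.suffix == ".hdr" else path.with_suffix(path.suffix + ".hdr")


def _binary_path_for_read(hdr: Path) -> Path:
    base = hdr.with_suffix("")
    candidates = [base] + [base.with_suffix(s) for s in (".img", ".bil", ".bip", ".bsq", ".dat")]
    for c in candidates:
        if c.exists() and c.is_file():
            return c
    raise EnviFormatError(f"no binary file found next to header {hdr}")


def _parse_header(text: str) -> dict:
    """Parse an ENVI text header into a {key: value} dict (keys lowercased)."""
    if not text.lstrip().lower().startswith("envi"):
        raise EnviFormatError("not an ENVI header (missing 'ENVI' magic line)")
    # Collapse brace-delimited blocks (wavelength lists span many lines).
    body = text.lstrip()[4:]
    fields: dict[str, str] = {}
    pattern = re.compile(r"^\s*([^={}\n]+?)\s*=\s*(\{.*?\}|[^\n]*)", re.S | re.M)
    for m in pattern.finditer(body):
        key = m.group(1).strip().lower()
        val = m.group(2).strip()
        fields[key] = val
    return fields


def read_cube(path: str | Path) -> HyperspectralCube:
    """Read an ENVI header/binary pair into a :class:`HyperspectralCube`.

    ``path`` may point at either file of the pair.  All three interleaves
    (BIL, BIP, BSQ) and the common integer/float pixel types are accepted;
    integer counts are promoted to float.
    """
    path = Path(path)
    hdr = _header_path(path)
    if not hdr.exists():
        raise EnviFormatError(f"header file not found: {hdr}")
    fields = _parse_header(hdr.read_text())

    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
        interleave = fields["interleave"].lower()
    except KeyError as exc:
        raise EnviFormatError(f"header missing required field: {exc}") from exc
    except ValueError as exc:
        raise EnviFormatError(f"garbled header field: {exc}") from exc

    if dtype_code not in _ENVI_DTYPES:
        raise EnviFormatError(f"unsupported ENVI data type code {dtype_code}")
    if interleave not in ("bil", "bip", "bsq"):
        raise EnviFormatError(f"unknown interleave {interleave!r}")

    wl_block = fields.get("wavelength")
    if wl_block is None:
        raise EnviFormatError("header has no wavelength block")
    wavelengths = np.array(
        [float(tok) for tok in wl_block.strip("{} \n").replace("\n", " ").split(",") if tok.strip()]
    )
    if len(wavelengths) != bands:
        raise EnviFormatError(
            f"header declares {bands} bands but lists {len(wavelengths)} wavelengths"
        )

    offset = int(fields.get("header offset", 0))
    byte_order = int(fields.get("byte order", 0))
    dtype = np.dtype(_ENVI_DTYPES[dtype_code]).newbyteorder("<" if byte_order == 0 else ">")

    binary = _binary_path_for_read(hdr)
    raw = np.fromfile(binary, dtype=dtype, offset=offset)
    expected = samples * lines * bands
    if raw.size != expected:
        raise EnviFormatError(
            f"binary holds {raw.size} values, header implies {expected} "
            f"({lines} lines x {samples} samples x {bands} bands)"
        )

    # Stored axis order per interleave, mapped to canonical (line, pixel, band).
    if interleave == "bil":  # (lines, bands, samples)
        cube = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":  # (lines, samples, bands)
        cube = raw.reshape(lines, samples, bands)
    else:  # bsq: (bands, lines, samples)
        cube = raw.reshape(bands, lines, samples).transpose(1, 2, 0)

    scan_id = fields.get("scan id", "").strip("{} ") or hdr.stem
    return HyperspectralCube(
        values=np.ascontiguousarray(cube, dtype=np.float64),
        wavelengths=wavelengths,
        scan_id=scan_id,
    )


def write_cube(
    cube: HyperspectralCube,
    path: str | Path,
    interleave: str = "bil",
    dtype: str | np.dtype = "float32",
) -> Path:
    """Write ``cube`` as an ENVI header/binary pair; returns the header path.

    The binary is written next to the header with an ``.img`` suffix.  Float32
    is the default storage type; writing is refused for cubes violating the
    container invariants (enforced at construction).
    """
    interleave = interleave.lower()
    if interleave not in ("bil", "bip", "bsq"):
        raise ValueError(f"unknown interleave {interleave!r}")
    dtype = np.dtype(dtype)
    if dtype not in _DTYPE_CODES:
        raise ValueError(f"dtype {dtype} has no ENVI type code")

    path = Path(path)
    hdr = _header_path(path)
    binary = hdr.with_suffix(".img")

    lines, samples, bands = cube.values.shape
    if interleave == "bil":
        arr = cube.values.transpose(0, 2, 1)
    elif interleave == "bip":
        arr = cube.values
    else:
        arr = cube.values.transpose(2, 0, 1)

    wl = ", ".join(f"{w:.6f}" for w in cube.wavelengths)
    header_text = (
        "ENVI\n"
        f"description = {{hempspec cube}}\n"
        f"samples = {samples}\n"
        f"lines = {lines}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_CODES[dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"scan id = {{{cube.scan_id}}}\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{{wl}}}\n"
    )
    hdr.write_text(header_text)
    np.ascontiguousarray(arr, dtype=dtype.newbyteorder("<")).tofile(binary)
    return hdr


# ---------------------------------------------------------------------------
# Spectra tables
# ---------------------------------------------------------------------------


@dataclass
class SpectraTable:
    """Samples x wavelengths table of (relative) reflectance with metadata.

    ``metadata`` carries one row per sample with the canonical columns
    (:data:`METADATA_COLUMNS`); ``values[i, j]`` is sample *i*'s reflectance
    at ``wavelengths[j]``.
    """

    metadata: pd.DataFrame
    values: np.ndarray
    wavelengths: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x wavelengths)")
        if len(self.metadata) != self.values.shape[0]:
            raise ValueError("metadata rows != spectra rows")
        if len(self.wavelengths) != self.values.shape[1]:
            raise ValueError("wavelength count != value columns")
        missing = [c for c in METADATA_COLUMNS if c not in self.metadata.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        ids = self.metadata["sample_id"]
        if ids.duplicated().any():
            dups = sorted(ids[ids.duplicated()].unique().tolist())
            raise ValueError(f"duplicate sample_id values: {dups}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectra contain non-finite values")

    def __len__(self) -> int:
        return self.values.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        """Single flat frame: metadata prefix then one column per nm value."""
        wl_cols = [f"{w:.4f}" for w in self.wavelengths]
        return pd.concat(
            [
                self.metadata.reset_index(drop=True)[METADATA_COLUMNS],
                pd.DataFrame(self.values, columns=wl_cols),
            ],
            axis=1,
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SpectraTable":
        """Inverse of :meth:`to_dataframe`; columns matched by name."""
        wl_cols = [c for c in df.columns if _is_number(c)]
        if not wl_cols:
            raise ValueError("no numeric wavelength columns found")
        wavelengths = np.array([float(c) for c in wl_cols])
        order = np.argsort(wavelengths)
        wl_cols = [wl_cols[i] for i in order]
        meta = df[[c for c in METADATA_COLUMNS if c in df.columns]].reset_index(drop=True)
        missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
        if missing:
            raise ValueError(f"table missing metadata columns: {missing}")
        return cls(
            metadata=meta[METADATA_COLUMNS],
            values=df[wl_cols].to_numpy(dtype=np.float64),
            wavelengths=wavelengths[order],
        )

    def subset(self, mask: np.ndarray) -> "SpectraTable":
        """Row subset by boolean mask or integer index array."""
        mask = np.asarray(mask)
        return SpectraTable(
            metadata=self.metadata.reset_index(drop=True).loc[
                np.flatnonzero(mask) if mask.dtype == bool else mask
            ].reset_index(drop=True),
            values=self.values[mask],
            wavelengths=self.wavelengths,
        )


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except (TypeError, ValueError):
        return False


def write_spectra_table(table: SpectraTable, path: str | Path) -> Path:
    path = Path(path)
    table.to_dataframe().to_csv(path, index=False, float_format="%.8g")
    return path


def read_spectra_table(path: str | Path) -> SpectraTable:
    df = pd.read_csv(path)
    return SpectraTable.from_dataframe(df)


# ---------------------------------------------------------------------------
# Label images (ground truth / segmentation masks)
# ---------------------------------------------------------------------------


def write_label_image(labels: np.ndarray, path: str | Path) -> Path:
    """Write an integer label image (0 = background) as TIFF."""
    labels = np.asarray(labels)
    if not np.issubdtype(labels.dtype, np.integer):
        raise ValueError("label image must be integer-valued")
    path = Path(path)
    tifffile.imwrite(path, labels.astype(np.int32))
    return path


def read_label_image(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(path)).astype(np.int64)
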