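"""Per-region mean spectra and standardization against the reference panel.

Each segmented organ's spectrum is the arithmetic mean over its pixels; the
scan's 20%-nominal Spectralon panel supplies a reference spectrum, and the
ratio sample/reference ("relative reflectance", a.u.) removes the shared
illumination and camera response.  The nominal 20% is deliberately not
multiplied back in — downstream modeling and plots use the relative quantity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.morphology import disk, erosion

from .io import METADATA_COLUMNS, HyperspectralCube, SpectraTable
from .segment import ReferenceRegion, SegmentationResult

__all__ = [
    "RegionSpectrum",
    "mean_spectrum",
    "reference_spectrum",
    "ratio_to_reference",
    "extract_region_spectra",
    "assemble_spectra_table",
]


@dataclass(frozen=True)
class RegionSpectrum:
    """Mean reflectance over one region's pixels (arbitrary units)."""

    region_id: int
    spectrum: np.ndarray
    pixel_count: int

    def __post_init__(self) -> None:
        if self.pixel_count < 1:
            raise ValueError("region must contain at least one pixel")


def mean_spectrum(cube: HyperspectralCube, mask: np.ndarray, region_id: int = 0) -> RegionSpectrum:
    """Per-band arithmetic mean of all pixels under ``mask``."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cube.values.shape[:2]:
        raise ValueError("mask shape does not match cube")
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty region")
    return RegionSpectrum(
        region_id=region_id,
        spectrum=cube.values[mask].mean(axis=0),
        pixel_count=n,
    )


def reference_spectrum(
    cube: HyperspectralCube, reference: ReferenceRegion, erode_px: int = 2
) -> RegionSpectrum:
    """Mean spectrum of the panel interior.

    The panel mask is eroded by ``erode_px`` pixels before averaging so the
    bright edge pixels (a known artifact of the scanned panel) do not bias the
    reference; erosion is skipped if it would empty the region.
    """
    mask = reference.mask
    if erode_px > 0:
        eroded = erosion(mask, disk(erode_px))
        if eroded.any():
            mask = eroded
    return mean_spectrum(cube, mask, region_id=reference.region_id or 0)


def ratio_to_reference(
    samples: list[RegionSpectrum], reference: RegionSpectrum
) -> list[RegionSpectrum]:
    """Element-wise sample/reference ratio spectra (relative reflectance).

    Requires a strictly positive reference at every band; the offending band
    index is named otherwise.  Reference pairing is per scan — callers must
    pass the reference extracted from the same cube as the samples.
    """
    ref = reference.spectrum
    bad = np.flatnonzero(ref <= 0)
    if bad.size:
        raise ValueError(
            f"reference spectrum non-positive at band indices {bad.tolist()[:5]}"
        )
    out = []
    for s in samples:
        if s.spectrum.shape != ref.shape:
            raise ValueError("sample and reference on different wavelength grids")
        out.append(
            RegionSpectrum(
                region_id=s.region_id,
                spectrum=s.spectrum / ref,
                pixel_count=s.pixel_count,
            )
        )
    return out


def extract_region_spectra(
    cube: HyperspectralCube, result: SegmentationResult
) -> list[RegionSpectrum]:
    """Mean spectrum of every labeled region, in region-id order."""
    out = []
    for rid in np.unique(result.regions):
        if rid == 0:
            continue
        out.append(mean_spectrum(cube, result.regions == rid, region_id=int(rid)))
    return out


def assemble_spectra_table(
    scans: list[tuple[HyperspectralCube, list[RegionSpectrum], pd.DataFrame]],
) -> SpectraTable:
    """Combine per-scan ratio spectra and region metadata into one table.

    ``scans`` holds (cube, ratio spectra, region metadata) triples; the
    metadata frame maps ``region_id`` to sample_id / cultivar / stage / organ
    / replicate.  Every region must be mapped, wavelength grids must agree,
    and sample ids must be unique across scans (enforced by the table
    container).
    """
    if not scans:
        raise ValueError("no scans to assemble")
    wl = scans[0][0].wavelengths
    rows, values = [], []
    for cube, spectra, meta in scans:
        if len(cube.wavelengths) != len(wl) or not np.allclose(cube.wavelengths, wl):
            raise ValueError(f"scan {cube.scan_id}: wavelength grid mismatch")
        mapping = meta.set_index("region_id")
        for s in spectra:
            if s.region_id not in mapping.index:
                raise ValueError(
                    f"scan {cube.scan_id}: region {s.region_id} has no metadata"
                )
            m = mapping.loc[s.region_id]
            rows.append(
                {
                    "sample_id": m["sample_id"],
                    "scan_id": cube.scan_id,
                    "cultivar": m.get("cultivar", ""),
                    "stage": m.get("stage", ""),
                    "organ": m.get("organ", ""),
                    "replicate": m.get("replicate", 0),
                }
            )
            values.append(s.spectrum)
    return SpectraTable(
        metadata=pd.DataFrame(rows, columns=METADATA_COLUMNS),
        values=np.vstack(values),
        wavelengths=wl,
    )
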