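"""Synthetic hyperspectral scenes and spectra with hemp-study structure.

The study scanned fresh hemp leaves and flowers (five CBD cultivars, five
growth stages two to ten weeks after flower initiation) on a flat tray next to
a 20%-nominal-reflectance Spectralon panel, under noticeably uneven halogen
illumination.  No raw cubes are publicly deposited, so this module generates
scenes and spectra datasets carrying the statistical structure that the
analysis pipeline assumes:

* vegetation-like reflectance — low visible reflectance with a green bump near
  550 nm, a chlorophyll absorption dip near 670 nm, a sharp red edge near
  700-720 nm, and an NIR plateau;
* class effects ordered organ > stage > cultivar, mirroring the separability
  the study observed (organs and stages form resolved PCA clusters, cultivars
  overlap);
* a spectrally flat tray background and in-frame reference panel;
* a smooth multiplicative illumination field (default amplitude +/-15%) and
  additive/multiplicative sensor noise;
* the study's sampling design (Table-1-style cell counts: 16-24 samples per
  cultivar x date x organ cell, 4 replicate plants per cultivar and date).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .io import METADATA_COLUMNS, HyperspectralCube, SpectraTable

__all__ = [
    "SpectralClassModel",
    "SceneObject",
    "SceneDesign",
    "SamplingDesign",
    "vegetation_spectrum",
    "render_scene",
    "generate_spectra_dataset",
    "build_sampling_design",
    "study_sampling_design",
    "default_class_models",
    "effective_class_curves",
    "build_scene_design",
    "default_wavelengths",
    "CULTIVARS",
    "STAGES",
    "STAGE_DATES",
    "ORGANS",
]

#: The five CBD hemp cultivars, in the study's order.
CULTIVARS = ("CW", "BX", "FL58", "FL70", "TJ")
#: Growth stages: weeks after flower initiation, one per sampling date.
STAGES = ("wk02", "wk04", "wk06", "wk08", "wk10")
STAGE_DATES = {
    "wk02": "09/24/2020",
    "wk04": "10/08/2020",
    "wk06": "10/22/2020",
    "wk08": "11/05/2020",
    "wk10": "11/19/2020",
}
ORGANS = ("leaf", "flower")

# Per-cell sample counts of the study design: {(cultivar, organ): counts by stage}.
_STUDY_COUNTS = {
    ("CW", "leaf"): (16, 16, 16, 16, 16),
    ("CW", "flower"): (24, 24, 24, 24, 24),
    ("BX", "leaf"): (16, 16, 16, 16, 16),
    ("BX", "flower"): (22, 21, 21, 22, 21),
    ("FL58", "leaf"): (16, 16, 16, 16, 16),
    ("FL58", "flower"): (16, 17, 16, 16, 16),
    ("FL70", "leaf"): (16, 16, 16, 16, 16),
    ("FL70", "flower"): (16, 16, 16, 16, 16),
    ("TJ", "leaf"): (16, 16, 16, 16, 16),
    ("TJ", "flower"): (16, 16, 16, 16, 16),
}


def default_wavelengths(n_bands: int = 462) -> np.ndarray:
    """The camera's wavelength grid: 400-1000 nm at ~1.3 nm over 462 bands."""
    return np.linspace(400.0, 1000.0, n_bands)


# ---------------------------------------------------------------------------
# Spectral class models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpectralClassModel:
    """Parametric vegetation reflectance curve for one (cultivar, stage, organ).

    The mean curve is a visible-range base (constant baseline + green Gaussian
    bump - chlorophyll Gaussian dip) blended into a flat NIR plateau through a
    logistic red edge.  ``within_class_sd`` is the per-wavelength multiplicative
    spread of individual samples around the mean curve.
    """

    visible_baseline: float = 0.05
    green_peak_amplitude: float = 0.04
    green_peak_center: float = 550.0
    green_peak_width: float = 28.0
    chl_absorption_depth: float = 0.04
    chl_absorption_center: float = 670.0
    chl_absorption_width: float = 10.0
    red_edge_center: float = 714.0
    red_edge_slope: float = 8.0
    nir_plateau: float = 0.45
    within_class_sd: float = 0.05
    label: tuple = ("", "", "")

    def __post_init__(self) -> None:
        for name in ("visible_baseline", "nir_plateau"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.chl_absorption_depth >= self.visible_baseline + self.green_peak_amplitude:
            raise ValueError(
                "chlorophyll absorption depth must stay below baseline + green peak"
            )
        if self.nir_plateau <= self.visible_baseline:
            raise ValueError("vegetation requires nir_plateau > visible_baseline")
        if self.within_class_sd < 0:
            raise ValueError("within_class_sd must be >= 0")

    def mean_curve(self, wavelengths: np.ndarray) -> np.ndarray:
        """Deterministic mean reflectance at each wavelength, in [0, 1]."""
        wl = np.asarray(wavelengths, dtype=np.float64)
        visible = (
            self.visible_baseline
            + self.green_peak_amplitude
            * np.exp(-0.5 * ((wl - self.green_peak_center) / self.green_peak_width) ** 2)
            - self.chl_absorption_depth
            * np.exp(-0.5 * ((wl - self.chl_absorption_center) / self.chl_absorption_width) ** 2)
        )
        edge = 1.0 / (1.0 + np.exp(-(wl - self.red_edge_center) / self.red_edge_slope))
        return np.clip(visible * (1.0 - edge) + self.nir_plateau * edge, 0.0, 1.0)


@lru_cache(maxsize=8)
def _smoothing_kernel(n: int, sigma: float) -> tuple[np.ndarray, np.ndarray]:
    """Band-correlation kernel matrix and its per-band row norms."""
    kernel = gaussian_filter1d(np.eye(n), sigma=sigma, axis=0, mode="nearest")
    return kernel, np.sqrt((kernel**2).sum(axis=0))


def _correlated_noise(rng: np.random.Generator, n: int, size: int, sigma: float = 6.0) -> np.ndarray:
    """(size, n) standard-normal noise, smooth along the wavelength axis.

    Each row has exactly unit marginal variance at every band (the Gaussian
    smoothing kernel is renormalized per band), so multiplicative spread stays
    calibrated while spectra remain smooth as real reflectance noise is.
    """
    z = rng.standard_normal((size, n))
    kernel, norms = _smoothing_kernel(n, sigma)
    return (z @ kernel) / norms


def vegetation_spectrum(
    model: SpectralClassModel,
    wavelengths: np.ndarray,
    rng: np.random.Generator | int | None = None,
    size: int | None = None,
) -> np.ndarray:
    """Draw reflectance spectra from a class model.

    With ``within_class_sd == 0`` (or ``rng=None``) this returns the
    deterministic mean curve.  Otherwise each draw is
    ``mean_curve * (1 + sd * z)`` with ``z`` smooth unit-variance noise,
    clipped to [0, 1]; the expectation equals the mean curve (clipping is
    vanishingly rare at realistic sd).

    Returns shape ``(n_wavelengths,)`` when ``size`` is None, else
    ``(size, n_wavelengths)``.
    """
    wl = np.asarray(wavelengths, dtype=np.float64)
    if wl.ndim != 1 or (len(wl) > 1 and not np.all(np.diff(wl) > 0)):
        raise ValueError("wavelengths must be a 1-D ascending vector")
    if wl.min() < 350 or wl.max() > 1100:
        raise ValueError("wavelengths outside the supported 350-1100 nm range")
    mean = model.mean_curve(wl)
    n_draws = 1 if size is None else size
    if model.within_class_sd == 0 or rng is None:
        out = np.tile(mean, (n_draws, 1))
    else:
        if isinstance(rng, (int, np.integer)):
            rng = np.random.default_rng(rng)
        noise = _correlated_noise(rng, len(wl), n_draws)
        out = np.clip(mean * (1.0 + model.within_class_sd * noise), 0.0, 1.0)
    return out[0] if size is None else out


def default_class_models(
    cultivars=CULTIVARS,
    stages=STAGES,
    organs=ORGANS,
    base: SpectralClassModel | None = None,
    cultivar_seed: int = 20220202,
) -> dict[tuple, SpectralClassModel]:
    """One class model per (cultivar, stage, organ) with study-like effects.

    Effect sizes are ordered organ > stage > cultivar: organs differ strongly
    in NIR plateau and red-edge slope; stages shift the chlorophyll dip down
    and the NIR plateau up monotonically (senescence: pigment degradation and
    water loss); cultivars get small fixed offsets drawn once from
    ``cultivar_seed`` (a constant, so the palette is stable across runs).
    """
    base = base or SpectralClassModel()
    rng = np.random.default_rng(cultivar_seed)
    cultivar_offsets = {
        c: {
            "visible_baseline": float(rng.normal(0, 0.0035)),
            "green_peak_amplitude": float(rng.normal(0, 0.005)),
            "chl_absorption_depth": float(rng.normal(0, 0.004)),
            "nir_plateau": float(rng.normal(0, 0.015)),
            "red_edge_center": float(rng.normal(0, 1.5)),
        }
        for c in cultivars
    }
    models: dict[tuple, SpectralClassModel] = {}
    for c in cultivars:
        off = cultivar_offsets[c]
        for si, s in enumerate(stages):
            for organ in organs:
                nir = base.nir_plateau + off["nir_plateau"] + 0.020 * si
                depth = max(
                    (base.chl_absorption_depth + off["chl_absorption_depth"])
                    * (1.0 - 0.12 * si),
                    0.002,
                )
                kwargs = dict(
                    visible_baseline=base.visible_baseline + off["visible_baseline"],
                    green_peak_amplitude=base.green_peak_amplitude
                    + off["green_peak_amplitude"],
                    chl_absorption_depth=depth,
                    red_edge_center=base.red_edge_center + off["red_edge_center"],
                    within_class_sd=base.within_class_sd,
                    label=(c, s, organ),
                )
                if organ == "flower":
                    kwargs["nir_plateau"] = min(nir + 0.15, 0.95)
                    kwargs["red_edge_slope"] = base.red_edge_slope + 6.0
                    kwargs["green_peak_amplitude"] += 0.01
                else:
                    kwargs["nir_plateau"] = min(nir, 0.95)
                    kwargs["red_edge_slope"] = base.red_edge_slope
                models[(c, s, organ)] = replace(base, **kwargs)
    return models


def effective_class_curves(
    models: dict[tuple, SpectralClassModel],
    wavelengths: np.ndarray,
    separation: float = 1.0,
) -> dict[tuple, np.ndarray]:
    """Class mean curves with between-class differences scaled by ``separation``.

    Deviations of each class mean from the grand mean (over the classes given)
    are multiplied by ``separation``; 0 collapses every class onto one shared
    curve (the null case), 1 reproduces the models as specified.
    """
    if separation < 0:
        raise ValueError("separation must be >= 0")
    wl = np.asarray(wavelengths, dtype=np.float64)
    curves = {k: m.mean_curve(wl) for k, m in models.items()}
    grand = np.mean(list(curves.values()), axis=0)
    return {
        k: np.clip(grand + separation * (c - grand), 0.0, 1.0)
        for k, c in curves.items()
    }


# ---------------------------------------------------------------------------
# Sampling design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SamplingDesign:
    """Cell counts of the greenhouse sampling design.

    ``counts[(cultivar, stage, organ)]`` is the number of sampled organs in
    that cell; ``replicates`` is the number of plants per cultivar and stage.
    """

    cultivars: tuple
    stages: tuple
    organs: tuple
    replicates: int
    counts: dict

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be a positive integer")
        for key, n in self.counts.items():
            if not (isinstance(n, (int, np.integer)) and n > 0):
                raise ValueError(f"cell count for {key} must be a positive integer")

    @property
    def plants_per_cultivar(self) -> int:
        return len(self.stages) * self.replicates

    @property
    def total_plants(self) -> int:
        return len(self.cultivars) * self.plants_per_cultivar

    @property
    def total_samples(self) -> int:
        return int(sum(self.counts.values()))

    def cell_count(self, cultivar: str, stage: str, organ: str) -> int:
        return self.counts[(cultivar, stage, organ)]


def build_sampling_design(
    cultivars=CULTIVARS,
    stages=STAGES,
    replicates: int = 4,
    organs=ORGANS,
    counts: dict | int | None = None,
) -> SamplingDesign:
    """Construct a sampling design and its plant totals.

    ``counts`` may be a full cell-count dict, a single per-cell count, or None
    (defaults to 4 organs per replicate plant, i.e. 4 x ``replicates`` per
    cell, the study's leaf-sampling rule).
    """
    cultivars = tuple(cultivars) if not isinstance(cultivars, int) else tuple(
        f"C{i+1}" for i in range(cultivars)
    )
    stages = tuple(stages) if not isinstance(stages, int) else tuple(
        f"S{i+1}" for i in range(stages)
    )
    if not cultivars or not stages:
        raise ValueError("need at least one cultivar and one stage")
    if isinstance(counts, dict):
        cell_counts = dict(counts)
    else:
        per_cell = int(counts) if counts is not None else 4 * replicates
        cell_counts = {
            (c, s, o): per_cell for c in cultivars for s in stages for o in organs
        }
    return SamplingDesign(
        cultivars=cultivars,
        stages=stages,
        organs=tuple(organs),
        replicates=replicates,
        counts=cell_counts,
    )


def study_sampling_design() -> SamplingDesign:
    """The study's design: 5 cultivars x 5 dates x 4 plants, leaf/flower counts
    as sampled (16 leaves per cell; 16-24 flowers depending on cultivar)."""
    counts = {
        (c, s, o): _STUDY_COUNTS[(c, o)][si]
        for c in CULTIVARS
        for si, s in enumerate(STAGES)
        for o in ORGANS
    }
    return build_sampling_design(CULTIVARS, STAGES, replicates=4, counts=counts)


# ---------------------------------------------------------------------------
# Spectra dataset generation
# ---------------------------------------------------------------------------


def generate_spectra_dataset(
    design: SamplingDesign,
    classes: dict[tuple, SpectralClassModel] | None = None,
    separation: float = 1.0,
    seed: int | np.random.Generator = 0,
    wavelengths: np.ndarray | None = None,
) -> tuple[SpectraTable, pd.DataFrame]:
    """Draw a spectra table following the sampling design.

    Each (cultivar, stage, organ) cell contributes exactly its designed number
    of rows, drawn around that class's effective mean curve (see
    :func:`effective_class_curves`) with the class's multiplicative
    within-class spread.  Returns the table plus a per-row label frame
    (cultivar / stage / organ).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    wl = default_wavelengths() if wavelengths is None else np.asarray(wavelengths, float)
    if classes is None:
        classes = default_class_models(design.cultivars, design.stages, design.organs)
    missing = [k for k in design.counts if k not in classes]
    if missing:
        raise ValueError(f"no class model for design cells: {missing[:3]}...")
    curves = effective_class_curves(
        {k: classes[k] for k in design.counts}, wl, separation
    )

    meta_rows = []
    blocks = []
    for c in design.cultivars:
        for s in design.stages:
            for o in design.organs:
                n = design.cell_count(c, s, o)
                model = classes[(c, s, o)]
                noise = _correlated_noise(rng, len(wl), n)
                block = np.clip(
                    curves[(c, s, o)] * (1.0 + model.within_class_sd * noise), 0.0, 1.0
                )
                blocks.append(block)
                for i in range(n):
                    meta_rows.append(
                        {
                            "sample_id": f"{c}_{s}_{o}_{i:03d}",
                            "scan_id": f"scan_{c}_{s}",
                            "cultivar": c,
                            "stage": s,
                            "organ": o,
                            "replicate": i % design.replicates + 1,
                        }
                    )
    table = SpectraTable(
        metadata=pd.DataFrame(meta_rows, columns=METADATA_COLUMNS),
        values=np.vstack(blocks),
        wavelengths=wl,
    )
    return table, table.metadata[["cultivar", "stage", "organ"]].copy()


# ---------------------------------------------------------------------------
# Scene design and rendering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SceneObject:
    """One plant piece laid on the tray: an ellipse (leaf) or a blob of
    overlapping ellipses (flower head)."""

    shape: str  # "ellipse" | "blob"
    center: tuple  # (line, pixel)
    radii: tuple  # (line semi-axis, pixel semi-axis) in px
    label: tuple  # class key (cultivar, stage, organ)
    angle_deg: float = 0.0


@dataclass
class SceneDesign:
    """Layout and acquisition model of one synthetic scan.

    The rendered cube is ``illumination(x, y) * response(lambda) *
    reflectance(lambda) * (1 + multiplicative noise) + additive noise``,
    clipped at zero.  ``illumination`` is a smooth spatial surface (the uneven
    lamp field over the tray); ``response(lambda)`` is a smooth per-scan
    spectral factor shared by every pixel, emulating the lamp/camera spectral
    response that drifts between scans and that the in-scan reference ratio
    is meant to cancel.  The reference panel is a spectrally flat rectangle of
    the given nominal reflectance; the tray background is spectrally flat too.
    """

    n_lines: int
    n_pixels: int
    objects: list
    reference_rect: tuple | None = (4, 4, 24, 40)  # (line0, pixel0, height, width)
    reference_reflectance: float = 0.20
    background_reflectance: float = 0.08
    illumination_amplitude: float = 0.15
    spectral_response_amplitude: float = 0.15
    additive_noise_sd: float = 0.005
    multiplicative_noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.illumination_amplitude < 1:
            raise ValueError("illumination amplitude must lie in [0, 1)")


def _ellipse_mask(n_lines, n_pixels, center, radii, angle_deg=0.0) -> np.ndarray:
    ll, pp = np.mgrid[0:n_lines, 0:n_pixels]
    dl, dp = ll - center[0], pp - center[1]
    if angle_deg:
        t = np.deg2rad(angle_deg)
        dl, dp = dl * np.cos(t) - dp * np.sin(t), dl * np.sin(t) + dp * np.cos(t)
    return (dl / radii[0]) ** 2 + (dp / radii[1]) ** 2 <= 1.0


def _object_mask(obj: SceneObject, n_lines: int, n_pixels: int) -> np.ndarray:
    if obj.shape == "ellipse":
        return _ellipse_mask(n_lines, n_pixels, obj.center, obj.radii, obj.angle_deg)
    if obj.shape == "blob":
        # Flower head: union of three overlapping lobes around the center.
        mask = np.zeros((n_lines, n_pixels), dtype=bool)
        rl, rp = obj.radii
        offsets = [(0, 0), (-0.55 * rl, 0.45 * rp), (0.55 * rl, -0.45 * rp)]
        for k, (dl, dp) in enumerate(offsets):
            mask |= _ellipse_mask(
                n_lines,
                n_pixels,
                (obj.center[0] + dl, obj.center[1] + dp),
                (0.75 * rl, 0.75 * rp),
                obj.angle_deg + 30.0 * k,
            )
        return mask
    raise ValueError(f"unknown object shape {obj.shape!r}")


def _illumination_field(design: SceneDesign, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative surface 1 + f(x, y), max |f| = amplitude."""
    if design.illumination_amplitude == 0:
        return np.ones((design.n_lines, design.n_pixels))
    y = np.linspace(-1, 1, design.n_lines)[:, None]
    x = np.linspace(-1, 1, design.n_pixels)[None, :]
    coef = rng.normal(size=5)
    f = coef[0] * x + coef[1] * y + coef[2] * x * y + coef[3] * x**2 + coef[4] * y**2
    f = f - f.mean()
    peak = np.max(np.abs(f))
    if peak > 0:
        f *= design.illumination_amplitude / peak
    return 1.0 + f


def _spectral_response(
    design: SceneDesign, rng: np.random.Generator, wl: np.ndarray
) -> np.ndarray:
    """Smooth per-scan spectral gain 1 + f(lambda), max |f| = amplitude.

    Built from three random low-frequency cosine components over the sampled
    range, so consecutive scans get different lamp/camera responses.
    """
    if design.spectral_response_amplitude == 0:
        return np.ones(len(wl))
    u = (wl - wl[0]) / max(wl[-1] - wl[0], 1.0)
    f = np.zeros(len(wl))
    for k in (1, 2, 3):
        f += rng.normal() / k * np.cos(np.pi * k * u + rng.uniform(0, 2 * np.pi))
    f -= f.mean()
    peak = np.max(np.abs(f))
    if peak > 0:
        f *= design.spectral_response_amplitude / peak
    return 1.0 + f


def render_scene(
    design: SceneDesign,
    classes: dict[tuple, SpectralClassModel],
    wavelengths: np.ndarray | None = None,
) -> tuple[HyperspectralCube, np.ndarray, pd.DataFrame]:
    """Render a scene to (cube, ground-truth label image, object metadata).

    Labels are 1..n in layout order with 0 = background; the reference panel
    is not part of the label image (its rectangle is in the metadata frame,
    kind = ``reference``).  Each object draws one spectral realization from
    its class model, shared by all its pixels, so regions of the same class
    differ by within-class spread as separately scanned organs do.
    """
    wl = default_wavelengths() if wavelengths is None else np.asarray(wavelengths, float)
    rng = np.random.default_rng(design.seed)
    nl, npx = design.n_lines, design.n_pixels

    labels = np.zeros((nl, npx), dtype=np.int32)
    reflectance = np.empty((nl, npx, len(wl)))
    reflectance[:] = design.background_reflectance

    ref_mask = np.zeros((nl, npx), dtype=bool)
    if design.reference_rect is not None:
        l0, p0, h, w = design.reference_rect
        if l0 < 0 or p0 < 0 or l0 + h > nl or p0 + w > npx:
            raise ValueError("reference rectangle outside the image")
        ref_mask[l0 : l0 + h, p0 : p0 + w] = True
        reflectance[ref_mask] = design.reference_reflectance

    records = []
    for i, obj in enumerate(design.objects, start=1):
        if obj.label not in classes:
            raise ValueError(f"no class model for object label {obj.label}")
        mask = _object_mask(obj, nl, npx)
        if np.any(mask & ((labels != 0) | ref_mask)):
            raise ValueError(
                f"object {i} overlaps a previous object or the reference panel"
            )
        labels[mask] = i
        spectrum = vegetation_spectrum(classes[obj.label], wl, rng)
        reflectance[mask] = spectrum
        c, s, o = obj.label
        records.append(
            {
                "object_id": i,
                "kind": obj.shape,
                "cultivar": c,
                "stage": s,
                "organ": o,
                "area_px": int(mask.sum()),
            }
        )
    if design.reference_rect is not None:
        records.append(
            {
                "object_id": 0,
                "kind": "reference",
                "cultivar": "",
                "stage": "",
                "organ": "",
                "area_px": int(ref_mask.sum()),
            }
        )

    illum = _illumination_field(design, rng)
    response = _spectral_response(design, rng, wl)
    cube = illum[:, :, None] * response[None, None, :] * reflectance
    if design.multiplicative_noise_sd > 0:
        gain = 1.0 + design.multiplicative_noise_sd * rng.standard_normal((nl, npx))
        cube *= gain[:, :, None]
    if design.additive_noise_sd > 0:
        cube += design.additive_noise_sd * rng.standard_normal(cube.shape)
    cube = np.clip(cube, 0.0, None)

    hcube = HyperspectralCube(values=cube, wavelengths=wl, scan_id=f"scene_{design.seed}")
    return hcube, labels.astype(np.int64), pd.DataFrame(records)


def build_scene_design(
    labels: list,
    n_lines: int = 160,
    n_pixels: int = 200,
    object_radius: float = 11.0,
    reference_rect: tuple | None = (4, 4, 24, 40),
    seed: int = 0,
    **kwargs,
) -> SceneDesign:
    """Lay out one object per label on a non-overlapping grid.

    ``labels`` is a list of class keys (cultivar, stage, organ); leaves become
    ellipses, flowers become blobs.  Objects are placed on a regular grid
    below the reference panel with jitter small enough to keep them disjoint.
    """
    rng = np.random.default_rng(seed)
    top = (reference_rect[0] + reference_rect[2] + 8) if reference_rect else 6
    cell = int(np.ceil(2.6 * object_radius))
    cols = max((n_pixels - 8) // cell, 1)
    rows = max((n_lines - top - 4) // cell, 1)
    if rows * cols < len(labels):
        raise ValueError(
            f"image too small for {len(labels)} objects "
            f"(grid holds {rows * cols} at radius {object_radius})"
        )
    objects = []
    for i, lab in enumerate(labels):
        r, c = divmod(i, cols)
        center = (
            top + cell * r + cell / 2 + rng.uniform(-1.5, 1.5),
            6 + cell * c + cell / 2 + rng.uniform(-1.5, 1.5),
        )
        stretch = rng.uniform(0.75, 0.95)
        organ = lab[2] if len(lab) >= 3 else "leaf"
        objects.append(
            SceneObject(
                shape="blob" if organ == "flower" else "ellipse",
                center=center,
                radii=(object_radius * stretch, object_radius),
                label=tuple(lab),
                angle_deg=float(rng.uniform(0, 180)),
            )
        )
    return SceneDesign(
        n_lines=n_lines,
        n_pixels=n_pixels,
        objects=objects,
        reference_rect=reference_rect,
        seed=seed,
        **kwargs,
    )
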