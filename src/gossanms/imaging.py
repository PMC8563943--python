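"""Secondary-ion imaging: per-pixel peak lists, ion maps, RGB overlays,
colocalization scores.

An :class:`IonImageCube` holds one centroided peak list per pixel of a
raster (all pixels share polarity).  Extracting an ion image sums, per
pixel, the intensity falling inside a mass window or matching a fragment
library group; the pixel sums conserve the cube's matched intensity
exactly.  Overlays normalize each channel independently to [0, 1].
Spatial co-occurrence of two maps is scored with Pearson correlation on
pixel intensities and the Jaccard overlap of Otsu-thresholded supports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .peaklist import PeakList
from .sims_annotation import DEFAULT_TOL_DA, FragmentLibraryEntry

__all__ = [
    "IonImageCube",
    "IonImage",
    "extract_image",
    "rgb_overlay",
    "colocalization",
    "ColocalizationScores",
]


@dataclass
class IonImageCube:
    """A (height x width) grid of per-pixel peak lists."""

    width: int
    height: int
    pixels: List[List[PeakList]]  # row-major: pixels[y][x]
    polarity: Optional[str] = None
    pixel_size_um: Optional[float] = None
    metadata: Dict = field(default_factory=dict)

    def __post_init__(self):
        if self.width < 1 or self.height < 1:
            raise ValueError("cube dimensions must be >= 1")
        if len(self.pixels) != self.height or any(
            len(row) != self.width for row in self.pixels
        ):
            raise ValueError("pixel grid does not match declared dimensions")
        for row in self.pixels:
            for pl in row:
                if pl.polarity is not None and pl.polarity != self.polarity:
                    raise ValueError("all pixels must share the cube polarity")

    def pixel(self, x: int, y: int) -> PeakList:
        return self.pixels[y][x]

    # -- long-format round trip ----------------------------------------------
    def to_long_frame(self):
        import pandas as pd

        rows = []
        for y, row in enumerate(self.pixels):
            for x, pl in enumerate(row):
                for mz, inten in pl:
                    rows.append((x, y, mz, inten))
        return pd.DataFrame(rows, columns=["x", "y", "mz", "intensity"])

    @classmethod
    def from_long_frame(
        cls, df, width=None, height=None, polarity=None, pixel_size_um=None
    ) -> "IonImageCube":
        width = int(width if width is not None else df["x"].max() + 1)
        height = int(height if height is not None else df["y"].max() + 1)
        grid = [
            [PeakList(np.empty(0), np.empty(0), polarity) for _ in range(width)]
            for _ in range(height)
        ]
        for (x, y), sub in df.groupby(["x", "y"]):
            grid[int(y)][int(x)] = PeakList.from_pairs(
                sub[["mz", "intensity"]].to_numpy(), polarity
            )
        return cls(width, height, grid, polarity, pixel_size_um)


@dataclass
class IonImage:
    """A nonnegative intensity grid plus the window/group it was built from."""

    values: np.ndarray  # shape (height, width)
    source: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("image must be 2-D")
        if np.any(self.values < 0):
            raise ValueError("image intensities must be nonnegative")

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def downsample(self, factor: int = 2) -> "IonImage":
        """Block-sum downsampling (intensity conserving)."""
        h, w = self.values.shape
        if h % factor or w % factor:
            raise ValueError("dimensions not divisible by downsampling factor")
        v = self.values.reshape(h // factor, factor, w // factor, factor)
        return IonImage(v.sum(axis=(1, 3)), f"{self.source} (/{factor})")


def _window_sum(pl: PeakList, lo: float, hi: float) -> float:
    i0 = np.searchsorted(pl.mz, lo, side="left")
    i1 = np.searchsorted(pl.mz, hi, side="right")
    return float(pl.intensity[i0:i1].sum())


def extract_image(
    cube: IonImageCube,
    window: Optional[Tuple[float, float]] = None,
    group: Optional[str] = None,
    library: Optional[Sequence[FragmentLibraryEntry]] = None,
    tol: float = DEFAULT_TOL_DA,
) -> IonImage:
    """Ion image for a mass window [lo, hi] or a fragment-library group.

    In group mode, the pixel value is the summed intensity of peaks within
    ``tol`` of any library entry carrying the tag (each peak counted once).
    A window outside the cube's mass range yields an all-zero image rather
    than an error.
    """
    if (window is None) == (group is None):
        raise ValueError("provide exactly one of window or group")
    out = np.zeros((cube.height, cube.width))
    if window is not None:
        lo, hi = window
        if hi < lo:
            raise ValueError(f"empty mass window ({lo}, {hi})")
        for y in range(cube.height):
            for x in range(cube.width):
                out[y, x] = _window_sum(cube.pixel(x, y), lo, hi)
        return IonImage(out, f"mz[{lo:g},{hi:g}]")
    if library is None:
        raise ValueError("group mode requires a fragment library")
    targets = [
        e.ion.mz
        for e in library
        if group in e.group_tags
        and (cube.polarity is None or e.ion.polarity == cube.polarity)
    ]
    if not targets:
        raise ValueError(f"no library entries tagged {group!r} for this polarity")
    targets = np.sort(np.asarray(targets))
    for y in range(cube.height):
        for x in range(cube.width):
            pl = cube.pixel(x, y)
            if len(pl) == 0:
                continue
            # peak matched once even if several entries are within tol
            nearest = targets[
                np.clip(np.searchsorted(targets, pl.mz), 0, targets.size - 1)
            ]
            prev = targets[
                np.clip(np.searchsorted(targets, pl.mz) - 1, 0, targets.size - 1)
            ]
            dist = np.minimum(np.abs(pl.mz - nearest), np.abs(pl.mz - prev))
            out[y, x] = pl.intensity[dist <= tol].sum()
    return IonImage(out, f"group[{group}]")


def rgb_overlay(r: IonImage, g: IonImage, b: IonImage) -> np.ndarray:
    """Compose an RGB array, each channel min-max normalized independently.

    An all-zero (or constant-zero-minimum) channel maps to zeros.  Returns a
    (height, width, 3) float array in [0, 1].
    """
    shapes = {r.values.shape, g.values.shape, b.values.shape}
    if len(shapes) != 1:
        raise ValueError(f"channel dimensions differ: {shapes}")
    chans = []
    for img in (r, g, b):
        v = img.values
        vmin, vmax = v.min(), v.max()
        if vmax > vmin:
            chans.append((v - vmin) / (vmax - vmin))
        else:
            chans.append(np.zeros_like(v))
    return np.stack(chans, axis=-1)


@dataclass(frozen=True)
class ColocalizationScores:
    pearson_r: Optional[float]  # None when either image is constant
    overlap_fraction: float  # Jaccard of thresholded supports
    threshold_a: float
    threshold_b: float


def _support(values: np.ndarray) -> Tuple[np.ndarray, float]:
    """Otsu-thresholded support mask (parameter-free default)."""
    from skimage.filters import threshold_otsu

    finite = values[np.isfinite(values)]
    if finite.max() == finite.min():
        return values > 0, 0.0
    t = float(threshold_otsu(values))
    return values > t, t


def colocalization(a: IonImage, b: IonImage) -> ColocalizationScores:
    """Pearson r on pixel intensities plus Jaccard overlap of supports."""
    if a.values.shape != b.values.shape:
        raise ValueError("images must share dimensions")
    va, vb = a.values.ravel(), b.values.ravel()
    if va.std() == 0 or vb.std() == 0:
        pearson = None
    else:
        pearson = float(np.corrcoef(va, vb)[0, 1])
    mask_a, ta = _support(a.values)
    mask_b, tb = _support(b.values)
    union = np.logical_or(mask_a, mask_b).sum()
    inter = np.logical_and(mask_a, mask_b).sum()
    overlap = float(inter / union) if union else 0.0
    return ColocalizationScores(pearson, overlap, ta, tb)
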