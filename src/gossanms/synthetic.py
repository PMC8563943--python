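"""Ground-truthed synthetic spectra, image cubes and fatty-acid profiles.

Every generator is a pure function of (config, seed): the same inputs give
byte-identical outputs.  Each returns its ground truth alongside the data,
so downstream stages can be scored without re-deriving anything.

What is emulated
----------------
* ``gen_fticr_peaklist`` — a negative-mode ultrahigh-resolution spectrum:
  thousands of deprotonated CHO/CHNO/CHOS ions over m/z 147.4-1000 with
  multiplicative mass noise at the 0.1 ppm level (internally calibrated
  magnet-class accuracy) and log-normal intensities.  Formula pools are
  built by rejection sampling under the same chemical-validity windows the
  assignment stage uses, so synthetic spectra occupy realistic van Krevelen
  space.
* ``gen_sims_spectrum`` — a secondary-ion fragment spectrum for one marker
  group: peaks at the library's theoretical masses with Da-scale jitter,
  log-normal intensity scatter around the group recipe, an always-present
  inorganic matrix background, and optional uniform chemical noise peaks.
* ``gen_image_cube`` — a raster of such spectra with group recipes painted
  into spatial layouts (filaments, ovoids, half-fields) over a matrix
  background; the layout masks are returned as ground truth.
* ``gen_fa_profile`` — a fungal-like fatty-acid intensity profile with a
  programmable even:odd intensity ratio on the short-chain (<= C20) side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .formula_assign import AssignmentConfig
from .masschem import IonSpecies, MolecularFormula
from .peaklist import PeakList
from .series_stats import FattyAcidIon
from .sims_annotation import FragmentLibraryEntry, load_library
from .imaging import IonImageCube

__all__ = [
    "FticrSimConfig",
    "SimsSimConfig",
    "CubeSimConfig",
    "gen_fticr_peaklist",
    "gen_sims_spectrum",
    "gen_image_cube",
    "gen_fa_profile",
    "half_field_masks",
    "filament_mask",
    "ovoid_mask",
]


# ---------------------------------------------------------------------------
# FTICR-like spectra
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FticrSimConfig:
    n_peaks: int = 2000
    #: CHO / CHNO / CHOS proportions (sum to 1)
    class_mix: Tuple[float, float, float] = (0.39, 0.51, 0.10)
    mass_range: Tuple[float, float] = (147.4, 1000.0)
    ppm_sigma: float = 0.1
    #: log-normal intensity scatter (sigma of log), scaled by ``intensity_scale``
    intensity_sigma: float = 1.0
    intensity_scale: float = 1e6
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError("class mix must sum to 1")
        if any(p < 0 for p in self.class_mix):
            raise ValueError("class proportions must be nonnegative")
        if self.mass_range[1] <= self.mass_range[0]:
            raise ValueError("empty mass range")


def _sample_formula(rng: np.random.Generator, cls: str, cfg: FticrSimConfig,
                    validity: AssignmentConfig) -> Optional[MolecularFormula]:
    """One rejection-sampling attempt at a neutral CHNOS molecule of ``cls``."""
    c = int(rng.integers(6, 46))
    o = int(rng.integers(2, 16))
    n = int(rng.integers(1, 6)) if cls == "CHNO" else 0
    s = int(rng.integers(1, 3)) if cls == "CHOS" else 0
    dbe = int(rng.integers(0, 21))
    h = 2 * c + 2 + n - 2 * dbe
    if h < 1:
        return None
    hc, oc = h / c, o / c
    if not (validity.hc_range[0] <= hc <= validity.hc_range[1]):
        return None
    if not (validity.oc_range[0] <= oc <= validity.oc_range[1]):
        return None
    counts = {"C": c, "H": h, "N": n, "O": o, "S": s}
    f = MolecularFormula({k: v for k, v in counts.items() if v})
    ion_mz = IonSpecies(f - MolecularFormula({"H": 1}), -1).mz
    if not (cfg.mass_range[0] <= ion_mz <= cfg.mass_range[1]):
        return None
    return f


def gen_fticr_peaklist(
    cfg: FticrSimConfig,
) -> Tuple[PeakList, pd.DataFrame]:
    """Synthetic negative-mode spectrum of deprotonated CHNOS molecules.

    Returns the observed peak list and a truth table with one row per peak:
    observed m/z, exact theoretical [M-H]- m/z, neutral formula and
    heteroatom class.  Observed m/z = theory * (1 + eps),
    eps ~ Normal(0, ppm_sigma * 1e-6).
    """
    rng = np.random.default_rng(cfg.seed)
    validity = AssignmentConfig()  # shared chemical-validity windows
    classes = ("CHO", "CHNO", "CHOS")
    n_per = rng.multinomial(cfg.n_peaks, cfg.class_mix)
    chosen: Dict[MolecularFormula, str] = {}
    for cls, n_target in zip(classes, n_per):
        if n_target == 0:
            continue
        got = 0
        attempts = 0
        while got < n_target:
            attempts += 1
            if attempts > 200 * n_target + 1000:
                raise RuntimeError(
                    f"formula pool for class {cls} infeasible under the "
                    "configured mass range and validity windows"
                )
            f = _sample_formula(rng, cls, cfg, validity)
            if f is None or f in chosen:
                continue
            chosen[f] = cls
            got += 1
    rows = []
    for f, cls in chosen.items():
        ion = IonSpecies(f - MolecularFormula({"H": 1}), -1)
        eps = rng.normal(0.0, cfg.ppm_sigma * 1e-6)
        mz_obs = ion.mz * (1.0 + eps)
        intensity = cfg.intensity_scale * rng.lognormal(0.0, cfg.intensity_sigma)
        rows.append((mz_obs, ion.mz, str(ion.formula), str(f), cls, intensity))
    truth = pd.DataFrame(
        rows,
        columns=["mz_obs", "mz_theory", "ion_formula", "neutral_formula",
                 "class", "intensity"],
    ).sort_values("mz_obs", ignore_index=True)
    peaks = PeakList(
        truth["mz_obs"].to_numpy(), truth["intensity"].to_numpy(), "negative",
        {"simulator": "fticr", "seed": cfg.seed},
    )
    return peaks, truth


# ---------------------------------------------------------------------------
# SIMS-like spectra
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimsSimConfig:
    #: relative abundance of each marker entry of the requested group
    marker_level: float = 100.0
    #: relative abundance of every matrix-tagged entry (always present)
    matrix_level: float = 20.0
    #: gaussian mass jitter sigma in Da (0 -> exact theoretical masses)
    mass_jitter_da: float = 0.002
    #: log-normal intensity scatter (sigma of log; 0 -> exact recipe levels)
    intensity_sigma: float = 0.3
    #: uniform-random low-level chemical noise peaks
    n_noise_peaks: int = 50
    noise_level: float = 2.0
    noise_mass_range: Tuple[float, float] = (20.0, 700.0)
    seed: int = 0

    def __post_init__(self):
        if self.marker_level < 0 or self.matrix_level < 0 or self.noise_level < 0:
            raise ValueError("abundances must be nonnegative")


def _recipe(
    library: Sequence[FragmentLibraryEntry], group: str, polarity: str,
    cfg: SimsSimConfig,
) -> List[Tuple[FragmentLibraryEntry, float]]:
    out = []
    for e in library:
        if e.ion.polarity != polarity:
            continue
        level = 0.0
        if group in e.group_tags:
            level = cfg.marker_level
        elif "matrix" in e.group_tags:
            level = cfg.matrix_level
        if level > 0:
            out.append((e, level))
    return out


def gen_sims_spectrum(
    cfg: SimsSimConfig,
    group: str,
    polarity: str = "positive",
    library: Optional[Sequence[FragmentLibraryEntry]] = None,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[PeakList, pd.DataFrame]:
    """Synthetic fragment spectrum dominated by one marker group.

    Peaks sit at the library's theoretical masses plus gaussian jitter;
    intensities are recipe level x log-normal multiplier.  Matrix ions are
    always present at ``matrix_level``.  Returns (peaks, truth table).
    """
    if library is None:
        library = load_library()
    groups = set().union(*(e.group_tags for e in library))
    if group not in groups:
        raise ValueError(f"unknown group {group!r}; library has {sorted(groups)}")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    recipe = _recipe(library, group, polarity, cfg)
    rows = []
    for entry, level in recipe:
        mz = entry.ion.mz + (
            rng.normal(0.0, cfg.mass_jitter_da) if cfg.mass_jitter_da else 0.0
        )
        inten = level * (
            rng.lognormal(0.0, cfg.intensity_sigma) if cfg.intensity_sigma else 1.0
        )
        rows.append((mz, inten, str(entry.ion), level, "marker" if group in entry.group_tags else "matrix"))
    for _ in range(cfg.n_noise_peaks):
        mz = rng.uniform(*cfg.noise_mass_range)
        inten = cfg.noise_level * rng.lognormal(0.0, cfg.intensity_sigma or 1.0)
        rows.append((mz, inten, "", 0.0, "noise"))
    truth = pd.DataFrame(
        rows, columns=["mz", "intensity", "ion", "level", "role"]
    ).sort_values("mz", ignore_index=True)
    peaks = PeakList(
        truth["mz"].to_numpy(), truth["intensity"].to_numpy(), polarity,
        {"simulator": "sims", "group": group, "seed": cfg.seed},
    )
    return peaks, truth


# ---------------------------------------------------------------------------
# image cubes
# ---------------------------------------------------------------------------

def half_field_masks(width: int, height: int) -> Tuple[np.ndarray, np.ndarray]:
    """Left/right half-field masks with a sharp vertical boundary."""
    left = np.zeros((height, width), dtype=bool)
    left[:, : width // 2] = True
    return left, ~left


def filament_mask(
    width: int, height: int, rng: np.random.Generator,
    n_strokes: int = 3, thickness: int = 2,
) -> np.ndarray:
    """Random-walk filament strokes, thickened; emulates hypha-like curves."""
    mask = np.zeros((height, width), dtype=bool)
    for _ in range(n_strokes):
        y = float(rng.uniform(0, height))
        for x in range(width):
            y += rng.normal(0, 1.0)
            y = min(max(y, 0), height - 1)
            y0, y1 = int(max(y - thickness, 0)), int(min(y + thickness + 1, height))
            mask[y0:y1, x] = True
    return mask


def ovoid_mask(
    width: int, height: int, center: Tuple[float, float],
    radii: Tuple[float, float],
) -> np.ndarray:
    """A filled ellipse (ovoid microstructure analogue)."""
    yy, xx = np.mgrid[0:height, 0:width]
    cx, cy = center
    rx, ry = radii
    return ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0


@dataclass(frozen=True)
class CubeSimConfig:
    width: int = 64
    height: int = 64
    polarity: str = "positive"
    pixel_size_um: float = 8.0
    spectrum: SimsSimConfig = field(
        default_factory=lambda: SimsSimConfig(n_noise_peaks=0)
    )
    #: allow two group layouts to overlap spatially
    allow_overlap: bool = False
    seed: int = 0


def gen_image_cube(
    cfg: CubeSimConfig,
    layouts: Dict[str, np.ndarray],
    library: Optional[Sequence[FragmentLibraryEntry]] = None,
) -> Tuple[IonImageCube, Dict[str, np.ndarray]]:
    """Paint group recipes into spatial layouts over a matrix background.

    ``layouts`` maps group tags to boolean masks of the cube's shape.  Every
    pixel carries the matrix-ion background; pixels inside a group's mask
    additionally carry that group's marker peaks.  Unless overlap is
    enabled, masks must be pairwise disjoint.  Returns the cube and a copy
    of the masks as ground truth.
    """
    if library is None:
        library = load_library()
    shape = (cfg.height, cfg.width)
    for g, m in layouts.items():
        if m.shape != shape:
            raise ValueError(f"layout {g!r} has shape {m.shape}, expected {shape}")
    if not cfg.allow_overlap:
        total = np.zeros(shape, dtype=int)
        for m in layouts.values():
            total += m.astype(int)
        if (total > 1).any():
            raise ValueError(
                "group layouts overlap; pass allow_overlap=True to permit"
            )
    rng = np.random.default_rng(cfg.seed)
    scfg = cfg.spectrum
    noise_free = (
        scfg.mass_jitter_da == 0
        and scfg.intensity_sigma == 0
        and scfg.n_noise_peaks == 0
    )
    groups_sorted = sorted(layouts)
    cache: Dict[Tuple[str, ...], PeakList] = {}

    def pixel_spectrum(members: Tuple[str, ...]) -> PeakList:
        if noise_free and members in cache:
            return cache[members]
        # recipe: matrix background everywhere; marker levels override for
        # entries belonging to any group painted at this pixel
        levels: Dict[int, Tuple[FragmentLibraryEntry, float]] = {}
        for idx, e in enumerate(library):
            if e.ion.polarity != cfg.polarity:
                continue
            if "matrix" in e.group_tags:
                levels[idx] = (e, scfg.matrix_level)
            for g in members:
                if g in e.group_tags:
                    levels[idx] = (e, scfg.marker_level)
                    break
        pairs = []
        for entry, level in levels.values():
            if level <= 0:
                continue
            mz = entry.ion.mz + (
                rng.normal(0.0, scfg.mass_jitter_da) if scfg.mass_jitter_da else 0.0
            )
            inten = level * (
                rng.lognormal(0.0, scfg.intensity_sigma)
                if scfg.intensity_sigma
                else 1.0
            )
            pairs.append((mz, inten))
        for _ in range(scfg.n_noise_peaks):
            pairs.append(
                (
                    rng.uniform(*scfg.noise_mass_range),
                    scfg.noise_level * rng.lognormal(0.0, scfg.intensity_sigma or 1.0),
                )
            )
        out = PeakList.from_pairs(pairs, cfg.polarity)
        if noise_free:
            cache[members] = out
        return out

    grid: List[List[PeakList]] = []
    for y in range(cfg.height):
        row = []
        for x in range(cfg.width):
            members = tuple(g for g in groups_sorted if layouts[g][y, x])
            row.append(pixel_spectrum(members))
        grid.append(row)
    cube = IonImageCube(
        cfg.width, cfg.height, grid, cfg.polarity, cfg.pixel_size_um,
        {"simulator": "cube", "seed": cfg.seed},
    )
    return cube, {g: m.copy() for g, m in layouts.items()}


# ---------------------------------------------------------------------------
# fatty-acid profiles
# ---------------------------------------------------------------------------

def _fa_grid(include_pufa: bool) -> List[Tuple[int, int, int]]:
    grid = []
    for c in range(11, 31):
        grid.append((c, 0, 0))
        grid.append((c, 1, 0))
    if include_pufa:
        grid += [(20, 5, 0), (20, 4, 0)]
    grid += [(c, 0, 1) for c in (24, 25, 26)]  # long-chain hydroxylated
    return grid


def gen_fa_profile(
    even_odd_ratio: float = 3.0,
    n_series_peaks: int = 200,
    seed: int = 0,
    include_pufa: bool = True,
    intensity_sigma: float = 0.25,
    cutoff: int = 20,
) -> Tuple[List[FattyAcidIon], pd.DataFrame]:
    """Fungal-like fatty-acid profile with a programmed short-chain
    even:odd intensity ratio.

    Peaks are allocated round-robin over a fixed (carbon, unsaturation,
    hydroxylation) grid; base weights follow a smooth short-chain-dominant
    profile, even-carbon short-chain weights are rescaled so the expected
    <=C20 even:odd intensity ratio equals the target exactly, and each
    peak's intensity is its weight times a mean-one log-normal multiplier.
    """
    if even_odd_ratio <= 0:
        raise ValueError("even:odd ratio must be positive")
    rng = np.random.default_rng(seed)
    grid = _fa_grid(include_pufa)
    # deterministic round-robin peak allocation over the grid
    alloc = [(grid[i % len(grid)]) for i in range(n_series_peaks)]

    def base_weight(c: int, u: int, oh: int) -> float:
        w = np.exp(-((c - 16.0) ** 2) / (2 * 4.0**2))  # short-chain dominance
        if u == 1:
            w *= 0.5
        elif u > 1:
            w *= 0.15
        if oh:
            w *= 0.2
        return float(w)

    w_even = sum(
        base_weight(*a) for a in alloc if a[0] % 2 == 0 and a[0] <= cutoff
    )
    w_odd = sum(
        base_weight(*a) for a in alloc if a[0] % 2 == 1 and a[0] <= cutoff
    )
    scale_even = even_odd_ratio * w_odd / w_even if w_even else 1.0
    mean_ln = float(np.exp(0.5 * intensity_sigma**2))
    fas = []
    rows = []
    for c, u, oh in alloc:
        w = base_weight(c, u, oh)
        if c % 2 == 0 and c <= cutoff:
            w *= scale_even
        mult = rng.lognormal(0.0, intensity_sigma) / mean_ln if intensity_sigma else 1.0
        fa = FattyAcidIon(c, u, oh, w * mult)
        fas.append(fa)
        rows.append((c, u, oh, w, fa.intensity))
    truth = pd.DataFrame(
        rows, columns=["carbons", "unsaturation", "hydroxylation",
                       "expected_intensity", "intensity"],
    )
    truth.attrs["target_even_odd_ratio"] = even_odd_ratio
    truth.attrs["cutoff"] = cutoff
    return fas, truth
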