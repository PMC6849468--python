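"""Synthetic inputs for the screening pipeline.

Three generators produce everything the downstream stages consume, each with
exact, known ground truth:

* :func:`render_scene` — an RGB view of a potted wheat plant (green foliage,
  optionally occluded by a blue support cage, on a white background) together
  with a per-pixel label raster, so segmentation can be scored exactly.
* :func:`generate_growth_series` — a piecewise-linear biomass trajectory
  (lag -> linear -> optional plateau) sampled at imaging days, emulating the
  sigmoidal accumulation of shoot biomass, with known breakpoints.
* :func:`generate_trait_table` — a balanced variety x N-level pot table with
  a controlled correlation structure among the digital and destructive traits.

All randomness flows from the single ``seed`` carried by each spec, so every
generator is bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.color import hsv2rgb

__all__ = [
    "LABEL_BACKGROUND",
    "LABEL_PLANT",
    "LABEL_CAGE",
    "LABEL_SPECKLE",
    "SceneSpec",
    "GrowthSpec",
    "TraitTableSpec",
    "render_scene",
    "generate_growth_series",
    "generate_trait_table",
]

# Class codes of the ground-truth label raster.
LABEL_BACKGROUND = 0
LABEL_PLANT = 1
LABEL_CAGE = 2
LABEL_SPECKLE = 3

VIEWS = ("side_0", "side_120", "side_240", "top")

# Hue bands (degrees) used when painting scene classes.  They sit well inside
# the default segmentation windows so that 8-bit quantisation cannot move a
# pixel across a class boundary.
_PLANT_HUE = (95.0, 140.0)
_CAGE_HUE = (215.0, 250.0)


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one rendered plant view.

    ``plant_pixel_count`` is the ground-truth number of plant pixels drawn
    before occlusion; ``cage_fraction`` of them are then re-labelled as cage
    (the blue support structure placed in each pot to keep plants upright).
    ``noise_speckle_count`` small green speckles (1-4 px) are scattered on the
    background to exercise the small-object filter.
    """

    view: str = "side_0"
    image_height: int = 256
    image_width: int = 256
    plant_pixel_count: int = 2000
    cage_fraction: float = 0.0
    noise_speckle_count: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.view not in VIEWS:
            raise ValueError(f"view must be one of {VIEWS}, got {self.view!r}")
        if self.image_height < 64 or self.image_width < 64:
            raise ValueError("image dimensions must be at least 64x64")
        if self.plant_pixel_count < 0:
            raise ValueError("plant_pixel_count must be >= 0")
        area = self.image_height * self.image_width
        if self.plant_pixel_count > 0.5 * area:
            raise ValueError(
                f"plant_pixel_count {self.plant_pixel_count} exceeds the drawable "
                f"limit of 0.5 x image area = {0.5 * area:.0f} pixels"
            )
        if not 0.0 <= self.cage_fraction < 1.0:
            raise ValueError("cage_fraction must lie in [0, 1)")
        if self.noise_speckle_count < 0:
            raise ValueError("noise_speckle_count must be >= 0")


def _grow_blob(rng: np.random.Generator, height: int, width: int, count: int) -> np.ndarray:
    """Grow a connected, vertically elongated pixel region of exactly ``count``
    pixels, returned as an (n, 2) array of (row, col) coordinates in growth
    order.

    Growth starts from a contiguous crown of pixels at the pot rim and every
    added pixel touches an earlier one, so *every prefix* of the returned
    order is a single 8-connected component.  Occlusion bookkeeping relies on
    this: re-labelling a suffix of the growth order as cage can never shatter
    the remaining plant into small fragments.  Upward moves are favoured so
    the blob reads as stems and leaves rather than a disc.
    """
    occupied = np.zeros((height, width), dtype=bool)
    base_row = int(height * 0.85)
    centre = width // 2
    frontier: list[tuple[int, int]] = []
    coords: list[tuple[int, int]] = []

    crown = int(min(count, rng.integers(3, 9)))
    start = int(np.clip(centre - crown // 2 + rng.integers(-width // 8, width // 8 + 1), 0, width - crown))
    for col in range(start, start + crown):
        occupied[base_row, col] = True
        coords.append((base_row, col))
        frontier.append((base_row, col))
    # Vertical moves are pushed twice so growth elongates upward/downward.
    moves = ((-1, 0), (-1, 0), (1, 0), (-1, -1), (-1, 1), (0, -1), (0, 1))
    while len(coords) < count:
        if not frontier:  # isolated pocket exhausted; restart near an existing pixel
            r, c = coords[rng.integers(len(coords))]
            frontier.append((r, c))
        idx = int(rng.integers(len(frontier)))
        r, c = frontier[idx]
        dr, dc = moves[int(rng.integers(len(moves)))]
        nr, nc = r + dr, c + dc
        if 0 <= nr < height and 0 <= nc < width and not occupied[nr, nc]:
            occupied[nr, nc] = True
            coords.append((nr, nc))
            frontier.append((nr, nc))
        else:
            # Retire frontier pixels with no free 8-neighbourhood.
            r0, r1 = max(r - 1, 0), min(r + 2, height)
            c0, c1 = max(c - 1, 0), min(c + 2, width)
            if occupied[r0:r1, c0:c1].all():
                frontier.pop(idx)
    return np.array(coords[:count], dtype=np.intp)


def render_scene(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render one plant view.

    Returns ``(image, labels)`` where ``image`` is an (H, W, 3) uint8 RGB
    raster and ``labels`` an (H, W) uint8 raster of ground-truth class codes
    (``LABEL_BACKGROUND``/``LABEL_PLANT``/``LABEL_CAGE``/``LABEL_SPECKLE``).

    Exactly ``spec.plant_pixel_count`` pixels are drawn as plant before
    occlusion; ``round(cage_fraction * plant_pixel_count)`` of them are then
    re-labelled (and re-painted) as cage, so the visible plant count is known
    exactly.  Deterministic for a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_height, spec.image_width
    labels = np.full((h, w), LABEL_BACKGROUND, dtype=np.uint8)

    hsv = np.zeros((h, w, 3), dtype=float)
    # White pot/backdrop with faint grey texture: hue irrelevant, S ~ 0, V high.
    hsv[..., 2] = rng.uniform(0.93, 1.0, size=(h, w))
    hsv[..., 1] = rng.uniform(0.0, 0.02, size=(h, w))

    if spec.plant_pixel_count > 0:
        coords = _grow_blob(rng, h, w, spec.plant_pixel_count)
        rows, cols = coords[:, 0], coords[:, 1]
        labels[rows, cols] = LABEL_PLANT
        n = len(rows)
        hsv[rows, cols, 0] = rng.uniform(*_PLANT_HUE, size=n) / 360.0
        hsv[rows, cols, 1] = rng.uniform(0.55, 0.9, size=n)
        hsv[rows, cols, 2] = rng.uniform(0.45, 0.8, size=n)

        n_occluded = int(round(spec.cage_fraction * spec.plant_pixel_count))
        if n_occluded > 0:
            # Occlude the most recently grown pixels (the canopy periphery):
            # the surviving prefix stays one connected component.
            orr, occ = rows[-n_occluded:], cols[-n_occluded:]
            labels[orr, occ] = LABEL_CAGE
            hsv[orr, occ, 0] = rng.uniform(*_CAGE_HUE, size=n_occluded) / 360.0
            hsv[orr, occ, 1] = rng.uniform(0.6, 0.9, size=n_occluded)
            hsv[orr, occ, 2] = rng.uniform(0.45, 0.8, size=n_occluded)

    # Blue cage uprights over the background (never over plant pixels, which
    # keeps the visible-plant bookkeeping exact).
    n_bars = int(rng.integers(2, 5))
    for col in rng.choice(np.arange(4, w - 4), size=n_bars, replace=False):
        bar = labels[:, col : col + 2]
        bg = bar == LABEL_BACKGROUND
        bar[bg] = LABEL_CAGE
        sub = hsv[:, col : col + 2]
        sub[bg, 0] = rng.uniform(*_CAGE_HUE, size=int(bg.sum())) / 360.0
        sub[bg, 1] = rng.uniform(0.6, 0.9, size=int(bg.sum()))
        sub[bg, 2] = rng.uniform(0.45, 0.8, size=int(bg.sum()))

    placed = 0
    attempts = 0
    while placed < spec.noise_speckle_count and attempts < 50 * (spec.noise_speckle_count + 1):
        attempts += 1
        r = int(rng.integers(1, h - 3))
        c = int(rng.integers(1, w - 3))
        # Speckles must not touch plant/cage pixels, otherwise they would merge
        # into a large connected component and stop being removable noise.
        if (labels[r - 1 : r + 4, c - 1 : c + 4] != LABEL_BACKGROUND).any():
            continue
        size = int(rng.integers(1, 5))  # 1-4 px, below any sensible area filter
        for dr, dc in ((0, 0), (0, 1), (1, 0), (1, 1))[:size]:
            labels[r + dr, c + dc] = LABEL_SPECKLE
            hsv[r + dr, c + dc, 0] = rng.uniform(*_PLANT_HUE) / 360.0
            hsv[r + dr, c + dc, 1] = rng.uniform(0.55, 0.9)
            hsv[r + dr, c + dc, 2] = rng.uniform(0.45, 0.8)
        placed += 1

    image = (hsv2rgb(hsv) * 255.0).round().astype(np.uint8)
    return image, labels


@dataclass(frozen=True)
class GrowthSpec:
    """Piecewise-linear growth trajectory of estimated biomass (kPix) vs DAS.

    One breakpoint gives lag -> linear; a second adds the plateau bend of the
    full sigmoid.  ``baseline_kpix`` is the mean biomass at the first
    observation day.
    """

    lag_slope: float = 2.0
    linear_slope: float = 12.0
    plateau_slope: float = 1.0
    breakpoints: tuple[float, ...] = (45.0,)
    observation_days: tuple[float, ...] = tuple(float(d) for d in range(26, 82, 5))
    baseline_kpix: float = 10.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        days = np.asarray(self.observation_days, dtype=float)
        if len(days) < 5:
            raise ValueError("at least 5 observation days are required")
        if not np.all(np.diff(days) > 0):
            raise ValueError("observation_days must be strictly increasing")
        if len(self.breakpoints) not in (1, 2):
            raise ValueError("one or two breakpoints are supported")
        for bp in self.breakpoints:
            if not days[0] < bp < days[-1]:
                raise ValueError(
                    f"breakpoint {bp} lies outside the observation range "
                    f"[{days[0]}, {days[-1]}]"
                )
        if len(self.breakpoints) == 2 and self.breakpoints[0] >= self.breakpoints[1]:
            raise ValueError("breakpoints must be increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def growth_mean(spec: GrowthSpec, das: np.ndarray) -> np.ndarray:
    """Noise-free piecewise-linear mean trajectory at the given days."""
    das = np.asarray(das, dtype=float)
    slopes = (spec.lag_slope, spec.linear_slope, spec.plateau_slope)
    x0 = spec.observation_days[0]
    y = np.empty_like(das)
    for j, x in enumerate(das):
        val = spec.baseline_kpix
        prev = x0
        for i, bp in enumerate((*spec.breakpoints, np.inf)):
            hi = min(x, bp)
            if hi > prev:
                val += slopes[i] * (hi - prev)
                prev = hi
            if x <= bp:
                break
        y[j] = val
    return y


def generate_growth_series(spec: GrowthSpec) -> pd.DataFrame:
    """Sample one growth series: columns ``das`` and ``eb_kpix``.

    Gaussian noise of SD ``noise_sd`` is added to the piecewise-linear mean;
    values are truncated at zero (biomass cannot be negative).  With
    ``noise_sd = 0`` the series lies exactly on the piecewise line.
    """
    rng = np.random.default_rng(spec.seed)
    das = np.asarray(spec.observation_days, dtype=float)
    eb = growth_mean(spec, das)
    if spec.noise_sd > 0:
        eb = eb + rng.normal(0.0, spec.noise_sd, size=len(das))
    return pd.DataFrame({"das": das, "eb_kpix": np.maximum(eb, 0.0)})


# Default per-trait means at (low, optimum) N, on the scale of a 15-variety
# pot screen: EB/TVA in kilopixels at mid linear phase, biomass/yield in grams
# per pot at harvest.
_TRAIT_BASE: dict[str, tuple[float, float]] = {
    "eb_kpix": (230.0, 760.0),
    "tva_kpix": (47.0, 195.0),
    "mb_g": (6.8, 26.8),
    "la_cm2": (170.0, 720.0),
    "dw_g": (12.3, 53.5),
    "gy_g": (6.0, 24.7),
}

CORRELATED_TRAITS = tuple(_TRAIT_BASE)

# Default target correlation among (EB, TVA, MB, LA, DW, GY): digital and
# destructive vegetative traits strongly positively coupled, harvest biomass
# and yield moderately coupled to vegetative size and strongly to each other.
_DEFAULT_CORR = np.array(
    [
        [1.00, 0.89, 0.94, 0.84, 0.60, 0.62],
        [0.89, 1.00, 0.82, 0.90, 0.55, 0.57],
        [0.94, 0.82, 1.00, 0.89, 0.65, 0.66],
        [0.84, 0.90, 0.89, 1.00, 0.60, 0.61],
        [0.60, 0.55, 0.65, 0.60, 1.00, 0.92],
        [0.62, 0.57, 0.66, 0.61, 0.92, 1.00],
    ]
)

# Residual SD per trait (pot-to-pot within variety x N).
_DEFAULT_RESID_SD: dict[str, float] = {
    "eb_kpix": 35.0,
    "tva_kpix": 9.0,
    "mb_g": 1.0,
    "la_cm2": 40.0,
    "dw_g": 1.8,
    "gy_g": 0.9,
}

# Ancillary harvest traits: (low-N mean, optimum-N mean, SD).
_ANCILLARY: dict[str, tuple[float, float, float]] = {
    "sn": (4.2, 15.4, 1.2),
    "gn": (34.8, 37.9, 3.5),
    "gw1000_g": (41.4, 44.3, 2.8),
    "shoot_n_pct": (0.35, 0.63, 0.05),
    "grain_n_pct": (2.1, 2.7, 0.15),
    "wsc_pct": (5.0, 8.8, 1.0),
}

N_LEVELS = ("low", "optimum")


@dataclass(frozen=True)
class TraitTableSpec:
    """Design of a balanced variety x N pot experiment.

    ``variety_effects``/``n_level_effects``/``interaction_effects`` are
    additive shifts per trait: a mapping trait -> length-``n_varieties``
    sequence, trait -> length-2 sequence (low, optimum), and trait ->
    (``n_varieties`` x 2) array respectively.  Unspecified traits default to a
    deterministic variety spread of ``variety_spread`` x residual SD, so the
    default table contains genuine varietal signal.
    """

    n_varieties: int = 15
    n_replicates: int = 15
    variety_effects: Mapping[str, Sequence[float]] | None = None
    n_level_effects: Mapping[str, Sequence[float]] | None = None
    interaction_effects: Mapping[str, np.ndarray] | None = None
    trait_correlation: np.ndarray | None = None
    residual_sd: Mapping[str, float] | None = None
    variety_spread: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_varieties < 1 or self.n_replicates < 1:
            raise ValueError("n_varieties and n_replicates must be >= 1")

    def correlation(self) -> np.ndarray:
        corr = self._corr_array()
        eigvals = np.linalg.eigvalsh(corr)
        if eigvals.min() < -1e-10:
            raise ValueError(
                f"trait_correlation is not positive semi-definite "
                f"(min eigenvalue {eigvals.min():.3g})"
            )
        return corr

    def _corr_array(self) -> np.ndarray:
        corr = _DEFAULT_CORR if self.trait_correlation is None else np.asarray(
            self.trait_correlation, dtype=float
        )
        k = len(CORRELATED_TRAITS)
        if corr.shape != (k, k):
            raise ValueError(f"trait_correlation must be {k}x{k}")
        if not np.allclose(corr, corr.T):
            raise ValueError("trait_correlation must be symmetric")
        return corr


def _effect_lookup(mapping, trait, default):
    if mapping is None or trait not in mapping:
        return default
    return np.asarray(mapping[trait], dtype=float)


def generate_trait_table(spec: TraitTableSpec) -> pd.DataFrame:
    """Generate the balanced pot table.

    One row per pot: identifiers (``pot_id``, ``variety``, ``n_level``), the
    six correlated traits (EB, TVA, MB, LA, DW, GY) drawn from a multivariate
    normal with the target correlation, and ancillary harvest traits (spike
    and grain counts, 1000-grain weight, N concentrations, WSC).  Grain N is
    negatively coupled to grain yield, as in real N screens where low-yielding
    pots concentrate N.  All values are truncated to stay positive and grain
    yield is capped below total dry biomass.
    """
    corr = spec.correlation()
    rng = np.random.default_rng(spec.seed)
    varieties = [f"V{i + 1:02d}" for i in range(spec.n_varieties)]
    resid = dict(_DEFAULT_RESID_SD)
    if spec.residual_sd is not None:
        resid.update(spec.residual_sd)

    sds = np.array([resid[t] for t in CORRELATED_TRAITS])
    cov = corr * np.outer(sds, sds)
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(len(sds)))

    # Deterministic default variety effects: one shared vigour gradient
    # (large varieties are large in every trait), scaled per trait by
    # variety_spread x residual SD.  Sharing the gradient preserves the
    # positive inter-trait correlation structure when varieties are pooled.
    eff_rng = np.random.default_rng(spec.seed + 1)
    grad = np.linspace(-1.0, 1.0, spec.n_varieties)[eff_rng.permutation(spec.n_varieties)]
    default_var_eff = {
        t: spec.variety_spread * resid[t] * grad for t in CORRELATED_TRAITS
    }

    rows = []
    pot = 0
    for vi, variety in enumerate(varieties):
        for ni, n_level in enumerate(N_LEVELS):
            n_shift = {}
            for t in CORRELATED_TRAITS:
                base = _TRAIT_BASE[t][ni]
                var_eff = _effect_lookup(spec.variety_effects, t, default_var_eff[t])[vi]
                nl_eff = _effect_lookup(spec.n_level_effects, t, np.zeros(2))[ni]
                inter = 0.0
                if spec.interaction_effects is not None and t in spec.interaction_effects:
                    inter = float(np.asarray(spec.interaction_effects[t])[vi, ni])
                # optimum-N varietal spread scales with the mean ratio
                scale = 1.0 if ni == 0 else _TRAIT_BASE[t][1] / _TRAIT_BASE[t][0]
                n_shift[t] = base + var_eff * scale + nl_eff + inter
            noise = rng.standard_normal((spec.n_replicates, len(sds))) @ chol.T
            if all(s == 0 for s in sds):
                noise = np.zeros((spec.n_replicates, len(sds)))
            for r in range(spec.n_replicates):
                pot += 1
                row = {"pot_id": f"P{pot:04d}", "variety": variety, "n_level": n_level}
                for j, t in enumerate(CORRELATED_TRAITS):
                    row[t] = max(n_shift[t] + noise[r, j], 0.01)
                for t, (mlow, mopt, sd) in _ANCILLARY.items():
                    mean = (mlow, mopt)[ni]
                    val = mean + (rng.normal(0.0, sd) if sd > 0 else 0.0)
                    row[t] = max(val, 0.01)
                # grain N tracks yield negatively
                gy_mean = n_shift["gy_g"]
                gy_sd = max(resid["gy_g"], 1e-9)
                z = (row["gy_g"] - gy_mean) / gy_sd
                row["grain_n_pct"] = max(row["grain_n_pct"] - 0.6 * _ANCILLARY["grain_n_pct"][2] * z, 0.01)
                row["gy_g"] = min(row["gy_g"], 0.95 * row["dw_g"])
                rows.append(row)
    return pd.DataFrame(rows)
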