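"""Synthetic fixtures with the statistical structure the pipeline assumes.

Three generators, all seeded through named substreams of one root seed:

* textured nuclear images whose binarized-texture statistics drift
  monotonically with a latent age parameter (Gaussian-smoothed white noise,
  kernel width increasing with age, mimicking coarsening chromatin puncta);
* per-cell feature tables where aging acts through a mean shift along a
  known drift direction and/or a cell-type composition shift — the latter is
  the reason the pipeline aggregates bootstrap means rather than single
  cells;
* behavior matrices of clustered readouts linearly coupled to a latent
  per-animal age score, with replicate (trial) noise.

These emulate the covariance structure of real data, not its physics: no
optics, no point-spread function, no real behavioral instruments.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

META_COLUMNS = ("animal", "age", "group", "celltype", "label", "organ", "channel")


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent generator derived from a root seed and a stream name."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(name.encode())]))


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Columns of a feature table that hold features (not metadata)."""
    return [c for c in table.columns if c not in META_COLUMNS]


def feature_matrix(table: pd.DataFrame) -> np.ndarray:
    return table[feature_columns(table)].to_numpy(dtype=float)


# --------------------------------------------------------------------------
# image fixture
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ImageFixtureSpec:
    n_nuclei: int = 12
    nucleus_radius_px: int = 12
    field_shape: tuple[int, ...] = (256, 256)
    channels: tuple[str, ...] = ("DAPI", "H3K4me1")
    age_latent: float = 0.5
    intensity_noise_sd: float = 5.0
    base_intensity: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if self.n_nuclei < 1:
            raise ValueError("n_nuclei must be >= 1")
        if self.nucleus_radius_px <= 0:
            raise ValueError("radius must be positive")
        if not 0.0 <= self.age_latent <= 1.0:
            raise ValueError("age_latent must lie in [0, 1]")

    def granularity(self, age: float) -> float:
        """Spatial autocorrelation length (px), strictly monotone in age."""
        return 1.0 + 3.0 * age


def _place_centers(rng, n, radius, shape, max_tries=10_000):
    lo = radius + 1
    centers: list[np.ndarray] = []
    for _ in range(max_tries):
        c = np.array([rng.uniform(lo, s - lo) for s in shape])
        if all(np.linalg.norm(c - o) >= 2 * radius + 2 for o in centers):
            centers.append(c)
            if len(centers) == n:
                return centers
    raise RuntimeError(f"could not place {n} non-overlapping nuclei in {shape}")


def make_image_fixture(spec: ImageFixtureSpec):
    """Return ``(image (C, *field), label mask, truth table)``.

    Every nucleus is a disk (or ball) textured with smoothed white noise at
    the age-dependent granularity; the truth table maps each mask label to
    its latent age.
    """
    from scipy import ndimage

    rng = substream(spec.seed, "image")
    ndim = len(spec.field_shape)
    centers = _place_centers(rng, spec.n_nuclei, spec.nucleus_radius_px, spec.field_shape)

    grids = np.meshgrid(*[np.arange(s) for s in spec.field_shape], indexing="ij")
    mask = np.zeros(spec.field_shape, dtype=np.int32)
    for lbl, c in enumerate(centers, start=1):
        dist2 = sum((g - ci) ** 2 for g, ci in zip(grids, c))
        mask[dist2 <= spec.nucleus_radius_px**2] = lbl

    sigma = spec.granularity(spec.age_latent)
    image = np.zeros((len(spec.channels),) + spec.field_shape, dtype=float)
    for ci in range(len(spec.channels)):
        noise = rng.standard_normal(spec.field_shape)
        tex = ndimage.gaussian_filter(noise, sigma)
        tex = tex / tex.std() * 30.0 + spec.base_intensity
        tex += rng.standard_normal(spec.field_shape) * spec.intensity_noise_sd
        image[ci] = np.clip(tex, 0, None) * (mask > 0)

    truth = pd.DataFrame({
        "label": np.arange(1, spec.n_nuclei + 1),
        "age_latent": spec.age_latent,
        **{f"centroid_{i}": [c[i] for c in centers] for i in range(ndim)},
    })
    return image, mask, truth


# --------------------------------------------------------------------------
# feature-table fixture
# --------------------------------------------------------------------------

def _linear_drift(age: float, ages: Sequence[float], scale: float) -> float:
    lo, hi = min(ages), max(ages)
    return scale * (age - lo) / (hi - lo) if hi > lo else 0.0


@dataclass(frozen=True)
class TableFixtureSpec:
    """Multi-group feature table with a known aging direction.

    ``drift_mode`` selects how age enters: ``"mean"`` shifts every cell
    type's mean along ``drift_vector``; ``"mixture"`` shifts the cell-type
    composition toward types located further along the drift direction (the
    single-cell clouds themselves do not move); ``"both"`` combines them.
    """

    n_animals_per_group: int = 4
    ages: tuple[float, ...] = (2.0, 15.0, 27.0)
    cells_per_animal: int = 1000
    n_features: int = 50
    drift_vector: np.ndarray | None = None     # default: first coordinate
    drift_scale: float = 3.0                   # magnitude at the oldest age
    drift_mode: str = "mean"
    n_celltypes: int = 2
    celltype_sep: float = 4.0                  # cell-type spacing along drift
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_features < 2:
            raise ValueError("n_features must be >= 2")
        if self.drift_mode not in ("mean", "mixture", "both"):
            raise ValueError("drift_mode must be mean|mixture|both")
        if self.cells_per_animal < 1 or self.n_animals_per_group < 1:
            raise ValueError("counts must be >= 1")

    def unit_drift(self) -> np.ndarray:
        if self.drift_vector is None:
            v = np.zeros(self.n_features)
            v[0] = 1.0
            return v
        v = np.asarray(self.drift_vector, dtype=float)
        n = np.linalg.norm(v)
        if n == 0:
            raise ValueError("drift_vector must be nonzero")
        return v / n

    def drift_magnitude(self, age: float) -> float:
        return _linear_drift(age, self.ages, self.drift_scale)

    def mixture_weights(self, age: float) -> np.ndarray:
        """Composition per age: old animals carry more of the 'late' types."""
        k = self.n_celltypes
        if k == 1:
            return np.ones(1)
        t = _linear_drift(age, self.ages, 1.0)  # 0 at youngest, 1 at oldest
        w = (1 - t) * np.linspace(2, 1, k) + t * np.linspace(1, 2, k)
        return w / w.sum()


def group_label(age: float, ages: Sequence[float]) -> str:
    if age == min(ages):
        return "young"
    if age == max(ages):
        return "old"
    return "middle"


def make_feature_fixture(spec: TableFixtureSpec) -> pd.DataFrame:
    """Per-cell feature table with metadata columns ``animal/age/group/celltype``."""
    rng = substream(spec.seed, "table")
    u = spec.unit_drift()
    d = spec.n_features
    k = spec.n_celltypes

    # cell-type base means spaced along the drift direction
    offsets = (np.arange(k) - (k - 1) / 2) * spec.celltype_sep
    base_means = offsets[:, None] * u[None, :]

    rows = []
    animal_id = 0
    for age in spec.ages:
        grp = group_label(age, spec.ages)
        mean_shift = spec.drift_magnitude(age) if spec.drift_mode in ("mean", "both") else 0.0
        if spec.drift_mode in ("mixture", "both"):
            weights = spec.mixture_weights(age)
        else:
            weights = np.full(k, 1.0 / k)
        for _ in range(spec.n_animals_per_group):
            animal_id += 1
            types = rng.choice(k, size=spec.cells_per_animal, p=weights)
            cells = (base_means[types]
                     + mean_shift * u[None, :]
                     + rng.standard_normal((spec.cells_per_animal, d)) * spec.noise_sd)
            df = pd.DataFrame(cells, columns=[f"f{i:03d}" for i in range(d)])
            df.insert(0, "celltype", [f"type{t}" for t in types])
            df.insert(0, "group", grp)
            df.insert(0, "age", age)
            df.insert(0, "animal", f"m{animal_id:03d}")
            rows.append(df)
    return pd.concat(rows, ignore_index=True)


# --------------------------------------------------------------------------
# behavior fixture
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BehaviorFixtureSpec:
    n_clusters: int = 9
    readouts_per_cluster: int = 3
    within_cluster_corr: float = 0.8
    coupling_to_age: tuple[float, ...] | None = None   # per-cluster signed weights
    # factor noise must dominate enough that distinct clusters stay
    # near-orthogonal despite sharing the age signal (cross-cluster
    # |r| <= w1*w2/sqrt((w1^2+s^2)(w2^2+s^2)) ~ 0.45 at s=1, |w|<=1)
    noise_sd: float = 1.0
    n_trials: int = 4
    trial_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.within_cluster_corr <= 1.0:
            raise ValueError("within_cluster_corr must be in (0, 1]")
        if self.n_trials < 2:
            raise ValueError("need >= 2 trials")

    def couplings(self) -> np.ndarray:
        if self.coupling_to_age is None:
            signs = np.where(np.arange(self.n_clusters) % 2 == 0, 1.0, -1.0)
            return signs
        w = np.asarray(self.coupling_to_age, dtype=float)
        if len(w) != self.n_clusters:
            raise ValueError("coupling_to_age length must equal n_clusters")
        return w


def make_behavior_fixture(spec: BehaviorFixtureSpec, image_values: Sequence[float]):
    """Return ``(long behavior table, truth table)``.

    The table has columns ``animal, readout, trial, value``; each cluster
    shares a latent factor ``coupling * z(image) + noise`` and trials carry
    i.i.d. replicate noise.  The truth table records each readout's cluster
    and coupling sign.
    """
    rng = substream(spec.seed, "behavior")
    t = np.asarray(image_values, dtype=float)
    if t.ndim != 1:
        raise ValueError("image_values must be one value per animal")
    n = len(t)
    z = (t - t.mean()) / (t.std() if t.std() > 0 else 1.0)
    w = spec.couplings()

    rho = spec.within_cluster_corr
    rows, truth = [], []
    for c in range(spec.n_clusters):
        factor = w[c] * z + rng.standard_normal(n) * spec.noise_sd
        for r in range(spec.readouts_per_cluster):
            name = f"b{c}_{r}"
            truth.append({"readout": name, "cluster": c, "coupling": w[c]})
            indiv = rng.standard_normal(n)
            base = np.sqrt(rho) * factor + np.sqrt(1 - rho) * indiv
            for tr in range(spec.n_trials):
                vals = base + rng.standard_normal(n) * spec.trial_noise_sd
                for a in range(n):
                    rows.append((f"a{a:03d}", name, tr, vals[a]))
    table = pd.DataFrame(rows, columns=["animal", "readout", "trial", "value"])
    return table, pd.DataFrame(truth)
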