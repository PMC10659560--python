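"""Bootstrap-mean aggregation, z-scoring and train/test splitting.

Aging shifts cell *composition* more than it moves individual cells, so the
pipeline's unit of analysis is the bootstrap mean: the average feature
vector of ``cells_per_bootstrap`` cells (default 200) drawn with replacement
within one animal, repeated ``n_bootstraps`` times (default 1000) to
equalize the number of data points per animal.  Axis construction is
validated over 100 random 75/25 train/test splits of the young and old
bootstrap rows; intermediate and perturbation groups are never trained on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .fixtures import feature_columns, substream


@dataclass(frozen=True)
class BootstrapConfig:
    cells_per_bootstrap: int = 200
    n_bootstraps_per_sample: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.cells_per_bootstrap < 1 or self.n_bootstraps_per_sample < 1:
            raise ValueError("bootstrap counts must be >= 1")


@dataclass(frozen=True)
class SplitConfig:
    train_fraction: float = 0.75
    n_iterations: int = 100
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


def bootstrap_means(table: pd.DataFrame, config: BootstrapConfig) -> pd.DataFrame:
    """Per-animal bootstrap means; metadata carried over from each animal.

    Sampling strata are always single animals — cells are never pooled
    across animals, because the composition signal lives at the animal level.
    """
    rng = substream(config.seed, "bootstrap")
    feats = feature_columns(table)
    meta = [c for c in table.columns if c not in feats and c != "celltype"]
    out = []
    for animal, sub in table.groupby("animal", sort=True):
        x = sub[feats].to_numpy(dtype=float)
        if len(x) == 0:
            raise ValueError(f"animal {animal!r} has no cells")
        idx = rng.integers(0, len(x), size=(config.n_bootstraps_per_sample,
                                            config.cells_per_bootstrap))
        means = x[idx].mean(axis=1)
        df = pd.DataFrame(means, columns=feats)
        for m in meta:
            df.insert(0, m, sub[m].iloc[0])
        out.append(df)
    return pd.concat(out, ignore_index=True)


class Standardizer:
    """Per-feature z-scoring fitted on a reference set, applied elsewhere.

    Zero-variance features get SD 1 so they transform to constant 0 instead
    of NaN; their names are recorded in ``constant_features``.
    """

    def __init__(self, mean: np.ndarray, sd: np.ndarray, features: Sequence[str]):
        self.mean = np.asarray(mean, dtype=float)
        self.sd = np.asarray(sd, dtype=float)
        self.features = list(features)
        self.constant_features: list[str] = []  # populated by fit

    @classmethod
    def fit(cls, reference: pd.DataFrame) -> "Standardizer":
        feats = feature_columns(reference)
        x = reference[feats].to_numpy(dtype=float)
        if len(x) < 2:
            raise ValueError("need >= 2 reference rows to fit a standardizer")
        mu = x.mean(axis=0)
        sd = x.std(axis=0, ddof=0)
        const = sd == 0
        sd = np.where(const, 1.0, sd)
        obj = cls(mu, sd, feats)
        obj.constant_features = [f for f, c in zip(feats, const) if c]
        return obj

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        x = out[self.features].to_numpy(dtype=float)
        out[self.features] = (x - self.mean) / self.sd
        return out

    def transform_array(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.mean) / self.sd

    def to_json(self) -> str:
        return json.dumps({"features": self.features,
                           "mean": self.mean.tolist(), "sd": self.sd.tolist()})

    @classmethod
    def from_json(cls, s: str) -> "Standardizer":
        d = json.loads(s)
        return cls(np.array(d["mean"]), np.array(d["sd"]), d["features"])


def split_iterations(
    table: pd.DataFrame,
    config: SplitConfig,
    *,
    by_animal: bool = False,
) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """Yield ``(train_idx, test_idx)`` pairs over young/old rows.

    Per iteration, ``train_fraction`` of the young+old rows go to training
    (sampled without replacement, stratified by animal so every animal — and
    hence both groups — contributes to every train set); all other rows
    (middle age, perturbations) are appended to the test side.  With
    ``by_animal=True``, whole animals are assigned to train or test instead.
    """
    rng = substream(config.seed, "splits")
    grp = table["group"].to_numpy()
    ref = np.flatnonzero((grp == "young") | (grp == "old"))
    other = np.flatnonzero((grp != "young") & (grp != "old"))
    if not (grp == "young").any() or not (grp == "old").any():
        raise ValueError("both young and old groups must be present")

    animals = table["animal"].to_numpy()
    for _ in range(config.n_iterations):
        train_parts, test_parts = [], []
        if by_animal:
            for g in ("young", "old"):
                ids = np.unique(animals[grp == g])
                if len(ids) < 2:
                    raise ValueError(f"group {g!r} has too few animals to split")
                n_tr = max(1, int(round(config.train_fraction * len(ids))))
                n_tr = min(n_tr, len(ids) - 1)
                perm = rng.permutation(ids)
                tr_ids = set(perm[:n_tr])
                sel = np.isin(table["animal"], list(tr_ids)) & np.isin(np.arange(len(table)), ref)
                train_parts.append(np.flatnonzero(sel))
                sel_te = np.isin(table["animal"], perm[n_tr:]) & np.isin(np.arange(len(table)), ref)
                test_parts.append(np.flatnonzero(sel_te))
        else:
            for a in np.unique(animals[ref]):
                rows = ref[animals[ref] == a]
                n_tr = int(round(config.train_fraction * len(rows)))
                n_tr = min(max(n_tr, 1), len(rows) - 1)
                perm = rng.permutation(rows)
                train_parts.append(perm[:n_tr])
                test_parts.append(perm[n_tr:])
        train = np.sort(np.concatenate(train_parts))
        test = np.sort(np.concatenate(test_parts + [other]))
        yield train, test
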