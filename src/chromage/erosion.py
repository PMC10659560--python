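"""Identity erosion: age-related loss of cell-type separation.

Two complementary readouts of how distinguishable cell (or organ) types
remain as animals age: silhouette scores of the type labels computed
directly on raw feature rows (information or Euclidean distance, 100
bootstraps for a CI), and per-feature two-sample Kolmogorov-Smirnov
distances between types, averaged over all type pairs.  Features whose
type separation is significant and whose KS distance correlates strongly
with age are the erosion signature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fixtures import feature_columns, feature_matrix, substream
from .hyperbolic import InfoDistanceConfig, distance_matrix


def silhouette_by_age(table: pd.DataFrame, *, metric: str = "euclidean",
                      n_boot: int = 100, max_cells: int = 300,
                      seed: int = 0,
                      info_config: InfoDistanceConfig = InfoDistanceConfig()) -> pd.DataFrame:
    """Silhouette of cell-type labels within each age group, with bootstrap CI.

    Rows are subsampled to ``max_cells`` per age before building the pairwise
    distance matrix (information distance is quadratic in cells); the
    bootstrap resamples cells with replacement within the age group.
    """
    from sklearn.metrics import silhouette_score

    rng = substream(seed, "silhouette")
    out = []
    for age, sub in table.groupby("age", sort=True):
        if sub["celltype"].nunique() < 2:
            raise ValueError(f"age {age}: need >= 2 cell types")
        if len(sub) > max_cells:
            sub = sub.iloc[rng.choice(len(sub), size=max_cells, replace=False)]
        x = feature_matrix(sub)
        labels = sub["celltype"].to_numpy()
        d = distance_matrix(x, metric, info_config)
        score = float(silhouette_score(d, labels, metric="precomputed"))
        boots = []
        for _ in range(n_boot):
            idx = rng.integers(0, len(x), size=len(x))
            if len(np.unique(labels[idx])) < 2:
                continue
            boots.append(silhouette_score(d[np.ix_(idx, idx)], labels[idx],
                                          metric="precomputed"))
        boots = np.asarray(boots)
        lo, hi = (np.percentile(boots, [2.5, 97.5]) if len(boots) else (score, score))
        out.append({"age": age, "silhouette": score, "ci_low": float(lo),
                    "ci_high": float(hi), "n_cells": len(x), "metric": metric})
    return pd.DataFrame(out)


def ks_distance_profile(table: pd.DataFrame, *, n_cells: int = 5000,
                        seed: int = 0) -> pd.DataFrame:
    """Pairwise-averaged two-sample KS distance per feature per age.

    Up to ``n_cells`` cells per (type, age) are drawn without replacement;
    when fewer are available all cells are used.  For more than two types
    the statistic is the mean KS over all C(N, 2) type pairs; p-values per
    pair come from ``scipy.stats.ks_2samp`` (exact for small samples) and
    are summarized by their maximum over pairs (conservative).
    """
    rng = substream(seed, "ks")
    feats = feature_columns(table)
    rows = []
    for age, sub in table.groupby("age", sort=True):
        types = sorted(sub["celltype"].unique())
        if len(types) < 2:
            raise ValueError(f"age {age}: need >= 2 types")
        samples = {}
        for t in types:
            cells = sub[sub["celltype"] == t]
            if len(cells) > n_cells:
                cells = cells.iloc[rng.choice(len(cells), size=n_cells, replace=False)]
            samples[t] = cells[feats].to_numpy(dtype=float)
        for fi, f in enumerate(feats):
            ks_vals, p_vals = [], []
            for i, ta in enumerate(types):
                for tb in types[i + 1:]:
                    res = stats.ks_2samp(samples[ta][:, fi], samples[tb][:, fi])
                    ks_vals.append(res.statistic)
                    p_vals.append(res.pvalue)
            rows.append({"age": age, "feature": f, "ks": float(np.mean(ks_vals)),
                         "p_max": float(np.max(p_vals))})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ErosionThresholds:
    """Two-stage significance gates for erosion features.

    Stage 1 screens for real type separation (KS test significant, and the
    feature's |Pearson r| of KS vs age above ``r_separation``); stage 2
    requires a significant, strong KS-age correlation (``r_age``).  The
    defaults are the conventional blood/tissue screening thresholds.
    """

    alpha: float = 0.05
    r_separation: float = 0.85
    r_age: float = 0.95


def significant_erosion_features(profile: pd.DataFrame,
                                 thresholds: ErosionThresholds = ErosionThresholds()) -> pd.DataFrame:
    """Per-feature erosion report with both significance gates logged.

    ``profile`` is the output of :func:`ks_distance_profile`; needs >= 3
    ages for the correlation stage.
    """
    if profile["age"].nunique() < 3:
        raise ValueError("need >= 3 ages for KS-age correlation")
    rows = []
    for f, sub in profile.groupby("feature", sort=False):
        sub = sub.sort_values("age")
        ks = sub["ks"].to_numpy()
        ages = sub["age"].to_numpy(dtype=float)
        sep_sig = bool((sub["p_max"] < thresholds.alpha).all())
        if np.std(ks) == 0:
            r, p = 0.0, 1.0
        else:
            res = stats.pearsonr(ages, ks)
            r, p = float(res.statistic), float(res.pvalue)
        passes = (sep_sig and abs(r) > thresholds.r_separation
                  and p < thresholds.alpha and abs(r) > thresholds.r_age)
        rows.append({"feature": f, "ks_mean": float(ks.mean()), "r": r, "p": p,
                     "separation_significant": sep_sig, "passes": passes})
    return pd.DataFrame(rows)
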