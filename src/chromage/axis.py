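"""Euclidean ImAge axes: centroid and SVM variants, projection, diagnostics.

The ImAge axis is an oriented line in the z-scored feature space fit on the
young and old reference groups only.  The centroid axis runs from the young
centroid to the old centroid; the SVM axis is the unit normal of a linear
max-margin separator, anchored at the centroid of all training points.
Projecting a data point onto the axis gives the ImAge readout ``p``; the
residual distance to the axis is the orthogonal distance
``d_o = sqrt(||x - origin||^2 - p^2)``.  Neither axis deforms the feature
space — it is a rigid projection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fixtures import feature_columns


@dataclass
class ImAgeAxis:
    origin: np.ndarray
    direction: np.ndarray       # unit vector, oriented young -> old
    method: str                 # "centroid" | "svm"
    threshold: float = 0.0      # decision boundary along the axis (p units)
    features: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(self.direction)
        if not np.isclose(n, 1.0):
            self.direction = self.direction / n

    def to_json(self) -> str:
        return json.dumps({"origin": self.origin.tolist(),
                           "direction": self.direction.tolist(),
                           "method": self.method, "threshold": self.threshold,
                           "features": self.features})

    @classmethod
    def from_json(cls, s: str) -> "ImAgeAxis":
        d = json.loads(s)
        return cls(np.array(d["origin"]), np.array(d["direction"]),
                   d["method"], d["threshold"], d.get("features", []))


def _groups(x: np.ndarray, labels: np.ndarray):
    young = x[labels == "young"]
    old = x[labels == "old"]
    if len(young) == 0 or len(old) == 0:
        raise ValueError("both young and old groups must be non-empty")
    return young, old


def _orient(axis: ImAgeAxis, young: np.ndarray, old: np.ndarray) -> ImAgeAxis:
    """Flip so the old group's mean projection exceeds the young group's."""
    py = (young - axis.origin) @ axis.direction
    po = (old - axis.origin) @ axis.direction
    if po.mean() < py.mean():
        axis.direction = -axis.direction
        axis.threshold = -axis.threshold
    return axis


def fit_centroid_axis(x: np.ndarray, labels: np.ndarray,
                      features: Sequence[str] = ()) -> ImAgeAxis:
    """Axis from the young centroid toward the old centroid."""
    x = np.asarray(x, dtype=float)
    young, old = _groups(x, np.asarray(labels))
    cy, co = young.mean(axis=0), old.mean(axis=0)
    d = co - cy
    n = np.linalg.norm(d)
    if n == 0:
        raise ValueError("young and old centroids coincide; axis undefined")
    axis = ImAgeAxis(cy, d / n, "centroid", features=list(features))
    # decision boundary: midpoint between the centroid projections
    axis.threshold = float(((cy + co) / 2 - axis.origin) @ axis.direction)
    return _orient(axis, young, old)


def fit_svm_axis(x: np.ndarray, labels: np.ndarray, C: float = 1.0,
                 features: Sequence[str] = ()) -> ImAgeAxis:
    """Axis along the normal of a soft-margin linear SVM (young vs old).

    Anchored at the centroid of all training points; the decision boundary
    of the SVM is kept as the classification threshold along the axis.
    """
    from sklearn.svm import SVC

    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    young, old = _groups(x, labels)
    y = (labels == "old").astype(int)
    clf = SVC(kernel="linear", C=C)
    clf.fit(x, y)
    w = clf.coef_.ravel()
    norm = np.linalg.norm(w)
    origin = x.mean(axis=0)
    axis = ImAgeAxis(origin, w / norm, "svm", features=list(features))
    # f(x) = w.x + b = 0  <=>  p = -b/||w|| - direction.origin
    axis.threshold = float(-clf.intercept_[0] / norm - (w / norm) @ origin)
    return _orient(axis, young, old)


def project(x: np.ndarray, axis: ImAgeAxis) -> pd.DataFrame:
    """ImAge readout ``p`` and orthogonal distance ``d_o`` per row."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != len(axis.origin):
        raise ValueError("dimensionality mismatch with axis")
    rel = x - axis.origin
    p = rel @ axis.direction
    d2 = np.einsum("ij,ij->i", rel, rel) - p**2
    d_o = np.sqrt(np.clip(d2, 0.0, None))
    return pd.DataFrame({"p": p, "d_o": d_o})


def axis_variance_fraction(x: np.ndarray, axis: ImAgeAxis) -> float:
    """Fraction of total variance lying along the axis direction."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("need >= 2 rows")
    total = x.var(axis=0, ddof=0).sum()
    if total == 0:
        raise ValueError("zero total variance")
    return float(((x - axis.origin) @ axis.direction).var(ddof=0) / total)


def separation_accuracy(x: np.ndarray, labels: np.ndarray, axis: ImAgeAxis) -> float:
    """Fraction of young/old rows on the correct side of the axis threshold."""
    labels = np.asarray(labels)
    sel = (labels == "young") | (labels == "old")
    p = project(np.asarray(x)[sel], axis)["p"].to_numpy()
    pred_old = p > axis.threshold
    truth_old = labels[sel] == "old"
    return float((pred_old == truth_old).mean())


def age_correlation(per_animal: pd.DataFrame, *, value: str = "p",
                    aggregation: str = "median") -> dict:
    """Pearson and Spearman correlation of per-animal readouts with age.

    ``per_animal`` holds one row per readout with columns ``animal, age``
    and the readout column; readouts are aggregated per animal first
    (median by default — the mean is available via ``aggregation``).
    """
    agg = per_animal.groupby("animal").agg(age=("age", "first"),
                                           v=(value, aggregation))
    if len(agg) < 3:
        raise ValueError("need >= 3 animals")
    if agg["v"].nunique() == 1 or agg["age"].nunique() == 1:
        raise ValueError("constant input")
    pr = stats.pearsonr(agg["age"], agg["v"])
    sr = stats.spearmanr(agg["age"], agg["v"])
    return {"pearson_r": float(pr.statistic), "pearson_p": float(pr.pvalue),
            "spearman_rho": float(sr.statistic), "spearman_p": float(sr.pvalue),
            "aggregation": aggregation, "n_animals": int(len(agg))}


def organ_pair_spearman(readouts: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Leave-one-age-group-out Spearman screen across organ pairs.

    ``readouts`` has one row per (animal, organ, channel) with columns
    ``animal, age, organ, channel, value``.  For every organ pair and
    channel, Spearman correlation of per-animal readouts is computed on the
    full age set and on every subset with one age group removed; p-values
    are Bonferroni-corrected by (#pairs x #channels x #subsets).  A pair is
    robust iff it is significant in the full set and in every subset.
    """
    organs = sorted(readouts["organ"].unique())
    channels = sorted(readouts["channel"].unique())
    ages = sorted(readouts["age"].unique())
    if len(ages) < 3:
        raise ValueError("need >= 3 age groups for leave-one-out")
    subsets = [("all", ages)] + [(f"drop_{a}", [b for b in ages if b != a]) for a in ages]
    pairs = [(a, b) for i, a in enumerate(organs) for b in organs[i + 1:]]
    n_tests = len(pairs) * len(channels) * len(subsets)

    rows = []
    for ch in channels:
        sub_ch = readouts[readouts["channel"] == ch]
        for oa, ob in pairs:
            wide = sub_ch[sub_ch["organ"].isin([oa, ob])].pivot_table(
                index=["animal", "age"], columns="organ", values="value").dropna()
            wide = wide.reset_index()
            for name, keep in subsets:
                w = wide[wide["age"].isin(keep)]
                if w["age"].nunique() < 2 or len(w) < 3:
                    raise ValueError("fewer than 2 age groups after removal")
                sr = stats.spearmanr(w[oa], w[ob])
                rows.append({"channel": ch, "organ_a": oa, "organ_b": ob,
                             "subset": name, "rho": float(sr.statistic),
                             "p": float(sr.pvalue),
                             "p_bonferroni": min(1.0, float(sr.pvalue) * n_tests)})
    report = pd.DataFrame(rows)
    robust = (report.assign(sig=report["p_bonferroni"] < alpha)
              .groupby(["channel", "organ_a", "organ_b"])["sig"].all()
              .rename("robust").reset_index())
    return report.merge(robust, on=["channel", "organ_a", "organ_b"])


def fit_axis(table: pd.DataFrame, method: str = "centroid", **kw) -> ImAgeAxis:
    """Fit an axis from a (z-scored) feature table with a ``group`` column."""
    x = table[feature_columns(table)].to_numpy(dtype=float)
    labels = table["group"].to_numpy()
    feats = feature_columns(table)
    if method == "centroid":
        return fit_centroid_axis(x, labels, features=feats)
    if method == "svm":
        return fit_svm_axis(x, labels, features=feats, **kw)
    raise ValueError("method must be 'centroid' or 'svm'")
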