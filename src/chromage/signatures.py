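"""Single-cell ImAge readouts and young/old signature calling.

The axis is constructed on bootstrap means, but single cells can be
projected onto it with the same standardizer and projection operator — no
refitting.  Because single-cell distributions of the young and old groups
overlap heavily, signature cells are defined by percentile exclusion: a
cell is a *young signature* if its readout falls below the old group's 5th
percentile, an *old signature* if above the young group's 95th percentile,
otherwise *intermediate*.  By construction each reference group contains at
most 5% of the other group's signature.  Raising the percentiles toward
0/100 purifies the signatures at the cost of cell counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .axis import ImAgeAxis, project
from .fixtures import feature_columns
from .resampling import Standardizer


@dataclass(frozen=True)
class SignatureConfig:
    """Percentile thresholds; (5, 95) trades purity for cell counts."""

    old_lower_percentile: float = 5.0     # young signature: a < q(old, this)
    young_upper_percentile: float = 95.0  # old signature:   a > q(young, this)

    def __post_init__(self):
        if not 0 <= self.old_lower_percentile < 100:
            raise ValueError("percentile out of range")
        if not 0 < self.young_upper_percentile <= 100:
            raise ValueError("percentile out of range")


def single_cell_readouts(cells: pd.DataFrame, axis: ImAgeAxis,
                         standardizer: Standardizer) -> pd.DataFrame:
    """Project single cells onto an axis built on bootstrap means.

    The standardizer must be the one fitted on the bootstrap-mean training
    rows; applying a cell-level refit would leak and shift the scale.
    """
    if standardizer is None:
        raise ValueError("standardizer from the bootstrap-mean training is required")
    z = standardizer.transform(cells)
    read = project(z[feature_columns(cells)].to_numpy(dtype=float), axis)
    out = cells.drop(columns=feature_columns(cells)).reset_index(drop=True)
    out["p"] = read["p"].to_numpy()
    out["d_o"] = read["d_o"].to_numpy()
    return out


def call_signatures(young: np.ndarray, old: np.ndarray, query: pd.DataFrame,
                    config: SignatureConfig = SignatureConfig(),
                    *, value: str = "p") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label query cells young/old/intermediate and tally per-animal proportions.

    ``young``/``old`` are reference single-cell readouts; ``query`` has
    columns ``animal`` and the readout column.  Thresholds use linear-
    interpolation percentiles; ties at a threshold are intermediate (strict
    inequalities).  If the references are so separated that both labels
    could apply, the larger margin wins.
    """
    young = np.asarray(young, dtype=float)
    old = np.asarray(old, dtype=float)
    if len(young) == 0 or len(old) == 0:
        raise ValueError("reference groups must be non-empty")
    q_old_lo = float(np.percentile(old, config.old_lower_percentile))
    q_young_hi = float(np.percentile(young, config.young_upper_percentile))
    if np.ptp(young) == 0 and np.ptp(old) == 0 and q_old_lo == q_young_hi:
        warnings.warn("degenerate references: all readouts equal; everything intermediate")

    a = query[value].to_numpy(dtype=float)
    is_young = a < q_old_lo
    is_old = a > q_young_hi
    both = is_young & is_old           # possible only when q_old_lo > q_young_hi
    if both.any():
        young_margin = q_old_lo - a
        old_margin = a - q_young_hi
        is_young = is_young & (~both | (young_margin > old_margin))
        is_old = is_old & (~both | (old_margin >= young_margin)) & ~is_young
    labels = np.where(is_young, "young", np.where(is_old, "old", "intermediate"))

    calls = query.copy()
    calls["label"] = labels
    props = (calls.groupby("animal")["label"]
             .value_counts(normalize=True).unstack(fill_value=0.0)
             .reindex(columns=["young", "intermediate", "old"], fill_value=0.0)
             .reset_index())
    return calls, props


def reprogramming_report(readouts: pd.DataFrame, *, value: str = "p",
                         config: SignatureConfig = SignatureConfig()) -> dict:
    """Compare a treated group against young/old references per animal.

    ``readouts`` holds single-cell (or bootstrap) readouts with columns
    ``animal, group`` (young | old | treated) and the readout column.  The
    reference animal is the old animal with the lowest median readout (the
    "youngest" old animal); each treated animal is tested against it with a
    Mann-Whitney U, the old-vs-treated variance difference with Levene, and
    signature proportions are reported as deltas vs that reference.
    """
    groups = set(readouts["group"].unique())
    if not {"young", "old", "treated"} <= groups:
        raise ValueError("need young, old and treated groups")
    med = readouts.groupby(["group", "animal"])[value].median()
    ref_animal = med.loc["old"].idxmin()
    ref_vals = readouts.query("group == 'old' and animal == @ref_animal")[value].to_numpy()

    per_animal = []
    for animal, sub in readouts[readouts["group"] == "treated"].groupby("animal"):
        mw = stats.mannwhitneyu(sub[value], ref_vals, alternative="two-sided")
        per_animal.append({"animal": animal, "median": float(sub[value].median()),
                           "median_shift": float(sub[value].median() - np.median(ref_vals)),
                           "mannwhitney_p": float(mw.pvalue)})

    old_groups = [g[value].to_numpy() for _, g in
                  readouts[readouts["group"] == "old"].groupby("animal")]
    treated_groups = [g[value].to_numpy() for _, g in
                      readouts[readouts["group"] == "treated"].groupby("animal")]
    if len(old_groups) < 2 or len(treated_groups) < 2:
        levene_p = float("nan")
    else:
        old_med = readouts.query("group == 'old'").groupby("animal")[value].median()
        tr_med = readouts.query("group == 'treated'").groupby("animal")[value].median()
        levene_p = float(stats.levene(old_med, tr_med).pvalue)

    y = readouts.query("group == 'young'")[value].to_numpy()
    o = readouts.query("group == 'old'")[value].to_numpy()
    _, props = call_signatures(y, o, readouts[readouts["group"].isin(["treated"])],
                               config, value=value)
    _, ref_props = call_signatures(y, o,
                                   readouts.query("group == 'old' and animal == @ref_animal"),
                                   config, value=value)
    ref_row = ref_props.iloc[0]
    props = props.assign(
        delta_young=props["young"] - ref_row["young"],
        delta_old=props["old"] - ref_row["old"])
    return {"reference_animal": ref_animal, "per_animal": pd.DataFrame(per_animal),
            "levene_p": levene_p, "signature_proportions": props}
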