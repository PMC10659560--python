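"""End-to-end orchestration: images or cell tables -> ImAge readouts.

These functions chain the modules the way a full analysis run does:

* :func:`extract_features` — segmented image + label mask -> per-cell TAS
  feature table;
* :func:`run_axis_pipeline` — per-cell table -> bootstrap means ->
  train/test split iterations with leakage-free z-scoring -> axis fit ->
  test-set readouts, separation accuracy and ImAge-age correlation.

Every run records its resolved configuration and seed so outputs are
reproducible byte-for-byte.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import axis as axis_mod
from . import segio, tas
from .fixtures import feature_columns
from .resampling import BootstrapConfig, SplitConfig, Standardizer, bootstrap_means, split_iterations


@dataclass(frozen=True)
class RunConfig:
    channels: tuple[str, ...] = ("DAPI", "H3K4me1")
    dimensionality: int = 2
    min_radius_um: float = 4.0
    pixel_size_um: float = 1.0
    axis_method: str = "centroid"        # "centroid" | "svm"
    svm_C: float = 1.0
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    split: SplitConfig = field(default_factory=SplitConfig)
    split_by_animal: bool = False    # hold out whole animals (no identity leak)
    seed: int = 0

    def __post_init__(self):
        if self.axis_method not in ("centroid", "svm"):
            raise ValueError("axis_method must be 'centroid' or 'svm'")
        if self.dimensionality not in (2, 3):
            raise ValueError("dimensionality must be 2 or 3")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bootstrap"] = dataclasses.asdict(self.bootstrap)
        d["split"] = dataclasses.asdict(self.split)
        return d


def extract_features(image, mask, config: RunConfig, *, source: str = "",
                     metadata: dict | None = None) -> pd.DataFrame:
    """Per-nucleus TAS feature table from an image and its label mask."""
    records = segio.load_labeled_image(
        image, mask, config.channels,
        max_project=(config.dimensionality == 2), source=source)
    records = segio.filter_small_objects(records, segio.SizeFilterSpec(
        config.min_radius_um, config.pixel_size_um, config.dimensionality))
    if not records:
        raise ValueError("no nuclei survived the size filter")
    names = tas.feature_names(config.channels, records[0].local_mask.ndim)
    rows = [tas.nucleus_features(r, config.channels) for r in records]
    df = pd.DataFrame(np.vstack(rows), columns=names)
    df.insert(0, "label", [r.label for r in records])
    for k, v in (metadata or {}).items():
        df.insert(0, k, v)
    return df


@dataclass
class AxisPipelineResult:
    readouts: pd.DataFrame            # test-set readouts over all iterations
    accuracies: np.ndarray            # one separation accuracy per iteration
    age_correlation: dict | None
    axis: axis_mod.ImAgeAxis          # from the final iteration
    standardizer: Standardizer        # from the final iteration
    bootstrap_table: pd.DataFrame
    config: RunConfig

    @property
    def accuracy_mean(self) -> float:
        return float(self.accuracies.mean())

    @property
    def accuracy_sd(self) -> float:
        return float(self.accuracies.std(ddof=1)) if len(self.accuracies) > 1 else 0.0


def run_axis_pipeline(cells: pd.DataFrame, config: RunConfig = RunConfig()) -> AxisPipelineResult:
    """Bootstrap, split, fit and project; the core ImAge computation.

    Per split iteration the z-scoring standardizer and the axis are fitted
    on the training rows only (young and old groups); every other row —
    test rows, intermediate ages, perturbations — is projected with the
    training transform, so no information leaks from test to train.
    """
    boot = bootstrap_means(cells, config.bootstrap)
    feats = feature_columns(boot)
    labels = boot["group"].to_numpy()

    readout_parts, accs = [], []
    std = ax = None
    for it, (train, test) in enumerate(split_iterations(boot, config.split,
                                                        by_animal=config.split_by_animal)):
        std = Standardizer.fit(boot.iloc[train])
        z = std.transform(boot)
        x = z[feats].to_numpy(dtype=float)
        if config.axis_method == "svm":
            ax = axis_mod.fit_svm_axis(x[train], labels[train], C=config.svm_C,
                                       features=feats)
        else:
            ax = axis_mod.fit_centroid_axis(x[train], labels[train], features=feats)
        accs.append(axis_mod.separation_accuracy(x[test], labels[test], ax))
        read = axis_mod.project(x[test], ax)
        part = boot.iloc[test][[c for c in boot.columns if c not in feats]].reset_index(drop=True)
        part["p"] = read["p"].to_numpy()
        part["d_o"] = read["d_o"].to_numpy()
        part["iteration"] = it
        readout_parts.append(part)

    readouts = pd.concat(readout_parts, ignore_index=True)
    try:
        corr = axis_mod.age_correlation(readouts)
    except (ValueError, KeyError):
        corr = None
    return AxisPipelineResult(readouts, np.asarray(accs), corr, ax, std, boot, config)
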