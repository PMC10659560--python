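"""Linking ImAge to behavioral readouts.

Rather than correlating each behavioral readout with ImAge separately, the
analysis finds the unit-norm linear combination of readouts maximizing the
Pearson correlation R with the per-animal ImAge values t.  To make the
coefficients unique, correlated readouts are first grouped into
near-orthogonal clusters (hierarchical clustering under the 1 - |r|
distance) and one medoid representative per cluster enters the
optimization.  The constrained maximizer has a closed form: alpha is the
ordinary least-squares coefficient vector of t on the standardized
representatives, normalized to unit length.  Stability is assessed by
leave-one-trial-out jackknife and by randomly recombining trials across
readouts; significance by permutation of animals (the unit-norm
optimization invalidates the parametric t distribution).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .fixtures import substream


def trial_mean_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Animals x readouts matrix of trial-averaged values, z-scored per readout."""
    wide = table.pivot_table(index="animal", columns="readout", values="value",
                             aggfunc="mean")
    return (wide - wide.mean()) / wide.std(ddof=0)


def filter_behaviors(table: pd.DataFrame, t: pd.Series | np.ndarray,
                     p_threshold: float = 0.3) -> pd.DataFrame:
    """Drop readouts whose univariate correlation p-value with t exceeds the cut.

    The 0.3 cut is deliberately loose: it removes only clearly uninformative
    readouts before the joint optimization.
    """
    wide = trial_mean_matrix(table)
    t = _align_t(t, wide.index)
    keep = []
    for r in wide.columns:
        p = stats.pearsonr(wide[r], t).pvalue
        if p <= p_threshold:
            keep.append(r)
    if not keep:
        raise ValueError("all readouts filtered out; nothing correlates with t")
    return table[table["readout"].isin(keep)].copy()


def _align_t(t, animals: Sequence[str]) -> np.ndarray:
    if isinstance(t, pd.Series):
        return t.reindex(animals).to_numpy(dtype=float)
    t = np.asarray(t, dtype=float)
    if len(t) != len(animals):
        raise ValueError("one ImAge value per animal required")
    return t


def cluster_behaviors(table: pd.DataFrame, *, merge_threshold: float = 0.5) -> dict:
    """Partition readouts into near-orthogonal clusters; pick medoid reps.

    Average-linkage clustering under d = 1 - |r|.  The cluster count is
    data-driven: candidate cuts at k = 2..n-1 are scored by silhouette, and
    the degenerate cuts (everything together / all singletons) are chosen
    when all readouts are mutually correlated above ``1 - merge_threshold``
    or all mutually near-orthogonal.
    """
    from sklearn.metrics import silhouette_score

    wide = trial_mean_matrix(table)
    names = list(wide.columns)
    n = len(names)
    if n == 1:
        return {"clusters": {names[0]: 0}, "representatives": [names[0]]}
    corr = np.corrcoef(wide.to_numpy().T)
    d = 1.0 - np.abs(corr)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2, 0.0, None)

    iu = np.triu_indices(n, 1)
    if d[iu].max() < merge_threshold:
        assign = np.zeros(n, dtype=int)
    elif d[iu].min() > merge_threshold:
        assign = np.arange(n)
    else:
        link = hierarchy.linkage(squareform(d, checks=False), method="average")
        best_k, best_s = 2, -np.inf
        for k in range(2, n):
            cand = hierarchy.fcluster(link, k, criterion="maxclust")
            if len(np.unique(cand)) != k:
                continue
            s = silhouette_score(d, cand, metric="precomputed")
            if s > best_s:
                best_k, best_s = k, s
        assign = hierarchy.fcluster(link, best_k, criterion="maxclust") - 1

    clusters = {name: int(c) for name, c in zip(names, assign)}
    reps = []
    for c in sorted(set(assign)):
        members = [i for i in range(n) if assign[i] == c]
        medoid = members[int(np.argmin(d[np.ix_(members, members)].sum(axis=1)))]
        reps.append(names[medoid])
    return {"clusters": clusters, "representatives": reps}


@dataclass
class BehaviorLinkResult:
    representatives: list[str]
    alpha: np.ndarray          # unit norm
    r: float                   # corr(F @ alpha, t)
    p_permutation: float
    clusters: dict | None = None
    alpha_sd: np.ndarray | None = None
    jackknife_alphas: np.ndarray | None = None


def _closed_form_alpha(f: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Unit-norm alpha maximizing corr(F alpha, t): normalized OLS coefficients.

    A rank-deficient design falls back to the pseudoinverse (minimum-norm
    ridge limit).
    """
    beta, *_ = np.linalg.lstsq(f, t - t.mean(), rcond=None)
    nrm = np.linalg.norm(beta)
    if nrm == 0:
        raise ValueError("t is orthogonal to all representatives")
    return beta / nrm


def optimize_alpha(representatives: pd.DataFrame, t, *,
                   n_permutations: int = 10_000, seed: int = 0) -> BehaviorLinkResult:
    """Maximize corr(sum_i alpha_i f_i, t) subject to ||alpha|| = 1.

    ``representatives`` is an animals x readouts frame (z-scored columns).
    The permutation p-value re-optimizes alpha on each shuffled t, so it is
    a valid test of the maximized statistic.
    """
    f = representatives.to_numpy(dtype=float)
    t = _align_t(t, representatives.index)
    n, k = f.shape
    if n <= k:
        raise ValueError("need more animals than representatives")
    alpha = _closed_form_alpha(f, t)
    score = f @ alpha
    r = float(stats.pearsonr(score, t).statistic)

    rng = substream(seed, "alpha-perm")
    count = 0
    for _ in range(n_permutations):
        tp = rng.permutation(t)
        try:
            ap = _closed_form_alpha(f, tp)
        except ValueError:
            continue
        rp = stats.pearsonr(f @ ap, tp).statistic
        if abs(rp) >= abs(r):
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return BehaviorLinkResult(list(representatives.columns), alpha, r, p)


def stabilize_alpha(table: pd.DataFrame, t, representatives: Sequence[str],
                    *, n_draws: int = 1000, seed: int = 0,
                    n_permutations: int = 2000) -> BehaviorLinkResult:
    """Average alpha over trial resamplings.

    Two schemes: leave-one-trial-out jackknife (one replicate per trial)
    and ``n_draws`` random recombinations where each readout independently
    contributes one uniformly chosen trial.  The reported alpha is the mean
    over recombination draws with its SD as spread; the jackknife replicates
    are returned for contamination diagnostics.  Skips the jackknife (with
    a note) when only one trial exists.
    """
    rng = substream(seed, "alpha-stab")
    sub = table[table["readout"].isin(representatives)]
    trials = sorted(sub["trial"].unique())
    animals = sorted(sub["animal"].unique())
    t = _align_t(t, animals)

    cube = (sub.pivot_table(index="animal", columns=["readout", "trial"],
                            values="value")
            .reindex(animals))

    def matrix_from_choice(choice: dict[str, list]) -> np.ndarray:
        cols = []
        for r in representatives:
            vals = np.mean([cube[(r, tr)].to_numpy() for tr in choice[r]], axis=0)
            sd = vals.std(ddof=0)
            cols.append((vals - vals.mean()) / (sd if sd > 0 else 1.0))
        return np.column_stack(cols)

    jack = []
    if len(trials) >= 2:
        for leave in trials:
            kept = [tr for tr in trials if tr != leave]
            f = matrix_from_choice({r: kept for r in representatives})
            jack.append(_closed_form_alpha(f, t))
    jack = np.array(jack) if jack else None

    draws = []
    for _ in range(n_draws):
        choice = {r: [trials[rng.integers(len(trials))]] for r in representatives}
        draws.append(_closed_form_alpha(matrix_from_choice(choice), t))
    draws = np.array(draws)
    # align signs to the first draw before averaging (alpha and -alpha tie)
    signs = np.sign(draws @ draws[0])
    signs[signs == 0] = 1.0
    draws_aligned = draws * signs[:, None]
    alpha = draws_aligned.mean(axis=0)
    alpha = alpha / np.linalg.norm(alpha)
    spread = draws_aligned.std(axis=0)

    f_full = matrix_from_choice({r: trials for r in representatives})
    rep_frame = pd.DataFrame(f_full, index=animals, columns=list(representatives))
    base = optimize_alpha(rep_frame, t, n_permutations=n_permutations, seed=seed)
    score = f_full @ alpha
    r = float(stats.pearsonr(score, t).statistic)
    return BehaviorLinkResult(list(representatives), alpha, r, base.p_permutation,
                              alpha_sd=spread, jackknife_alphas=jack)


def behavior_link(table: pd.DataFrame, t, *, p_threshold: float = 0.3,
                  n_permutations: int = 10_000, seed: int = 0) -> BehaviorLinkResult:
    """Full chain: filter -> cluster -> optimize on cluster representatives."""
    reduced = filter_behaviors(table, t, p_threshold)
    grouping = cluster_behaviors(reduced)
    wide = trial_mean_matrix(reduced)[grouping["representatives"]]
    res = optimize_alpha(wide, t, n_permutations=n_permutations, seed=seed)
    res.clusters = grouping["clusters"]
    return res
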