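"""Extractant-condition selection analytics for IP pre-screens.

A pre-screen IPs the bait under many candidate extraction conditions and
asks which small subset to carry forward.  The inputs are a condition x
protein matrix of log2 abundances where NaN marks not-detected (distinct
from any numeric abundance).  Provided analytics: detection coverage of a
condition subset relative to the union over all conditions, a Monte-Carlo
benchmark of a chosen subset against random subsets of the same size,
pairwise condition correlation over shared detections, and hierarchical
clustering of condition profiles.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage


@dataclass
class CoverageReport:
    subset: tuple[str, ...]
    covered: int
    union_total: int

    @property
    def fraction(self) -> float:
        return self.covered / self.union_total if self.union_total else 0.0


@dataclass
class SubsetBenchmark:
    subset_size: int
    n_draws: int
    seed: int
    chosen_fraction: float
    draw_fractions: np.ndarray

    @property
    def percentile(self) -> float:
        """Fraction of random draws the chosen subset strictly surpasses."""
        return float(np.mean(self.draw_fractions < self.chosen_fraction))


def _check_conditions(matrix: pd.DataFrame, subset: Sequence[str]) -> None:
    unknown = set(subset) - set(matrix.index)
    if unknown:
        raise KeyError(f"unknown condition(s): {sorted(unknown)}")


def detection_coverage(matrix: pd.DataFrame, subset: Sequence[str]) -> CoverageReport:
    """Share of the all-condition protein union detected within a subset."""
    _check_conditions(matrix, subset)
    union_total = int(matrix.notna().any(axis=0).sum())
    if len(subset) == 0:
        return CoverageReport(tuple(subset), 0, union_total)
    covered = int(matrix.loc[list(subset)].notna().any(axis=0).sum())
    return CoverageReport(tuple(subset), covered, union_total)


def random_subset_benchmark(
    matrix: pd.DataFrame,
    chosen_subset: Sequence[str],
    subset_size: int = 6,
    n_draws: int = 1000,
    seed: int = 0,
) -> SubsetBenchmark:
    """Benchmark a chosen condition subset against random same-size subsets.

    Draws ``n_draws`` uniform subsets without replacement and reports the
    fraction whose coverage is strictly below the chosen subset's
    ("surpassed"; ties do not count).  Deterministic given the seed.
    """
    if subset_size > len(matrix.index):
        raise ValueError(
            f"subset_size {subset_size} exceeds {len(matrix.index)} conditions"
        )
    _check_conditions(matrix, chosen_subset)
    rng = np.random.default_rng(seed)
    chosen = detection_coverage(matrix, chosen_subset).fraction
    conds = np.asarray(matrix.index)
    detected = matrix.notna().to_numpy()
    union_total = int(detected.any(axis=0).sum())
    fracs = np.empty(n_draws)
    for i in range(n_draws):
        pick = rng.choice(len(conds), size=subset_size, replace=False)
        fracs[i] = detected[pick].any(axis=0).sum() / union_total
    return SubsetBenchmark(
        subset_size=subset_size,
        n_draws=n_draws,
        seed=seed,
        chosen_fraction=chosen,
        draw_fractions=fracs,
    )


def exhaustive_subset_percentile(
    matrix: pd.DataFrame, chosen_subset: Sequence[str], subset_size: int
) -> float:
    """Exact percentile over all size-k subsets (small matrices only)."""
    chosen = detection_coverage(matrix, chosen_subset).fraction
    fracs = [
        detection_coverage(matrix, combo).fraction
        for combo in itertools.combinations(matrix.index, subset_size)
    ]
    return float(np.mean([f < chosen for f in fracs]))


def condition_correlation(matrix: pd.DataFrame, min_shared: int = 3) -> pd.DataFrame:
    """Pairwise Pearson correlation of condition profiles.

    Computed over proteins detected in both conditions of each pair;
    pairs sharing fewer than ``min_shared`` proteins are NaN (undefined).
    Diagonal is 1 and the table is symmetric.
    """
    if len(matrix.index) < 2:
        raise ValueError("need >= 2 conditions")
    conds = list(matrix.index)
    out = pd.DataFrame(np.eye(len(conds)), index=conds, columns=conds)
    for a, b in itertools.combinations(conds, 2):
        sub = matrix.loc[[a, b]].dropna(axis=1).T
        if len(sub) < min_shared:
            r = float("nan")
        else:
            sa, sb = sub[a].std(ddof=1), sub[b].std(ddof=1)
            r = float(sub[a].corr(sub[b])) if sa > 0 and sb > 0 else float("nan")
        out.loc[a, b] = out.loc[b, a] = r
    return out


def cluster_conditions(
    matrix: pd.DataFrame,
    method: str = "average",
    metric: str = "euclidean",
) -> tuple[np.ndarray, list[str]]:
    """Agglomerative clustering of condition profiles.

    Not-detected entries are replaced by a detection floor (matrix minimum
    minus 1 on the log2 scale) for distance computation, so shared absence
    clusters conditions together.  Conditions are processed in label order
    for deterministic ties.  Returns ``(linkage_matrix, leaf_order)``.
    """
    if len(matrix.index) < 2:
        raise ValueError("need >= 2 conditions")
    mat = matrix.sort_index()
    floor = float(np.nanmin(mat.to_numpy())) - 1.0
    filled = mat.fillna(floor)
    Z = linkage(filled.to_numpy(float), method=method, metric=metric)
    order = [mat.index[i] for i in leaves_list(Z)]
    return Z, order


def cut_condition_clusters(
    matrix: pd.DataFrame, n_clusters: int, method: str = "average",
    metric: str = "euclidean",
) -> dict[str, int]:
    """Cluster labels for each condition at a chosen cut of the tree."""
    from scipy.cluster.hierarchy import fcluster

    Z, _ = cluster_conditions(matrix, method=method, metric=metric)
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    return dict(zip(matrix.sort_index().index, (int(x) for x in labels)))


def benchmark_binomial_se(benchmark: SubsetBenchmark) -> float:
    """Binomial standard error of the Monte-Carlo percentile."""
    p = benchmark.percentile
    return math.sqrt(max(p * (1 - p), 1e-12) / benchmark.n_draws)
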