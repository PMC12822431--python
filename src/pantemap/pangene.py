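"""Pangenome occupancy classification and growth-curve simulation.

Gene clusters (orthogroups) observed across a panel of genome assemblies
are classified by occupancy — the number of genomes carrying at least one
member — into core, softcore, dispensable and private classes, and the
pan/core genome growth is estimated by random subsampling of genomes
("totally random" resampling: independent random subsets at every subset
size).
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError, ParameterError

__all__ = [
    "default_occupancy_thresholds",
    "classify_occupancy",
    "growth_curves",
    "compare_groups",
]

OCCUPANCY_LABELS = ("core", "softcore", "dispensable", "private")


def default_occupancy_thresholds(n_genomes: int) -> dict[str, tuple[int, int]]:
    """Occupancy bands generalizing the 14-genome convention
    (core = n, softcore = n-2..n-1, dispensable = 2..n-3, private = 1)."""
    if n_genomes < 4:
        raise ParameterError("need >= 4 genomes for the four-class scheme")
    return {
        "core": (n_genomes, n_genomes),
        "softcore": (n_genomes - 2, n_genomes - 1),
        "dispensable": (2, n_genomes - 3),
        "private": (1, 1),
    }


def _validate_thresholds(thresholds: Mapping[str, tuple[int, int]],
                         n_genomes: int) -> None:
    covered = np.zeros(n_genomes + 1, dtype=int)
    for label, (lo, hi) in thresholds.items():
        if lo > hi or lo < 1 or hi > n_genomes:
            raise ConfigError(f"bad band for {label!r}: [{lo}, {hi}]")
        covered[lo:hi + 1] += 1
    if np.any(covered[1:] != 1):
        raise ConfigError(
            f"occupancy bands must partition [1, {n_genomes}] exactly once")


def classify_occupancy(
    presence: pd.DataFrame,
    thresholds: Mapping[str, tuple[int, int]] | None = None,
) -> tuple[pd.Series, pd.Series]:
    """Label each gene cluster by its genome occupancy.

    Parameters
    ----------
    presence
        Boolean/0-1 matrix, rows = clusters, columns = genomes.
    thresholds
        ``label -> (lo, hi)`` inclusive occupancy bands; must partition
        ``[1, n_genomes]``.  Defaults to
        :func:`default_occupancy_thresholds`.

    Returns
    -------
    labels : Series (cluster -> label), counts : Series (label -> count).
    """
    if presence.empty:
        raise DataError("empty cluster table")
    n_genomes = presence.shape[1]
    if thresholds is None:
        thresholds = default_occupancy_thresholds(n_genomes)
    _validate_thresholds(thresholds, n_genomes)

    occ = presence.astype(bool).sum(axis=1)
    if (occ == 0).any():
        bad = occ.index[occ == 0][:5].tolist()
        raise DataError(f"clusters with zero occupancy: {bad} ...")

    labels = pd.Series(index=presence.index, dtype=object)
    for label, (lo, hi) in thresholds.items():
        labels[(occ >= lo) & (occ <= hi)] = label
    order = [l for l in OCCUPANCY_LABELS if l in thresholds] + \
        [l for l in thresholds if l not in OCCUPANCY_LABELS]
    counts = labels.value_counts().reindex(order, fill_value=0)
    return labels, counts


def growth_curves(
    presence: pd.DataFrame,
    n_subsets_per_size: int = 500,
    n_repeats: int = 30,
    seed: int = 0,
    max_size: int | None = None,
) -> pd.DataFrame:
    """Pan/core genome size as a function of the number of sampled genomes.

    For each subset size ``k`` in ``1..n``, ``n_subsets_per_size *
    n_repeats`` random genome subsets are drawn (each subset without
    replacement; subsets independent of each other).  ``pan(k)`` counts
    clusters present in at least one subset member and ``core(k)``
    clusters present in all members.

    Returns a DataFrame indexed by ``k`` with columns ``pan_mean``,
    ``core_mean``, ``pan_q05``, ``pan_q95``, ``core_q05``, ``core_q95``
    and ``n_samples``.
    """
    if presence.empty:
        raise DataError("empty cluster table")
    n = presence.shape[1]
    if max_size is not None and max_size > n:
        raise ParameterError(f"subset size {max_size} exceeds {n} genomes")
    kmax = max_size or n
    mat = presence.astype(bool).to_numpy()
    rng = np.random.default_rng(seed)
    draws = n_subsets_per_size * n_repeats

    rows = []
    for k in range(1, kmax + 1):
        pan = np.empty(draws, dtype=np.int64)
        core = np.empty(draws, dtype=np.int64)
        for d in range(draws):
            cols = rng.choice(n, size=k, replace=False)
            sub = mat[:, cols]
            pan[d] = sub.any(axis=1).sum()
            core[d] = sub.all(axis=1).sum()
        rows.append({
            "k": k,
            "pan_mean": pan.mean(),
            "core_mean": core.mean(),
            "pan_q05": np.quantile(pan, 0.05),
            "pan_q95": np.quantile(pan, 0.95),
            "core_q05": np.quantile(core, 0.05),
            "core_q95": np.quantile(core, 0.95),
            "n_samples": draws,
        })
    return pd.DataFrame(rows).set_index("k")


def compare_groups(values_a: Sequence[float],
                   values_b: Sequence[float]) -> dict:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) comparison.

    Uses the exact null distribution for small samples without ties and
    the tie-corrected normal approximation otherwise.  Returns a dict
    with ``p``, ``statistic``, ``median_a``, ``median_b``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DataError("both groups must be non-empty")
    if np.unique(np.concatenate([a, b])).size == 1:
        warnings.warn("all values tied across both groups; p = 1")
        return {"p": 1.0, "statistic": float(a.size * b.size / 2),
                "median_a": float(np.median(a)), "median_b": float(np.median(b))}
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return {"p": float(res.pvalue), "statistic": float(res.statistic),
            "median_a": float(np.median(a)), "median_b": float(np.median(b))}
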