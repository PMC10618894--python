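"""Two-group permutation test for site-level statistics.

The statistic is the absolute difference in group means. Group labels are
permuted (all distinct splits when exhaustively feasible, else Monte-Carlo),
and the p-value is the proportion of permuted statistics strictly larger than
the observed one — matching the convention that re-labelings tied with the
observed value do not count as more extreme. An inclusive variant
(>= with the observed split counted, so p can never be exactly 0) is
available via ``inclusive=True``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np

EXHAUSTIVE_LIMIT = 100_000


@dataclass
class PermutationResult:
    observed_stat: float
    n_perm: int
    p_value: float
    seed: Optional[int]
    exhaustive: bool
    perm_stats: Optional[np.ndarray] = None


def two_group_abs_meandiff_test(
    values: Sequence[float],
    labels: Sequence,
    n_perm: int = 10_000,
    seed: Optional[int] = None,
    exhaustive: Optional[bool] = None,
    inclusive: bool = False,
    return_perm_stats: bool = False,
) -> PermutationResult:
    """Permutation test of |mean(group A) - mean(group B)|.

    Parameters
    ----------
    values, labels :
        Equal-length; ``labels`` must contain exactly two distinct values,
        each with at least two observations.
    exhaustive :
        ``None`` (default) enumerates all C(n, n1) splits when that count is
        at most 100,000, otherwise samples ``n_perm`` random label
        permutations. ``True``/``False`` force the choice.
    inclusive :
        When True, p = (#{permuted >= observed} + 1) / (n_perm + 1) for
        Monte-Carlo runs, and #{>= observed}/#splits for exhaustive runs.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise ValueError("values and labels must have the same length")
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError("labels must be binary")
    mask = labels == uniq[0]
    n1, n2 = int(mask.sum()), int((~mask).sum())
    if min(n1, n2) < 2:
        raise ValueError("each group needs >= 2 values")
    n = n1 + n2
    observed = abs(values[mask].mean() - values[~mask].mean())

    n_splits = math.comb(n, n1)
    if exhaustive is None:
        exhaustive = n_splits <= EXHAUSTIVE_LIMIT
    if exhaustive and n_splits > EXHAUSTIVE_LIMIT:
        raise ValueError(f"C({n},{n1}) = {n_splits} splits is too many to enumerate")

    total = values.sum()
    if exhaustive:
        stats = np.empty(n_splits)
        for k, idx in enumerate(combinations(range(n), n1)):
            s1 = values[list(idx)].sum()
            stats[k] = abs(s1 / n1 - (total - s1) / n2)
        greater = int((stats > observed + 1e-12).sum())
        geq = int((stats >= observed - 1e-12).sum())
        p = (geq if inclusive else greater) / n_splits
        return PermutationResult(
            observed_stat=float(observed), n_perm=n_splits, p_value=float(p),
            seed=seed, exhaustive=True,
            perm_stats=stats if return_perm_stats else None,
        )

    rng = np.random.default_rng(seed)
    stats = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(n)
        s1 = values[perm[:n1]].sum()
        stats[k] = abs(s1 / n1 - (total - s1) / n2)
    if inclusive:
        p = (int((stats >= observed - 1e-12).sum()) + 1) / (n_perm + 1)
    else:
        p = int((stats > observed + 1e-12).sum()) / n_perm
    return PermutationResult(
        observed_stat=float(observed), n_perm=n_perm, p_value=float(p),
        seed=seed, exhaustive=False,
        perm_stats=stats if return_perm_stats else None,
    )
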