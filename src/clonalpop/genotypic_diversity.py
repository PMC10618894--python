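"""Genotypic richness and evenness for clonal samples.

GD = (G - 1)/(N - 1) scales MLG richness G by sample size N: 0 when every
shoot is the same clone, 1 when every shoot is a distinct genet. The
Shannon and Gini-Simpson indices are converted to effective numbers of MLGs
(exp of Shannon, reciprocal of Gini-Simpson) and passed through the same
(E - 1)/(N - 1) scaling, giving GD_Shannon and GD_Simpson. Because richness
emphasizes rare MLGs, Shannon weighs by abundance, and Gini-Simpson
emphasizes common MLGs, G >= eff_Shannon >= eff_Simpson always, so
GD >= GD_Shannon >= GD_Simpson; the gaps measure unevenness of clone sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MicrosatDataset
from .mlg_clones import MLGAssignment


@dataclass
class GenotypicSummary:
    N: int
    G: int
    GD: float
    GD_shannon: float
    GD_simpson: float
    eff_shannon: float
    eff_simpson: float


def gd_richness(G: int, N: int) -> float:
    """(G - 1)/(N - 1); NaN when N < 2 (undefined)."""
    if not 1 <= G <= N:
        raise ValueError("need 1 <= G <= N")
    if N < 2:
        return float("nan")
    return (G - 1) / (N - 1)


def effective_numbers(mlg_counts) -> tuple[float, float]:
    """Effective MLG numbers: (exp Shannon, 1 / Gini-Simpson complement).

    ``eff_shannon = exp(-sum p ln p)``, ``eff_simpson = 1 / sum p^2`` with
    p the relative MLG abundances.
    """
    counts = np.asarray(list(mlg_counts), dtype=float)
    if counts.size == 0:
        raise ValueError("empty abundance vector")
    if (counts <= 0).any() or not np.allclose(counts, np.round(counts)):
        raise ValueError("counts must be positive integers")
    p = counts / counts.sum()
    eff_shannon = float(np.exp(-(p * np.log(p)).sum()))
    eff_simpson = float(1.0 / (p ** 2).sum())
    return eff_shannon, eff_simpson


def gd_effective(mlg_counts, N: int | None = None) -> tuple[float, float]:
    """(E - 1)/(N - 1) applied to both effective numbers."""
    counts = np.asarray(list(mlg_counts), dtype=float)
    if N is None:
        N = int(counts.sum())
    if int(counts.sum()) != N:
        raise ValueError("counts must sum to N")
    if N < 2:
        return float("nan"), float("nan")
    es, esim = effective_numbers(counts)
    return (es - 1) / (N - 1), (esim - 1) / (N - 1)


def summarize_counts(mlg_counts) -> GenotypicSummary:
    counts = np.asarray(list(mlg_counts), dtype=int)
    N, G = int(counts.sum()), int(len(counts))
    es, esim = effective_numbers(counts)
    gds, gdsim = gd_effective(counts, N) if N >= 2 else (float("nan"),) * 2
    return GenotypicSummary(
        N=N, G=G, GD=gd_richness(G, N), GD_shannon=gds, GD_simpson=gdsim,
        eff_shannon=es, eff_simpson=esim,
    )


def site_genotypic_summary(ds: MicrosatDataset, mlgs: MLGAssignment) -> pd.DataFrame:
    """Per-site, per-period, and total genotypic-diversity rows.

    One row per (period, site), a pooled row per period (site ``__period__``),
    and a grand-total row (period/site ``__total__``), with columns mirroring
    a standard clonal-diversity table: N, MLG, GD, GD_Shannon, GD_Simpson.
    """
    pos = {sid: i for i, sid in enumerate(ds.sample_ids)}
    rows = []

    def counts_for(idx) -> list[int]:
        mids = [mlgs.mlg_of[ds.sample_ids[i]] for i in idx]
        return list(pd.Series(mids).value_counts())

    for period, pidx in ds.by_period().items():
        psub = set(pidx.tolist())
        for site, sidx in ds.by_site().items():
            idx = [i for i in sidx if i in psub]
            if not idx:
                continue
            rows.append((period, site, counts_for(idx)))
        rows.append((period, "__period__", counts_for(pidx)))
    rows.append(("__total__", "__total__", counts_for(range(ds.n_samples))))

    out = []
    for period, site, counts in rows:
        s = summarize_counts(counts)
        out.append((period, site, s.N, s.G, s.GD, s.GD_shannon, s.GD_simpson,
                    s.eff_shannon, s.eff_simpson))
    return pd.DataFrame(out, columns=["period", "site", "N", "MLG", "GD",
                                      "GD_shannon", "GD_simpson",
                                      "eff_shannon", "eff_simpson"])
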