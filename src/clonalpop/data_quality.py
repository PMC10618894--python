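"""Data-quality checks: HWE exact tests, multilocus linkage disequilibrium,
and null-allele frequency estimators.

All three are meant to run on clone-corrected data — replicate shoots of one
genet are not independent draws from the mating pool, so including them
inflates every departure these tests look for.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotype_io import MISSING, MicrosatDataset


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test (Monte-Carlo, probability ordering)
# ---------------------------------------------------------------------------

def _log_table_prob(genotypes: np.ndarray) -> float:
    """Log conditional probability of a genotype array given allele counts.

    Guo-Thompson style: P = n! 2^H prod_a m_a! / [(2n)! prod_{i<=j} n_ij!]
    with H heterozygous individuals, m_a allele counts, n_ij genotype counts.
    """
    n = len(genotypes)
    het = int((genotypes[:, 0] != genotypes[:, 1]).sum())
    _, allele_counts = np.unique(genotypes.ravel(), return_counts=True)
    pairs = [tuple(g) for g in genotypes]
    _, geno_counts = np.unique(pairs, axis=0, return_counts=True)
    return float(
        gammaln(n + 1) + het * np.log(2.0) + gammaln(allele_counts + 1).sum()
        - gammaln(2 * n + 1) - gammaln(geno_counts + 1).sum()
    )


def hwe_exact(locus_genotypes: np.ndarray, mc_reps: int = 10_000,
              seed: Optional[int] = None) -> float:
    """Monte-Carlo exact HWE test for one locus.

    ``locus_genotypes`` is an (n, 2) array of scored allele pairs. Alleles
    are shuffled into random genotype tables conditional on allele counts;
    p is the fraction of tables whose conditional probability is <= that of
    the observed table (probability ordering). Monomorphic input returns 1.
    """
    g = np.asarray(locus_genotypes)
    g = g[g[:, 0] != MISSING]
    if len(g) < 2:
        raise ValueError("need >= 2 scored individuals")
    if len(np.unique(g.ravel())) < 2:
        return 1.0
    obs = _log_table_prob(np.sort(g, axis=1))
    rng = np.random.default_rng(seed)
    pool = g.ravel().copy()
    hits = 0
    for _ in range(mc_reps):
        rng.shuffle(pool)
        table = np.sort(pool.reshape(-1, 2), axis=1)
        if _log_table_prob(table) <= obs + 1e-9:
            hits += 1
    return hits / mc_reps


def hwe_table(ds_cc: MicrosatDataset, mc_reps: int = 2000,
              seed: Optional[int] = None) -> pd.DataFrame:
    """HWE p per locus per site (plus pooled), on clone-corrected input."""
    strata = {"__all__": np.arange(ds_cc.n_samples)}
    strata.update(ds_cc.by_site())
    rows = []
    for k, (stratum, idx) in enumerate(strata.items()):
        for j, locus in enumerate(ds_cc.locus_names):
            g = ds_cc.genotypes[idx, j]
            g = g[g[:, 0] != MISSING]
            if len(g) < 2:
                p = float("nan")
            else:
                sub_seed = None if seed is None else seed + 1000 * k + j
                p = hwe_exact(g, mc_reps=mc_reps, seed=sub_seed)
            rows.append((stratum, locus, p))
    return pd.DataFrame(rows, columns=["stratum", "locus", "hwe_p"])


# ---------------------------------------------------------------------------
# index of association
# ---------------------------------------------------------------------------

def _locus_distances(ds: MicrosatDataset, rows: np.ndarray) -> np.ndarray:
    """(n_pairs, n_loci) per-locus distances between individual pairs.

    Per locus: 0 if the two genotypes share both alleles, 0.5 if one, 1 if
    none (missing treated as 0 distance contribution for that pair/locus).
    """
    geno = ds.genotypes[rows]
    n = len(rows)
    pairs = list(combinations(range(n), 2))
    out = np.zeros((len(pairs), ds.n_loci))
    for j in range(ds.n_loci):
        for k, (a, b) in enumerate(pairs):
            g1, g2 = geno[a, j], geno[b, j]
            if g1[0] == MISSING or g2[0] == MISSING:
                continue
            shared = 0
            c2 = list(g2)
            for allele in g1:
                if allele in c2:
                    c2.remove(allele)
                    shared += 1
            out[k, j] = (2 - shared) / 2.0
    return out


def index_of_association(ds_cc: MicrosatDataset, rows=None) -> tuple[float, float]:
    """Multilocus linkage disequilibrium: (Ia, rbarD).

    With per-locus pairwise distances d_l, total D = sum_l d_l:
    Ia = Var(D)/sum_l Var(d_l) - 1, and rbarD standardizes by the maximum
    attainable covariance, (Var(D) - sum Var(d_l)) / (2 sum_{l<m}
    sqrt(Var d_l Var d_m)). Both are 0 in expectation at linkage equilibrium;
    rbarD is 1 for perfectly associated loci.
    """
    if rows is None:
        rows = np.arange(ds_cc.n_samples)
    rows = np.asarray(rows)
    if ds_cc.n_loci < 2:
        raise ValueError("need >= 2 loci")
    if len(rows) < 3:
        raise ValueError("need >= 3 individuals")
    d = _locus_distances(ds_cc, rows)
    var_l = d.var(axis=0)  # population variance over pairs, poppr convention
    VO = d.sum(axis=1).var()
    VE = var_l.sum()
    if VE == 0:
        return float("nan"), float("nan")
    ia = VO / VE - 1.0
    denom = 0.0
    for l, m in combinations(range(ds_cc.n_loci), 2):
        denom += np.sqrt(var_l[l] * var_l[m])
    rbard = (VO - VE) / (2 * denom) if denom > 0 else float("nan")
    return float(ia), float(rbard)


# ---------------------------------------------------------------------------
# null alleles
# ---------------------------------------------------------------------------

def null_allele_estimates(H_o: float, H_e: float) -> tuple[float, float, bool]:
    """(r_chakraborty, r_brookfield1, floored).

    r_c = (He - Ho)/(He + Ho); r_b = (He - Ho)/(1 + He). Negative estimates
    (observed excess) are floored at 0 with ``floored=True``.
    """
    if H_e <= 0:
        raise ValueError("H_e must be > 0")
    r_c = (H_e - H_o) / (H_e + H_o)
    r_b = (H_e - H_o) / (1.0 + H_e)
    floored = r_c < 0 or r_b < 0
    return max(r_c, 0.0), max(r_b, 0.0), floored


def null_allele_table(ds_cc: MicrosatDataset) -> pd.DataFrame:
    """Per-locus null-allele estimates from pooled Ho/He."""
    from .genetic_diversity import heterozygosities

    het = heterozygosities(ds_cc)
    rows = []
    for rec in het.itertuples(index=False):
        if rec.locus == "__mean__":
            continue
        if rec.H_e <= 0:
            rows.append((rec.locus, float("nan"), float("nan"), False))
            continue
        r_c, r_b, fl = null_allele_estimates(rec.H_o, rec.H_e)
        rows.append((rec.locus, r_c, r_b, fl))
    return pd.DataFrame(rows, columns=["locus", "r_chakraborty",
                                       "r_brookfield1", "floored"])
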