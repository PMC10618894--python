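"""Allele-level diversity on clone-corrected data.

All functions here expect clone-corrected input (one representative per MLG
per stratum; see :func:`clonalpop.mlg_clones.collapse_clones`) so that clonal
replicates do not pseudo-replicate allele counts.

Rarefied allelic richness follows the hypergeometric (El Mousadik & Petit)
formulation on 2g genes drawn from the 2N scored genes at a locus. The
inbreeding coefficient is the Weir & Cockerham small-sample f, combined
across alleles and loci by summing variance components; its significance is
judged by permuting alleles among individuals within the stratum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotype_io import MISSING, MicrosatDataset


# ---------------------------------------------------------------------------
# allele counts / frequencies
# ---------------------------------------------------------------------------

def allele_counts(ds: MicrosatDataset, rows=None) -> dict[str, dict[int, int]]:
    """Per-locus allele -> gene-copy count over the given sample rows."""
    if rows is None:
        rows = np.arange(ds.n_samples)
    out: dict[str, dict[int, int]] = {}
    for j, locus in enumerate(ds.locus_names):
        g = ds.genotypes[rows, j]
        g = g[g[:, 0] != MISSING]
        alleles, counts = np.unique(g.ravel(), return_counts=True)
        out[locus] = {int(a): int(c) for a, c in zip(alleles, counts)}
    return out


def allele_summary(ds_cc: MicrosatDataset) -> pd.DataFrame:
    """Per-stratum (site and pooled) per-locus allele counts and frequencies.

    Returns a tidy frame: stratum, locus, allele, count, frequency, n_genes.
    """
    strata: dict[str, np.ndarray] = {"__all__": np.arange(ds_cc.n_samples)}
    strata.update(ds_cc.by_site())
    rows = []
    for stratum, idx in strata.items():
        for locus, table in allele_counts(ds_cc, idx).items():
            total = sum(table.values())
            for a, c in sorted(table.items()):
                rows.append((stratum, locus, a, c,
                             c / total if total else np.nan, total))
    return pd.DataFrame(rows, columns=["stratum", "locus", "allele", "count",
                                       "frequency", "n_genes"])


def private_alleles(ds_cc: MicrosatDataset, by: str = "period") -> pd.DataFrame:
    """Alleles observed in exactly one period (or site): presence/absence."""
    groups = ds_cc.by_period() if by == "period" else ds_cc.by_site()
    seen: dict[str, set[tuple[str, int]]] = {}
    for g, idx in groups.items():
        seen[g] = {(loc, a) for loc, t in allele_counts(ds_cc, idx).items()
                   for a in t}
    rows = []
    for g, alleles in seen.items():
        others = set().union(*(v for k, v in seen.items() if k != g)) if len(seen) > 1 else set()
        for loc, a in sorted(alleles - others):
            rows.append((g, loc, a))
    return pd.DataFrame(rows, columns=[by, "locus", "allele"])


# ---------------------------------------------------------------------------
# rarefied richness
# ---------------------------------------------------------------------------

def rarefied_richness_locus(gene_counts, g: int) -> float:
    """Expected allele count in a draw of 2g genes (g diploid individuals).

    ``sum_a [1 - C(2N - n_a, 2g) / C(2N, 2g)]`` over alleles with gene-copy
    counts n_a and 2N total genes, computed with log-gammas for stability.
    """
    counts = np.asarray(list(gene_counts), dtype=int)
    if (counts <= 0).any():
        raise ValueError("gene counts must be positive")
    total = int(counts.sum())
    k = 2 * g
    if k > total:
        raise ValueError(f"rarefaction draw 2g={k} exceeds {total} scored genes")

    def logC(n, r):
        return gammaln(n + 1) - gammaln(r + 1) - gammaln(n - r + 1)

    probs_absent = np.where(
        total - counts >= k,
        np.exp(logC(total - counts, k) - logC(total, k)),
        0.0,
    )
    return float((1.0 - probs_absent).sum())


def rarefied_richness(ds_cc: MicrosatDataset, g: int = 5, rows=None) -> float:
    """Mean over loci of rarefied allele counts at g diploid individuals.

    Loci where fewer than g individuals were scored are excluded (NaN if
    none remain).
    """
    counts = allele_counts(ds_cc, rows)
    vals = []
    for locus, table in counts.items():
        total = sum(table.values())
        if total >= 2 * g and table:
            vals.append(rarefied_richness_locus(list(table.values()), g))
    return float(np.mean(vals)) if vals else float("nan")


# ---------------------------------------------------------------------------
# heterozygosities
# ---------------------------------------------------------------------------

def heterozygosities(ds_cc: MicrosatDataset, rows=None,
                     unbiased: bool = False) -> pd.DataFrame:
    """Observed and expected heterozygosity per locus plus a mean row.

    H_o = fraction heterozygous among scored individuals. H_e = 1 - sum p^2
    (no small-sample correction, the GenAlEx convention); ``unbiased=True``
    applies Nei's 2N/(2N-1) factor.
    """
    if rows is None:
        rows = np.arange(ds_cc.n_samples)
    recs = []
    for j, locus in enumerate(ds_cc.locus_names):
        g = ds_cc.genotypes[rows, j]
        g = g[g[:, 0] != MISSING]
        n = len(g)
        if n == 0:
            raise ValueError(f"locus {locus} has zero scored samples")
        ho = float((g[:, 0] != g[:, 1]).mean())
        _, counts = np.unique(g.ravel(), return_counts=True)
        p = counts / counts.sum()
        he = float(1.0 - (p ** 2).sum())
        if unbiased and n > 0:
            he *= 2 * n / (2 * n - 1)
        recs.append((locus, n, ho, he))
    df = pd.DataFrame(recs, columns=["locus", "n", "H_o", "H_e"])
    mean = pd.DataFrame([("__mean__", df["n"].mean(), df["H_o"].mean(),
                          df["H_e"].mean())], columns=df.columns)
    return pd.concat([df, mean], ignore_index=True)


# ---------------------------------------------------------------------------
# Weir & Cockerham f (Fis) and its randomization test
# ---------------------------------------------------------------------------

def _wc_components(ds: MicrosatDataset, rows) -> tuple[float, float]:
    """Sum of W&C (1984) single-population variance components (b, c).

    Per allele A at a locus with n scored individuals, frequency p and
    observed heterozygote frequency h (individuals carrying A with one copy):
    b = n/(n-1) * [p(1-p) - (2n-1)/(4n) * h],  c = h/2.
    f = 1 - sum(c)/sum(b + c) over alleles and loci.
    """
    sum_b = sum_c = 0.0
    any_poly = False
    for j in range(ds.n_loci):
        g = ds.genotypes[rows, j]
        g = g[g[:, 0] != MISSING]
        n = len(g)
        if n < 2:
            continue
        alleles, counts = np.unique(g.ravel(), return_counts=True)
        if len(alleles) < 2:
            continue
        any_poly = True
        het = g[:, 0] != g[:, 1]
        for a, cnt in zip(alleles, counts):
            p = cnt / (2 * n)
            h = float((het & ((g[:, 0] == a) | (g[:, 1] == a))).mean())
            b = n / (n - 1) * (p * (1 - p) - (2 * n - 1) / (4 * n) * h)
            c = h / 2.0
            sum_b += b
            sum_c += c
    if not any_poly:
        return float("nan"), float("nan")
    return sum_b, sum_c


def fis_estimate(ds_cc: MicrosatDataset, rows=None) -> float:
    """Multilocus Weir & Cockerham f; NaN if all loci are monomorphic."""
    if rows is None:
        rows = np.arange(ds_cc.n_samples)
    if len(rows) < 2:
        raise ValueError("need >= 2 individuals")
    b, c = _wc_components(ds_cc, rows)
    if math.isnan(b):
        return float("nan")
    denom = b + c
    if denom == 0:
        return float("nan")
    return float(1.0 - c / denom)


def fis_randomization_test(ds_cc: MicrosatDataset, rows=None,
                           n_rand: int = 10_000,
                           seed: Optional[int] = None) -> tuple[float, float]:
    """(p_gt, p_lt): permute alleles among individuals within the stratum.

    p_gt = fraction of randomized f >= observed (heterozygote-deficit side),
    p_lt = fraction <= observed (excess side). Both include the observed
    arrangement via the (count + 1)/(n_rand + 1) convention.
    """
    if rows is None:
        rows = np.arange(ds_cc.n_samples)
    rows = np.asarray(rows)
    observed = fis_estimate(ds_cc, rows)
    if math.isnan(observed):
        return float("nan"), float("nan")
    rng = np.random.default_rng(seed)
    sub = ds_cc.genotypes[rows].copy()
    miss = sub[:, :, 0] == MISSING
    n_ge = n_le = 0
    work = MicrosatDataset(
        sample_ids=[f"s{i}" for i in range(len(rows))],
        sites=["x"] * len(rows), periods=["x"] * len(rows),
        locus_names=list(ds_cc.locus_names), genotypes=sub.copy(),
    )
    for _ in range(n_rand):
        geno = work.genotypes
        for j in range(ds_cc.n_loci):
            scored = ~miss[:, j]
            pool = sub[scored, j].ravel().copy()
            rng.shuffle(pool)
            geno[scored, j] = np.sort(pool.reshape(-1, 2), axis=1)
        f = fis_estimate(work)
        if f >= observed - 1e-12:
            n_ge += 1
        if f <= observed + 1e-12:
            n_le += 1
    return ((n_ge + 1) / (n_rand + 1), (n_le + 1) / (n_rand + 1))


# ---------------------------------------------------------------------------
# allele accumulation curves
# ---------------------------------------------------------------------------

def allele_accumulation(ds_cc: MicrosatDataset, rows=None,
                        n_perm: int = 10_000,
                        seed: Optional[int] = None) -> pd.DataFrame:
    """Mean and SD of cumulative distinct-allele count versus samples drawn.

    For each m = 1..N the number of distinct alleles (summed over loci) seen
    in the first m samples of a random sample order, averaged over ``n_perm``
    permutations (sampling without replacement — the rarefaction form of a
    species-accumulation curve applied to allele incidence).
    """
    if rows is None:
        rows = np.arange(ds_cc.n_samples)
    rows = np.asarray(rows)
    N = len(rows)
    if N < 2:
        raise ValueError("need >= 2 samples")
    # incidence matrix: sample x (locus, allele) present/absent
    cols: dict[tuple[int, int], int] = {}
    geno = ds_cc.genotypes[rows]
    for j in range(ds_cc.n_loci):
        for a in np.unique(geno[:, j][geno[:, j, 0] != MISSING].ravel()):
            cols[(j, int(a))] = len(cols)
    inc = np.zeros((N, len(cols)), dtype=bool)
    for i in range(N):
        for j in range(ds_cc.n_loci):
            a, b = geno[i, j]
            if a != MISSING:
                inc[i, cols[(j, int(a))]] = True
                inc[i, cols[(j, int(b))]] = True
    rng = np.random.default_rng(seed)
    sums = np.zeros(N)
    sq = np.zeros(N)
    for _ in range(n_perm):
        order = rng.permutation(N)
        seen = np.maximum.accumulate(inc[order], axis=0)
        k = seen.sum(axis=1).astype(float)
        sums += k
        sq += k ** 2
    mean = sums / n_perm
    var = np.maximum(sq / n_perm - mean ** 2, 0.0)
    return pd.DataFrame({"m": np.arange(1, N + 1), "mean_alleles": mean,
                         "sd_alleles": np.sqrt(var)})


# ---------------------------------------------------------------------------
# per-site diversity table
# ---------------------------------------------------------------------------

@dataclass
class DiversitySummary:
    site: str
    N: int
    G: int
    A_t: float
    A_r: float
    H_o: float
    H_e: float
    F_is: float
    p_gt: float
    p_lt: float


def site_diversity_table(ds_cc: MicrosatDataset, g_rarefy: int = 5,
                         n_rand: int = 1000,
                         seed: Optional[int] = None) -> pd.DataFrame:
    """Per-site diversity summary on clone-corrected data.

    Columns: site, N (clone-corrected individuals), A_t (mean alleles per
    locus), A_r (rarefied to ``g_rarefy`` diploids), H_o, H_e, F_is, and the
    two randomization p-values. Sites too small to rarefy get NaN A_r.
    """
    rows_out = []
    for k, (site, idx) in enumerate(ds_cc.by_site().items()):
        counts = allele_counts(ds_cc, idx)
        at = float(np.mean([len(t) for t in counts.values() if t]))
        try:
            ar = rarefied_richness(ds_cc, g=g_rarefy, rows=idx)
        except ValueError:
            ar = float("nan")
        het = heterozygosities(ds_cc, rows=idx)
        ho = float(het.loc[het["locus"] == "__mean__", "H_o"].iloc[0])
        he = float(het.loc[het["locus"] == "__mean__", "H_e"].iloc[0])
        fis = fis_estimate(ds_cc, idx) if len(idx) >= 2 else float("nan")
        if len(idx) >= 2 and not math.isnan(fis):
            sub_seed = None if seed is None else seed + k
            p_gt, p_lt = fis_randomization_test(ds_cc, idx, n_rand=n_rand,
                                                seed=sub_seed)
        else:
            p_gt = p_lt = float("nan")
        rows_out.append((site, len(idx), at, ar, ho, he, fis, p_gt, p_lt))
    return pd.DataFrame(rows_out, columns=["site", "N", "A_t", "A_r", "H_o",
                                           "H_e", "F_is", "p_gt", "p_lt"])
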