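"""Heterozygosity-excess bottleneck test and allele-frequency mode-shift.

After a recent crash in effective size, rare alleles are lost faster than
gene diversity, so for a while the observed heterozygosity He exceeds the
equilibrium heterozygosity Heq expected for the observed allele count k.
Heq's distribution conditional on k is obtained by coalescent simulation of
the sampled gene copies under a two-phase microsatellite mutation model
(TPM): each mutation is a single repeat step with probability ``p_smm``,
otherwise a multi-step change whose magnitude is geometric with a stated
variance and whose sign is equiprobable. The scaled mutation rate theta is
tuned by bisection so that simulated allele counts center on k, and
replicates are retained only when they yield exactly k alleles.

A one-tailed Wilcoxon signed-rank test across loci on the standardized
differences (He - mean Heq)/sd Heq gives the site-level excess probability.
The mode-shift test bins pooled allele frequencies into ten classes of width
0.1: at equilibrium the rarest class (0, 0.1] holds the most alleles
(L-shape); a spectrum whose modal class is elsewhere is "shifted".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import MISSING, MicrosatDataset


@dataclass
class TPMParams:
    """Two-phase mutation model parameters.

    ``p_smm`` is the proportion of strictly single-step mutations;
    ``var_geom`` the variance of the geometric magnitude distribution of the
    multi-step component. The geometric success probability q solves
    var = (1-q)/q^2, i.e. q = (sqrt(1 + 4 var) - 1) / (2 var), so the mean
    multi-step magnitude is 1/q (var_geom = 0.36 gives q ~ 0.781, mean step
    ~ 1.28 repeats).
    """

    p_smm: float = 0.0
    var_geom: float = 0.36

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_smm <= 1.0:
            raise ValueError("p_smm must be in [0, 1]")
        if self.var_geom < 0:
            raise ValueError("var_geom must be >= 0")

    @property
    def geom_q(self) -> float:
        v = self.var_geom
        if v == 0:
            return 1.0
        return (math.sqrt(1.0 + 4.0 * v) - 1.0) / (2.0 * v)


class ConditioningError(RuntimeError):
    """Raised when rejection sampling cannot hit the observed allele count."""


def _simulate_batch(n_genes: int, theta: float, params: TPMParams, B: int,
                    rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Coalescent batch: B replicates of n_genes gene copies under the TPM.

    Returns (k, He) arrays: allele counts and unbiased gene diversities.
    The genealogy is generated root-to-tips: while j lineages exist the
    interval is Exp(j(j-1)/2) in coalescent units, each lineage accumulating
    Poisson(theta/2 * t) mutations.
    """
    state = np.zeros((B, n_genes), dtype=np.int64)
    arangeB = np.arange(B)
    q = params.geom_q
    for j in range(2, n_genes + 1):
        # split a uniformly chosen lineage (j-1 -> j)
        src = rng.integers(0, j - 1, size=B)
        state[:, j - 1] = state[arangeB, src]
        t = rng.exponential(scale=2.0 / (j * (j - 1)), size=B)
        counts = rng.poisson(lam=(theta / 2.0) * t[:, None], size=(B, j))
        K = int(counts.sum())
        if K:
            if params.p_smm >= 1.0:
                mag = np.ones(K, dtype=np.int64)
            else:
                geom = rng.geometric(q, size=K) if q < 1.0 else np.ones(K, np.int64)
                mag = np.where(rng.random(K) < params.p_smm, 1, geom)
            steps = mag * rng.choice((-1, 1), size=K)
            flat = np.zeros(B * j, dtype=np.int64)
            cell = np.repeat(np.arange(B * j), counts.ravel())
            np.add.at(flat, cell, steps)
            state[:, :j] += flat.reshape(B, j)
    srt = np.sort(state, axis=1)
    new = np.ones((B, n_genes), dtype=bool)
    new[:, 1:] = srt[:, 1:] != srt[:, :-1]
    k = new.sum(axis=1)
    he = np.empty(B)
    for b in range(B):
        _, c = np.unique(state[b], return_counts=True)
        p = c / n_genes
        he[b] = 1.0 - (p ** 2).sum()
    he *= n_genes / (n_genes - 1)
    return k, he


@dataclass
class HeqDistribution:
    mean: float
    sd: float
    samples: np.ndarray
    theta: float


def simulate_heq(k_obs: int, n_genes: int, params: TPMParams | None = None,
                 iters: int = 10_000, seed: Optional[int] = None,
                 batch: int = 500, max_batches: int = 400) -> HeqDistribution:
    """Equilibrium heterozygosity distribution conditional on k_obs alleles.

    theta is tuned by bisection until the simulated mean allele count matches
    ``k_obs``, then replicates with exactly ``k_obs`` alleles are retained by
    rejection sampling until ``iters`` are collected.
    """
    if params is None:
        params = TPMParams()
    if k_obs < 2:
        raise ValueError("k_obs must be >= 2 (monomorphic loci are excluded)")
    if n_genes < k_obs:
        raise ValueError("n_genes must be >= k_obs")
    rng = np.random.default_rng(seed)

    def mean_k(theta: float, B: int = 300) -> float:
        k, _ = _simulate_batch(n_genes, theta, params, B, rng)
        return float(k.mean())

    lo, hi = 1e-3, 1.0
    while mean_k(hi) < k_obs and hi < 1e4:
        hi *= 4.0
    for _ in range(14):
        mid = math.sqrt(lo * hi)
        if mean_k(mid) < k_obs:
            lo = mid
        else:
            hi = mid
    theta = math.sqrt(lo * hi)

    kept: list[np.ndarray] = []
    n_kept = 0
    for _ in range(max_batches):
        k, he = _simulate_batch(n_genes, theta, params, batch, rng)
        sel = he[k == k_obs]
        if sel.size:
            kept.append(sel)
            n_kept += sel.size
        if n_kept >= iters:
            break
    if n_kept < max(10, iters // 20):
        raise ConditioningError(
            f"only {n_kept} replicates matched k={k_obs} within the budget"
        )
    samples = np.concatenate(kept)[:iters]
    return HeqDistribution(mean=float(samples.mean()),
                           sd=float(samples.std(ddof=1)),
                           samples=samples, theta=theta)


def heterozygote_excess_test(he_obs, heq_means, heq_sds) -> float:
    """One-tailed Wilcoxon signed-rank p for heterozygosity excess.

    The per-locus signed values are (He_obs - Heq_mean)/Heq_sd; the
    alternative is that they are shifted above zero. Returns NaN when all
    differences are zero (degenerate).
    """
    he_obs = np.asarray(he_obs, float)
    heq_means = np.asarray(heq_means, float)
    heq_sds = np.asarray(heq_sds, float)
    if len(he_obs) < 2:
        raise ValueError("need >= 2 usable loci")
    d = (he_obs - heq_means) / np.where(heq_sds > 0, heq_sds, np.nan)
    d = d[~np.isnan(d)]
    if len(d) < 2 or np.allclose(d, 0):
        return float("nan")
    return float(stats.wilcoxon(d, alternative="greater").pvalue)


def mode_shift(allele_frequencies) -> str:
    """Classify a pooled allele-frequency spectrum: 'L-shaped' or 'shifted'.

    Frequencies are binned into ten classes of width 0.1; the spectrum is
    L-shaped iff the rarest class (0, 0.1] contains at least as many alleles
    as any other class.
    """
    f = np.asarray(list(allele_frequencies), dtype=float)
    f = f[(f > 0) & (f < 1.0 + 1e-12)]
    if f.size == 0:
        raise ValueError("no polymorphic alleles")
    bins = np.minimum((np.ceil(f / 0.1) - 1).astype(int), 9)
    counts = np.bincount(bins, minlength=10)
    return "L-shaped" if counts[0] >= counts[1:].max() else "shifted"


@dataclass
class BottleneckResult:
    per_locus: pd.DataFrame  # locus, k_obs, n_genes, He_obs, Heq_mean, Heq_sd, std_diff
    wilcoxon_p: float
    mode_shift: str


def bottleneck_test(ds_cc: MicrosatDataset, rows=None,
                    params: TPMParams | None = None, iters: int = 10_000,
                    seed: Optional[int] = None) -> BottleneckResult:
    """Run the full heterozygosity-excess + mode-shift analysis on one
    stratum of clone-corrected data.

    Monomorphic loci are excluded. Sample size per locus is 2 x the number of
    clone-corrected individuals scored at that locus.
    """
    if params is None:
        params = TPMParams()
    if rows is None:
        rows = np.arange(ds_cc.n_samples)
    rows = np.asarray(rows)
    recs = []
    all_freqs: list[float] = []
    for j, locus in enumerate(ds_cc.locus_names):
        g = ds_cc.genotypes[rows, j]
        g = g[g[:, 0] != MISSING]
        n = len(g)
        if n < 2:
            continue
        alleles, counts = np.unique(g.ravel(), return_counts=True)
        p = counts / counts.sum()
        all_freqs.extend(p.tolist())
        k = len(alleles)
        if k < 2:
            continue
        n_genes = 2 * n
        he_obs = (1.0 - (p ** 2).sum()) * n_genes / (n_genes - 1)
        sub_seed = None if seed is None else seed + j
        heq = simulate_heq(k, n_genes, params, iters=iters, seed=sub_seed)
        std = (he_obs - heq.mean) / heq.sd if heq.sd > 0 else float("nan")
        recs.append((locus, k, n_genes, he_obs, heq.mean, heq.sd, std))
    per_locus = pd.DataFrame(recs, columns=["locus", "k_obs", "n_genes",
                                            "He_obs", "Heq_mean", "Heq_sd",
                                            "std_diff"])
    if len(per_locus) >= 2:
        p = heterozygote_excess_test(per_locus["He_obs"],
                                     per_locus["Heq_mean"],
                                     per_locus["Heq_sd"])
    else:
        p = float("nan")
    return BottleneckResult(per_locus=per_locus, wilcoxon_p=p,
                            mode_shift=mode_shift(all_freqs))
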