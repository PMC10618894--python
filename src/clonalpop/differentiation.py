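"""Population differentiation and ordination.

Jost's Dest measures actual allelic differentiation between populations on
the effective-number scale; it is computed per locus from Nei & Chesser's
unbiased within- and total-heterozygosity estimators and averaged over loci
(arithmetically by default, or via the harmonic-mean transformation).
AMOVA decomposes squared allele-identity distances between individuals into
hierarchical variance components whose ratios are Phi-statistics (reported
as F_st / F_sg here, as is conventional for allele-identity AMOVA).
PCoA embeds a site-level genetic distance matrix by Gower double-centering;
percent explained variation is taken over positive eigenvalues only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.spatial.distance import squareform

from .genotype_io import MISSING, MicrosatDataset


@dataclass
class DistanceMatrix:
    """Symmetric non-negative pairwise distances with entity labels."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("matrix must be symmetric")
        np.fill_diagonal(self.values, 0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


# ---------------------------------------------------------------------------
# allele frequencies per population
# ---------------------------------------------------------------------------

def _pop_freqs(ds: MicrosatDataset, idx: np.ndarray) -> dict[str, dict[int, float]]:
    out = {}
    for j, locus in enumerate(ds.locus_names):
        g = ds.genotypes[idx, j]
        g = g[g[:, 0] != MISSING]
        if len(g) == 0:
            out[locus] = {}
            continue
        alleles, counts = np.unique(g.ravel(), return_counts=True)
        out[locus] = {int(a): c / counts.sum() for a, c in zip(alleles, counts)}
    return out


# ---------------------------------------------------------------------------
# Jost's Dest
# ---------------------------------------------------------------------------

def _dest_locus(ds: MicrosatDataset, idx1: np.ndarray, idx2: np.ndarray,
                j: int) -> Optional[float]:
    """Per-locus D between two populations (Nei-Chesser unbiased Ht, Hs)."""
    gs = []
    for idx in (idx1, idx2):
        g = ds.genotypes[idx, j]
        g = g[g[:, 0] != MISSING]
        if len(g) < 2:
            return None
        gs.append(g)
    n1, n2 = len(gs[0]), len(gs[1])
    n_harm = 2.0 / (1.0 / n1 + 1.0 / n2)
    alleles = np.unique(np.concatenate([g.ravel() for g in gs]))
    P = np.zeros((2, len(alleles)))
    Ho = 0.0
    for i, g in enumerate(gs):
        for a_i, a in enumerate(alleles):
            P[i, a_i] = (g == a).sum() / (2 * len(g))
        Ho += (g[:, 0] != g[:, 1]).mean() / 2.0
    hs_raw = 1.0 - (P ** 2).sum(axis=1).mean()
    pbar = P.mean(axis=0)
    ht_raw = 1.0 - (pbar ** 2).sum()
    s = 2  # populations
    Hs = (n_harm / (n_harm - 1.0)) * (hs_raw - Ho / (2.0 * n_harm))
    Ht = ht_raw + Hs / (n_harm * s) - Ho / (2.0 * n_harm * s)
    if Hs >= 1.0:
        return None
    D = (s / (s - 1.0)) * (Ht - Hs) / (1.0 - Hs)
    return float(D)


def _dest_combined(ds: MicrosatDataset, idx1, idx2,
                   combine: str = "arithmetic") -> float:
    vals = []
    for j in range(ds.n_loci):
        d = _dest_locus(ds, idx1, idx2, j)
        if d is not None:
            vals.append(d)
    if not vals:
        return 0.0
    vals = np.asarray(vals)
    if combine == "arithmetic":
        return float(vals.mean())
    if combine == "harmonic":
        # transform to (1+D)/(1-D), harmonic-mean, back-transform
        v = np.clip(vals, -0.999999, 0.999999)
        t = (1.0 + v) / (1.0 - v)
        h = len(t) / (1.0 / t).sum()
        return float((h - 1.0) / (h + 1.0))
    raise ValueError("combine must be 'arithmetic' or 'harmonic'")


def dest_pairwise(ds_cc: MicrosatDataset, n_perm: int = 9999,
                  seed: Optional[int] = None,
                  combine: str = "arithmetic") -> tuple[DistanceMatrix, pd.DataFrame]:
    """Pairwise Dest between sites with permutation p-values.

    p is the fraction of permutations (individuals shuffled between the two
    sites) with Dest >= observed. Monomorphic pairs give D = 0, p = 1.
    Requires >= 2 sites with >= 2 individuals each.
    """
    by_site = {s: i for s, i in ds_cc.by_site().items() if len(i) >= 2}
    sites = list(by_site)
    if len(sites) < 2:
        raise ValueError("need >= 2 sites with >= 2 individuals")
    n = len(sites)
    D = np.zeros((n, n))
    P = np.full((n, n), np.nan)
    rng = np.random.default_rng(seed)
    for i1, i2 in combinations(range(n), 2):
        idx1, idx2 = by_site[sites[i1]], by_site[sites[i2]]
        obs = _dest_combined(ds_cc, idx1, idx2, combine)
        pooled = np.concatenate([idx1, idx2])
        n1 = len(idx1)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            if _dest_combined(ds_cc, perm[:n1], perm[n1:], combine) >= obs - 1e-12:
                count += 1
        D[i1, i2] = D[i2, i1] = max(obs, 0.0)
        P[i1, i2] = P[i2, i1] = count / n_perm if n_perm else float("nan")
    return (DistanceMatrix(labels=sites, values=D),
            pd.DataFrame(P, index=sites, columns=sites))


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

@dataclass
class AmovaResult:
    components: dict[str, float]  # variance components by level
    phi: dict[str, float]         # F_st (and F_sg when hierarchical)
    p_values: dict[str, float]
    n_perm: int


def _indicator_matrix(ds: MicrosatDataset, rows: np.ndarray,
                      interpolate_missing: bool,
                      strata: Optional[Sequence[str]] = None) -> np.ndarray:
    """Allele-dosage design matrix; squared distances follow as
    ||x_i - x_j||^2 / 2 (the Smouse-Peakall codominant genotype distance).

    Missing calls become the stratum's expected dosage (2 * frequency) when
    interpolating, else the pooled expectation.
    """
    blocks = []
    geno = ds.genotypes[rows]
    strat = np.asarray(strata if strata is not None else ["_"] * len(rows))
    for j in range(ds.n_loci):
        g = geno[:, j]
        scored = g[:, 0] != MISSING
        alleles = np.unique(g[scored].ravel())
        if len(alleles) == 0:
            continue
        dos = np.zeros((len(rows), len(alleles)))
        for a_i, a in enumerate(alleles):
            dos[:, a_i] = (g == a).sum(axis=1)
        if (~scored).any():
            for s in np.unique(strat):
                sel = (strat == s) & scored
                source = sel if interpolate_missing and sel.any() else scored
                expect = 2.0 * dos[source].mean(axis=0) / 2.0
                fill = (strat == s) & ~scored
                dos[fill] = expect
        blocks.append(dos)
    return np.hstack(blocks)


def _amova_ss(d2: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """(SS among listed groups decomposition) helper: returns SS_total and
    SS_within for a partition, from a squared-distance matrix."""
    n = len(groups)
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in np.unique(groups):
        sel = np.nonzero(groups == g)[0]
        sub = d2[np.ix_(sel, sel)]
        ss_within += sub.sum() / (2.0 * len(sel))
    return ss_total, ss_within


def _amova_components(d2: np.ndarray, sites: np.ndarray,
                      groups: Optional[np.ndarray]) -> tuple[dict, dict]:
    """Excoffier-style variance components from squared distances.

    One level: sites only. Two levels: sites nested in groups.
    """
    n = len(sites)
    site_labels, site_sizes = np.unique(sites, return_counts=True)
    ss_total, ss_within_sites = _amova_ss(d2, sites)
    df_total = n - 1
    if groups is None:
        s = len(site_labels)
        df_among, df_within = s - 1, n - s
        ss_among = ss_total - ss_within_sites
        sigma_w = ss_within_sites / df_within
        n0 = (n - (site_sizes ** 2).sum() / n) / (s - 1)
        sigma_a = (ss_among / df_among - sigma_w) / n0
        total = sigma_a + sigma_w
        comp = {"among_sites": sigma_a, "within_sites": sigma_w}
        phi = {"F_st": sigma_a / total if total > 0 else float("nan")}
        return comp, phi
    # hierarchical: groups / sites within groups / within sites
    g_labels = np.unique(groups)
    s = len(site_labels)
    g_count = len(g_labels)
    _, ss_within_groups = _amova_ss(d2, groups)
    ss_groups = ss_total - ss_within_groups
    ss_sites_in_groups = ss_within_groups - ss_within_sites
    df_g, df_sg, df_w = g_count - 1, s - g_count, n - s
    sigma_w = ss_within_sites / df_w
    # coefficients (Excoffier et al. 1992 unequal-size formulation)
    site_of = {}
    for lab in site_labels:
        gsel = np.unique(np.asarray(groups)[sites == lab])
        site_of[lab] = gsel[0]
    n_sizes = {lab: int((sites == lab).sum()) for lab in site_labels}
    g_sizes = {g: int((groups == g).sum()) for g in g_labels}
    sum_n2_over_g = sum(
        sum(n_sizes[lab] ** 2 for lab in site_labels if site_of[lab] == g) / g_sizes[g]
        for g in g_labels
    )
    n_prime = (n - sum_n2_over_g) / df_sg
    sum_n2 = sum(v ** 2 for v in n_sizes.values())
    n_dprime = (sum_n2_over_g - sum_n2 / n) / df_g
    n_g = (n - sum(v ** 2 for v in g_sizes.values()) / n) / df_g
    sigma_b = (ss_sites_in_groups / df_sg - sigma_w) / n_prime
    sigma_a = (ss_groups / df_g - sigma_w - n_dprime * sigma_b) / n_g
    total = sigma_a + sigma_b + sigma_w
    comp = {"among_groups": sigma_a, "among_sites_within_groups": sigma_b,
            "within_sites": sigma_w}
    phi = {
        "F_ct": sigma_a / total if total > 0 else float("nan"),
        "F_sg": sigma_b / (sigma_b + sigma_w) if (sigma_b + sigma_w) > 0 else float("nan"),
        "F_st": (sigma_a + sigma_b) / total if total > 0 else float("nan"),
    }
    return comp, phi


def amova_fst(ds_cc: MicrosatDataset, groups: Optional[Sequence[str]] = None,
              n_perm: int = 999, seed: Optional[int] = None,
              interpolate_missing: bool = True) -> AmovaResult:
    """AMOVA over sites (optionally nested in groups, e.g. sampling periods).

    ``groups`` maps each sample to a higher-level group label (same length
    as the dataset); None gives the one-level analysis. Sites with a single
    individual are dropped with a warning. Significance per statistic comes
    from the standard permutation schemes: individuals among sites (F_st,
    one-level and F_sg), whole sites among groups (F_ct).
    """
    import warnings as _warnings

    sites_all = np.asarray(ds_cc.sites)
    keep = np.ones(ds_cc.n_samples, dtype=bool)
    for lab, cnt in zip(*np.unique(sites_all, return_counts=True)):
        if cnt < 2:
            _warnings.warn(f"site {lab} has one individual; dropped from AMOVA")
            keep &= sites_all != lab
    rows = np.nonzero(keep)[0]
    sites = sites_all[rows]
    if len(np.unique(sites)) < 2:
        raise ValueError("need >= 2 sites")
    grp = None if groups is None else np.asarray(groups)[rows]

    X = _indicator_matrix(ds_cc, rows, interpolate_missing, strata=sites)
    sq = (X ** 2).sum(axis=1)
    d2 = (sq[:, None] + sq[None, :] - 2.0 * X @ X.T) / 2.0
    np.fill_diagonal(d2, 0.0)
    d2 = np.maximum(d2, 0.0)

    comp, phi = _amova_components(d2, sites, grp)
    rng = np.random.default_rng(seed)
    p_values: dict[str, float] = {}
    n = len(rows)
    if n_perm > 0:
        # F_st (and one-level sigma_a): permute individuals among sites
        count_st = 0
        count_sg = 0
        for _ in range(n_perm):
            perm_sites = sites[rng.permutation(n)]
            c_p, phi_p = _amova_components(d2, perm_sites, grp)
            if phi_p["F_st"] >= phi["F_st"] - 1e-12:
                count_st += 1
            if grp is not None and phi_p.get("F_sg", -np.inf) >= phi["F_sg"] - 1e-12:
                count_sg += 1
        p_values["F_st"] = (count_st + 1) / (n_perm + 1)
        if grp is not None:
            p_values["F_sg"] = (count_sg + 1) / (n_perm + 1)
            # F_ct: permute whole sites among groups
            site_labels = np.unique(sites)
            group_of = {lab: grp[sites == lab][0] for lab in site_labels}
            glabs = np.array([group_of[lab] for lab in site_labels])
            count_ct = 0
            for _ in range(n_perm):
                shuffled = glabs[rng.permutation(len(glabs))]
                gmap = dict(zip(site_labels, shuffled))
                perm_grp = np.array([gmap[s] for s in sites])
                _, phi_p = _amova_components(d2, sites, perm_grp)
                if phi_p["F_ct"] >= phi["F_ct"] - 1e-12:
                    count_ct += 1
            p_values["F_ct"] = (count_ct + 1) / (n_perm + 1)
    return AmovaResult(components=comp, phi=phi, p_values=p_values,
                       n_perm=n_perm)


# ---------------------------------------------------------------------------
# Nei (1972) standard genetic distance
# ---------------------------------------------------------------------------

def nei_distance(freqs_a: dict[str, dict[int, float]],
                 freqs_b: dict[str, dict[int, float]]) -> float:
    """Nei's standard distance D = -ln(Jxy / sqrt(Jx * Jy)), identities
    summed over the shared locus set. Returns inf when the populations share
    no alleles (zero identity)."""
    shared = [l for l in freqs_a if l in freqs_b and freqs_a[l] and freqs_b[l]]
    if not shared:
        raise ValueError("no shared loci")
    jxy = jx = jy = 0.0
    for locus in shared:
        fa, fb = freqs_a[locus], freqs_b[locus]
        jx += sum(v * v for v in fa.values())
        jy += sum(v * v for v in fb.values())
        jxy += sum(fa[a] * fb.get(a, 0.0) for a in fa)
    if jxy <= 0:
        return math.inf
    return float(-math.log(jxy / math.sqrt(jx * jy)))


def nei_distance_matrix(ds_cc: MicrosatDataset) -> DistanceMatrix:
    by_site = ds_cc.by_site()
    sites = list(by_site)
    freqs = {s: _pop_freqs(ds_cc, idx) for s, idx in by_site.items()}
    n = len(sites)
    M = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        M[i, j] = M[j, i] = nei_distance(freqs[sites[i]], freqs[sites[j]])
    return DistanceMatrix(labels=sites, values=M)


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

@dataclass
class PcoaResult:
    labels: list[str]
    coordinates: np.ndarray       # (n, n_pos_axes), scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray       # all eigenvalues, descending
    percent_explained: np.ndarray  # per positive axis, of positive-eigenvalue sum


def pcoa(dist: DistanceMatrix) -> PcoaResult:
    """Classical multidimensional scaling (Gower double-centering).

    Negative eigenvalues (possible for non-Euclidean genetic distances) are
    dropped from both the coordinates and the explained-variation
    denominator. Ties in eigenvalues are ordered stably.
    """
    D = dist.values
    n = len(dist.labels)
    if n < 3:
        raise ValueError("need >= 3 entities")
    A = -0.5 * D ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = J @ A @ J
    B = (B + B.T) / 2.0
    vals, vecs = eigh(B)
    order = np.argsort(-vals, kind="stable")
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > max(1e-10, 1e-9 * abs(vals).max())
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    percent = 100.0 * vals[pos] / vals[pos].sum()
    return PcoaResult(labels=list(dist.labels), coordinates=coords,
                      eigenvalues=vals, percent_explained=percent)
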