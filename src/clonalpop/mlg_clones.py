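"""Multilocus genotype (MLG) assignment, clonal-identity tests, clone records.

In clonal plants, repeated observations of the same multilocus genotype are
candidate members of one genet. Samples are grouped by complete allele matches
at all co-scored loci, with a deterministic merge rule for samples that could
not be scored at every locus. Whether a repeated MLG is plausibly one clone
(rather than repeated sexual production of the same genotype) is judged with
psex: the binomial probability of drawing the genotype as many times as it was
observed given its per-genotype probability pgen under random mating.

Allele frequencies for pgen are clone-corrected by the round-robin scheme:
for each locus, MLGs are re-identified with that locus left out, and the
locus's frequencies are counted over one representative per reduced MLG. This
avoids the circularity of using clonal copies to estimate the frequencies used
to judge clonality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import MISSING, CoordinatesMissingError, MicrosatDataset

DEFAULT_PSEX_THRESHOLD = 0.01


class MLGError(ValueError):
    pass


@dataclass
class MLGAssignment:
    """Mapping of samples to MLGs with clonal-identity evidence.

    ``mlg_of`` maps sample_id -> mlg_id; ``members`` maps mlg_id -> sample_id
    list; ``psex`` holds the multiple-encounter probability for each MLG
    observed at least twice (pooled-data frequencies unless per-site was
    requested). ``flagged`` lists samples whose missing-data merge was
    ambiguous (kept as their own MLG) or that had too few scored loci.
    """

    mlg_of: dict[str, str]
    members: dict[str, list[str]]
    flagged: list[str] = field(default_factory=list)
    psex: dict[str, float] = field(default_factory=dict)

    @property
    def n_mlg(self) -> int:
        return len(self.members)

    def counts(self) -> pd.Series:
        """MLG abundance (number of shoots per MLG)."""
        return pd.Series({m: len(v) for m, v in self.members.items()},
                         name="n_obs").sort_index()

    def table(self) -> pd.DataFrame:
        rows = []
        for sid, mid in self.mlg_of.items():
            rows.append((sid, mid, len(self.members[mid]),
                         self.psex.get(mid, np.nan)))
        return pd.DataFrame(rows, columns=["sample_id", "mlg_id", "n_obs", "psex"])


def _compatible(g1: np.ndarray, g2: np.ndarray) -> tuple[bool, int]:
    """Match at every co-scored locus; returns (compatible, n co-scored)."""
    scored = (g1[:, 0] != MISSING) & (g2[:, 0] != MISSING)
    if not scored.any():
        return False, 0
    same = (g1[scored] == g2[scored]).all()
    return bool(same), int(scored.sum())


def assign_mlgs(ds: MicrosatDataset, min_scored_loci: int = 7) -> MLGAssignment:
    """Group samples into MLGs by complete allele matches at co-scored loci.

    Samples with no missing data are grouped by exact genotype. Samples with
    missing loci are then merged into an existing MLG only when (a) they match
    it at every co-scored locus, (b) they share at least ``min_scored_loci``
    scored loci with it, and (c) exactly one MLG is compatible; an ambiguous
    sample (>= 2 compatible MLGs) is kept as its own MLG and flagged for
    review. Samples scored at fewer than ``min_scored_loci`` loci are flagged
    as unassigned (their mlg_id is ``"unassigned:<sample_id>"``).

    Raises :class:`MLGError` if a sample has all loci missing.
    """
    if min_scored_loci < 1:
        raise MLGError("min_scored_loci must be >= 1")
    miss = ds.missing_mask()
    if (miss.all(axis=1)).any():
        bad = [s for s, m in zip(ds.sample_ids, miss.all(axis=1)) if m]
        raise MLGError(f"all loci missing for sample(s): {bad}")

    n_scored = (~miss).sum(axis=1)
    mlg_of: dict[str, str] = {}
    members: dict[str, list[str]] = {}
    flagged: list[str] = []
    reps: dict[str, np.ndarray] = {}  # mlg_id -> representative genotype
    counter = 0

    def new_mlg(i: int) -> None:
        nonlocal counter
        counter += 1
        mid = f"MLG{counter:04d}"
        mlg_of[ds.sample_ids[i]] = mid
        members[mid] = [ds.sample_ids[i]]
        reps[mid] = ds.genotypes[i]

    # pass 1: complete genotypes, grouped exactly
    complete = [i for i in range(ds.n_samples) if not miss[i].any()]
    seen: dict[bytes, str] = {}
    for i in complete:
        key = ds.genotypes[i].tobytes()
        if key in seen:
            mid = seen[key]
            mlg_of[ds.sample_ids[i]] = mid
            members[mid].append(ds.sample_ids[i])
        else:
            new_mlg(i)
            seen[key] = mlg_of[ds.sample_ids[i]]

    # pass 2: incomplete genotypes, fewest-missing first (deterministic order)
    incomplete = sorted(
        (i for i in range(ds.n_samples) if miss[i].any()),
        key=lambda i: (int(miss[i].sum()), ds.sample_ids[i]),
    )
    for i in incomplete:
        sid = ds.sample_ids[i]
        if n_scored[i] < min_scored_loci:
            mid = f"unassigned:{sid}"
            mlg_of[sid] = mid
            members[mid] = [sid]
            flagged.append(sid)
            continue
        hits = []
        for mid, rep in reps.items():
            ok, shared = _compatible(ds.genotypes[i], rep)
            if ok and shared >= min_scored_loci:
                hits.append(mid)
        if len(hits) == 1:
            mlg_of[sid] = hits[0]
            members[hits[0]].append(sid)
        else:
            if len(hits) >= 2:
                flagged.append(sid)
            new_mlg(i)
    return MLGAssignment(mlg_of=mlg_of, members=members, flagged=flagged)


# ---------------------------------------------------------------------------
# allele frequencies and psex
# ---------------------------------------------------------------------------

@dataclass
class AlleleFrequencyTable:
    """Per-stratum, per-locus allele -> frequency mapping.

    ``freqs[stratum][locus]`` is a dict allele -> frequency summing to 1.
    The stratum ``"__all__"`` pools every sample.
    """

    freqs: dict[str, dict[str, dict[int, float]]]

    def locus(self, locus: str, stratum: str = "__all__") -> dict[int, float]:
        return self.freqs[stratum][locus]


POOLED = "__all__"


def _count_freqs(ds: MicrosatDataset, rows: np.ndarray, locus_j: int) -> dict[int, float]:
    g = ds.genotypes[rows, locus_j]
    g = g[g[:, 0] != MISSING]
    if g.size == 0:
        raise MLGError(f"no scored samples at locus {ds.locus_names[locus_j]}")
    alleles, counts = np.unique(g.ravel(), return_counts=True)
    total = counts.sum()
    return {int(a): c / total for a, c in zip(alleles, counts)}


def round_robin_frequencies(
    ds: MicrosatDataset,
    mlgs: Optional[MLGAssignment] = None,
    per_site: bool = True,
    min_scored_loci: int = 1,
) -> AlleleFrequencyTable:
    """Round-robin clone-corrected allele frequencies.

    For each locus, MLGs are re-identified on the dataset with that locus
    excluded; one representative per reduced MLG (the sample with fewest
    missing loci, ties by id) contributes to the locus's allele counts, which
    are then normalized. Frequencies are computed per site and pooled.
    """
    strata: dict[str, np.ndarray] = {POOLED: np.arange(ds.n_samples)}
    if per_site:
        strata.update(ds.by_site())
    out: dict[str, dict[str, dict[int, float]]] = {s: {} for s in strata}
    miss_count = ds.missing_mask().sum(axis=1)
    for j, locus in enumerate(ds.locus_names):
        reduced = ds.subset_loci([l for l in ds.locus_names if l != locus])
        for stratum, rows in strata.items():
            sub = reduced.subset(rows)
            asn = assign_mlgs(sub, min_scored_loci=min(min_scored_loci,
                                                       sub.n_loci))
            rep_rows = []
            pos = {sid: i for i, sid in enumerate(ds.sample_ids)}
            for mid, mem in asn.members.items():
                best = min(mem, key=lambda s: (miss_count[pos[s]], s))
                rep_rows.append(pos[best])
            out[stratum][locus] = _count_freqs(ds, np.asarray(rep_rows), j)
    return AlleleFrequencyTable(freqs=out)


def pgen(genotype: np.ndarray, freqs: dict[str, dict[int, float]] | AlleleFrequencyTable,
         locus_names: list[str] | None = None, stratum: str = POOLED) -> float:
    """Probability of one multilocus genotype under random mating.

    Product over scored loci of ``f_a * f_b * 2**h`` (h = 1 for heterozygotes).
    MISSING loci are skipped. Raises :class:`MLGError` for alleles absent from
    the frequency table.
    """
    if isinstance(freqs, AlleleFrequencyTable):
        freqs = freqs.freqs[stratum]
    if locus_names is None:
        locus_names = list(freqs.keys())
    genotype = np.asarray(genotype)
    p = 1.0
    for j, locus in enumerate(locus_names):
        a, b = int(genotype[j, 0]), int(genotype[j, 1])
        if a == MISSING:
            continue
        table = freqs[locus]
        if a not in table or b not in table:
            raise MLGError(f"allele absent from frequency table at {locus}")
        term = table[a] * table[b]
        if a != b:
            term *= 2.0
        p *= term
    return p


def psex_multiple(pgen_value: float, n_obs: int, n_samples: int) -> float:
    """P(seeing an MLG >= n_obs times in n_samples draws | pgen).

    Binomial upper tail ``P(X >= n_obs)`` with ``X ~ Bin(n_samples, pgen)``.
    Values below a threshold (conventionally 0.01) support clonal identity of
    the repeats.
    """
    if not 0.0 <= pgen_value <= 1.0:
        raise MLGError("pgen must be in [0, 1]")
    if n_obs < 2 or n_obs > n_samples:
        raise MLGError("need 2 <= n_obs <= n_samples")
    return float(stats.binom.sf(n_obs - 1, n_samples, pgen_value))


def attach_psex(ds: MicrosatDataset, mlgs: MLGAssignment,
                freqs: Optional[AlleleFrequencyTable] = None,
                per_site: bool = False) -> MLGAssignment:
    """Compute psex for every MLG observed >= 2 times; fills ``mlgs.psex``.

    With ``per_site=True`` the frequencies of the MLG's own (first) site are
    used; otherwise pooled frequencies.
    """
    if freqs is None:
        freqs = round_robin_frequencies(ds, mlgs, per_site=per_site)
    pos = {sid: i for i, sid in enumerate(ds.sample_ids)}
    for mid, mem in mlgs.members.items():
        if len(mem) < 2:
            continue
        i = pos[mem[0]]
        stratum = ds.sites[i] if per_site else POOLED
        pg = pgen(ds.genotypes[i], freqs, ds.locus_names, stratum=stratum)
        mlgs.psex[mid] = psex_multiple(pg, len(mem), ds.n_samples)
    return mlgs


# ---------------------------------------------------------------------------
# clone correction and clone records
# ---------------------------------------------------------------------------

def collapse_clones(ds: MicrosatDataset, mlgs: MLGAssignment,
                    scope: str = "per_site") -> MicrosatDataset:
    """One representative per MLG (per site for ``per_site`` scope, else one
    per MLG globally). The representative is the sample with fewest missing
    loci, ties broken by sample_id."""
    if scope not in ("per_site", "global"):
        raise MLGError("scope must be 'per_site' or 'global'")
    miss_count = ds.missing_mask().sum(axis=1)
    pos = {sid: i for i, sid in enumerate(ds.sample_ids)}
    keep: list[int] = []
    groups: dict[tuple, list[str]] = {}
    for sid, mid in mlgs.mlg_of.items():
        key = (mid, ds.sites[pos[sid]]) if scope == "per_site" else (mid,)
        groups.setdefault(key, []).append(sid)
    for key, mem in groups.items():
        best = min(mem, key=lambda s: (miss_count[pos[s]], s))
        keep.append(pos[best])
    keep.sort()
    return ds.subset(keep)


@dataclass
class CloneRecord:
    """Abundance and spatial extent of one MLG, per period and combined."""

    mlg_id: str
    n_shoots: dict[str, int]
    max_extent: dict[str, float]  # meters; includes key "combined"
    sites: set[str]


def clone_records(ds: MicrosatDataset, mlgs: MLGAssignment) -> list[CloneRecord]:
    """Shoot counts, max pairwise sample distance per period and overall, and
    the site set, for every MLG. Requires coordinates."""
    xy = ds.coords()  # raises CoordinatesMissingError when absent
    pos = {sid: i for i, sid in enumerate(ds.sample_ids)}
    records = []
    for mid in sorted(mlgs.members):
        mem = mlgs.members[mid]
        idx = np.array([pos[s] for s in mem])
        periods = [ds.periods[i] for i in idx]
        n_shoots: dict[str, int] = {}
        max_extent: dict[str, float] = {}
        for per in dict.fromkeys(periods):
            sub = idx[[p == per for p in periods]]
            n_shoots[per] = len(sub)
            max_extent[per] = _max_pairwise(xy[sub])
        max_extent["combined"] = _max_pairwise(xy[idx])
        records.append(CloneRecord(
            mlg_id=mid, n_shoots=n_shoots, max_extent=max_extent,
            sites={ds.sites[i] for i in idx},
        ))
    return records


def _max_pairwise(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    from scipy.spatial.distance import pdist
    return float(pdist(points).max())


def clone_record_table(records: list[CloneRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        for per, n in r.n_shoots.items():
            rows.append((r.mlg_id, per, n, r.max_extent[per],
                         r.max_extent["combined"], ";".join(sorted(r.sites))))
    return pd.DataFrame(rows, columns=["mlg_id", "period", "n_shoots",
                                       "max_extent_m", "combined_extent_m",
                                       "sites"])
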