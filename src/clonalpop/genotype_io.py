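"""Microsatellite genotype tables: the core dataset container and file dialects.

The universal input for every analysis in this package is a table of
co-dominant diploid allele calls (fragment sizes, positive integers) for a set
of samples at a set of loci, together with per-sample metadata: a site label,
a sampling-period label (e.g. ``pre`` / ``post``), and optional projected
coordinates in meters.

Three on-disk dialects are supported:

``tidy_csv``
    One row per sample × locus: columns ``sample_id, site, period, easting,
    northing, locus, allele1, allele2``. Blank allele cells mean missing.
``genalex``
    GenAlEx co-dominant CSV: two header rows (counts then column names), two
    columns per locus, missing encoded as ``0``.
``genepop``
    Classic genepop text: title line, locus names, ``Pop`` blocks, six-digit
    genotypes (``0000``/``000000`` missing). Site labels are taken from the
    identifier before the comma; period/coordinates are not representable and
    round-trip through a sidecar only when written by this package.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel allele value for a missing locus call. A call is either both
#: alleles present or both missing; one-sided calls are coerced to missing.
MISSING = 0

DIALECTS = ("tidy_csv", "genalex", "genepop")


class GenotypeIOError(ValueError):
    """Raised for malformed genotype files or invalid dataset construction."""


class CoordinatesMissingError(ValueError):
    """Raised when a spatial operation needs coordinates that are absent."""


@dataclass
class MicrosatDataset:
    """Samples × loci diploid microsatellite calls with site/period metadata.

    Parameters
    ----------
    sample_ids :
        Unique sample identifiers, length ``n_samples``.
    sites :
        Site label per sample.
    periods :
        Sampling-period label per sample (free labels; ``pre``/``post`` by
        convention).
    locus_names :
        Ordered locus names, length ``n_loci``.
    genotypes :
        Integer array of shape ``(n_samples, n_loci, 2)``. Allele sizes are
        positive; a missing call is ``(0, 0)``. Pairs are stored in canonical
        ``(min, max)`` order.
    easting, northing :
        Optional projected coordinates in meters (NaN where unknown).
    """

    sample_ids: list[str]
    sites: list[str]
    periods: list[str]
    locus_names: list[str]
    genotypes: np.ndarray
    easting: Optional[np.ndarray] = None
    northing: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int64)
        n, L = len(self.sample_ids), len(self.locus_names)
        if self.genotypes.shape != (n, L, 2):
            raise GenotypeIOError(
                f"genotypes shape {self.genotypes.shape} != ({n}, {L}, 2)"
            )
        if len(set(self.sample_ids)) != n:
            dupes = pd.Series(self.sample_ids)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise GenotypeIOError(f"duplicate sample ids: {dupes}")
        if len(self.sites) != n or len(self.periods) != n:
            raise GenotypeIOError("sites/periods length mismatch")
        if (self.genotypes < 0).any():
            raise GenotypeIOError("negative allele size")
        # enforce the both-or-neither rule and canonical (min, max) order
        half = (self.genotypes == MISSING).sum(axis=2) == 1
        if half.any():
            ns, ls = np.nonzero(half)
            for i, j in zip(ns, ls):
                logger.warning(
                    "half-called locus %s for sample %s coerced to MISSING",
                    self.locus_names[j], self.sample_ids[i],
                )
            self.genotypes[half] = MISSING
        self.genotypes = np.sort(self.genotypes, axis=2)
        for arr_name in ("easting", "northing"):
            arr = getattr(self, arr_name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != (n,):
                    raise GenotypeIOError(f"{arr_name} length mismatch")
                setattr(self, arr_name, arr)

    # -- basic properties ---------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_samples, n_loci) array, True where the call is missing."""
        return self.genotypes[:, :, 0] == MISSING

    def has_coordinates(self) -> bool:
        return (
            self.easting is not None
            and self.northing is not None
            and not np.isnan(self.easting).any()
            and not np.isnan(self.northing).any()
        )

    def coords(self) -> np.ndarray:
        """(n_samples, 2) easting/northing; raises if any are absent."""
        if not self.has_coordinates():
            raise CoordinatesMissingError(
                "dataset has no (complete) coordinates; spatial operations "
                "require easting/northing for every sample"
            )
        return np.column_stack([self.easting, self.northing])

    def subset(self, index: Sequence[int] | np.ndarray) -> "MicrosatDataset":
        """New dataset restricted to the given sample positions (in order)."""
        index = np.asarray(index, dtype=int)
        return MicrosatDataset(
            sample_ids=[self.sample_ids[i] for i in index],
            sites=[self.sites[i] for i in index],
            periods=[self.periods[i] for i in index],
            locus_names=list(self.locus_names),
            genotypes=self.genotypes[index].copy(),
            easting=None if self.easting is None else self.easting[index].copy(),
            northing=None if self.northing is None else self.northing[index].copy(),
        )

    def subset_loci(self, loci: Sequence[str]) -> "MicrosatDataset":
        idx = [self.locus_names.index(l) for l in loci]
        return MicrosatDataset(
            sample_ids=list(self.sample_ids),
            sites=list(self.sites),
            periods=list(self.periods),
            locus_names=list(loci),
            genotypes=self.genotypes[:, idx].copy(),
            easting=None if self.easting is None else self.easting.copy(),
            northing=None if self.northing is None else self.northing.copy(),
        )

    def by_site(self) -> dict[str, np.ndarray]:
        """Site label -> array of sample positions, in first-appearance order."""
        out: dict[str, list[int]] = {}
        for i, s in enumerate(self.sites):
            out.setdefault(s, []).append(i)
        return {k: np.asarray(v) for k, v in out.items()}

    def by_period(self) -> dict[str, np.ndarray]:
        out: dict[str, list[int]] = {}
        for i, p in enumerate(self.periods):
            out.setdefault(p, []).append(i)
        return {k: np.asarray(v) for k, v in out.items()}

    def to_frame(self) -> pd.DataFrame:
        """Tidy one-row-per-sample-per-locus DataFrame (the tidy_csv layout)."""
        rows = []
        e = self.easting if self.easting is not None else np.full(self.n_samples, np.nan)
        n_ = self.northing if self.northing is not None else np.full(self.n_samples, np.nan)
        for i, sid in enumerate(self.sample_ids):
            for j, loc in enumerate(self.locus_names):
                a, b = self.genotypes[i, j]
                rows.append(
                    (sid, self.sites[i], self.periods[i], e[i], n_[i], loc,
                     a if a != MISSING else pd.NA, b if b != MISSING else pd.NA)
                )
        return pd.DataFrame(
            rows,
            columns=["sample_id", "site", "period", "easting", "northing",
                     "locus", "allele1", "allele2"],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MicrosatDataset):
            return NotImplemented
        coords_eq = True
        for a, b in ((self.easting, other.easting), (self.northing, other.northing)):
            an = a is None or np.isnan(np.asarray(a, float)).all()
            bn = b is None or np.isnan(np.asarray(b, float)).all()
            if an != bn:
                coords_eq = False
            elif not an:
                coords_eq = coords_eq and np.allclose(a, b, equal_nan=True)
        return (
            coords_eq
            and self.sample_ids == other.sample_ids
            and self.sites == other.sites
            and self.periods == other.periods
            and self.locus_names == other.locus_names
            and np.array_equal(self.genotypes, other.genotypes)
        )


@dataclass
class MissingnessSummary:
    """Missing-data proportions: overall, per locus, and per sample."""

    fraction_missing_overall: float
    per_locus: pd.Series
    per_sample: pd.Series


def summarize_missing(ds: MicrosatDataset) -> MissingnessSummary:
    """Proportions of missing locus calls overall, per locus, and per sample."""
    if ds.n_samples == 0 or ds.n_loci == 0:
        raise GenotypeIOError("cannot summarize an empty dataset")
    miss = ds.missing_mask()
    return MissingnessSummary(
        fraction_missing_overall=float(miss.mean()),
        per_locus=pd.Series(miss.mean(axis=0), index=ds.locus_names),
        per_sample=pd.Series(miss.mean(axis=1), index=ds.sample_ids),
    )


# ---------------------------------------------------------------------------
# tidy_csv
# ---------------------------------------------------------------------------

def _read_tidy_csv(path: Path) -> MicrosatDataset:
    df = pd.read_csv(path, dtype={"sample_id": str, "site": str, "period": str,
                                  "locus": str})
    required = {"sample_id", "site", "period", "locus", "allele1", "allele2"}
    if not required.issubset(df.columns):
        raise GenotypeIOError(f"tidy_csv needs columns {sorted(required)}")
    locus_names = list(pd.unique(df["locus"]))
    sample_ids = list(pd.unique(df["sample_id"]))
    meta = df.drop_duplicates("sample_id").set_index("sample_id")
    n, L = len(sample_ids), len(locus_names)
    geno = np.zeros((n, L, 2), dtype=np.int64)
    sidx = {s: i for i, s in enumerate(sample_ids)}
    lidx = {l: j for j, l in enumerate(locus_names)}
    for row in df.itertuples(index=False):
        i, j = sidx[row.sample_id], lidx[row.locus]
        geno[i, j] = [_allele_token(row.allele1), _allele_token(row.allele2)]
    has_xy = {"easting", "northing"}.issubset(df.columns)
    return MicrosatDataset(
        sample_ids=sample_ids,
        sites=[str(meta.loc[s, "site"]) for s in sample_ids],
        periods=[str(meta.loc[s, "period"]) for s in sample_ids],
        locus_names=locus_names,
        genotypes=geno,
        easting=meta.loc[sample_ids, "easting"].to_numpy(float) if has_xy else None,
        northing=meta.loc[sample_ids, "northing"].to_numpy(float) if has_xy else None,
    )


def _allele_token(tok) -> int:
    if tok is None or (isinstance(tok, float) and np.isnan(tok)) or tok is pd.NA:
        return MISSING
    if isinstance(tok, str):
        tok = tok.strip()
        if tok == "" or tok.lower() in {"na", "nan"}:
            return MISSING
    try:
        val = int(float(tok)) if float(tok) == int(float(tok)) else None
    except (TypeError, ValueError):
        val = None
    if val is None or val < 0:
        raise GenotypeIOError(f"non-integer allele token: {tok!r}")
    return val


def _write_tidy_csv(ds: MicrosatDataset, path: Path) -> None:
    ds.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# GenAlEx co-dominant CSV
# ---------------------------------------------------------------------------

def _read_genalex(path: Path) -> MicrosatDataset:
    raw = [line.rstrip("\n").split(",") for line in
           Path(path).read_text().splitlines() if line.strip() != ""]
    if len(raw) < 3:
        raise GenotypeIOError("genalex file too short")
    try:
        n_loci = int(raw[0][0])
        n_samples = int(raw[0][1])
    except (IndexError, ValueError) as exc:
        raise GenotypeIOError("genalex header row 1 must start with counts") from exc
    header = raw[1]
    locus_names = [header[2 + 2 * j].strip() for j in range(n_loci)]
    body = raw[2:2 + n_samples]
    if len(body) < n_samples:
        raise GenotypeIOError("genalex sample rows fewer than declared")
    sample_ids, sites, geno = [], [], np.zeros((n_samples, n_loci, 2), np.int64)
    for i, row in enumerate(body):
        sample_ids.append(row[0].strip())
        sites.append(row[1].strip())
        for j in range(n_loci):
            geno[i, j] = [_allele_token(row[2 + 2 * j]), _allele_token(row[3 + 2 * j])]
    # period / coordinates live in optional trailing columns written by us
    extra = header[2 + 2 * n_loci:]
    periods = ["all"] * n_samples
    easting = northing = None
    if extra[:1] == ["period"]:
        periods = [row[2 + 2 * n_loci].strip() for row in body]
        if extra[1:3] == ["easting", "northing"]:
            easting = np.array([_float_or_nan(row[3 + 2 * n_loci]) for row in body])
            northing = np.array([_float_or_nan(row[4 + 2 * n_loci]) for row in body])
    return MicrosatDataset(sample_ids, sites, periods, locus_names, geno,
                           easting, northing)


def _float_or_nan(tok: str) -> float:
    tok = tok.strip()
    return float(tok) if tok else np.nan


def _write_genalex(ds: MicrosatDataset, path: Path) -> None:
    sites_order = list(dict.fromkeys(ds.sites))
    lines = []
    first = [str(ds.n_loci), str(ds.n_samples), str(len(sites_order))]
    first += [str(sum(s == site for s in ds.sites)) for site in sites_order]
    lines.append(",".join(first))
    header = ["sample_id", "site"]
    for loc in ds.locus_names:
        header += [loc, ""]
    header += ["period"]
    has_xy = ds.easting is not None and ds.northing is not None
    if has_xy:
        header += ["easting", "northing"]
    lines.append(",".join(header))
    for i, sid in enumerate(ds.sample_ids):
        row = [sid, ds.sites[i]]
        for j in range(ds.n_loci):
            row += [str(ds.genotypes[i, j, 0]), str(ds.genotypes[i, j, 1])]
        row.append(ds.periods[i])
        if has_xy:
            e, n_ = ds.easting[i], ds.northing[i]
            row += ["" if np.isnan(e) else repr(float(e)),
                    "" if np.isnan(n_) else repr(float(n_))]
        lines.append(",".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# genepop
# ---------------------------------------------------------------------------

def _read_genepop(path: Path) -> MicrosatDataset:
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise GenotypeIOError("empty genepop file")
    lines = [l for l in lines if l.strip() != ""]
    # title line, then locus names until first 'Pop' (one per line or comma list)
    locus_names: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        locus_names += [t.strip() for t in lines[i].split(",") if t.strip()]
        i += 1
    if i == len(lines):
        raise GenotypeIOError("genepop file has no Pop block")
    sample_ids, sites, rows = [], [], []
    pop_counter = 0
    for line in lines[i:]:
        if line.strip().lower() == "pop":
            pop_counter += 1
            continue
        if "," not in line:
            raise GenotypeIOError(f"genepop sample line lacks comma: {line!r}")
        ident, genostr = line.split(",", 1)
        ident = ident.strip()
        toks = genostr.split()
        if len(toks) != len(locus_names):
            raise GenotypeIOError(
                f"sample {ident!r}: {len(toks)} genotypes for "
                f"{len(locus_names)} loci"
            )
        pair_row = []
        for tok in toks:
            if not re.fullmatch(r"\d+", tok) or len(tok) not in (4, 6):
                raise GenotypeIOError(f"bad genepop genotype token {tok!r}")
            w = len(tok) // 2
            pair_row.append((int(tok[:w]), int(tok[w:])))
        rows.append(pair_row)
        sites.append(ident if ident else f"pop{pop_counter}")
        sample_ids.append(f"{ident}_{len(sample_ids) + 1}")
    geno = np.array(rows, dtype=np.int64)
    ds = MicrosatDataset(sample_ids, sites, ["all"] * len(sample_ids),
                         locus_names, geno)
    sidecar = Path(str(path) + ".meta.csv")
    if sidecar.exists():
        meta = pd.read_csv(sidecar, dtype={"sample_id": str})
        ds.sample_ids = list(meta["sample_id"])
        ds.sites = [str(s) for s in meta["site"]]
        ds.periods = [str(p) for p in meta["period"]]
        if {"easting", "northing"}.issubset(meta.columns):
            ds.easting = meta["easting"].to_numpy(float)
            ds.northing = meta["northing"].to_numpy(float)
        if "position" in meta.columns:
            inverse = np.argsort(meta["position"].to_numpy())
            ds = ds.subset(inverse)
    return ds


def _write_genepop(ds: MicrosatDataset, path: Path) -> None:
    width = 3 if int(ds.genotypes.max(initial=0)) > 99 else 2
    lines = ["clonalpop genepop export"]
    lines += list(ds.locus_names)
    by_site = ds.by_site()
    order: list[int] = []  # original positions in written (Pop-grouped) order
    for site, idx in by_site.items():
        lines.append("Pop")
        for i in idx:
            toks = [
                f"{ds.genotypes[i, j, 0]:0{width}d}{ds.genotypes[i, j, 1]:0{width}d}"
                for j in range(ds.n_loci)
            ]
            lines.append(f"{site} , " + " ".join(toks))
            order.append(int(i))
    Path(path).write_text("\n".join(lines) + "\n")
    # genepop cannot carry ids/periods/coordinates; a sidecar (in written
    # order, with original positions) keeps the round trip lossless
    meta = pd.DataFrame({
        "sample_id": [ds.sample_ids[i] for i in order],
        "site": [ds.sites[i] for i in order],
        "period": [ds.periods[i] for i in order],
        "position": order,
    })
    if ds.easting is not None and ds.northing is not None:
        meta["easting"] = ds.easting[order]
        meta["northing"] = ds.northing[order]
    meta.to_csv(Path(str(path) + ".meta.csv"), index=False)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

_READERS = {"tidy_csv": _read_tidy_csv, "genalex": _read_genalex,
            "genepop": _read_genepop}
_WRITERS = {"tidy_csv": _write_tidy_csv, "genalex": _write_genalex,
            "genepop": _write_genepop}


def read_genotypes(path: str | Path, dialect: str = "tidy_csv") -> MicrosatDataset:
    """Read a genotype table in the named dialect.

    Half-called loci (one allele present, the other missing) are coerced to
    MISSING with a logged warning. Raises :class:`GenotypeIOError` on unknown
    dialects, duplicate sample ids, or non-integer allele tokens.
    """
    if dialect not in _READERS:
        raise GenotypeIOError(f"unknown dialect {dialect!r}; choose from {DIALECTS}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return _READERS[dialect](path)


def write_genotypes(ds: MicrosatDataset, path: str | Path,
                    dialect: str = "tidy_csv") -> None:
    """Write a dataset in the named dialect (inverse of :func:`read_genotypes`)."""
    if dialect not in _WRITERS:
        raise GenotypeIOError(f"unknown dialect {dialect!r}; choose from {DIALECTS}")
    _WRITERS[dialect](ds, Path(path))
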