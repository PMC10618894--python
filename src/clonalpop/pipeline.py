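"""End-to-end before/after analysis: one call produces the full report
bundle (diversity tables, clone records, permutation comparisons,
bottleneck and Ne tables, differentiation matrices, ordination scores, and
spatial summaries) as TSV files plus a JSON manifest.

Sites below ``min_site_n`` individuals are kept in the summary tables but
excluded from every statistical comparison, mirroring the usual handling of
under-sampled sites. Statistics that come out infinite (LD-Ne with no drift
signal) are excluded pairwise from permutation comparisons, with a note in
the manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .bottleneck import TPMParams, bottleneck_test
from .data_quality import index_of_association, null_allele_table
from .differentiation import amova_fst, dest_pairwise, nei_distance_matrix, pcoa
from .genetic_diversity import site_diversity_table
from .genotype_io import MicrosatDataset, read_genotypes, summarize_missing
from .genotypic_diversity import site_genotypic_summary
from .mlg_clones import assign_mlgs, attach_psex, clone_record_table, \
    clone_records, collapse_clones
from .ne_ld import estimate_ne
from .permutation import two_group_abs_meandiff_test
from .spatial import site_centroids, within_site_spacing

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    input_path: Optional[str] = None
    dialect: str = "tidy_csv"
    min_scored_loci: int = 7
    psex_threshold: float = 0.01
    rarefaction_g: int = 5
    n_perm_sites: int = 10_000     # site-level two-group permutation tests
    n_perm_diff: int = 999         # Dest / AMOVA permutations
    n_rand_fis: int = 1000
    bottleneck_iters: int = 2000
    tpm_p_smm: float = 0.0
    tpm_var_geom: float = 0.36
    pcrit: float = 0.0
    alpha_adjusted: float = 0.0038
    min_site_n: int = 3
    run_bottleneck: bool = True
    seed: int = 0
    output_dir: str = "clonalpop_report"

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        return cls(**json.loads(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


#: statistics compared between periods when two periods are present
SITE_COMPARISON_STATS = ["GD", "GD_shannon", "GD_simpson", "MLG", "A_t",
                         "A_r", "H_o", "H_e", "F_is", "Ne"]


def run_report(config: AnalysisConfig,
               dataset: Optional[MicrosatDataset] = None) -> dict:
    """Run every stage and write the report bundle to ``config.output_dir``.

    Returns the manifest dict. Stage failures are re-raised with the stage
    name; tables written before the failure are retained.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": json.loads(config.to_json()),
        "stages": {},
        "warnings": [],
    }
    if dataset is None:
        if config.input_path is None:
            raise ValueError("config.input_path required when no dataset given")
        dataset = read_genotypes(config.input_path, config.dialect)

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:
                manifest["stages"][name] = {"status": "error", "error": str(exc)}
                _write_manifest(out, manifest)
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            manifest["stages"][name] = {
                "status": "ok", "seconds": round(time.perf_counter() - t0, 3),
            }
            logger.info("stage %s done in %.2fs", name,
                        time.perf_counter() - t0)
            return result
        return deco

    miss = stage("missingness")(lambda: summarize_missing(dataset))
    manifest["fraction_missing_overall"] = miss.fraction_missing_overall

    mlgs = stage("mlg_assignment")(
        lambda: attach_psex(dataset,
                            assign_mlgs(dataset, config.min_scored_loci)))
    mlgs.table().to_csv(out / "mlg_table.tsv", sep="\t", index=False)

    gd = stage("genotypic_diversity")(
        lambda: site_genotypic_summary(dataset, mlgs))
    gd.to_csv(out / "genotypic_diversity.tsv", sep="\t", index=False)

    if dataset.has_coordinates():
        recs = stage("clone_records")(lambda: clone_records(dataset, mlgs))
        clone_record_table(recs).to_csv(out / "clone_records.tsv", sep="\t",
                                        index=False)
        stage("spatial")(lambda: (
            within_site_spacing(dataset).to_csv(out / "within_site_spacing.tsv",
                                                sep="\t", index=False),
            site_centroids(dataset).to_csv(out / "site_centroids.tsv",
                                           sep="\t", index=False)))
    else:
        manifest["warnings"].append("no coordinates: spatial stages skipped")

    ds_cc = stage("clone_correction")(
        lambda: collapse_clones(dataset, mlgs, scope="per_site"))

    # small sites excluded from statistics, retained in summaries
    site_sizes = {s: len(i) for s, i in ds_cc.by_site().items()}
    small = [s for s, n in site_sizes.items() if n < config.min_site_n]
    if small:
        manifest["warnings"].append(
            f"sites below min N ({config.min_site_n}) excluded from tests: {small}")
    big_rows = np.array([i for i, s in enumerate(ds_cc.sites)
                         if s not in small])
    ds_stats = ds_cc.subset(big_rows) if small else ds_cc

    div = stage("genetic_diversity")(
        lambda: site_diversity_table(ds_cc, g_rarefy=config.rarefaction_g,
                                     n_rand=config.n_rand_fis,
                                     seed=config.seed + 11))
    div.to_csv(out / "genetic_diversity.tsv", sep="\t", index=False)

    qc = stage("quality")(lambda: {
        "ia": {p: index_of_association(ds_stats, rows=idx)
               for p, idx in ds_stats.by_period().items()
               if len(idx) >= 3 and ds_stats.n_loci >= 2},
        "null": null_allele_table(ds_stats),
    })
    qc["null"].to_csv(out / "null_alleles.tsv", sep="\t", index=False)
    manifest["index_of_association"] = {
        p: {"Ia": v[0], "rbarD": v[1]} for p, v in qc["ia"].items()}

    ne_rows = []
    for site, idx in ds_stats.by_site().items():
        try:
            est = estimate_ne(ds_stats, rows=idx, pcrit=config.pcrit)
            ne_rows.append((site, est.Ne_point, est.ci_low, est.ci_high,
                            est.r2_mean, est.n_comparisons))
        except ValueError as exc:
            manifest["warnings"].append(f"Ne at {site}: {exc}")
            ne_rows.append((site, float("nan"), float("nan"), float("nan"),
                            float("nan"), 0))
    ne_df = pd.DataFrame(ne_rows, columns=["site", "Ne", "ci_low", "ci_high",
                                           "r2_mean", "n_comparisons"])
    ne_df.to_csv(out / "ne_ld.tsv", sep="\t", index=False)
    manifest["stages"]["ne_ld"] = {"status": "ok"}

    if config.run_bottleneck:
        bt_rows = []
        params = TPMParams(p_smm=config.tpm_p_smm,
                           var_geom=config.tpm_var_geom)
        for k, (site, idx) in enumerate(ds_stats.by_site().items()):
            res = bottleneck_test(ds_stats, rows=idx, params=params,
                                  iters=config.bottleneck_iters,
                                  seed=config.seed + 100 + k)
            bt_rows.append((site, len(idx),
                            float(res.per_locus["k_obs"].mean())
                            if len(res.per_locus) else float("nan"),
                            res.wilcoxon_p, res.mode_shift))
        pd.DataFrame(bt_rows, columns=["site", "N", "mean_k", "wilcoxon_p",
                                       "mode_shift"]).to_csv(
            out / "bottleneck.tsv", sep="\t", index=False)
        manifest["stages"]["bottleneck"] = {"status": "ok"}

    dest_m, dest_p = stage("dest")(
        lambda: dest_pairwise(ds_stats, n_perm=config.n_perm_diff,
                              seed=config.seed + 7))
    _write_dest(out / "dest_matrix.tsv", dest_m, dest_p)

    periods = list(dict.fromkeys(ds_stats.periods))
    am = stage("amova")(lambda: amova_fst(
        ds_stats, groups=ds_stats.periods if len(periods) == 2 else None,
        n_perm=config.n_perm_diff, seed=config.seed + 13))
    manifest["amova"] = {"components": am.components, "phi": am.phi,
                         "p_values": am.p_values}

    pc = stage("pcoa")(lambda: pcoa(nei_distance_matrix(ds_stats)))
    pd.DataFrame(pc.coordinates, index=pc.labels).to_csv(
        out / "pcoa_scores.tsv", sep="\t")
    manifest["pcoa_percent_explained"] = pc.percent_explained[:3].tolist()

    if len(periods) == 2:
        comp = stage("period_comparison")(lambda: _period_comparison(
            dataset, ds_stats, gd, div, ne_df, small, config, manifest))
        comp.to_csv(out / "period_comparison.tsv", sep="\t", index=False)

    _write_manifest(out, manifest)
    return manifest


def _period_comparison(dataset, ds_stats, gd, div, ne_df, small, config,
                       manifest) -> pd.DataFrame:
    """Two-group permutation tests on per-site statistics, pre vs post."""
    site_period = {}
    for s, idx in ds_stats.by_site().items():
        site_period[s] = ds_stats.periods[idx[0]]
    gd_sites = gd[(~gd["site"].str.startswith("__")) & (~gd["site"].isin(small))]
    merged = gd_sites.merge(div, on="site", suffixes=("", "_cc"))
    merged = merged.merge(ne_df[["site", "Ne"]], on="site")
    rows = []
    for k, stat in enumerate(SITE_COMPARISON_STATS):
        if stat not in merged.columns:
            continue
        vals = merged[stat].to_numpy(float)
        labels = np.array([site_period[s] for s in merged["site"]])
        ok = np.isfinite(vals)
        if (~ok).any():
            manifest["warnings"].append(
                f"{stat}: {int((~ok).sum())} non-finite site value(s) "
                "excluded pairwise from the permutation comparison")
        vals, labels = vals[ok], labels[ok]
        if min((labels == labels[0]).sum(),
               (labels != labels[0]).sum()) < 2:
            continue
        res = two_group_abs_meandiff_test(
            vals, labels, n_perm=config.n_perm_sites,
            seed=config.seed + 1000 + k, exhaustive=None)
        rows.append((stat, res.observed_stat, res.n_perm, res.p_value,
                     res.exhaustive))
    return pd.DataFrame(rows, columns=["statistic", "observed_abs_meandiff",
                                       "n_perm", "p_value", "exhaustive"])


def _write_dest(path: Path, dest_m, dest_p) -> None:
    """Dest below the diagonal, permutation p above (the customary layout)."""
    n = len(dest_m.labels)
    M = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(n):
            if i > j:
                M[i, j] = dest_m.values[i, j]
            elif i < j:
                M[i, j] = dest_p.iloc[i, j]
    pd.DataFrame(M, index=dest_m.labels, columns=dest_m.labels).to_csv(
        path, sep="\t")


def _write_manifest(out: Path, manifest: dict) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=default))
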