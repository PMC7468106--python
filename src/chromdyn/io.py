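"""Readers, writers, configuration and the end-to-end pipeline.

All genomic coordinates are 0-based half-open internally. TSV files are
tab-separated with required headers, '#'-prefixed comment lines and no
quoting. Count tables serialise the (replicate, time) MultiIndex as
``r{rep}_t{minutes}`` column names. Every pipeline run writes a manifest
(input hashes, config, package version) so it can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._normalize import TIME_GRID, average_replicates, normalize_counts
from . import cluster as _cluster
from . import dynamics as _dynamics
from . import finemap as _finemap
from . import linkage as _linkage
from . import prioritize as _prioritize
from . import structure as _structure
from . import synth as _synth

log = logging.getLogger("chromdyn")

__all__ = [
    "PipelineConfig",
    "read_bed", "write_bed",
    "read_counts", "write_counts",
    "read_interactions", "write_interactions",
    "read_genes", "read_gwas", "read_ld", "read_matrix",
    "run_pipeline",
]


# --- BED -----------------------------------------------------------------

def read_bed(path) -> pd.DataFrame:
    """Read a >= 3 column BED file into 0-based half-open intervals."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 columns")
            chrom, s, e = parts[0], parts[1], parts[2]
            try:
                start, end = int(s), int(e)
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from err
            if start >= end:
                raise ValueError(f"{path}:{lineno}: empty or inverted interval")
            rows.append((chrom, start, end, *parts[3:], lineno))
    ncols = max((len(r) for r in rows), default=4)
    names = ["chrom", "start", "end"] + [f"col{i}" for i in range(4, ncols)] + ["line"]
    df = pd.DataFrame(rows, columns=names[: ncols - 1] + ["line"]) if rows else pd.DataFrame(
        columns=["chrom", "start", "end", "line"]
    )
    return df


def write_bed(df: pd.DataFrame, path, extra_cols=()) -> None:
    cols = ["chrom", "start", "end", *extra_cols]
    with open(path, "w") as fh:
        for _, r in df.iterrows():
            fh.write("\t".join(str(r[c]) for c in cols) + "\n")


# --- counts --------------------------------------------------------------

def write_counts(counts: pd.DataFrame, path) -> None:
    out = counts.copy()
    out.columns = [f"r{r}_t{t}" for r, t in counts.columns]
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    tuples = []
    for c in df.columns:
        if not (c.startswith("r") and "_t" in c):
            raise ValueError(f"{path}: bad count column {c!r} (expected r<rep>_t<minutes>)")
        r, t = c[1:].split("_t")
        tuples.append((int(r), int(t)))
    df.columns = pd.MultiIndex.from_tuples(tuples)
    return df


# --- interactions --------------------------------------------------------

def write_interactions(interactions: pd.DataFrame, scores: pd.DataFrame, path) -> None:
    out = interactions.copy()
    for t in scores.columns:
        out[f"score_t{t}"] = scores.loc[out["interaction_id"]].reset_index(drop=True)[t]
    out.to_csv(path, sep="\t", index=False)


def read_interactions(path, times=TIME_GRID) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Parse interaction records plus per-time score columns.

    The header must carry one ``score_t{minutes}`` column per configured
    time point; a mismatch is a format error.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    score_cols = [c for c in df.columns if c.startswith("score_t")]
    got = sorted(int(c[len("score_t"):]) for c in score_cols)
    if got != sorted(int(t) for t in times):
        raise ValueError(
            f"{path}: score columns {got} do not match time grid {sorted(times)}"
        )
    inter = df.drop(columns=score_cols)
    scores = df.set_index("interaction_id")[[f"score_t{t}" for t in sorted(times)]]
    scores.columns = [int(t) for t in sorted(times)]
    return inter, scores


# --- other simple tables -------------------------------------------------

def read_genes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    needed = {"gene_id", "chrom", "tss", "strand"}
    if not needed.issubset(df.columns):
        raise ValueError(f"{path}: gene table needs columns {sorted(needed)}")
    return df


def read_gwas(path, one_based: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    needed = {"rsid", "chrom", "pos", "beta", "se"}
    if not needed.issubset(df.columns):
        raise ValueError(f"{path}: GWAS table needs columns {sorted(needed)}")
    if one_based:
        df = df.assign(pos=df["pos"] - 1)  # convert to 0-based
    return df


def read_ld(path) -> np.ndarray:
    m = np.loadtxt(path, delimiter="\t")
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{path}: LD matrix must be square")
    return m


def read_matrix(path) -> np.ndarray:
    return np.loadtxt(path, delimiter="\t")


# --- config --------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Thresholds and paths driving a full pipeline run.

    Defaults mirror the study's retention rules: CHiCAGO-like score > 5 at
    one time point, gene totals >= 10 per replicate, alpha = 0.05,
    inclusive LR > 1, link correlation 0.5, LD r^2 >= 0.8, ABF prior
    omega = 0.04, credible level 0.99, 90% reciprocal TAD overlap.
    """

    outdir: str = "chromdyn_out"
    seed: int = 0
    times: tuple = TIME_GRID
    score_threshold: float = 5.0
    min_gene_total: int = 10
    alpha: float = 0.05
    lr_inclusive: float = 1.0
    r_link: float = 0.5
    r2_ld: float = 0.8
    omega: float = 0.04
    level: float = 0.99
    min_frac: float = 0.9
    n_clusters: int = 6
    # synthetic-run scale
    n_fragments: int = 400
    n_genes: int = 25
    n_peaks: int = 80
    chrom_length: int = 10_000_000
    dyn_fraction: float = 0.4
    replicates: int = 3
    paths: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not 0 < self.level < 1 or not 0 < self.alpha < 1:
            raise ValueError("alpha and level must be in (0, 1)")
        if not 0 < self.min_frac <= 1:
            raise ValueError("min_frac must be in (0, 1]")
        if self.omega < 0 or self.score_threshold < 0:
            raise ValueError("omega and score_threshold must be >= 0")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["times"] = list(d["times"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["times"] = tuple(d.get("times", TIME_GRID))
        return cls(**d)


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


# --- pipeline ------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on a synthetic bundle and write all artifacts.

    Stages: simulate -> dynamics (peaks/interactions/genes) -> prefilter +
    cluster peaks -> link + correlate + enrich -> fine-map -> prioritise ->
    structure metrics -> report. Deterministic given ``config.seed``.
    Returns the report dict (also written as JSON with a manifest).
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.seed)

    log.info("simulating scaffold and time courses (seed=%d)", seed)
    scaffold = _synth.simulate_genome(
        length=config.chrom_length, n_fragments=config.n_fragments,
        n_genes=config.n_genes, n_peaks=config.n_peaks, seed=seed,
    )
    sim = _synth.simulate_timecourses(
        scaffold, dyn_fraction=config.dyn_fraction,
        replicates=config.replicates, seed=seed + 1, times=config.times,
    )
    gwas, ld = _synth.simulate_gwas_locus(scaffold, n_snps=len(scaffold.snps), seed=seed + 2)

    (out / "scaffold.json").write_text(scaffold.to_json())
    write_counts(sim["peak_counts"], out / "peak_counts.tsv")
    write_counts(sim["gene_counts"], out / "gene_counts.tsv")
    write_counts(sim["interaction_counts"], out / "interaction_counts.tsv")

    log.info("classifying dynamics")
    calls = {}
    for kind, tbl in [
        ("peak", sim["peak_counts"]),
        ("interaction", sim["interaction_counts"]),
        ("gene", sim["gene_counts"]),
    ]:
        calls[kind] = _dynamics.classify_profiles(tbl, alpha=config.alpha, seed=seed)
        calls[kind].to_csv(out / f"calls_{kind}.tsv", sep="\t")

    log.info("clustering dynamic peaks")
    retained = _cluster.prefilter_for_clustering(
        calls["peak"], scaffold.peaks, scaffold.genes, lr_threshold=config.lr_inclusive
    )
    cluster_assign = {}
    if len(retained) >= config.n_clusters:
        prof = average_replicates(normalize_counts(sim["peak_counts"])).loc[retained]
        prof = prof.sub(prof.mean(axis=1), axis=0)
        model = _cluster.cluster_profiles(prof, K=config.n_clusters, seed=seed)
        cluster_assign = dict(zip(retained, (int(x) for x in model.labels_)))
        pd.Series(cluster_assign, name="cluster").rename_axis("peak_id").to_csv(
            out / "clusters.tsv", sep="\t"
        )

    log.info("building and correlating links")
    kept_inter, kept_genes = _linkage.filter_features(
        scaffold.interactions, sim["interaction_scores"], sim["gene_counts"],
        score_threshold=config.score_threshold, min_gene_total=config.min_gene_total,
        bait_frag_ids=scaffold.genes["bait_frag_id"],
    )
    kept_inter = kept_inter[~kept_inter["interaction_id"].astype(str).str.endswith("_rev")]
    links = _linkage.build_links(
        scaffold.peaks, kept_inter, scaffold.fragments, kept_genes=kept_genes
    )
    links = _linkage.correlate_links(
        links, sim["peak_counts"], sim["interaction_counts"], sim["gene_counts"]
    )
    links.to_csv(out / "links.tsv", sep="\t", index=False)
    enrich = _linkage.background_enrichment(
        links, sim["peak_counts"], sim["interaction_counts"], sim["gene_counts"],
        seed=seed + 3,
    )
    enrich_out = {k: v for k, v in enrich.items() if k != "null"}
    (out / "enrichment.json").write_text(json.dumps(enrich_out, indent=2, default=float))

    log.info("fine-mapping")
    cs = _finemap.credible_set(gwas, level=config.level, omega=config.omega)
    cs.table.to_csv(out / "credible_set.tsv", sep="\t", index=False)

    log.info("prioritising")
    cred_snps = gwas[gwas["rsid"].isin(cs.members)]
    pairs = _prioritize.overlap_snps_peaks(cred_snps, scaffold.peaks)
    hits = _prioritize.assign_genes(pairs, links, r_threshold=config.r_link)
    hits.to_csv(out / "hits.tsv", sep="\t", index=False)
    comp = _prioritize.compartment_membership(cred_snps, scaffold.compartments_by_time)
    comp.to_csv(out / "compartments_snps.tsv", sep="\t", index=False)

    log.info("structure metrics")
    t_struct = sorted(scaffold.tads_by_time)
    tad_consistency = {
        str(t): _structure.reciprocal_overlap_fraction(
            scaffold.tads_by_time[t_struct[0]], scaffold.tads_by_time[t], config.min_frac
        )
        for t in t_struct
    }
    trend = _structure.compartment_corr_trend(scaffold.eigen_by_time)

    report = _prioritize.summary_report(
        hits=hits if len(hits) else None,
        calls=pd.concat(calls.values()),
        links=links,
        compartment_classes=comp,
    )
    report["tad_consistency_vs_t0"] = tad_consistency
    report["compartment_corr_slope_per_min"] = trend["slope"]
    report["n_clustered_peaks"] = len(cluster_assign)
    report["enrichment"] = enrich_out

    manifest = {
        "version": __version__,
        "seed": seed,
        "coordinate_convention": "0-based half-open",
        "config": {**dataclasses.asdict(config), "times": list(config.times)},
        "outputs": sorted(p.name for p in out.iterdir()),
        "scaffold_digest": scaffold.digest(),
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True, default=float))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return report
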