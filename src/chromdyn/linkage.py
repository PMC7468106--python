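"""Linking accessibility peaks, promoter interactions and gene expression.

A link is one (ATAC peak, CHi-C interaction, gene) triplet: the peak lies
wholly inside the interaction's otherEnd fragment and the gene sits on the
interaction's bait fragment. Pairwise Pearson correlations over the
replicate-averaged, normalised six-point time courses measure co-dynamics;
links are stratified by bait-otherEnd distance and compared against a
randomised background with a two-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._normalize import average_replicates, normalize_counts

__all__ = [
    "STRATA",
    "filter_features",
    "build_links",
    "correlate_links",
    "background_enrichment",
    "log2_span",
]

#: Half-open promoter-distance strata [low, high) in bp; links >= 5 Mb drop.
STRATA = (
    (0, 200_000, "<200 kb"),
    (200_000, 500_000, "200-500 kb"),
    (500_000, 1_000_000, "500 kb-1 Mb"),
    (1_000_000, 5_000_000, "1-5 Mb"),
)


def assign_stratum(distance: float) -> str | None:
    for lo, hi, name in STRATA:
        if lo <= distance < hi:
            return name
    return None


def filter_features(
    interactions: pd.DataFrame,
    interaction_scores: pd.DataFrame,
    gene_counts: pd.DataFrame,
    score_threshold: float = 5.0,
    min_gene_total: int = 10,
    bait_frag_ids=None,
) -> tuple[pd.DataFrame, list]:
    """Apply the interaction-score and gene-count retention filters.

    An interaction is kept iff its score strictly exceeds ``score_threshold``
    at >= 1 time point. A gene is kept iff its summed counts over the time
    course reach ``min_gene_total`` in **every** replicate. Bait-to-bait
    interactions (otherEnd fragment also a bait) are registered twice, with
    the bait and otherEnd roles swapped on the duplicate.
    """
    missing = set(interactions["interaction_id"]) - set(interaction_scores.index)
    if missing:
        raise ValueError(f"missing score rows for {sorted(missing)[:3]}...")
    keep_ids = interaction_scores.index[
        (interaction_scores > score_threshold).any(axis=1)
    ]
    kept = interactions[interactions["interaction_id"].isin(keep_ids)].copy()

    if bait_frag_ids is not None:
        baits = set(bait_frag_ids)
        b2b = kept[kept["oe_frag_id"].isin(baits)]
        if len(b2b):
            swapped = b2b.copy()
            swapped["bait_frag_id"] = b2b["oe_frag_id"].to_numpy()
            swapped["oe_frag_id"] = b2b["bait_frag_id"].to_numpy()
            swapped["interaction_id"] = swapped["interaction_id"].astype(str) + "_rev"
            kept = pd.concat([kept, swapped], ignore_index=True)

    totals = gene_counts.T.groupby(level=0).sum().T  # per-replicate totals
    kept_genes = totals.index[(totals >= min_gene_total).all(axis=1)].tolist()
    return kept.reset_index(drop=True), kept_genes


def build_links(
    peaks: pd.DataFrame,
    interactions: pd.DataFrame,
    fragments: pd.DataFrame,
    genes: pd.DataFrame | None = None,
    kept_genes=None,
) -> pd.DataFrame:
    """Join peaks to interactions via otherEnd fragments, expanding genes.

    One link per (peak inside otherEnd fragment) x (interaction from that
    fragment) x (gene on the interaction's bait). Distance is the absolute
    difference between bait and otherEnd fragment midpoints. Peaks without
    a fragment assignment are skipped and counted in ``.attrs['skipped']``.
    """
    mid = fragments.set_index("frag_id").eval("(start + end) / 2")
    frag_iv = fragments.set_index("frag_id")[["start", "end"]]
    rows, skipped = [], 0
    inter_by_oe = interactions.groupby("oe_frag_id")
    for _, pk in peaks.iterrows():
        fid = pk.get("frag_id")
        if fid is None or (isinstance(fid, float) and np.isnan(fid)) or fid not in frag_iv.index:
            skipped += 1
            continue
        if not (frag_iv.loc[fid, "start"] <= pk["start"] and pk["end"] <= frag_iv.loc[fid, "end"]):
            skipped += 1
            continue
        if fid not in inter_by_oe.groups:
            continue
        for _, it in inter_by_oe.get_group(fid).iterrows():
            gene_ids = (
                it["gene_ids"].split(",") if isinstance(it["gene_ids"], str) else list(it["gene_ids"])
            )
            dist = abs(float(mid.loc[it["bait_frag_id"]]) - float(mid.loc[fid]))
            for gid in gene_ids:
                if kept_genes is not None and gid not in kept_genes:
                    continue
                rows.append(
                    (pk["peak_id"], it["interaction_id"], it["bait_frag_id"], fid, gid, dist)
                )
    links = pd.DataFrame(
        rows,
        columns=["peak_id", "interaction_id", "bait_frag_id", "oe_frag_id", "gene_id", "distance"],
    )
    links.attrs["skipped"] = skipped
    return links


def _averaged_normalized(counts: pd.DataFrame) -> pd.DataFrame:
    return average_replicates(normalize_counts(counts))


def correlate_links(
    links: pd.DataFrame,
    peak_counts: pd.DataFrame,
    interaction_counts: pd.DataFrame,
    gene_counts: pd.DataFrame,
) -> pd.DataFrame:
    """Attach the three pairwise Pearson correlations and distance strata.

    Series are normalised (CPM + log2(x+1)) and replicate-averaged before
    correlating. Zero-variance series make a correlation undefined; such
    links are flagged ``excluded`` and dropped from enrichment. Links at
    >= 5 Mb are removed.
    """
    pk = _averaged_normalized(peak_counts)
    ic = _averaged_normalized(interaction_counts)
    gn = _averaged_normalized(gene_counts)

    out = links.copy()
    out["stratum"] = [assign_stratum(d) for d in out["distance"]]
    out = out[out["stratum"].notna()].reset_index(drop=True)

    def corr(a, b):
        if np.std(a) == 0 or np.std(b) == 0:
            return np.nan
        return float(np.corrcoef(a, b)[0, 1])

    r1, r2, r3 = [], [], []
    for _, ln in out.iterrows():
        a = pk.loc[ln["peak_id"]].to_numpy()
        c = ic.loc[ln["interaction_id"]].to_numpy()
        g = gn.loc[ln["gene_id"]].to_numpy()
        r1.append(corr(a, c))
        r2.append(corr(a, g))
        r3.append(corr(g, c))
    out["r_atac_chic"] = r1
    out["r_atac_gene"] = r2
    out["r_gene_chic"] = r3
    out["excluded"] = out[["r_atac_chic", "r_atac_gene", "r_gene_chic"]].isna().any(axis=1)
    return out


def background_enrichment(
    links: pd.DataFrame,
    peak_counts: pd.DataFrame,
    interaction_counts: pd.DataFrame,
    gene_counts: pd.DataFrame,
    n_draws: int | None = None,
    seed: int = 0,
    measure: str = "r_atac_gene",
) -> dict:
    """Randomised-background enrichment test per distance stratum.

    The null is built by drawing ``n_draws`` uniformly random (peak,
    interaction, gene) triplets with no genomic restriction and computing
    the same Pearson correlation. Observed links in each stratum are
    compared with the null by a two-sided Wilcoxon rank-sum test.

    Returns ``{stratum: {"n", "median_r", "p_value"}}`` plus the null sample
    under the key ``"null"``.
    """
    if n_draws is not None and n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    obs = links[~links["excluded"].astype(bool)] if "excluded" in links else links
    if n_draws is None:
        n_draws = max(10_000, len(obs))
    rng = np.random.default_rng(seed)

    pk = _averaged_normalized(peak_counts).to_numpy()
    ic = _averaged_normalized(interaction_counts).to_numpy()
    gn = _averaged_normalized(gene_counts).to_numpy()

    pi = rng.integers(len(pk), size=n_draws)
    ii = rng.integers(len(ic), size=n_draws)
    gi = rng.integers(len(gn), size=n_draws)

    def pearson_rows(A, B):
        A = A - A.mean(axis=1, keepdims=True)
        B = B - B.mean(axis=1, keepdims=True)
        denom = np.sqrt((A**2).sum(axis=1) * (B**2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            return (A * B).sum(axis=1) / denom

    null = {
        "r_atac_chic": pearson_rows(pk[pi], ic[ii]),
        "r_atac_gene": pearson_rows(pk[pi], gn[gi]),
        "r_gene_chic": pearson_rows(gn[gi], ic[ii]),
    }[measure]
    null = null[np.isfinite(null)]

    results: dict = {"null": null}
    for _, _, name in STRATA:
        vals = obs.loc[obs["stratum"] == name, measure].dropna().to_numpy()
        if len(vals) < 2:
            results[name] = {"n": int(len(vals)), "median_r": np.nan, "p_value": np.nan}
            continue
        p = float(stats.ranksums(vals, null).pvalue)
        results[name] = {"n": int(len(vals)), "median_r": float(np.median(vals)), "p_value": p}
    return results


def log2_span(series, pseudocount: float = 1.0) -> float:
    """log2 fold change across the time course: log2((max+c)/(min+c))."""
    s = np.asarray(series, dtype=float)
    if s.size == 0:
        raise ValueError("empty series")
    return float(np.log2((s.max() + pseudocount) / (s.min() + pseudocount)))
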