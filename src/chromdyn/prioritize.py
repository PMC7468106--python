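"""GWAS prioritisation: credible SNPs -> peaks -> genes -> compartments.

Credible-set or LD-expanded SNPs are intersected with accessibility peaks
(half-open intervals); peaks carrying a SNP are assigned genes through
links whose three pairwise time-course correlations all reach the
"highly correlated" threshold (signed, default 0.5); SNPs are classified
by their A/B compartment membership over time; and the printed summary
ratios (rounded half away from zero) are assembled into a report.
"""

from __future__ import annotations

import decimal

import numpy as np
import pandas as pd

__all__ = [
    "ld_expand",
    "overlap_snps_peaks",
    "assign_genes",
    "compartment_membership",
    "percentage",
    "summary_report",
]


def ld_expand(lead: str, ld: np.ndarray, rsids, r2_threshold: float = 0.8) -> list[str]:
    """All SNPs with r^2 to the lead >= threshold; the lead is always kept."""
    rsids = list(rsids)
    if lead not in rsids:
        raise ValueError(f"lead SNP {lead!r} not in panel")
    i = rsids.index(lead)
    r2 = np.asarray(ld)[i]
    out = [r for r, v in zip(rsids, r2) if v >= r2_threshold]
    if lead not in out:
        out.append(lead)
    return out


def overlap_snps_peaks(snps: pd.DataFrame, peaks: pd.DataFrame) -> pd.DataFrame:
    """(snp, peak) pairs where peak.start <= pos < peak.end on one chromosome."""
    rows = []
    for _, s in snps.iterrows():
        hit = peaks[
            (peaks["chrom"] == s["chrom"])
            & (peaks["start"] <= s["pos"])
            & (s["pos"] < peaks["end"])
        ]
        for _, p in hit.iterrows():
            rows.append((s["rsid"], int(s["pos"]), p["peak_id"]))
    return pd.DataFrame(rows, columns=["rsid", "pos", "peak_id"])


def assign_genes(
    pairs: pd.DataFrame,
    links: pd.DataFrame,
    r_threshold: float = 0.5,
    absolute: bool = False,
) -> pd.DataFrame:
    """Expand SNP-peak pairs to genes via highly correlated links.

    A hit requires the peak's link to the gene to have all three pairwise
    correlations >= ``r_threshold`` (signed by default; ``absolute=True``
    thresholds |r| instead). One row per (snp, peak, gene).
    """
    rcols = ["r_atac_chic", "r_atac_gene", "r_gene_chic"]
    r = links[rcols].abs() if absolute else links[rcols]
    good = links[(r >= r_threshold).all(axis=1)]
    merged = pairs.merge(good, on="peak_id", how="inner")
    cols = ["rsid", "pos", "peak_id", "interaction_id", "gene_id", "distance", "stratum", *rcols]
    return merged[[c for c in cols if c in merged.columns]].drop_duplicates(
        subset=["rsid", "peak_id", "gene_id"]
    ).reset_index(drop=True)


def compartment_membership(snps: pd.DataFrame, compartments_by_time: dict) -> pd.DataFrame:
    """Per-SNP A/B trajectory across time points and a consistency class.

    Classes: ``consistent A``, ``consistent B``, ``switching`` (any label
    change between assigned time points), ``unassigned`` (never inside a
    compartment). Overlapping intervals within one time point are rejected.
    """
    times = sorted(compartments_by_time)
    if len(times) < 2:
        raise ValueError("need compartment tracks at >= 2 time points")
    for t in times:
        trk = compartments_by_time[t].sort_values(["chrom", "start"])
        for _, sub in trk.groupby("chrom"):
            if (sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]).any():
                raise ValueError(f"overlapping compartment intervals at t={t}")
    rows = []
    for _, s in snps.iterrows():
        traj = []
        for t in times:
            trk = compartments_by_time[t]
            hit = trk[
                (trk["chrom"] == s["chrom"])
                & (trk["start"] <= s["pos"])
                & (s["pos"] < trk["end"])
            ]
            traj.append(hit["label"].iloc[0] if len(hit) else None)
        seen = [x for x in traj if x is not None]
        if not seen:
            cls = "unassigned"
        elif all(x == "A" for x in seen):
            cls = "consistent A"
        elif all(x == "B" for x in seen):
            cls = "consistent B"
        else:
            cls = "switching"
        rows.append((s["rsid"], *traj, cls))
    return pd.DataFrame(rows, columns=["rsid", *[f"t{t}" for t in times], "class"])


def percentage(numerator: float, denominator: float, decimals: int = 0) -> float:
    """numerator/denominator x 100, rounded half away from zero."""
    if denominator == 0:
        raise ZeroDivisionError("zero denominator for percentage")
    q = decimal.Decimal(1).scaleb(-decimals)
    val = decimal.Decimal(numerator) / decimal.Decimal(denominator) * 100
    return float(val.quantize(q, rounding=decimal.ROUND_HALF_UP))


def _round_half_away(x: float, decimals: int) -> float:
    q = decimal.Decimal(1).scaleb(-decimals)
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def summary_report(
    hits: pd.DataFrame | None = None,
    calls: pd.DataFrame | None = None,
    links: pd.DataFrame | None = None,
    compartment_classes: pd.DataFrame | None = None,
    extra_ratios: dict | None = None,
) -> dict:
    """Assemble headline counts, rounded percentages and means.

    ``extra_ratios`` maps name -> (numerator, denominator[, decimals]) for
    ad-hoc printed ratios. Mean genes per peak is distinct genes over
    distinct peaks at one decimal.
    """
    rep: dict = {}
    if calls is not None:
        n = len(calls)
        rep["n_features"] = n
        rep["n_dynamic_bic"] = int(calls["dynamic_by_bic"].sum())
        rep["n_dynamic_lr"] = int(calls["dynamic_by_lr"].sum())
        if n:
            rep["pct_dynamic_bic"] = percentage(rep["n_dynamic_bic"], n)
            rep["pct_dynamic_lr"] = percentage(rep["n_dynamic_lr"], n)
    if links is not None:
        rep["n_links"] = len(links)
        rep["links_per_stratum"] = links["stratum"].value_counts().to_dict()
    if hits is not None:
        n_peaks = hits["peak_id"].nunique()
        n_genes = hits["gene_id"].nunique()
        rep["n_hit_snps"] = hits["rsid"].nunique()
        rep["n_hit_peaks"] = int(n_peaks)
        rep["n_hit_genes"] = int(n_genes)
        if n_peaks == 0:
            raise ZeroDivisionError("zero denominator for genes-per-peak")
        rep["mean_genes_per_peak"] = _round_half_away(n_genes / n_peaks, 1)
    if compartment_classes is not None:
        counts = compartment_classes["class"].value_counts().to_dict()
        rep["compartment_classes"] = counts
        total = len(compartment_classes)
        if total:
            rep["pct_consistent_A"] = percentage(counts.get("consistent A", 0), total)
    for name, ratio in (extra_ratios or {}).items():
        num, den, *rest = ratio
        rep[name] = percentage(num, den, decimals=rest[0] if rest else 0)
    return rep
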