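"""Synthetic genome scaffold and time-course count generator.

Emulates, at desk scale, the structure of a stimulated CD4+ T-cell
multi-omic time course: a single chromosome tiled by restriction-fragment
surrogates, promoter bait fragments mapped to genes, ATAC-like peaks lying
inside fragments, CHi-C-like bait/otherEnd interactions, per-time-point TAD
and A/B compartment tracks, and a GWAS locus with one causal variant and LD
decay. Every generated object carries ground-truth labels so downstream
stages can be scored.

Counts are negative-binomial around an exponentiated latent mean; dynamic
features draw their latent mean from a squared-exponential GP on the
log2(1 + minutes) axis, static features have a constant latent mean.
Replicates are conditionally independent given the latent mean.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._normalize import TIME_GRID, transform_times

__all__ = ["ScaffoldBundle", "simulate_genome", "simulate_timecourses", "simulate_gwas_locus"]

#: Time points (minutes) at which Hi-C structure tracks are sampled.
HIC_TIME_GRID = (0, 20, 60, 240, 1440)


@dataclass
class ScaffoldBundle:
    """Toy genome scaffold with ground truth.

    DataFrames follow 0-based half-open coordinates on a single chromosome.
    """

    chrom: str
    length: int
    fragments: pd.DataFrame  # frag_id, chrom, start, end
    genes: pd.DataFrame      # gene_id, chrom, tss, strand, bait_frag_id
    peaks: pd.DataFrame      # peak_id, chrom, start, end, frag_id
    interactions: pd.DataFrame  # interaction_id, bait_frag_id, oe_frag_id, gene_ids
    tads_by_time: dict = field(default_factory=dict)
    compartments_by_time: dict = field(default_factory=dict)  # time -> df(chrom,start,end,label)
    eigen_by_time: pd.DataFrame | None = None  # bins x time columns of eigen-scores
    snps: pd.DataFrame | None = None  # rsid, chrom, pos, beta, se
    ld: np.ndarray | None = None
    truth: dict = field(default_factory=dict)

    def validate(self) -> None:
        f = self.fragments.sort_values("start")
        if not (f["start"].iloc[0] == 0 and f["end"].iloc[-1] == self.length):
            raise AssertionError("fragments do not span the chromosome")
        if not np.array_equal(f["end"].to_numpy()[:-1], f["start"].to_numpy()[1:]):
            raise AssertionError("fragments do not tile without gaps/overlap")
        if len(self.peaks):
            merged = self.peaks.merge(self.fragments, on="frag_id", suffixes=("", "_f"))
            inside = (merged["start"] >= merged["start_f"]) & (merged["end"] <= merged["end_f"])
            if not inside.all():
                raise AssertionError("peak outside its fragment")
        if not self.genes["bait_frag_id"].isin(self.fragments["frag_id"]).all():
            raise AssertionError("bait fragment not in fragment set")
        if self.ld is not None:
            if not np.allclose(self.ld, self.ld.T):
                raise AssertionError("LD matrix not symmetric")
            if not np.allclose(np.diag(self.ld), 1.0):
                raise AssertionError("LD diagonal not 1")
            if self.ld.min() < 0 or self.ld.max() > 1 + 1e-12:
                raise AssertionError("LD entries outside [0, 1]")

    # --- serialisation -------------------------------------------------
    def to_json(self) -> str:
        """Lossless, deterministic JSON serialisation of the bundle."""
        def df(d: pd.DataFrame):
            return {"columns": list(d.columns), "data": d.to_numpy().tolist()}

        payload = {
            "chrom": self.chrom,
            "length": self.length,
            "fragments": df(self.fragments),
            "genes": df(self.genes),
            "peaks": df(self.peaks),
            "interactions": df(self.interactions),
            "tads_by_time": {str(t): df(v) for t, v in self.tads_by_time.items()},
            "compartments_by_time": {str(t): df(v) for t, v in self.compartments_by_time.items()},
            "eigen_by_time": None
            if self.eigen_by_time is None
            else {
                "index": self.eigen_by_time.index.tolist(),
                "columns": [int(c) for c in self.eigen_by_time.columns],
                "data": self.eigen_by_time.to_numpy().tolist(),
            },
            "snps": None if self.snps is None else df(self.snps),
            "ld": None if self.ld is None else np.asarray(self.ld).tolist(),
            "truth": self.truth,
        }
        return json.dumps(payload, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ScaffoldBundle":
        p = json.loads(text)

        def df(d):
            return pd.DataFrame(d["data"], columns=d["columns"])

        eig = p["eigen_by_time"]
        return cls(
            chrom=p["chrom"],
            length=p["length"],
            fragments=df(p["fragments"]),
            genes=df(p["genes"]),
            peaks=df(p["peaks"]),
            interactions=df(p["interactions"]),
            tads_by_time={int(t): df(v) for t, v in p["tads_by_time"].items()},
            compartments_by_time={int(t): df(v) for t, v in p["compartments_by_time"].items()},
            eigen_by_time=None
            if eig is None
            else pd.DataFrame(eig["data"], index=eig["index"], columns=eig["columns"]),
            snps=None if p["snps"] is None else df(p["snps"]),
            ld=None if p["ld"] is None else np.asarray(p["ld"], dtype=float),
            truth=p["truth"],
        )

    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()


def simulate_genome(
    length: int = 10_000_000,
    n_fragments: int = 2000,
    n_genes: int = 50,
    n_peaks: int = 300,
    seed: int = 0,
    chrom: str = "chr1",
    n_snps: int = 50,
    interactions_per_peak: tuple[int, int] = (1, 3),
    max_interaction_span: int = 5_000_000,
) -> ScaffoldBundle:
    """Build a deterministic toy genome scaffold.

    Fragments are a homogeneous random partition of the chromosome; genes
    sit on distinct bait fragments; peaks lie wholly inside non-bait
    fragments; each peak's fragment interacts with 1-3 nearby baits.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    for name, v in [("n_fragments", n_fragments), ("n_genes", n_genes), ("n_peaks", n_peaks)]:
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    if n_fragments < 1:
        raise ValueError("need at least one fragment")
    if n_genes + n_peaks > 0 and n_fragments < n_genes + 1:
        raise ValueError("need more fragments than genes")
    rng = np.random.default_rng(seed)

    cuts = np.sort(rng.choice(np.arange(1, length), size=n_fragments - 1, replace=False))
    starts = np.concatenate(([0], cuts))
    ends = np.concatenate((cuts, [length]))
    fragments = pd.DataFrame(
        {"frag_id": np.arange(n_fragments), "chrom": chrom, "start": starts, "end": ends}
    )

    bait_ids = np.sort(rng.choice(n_fragments, size=n_genes, replace=False))
    gene_rows = []
    for i, b in enumerate(bait_ids):
        s, e = int(starts[b]), int(ends[b])
        tss = int(rng.integers(s, e))
        strand = "+" if rng.random() < 0.5 else "-"
        gene_rows.append((f"gene{i}", chrom, tss, strand, int(b)))
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "tss", "strand", "bait_frag_id"])

    non_bait = np.setdiff1d(np.arange(n_fragments), bait_ids)
    peak_rows = []
    if n_peaks > 0:
        host = rng.choice(non_bait if len(non_bait) else np.arange(n_fragments),
                          size=n_peaks, replace=n_peaks > len(non_bait))
        for i, fr in enumerate(np.sort(host)):
            s, e = int(starts[fr]), int(ends[fr])
            w = int(min(max(200, rng.integers(200, 1001)), e - s))
            p0 = int(rng.integers(s, e - w + 1)) if e - s > w else s
            peak_rows.append((f"peak{i}", chrom, p0, p0 + w, int(fr)))
    peaks = pd.DataFrame(peak_rows, columns=["peak_id", "chrom", "start", "end", "frag_id"])

    # interactions: each peak-hosting fragment contacts nearby baits
    frag_mid = (starts + ends) / 2.0
    bait_mid = frag_mid[bait_ids] if n_genes else np.array([])
    inter_rows = []
    iid = 0
    if n_genes:
        bait_by_frag = genes.groupby("bait_frag_id")["gene_id"].apply(list).to_dict()
        for fr in sorted(set(peaks["frag_id"])) if len(peaks) else []:
            d = np.abs(bait_mid - frag_mid[fr])
            near = bait_ids[d <= max_interaction_span]
            if len(near) == 0:
                continue
            k = int(rng.integers(interactions_per_peak[0], interactions_per_peak[1] + 1))
            k = min(k, len(near))
            order = np.argsort(np.abs(frag_mid[near] - frag_mid[fr]))
            chosen = near[order[:k]]
            for b in chosen:
                inter_rows.append(
                    (f"int{iid}", int(b), int(fr), ",".join(bait_by_frag[int(b)]))
                )
                iid += 1
    interactions = pd.DataFrame(
        inter_rows, columns=["interaction_id", "bait_frag_id", "oe_frag_id", "gene_ids"]
    )

    # TAD tracks: ~1 Mb tiles with small per-time boundary jitter
    tads_by_time = {}
    base_bounds = np.arange(0, length + 1, max(length // 10, 1))
    for t in HIC_TIME_GRID:
        jitter = rng.integers(-20_000, 20_001, size=len(base_bounds))
        jitter[0] = jitter[-1] = 0
        b = np.clip(base_bounds + jitter, 0, length)
        b = np.sort(b)
        tads_by_time[t] = pd.DataFrame(
            {"chrom": chrom, "start": b[:-1], "end": b[1:]}
        ).query("end > start").reset_index(drop=True)

    # compartments: smooth eigen-score per 100 kb bin, drifting over time
    bin_size = 100_000
    bin_starts = np.arange(0, length, bin_size)
    base = np.cumsum(rng.normal(0, 0.4, size=len(bin_starts)))
    base -= base.mean()
    eig = {}
    walk = base.copy()
    for t in HIC_TIME_GRID:
        walk = walk + rng.normal(0, 0.08, size=len(bin_starts))
        eig[t] = walk - walk.mean()
    eigen_by_time = pd.DataFrame(eig, index=bin_starts)
    compartments_by_time = {}
    for t in HIC_TIME_GRID:
        lab = np.where(eigen_by_time[t].to_numpy() >= 0, "A", "B")
        rows, cur = [], None
        for bs, lb in zip(bin_starts, lab):
            if cur is not None and cur[2] == lb and cur[1] == bs:
                cur = (cur[0], bs + bin_size, lb)
            else:
                if cur is not None:
                    rows.append(cur)
                cur = (bs, bs + bin_size, lb)
        rows.append(cur)
        compartments_by_time[t] = pd.DataFrame(
            [(chrom, s, min(e, length), lb) for s, e, lb in rows],
            columns=["chrom", "start", "end", "label"],
        )

    # SNP panel clustered near the middle of the chromosome
    center = length // 2
    pos = np.sort(rng.choice(np.arange(max(0, center - 250_000), min(length, center + 250_000)),
                             size=n_snps, replace=False)) if n_snps else np.array([], dtype=int)
    snps = pd.DataFrame(
        {"rsid": [f"rs{i}" for i in range(n_snps)], "chrom": chrom,
         "pos": pos.astype(int), "beta": 0.0, "se": 0.1}
    )
    ld = _ld_from_positions(pos, decay=1.0 / 50_000) if n_snps else None

    bundle = ScaffoldBundle(
        chrom=chrom, length=int(length), fragments=fragments, genes=genes, peaks=peaks,
        interactions=interactions, tads_by_time=tads_by_time,
        compartments_by_time=compartments_by_time, eigen_by_time=eigen_by_time,
        snps=snps, ld=ld,
        truth={"dynamic": {}, "true_links": [], "causal_snp": None},
    )
    bundle.validate()
    return bundle


def _ld_from_positions(pos: np.ndarray, decay: float) -> np.ndarray:
    """Exponential-decay correlation squared elementwise: PSD by construction
    (Ornstein-Uhlenbeck kernel, Schur-squared)."""
    d = np.abs(pos[:, None].astype(float) - pos[None, :].astype(float))
    r = np.exp(-decay * d)
    return r * r


def amplitude_for_snr(
    snr: float,
    dispersion: float = 10.0,
    base_log_mean: float = np.log(100.0),
    times=TIME_GRID,
    lengthscale_factor: float = 0.3,
) -> float:
    """GP amplitude giving a target signal-to-noise variance ratio.

    Signal variance is defined as the expected variance of the latent
    trajectory *across the sampled time points* (a GP draw's realized
    temporal variance is the prior amplitude times ``1 - mean(R)`` for RBF
    correlation matrix R on the grid). Noise variance is the log2-scale
    count noise at the baseline mean by the delta method,
    ``(1/mu + 1/dispersion) / ln(2)^2`` for the negative binomial.
    """
    t_axis = transform_times(np.asarray(times, dtype=float))
    span = t_axis.max() - t_axis.min()
    d2 = (t_axis[:, None] - t_axis[None, :]) ** 2
    R = np.exp(-0.5 * d2 / (lengthscale_factor * span) ** 2)
    realized_frac = 1.0 - R.mean()
    mu = np.exp(base_log_mean)
    noise_var = (1.0 / mu + 1.0 / dispersion) / np.log(2.0) ** 2
    return float(np.sqrt(snr * noise_var / realized_frac))


def _gp_draw(rng, t_axis: np.ndarray, amplitude: float, lengthscale: float) -> np.ndarray:
    d2 = (t_axis[:, None] - t_axis[None, :]) ** 2
    K = amplitude**2 * np.exp(-0.5 * d2 / lengthscale**2) + 1e-10 * np.eye(len(t_axis))
    return rng.multivariate_normal(np.zeros(len(t_axis)), K, method="cholesky")


def _nb_counts(rng, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with size=dispersion: var = mu + mu^2/dispersion."""
    mean = np.maximum(mean, 1e-8)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def simulate_timecourses(
    scaffold: ScaffoldBundle,
    dyn_fraction: float = 0.3,
    signal_params: dict | None = None,
    noise_params: dict | None = None,
    replicates: int = 3,
    seed: int = 0,
    times=TIME_GRID,
    linked_fraction: float = 0.5,
) -> dict:
    """Simulate counts for peaks, interactions and genes with known truth.

    Dynamic features draw a latent log2-scale trajectory from a
    squared-exponential GP on log2(1 + minutes); static features are flat.
    A ``linked_fraction`` of dynamic peaks shares its latent trajectory with
    one of its interactions and that interaction's gene, producing true
    correlated links recorded in ``scaffold.truth['true_links']``.

    Returns a dict with (replicate, time)-column count DataFrames
    ``peak_counts``, ``interaction_counts``, ``gene_counts``, an
    ``interaction_scores`` table (CHiCAGO-like scores per time point), and
    a ``truth`` dict mapping feature id -> "dynamic" | "static".
    """
    if not 0 <= dyn_fraction <= 1:
        raise ValueError("dyn_fraction must be in [0, 1]")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    sp = {"amplitude": 1.0, "lengthscale_factor": 0.3, "base_log_mean": np.log(100.0)}
    sp.update(signal_params or {})
    npr = {"dispersion": 10.0}
    npr.update(noise_params or {})
    rng = np.random.default_rng(seed)

    times = np.asarray(times, dtype=float)
    t_axis = transform_times(times)
    span = t_axis.max() - t_axis.min()
    ell = sp["lengthscale_factor"] * span
    T = len(times)

    ids = (
        [("peak", i) for i in scaffold.peaks["peak_id"]]
        + [("interaction", i) for i in scaffold.interactions["interaction_id"]]
        + [("gene", i) for i in scaffold.genes["gene_id"]]
    )
    truth: dict[str, str] = {}
    latent: dict[str, np.ndarray] = {}
    for kind, fid in ids:
        dyn = rng.random() < dyn_fraction
        truth[fid] = "dynamic" if dyn else "static"
        f = _gp_draw(rng, t_axis, sp["amplitude"], ell) if dyn else np.zeros(T)
        latent[fid] = f

    # plant shared-dynamics links: dynamic peak copies its latent to one
    # interaction from its fragment and to that interaction's first gene
    true_links = []
    inter_by_oe = scaffold.interactions.groupby("oe_frag_id")
    for _, pk in scaffold.peaks.iterrows():
        pid = pk["peak_id"]
        if truth[pid] != "dynamic" or rng.random() > linked_fraction:
            continue
        if pk["frag_id"] not in inter_by_oe.groups:
            continue
        sub = inter_by_oe.get_group(pk["frag_id"])
        row = sub.iloc[int(rng.integers(len(sub)))]
        iid = row["interaction_id"]
        gid = row["gene_ids"].split(",")[0]
        share = latent[pid]
        jit = 0.1 * sp["amplitude"]
        latent[iid] = share + rng.normal(0, jit, size=T)
        latent[gid] = share + rng.normal(0, jit, size=T)
        truth[iid] = truth[gid] = "dynamic"
        true_links.append({"peak_id": pid, "interaction_id": str(iid), "gene_id": gid})

    def counts_for(fids):
        data = {}
        for fid in fids:
            mu = np.exp(sp["base_log_mean"] + np.log(2.0) * latent[fid])
            mat = np.stack(
                [_nb_counts(rng, mu, npr["dispersion"]) for _ in range(replicates)]
            )
            data[fid] = mat.ravel()
        cols = pd.MultiIndex.from_tuples(
            [(r, int(t)) for r in range(1, replicates + 1) for t in times]
        )
        return pd.DataFrame.from_dict(data, orient="index", columns=cols)

    peak_counts = counts_for(scaffold.peaks["peak_id"])
    interaction_counts = counts_for(scaffold.interactions["interaction_id"])
    gene_counts = counts_for(scaffold.genes["gene_id"])

    # CHiCAGO-like scores: high where counts are high; always one point > 5
    sc = {}
    for iid in scaffold.interactions["interaction_id"]:
        base = 2.0 + 4.0 * rng.random()
        prof = base + 2.0 * np.maximum(latent[iid], 0) + rng.normal(0, 0.5, size=T)
        prof[int(rng.integers(T))] += 4.0
        sc[iid] = np.maximum(prof, 0.0)
    interaction_scores = pd.DataFrame.from_dict(
        sc, orient="index", columns=[int(t) for t in times]
    )

    scaffold.truth["dynamic"] = truth
    scaffold.truth["true_links"] = true_links
    return {
        "peak_counts": peak_counts,
        "interaction_counts": interaction_counts,
        "gene_counts": gene_counts,
        "interaction_scores": interaction_scores,
        "truth": truth,
        "true_links": true_links,
    }


def simulate_gwas_locus(
    scaffold: ScaffoldBundle | None = None,
    causal_snp: str | None = None,
    effect: tuple[float, float] = (0.25, 0.05),
    n_snps: int = 50,
    ld_decay: float = 1.0 / 50_000,
    seed: int = 0,
    positions: np.ndarray | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Simulate one GWAS locus: summary statistics plus an LD (r^2) matrix.

    The causal SNP has true log odds ratio ``effect[0]`` with standard error
    ``effect[1]``; non-causal effects attenuate as E[beta_j] = r_j^2 * beta
    (single-causal-variant regime). Sampling noise is N(0, se^2) with
    LD-induced correlation across SNPs (Corr = r, the signed allelic
    correlation): effect estimates from one cohort share sampling error
    according to LD, so proxies and the causal variant move together.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    beta_c, se = effect
    if se <= 0:
        raise ValueError("se must be positive")
    rng = np.random.default_rng(seed)

    if scaffold is not None and scaffold.snps is not None and len(scaffold.snps) >= n_snps:
        sub = scaffold.snps.iloc[:n_snps].reset_index(drop=True)
        pos = sub["pos"].to_numpy()
        rsids = sub["rsid"].tolist()
        chrom = scaffold.chrom
    else:
        if positions is None:
            positions = np.sort(rng.choice(500_000, size=n_snps, replace=False))
        pos = np.asarray(positions)[:n_snps]
        rsids = [f"rs{i}" for i in range(n_snps)]
        chrom = "chr1"
    ld = _ld_from_positions(pos, ld_decay)

    if causal_snp is None:
        causal_idx = int(rng.integers(n_snps))
        causal_snp = rsids[causal_idx]
    else:
        if causal_snp not in rsids:
            raise ValueError(f"causal SNP {causal_snp!r} not in panel")
        causal_idx = rsids.index(causal_snp)

    r2_to_causal = ld[:, causal_idx]
    corr = np.sqrt(ld)  # signed allelic correlation (non-negative here)
    L = np.linalg.cholesky(corr + 1e-8 * np.eye(n_snps))
    betas = r2_to_causal * beta_c + se * (L @ rng.standard_normal(n_snps))
    stats = pd.DataFrame(
        {"rsid": rsids, "chrom": chrom, "pos": pos.astype(int),
         "beta": betas, "se": se}
    )
    stats.attrs["causal_snp"] = causal_snp
    if scaffold is not None:
        scaffold.truth["causal_snp"] = causal_snp
    return stats, ld
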