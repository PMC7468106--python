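"""Peak-interaction-gene link construction, correlation and enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from chromdyn.linkage import (
    assign_stratum,
    background_enrichment,
    build_links,
    correlate_links,
    filter_features,
    log2_span,
)

TIMES = [0, 20, 60, 120, 240, 1440]


def _scores(rows: dict) -> pd.DataFrame:
    return pd.DataFrame.from_dict(rows, orient="index", columns=TIMES)


def _counts(rows: dict, reps=2) -> pd.DataFrame:
    cols = pd.MultiIndex.from_tuples([(r, t) for r in range(1, reps + 1) for t in TIMES])
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def _inter(rows) -> pd.DataFrame:
    return pd.DataFrame(
        rows, columns=["interaction_id", "bait_frag_id", "oe_frag_id", "gene_ids"]
    )


def test_interaction_kept_only_if_score_exceeds_threshold():
    inter = _inter([("i1", 1, 2, "g1"), ("i2", 1, 3, "g1")])
    scores = _scores({"i1": [0, 0, 0, 5.1, 0, 0], "i2": [5.0, 5.0, 5.0, 5.0, 5.0, 5.0]})
    genes = _counts({"g1": [100] * 12})
    kept, _ = filter_features(inter, scores, genes)
    assert kept["interaction_id"].tolist() == ["i1"]  # "over 5" is strict


def test_gene_dropped_unless_total_reached_in_every_replicate():
    inter = _inter([("i1", 1, 2, "g1")])
    scores = _scores({"i1": [9, 9, 9, 9, 9, 9]})
    genes = _counts({"g_low": [1, 2, 2, 2, 1, 1] + [100] * 6,  # rep1 total 9
                     "g_ok": [2, 2, 2, 2, 1, 1] + [100] * 6})  # rep1 total 10
    _, kept_genes = filter_features(inter, scores, genes)
    assert kept_genes == ["g_ok"]


def test_bait_to_bait_registered_as_two_interactions():
    inter = _inter([("i1", 1, 2, "g1")])  # otherEnd 2 is itself a bait
    scores = _scores({"i1": [9, 0, 0, 0, 0, 0]})
    genes = _counts({"g1": [100] * 12})
    kept, _ = filter_features(inter, scores, genes, bait_frag_ids=[1, 2])
    assert len(kept) == 2
    fwd, rev = kept.iloc[0], kept.iloc[1]
    assert (fwd["bait_frag_id"], fwd["oe_frag_id"]) == (1, 2)
    assert (rev["bait_frag_id"], rev["oe_frag_id"]) == (2, 1)


def test_missing_score_row_is_a_format_error():
    inter = _inter([("i1", 1, 2, "g1")])
    with pytest.raises(ValueError, match="score"):
        filter_features(inter, _scores({"other": [9] * 6}), _counts({"g1": [100] * 12}))


FRAGS = pd.DataFrame(
    {"frag_id": [1, 2, 3], "chrom": "chr1",
     "start": [0, 100_000, 500_000], "end": [100_000, 500_000, 900_000]}
)


def test_one_peak_many_baits_gives_one_link_per_bait_and_gene():
    peaks = pd.DataFrame(
        [("p1", "chr1", 10_000, 10_400, 1)],
        columns=["peak_id", "chrom", "start", "end", "frag_id"],
    )
    inter = _inter([("i1", 2, 1, "gA"), ("i2", 3, 1, "gB,gC")])
    links = build_links(peaks, inter, FRAGS)
    assert len(links) == 3  # bait 2 (1 gene) + bait 3 (2 genes)
    assert set(links["gene_id"]) == {"gA", "gB", "gC"}
    # distance = |bait midpoint - otherEnd midpoint|
    d12 = abs(300_000 - 50_000)
    assert links.loc[links["interaction_id"] == "i1", "distance"].iloc[0] == d12


def test_peak_in_fragment_without_interactions_yields_no_links():
    peaks = pd.DataFrame(
        [("p1", "chr1", 600_000, 600_400, 3)],
        columns=["peak_id", "chrom", "start", "end", "frag_id"],
    )
    inter = _inter([("i1", 2, 1, "gA")])
    assert len(build_links(peaks, inter, FRAGS)) == 0


def test_peak_without_fragment_is_skipped_with_count():
    peaks = pd.DataFrame(
        [("p1", "chr1", 10_000, 10_400, None)],
        columns=["peak_id", "chrom", "start", "end", "frag_id"],
    )
    links = build_links(peaks, _inter([("i1", 2, 1, "gA")]), FRAGS)
    assert len(links) == 0 and links.attrs["skipped"] == 1


def test_stratum_boundaries_are_half_open():
    assert assign_stratum(150_000) == "<200 kb"
    assert assign_stratum(200_000) == "200-500 kb"
    assert assign_stratum(350_000) == "200-500 kb"
    assert assign_stratum(500_000) == "500 kb-1 Mb"
    assert assign_stratum(1_000_000) == "1-5 Mb"
    assert assign_stratum(5_000_000) is None  # dropped


def _mirrored_tables():
    """Counts engineered so the normalised averaged series are u and 7-u."""
    u = np.arange(1.0, 7.0)
    c = 2.0**u - 1          # peak series -> normalised exactly u
    d = 2.0 ** (7 - u) - 1  # gene series -> normalised exactly 7-u
    total = 1e6
    peak_counts = _counts({"p1": list(c) * 2, "fill_p": list(total - c) * 2})
    gene_counts = _counts({"gA": list(d) * 2, "fill_g": list(total - d) * 2})
    inter_counts = _counts({"i1": list(c) * 2, "fill_i": list(total - c) * 2})
    return peak_counts, inter_counts, gene_counts


def test_correlations_identity_and_mirror():
    peaks = pd.DataFrame(
        [("p1", "chr1", 10_000, 10_400, 1)],
        columns=["peak_id", "chrom", "start", "end", "frag_id"],
    )
    links = build_links(peaks, _inter([("i1", 2, 1, "gA")]), FRAGS)
    pk, ic, gn = _mirrored_tables()
    out = correlate_links(links, pk, ic, gn)
    assert out["r_atac_chic"].iloc[0] == pytest.approx(1.0)   # identical series
    assert out["r_atac_gene"].iloc[0] == pytest.approx(-1.0)  # mirrored series
    assert not out["excluded"].iloc[0]


def test_zero_variance_series_is_flagged_excluded():
    peaks = pd.DataFrame(
        [("p1", "chr1", 10_000, 10_400, 1)],
        columns=["peak_id", "chrom", "start", "end", "frag_id"],
    )
    links = build_links(peaks, _inter([("i1", 2, 1, "gA")]), FRAGS)
    pk, ic, gn = _mirrored_tables()
    # flat gene series with the filler adjusted so library sizes stay equal
    gn.loc["gA"] = 100.0
    gn.loc["fill_g"] = 1e6 - 100.0
    out = correlate_links(links, pk, ic, gn)
    assert out["excluded"].iloc[0]
    assert np.isnan(out["r_atac_gene"].iloc[0])


def test_log2_span_examples():
    assert log2_span([5, 5, 5]) == 0.0
    assert log2_span([1000, 8000]) == pytest.approx(3.0, abs=0.01)
    assert log2_span([0, 0, 0]) == 0.0
    with pytest.raises(ValueError):
        log2_span([])


def test_background_draw_count_must_be_positive(sim_small):
    links = pd.DataFrame(
        {"stratum": ["<200 kb"], "r_atac_gene": [0.9], "excluded": [False]}
    )
    with pytest.raises(ValueError):
        background_enrichment(
            links, sim_small["peak_counts"], sim_small["interaction_counts"],
            sim_small["gene_counts"], n_draws=0,
        )


def test_background_null_exchangeable_across_seeds(sim_small):
    links = pd.DataFrame(columns=["stratum", "r_atac_gene", "excluded"])
    kw = dict(
        peak_counts=sim_small["peak_counts"],
        interaction_counts=sim_small["interaction_counts"],
        gene_counts=sim_small["gene_counts"],
        n_draws=2000,
    )
    null1 = background_enrichment(links, seed=1, **kw)["null"]
    null2 = background_enrichment(links, seed=2, **kw)["null"]
    assert sstats.ks_2samp(null1, null2).pvalue > 0.01


def test_observed_sampled_from_null_is_not_flagged(sim_small):
    """Calibration: null-distributed links rarely reject at alpha=0.01."""
    kw = dict(
        peak_counts=sim_small["peak_counts"],
        interaction_counts=sim_small["interaction_counts"],
        gene_counts=sim_small["gene_counts"],
    )
    pool = background_enrichment(
        pd.DataFrame(columns=["stratum", "r_atac_gene", "excluded"]),
        n_draws=4000, seed=5, **kw,
    )["null"]
    rng = np.random.default_rng(5)
    rejections = 0
    for rep in range(20):
        obs = rng.choice(pool, size=500, replace=False)
        links = pd.DataFrame(
            {"stratum": "<200 kb", "r_atac_gene": obs, "excluded": False}
        )
        res = background_enrichment(links, n_draws=2000, seed=100 + rep, **kw)
        rejections += res["<200 kb"]["p_value"] < 0.01
    assert rejections <= 2
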