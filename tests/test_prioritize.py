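"""LD expansion, SNP-peak-gene assignment, compartments and reporting."""

import numpy as np
import pandas as pd
import pytest

from chromdyn.prioritize import (
    assign_genes,
    compartment_membership,
    ld_expand,
    overlap_snps_peaks,
    percentage,
    summary_report,
)

RSIDS = ["rs0", "rs1", "rs2", "rs3"]
LD = np.array(
    [
        [1.0, 0.8, 0.79, 0.1],
        [0.8, 1.0, 0.5, 0.1],
        [0.79, 0.5, 1.0, 0.1],
        [0.1, 0.1, 0.1, 1.0],
    ]
)


def test_ld_expand_threshold_is_inclusive():
    out = ld_expand("rs0", LD, RSIDS, r2_threshold=0.8)
    assert "rs1" in out      # exactly 0.8 included
    assert "rs2" not in out  # 0.79 excluded
    assert "rs0" in out      # lead always included (r^2 = 1)


def test_ld_expand_idempotent_and_errors():
    out = ld_expand("rs0", LD, RSIDS)
    again = set()
    for lead in out:
        again |= set(x for x in ld_expand(lead, LD, RSIDS) if x in out)
    assert set(out) == again  # re-expanding within the set adds nothing new
    with pytest.raises(ValueError):
        ld_expand("rs_missing", LD, RSIDS)


PEAKS = pd.DataFrame(
    [("p1", "chr1", 100, 200), ("p2", "chr1", 300, 400), ("p3", "chr2", 100, 200)],
    columns=["peak_id", "chrom", "start", "end"],
)


def test_snp_peak_overlap_half_open_convention():
    snps = pd.DataFrame(
        {"rsid": ["a", "b", "c", "d"], "chrom": "chr1", "pos": [100, 200, 250, 399]}
    )
    pairs = overlap_snps_peaks(snps, PEAKS)
    got = set(zip(pairs["rsid"], pairs["peak_id"]))
    assert ("a", "p1") in got   # pos == start included
    assert ("b", "p1") not in got  # pos == end excluded
    assert ("c", "p1") not in got and ("c", "p2") not in got
    assert ("d", "p2") in got


def test_chromosome_mismatch_is_a_non_match_not_an_error():
    snps = pd.DataFrame({"rsid": ["x"], "chrom": "chrX", "pos": [150]})
    assert len(overlap_snps_peaks(snps, PEAKS)) == 0


def _links(rows):
    return pd.DataFrame(
        rows, columns=["peak_id", "gene_id", "r_atac_chic", "r_atac_gene", "r_gene_chic"]
    )


def test_assign_genes_requires_all_three_correlations():
    pairs = pd.DataFrame({"rsid": ["a"], "pos": [150], "peak_id": ["p1"]})
    hits = assign_genes(pairs, _links([("p1", "g1", 0.9, 0.8, 0.7)]))
    assert len(hits) == 1
    none = assign_genes(pairs, _links([("p1", "g1", 0.9, 0.4, 0.7)]))
    assert len(none) == 0
    # signed threshold: strong negative correlation does not qualify...
    neg = assign_genes(pairs, _links([("p1", "g1", -0.9, 0.8, 0.7)]))
    assert len(neg) == 0
    # ...unless absolute mode is requested
    absmode = assign_genes(pairs, _links([("p1", "g1", -0.9, 0.8, 0.7)]), absolute=True)
    assert len(absmode) == 1


def test_two_qualifying_genes_give_two_hits():
    pairs = pd.DataFrame({"rsid": ["a"], "pos": [150], "peak_id": ["p1"]})
    hits = assign_genes(
        pairs, _links([("p1", "g1", 0.9, 0.8, 0.7), ("p1", "g2", 0.6, 0.6, 0.6)])
    )
    assert sorted(hits["gene_id"]) == ["g1", "g2"]


def _tracks(labels_by_time):
    out = {}
    for t, labels in labels_by_time.items():
        out[t] = pd.DataFrame(
            [("chr1", 0, 1000, labels[0]), ("chr1", 1000, 2000, labels[1])],
            columns=["chrom", "start", "end", "label"],
        )
    return out


def test_compartment_classes():
    snps = pd.DataFrame({"rsid": ["s1", "s2", "s3"], "chrom": "chr1",
                         "pos": [500, 1500, 500]})
    tracks = _tracks({20: ("B", "A"), 240: ("A", "A")})
    out = compartment_membership(snps, tracks).set_index("rsid")
    assert out.loc["s1", "class"] == "switching"      # B at 20 min, A at 4 h
    assert out.loc["s2", "class"] == "consistent A"
    snps_out = pd.DataFrame({"rsid": ["far"], "chrom": "chr9", "pos": [10]})
    assert compartment_membership(snps_out, tracks)["class"].iloc[0] == "unassigned"


def test_overlapping_compartments_rejected():
    bad = {
        0: pd.DataFrame([("chr1", 0, 1000, "A"), ("chr1", 500, 1500, "B")],
                        columns=["chrom", "start", "end", "label"]),
        20: pd.DataFrame([("chr1", 0, 1000, "A")],
                         columns=["chrom", "start", "end", "label"]),
    }
    snps = pd.DataFrame({"rsid": ["s"], "chrom": "chr1", "pos": [10]})
    with pytest.raises(ValueError, match="overlap"):
        compartment_membership(snps, bad)


def test_percentage_rounds_half_away_from_zero():
    assert percentage(63_843, 271_398) == 24.0
    assert percentage(7_852, 74_583) == 11.0   # 10.528% -> 11
    assert percentage(2_131, 2_192) == 97.0
    assert percentage(0, 100) == 0.0
    assert percentage(105, 1000, decimals=1) == 10.5
    assert percentage(1, 8) == 13.0  # 12.5 rounds away from zero
    with pytest.raises(ZeroDivisionError):
        percentage(1, 0)


def test_report_mean_genes_per_peak_one_decimal():
    hits = pd.DataFrame(
        {"rsid": [f"s{i}" for i in range(10)],
         "peak_id": ["p1", "p2"] * 5,
         "gene_id": [f"g{i}" for i in range(5)] * 2}
    )
    rep = summary_report(hits=hits)
    assert rep["n_hit_peaks"] == 2 and rep["n_hit_genes"] == 5
    assert rep["mean_genes_per_peak"] == 2.5
    rep2 = summary_report(extra_ratios={"chic_dynamic_pct": (63_843, 271_398)})
    assert rep2["chic_dynamic_pct"] == 24.0
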