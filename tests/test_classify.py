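import numpy as np
import pandas as pd
import pytest

from polyac.classify import (
    ClassifyConfig, call_apa_te, call_dge, classify_genes, compile_report,
    occupancy,
)
from polyac.counting import CountMatrix
from polyac.differential import DesignSpec

from conftest import CD9_PAC_ROWS, CD9_SAMPLES


def _design():
    return DesignSpec(CD9_SAMPLES, ["Ctrl"] * 3 + ["Kd"] * 3, reference="Ctrl")


def _gene_pacs(rows):
    """rows: (name, ordinal, occ_ref, occ_alt, padj[, category, coord])"""
    recs = []
    for row in rows:
        name, ordinal, occ_ref, occ_alt, padj = row[:5]
        cat = row[5] if len(row) > 5 else "exon"
        coord = row[6] if len(row) > 6 else 100
        recs.append({
            "name": name, "gene": "g", "category": cat, "chrom": "chr1",
            "coord": coord, "ordinal": ordinal, "occ_ref": occ_ref,
            "occ_alt": occ_alt, "delta_occ": occ_alt - occ_ref,
            "eligible": max(occ_ref, occ_alt) >= 0.05, "padj": padj,
        })
    return pd.DataFrame(recs).set_index("name")


class TestOccupancy:
    def test_single_pac_gene_is_one(self):
        cm = CountMatrix("pac", pd.DataFrame(
            {s: [10] for s in CD9_SAMPLES}, index=["g_exon_chr1:1_PAS-1"]))
        occ = occupancy(cm, _design(), sf=pd.Series(1.0, index=CD9_SAMPLES))
        assert occ["occ_ref"].iloc[0] == 1.0 and occ["occ_alt"].iloc[0] == 1.0

    def test_published_counts_occupancy(self):
        cm = CountMatrix("pac", pd.DataFrame.from_dict(
            CD9_PAC_ROWS, orient="index", columns=CD9_SAMPLES))
        occ = occupancy(cm, _design(), sf=pd.Series(1.0, index=CD9_SAMPLES))
        # distal cluster holds ~88% of control signal (5053/5713 pooled)
        pas2 = occ.loc["CD9_exon_chr12:6346929_PAS-2"]
        assert pas2["occ_ref"] == pytest.approx(5053 / 5713, abs=1e-12)
        assert bool(occ["eligible"].all())
        # usage swings toward the proximal cluster on knockdown
        assert occ.loc["CD9_exon_chr12:6346929_PAS-1", "delta_occ"] > 0.10

    def test_low_share_both_conditions_ineligible(self):
        cm = CountMatrix("pac", pd.DataFrame(
            {s: [4, 96] for s in CD9_SAMPLES},
            index=["g_exon_chr1:1_PAS-1", "g_exon_chr1:1_PAS-2"]))
        occ = occupancy(cm, _design(), sf=pd.Series(1.0, index=CD9_SAMPLES))
        assert not occ["eligible"].loc["g_exon_chr1:1_PAS-1"]

    def test_silent_condition_gives_na_judged_on_other(self):
        cm = CountMatrix("pac", pd.DataFrame(
            [[10, 12, 11, 0, 0, 0], [30, 28, 31, 0, 0, 0]],
            index=["g_exon_chr1:1_PAS-1", "g_exon_chr1:1_PAS-2"],
            columns=CD9_SAMPLES))
        occ = occupancy(cm, _design(), sf=pd.Series(1.0, index=CD9_SAMPLES))
        assert occ["occ_alt"].isna().all()
        assert occ["eligible"].all()

    def test_intergenic_excluded(self):
        cm = CountMatrix("pac", pd.DataFrame(
            {s: [10, 5] for s in CD9_SAMPLES},
            index=["g_exon_chr1:1_PAS-1", "intergenic_PAS-1"]))
        occ = occupancy(cm, _design(), sf=pd.Series(1.0, index=CD9_SAMPLES))
        assert "intergenic_PAS-1" not in occ.index


class TestCallDge:
    @pytest.mark.parametrize("log2fc,padj,expected", [
        (2.0, 0.001, "UP"),
        (-2.0, 0.001, "DOWN"),
        (0.5, 0.0001, "NC"),      # below log2(1.5) ~ 0.585
        (2.0, 0.2, "NC"),
        (np.nan, np.nan, "NC"),
    ])
    def test_thresholds(self, log2fc, padj, expected):
        assert call_dge(log2fc, padj) == expected


class TestCallApaTe:
    def test_proximal_gain_is_shortening(self):
        pacs = _gene_pacs([
            ("p1", 1, 0.3, 0.7, 0.001),
            ("p2", 2, 0.7, 0.3, 0.001),
        ])
        te, apa = call_apa_te(pacs)
        assert (te, apa) == ("none", "APA_shortening")

    def test_distal_gain_is_lengthening(self):
        pacs = _gene_pacs([
            ("p1", 1, 0.7, 0.3, 0.001),
            ("p2", 2, 0.3, 0.7, 0.001),
        ])
        assert call_apa_te(pacs) == ("none", "APA_lengthening")

    def test_no_significant_change_in_two_exons_is_silent(self):
        pacs = _gene_pacs([
            ("p1", 1, 0.5, 0.52, 0.8, "exon", 100),
            ("p2", 1, 0.5, 0.48, 0.8, "exon", 900),
        ])
        assert call_apa_te(pacs) == ("none", "none")

    def test_cross_exon_shift_is_te(self):
        pacs = _gene_pacs([
            ("p1", 1, 0.3, 0.7, 0.001, "exon", 100),
            ("p2", 1, 0.7, 0.3, 0.001, "exon", 900),
        ])
        te, apa = call_apa_te(pacs)
        assert te == "TE" and apa == "none"

    def test_middle_pac_drop_feeding_both_flanks_is_both(self):
        pacs = _gene_pacs([
            ("p1", 1, 0.30, 0.45, 0.3),
            ("p2", 2, 0.40, 0.10, 0.001),
            ("p3", 3, 0.30, 0.45, 0.3),
        ])
        assert call_apa_te(pacs) == ("none", "APA_both")

    def test_significant_but_small_shift_does_not_trigger(self):
        pacs = _gene_pacs([
            ("p1", 1, 0.50, 0.55, 0.001),
            ("p2", 2, 0.50, 0.45, 0.001),
        ])
        assert call_apa_te(pacs) == ("none", "none")

    def test_single_eligible_pac_never_calls(self):
        pacs = _gene_pacs([
            ("p1", 1, 0.97, 0.97, 0.001),
            ("p2", 2, 0.03, 0.03, 0.001),
        ])
        assert call_apa_te(pacs) == ("none", "none")

    def test_pair_exclusivity_one_verdict_per_pair(self):
        # one significant same-exon pair yields exactly one APA direction
        pacs = _gene_pacs([
            ("p1", 1, 0.3, 0.7, 0.001),
            ("p2", 2, 0.7, 0.3, 0.2),
        ])
        te, apa = call_apa_te(pacs)
        assert te == "none" and apa == "APA_shortening"

    def test_mirrored_ordinals_flip_direction(self):
        fwd = _gene_pacs([
            ("p1", 1, 0.3, 0.7, 0.001),
            ("p2", 2, 0.7, 0.3, 0.001),
        ])
        mirrored = _gene_pacs([
            ("p1", 2, 0.3, 0.7, 0.001),
            ("p2", 1, 0.7, 0.3, 0.001),
        ])
        assert call_apa_te(fwd)[1] == "APA_shortening"
        assert call_apa_te(mirrored)[1] == "APA_lengthening"

    def test_missing_ordinals_are_an_error(self):
        pacs = _gene_pacs([("p1", 1, 0.3, 0.7, 0.001)])
        pacs["ordinal"] = np.nan
        with pytest.raises(ValueError, match="ordinal"):
            call_apa_te(pacs)


class TestReport:
    def _tables(self):
        pac = CountMatrix("pac", pd.DataFrame(
            [[100, 110, 90, 400, 380, 420],
             [300, 280, 310, 120, 130, 110],
             [50, 55, 45, 52, 48, 50]],
            index=["cd9like_exon_chr1:100_PAS-1", "cd9like_exon_chr1:100_PAS-2",
                   "solo_exon_chr2:50_PAS-1"],
            columns=CD9_SAMPLES))
        gene_res = pd.DataFrame(
            {"base_mean": [250.0, 50.0], "log2fc": [0.4, 0.0],
             "padj": [0.3, 0.9]}, index=["cd9like", "solo"])
        pac_res = pd.DataFrame(
            {"base_mean": [200.0, 210.0, 50.0], "log2fc": [2.0, -1.3, 0.0],
             "padj": [0.001, 0.001, 0.9]}, index=pac.data.index)
        return pac, gene_res, pac_res

    def test_gene_and_pac_rows(self):
        pac, gene_res, pac_res = self._tables()
        occ = occupancy(pac, _design())
        calls = classify_genes(gene_res, pac_res, occ)
        report = compile_report(gene_res, pd.DataFrame(), pac_res, calls)
        by_gene = report.groupby("gene").size()
        assert by_gene["cd9like"] == 3  # gene row + two cluster rows
        assert by_gene["solo"] == 1     # single-cluster gene: gene row only
        cd9row = report[(report.gene == "cd9like") & (report.row_type == "gene")]
        assert cd9row["apa"].iloc[0] == "APA_shortening"

    def test_deterministic_output(self):
        pac, gene_res, pac_res = self._tables()
        outs = []
        for _ in range(2):
            occ = occupancy(pac, _design())
            calls = classify_genes(gene_res, pac_res, occ)
            outs.append(compile_report(gene_res, pd.DataFrame(), pac_res, calls)
                        .to_csv(index=False))
        assert outs[0] == outs[1]

    def test_missing_gene_row_is_consistency_error(self):
        pac, gene_res, pac_res = self._tables()
        occ = occupancy(pac, _design())
        with pytest.raises(ValueError, match="absent from the gene table"):
            classify_genes(gene_res.drop(index="cd9like"), pac_res, occ)

    def test_intronic_rows_excluded_unless_enabled(self):
        pac = CountMatrix("pac", pd.DataFrame(
            [[100] * 6, [80] * 6],
            index=["g_exon_chr1:100_PAS-1", "g_intron_chr1:500_PAS-1"],
            columns=CD9_SAMPLES))
        gene_res = pd.DataFrame({"base_mean": [90.0], "log2fc": [0.0],
                                 "padj": [0.9]}, index=["g"])
        pac_res = pd.DataFrame({"base_mean": [100.0, 80.0], "log2fc": [0.0, 0.0],
                                "padj": [0.9, 0.9]}, index=pac.data.index)
        occ = occupancy(pac, _design())
        calls = classify_genes(gene_res, pac_res, occ)
        assert len(calls[0].pac_rows) == 1
        calls_i = classify_genes(gene_res, pac_res, occ,
                                 ClassifyConfig(include_introns=True))
        assert len(calls_i[0].pac_rows) == 2
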