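"""Start-site aggregation, SL2 ratios, upstream distances, gene calls."""

import numpy as np
import pandas as pd
import pytest

from slclip.classify import CLASSIFICATION_COLUMNS
from slclip.gene_summary import (
    Annotation,
    aggregate_start_sites,
    classify_gene,
    dominant_starts,
    flag_low_sl_genes,
    sl2_ratio,
    sl2_variant_profile,
    sl_variant_usage,
    start_site_report,
    trans_spliced_sweep,
)


def _rows(n, ref_id="tx1", start=0, read_class="SL1", sl_name="SL1",
          family="SL1", confident=True, prefix="r"):
    rows = []
    for i in range(n):
        is_sl = read_class not in ("endogenous_hairpin", "unidentified",
                                   "sense_untested")
        rows.append({
            "read_id": f"{prefix}{ref_id}{start}{read_class}{i}",
            "ref_id": ref_id, "start_pos": start, "is_antisense": True,
            "clip5_len": 100, "read_class": read_class,
            "sl_name": sl_name if is_sl and read_class == sl_name else None,
            "sl_family": family if is_sl else None,
            "sl_score": 20 if is_sl else None,
            "sl_trunc": 0 if is_sl else None,
            "sl_end_offset": 0 if is_sl else None,
            "sl_confident": bool(confident and is_sl),
            "hp_matched_nt": 15 if read_class == "endogenous_hairpin" else None,
        })
    return rows


def _df(*chunks):
    return pd.DataFrame([r for c in chunks for r in c],
                        columns=CLASSIFICATION_COLUMNS)


GFF = """##gff-version 3
##sequence-region chr1 1 20000
chr1\tsrc\tgene\t1\t1000\t.\t+\t.\tID=gUP;biotype=protein_coding
chr1\tsrc\tgene\t1100\t2000\t.\t+\t.\tID=gA;biotype=protein_coding
chr1\tsrc\tmRNA\t1100\t2000\t.\t+\t.\tID=tx1;Parent=gA
chr1\tsrc\tgene\t5000\t5800\t.\t-\t.\tID=gB;biotype=protein_coding
chr1\tsrc\tmRNA\t5000\t5800\t.\t-\t.\tID=tx2;Parent=gB
chr1\tsrc\tgene\t5900\t6900\t.\t-\t.\tID=gDOWN;biotype=protein_coding
chr1\tsrc\tgene\t10000\t10500\t.\t+\t.\tID=gOVL1;biotype=protein_coding
chr1\tsrc\tgene\t10400\t11000\t.\t+\t.\tID=gOVL2;biotype=protein_coding
chr2\tsrc\tgene\t100\t400\t.\t+\t.\tID=gFIRST;biotype=protein_coding
"""


@pytest.fixture()
def annotation(tmp_path):
    p = tmp_path / "a.gff3"
    p.write_text(GFF)
    return Annotation.from_gff3(p)


class TestAggregation:
    def test_single_position_single_class(self):
        sites = aggregate_start_sites(_df(_rows(10)))
        assert len(sites) == 1
        row = sites.iloc[0]
        assert row["n_total"] == 10 and row["n_sl"] == 10
        assert row["n[SL1]"] == 10

    def test_dominant_position_by_support(self):
        df = _df(_rows(60, start=5), _rows(40, start=9))
        dom = dominant_starts(aggregate_start_sites(df))
        assert dom.iloc[0]["start_pos"] == 5

    def test_dominant_tie_breaks_to_5prime_most(self):
        df = _df(_rows(40, start=9), _rows(40, start=5))
        dom = dominant_starts(aggregate_start_sites(df))
        assert dom.iloc[0]["start_pos"] == 5

    def test_counts_conserve_total(self):
        df = _df(_rows(7), _rows(5, read_class="endogenous_hairpin"),
                 _rows(3, read_class="unidentified", start=4),
                 _rows(2, ref_id="tx2", read_class="SL2.1", sl_name="SL2.1",
                       family="SL2"))
        sites = aggregate_start_sites(df)
        assert sites["n_total"].sum() == len(df)
        class_cols = [c for c in sites.columns if c.startswith("n[")]
        assert sites[class_cols].to_numpy().sum() == len(df)

    def test_unannotated_transcript_binned_by_ref_id(self, annotation):
        df = _df(_rows(4, ref_id="txZ"))
        sites = aggregate_start_sites(df, annotation)
        assert sites.iloc[0]["gene_id"] == "txZ"


class TestSL2Ratio:
    def _sites(self, n_sl2, n_sl1):
        df = _df(_rows(n_sl2, read_class="SL2.1", sl_name="SL2.1", family="SL2"),
                 _rows(n_sl1))
        return aggregate_start_sites(df)

    def test_ratio_and_categories(self):
        out = sl2_ratio(self._sites(7, 3))
        assert out.iloc[0]["sl2_ratio"] == pytest.approx(0.70)
        assert out.iloc[0]["category"] == "SL2"
        assert sl2_ratio(self._sites(0, 10)).iloc[0]["category"] == "SL1"

    def test_boundaries_are_strict(self):
        assert sl2_ratio(self._sites(6, 4)).iloc[0]["category"] == "intermediate"
        assert sl2_ratio(self._sites(4, 6)).iloc[0]["category"] == "intermediate"

    def test_sites_below_min_discriminable_excluded(self):
        assert sl2_ratio(self._sites(5, 4)).empty
        assert len(sl2_ratio(self._sites(5, 5))) == 1

    def test_sl2x_counts_toward_family_totals(self):
        df = _df(_rows(6, read_class="SL2.X", sl_name=None, family="SL2"),
                 _rows(4))
        out = sl2_ratio(aggregate_start_sites(df))
        assert out.iloc[0]["sl2_ratio"] == pytest.approx(0.6)


class TestUpstreamDistance:
    def test_plus_strand_distance(self, annotation):
        assert annotation.upstream_distance("gA") == 100

    def test_minus_strand_mirror(self, annotation):
        assert annotation.upstream_distance("gB") == 100

    def test_first_gene_undefined(self, annotation):
        assert annotation.upstream_distance("gFIRST") is None
        assert annotation.upstream_distance("gUP") is None

    def test_overlapping_upstream_gene_gives_zero(self, annotation):
        assert annotation.upstream_distance("gOVL2") == 0

    def test_unknown_gene_undefined(self, annotation):
        assert annotation.upstream_distance("nope") is None


class TestGeneCall:
    def test_majority_sl_is_trans_spliced(self):
        df = _df(_rows(15), _rows(5, read_class="endogenous_hairpin"))
        call = classify_gene(aggregate_start_sites(df), min_reads=20)
        assert call.iloc[0]["status"] == "trans_spliced"
        assert call.iloc[0]["sl_fraction"] == pytest.approx(0.75)

    def test_19_reads_is_low_coverage(self):
        df = _df(_rows(14), _rows(5, read_class="endogenous_hairpin"))
        call = classify_gene(aggregate_start_sites(df), min_reads=20)
        assert call.iloc[0]["status"] == "low_coverage"

    def test_hairpin_dominated_gene(self):
        df = _df(_rows(3), _rows(17, read_class="endogenous_hairpin"))
        call = classify_gene(aggregate_start_sites(df))
        assert call.iloc[0]["status"] == "hairpin"

    def test_only_unidentified_reads(self):
        df = _df(_rows(25, read_class="unidentified"))
        call = classify_gene(aggregate_start_sites(df))
        assert call.iloc[0]["status"] == "unidentified"

    def test_sweep_is_monotone_in_threshold(self):
        df = _df(_rows(15), _rows(5, read_class="endogenous_hairpin"),
                 _rows(30, ref_id="tx2", read_class="SL2.1", sl_name="SL2.1",
                       family="SL2"),
                 _rows(25, ref_id="tx3", read_class="endogenous_hairpin"),
                 _rows(12, ref_id="tx3"))
        sweep = trans_spliced_sweep(aggregate_start_sites(df),
                                    thresholds=np.linspace(0.05, 0.95, 10))
        fr = sweep["frac_trans_spliced"].to_numpy()
        assert (np.diff(fr) <= 1e-12).all()


class TestLowSLFlag:
    def _sites(self, n_total, n_sl):
        df = _df(_rows(n_sl), _rows(n_total - n_sl, read_class="unidentified"))
        return aggregate_start_sites(df)

    def test_flagged_at_9_percent(self):
        assert flag_low_sl_genes(self._sites(100, 9)) == ["tx1"]

    def test_exactly_10_percent_not_flagged(self):
        assert flag_low_sl_genes(self._sites(100, 10)) == []

    def test_insufficient_support_not_flagged(self):
        assert flag_low_sl_genes(self._sites(99, 0)) == []


class TestVariantUsage:
    def test_all_sl1(self):
        usage = sl_variant_usage(_df(_rows(10)))
        assert usage.iloc[0]["frac_all"] == 1.0

    def test_within_sl2_fractions(self):
        df = _df(_rows(21, read_class="SL2.1", sl_name="SL2.1", family="SL2"),
                 _rows(15, read_class="SL2.8", sl_name="SL2.8", family="SL2"),
                 _rows(64, read_class="SL2.3", sl_name="SL2.3", family="SL2"))
        usage = sl_variant_usage(df).set_index("sl_name")
        assert usage.loc["SL2.1", "frac_within_family"] == pytest.approx(0.21)
        assert usage.loc["SL2.8", "frac_within_family"] == pytest.approx(0.15)

    def test_unconfident_and_ambiguous_excluded(self):
        df = _df(_rows(5), _rows(3, confident=False),
                 _rows(2, read_class="SL.X", sl_name=None, family=None))
        usage = sl_variant_usage(df)
        assert usage["n"].sum() == 5

    def test_sl2x_tallied_separately(self):
        df = _df(_rows(4, read_class="SL2.1", sl_name="SL2.1", family="SL2"),
                 _rows(6, read_class="SL2.X", sl_name=None, family="SL2"))
        usage = sl_variant_usage(df).set_index("sl_name")
        assert usage.loc["SL2.X", "n"] == 6
        assert usage.loc["SL2.1", "frac_within_family"] == pytest.approx(0.4)


class TestVariantProfile:
    def test_single_variant_site_is_one_hot(self):
        df = _df(_rows(12, read_class="SL2.1", sl_name="SL2.1", family="SL2"))
        sites = aggregate_start_sites(df)
        prof = sl2_variant_profile(df, sites)
        assert prof.shape == (1, 1)
        assert prof.iloc[0]["SL2.1"] == 1.0

    def test_rows_sum_to_one(self):
        df = _df(_rows(8, read_class="SL2.1", sl_name="SL2.1", family="SL2"),
                 _rows(4, read_class="SL2.8", sl_name="SL2.8", family="SL2"))
        prof = sl2_variant_profile(df, aggregate_start_sites(df))
        assert np.allclose(prof.sum(axis=1), 1.0)

    def test_empty_site_set(self):
        df = _df(_rows(3, read_class="SL2.1", sl_name="SL2.1", family="SL2"))
        assert sl2_variant_profile(df, pd.DataFrame(
            columns=["gene_id", "ref_id", "start_pos"])).empty


class TestStartSiteReport:
    def test_two_promoter_gene(self, annotation):
        """A distal hairpin promoter and a proximal SL promoter get two rows
        with distinct majority labels."""
        df = _df(_rows(30, read_class="endogenous_hairpin", start=0),
                 _rows(20, start=350))
        report = start_site_report(df, "gA", annotation)
        assert list(report["majority_label"]) == ["hairpin", "SL"]
        # genomic lift: + strand gene starting at 1100
        assert list(report["genomic_pos"]) == [1100, 1450]

    def test_minority_mixture_is_no_evidence(self):
        df = _df(_rows(5), _rows(5, read_class="endogenous_hairpin"))
        report = start_site_report(df, "tx1")
        assert report.iloc[0]["majority_label"] == "no-evidence"

    def test_gene_without_reads_gives_empty_report(self):
        assert start_site_report(_df(_rows(3)), "ghost").empty
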