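"""Catalog parsing, locus chaining, LD pruning, and panel assembly."""

import datetime

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from riskdrift import LdTable, Locus, assign_loci, build_panels, prune_locus, read_catalog
from riskdrift.catalog import CatalogFormatError, CatalogValidationError

from helpers import make_snp

CATALOG_HEADER = "rsid\tchrom\tpos\trisk_allele\traf\tor\tpvalue\treport_date\tsource\tn_cases\tn_controls\n"


def write_catalog(tmp_path, rows, name="catalog.tsv"):
    path = tmp_path / name
    path.write_text(CATALOG_HEADER + "".join(rows))
    return path


def row(rsid="rs1", chrom="1", pos=1000000, raf=0.3, orr=1.2, p=1e-9,
        date="2009-06-01", source="s1"):
    return f"{rsid}\t{chrom}\t{pos}\tA\t{raf}\t{orr}\t{p}\t{date}\t{source}\t1000\t1000\n"


class TestReadCatalog:
    def test_wellformed_rows_pass_through(self, tmp_path):
        path = write_catalog(tmp_path, [row("rs1"), row("rs2", pos=2), row("rs3", pos=3)])
        records = read_catalog(path)
        assert len(records) == 3
        assert records[0].odds_ratio == pytest.approx(1.2)

    def test_subthreshold_pvalue_excluded(self, tmp_path):
        path = write_catalog(tmp_path, [row("rs1", p=1e-7), row("rs2", p=4.9e-8)])
        records = read_catalog(path, alpha=5e-8)
        assert [r.rsid for r in records] == ["rs2"]

    def test_invalid_raf_rejected_with_row(self, tmp_path):
        path = write_catalog(tmp_path, [row("rs1", raf=1.2)])
        with pytest.raises(CatalogValidationError, match="rs1"):
            read_catalog(path)

    def test_missing_column_is_format_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("rsid\tchrom\tpos\n")
        with pytest.raises(CatalogFormatError, match="missing columns"):
            read_catalog(path)

    def test_protective_allele_flipped_to_risk_orientation(self, tmp_path):
        path = write_catalog(tmp_path, [row("rs1", raf=0.7, orr=0.8)])
        (rec,) = read_catalog(path)
        assert rec.odds_ratio == pytest.approx(1.25)
        assert rec.raf == pytest.approx(0.3)


class TestAssignLoci:
    def test_nearby_snps_share_a_locus(self):
        snps = [make_snp("a", pos=100_000), make_snp("b", pos=500_000)]
        loci = assign_loci(snps)
        assert len(loci) == 1 and len(loci[0]) == 2

    def test_single_linkage_chains_through_middle_snp(self):
        snps = [make_snp("a", pos=1), make_snp("b", pos=400_001), make_snp("c", pos=800_001)]
        assert len(assign_loci(snps)) == 1
        # remove the middle SNP and the chain breaks
        assert len(assign_loci([snps[0], snps[2]])) == 2

    def test_chromosomes_never_merge(self):
        snps = [make_snp("a", chrom="1", pos=100), make_snp("b", chrom="2", pos=100)]
        assert len(assign_loci(snps)) == 2

    def test_empty_input(self):
        assert assign_loci([]) == []


def locus_of(*snps):
    return Locus(locus_id="L", chromosome=snps[0].chromosome, snps=tuple(snps))


class TestPruneLocus:
    def two_snp_setup(self, r2):
        a = make_snp("a", pos=100, p_value=1e-20)
        b = make_snp("b", pos=200, p_value=1e-10)
        ld = LdTable({("a", "b"): r2})
        return locus_of(a, b), ld

    def test_high_ld_keeps_only_top_snp(self):
        locus, ld = self.two_snp_setup(0.9)
        assert [s.rsid for s in prune_locus(locus, ld)] == ["a"]

    def test_low_ld_keeps_both(self):
        locus, ld = self.two_snp_setup(0.5)
        assert [s.rsid for s in prune_locus(locus, ld)] == ["a", "b"]

    def test_threshold_one_keeps_all(self):
        locus, ld = self.two_snp_setup(1.0)
        assert len(prune_locus(locus, ld, r2_max=1.0)) == 2

    def test_threshold_zero_keeps_exactly_one(self):
        locus, ld = self.two_snp_setup(0.0)
        assert len(prune_locus(locus, ld, r2_max=0.0)) == 1

    def test_missing_pair_is_an_error(self):
        locus = locus_of(make_snp("a", pos=1), make_snp("b", pos=2))
        with pytest.raises(KeyError, match="no r2 value"):
            prune_locus(locus, LdTable())

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        r2s=st.lists(st.floats(0, 1), min_size=3, max_size=3),
        r2_max=st.sampled_from([0.0, 0.25, 0.5, 0.75]),
    )
    def test_pruning_is_idempotent(self, r2s, r2_max):
        snps = [make_snp(n, pos=i + 1, p_value=10.0 ** -(9 + i)) for i, n in enumerate("abc")]
        ld = LdTable({("a", "b"): r2s[0], ("a", "c"): r2s[1], ("b", "c"): r2s[2]})
        once = prune_locus(locus_of(*snps), ld, r2_max=r2_max)
        twice = prune_locus(locus_of(*once), ld, r2_max=r2_max)
        assert [s.rsid for s in once] == [s.rsid for s in twice]


class TestBuildPanels:
    DATES = ["2007-12-31", "2009-12-31", "2011-12-31", "2013-12-31"]

    def test_snp_enters_at_first_panel_after_report(self):
        rec = make_snp("a", report_date="2008-06-01")
        panels = build_panels([rec], self.DATES)
        assert [p.k for p in panels] == [0, 1, 1, 1]

    def test_or_updated_only_by_more_significant_report(self):
        first = make_snp("a", odds_ratio=1.30, p_value=1e-9, report_date="2009-01-01")
        second = make_snp(
            "a", odds_ratio=1.25, p_value=1e-15, report_date="2012-01-01", source="s2"
        )
        panels = build_panels([first, second], self.DATES)
        assert panels[1].snps[0].odds_ratio == pytest.approx(1.30)
        assert panels[3].snps[0].odds_ratio == pytest.approx(1.25)

    def test_tied_pvalue_keeps_earlier_report(self):
        first = make_snp("a", odds_ratio=1.30, p_value=1e-9, report_date="2009-01-01")
        second = make_snp("a", odds_ratio=1.10, p_value=1e-9, report_date="2012-01-01", source="s2")
        panels = build_panels([first, second], self.DATES)
        assert panels[3].snps[0].odds_ratio == pytest.approx(1.30)

    def test_empty_records_give_empty_panels(self):
        panels = build_panels([], self.DATES)
        assert [p.k for p in panels] == [0, 0, 0, 0]

    def test_duplicate_rows_rejected(self):
        rec = make_snp("a")
        with pytest.raises(ValueError, match="duplicate"):
            build_panels([rec, rec], self.DATES)

    def test_panels_contain_no_future_reports(self):
        records = [
            make_snp("a", report_date="2008-01-01"),
            make_snp("b", report_date="2010-01-01", pos=5_000_000),
            make_snp("c", report_date="2012-01-01", pos=9_000_000),
        ]
        panels = build_panels(records, self.DATES)
        for panel in panels:
            assert all(s.report_date <= panel.date for s in panel.snps)

    def test_effective_or_matches_minimum_p_brute_force(self):
        rng = np.random.default_rng(11)
        reports = []
        for i in range(6):
            reports.append(
                make_snp(
                    "a",
                    odds_ratio=float(rng.uniform(1.05, 1.5)),
                    p_value=float(10.0 ** -rng.uniform(8, 20)),
                    report_date=f"{2007 + i}-03-01",
                    source=f"s{i}",
                )
            )
        panels = build_panels(reports, self.DATES)
        for panel in panels:
            eligible = [r for r in reports if r.report_date <= panel.date]
            if not eligible:
                assert panel.k == 0
                continue
            best = min(eligible, key=lambda r: r.p_value)
            assert panel.snps[0].odds_ratio == pytest.approx(best.odds_ratio)

    def test_nonincreasing_dates_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            build_panels([], ["2009-01-01", "2009-01-01"])
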