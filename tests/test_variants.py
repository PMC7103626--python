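"""Heuristic variant filter and TEC -> iPSC inheritance comparison."""

import numpy as np
import pandas as pd
import pytest

from medseq.variants import (
    VariantFixtureSpec,
    compare_inheritance,
    exonic_nonsyn_filter,
    heuristic_filter,
    make_variant_fixture,
    read_variant_table,
)


def variant(pos=100, filter_pass=True, depth=30, vaf=0.3, pop_af=0.0, **extra):
    rec = {"contig": "chr1", "pos": pos, "ref": "A", "alt": "T",
           "filter_pass": filter_pass, "depth": depth, "vaf": vaf, "pop_af": pop_af}
    rec.update(extra)
    return rec


class TestHeuristicFilter:
    def test_depth_gate(self):
        kept, reasons = heuristic_filter(pd.DataFrame([variant(depth=5)]))
        assert kept.empty and reasons["depth"] == 1
        kept, _ = heuristic_filter(pd.DataFrame([variant(depth=6)]))
        assert len(kept) == 1

    def test_population_af_gate(self):
        kept, reasons = heuristic_filter(pd.DataFrame([variant(pop_af=0.0003)]))
        assert kept.empty and reasons["pop_af"] == 1
        kept, _ = heuristic_filter(pd.DataFrame([variant(pop_af=0.0002)]))
        assert len(kept) == 1

    def test_missing_population_af_is_novel(self):
        df = pd.DataFrame([variant(pop_af=np.nan)])
        kept, _ = heuristic_filter(df)
        assert len(kept) == 1

    def test_caller_filter_gate(self):
        kept, reasons = heuristic_filter(pd.DataFrame([variant(filter_pass=False)]))
        assert kept.empty and reasons["caller_filter"] == 1

    def test_idempotent_and_order_independent(self):
        df = pd.DataFrame([variant(pos=p, depth=d)
                           for p, d in [(1, 3), (2, 30), (3, 100), (4, 5)]])
        once, _ = heuristic_filter(df)
        twice, reasons = heuristic_filter(once)
        assert once.equals(twice)
        assert sum(reasons.values()) == 0
        shuffled, _ = heuristic_filter(df.iloc[::-1])
        assert set(shuffled["pos"]) == set(once["pos"])

    def test_malformed_record_errors(self):
        with pytest.raises(ValueError, match="ref equals alt"):
            heuristic_filter(pd.DataFrame([dict(variant(), ref="A", alt="A")]))


class TestExonicNonsynFilter:
    def test_consequence_classes(self):
        df = pd.DataFrame([
            variant(pos=1, region_class="exonic", consequence="frameshift"),
            variant(pos=2, region_class="exonic", consequence="synonymous"),
            variant(pos=3, region_class="intronic", consequence="unknown"),
        ])
        kept = exonic_nonsyn_filter(df)
        assert list(kept["pos"]) == [1]

    def test_missing_annotation_errors(self):
        with pytest.raises(ValueError, match="region_class"):
            exonic_nonsyn_filter(pd.DataFrame([variant()]))


class TestCompareInheritance:
    def test_classes_partition_rows(self):
        spec = VariantFixtureSpec(seed=3, n_shared=2, n_partial=1,
                                  n_private_tec=3, n_private_ipsc=2)
        tec, ipsc, lineage = make_variant_fixture(spec)
        table, summary = compare_inheritance(tec, ipsc, lineage)
        row = summary.iloc[0]
        assert row["all"] == 2 and row["some"] == 1 and row["none"] == 3
        assert row["all"] + row["some"] + row["none"] == row["n_variants"] == len(table)

    def test_private_ipsc_variants_not_rows(self):
        spec = VariantFixtureSpec(seed=4, n_shared=1, n_private_tec=0, n_private_ipsc=5)
        tec, ipsc, lineage = make_variant_fixture(spec)
        table, _ = compare_inheritance(tec, ipsc, lineage)
        tec_keys = set(map(tuple, tec["TEC1"][["contig", "pos"]].to_numpy()))
        assert set(map(tuple, table[["contig", "pos"]].to_numpy())) <= tec_keys

    def test_absence_distinct_from_zero_vaf(self):
        tec = {"T": pd.DataFrame([variant(pos=10, vaf=0.2)])}
        ipsc = {"c1": pd.DataFrame([variant(pos=10, vaf=0.0)]),
                "c2": pd.DataFrame([variant(pos=99)])}
        table, _ = compare_inheritance(tec, ipsc, {"c1": "T", "c2": "T"})
        assert table.loc[0, "vaf_c1"] == 0.0          # present with VAF 0
        assert np.isnan(table.loc[0, "vaf_c2"])        # absent
        assert table.loc[0, "inheritance"] == "some"

    def test_unknown_parent_errors(self):
        tec = {"T": pd.DataFrame([variant()])}
        ipsc = {"c1": pd.DataFrame([variant()])}
        with pytest.raises(ValueError, match="unknown parental"):
            compare_inheritance(tec, ipsc, {"c1": "missing"})

    def test_fixture_deterministic(self):
        spec = VariantFixtureSpec(seed=5)
        t1, i1, _ = make_variant_fixture(spec)
        t2, i2, _ = make_variant_fixture(spec)
        assert t1["TEC1"].equals(t2["TEC1"])
        for clone in i1:
            assert i1[clone].equals(i2[clone])


class TestReadVariantTable:
    def test_tsv_round_trip(self, tmp_path):
        df = pd.DataFrame([variant(pos=1), variant(pos=2, depth=4)])
        p = tmp_path / "v.tsv"
        df.to_csv(p, sep="\t", index=False)
        loaded = read_variant_table(str(p))
        assert len(loaded) == 2 and loaded["depth"].tolist() == [30, 4]

    def test_vcf_info_mapping(self, tmp_path):
        vcf = (
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=DP,Number=1,Type=Integer,Description="depth">\n'
            '##INFO=<ID=AF,Number=1,Type=Float,Description="vaf">\n'
            '##INFO=<ID=POP_AF,Number=1,Type=Float,Description="population AF">\n'
            "##contig=<ID=chr1,length=100000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t150\t.\tG\tC\t50\tPASS\tDP=44;AF=0.31;POP_AF=0.0001\n"
            "chr1\t250\t.\tG\tC\t50\tLowQual\tDP=44;AF=0.31\n"
        )
        p = tmp_path / "v.vcf"
        p.write_text(vcf)
        df = read_variant_table(str(p))
        assert len(df) == 2
        first = df.iloc[0]
        assert (first["pos"], first["depth"], first["vaf"]) == (150, 44, pytest.approx(0.31))
        assert first["pop_af"] == pytest.approx(0.0001)
        assert not df.iloc[1]["filter_pass"]
        assert np.isnan(df.iloc[1]["pop_af"])
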