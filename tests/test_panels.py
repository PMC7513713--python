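"""Genotype readers, roster validation, and standardized heterozygosity."""

import numpy as np
import pytest

from matechoice import (
    GenotypePanel,
    RosterEntry,
    read_genotypes,
    read_roster,
    standardized_heterozygosity,
)
from matechoice.panels import PanelValidationError

from conftest import random_panel


def smlh_oracle(panel):
    """Independent sMLH: explicit per-locus mean-heterozygosity sums via call sets."""
    hbar = {}
    for loc in panel.loci:
        hets, typed = 0, 0
        for iid in panel.individual_ids:
            c = panel.call(iid, loc)
            if c is not None:
                typed += 1
                hets += len(c) == 2
        if typed:
            hbar[loc] = hets / typed
    out = {}
    for iid in panel.individual_ids:
        h_raw, denom = 0, 0.0
        for loc in panel.loci:
            c = panel.call(iid, loc)
            if c is not None:
                h_raw += len(c) == 2
                denom += hbar[loc]
        out[iid] = h_raw / denom if denom > 0 else float("nan")
    return out


class TestReaders:
    def test_wide_csv_roundtrip_with_missing(self, tmp_path):
        p = tmp_path / "g.csv"
        p.write_text("id,L1,L2\nd1,AG,..\n")
        panel = read_genotypes(p, "wide_csv")
        assert panel.call("d1", "L1") == frozenset({"A", "G"})
        assert panel.call("d1", "L2") is None

    def test_two_col_csv_microsat(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("id,Loc1.1,Loc1.2,Loc2.1,Loc2.2\nd1,212,216,0,0\nd2,212,212,150,154\n")
        panel = read_genotypes(p, "two_col_csv")
        assert panel.call("d1", "Loc1") == frozenset({"212", "216"})
        assert panel.call("d1", "Loc2") is None
        assert panel.call("d2", "Loc1") == frozenset({"212"})

    def test_vcf_het_call(self, tmp_path):
        p = tmp_path / "g.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n"
            "1\t100\tsnp1\tC\tT\t.\tPASS\t.\tGT\t0/1\t./.\n"
        )
        panel = read_genotypes(p, "vcf")
        assert panel.call("s1", "snp1") == frozenset({"C", "T"})
        assert panel.call("s2", "snp1") is None

    def test_multiallelic_vcf_rejected(self, tmp_path):
        p = tmp_path / "g.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            "1\t100\tsnp1\tC\tT,G\t.\tPASS\t.\tGT\t0/1\n"
        )
        with pytest.raises(PanelValidationError, match="biallelic"):
            read_genotypes(p, "vcf")

    def test_duplicate_individual_rejected(self, tmp_path):
        p = tmp_path / "g.csv"
        p.write_text("id,L1\nd1,AG\nd1,AA\n")
        with pytest.raises(PanelValidationError, match="duplicate"):
            read_genotypes(p, "wide_csv")

    def test_half_call_treated_as_missing(self, tmp_path):
        p = tmp_path / "g.csv"
        p.write_text("id,L1\nd1,A/.\nd2,AA\n")
        panel = read_genotypes(p, "wide_csv")
        assert panel.call("d1", "L1") is None


class TestRoster:
    def _write(self, tmp_path, rows):
        p = tmp_path / "r.csv"
        header = "individual_id,enclosure_year_id,sex,age,weight,bred,n_offspring\n"
        p.write_text(header + "\n".join(rows) + "\n")
        return p

    def test_valid_rows_accepted(self, tmp_path):
        p = self._write(tmp_path, ["d1,A2011,F,2,7.5,1,2", "d2,A2011,M,4,10.1,0,0"])
        roster = read_roster(p)
        assert len(roster) == 2 and roster[0].bred == 1

    @pytest.mark.parametrize(
        "row,match",
        [
            ("d1,A2011,F,2,7.5,1,5", "exceeds"),  # female litter cap of 4
            ("d1,A2011,M,2,9.0,0,1", "inconsistent"),  # bred=0 with offspring
            ("d1,A2011,X,2,9.0,0,0", "sex"),  # unknown sex code
        ],
    )
    def test_invalid_rows_rejected(self, tmp_path, row, match):
        p = self._write(tmp_path, [row])
        with pytest.raises(PanelValidationError, match=match):
            read_roster(p)

    def test_individual_may_repeat_across_enclosure_years(self, tmp_path):
        p = self._write(tmp_path, ["d1,A2011,F,2,7.5,0,0", "d1,A2012,F,3,7.9,1,1"])
        assert len(read_roster(p)) == 2


class TestStandardizedHeterozygosity:
    def test_hand_example(self):
        # 2 individuals, 2 loci, no missing; ind1 het at both, ind2 at none:
        # Hbar = (0.5, 0.5) so h_std = (2/1, 0/1)
        panel = GenotypePanel.from_calls(
            "T",
            {
                "i1": {"L1": ("a", "b"), "L2": ("c", "d")},
                "i2": {"L1": ("a", "a"), "L2": ("c", "c")},
            },
        )
        res = {r.individual_id: r for r in standardized_heterozygosity(panel)}
        assert res["i1"].h_std == pytest.approx(2.0)
        assert res["i2"].h_std == pytest.approx(0.0)
        assert res["i1"].h_raw == 2 and res["i1"].n_typed == 2

    def test_all_homozygous_flagged_undefined(self):
        panel = GenotypePanel.from_calls(
            "T",
            {"i1": {"L1": ("a", "a")}, "i2": {"L1": ("b", "b")}},
        )
        res = standardized_heterozygosity(panel)
        assert all(not r.defined for r in res)

    def test_complete_data_mean_is_one(self, rng):
        for _ in range(20):
            panel = random_panel(rng, n_individuals=8, n_loci=10, missing_rate=0.0)
            vals = [r.h_std for r in standardized_heterozygosity(panel)]
            assert np.mean(vals) == pytest.approx(1.0, abs=1e-12)

    def test_matches_oracle_under_missingness(self, rng):
        for _ in range(20):
            panel = random_panel(rng, n_individuals=7, n_loci=9, missing_rate=0.25)
            oracle = smlh_oracle(panel)
            for r in standardized_heterozygosity(panel):
                expect = oracle[r.individual_id]
                if np.isnan(expect):
                    assert not r.defined
                else:
                    assert r.h_std == pytest.approx(expect, abs=1e-12)

    def test_invariant_to_locus_order_and_individual_permutation(self, rng):
        panel = random_panel(rng, n_individuals=6, n_loci=8, missing_rate=0.2)
        base = {r.individual_id: r.h_std for r in standardized_heterozygosity(panel)}
        order = rng.permutation(panel.n_loci)
        shuffled = GenotypePanel(
            "T",
            list(panel.individual_ids),
            [panel.loci[l] for l in order],
            panel.codes[:, order].copy(),
            [panel.alleles[l] for l in order],
        )
        perm = rng.permutation(panel.n_individuals)
        permuted = GenotypePanel(
            "T",
            [panel.individual_ids[i] for i in perm],
            list(panel.loci),
            panel.codes[perm].copy(),
            [list(a) for a in panel.alleles],
        )
        for other in (shuffled, permuted):
            res = {r.individual_id: r.h_std for r in standardized_heterozygosity(other)}
            for iid, val in base.items():
                assert res[iid] == pytest.approx(val, abs=1e-12) or (
                    np.isnan(val) and np.isnan(res[iid])
                )

    def test_untyped_locus_dropped_with_warning(self):
        panel = GenotypePanel.from_calls(
            "T",
            {
                "i1": {"L1": ("a", "b"), "L2": None},
                "i2": {"L1": ("a", "a"), "L2": None},
            },
            loci=["L1", "L2"],
        )
        with pytest.warns(UserWarning, match="dropping"):
            res = standardized_heterozygosity(panel)
        assert res[0].n_typed == 1


def test_roster_entry_invariants_direct():
    with pytest.raises(PanelValidationError):
        RosterEntry("d1", "A2011", "F", 2, 7.0, bred=1, n_offspring=0)
    ok = RosterEntry("d1", "A2011", "M", 3, None, bred=1, n_offspring=6)
    assert ok.n_offspring == 6  # males may sire more than one litter
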