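"""Reading, filtering, clumping, instrument selection and harmonization."""

import numpy as np
import pandas as pd
import pytest

from protmr import (RegionSpec, exclude_region, harmonize, ld_clump,
                    make_table, read_sumstats, select_instruments,
                    sim_region)

from conftest import row, table


class TestReadValidate:
    def test_well_formed_tsv_roundtrip(self, tmp_path):
        df = pd.DataFrame([row(snp_id=f"rs{i}", pos=1000 + i)
                           for i in range(3)])
        path = tmp_path / "x.tsv"
        df.to_csv(path, sep="\t", index=False)
        t = read_sumstats(path, trait_id="prot")
        assert len(t) == 3
        assert t.trait_id == "prot"

    def test_custom_dialect_and_comma(self, tmp_path):
        df = pd.DataFrame([row()]).rename(columns={
            "snp_id": "MarkerName", "pval": "P.value", "beta": "Effect"})
        path = tmp_path / "x.csv"
        df.to_csv(path, index=False)
        t = read_sumstats(path, dialect={"snp": "MarkerName",
                                         "p": "P.value", "beta": "Effect"})
        assert t.df.loc[0, "snp_id"] == "rs1"

    def test_lowercase_alleles_normalized(self, tmp_path):
        rows = [row(snp_id=f"rs{i}", ea="a", oa="g") for i in range(3)]
        path = tmp_path / "x.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        t = read_sumstats(path)
        expected = pd.DataFrame([row(snp_id=f"rs{i}") for i in range(3)])
        assert len(t) == 3
        assert list(t.df["effect_allele"]) == list(expected["effect_allele"])
        assert list(t.df["other_allele"]) == list(expected["other_allele"])

    def test_missing_column_is_named(self, tmp_path):
        df = pd.DataFrame([row()]).drop(columns=["se"])
        path = tmp_path / "x.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="se"):
            read_sumstats(path)

    def test_empty_file_hard_error(self, tmp_path):
        path = tmp_path / "x.tsv"
        path.write_text("snp_id\tchrom\tpos\teffect_allele\tother_allele\t"
                        "eaf\tbeta\tse\tpval\tn\n")
        with pytest.raises(ValueError, match="empty"):
            read_sumstats(path)

    @pytest.mark.parametrize("bad,reason", [
        (dict(se=0.0), "nonpositive SE"),
        (dict(pval=0.0), "p-value outside (0,1]"),
        (dict(eaf=1.5), "EAF outside [0,1]"),
        (dict(ea="A", oa="A"), "identical alleles"),
        (dict(ea="N"), "non-ACGT allele"),
    ])
    def test_invariant_violations_dropped_and_logged(self, bad, reason):
        rows = [row(snp_id="rs_ok"), row(snp_id="rs_bad", **bad)]
        t = table(rows)
        assert t.snps == ["rs_ok"]
        assert ("rs_bad", reason) in t.validation_log

    def test_duplicate_snp_keeps_first(self):
        t = table([row(snp_id="rs1", beta=0.1), row(snp_id="rs1", beta=0.9)])
        assert len(t) == 1
        assert t.df.loc[0, "beta"] == 0.1


class TestExcludeRegion:
    MHC = RegionSpec("6", 26_000_000, 34_000_000)

    @pytest.mark.parametrize("chrom,pos,kept", [
        ("6", 30_000_000, False),   # inside the MHC
        ("6", 25_999_999, True),    # one bp outside
        ("6", 34_000_000, False),   # inclusive right edge
        ("7", 30_000_000, True),    # wrong chromosome
    ])
    def test_boundaries(self, chrom, pos, kept):
        t = table([row(snp_id="rs1", chrom=chrom, pos=pos)])
        out = exclude_region(t, self.MHC)
        assert (len(out) == 1) == kept

    def test_empty_result_permitted(self):
        t = table([row(chrom="6", pos=27_000_000)])
        assert len(exclude_region(t, self.MHC)) == 0


def _ld_frame(ids, r2):
    return pd.DataFrame(r2, index=ids, columns=ids)


class TestLDClump:
    def test_dominant_snp_wins(self):
        t = table([row(snp_id="a", pval=1e-10), row(snp_id="b", pos=2000,
                                                    pval=1e-9)])
        ld = _ld_frame(["a", "b"], [[1.0, 0.5], [0.5, 1.0]])
        out = ld_clump(t, ld, r2_max=0.001)
        assert out.snps == ["a"]

    def test_independent_all_kept(self):
        t = table([row(snp_id=s, pos=1000 * i, pval=10.0 ** -(9 + i))
                   for i, s in enumerate("abc")])
        out = ld_clump(t, _ld_frame(list("abc"), np.eye(3)), r2_max=0.001)
        assert sorted(out.snps) == ["a", "b", "c"]

    def test_matches_bruteforce_greedy_on_ar1_grid(self, rng):
        # independent re-implementation of the greedy rule as the oracle
        m, rho, r2_max = 10, 0.6, 0.1
        idx = np.arange(m)
        r2 = (rho ** np.abs(idx[:, None] - idx[None, :])) ** 2
        ids = [f"s{i}" for i in range(m)]
        pvals = rng.uniform(1e-12, 1e-6, size=m)
        t = table([row(snp_id=ids[i], pos=1000 * (i + 1), pval=pvals[i])
                   for i in range(m)])
        out = ld_clump(t, _ld_frame(ids, r2), r2_max=r2_max)

        order = np.argsort(pvals, kind="stable")
        kept = []
        for i in order:
            if all(r2[i, j] < r2_max for j in kept):
                kept.append(i)
        assert out.snps == [ids[i] for i in sorted(
            kept, key=lambda j: pvals[j])]

    def test_missing_snp_policies(self):
        t = table([row(snp_id="a", pval=1e-10),
                   row(snp_id="zz", pos=2000, pval=1e-9)])
        ld = _ld_frame(["a"], [[1.0]])
        log = []
        out = ld_clump(t, ld, r2_max=0.5, log=log)
        assert out.snps == ["a"] and ("zz", "missing-from-ld") in log
        with pytest.raises(KeyError, match="zz"):
            ld_clump(t, ld, r2_max=0.5, missing="error")


class TestSelectInstruments:
    CIS = RegionSpec("1", 500_000, 1_500_000)

    def test_p_threshold_is_strict(self):
        t = table([row(snp_id="weak", pval=6e-8),
                   row(snp_id="strong", pos=1_000_100, pval=1e-9)])
        inst = select_instruments(t, p_max=5e-8, cis=self.CIS, ld=None)
        assert inst.table.snps == ["strong"]
        assert ("weak", "above-p-threshold") in inst.selection_log

    def test_trans_and_mhc_reasons(self):
        # cis window deliberately straddles the MHC so both filters act
        cis6 = RegionSpec("6", 25_000_000, 35_000_000)
        t = table([row(snp_id="cis", chrom="6", pos=25_500_000, pval=1e-9),
                   row(snp_id="far", chrom="2", pos=1_000_000, pval=1e-9),
                   row(snp_id="mhc", chrom="6", pos=30_000_000, pval=1e-9)])
        inst = select_instruments(t, cis=cis6)
        assert inst.table.snps == ["cis"]
        assert ("far", "trans") in inst.selection_log
        assert ("mhc", "mhc") in inst.selection_log

    def test_one_causal_snp_region_yields_one_instrument(self):
        t, ld, _ = sim_region(40, 0.9, causal_idx=20, beta_causal=0.12,
                              n=54_219, seed=11)
        inst = select_instruments(t, cis=RegionSpec("1", 1, 10_000_000),
                                  ld=ld, r2_max=0.001)
        assert inst.n_instruments == 1
        # the surviving instrument sits on the causal peak
        assert abs(int(inst.table.snps[0].split("_")[1]) - 20) <= 3

    def test_row_order_invariance(self, rng):
        t, ld, _ = sim_region(30, 0.8, causal_idx=15, beta_causal=0.12,
                              n=54_219, seed=12)
        shuffled = make_table(t.df.sample(frac=1.0, random_state=3),
                              t.trait_id)
        a = select_instruments(t, cis=RegionSpec("1", 1, 10_000_000),
                               ld=ld)
        b = select_instruments(shuffled, cis=RegionSpec("1", 1, 10_000_000),
                               ld=ld)
        assert a.table.snps == b.table.snps

    def test_zero_survivors_flagged(self):
        t = table([row(pval=0.5)])
        inst = select_instruments(t, cis=self.CIS)
        assert inst.status == "empty" and inst.n_instruments == 0


class TestHarmonize:
    def test_allele_swap_flips_beta_and_eaf(self):
        exp = table([row(ea="A", oa="G", beta=0.5, eaf=0.3)])
        out = table([row(ea="G", oa="A", beta=0.2, eaf=0.7)], "out")
        h = harmonize(exp, out)
        assert h.nsnp == 1
        assert h.df.loc[0, "beta_out"] == pytest.approx(-0.2)
        assert h.df.loc[0, "eaf_out"] == pytest.approx(0.3)

    def test_strand_flip_recognized(self):
        exp = table([row(ea="A", oa="G", beta=0.5)])
        out = table([row(ea="T", oa="C", beta=0.2)], "out")
        h = harmonize(exp, out)
        assert h.nsnp == 1
        assert h.df.loc[0, "beta_out"] == pytest.approx(0.2)

    def test_maximally_ambiguous_palindrome_dropped(self):
        exp = table([row(ea="A", oa="T", eaf=0.50)])
        out = table([row(ea="A", oa="T", eaf=0.50, beta=0.2)], "out")
        h = harmonize(exp, out)
        assert h.nsnp == 0
        assert ("rs1", "palindromic-ambiguous") in h.dropped

    def test_informative_palindrome_kept_unchanged(self):
        # hand-harmonized expectation: same alleles, both EAFs rare -> keep
        exp = table([row(ea="A", oa="T", eaf=0.10, beta=0.5)])
        out = table([row(ea="A", oa="T", eaf=0.12, beta=0.2)], "out")
        h = harmonize(exp, out, palindrome_eaf_limit=0.42)
        assert h.nsnp == 1
        assert h.df.loc[0, "beta_out"] == pytest.approx(0.2)
        assert h.df.loc[0, "eaf_out"] == pytest.approx(0.12)

    def test_palindrome_missing_eaf_always_dropped(self):
        exp = table([row(ea="C", oa="G", eaf=np.nan)])
        out = table([row(ea="C", oa="G", eaf=0.1)], "out")
        assert harmonize(exp, out).nsnp == 0

    def test_incompatible_alleles_dropped(self):
        exp = table([row(ea="A", oa="G")])
        out = table([row(ea="A", oa="C")], "out")
        h = harmonize(exp, out)
        assert h.nsnp == 0
        assert ("rs1", "incompatible alleles") in h.dropped

    def test_no_shared_snps_flagged_empty(self):
        exp = table([row(snp_id="rs1")])
        out = table([row(snp_id="rs2")], "out")
        assert harmonize(exp, out).status == "empty"

    def test_idempotent(self, rng):
        # harmonizing an already-aligned pair changes nothing
        exp = table([row(snp_id=f"rs{i}", pos=1000 * (i + 1),
                         beta=rng.normal(), eaf=float(rng.uniform(0.05, .95)))
                     for i in range(20)])
        out = table([row(snp_id=f"rs{i}", pos=1000 * (i + 1),
                         ea="G", oa="A", beta=rng.normal(),
                         eaf=float(rng.uniform(0.05, 0.95)))
                     for i in range(20)], "out")
        h1 = harmonize(exp, out)
        realigned = table([
            dict(row(snp_id=r["snp_id"], ea=r["effect_allele"],
                     oa=r["other_allele"], beta=r["beta_out"],
                     se=r["se_out"], eaf=r["eaf_out"], pval=r["pval_out"]),
                 pos=1000)
            for _, r in h1.df.iterrows()], "out")
        h2 = harmonize(exp, realigned)
        assert h2.nsnp == h1.nsnp
        np.testing.assert_allclose(h2.df["beta_out"], h1.df["beta_out"])
        np.testing.assert_allclose(h2.df["eaf_out"], h1.df["eaf_out"])

    def test_exclude_then_clump_commutes_for_nonlead_exclusions(self):
        ids = list("abcd")
        r2 = np.eye(4)
        r2[2, 3] = r2[3, 2] = 0.9  # c leads d
        t = table([row(snp_id="a", pval=1e-12),
                   row(snp_id="b", chrom="6", pos=27_000_000, pval=1e-7),
                   row(snp_id="c", pos=5000, pval=1e-10),
                   row(snp_id="d", pos=6000, pval=1e-9)])
        ld = _ld_frame(ids, r2)
        mhc = RegionSpec("6", 26_000_000, 34_000_000)
        a = ld_clump(exclude_region(t, mhc), ld, 0.5)
        b = exclude_region(ld_clump(t, ld, 0.5), mhc)
        assert a.snps == b.snps
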