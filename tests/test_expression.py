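"""ΔΔCt relative quantification, gene ratios and group statistics."""

import numpy as np
import pandas as pd
import pytest

from ectpipe.expression import (
    CtTable,
    compare_groups,
    gene_ratio,
    relative_quantify,
    sidak_adjust,
)
from ectpipe.synth import gen_ct_table

REFS = ("GAPDH", "RPL13A")


def _table(rows):
    return CtTable(pd.DataFrame(rows), REFS)


def _row(sample, group, gene, ct, rep=1):
    return dict(sample=sample, group=group, gene=gene, replicate=rep, ct=ct)


class TestRelativeQuantify:
    def test_worked_example_rq_of_four(self):
        # test sample: Ct_gene 25 with refs 20/22 (mean 21) -> dCt 4;
        # calibrator dCt 6 -> ddCt -2 -> RQ 4
        rows = [
            _row("s1", "cal", "GAPDH", 20.0), _row("s1", "cal", "RPL13A", 22.0),
            _row("s1", "cal", "GOI", 27.0),   # dCt 6
            _row("s2", "test", "GAPDH", 20.0), _row("s2", "test", "RPL13A", 22.0),
            _row("s2", "test", "GOI", 25.0),  # dCt 4
        ]
        rq = relative_quantify(_table(rows), "cal")
        goi = rq[(rq.gene == "GOI") & (rq.group == "test")].iloc[0]
        assert goi.ddct == pytest.approx(-2.0, abs=1e-12)
        assert goi.rq == pytest.approx(4.0, abs=1e-12)
        assert goi.log2fc == pytest.approx(2.0, abs=1e-12)

    def test_reference_gene_rq_is_one_in_calibrator(self):
        rows = [
            _row("s1", "cal", "GAPDH", 20.0), _row("s1", "cal", "RPL13A", 22.0),
            _row("s1", "cal", "GOI", 25.0),
        ]
        rq = relative_quantify(_table(rows), "cal")
        for ref in REFS:
            assert rq[rq.gene == ref].iloc[0].rq == pytest.approx(1.0)

    def test_synthetic_round_trip_exact(self):
        true = {"MYH7": {"WT": 1.0, "MUT": 4.0}, "NPPB": {"WT": 1.0, "MUT": 0.25}}
        tab, _ = gen_ct_table(true, noise_sd=0.0, n_samples=4, seed=3)
        rq = relative_quantify(CtTable(tab, REFS), "WT")
        for gene, per_group in true.items():
            for group, expected in per_group.items():
                got = rq[(rq.gene == gene) & (rq.group == group)].rq
                np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_calibrator_geomean_rq_is_one(self):
        tab, _ = gen_ct_table({"G1": {"a": 1.0, "b": 2.0}}, noise_sd=0.3, seed=4)
        rq = relative_quantify(CtTable(tab, REFS), "a")
        cal = rq[(rq.group == "a") & (rq.gene == "G1")].rq
        assert np.exp(np.mean(np.log(cal))) == pytest.approx(1.0, rel=1e-12)

    def test_two_refs_equal_single_pseudo_reference(self):
        """Normalizing by the mean Ct of two references equals normalizing by
        one pseudo-reference whose Ct is their arithmetic mean."""
        tab, _ = gen_ct_table({"G1": {"a": 1.0, "b": 3.0}}, noise_sd=0.2, seed=5)
        rq2 = relative_quantify(CtTable(tab, REFS), "a")
        pseudo = (
            tab[tab.gene.isin(REFS)]
            .groupby(["sample", "group", "replicate"], as_index=False)["ct"].mean()
        )
        pseudo["gene"] = "PSEUDO"
        tab1 = pd.concat([tab[~tab.gene.isin(REFS)], pseudo], ignore_index=True)
        rq1 = relative_quantify(CtTable(tab1, ("PSEUDO",)), "a")
        a = rq2[rq2.gene == "G1"].sort_values("sample").rq.to_numpy()
        b = rq1[rq1.gene == "G1"].sort_values("sample").rq.to_numpy()
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_missing_reference_gene_error(self):
        rows = [_row("s1", "cal", "GAPDH", 20.0), _row("s1", "cal", "GOI", 25.0)]
        with pytest.raises(ValueError, match="RPL13A"):
            _table(rows)

    def test_duplicate_spread_flagged(self):
        rows = [
            _row("s1", "cal", "GAPDH", 20.0, rep=1),
            _row("s1", "cal", "GAPDH", 21.0, rep=2),  # 1.0 cycle spread
            _row("s1", "cal", "RPL13A", 22.0),
            _row("s1", "cal", "GOI", 25.0),
        ]
        t = _table(rows)
        assert len(t.flagged) == 1
        assert t.flagged.iloc[0].gene == "GAPDH"


class TestGeneRatio:
    def _rq(self):
        true = {"MYH7": {"WT": 1.0, "MUT": 2.0}, "MYH6": {"WT": 1.0, "MUT": 1.0}}
        tab, _ = gen_ct_table(true, noise_sd=0.0, n_samples=3, seed=6)
        return relative_quantify(CtTable(tab, REFS), "WT")

    def test_equal_rqs_ratio_one(self):
        rq = self._rq()
        r = gene_ratio(rq, "MYH6", "MYH6")
        assert (r["mean"] == 1.0).all()
        assert (r["sem"] == 0.0).all()

    def test_constant_ratio_mean_and_sem(self):
        rq = self._rq()
        r = gene_ratio(rq, "MYH7", "MYH6")
        mut = r[r.group == "MUT"].iloc[0]
        assert mut["mean"] == pytest.approx(2.0, rel=1e-12)
        assert mut["sem"] == pytest.approx(0.0, abs=1e-12)

    def test_group_summary_matches_flat_recomputation(self):
        rq = self._rq().copy()
        rng = np.random.default_rng(0)
        rq["rq"] = rq["rq"] * rng.uniform(0.9, 1.1, len(rq))
        out = gene_ratio(rq, "MYH7", "MYH6")
        piv = rq.pivot_table(index=["sample", "group"], columns="gene", values="rq")
        flat = (piv["MYH7"] / piv["MYH6"]).reset_index()
        for _, row in out.iterrows():
            vals = flat[flat.group == row.group][0]
            assert row["mean"] == pytest.approx(vals.mean())


class TestCompareGroups:
    def test_identical_groups_p_is_one(self):
        out = compare_groups({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert out.iloc[0].p == pytest.approx(1.0)
        assert not out.iloc[0].significant

    def test_sidak_closed_form(self):
        assert sidak_adjust(0.01, 3) == pytest.approx(1 - 0.99**3, abs=1e-12)
        assert sidak_adjust(0.01, 3) == pytest.approx(0.029701, abs=1e-9)

    def test_t_statistic_matches_textbook_formula(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 10)
        out = compare_groups({"a": a, "b": b})
        sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (
            len(a) + len(b) - 2)
        t_expected = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
        assert out.iloc[0].statistic == pytest.approx(t_expected, abs=1e-12)

    def test_multigroup_has_anova_and_all_pairs(self):
        out = compare_groups({"a": [1, 2, 3], "b": [2, 3, 4], "c": [8, 9, 10]})
        assert out.iloc[0].test == "one-way ANOVA"
        assert len(out) == 1 + 3
        for _, row in out.iloc[1:].iterrows():
            assert row.p_adj == pytest.approx(sidak_adjust(row.p, 3), abs=1e-15)

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups({"a": [1.0], "b": [1.0, 2.0]})
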