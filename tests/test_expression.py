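"""Expression I/O, Mann-Whitney differential expression, module-mean
profiles, and delta-Ct normalization."""

import numpy as np
import pandas as pd
import pytest

from netmark.expression import (
    CtTable,
    ExpressionDataset,
    gene_de_scan,
    mann_whitney,
    module_de,
    module_mean_profile,
    pcr_normalize,
    read_expression,
    write_expression,
)
from netmark.modularity import ModulePartition
from netmark.synthdata import ExpressionScenario, synth_ct, synth_expression

from conftest import mannwhitney_exact_oracle


def _toy_dataset():
    matrix = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0], [5.0, 5.0, 5.0, 5.0]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    labels = pd.Series(["good", "good", "poor", "poor"],
                       index=["s1", "s2", "s3", "s4"])
    return ExpressionDataset(matrix=matrix, labels=labels)


class TestDatasetIO:
    def test_round_trip_identity(self, tmp_path):
        ds = _toy_dataset()
        mp, pp = tmp_path / "m.tsv", tmp_path / "p.tsv"
        write_expression(ds, mp, pp)
        back = read_expression(mp, pp)
        pd.testing.assert_frame_equal(back.matrix, ds.matrix, check_names=False)
        assert back.labels.tolist() == ds.labels.tolist()

    def test_labels_derived_from_ef_by_40_percent_rule(self, tmp_path):
        mp = tmp_path / "m.tsv"
        pp = tmp_path / "p.tsv"
        mp.write_text("gene\ts1\ts2\ng1\t1.0\t2.0\n")
        pp.write_text("sample\tef\ns1\t41\ns2\t40\n")
        ds = read_expression(mp, pp)
        assert ds.labels["s1"] == "good"
        assert ds.labels["s2"] == "poor"

    def test_sample_missing_from_phenotype_rejected(self, tmp_path):
        mp = tmp_path / "m.tsv"
        pp = tmp_path / "p.tsv"
        mp.write_text("gene\ts1\ts2\ng1\t1.0\t2.0\n")
        pp.write_text("sample\tlabel\ns1\tgood\n")
        with pytest.raises(ValueError, match="absent"):
            read_expression(mp, pp)

    def test_ef_label_conflict_rejected(self):
        matrix = pd.DataFrame([[1.0, 2.0]], index=["g"], columns=["s1", "s2"])
        labels = pd.Series(["good", "poor"], index=["s1", "s2"])
        ef = pd.Series([35.0, 30.0], index=["s1", "s2"])  # 35 => poor, not good
        with pytest.raises(ValueError, match="inconsistency"):
            ExpressionDataset(matrix=matrix, labels=labels, ef=ef)

    def test_duplicate_gene_ids_rejected(self):
        matrix = pd.DataFrame([[1.0, 2.0], [3.0, 4.0]],
                              index=["g", "g"], columns=["s1", "s2"])
        labels = pd.Series(["good", "poor"], index=["s1", "s2"])
        with pytest.raises(ValueError, match="duplicate gene"):
            ExpressionDataset(matrix=matrix, labels=labels)

    def test_missing_values_rejected(self):
        matrix = pd.DataFrame([[1.0, np.nan]], index=["g"], columns=["s1", "s2"])
        labels = pd.Series(["good", "poor"], index=["s1", "s2"])
        with pytest.raises(ValueError, match="[Mm]issing"):
            ExpressionDataset(matrix=matrix, labels=labels)


class TestMannWhitney:
    def test_fully_separated_small_groups(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2 / C(6,3)

    def test_identical_constant_data_gives_one(self):
        u, p = mann_whitney([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert p == 1.0
        assert u == 4.5

    def test_u_complement_identity(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.normal(size=int(rng.integers(2, 8)))
            y = rng.normal(size=int(rng.integers(2, 8)))
            u_xy, _ = mann_whitney(x, y)
            u_yx, _ = mann_whitney(y, x)
            assert u_xy + u_yx == pytest.approx(len(x) * len(y))

    def test_exact_p_matches_enumeration_oracle(self):
        rng = np.random.default_rng(8)
        for n1 in range(2, 7):
            for n2 in range(2, 7):
                if n1 + n2 > 12:
                    continue
                x = rng.normal(size=n1)
                y = rng.normal(size=n2)
                u, p = mann_whitney(x, y, mode="exact")
                u_o, p_o = mannwhitney_exact_oracle(x, y)
                assert u == pytest.approx(u_o)
                assert p == pytest.approx(p_o, rel=1e-9)

    def test_exact_and_approx_agree_for_moderate_groups(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            x = rng.normal(size=8)
            y = rng.normal(size=8)
            _, p_e = mann_whitney(x, y, mode="exact")
            _, p_a = mann_whitney(x, y, mode="approx")
            assert abs(p_e - p_a) < 0.02

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestGeneDE:
    def test_planted_shift_detected(self):
        sc = ExpressionScenario(n_genes=50, de_genes={"G0007": 2.0}, seed=4)
        ds = synth_expression(sc)
        out = gene_de_scan(ds).set_index("unit")
        assert out.loc["G0007", "p_nominal"] < 0.01
        assert out.loc["G0007", "direction"] == 1  # up in poor

    def test_null_p_values_roughly_uniform(self):
        # discrete rank-test p-values: count KS rejections over cohorts
        # instead of asserting on a single draw
        from scipy import stats
        rejections = 0
        for seed in range(15, 21):
            ds = synth_expression(ExpressionScenario(n_genes=200, seed=seed))
            p = gene_de_scan(ds, mode="approx")["p_nominal"].to_numpy()
            if stats.kstest(p, "uniform").pvalue < 0.01:
                rejections += 1
        assert rejections <= 2

    def test_constant_gene_p_one(self):
        ds = _toy_dataset()
        out = gene_de_scan(ds, genes=["g3"]).set_index("unit")
        assert out.loc["g3", "p_nominal"] == 1.0

    def test_unknown_gene_listed_in_error(self):
        with pytest.raises(ValueError, match="nope"):
            gene_de_scan(_toy_dataset(), genes=["g1", "nope"])


class TestModuleProfileAndDE:
    def test_single_gene_module_equals_row(self):
        ds = _toy_dataset()
        prof = module_mean_profile(ds, {"g1"})
        assert prof.tolist() == ds.matrix.loc["g1"].tolist()

    def test_two_gene_mean(self):
        ds = _toy_dataset()
        prof = module_mean_profile(ds, {"g1", "g2"})
        assert prof.tolist() == pytest.approx([2.5, 2.5, 2.5, 2.5])

    def test_genes_without_data_dropped(self, caplog):
        import logging
        ds = _toy_dataset()
        with caplog.at_level(logging.INFO, logger="netmark.expression"):
            prof = module_mean_profile(ds, {"g1", "g2", "ghost1", "ghost2"})
        assert prof.tolist() == pytest.approx([2.5, 2.5, 2.5, 2.5])
        assert "2 of 4" in caplog.text

    def test_zero_overlap_rejected(self):
        with pytest.raises(ValueError, match="no module gene"):
            module_mean_profile(_toy_dataset(), {"ghost"})

    def test_gene_order_invariance(self):
        ds = _toy_dataset()
        assert module_mean_profile(ds, ["g2", "g1"]).tolist() == \
            module_mean_profile(ds, ["g1", "g2"]).tolist()

    def test_planted_module_has_smallest_adjusted_p(self):
        genes = [f"G{i:04d}" for i in range(1, 61)]
        planted = genes[:6]
        sc = ExpressionScenario(
            n_genes=60, de_genes={g: 1.5 for g in planted}, seed=6)
        ds = synth_expression(sc)
        assignment = {g: (1 if g in planted else 2 + (i % 8))
                      for i, g in enumerate(genes)}
        part = ModulePartition(assignment=assignment, q=float("nan"))
        out = module_de(ds, part)
        best = out.sort_values("p_adj").iloc[0]
        assert best["unit"] == 1

    def test_single_module_adjustment_is_identity(self):
        ds = _toy_dataset()
        part = ModulePartition(assignment={"g1": 1, "g2": 1}, q=float("nan"))
        out = module_de(ds, part)
        assert len(out) == 1
        assert out["p_adj"].iloc[0] == pytest.approx(out["p_nominal"].iloc[0])

    def test_all_null_modules_rarely_significant(self):
        hits = 0
        reps = 40
        for seed in range(reps):
            sc = ExpressionScenario(n_genes=40, seed=1000 + seed)
            ds = synth_expression(sc)
            assignment = {g: i % 5 for i, g in enumerate(ds.genes)}
            part = ModulePartition(assignment=assignment, q=float("nan"))
            out = module_de(ds, part, mode="approx")
            if out["p_adj"].min() <= 0.05:
                hits += 1
        assert hits <= 0.1 * reps + 2

    def test_no_overlap_rejected(self):
        part = ModulePartition(assignment={"ghost": 1}, q=float("nan"))
        with pytest.raises(ValueError, match="no module overlaps"):
            module_de(_toy_dataset(), part)


class TestPcrNormalize:
    def test_closed_form_values(self):
        ct = pd.DataFrame(
            {"REF": [20.0, 25.0], "A": [20.0, 28.0], "B": [19.0, 22.0]},
            index=["s1", "s2"],
        )
        table = CtTable(ct=ct, reference_gene="REF")
        norm = pcr_normalize(table)
        assert norm["REF"].tolist() == pytest.approx([1.0, 1.0])
        assert norm.loc["s1", "A"] == pytest.approx(1.0)     # equal Ct
        assert norm.loc["s2", "A"] == pytest.approx(0.125)   # +3 cycles
        assert norm.loc["s1", "B"] == pytest.approx(2.0)     # -1 cycle

    def test_per_sample_shift_invariance(self):
        table = synth_ct(6, ["REF", "TRAF2", "UBC"], "REF", seed=2)
        norm = pcr_normalize(table)
        shifted = table.ct.copy()
        shifted.iloc[0] += 2.0
        norm2 = pcr_normalize(CtTable(ct=shifted, reference_gene="REF"))
        pd.testing.assert_series_equal(norm.iloc[0], norm2.iloc[0])

    def test_missing_reference_rejected(self):
        ct = pd.DataFrame({"A": [20.0]}, index=["s1"])
        with pytest.raises(ValueError, match="reference"):
            CtTable(ct=ct, reference_gene="REF")

    def test_nonpositive_ct_rejected(self):
        ct = pd.DataFrame({"REF": [20.0], "A": [-1.0]}, index=["s1"])
        with pytest.raises(ValueError, match="positive"):
            CtTable(ct=ct, reference_gene="REF")
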