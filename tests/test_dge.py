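"""Differential-expression stage: t statistics, BH adjustment, DEG filter,
cross-dataset intersection/merge, and the limma cross-check."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from neuromarker import (
    DEGFilter,
    ExpressionDataset,
    apply_deg_filter,
    collapse_duplicate_genes,
    differential_expression,
    gen_expression,
    intersect_and_merge,
    normalize_log2,
)
from neuromarker.synthetic import SynthConfig


def _ds(values: dict, n_case: int, n_control: int, **kw) -> ExpressionDataset:
    df = pd.DataFrame(values).T
    df.columns = [f"s{i}" for i in range(n_case + n_control)]
    groups = pd.Series(
        ["case"] * n_case + ["control"] * n_control, index=df.columns
    )
    return ExpressionDataset(df, groups, **kw)


class TestNormalizeLog2:
    def test_log_scale_passthrough(self):
        values = pd.DataFrame({"s0": [15.2, 3.0], "s1": [1.0, 2.0]},
                              index=["A", "B"])
        groups = pd.Series({"s0": "case", "s1": "control"})
        ds = normalize_log2(values, groups)
        assert not ds.log_transformed
        assert ds.values.loc["A", "s0"] == 15.2

    def test_linear_scale_transformed(self):
        values = pd.DataFrame({"s0": [1023.0, 3.0], "s1": [1.0, 2.0]},
                              index=["A", "B"])
        groups = pd.Series({"s0": "case", "s1": "control"})
        ds = normalize_log2(values, groups)
        assert ds.log_transformed
        assert ds.values.loc["A", "s0"] == pytest.approx(10.0)

    def test_negative_linear_value_rejected(self):
        values = pd.DataFrame({"s0": [1023.0, -1.0], "s1": [1.0, 2.0]},
                              index=["A", "B"])
        groups = pd.Series({"s0": "case", "s1": "control"})
        with pytest.raises(ValueError, match="negative"):
            normalize_log2(values, groups)


class TestDifferentialExpression:
    def test_exact_fold_change_and_direction(self, tiny_dataset):
        rec = differential_expression(tiny_dataset).set_index("gene")
        assert rec.loc["G0", "log2fc"] == pytest.approx(2.0)
        assert rec.loc["G0", "regulation"] == "Up"

    def test_label_swap_negates_lfc_keeps_p(self, tiny_dataset):
        swapped = ExpressionDataset(
            tiny_dataset.values,
            tiny_dataset.groups.map({"case": "control", "control": "case"}),
        )
        a = differential_expression(tiny_dataset).set_index("gene")
        b = differential_expression(swapped).set_index("gene")
        assert np.allclose(a["log2fc"], -b.loc[a.index, "log2fc"])
        assert np.allclose(a["p"], b.loc[a.index, "p"])

    def test_small_group_error_names_group(self):
        ds = _ds({"A": [1, 2, 3, 4], "B": [2, 3, 4, 5]}, 3, 1)
        with pytest.raises(ValueError, match="control"):
            differential_expression(ds)

    def test_zero_variance_without_shrinkage(self):
        ds = _ds({"flat": [5, 5, 5, 5, 5, 5], "shift": [7, 7, 7, 5, 5, 5],
                  "noisy": [5.1, 4.9, 5.2, 5.0, 4.8, 5.3]}, 3, 3)
        rec = differential_expression(ds, shrinkage=None).set_index("gene")
        assert rec.loc["flat", "p"] == 1.0
        assert rec.loc["shift", "p"] == 0.0

    def test_bh_invariants(self):
        cfg = SynthConfig(seed=5, n_genes=200, n_de=10)
        ds, _ = gen_expression(cfg)
        rec = differential_expression(ds)
        assert ((rec["p_adj"] >= rec["p"] - 1e-12) & (rec["p_adj"] <= 1)).all()
        by_p = rec.sort_values("p")
        assert by_p["p_adj"].is_monotonic_increasing

    def test_null_type1_rate(self):
        """Synthetic null: raw p < 0.05 in ~5% of genes over seeds."""
        rates = []
        for seed in range(10):
            ds, _ = gen_expression(
                SynthConfig(seed=seed, n_genes=1000, de_log2fc=0.0)
            )
            rec = differential_expression(ds)
            rates.append((rec["p"] < 0.05).mean())
        assert 0.03 < np.mean(rates) < 0.07

    def test_matches_limma_moderated_t(self, tmp_path):
        """Independent oracle: Bioconductor limma eBayes on the same matrix."""
        assert shutil.which("Rscript"), "Rscript expected on PATH"
        ds, _ = gen_expression(SynthConfig(seed=3, n_genes=60, n_de=6))
        rec = differential_expression(ds).set_index("gene")
        ds.values.to_csv(tmp_path / "m.csv")
        design = ",".join(
            "1" if ds.groups[s] == "case" else "0" for s in ds.sample_ids
        )
        script = tmp_path / "limma.R"
        script.write_text(
            "suppressMessages(library(limma))\n"
            f'm <- as.matrix(read.csv("{tmp_path}/m.csv", row.names=1))\n'
            f"design <- cbind(Intercept=1, case=c({design}))\n"
            "fit <- eBayes(lmFit(m, design))\n"
            'tt <- topTable(fit, coef="case", number=Inf, sort.by="none")\n'
            f'write.csv(tt[,c("logFC","t","P.Value")], "{tmp_path}/out.csv")\n'
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "out.csv", index_col=0)
        mine = rec.loc[ref.index]
        assert np.allclose(mine["log2fc"], ref["logFC"], atol=1e-9)
        assert np.allclose(mine["t"], ref["t"], rtol=0.02)
        assert np.allclose(mine["p"], ref["P.Value"], atol=0.01)


class TestDEGFilter:
    def _records(self, rows):
        return pd.DataFrame(rows, columns=["gene", "log2fc", "p_adj"]).assign(
            t=0.0, p=0.0
        )

    def test_boundary_semantics(self):
        rec = self._records(
            [("at_thr", 1.5, 0.01), ("at_alpha", 2.0, 0.05), ("weak", -1.6, 0.2),
             ("down", -1.8, 0.01)]
        )
        kept = apply_deg_filter(rec).genes
        assert kept == {"at_alpha", "down"}  # 1.5 strict out, 0.05 inclusive in

    def test_up_down_partition(self):
        rec = self._records([("u", 2.0, 0.01), ("d", -2.0, 0.01)])
        degs = apply_deg_filter(rec)
        assert degs.up == {"u"} and degs.down == {"d"}

    def test_idempotent_and_order_independent(self):
        rec = self._records(
            [("a", 2.0, 0.01), ("b", 1.2, 0.01), ("c", -3.0, 0.04)]
        )
        once = apply_deg_filter(rec)
        again = apply_deg_filter(once.records)
        assert once.genes == again.genes
        shuffled = apply_deg_filter(rec.sample(frac=1, random_state=0))
        assert shuffled.genes == once.genes

    def test_invalid_filter_params(self):
        with pytest.raises(ValueError):
            DEGFilter(lfc_threshold=0)
        with pytest.raises(ValueError):
            DEGFilter(alpha=1.5)


class TestIntersectMerge:
    def _pair(self):
        a = _ds({g: np.arange(6) + i for i, g in enumerate("ABCD")}, 3, 3,
                name="dsA")
        b = _ds({g: np.arange(4) + i for i, g in enumerate("ABCD")}, 2, 2,
                name="dsB")
        return a, b

    def test_intersection_and_union_merge(self):
        a, b = self._pair()
        inter, merged = intersect_and_merge([{"A", "B", "C"}, {"B", "C", "D"}],
                                            [a, b])
        assert inter == {"B", "C"}
        assert sorted(merged.values.index) == ["A", "B", "C", "D"]
        assert merged.values.shape == (4, 10)
        assert {s.split(":")[0] for s in merged.sample_ids} == {"dsA", "dsB"}

    def test_identical_and_disjoint_sets(self):
        a, b = self._pair()
        inter, _ = intersect_and_merge([{"A", "B"}, {"A", "B"}], [a, b])
        assert inter == {"A", "B"}
        inter, merged = intersect_and_merge([{"A"}, {"B"}], [a, b])
        assert inter == set()
        assert sorted(merged.values.index) == ["A", "B"]

    def test_empty_union_error(self):
        a, b = self._pair()
        with pytest.raises(ValueError, match="empty"):
            intersect_and_merge([set(), set()], [a, b])


def test_collapse_duplicates_keeps_highest_mean_probe():
    values = pd.DataFrame(
        [[1.0, 1.0], [5.0, 5.0], [2.0, 2.0]],
        index=["A", "A", "B"],
        columns=["s0", "s1"],
    )
    out = collapse_duplicate_genes(values)
    assert list(out.index) == ["A", "B"]
    assert out.loc["A", "s0"] == 5.0
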