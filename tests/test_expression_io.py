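"""Expression I/O, log2 transform, gene ordering and byte rescaling."""

import io

import numpy as np
import pandas as pd
import pytest

import aiocnn as ac
from aiocnn.errors import (
    MissingGeneError,
    SizingError,
    StateError,
    ValidationError,
)


def _tsv(text: str) -> io.StringIO:
    return io.StringIO(text.strip() + "\n")


class TestReadExpressionTable:
    def test_parses_samples_by_genes(self):
        mat = ac.read_expression_table(_tsv(
            "id\tTP53\tBRCA1\tEGFR\tMYC\n"
            "s1\t0.0\t1.5\t2.0\t3.0\n"
            "s2\t1.0\t0.5\t0.0\t4.0\n"
            "s3\t2.0\t2.5\t1.0\t5.0\n"
        ), sep="\t")
        assert mat.shape == (3, 4)
        assert mat.sample_ids == ["s1", "s2", "s3"]
        assert mat.gene_ids == ["TP53", "BRCA1", "EGFR", "MYC"]

    def test_genes_by_samples_orientation_transposes(self):
        mat = ac.read_expression_table(_tsv(
            "gene\ts1\ts2\nTP53\t1\t2\nMYC\t3\t4\n"
        ), sep="\t", orientation="genes_by_samples")
        assert mat.shape == (2, 2)
        assert mat.gene_ids == ["TP53", "MYC"]
        assert mat.values[1, 0] == 2.0

    def test_duplicate_gene_is_named_in_error(self):
        with pytest.raises(ValidationError, match="TP53"):
            ac.read_expression_table(_tsv(
                "id\tTP53\tTP53\ns1\t1\t2\n"
            ), sep="\t")

    def test_negative_fpkm_reports_coordinates(self):
        with pytest.raises(ValidationError, match="s2.*MYC|MYC.*s2"):
            ac.read_expression_table(_tsv(
                "id\tTP53\tMYC\ns1\t1\t2\ns2\t1\t-2.0\n"
            ), sep="\t")


class TestLog2Transform:
    @pytest.mark.parametrize("fpkm,expected", [(0.0, 0.0), (1.0, 1.0), (3.0, 2.0)])
    def test_pseudocount_one_values(self, fpkm, expected):
        mat = ac.ExpressionMatrix(["s"], ["g"], [[fpkm]], scale="fpkm")
        assert ac.log2_transform(mat).values[0, 0] == pytest.approx(expected)

    def test_double_application_is_a_state_error(self):
        mat = ac.ExpressionMatrix(["s"], ["g"], [[1.0]], scale="fpkm")
        with pytest.raises(StateError):
            ac.log2_transform(ac.log2_transform(mat))

    def test_round_trip_recovers_fpkm(self):
        rng = np.random.default_rng(0)
        vals = rng.gamma(1.0, 10.0, size=(5, 20))
        mat = ac.ExpressionMatrix(
            [f"s{i}" for i in range(5)], [f"g{j}" for j in range(20)], vals
        )
        from aiocnn.expression import inverse_log2

        back = inverse_log2(ac.log2_transform(mat))
        np.testing.assert_allclose(back.values, vals, atol=1e-9)


class TestSharedGeneOrder:
    ann = pd.DataFrame({
        "symbol": ["A", "B", "C", "D"],
        "chromosome": ["1", "1", "1", "2"],
        "tss": [500, 100, 50, 10],
    })

    def test_sorts_by_tss_within_chromosome(self):
        order = ac.shared_gene_order(self.ann, [{"A", "B", "C"}, {"B", "C", "D"}], 2)
        assert order == ["C", "B"]

    def test_numeric_chromosome_ordering(self):
        # chr2 precedes chr10 numerically even though "10" < "2" as strings
        ann = pd.DataFrame({
            "symbol": ["w", "x", "y", "z"],
            "chromosome": ["10", "2", "10", "2"],
            "tss": [1, 5, 2, 1],
        })
        order = ac.shared_gene_order(ann, [{"w", "x", "y", "z"}], 4)
        assert order == ["z", "x", "w", "y"]

    def test_special_contigs_after_autosomes(self):
        ann = pd.DataFrame({
            "symbol": ["m", "x", "a", "y"],
            "chromosome": ["MT", "X", "22", "Y"],
            "tss": [1, 1, 1, 1],
        })
        order = ac.shared_gene_order(ann, [set("mxay")], 4)
        assert order == ["a", "x", "y", "m"]

    def test_truncation_to_image_capacity(self):
        # a 16,889-gene shared list truncates to the first 16,384
        n = 16_889
        ann = pd.DataFrame({
            "symbol": [f"g{i:05d}" for i in range(n)],
            "chromosome": ["1"] * n,
            "tss": np.arange(n) * 10,
        })
        order = ac.shared_gene_order(ann, [set(ann["symbol"])], 16_384)
        assert len(order) == 16_384
        assert order[0] == "g00000" and order[-1] == "g16383"

    def test_undersized_intersection_reports_both_counts(self):
        with pytest.raises(SizingError, match="3.*4|4.*3"):
            ac.shared_gene_order(self.ann, [{"A", "B", "C"}], 4)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        shuffled = self.ann.iloc[rng.permutation(len(self.ann))]
        a = ac.shared_gene_order(self.ann, [set("ABCD"), set("ABC")], 3)
        b = ac.shared_gene_order(shuffled, [set("ABC"), set("ABCD")], 3)
        assert a == b


class TestRescalePerGene:
    def _mat(self, cols):
        vals = np.array(cols, dtype=float).T
        genes = [f"g{j}" for j in range(vals.shape[1])]
        return ac.ExpressionMatrix(
            [f"s{i}" for i in range(vals.shape[0])], genes, vals, scale="log2"
        ), genes

    def test_endpoints_and_half_even_midpoint(self):
        mat, genes = self._mat([[2.0, 4.0, 6.0]])
        scaled, _ = ac.rescale_per_gene(mat, genes)
        assert scaled.values[:, 0].tolist() == [0, 128, 255]

    def test_constant_gene_maps_to_zero(self):
        mat, genes = self._mat([[5.0, 5.0, 5.0]])
        scaled, _ = ac.rescale_per_gene(mat, genes)
        assert scaled.values[:, 0].tolist() == [0, 0, 0]

    def test_prefit_scaler_clips_out_of_range(self):
        train, genes = self._mat([[0.0, 10.0]])
        _, scaler = ac.rescale_per_gene(train, genes)
        test, _ = self._mat([[20.0, -5.0]])
        scaled, _ = ac.rescale_per_gene(test, genes, scaler)
        assert scaled.values[:, 0].tolist() == [255, 0]

    def test_missing_order_gene_raises(self):
        mat, _ = self._mat([[1.0, 2.0]])
        with pytest.raises(MissingGeneError):
            ac.rescale_per_gene(mat, ["nope"])

    def test_range_and_extremes_property(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(5, 2, size=(40, 12))
        genes = [f"g{j}" for j in range(12)]
        mat = ac.ExpressionMatrix(
            [f"s{i}" for i in range(40)], genes, vals, scale="log2"
        )
        scaled, _ = ac.rescale_per_gene(mat, genes)
        v = scaled.values
        assert v.min() >= 0 and v.max() <= 255
        for j in range(12):  # cohort min -> 0, max -> 255 for non-constant genes
            assert v[np.argmin(vals[:, j]), j] == 0
            assert v[np.argmax(vals[:, j]), j] == 255

    def test_fpkm_scale_is_rejected(self):
        mat = ac.ExpressionMatrix(["s"], ["g"], [[1.0]], scale="fpkm")
        with pytest.raises(StateError):
            ac.rescale_per_gene(mat, ["g"])

    def test_scaler_text_round_trip(self, tmp_path):
        mat, genes = self._mat([[1.0, 3.0], [0.0, 2.0]])
        _, scaler = ac.rescale_per_gene(mat, genes)
        path = tmp_path / "scaler.tsv"
        scaler.save(path)
        loaded = ac.ScalerParams.load(path)
        assert loaded.genes == scaler.genes
        np.testing.assert_array_equal(loaded.mins, scaler.mins)
        np.testing.assert_array_equal(loaded.maxs, scaler.maxs)


class TestReadLabels:
    def test_ki67_percentage_dichotomized_at_20(self):
        labels = ac.read_labels(_tsv(
            "sample_id\tki67_percent\ns1\t20\ns2\t20.1\ns3\t\n"
        ), sep="\t")
        assert labels.loc["s1", "ki67"] == 0
        assert labels.loc["s2", "ki67"] == 1
        assert pd.isna(labels.loc["s3", "ki67"])

    def test_nhg_grade_strings_coded_zero_based(self):
        labels = ac.read_labels(_tsv(
            "sample_id\tnhg\ns1\tGrade III\ns2\tI\ns3\t2\n"
        ), sep="\t")
        assert labels.loc["s1", "nhg"] == 2
        assert labels.loc["s2", "nhg"] == 0
        assert labels.loc["s3", "nhg"] == 1  # numeric grades are 1-based

    def test_invalid_nhg_raises(self):
        with pytest.raises(ValidationError):
            ac.read_labels(_tsv("sample_id\tnhg\ns1\tIV\n"), sep="\t")

    def test_survival_requires_both_columns(self):
        with pytest.raises(ValidationError):
            ac.read_labels(_tsv(
                "sample_id\tsurvival_days\ns1\t100\n"
            ), sep="\t")
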