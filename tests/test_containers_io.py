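"""Container invariants and file-format round trips."""

import numpy as np
import pandas as pd
import pytest

import dmdgp
from dmdgp.containers import GenotypeMatrix, TraitTensor, infer_blocks
from dmdgp.io import (
    filter_by_maf,
    mean_impute_tensor,
    read_genotype_matrix,
    read_grm_csv,
    read_prediction_report,
    read_trait_tensor,
    write_grm_csv,
    write_prediction_report,
)

VCF_TEXT = """##fileformat=VCFv4.2
##contig=<ID=1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
1\t100\tsnp1\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\t1/1
1\t150\tsnp2\tA\tG,T\t.\t.\t.\tGT\t0/0\t0/1\t1/1
1\t200\tsnp3\tC\tT\t.\t.\t.\tGT\t0/1\t0/1\t0/0
1\t250\tsnp4\tG\tA\t.\t.\t.\tGT\t1/1\t0/0\t0/1
1\t300\tsnp5\tT\tC\t.\t.\t.\tGT\t0/0\t0/0\t0/1
1\t350\tsnp6\tT\tC\t.\t.\t.\tGT\t0/1\t1/1\t0/0
"""


def _long_frame(days=(15, 16, 17, 20, 21), lines=("A", "B"), traits=("t1", "t2")):
    rows = [
        (line, trait, day, float((hash((line, trait, day)) % 13) - 6))
        for line in lines for trait in traits for day in days
    ]
    return pd.DataFrame(rows, columns=["line", "trait", "day", "value"])


class TestGenotypeIO:
    def test_dosage_table_parse(self, tmp_path):
        pd.DataFrame([[0, 1], [2, 1], [1, 0]], index=["a", "b", "c"],
                     columns=["m1", "m2"]).to_csv(tmp_path / "d.csv")
        G = read_genotype_matrix(tmp_path / "d.csv")
        assert (G.n_lines, G.n_markers) == (3, 2)
        assert np.allclose(G.maf, [0.5, 1 / 3])

    def test_vcf_skips_multiallelic(self, tmp_path):
        path = tmp_path / "t.vcf"
        path.write_text(VCF_TEXT)
        G = read_genotype_matrix(path, format="vcf")
        # one of six records is triallelic and must be dropped
        assert G.n_markers == 5
        assert "snp2" not in G.marker_ids
        assert G.line_ids == ["S1", "S2", "S3"]
        assert G.dosages[0, 0] == 0 and G.dosages[2, 0] == 2

    def test_vcf_missing_call_is_error(self, tmp_path):
        path = tmp_path / "t.vcf"
        path.write_text(VCF_TEXT.replace("1\t300\tsnp5\tT\tC\t.\t.\t.\tGT\t0/0\t0/0\t0/1",
                                         "1\t300\tsnp5\tT\tC\t.\t.\t.\tGT\t0/0\t./.\t0/1"))
        with pytest.raises(ValueError, match="S2.*snp5"):
            read_genotype_matrix(path, format="vcf")

    def test_non_integer_dosage_names_cell(self, tmp_path):
        pd.DataFrame([[0, 1.5], [2, 1], [1, 0]], index=["a", "b", "c"],
                     columns=["m1", "m2"]).to_csv(tmp_path / "d.csv")
        with pytest.raises(ValueError, match="'a'.*'m2'"):
            read_genotype_matrix(tmp_path / "d.csv")

    def test_maf_filter_threshold_and_idempotence(self):
        # frequencies straddling 0.05 on both sides
        rng = np.random.default_rng(3)
        freqs = np.array([0.01, 0.03, 0.04, 0.05, 0.07, 0.2, 0.3, 0.45, 0.02, 0.12])
        dos = np.array([rng.binomial(2, f, size=200) for f in freqs]).T
        G = GenotypeMatrix([f"l{i}" for i in range(200)],
                           [f"m{j}" for j in range(10)], dos)
        flt = filter_by_maf(G, 0.05)
        survivors = [G.marker_ids[j] for j in range(10) if G.maf[j] >= 0.05]
        assert flt.marker_ids == survivors
        again = filter_by_maf(flt, 0.05)
        assert again.marker_ids == flt.marker_ids
        assert filter_by_maf(G, 0.0).n_markers == 10  # identity at zero

    def test_all_removed_is_error(self):
        G = GenotypeMatrix(["a", "b", "c"], ["m1"], np.array([[0], [0], [1]]))
        with pytest.raises(ValueError, match="threshold"):
            filter_by_maf(G, 0.4)


class TestTraitTensorIO:
    def test_block_inference_from_days(self, tmp_path):
        df = _long_frame()
        df.to_csv(tmp_path / "p.csv", index=False)
        t = read_trait_tensor(tmp_path / "p.csv", layout="long")
        assert [b.tolist() for b in t.blocks] == [[0, 1, 2], [3, 4]]

    def test_long_and_wide_layouts_agree(self, tmp_path):
        df = _long_frame()
        df.to_csv(tmp_path / "long.csv", index=False)
        wide = df.pivot_table(index=["line", "trait"], columns="day",
                              values="value").reset_index()
        wide.columns = [str(c) for c in wide.columns]
        wide.to_csv(tmp_path / "wide.csv", index=False)
        tl = read_trait_tensor(tmp_path / "long.csv", layout="long")
        tw = read_trait_tensor(tmp_path / "wide.csv", layout="wide")
        assert tl.line_ids == tw.line_ids and tl.trait_ids == tw.trait_ids
        np.testing.assert_array_equal(tl.values, tw.values)

    def test_field_design_gives_five_blocks_of_five(self, tmp_path):
        days = tuple(dmdgp.gapped_days())  # 25 days, 5-day weekly blocks from day 15
        _long_frame(days=days).to_csv(tmp_path / "p.csv", index=False)
        t = read_trait_tensor(tmp_path / "p.csv", layout="long")
        assert len(t.blocks) == 5
        assert all(len(b) == 5 for b in t.blocks)

    def test_missing_combination_is_error(self, tmp_path):
        df = _long_frame().iloc[:-1]
        df.to_csv(tmp_path / "p.csv", index=False)
        with pytest.raises(ValueError, match="missing"):
            read_trait_tensor(tmp_path / "p.csv", layout="long")

    def test_duplicate_combination_is_error(self, tmp_path):
        df = _long_frame()
        pd.concat([df, df.iloc[[0]]]).to_csv(tmp_path / "p.csv", index=False)
        with pytest.raises(ValueError, match="duplicate"):
            read_trait_tensor(tmp_path / "p.csv", layout="long")

    def test_nonconsecutive_days_within_block_rejected(self):
        with pytest.raises(ValueError):
            TraitTensor(["a", "b"], ["t"], np.array([1, 2, 4]),
                        np.zeros((2, 1, 3)), [np.array([0, 1, 2])])
        assert [b.tolist() for b in infer_blocks(np.array([1, 2, 4]))] == [[0, 1], [2]]


class TestImputation:
    def test_mean_fill(self):
        values = np.array([[[1.0]], [[3.0]], [[np.nan]]])
        t = TraitTensor(["a", "b", "c"], ["t"], np.array([1]), values)
        out = mean_impute_tensor(t)
        assert out.values[2, 0, 0] == 2.0

    def test_identity_when_complete(self, small_population):
        _, tensor, _ = small_population
        out = mean_impute_tensor(tensor)
        np.testing.assert_array_equal(out.values, tensor.values)

    def test_matches_independent_column_mean_fill(self, rng):
        values = rng.normal(size=(30, 4, 6))
        mask = rng.random(values.shape) < 0.05
        holed = np.where(mask, np.nan, values)
        t = TraitTensor([f"l{i}" for i in range(30)],
                        [f"t{j}" for j in range(4)], np.arange(1, 7), holed)
        out = mean_impute_tensor(t)
        # independent oracle: per trait x day loop over columns
        expect = holed.copy()
        for j in range(4):
            for ti in range(6):
                col = expect[:, j, ti]
                col[np.isnan(col)] = np.nanmean(holed[:, j, ti])
        np.testing.assert_allclose(out.values, expect)

    def test_entirely_missing_slice_is_error(self):
        values = np.full((3, 1, 1), np.nan)
        t = TraitTensor(["a", "b", "c"], ["t"], np.array([1]), values)
        with pytest.raises(ValueError, match="entirely missing"):
            mean_impute_tensor(t)


class TestReports:
    def test_round_trip_bit_exact(self, tmp_path, rng):
        from dmdgp.pipeline import PredictionResult

        acc = rng.normal(size=(2, 3))
        res = PredictionResult(
            accuracy=acc, accuracy_sd=np.abs(rng.normal(size=(2, 3))),
            mse=np.abs(rng.normal(size=(2, 3))), mode="recursive",
            scenario="full_series", trait_ids=["x", "y"],
            time_axis=np.array([16, 17, 18]), metadata={"seed": 7},
        )
        write_prediction_report(res, tmp_path / "rep")
        back = read_prediction_report(tmp_path / "rep")
        np.testing.assert_array_equal(back["accuracy"], acc)  # bit-exact
        assert back["metadata"]["seed"] == 7
        assert back["trait_ids"] == ["x", "y"]

    def test_grm_csv_round_trip(self, tmp_path, small_population):
        G, _, _ = small_population
        grm = dmdgp.compute_grm(G)
        write_grm_csv(grm, tmp_path / "grm.csv")
        back = read_grm_csv(tmp_path / "grm.csv")
        assert back.line_ids == grm.line_ids
        np.testing.assert_allclose(back.K, grm.K, atol=1e-12)
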