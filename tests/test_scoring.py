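"""Scoring engine: file I/O, harmonization, PRS algebra, adjustment states."""

import numpy as np
import pandas as pd
import pytest

from metaprs.exceptions import (
    ContractError,
    HarmonizationError,
    ScoreFileFormatError,
    ValidationError,
)
from metaprs.scoring import (
    GenotypeMatrix,
    ScoreVector,
    VariantWeightTable,
    adjust_for_pcs,
    blend_scores,
    compute_prs,
    harmonize,
    read_score_file,
    standardize,
    write_score_file,
)

from conftest import make_table

FIXTURE = """\
#pgs_name=toy_score
#genome_build=GRCh37
rsID\tchr_name\tchr_position\teffect_allele\tother_allele\teffect_weight
rs1\t1\t100\tA\tG\t0.123
rs2\t2\t200\tC\tT\t-0.456
rs3\t3\t300\tG\tA\t1.5e-3
"""


class TestScoreFileIO:
    def test_parse_fidelity(self, tmp_path):
        p = tmp_path / "toy.txt"
        p.write_text(FIXTURE)
        tab = read_score_file(p)
        assert tab.n_variants == 3
        assert tab.df["weight"].tolist() == [0.123, -0.456, 0.0015]
        assert tab.df["variant_id"].tolist() == ["rs1", "rs2", "rs3"]
        assert tab.metadata["header_lines"][0] == "#pgs_name=toy_score"

    def test_round_trip_identity(self, tmp_path):
        rng = np.random.default_rng(3)
        n = 1000
        alleles = np.array(list("ACGT"))
        ea = alleles[rng.integers(0, 4, n)]
        oa = alleles[(np.searchsorted(alleles, ea) + rng.integers(1, 4, n)) % 4]
        tab = make_table(
            [f"rs{i}" for i in range(n)],
            ["7"] * n,
            list(range(1, n + 1)),
            list(ea),
            list(oa),
            rng.standard_normal(n),
        )
        p = tmp_path / "rt.txt"
        write_score_file(tab, p)
        back = read_score_file(p)
        pd.testing.assert_frame_equal(
            back.df[tab.df.columns].astype(tab.df.dtypes.to_dict()), tab.df
        )

    def test_metadata_preserved_on_round_trip(self, tmp_path):
        p = tmp_path / "toy.txt"
        p.write_text(FIXTURE)
        tab = read_score_file(p)
        q = tmp_path / "copy.txt"
        write_score_file(tab, q)
        assert read_score_file(q).metadata["header_lines"] == tab.metadata["header_lines"]

    def test_missing_weight_column_is_format_error(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("rsID\teffect_allele\tother_allele\nrs1\tA\tG\n")
        with pytest.raises(ScoreFileFormatError, match="effect_weight"):
            read_score_file(p)

    def test_non_acgt_allele_names_row(self):
        with pytest.raises(ValidationError, match="row 1"):
            make_table(["rs1", "rs2"], ["1", "1"], [1, 2], ["A", "Z"], ["G", "C"], [1.0, 1.0])

    def test_duplicate_variant_id_rejected(self):
        with pytest.raises(ValidationError, match="duplicated"):
            make_table(["rs1", "rs1"], ["1", "1"], [1, 2], ["A", "A"], ["G", "G"], [1.0, 1.0])


class TestGenotypeIO:
    def test_dosage_tsv_round_trip(self, tiny_geno, tmp_path):
        p = tmp_path / "geno.tsv"
        tiny_geno.to_dosage_tsv(p)
        back = GenotypeMatrix.from_dosage_tsv(p)
        np.testing.assert_array_equal(back.dosages, tiny_geno.dosages)
        assert list(back.sample_ids) == list(tiny_geno.sample_ids)
        pd.testing.assert_frame_equal(back.variants, tiny_geno.variants)

    def test_vcf_round_trip(self, tiny_geno, tmp_path):
        p = tmp_path / "geno.vcf"
        tiny_geno.to_vcf(p)
        back = GenotypeMatrix.from_vcf(p)
        np.testing.assert_allclose(back.dosages, tiny_geno.dosages, atol=1e-3)
        assert list(back.variants["variant_id"]) == list(
            tiny_geno.variants["variant_id"]
        )
        assert list(back.variants["allele2"]) == list(tiny_geno.variants["allele2"])


class TestHarmonize:
    def test_identity_orientation(self, tiny_geno):
        tab = make_table(
            ["rs1", "rs2", "rs3"], ["1"] * 3, [100, 200, 300],
            ["G", "T", "A"], ["A", "C", "G"], [1.0, 2.0, 3.0],
        )
        harm, rep = harmonize(tab, tiny_geno)
        assert rep.flipped == 0 and rep.dropped_ambiguous == 0
        assert rep.matched == 3 and rep.unmatched == 0
        assert not harm.df["flipped"].any()

    def test_flip_algebra_contribution_zero(self):
        # one variant, table alleles swapped vs genotype, dosage 2, weight 1
        geno = GenotypeMatrix(
            sample_ids=np.array(["s"]),
            variants=pd.DataFrame(
                dict(variant_id=["rs1"], chr=["1"], pos=[1],
                     allele1=["A"], allele2=["G"], af=[0.5])
            ),
            dosages=np.array([[2.0]]),
        )
        tab = make_table(["rs1"], ["1"], [1], ["A"], ["G"], [1.0])
        harm, rep = harmonize(tab, geno)
        assert rep.flipped == 1
        score = compute_prs(geno, harm)
        assert score.values[0] == pytest.approx(0.0)  # w * (2 - d)

    def test_ambiguous_policy_drop_vs_keep(self):
        rng = np.random.default_rng(0)
        pairs = [("A", "G")] * 8 + [("A", "T"), ("C", "G")]
        geno = GenotypeMatrix(
            sample_ids=np.array(["s1", "s2"]),
            variants=pd.DataFrame(
                dict(
                    variant_id=[f"rs{i}" for i in range(10)],
                    chr=["1"] * 10,
                    pos=list(range(1, 11)),
                    allele1=[p[0] for p in pairs],
                    allele2=[p[1] for p in pairs],
                    af=[0.5] * 10,
                )
            ),
            dosages=rng.integers(0, 3, (2, 10)).astype(float),
        )
        tab = make_table(
            [f"rs{i}" for i in range(10)], ["1"] * 10, list(range(1, 11)),
            [p[1] for p in pairs], [p[0] for p in pairs], [1.0] * 10,
        )
        harm, rep = harmonize(tab, geno, ambiguous_policy="drop")
        assert rep.matched == 8 and rep.dropped_ambiguous == 2
        harm2, rep2 = harmonize(tab, geno, ambiguous_policy="keep")
        assert rep2.matched == 10 and rep2.dropped_ambiguous == 0

    def test_positional_fallback_matches_on_alleles(self, tiny_geno):
        tab = make_table(["other_name"], ["1"], [200], ["T"], ["C"], [1.0])
        harm, rep = harmonize(tab, tiny_geno)
        assert rep.matched == 1
        assert harm.df["geno_index"].iloc[0] == 1

    def test_zero_matches_is_hard_error(self, tiny_geno):
        tab = make_table(["nope"], ["9"], [9], ["A"], ["G"], [1.0])
        with pytest.raises(HarmonizationError):
            harmonize(tab, tiny_geno)


class TestComputePrs:
    def test_hand_arithmetic(self):
        geno = GenotypeMatrix(
            sample_ids=np.array(["s1", "s2"]),
            variants=pd.DataFrame(
                dict(variant_id=["v1", "v2"], chr=["1", "1"], pos=[1, 2],
                     allele1=["A", "A"], allele2=["G", "G"], af=[0.5, 0.5])
            ),
            dosages=np.array([[0.0, 2.0], [1.0, 1.0]]),
        )
        tab = make_table(["v1", "v2"], ["1", "1"], [1, 2], ["G", "G"], ["A", "A"], [0.5, -1.0])
        harm, _ = harmonize(tab, geno)
        score = compute_prs(geno, harm)
        assert score.values.tolist() == [-2.0, -0.5]

    def test_missing_imputed_as_twice_af(self):
        geno = GenotypeMatrix(
            sample_ids=np.array(["s1"]),
            variants=pd.DataFrame(
                dict(variant_id=["v1"], chr=["1"], pos=[1],
                     allele1=["A"], allele2=["G"], af=[0.25])
            ),
            dosages=np.array([[np.nan]]),
        )
        tab = make_table(["v1"], ["1"], [1], ["G"], ["A"], [1.0])
        harm, _ = harmonize(tab, geno)
        assert compute_prs(geno, harm).values[0] == pytest.approx(0.5)

    def test_all_zero_weights_give_zero_scores(self, tiny_geno):
        tab = make_table(
            ["rs1", "rs2", "rs3"], ["1"] * 3, [100, 200, 300],
            ["G", "T", "A"], ["A", "C", "G"], [0.0, 0.0, 0.0],
        )
        harm, _ = harmonize(tab, tiny_geno)
        assert np.all(compute_prs(tiny_geno, harm).values == 0.0)

    def test_unharmonized_table_rejected(self, tiny_geno):
        tab = make_table(["rs1"], ["1"], [100], ["G"], ["A"], [1.0])
        with pytest.raises(ContractError):
            compute_prs(tiny_geno, tab)

    def test_scoring_is_linear_in_weights(self, tiny_geno):
        rng = np.random.default_rng(5)
        w1, w2 = rng.standard_normal(3), rng.standard_normal(3)
        a, b = 0.7, -2.3

        def score(w):
            tab = make_table(
                ["rs1", "rs2", "rs3"], ["1"] * 3, [100, 200, 300],
                ["G", "T", "A"], ["A", "C", "G"], w,
            )
            harm, _ = harmonize(tab, tiny_geno)
            return compute_prs(tiny_geno, harm).values

        combo = score(a * w1 + b * w2)
        np.testing.assert_allclose(combo, a * score(w1) + b * score(w2), atol=1e-10)

    def test_flip_consistency(self, tiny_geno):
        """Scoring an all-swapped table equals 2*sum(w) - original score."""
        w = np.array([0.5, -1.0, 2.0])
        fwd = make_table(
            ["rs1", "rs2", "rs3"], ["1"] * 3, [100, 200, 300],
            ["G", "T", "A"], ["A", "C", "G"], w,
        )
        rev = make_table(
            ["rs1", "rs2", "rs3"], ["1"] * 3, [100, 200, 300],
            ["A", "C", "G"], ["G", "T", "A"], w,
        )
        s_fwd = compute_prs(tiny_geno, harmonize(fwd, tiny_geno)[0]).values
        s_rev = compute_prs(tiny_geno, harmonize(rev, tiny_geno)[0]).values
        np.testing.assert_allclose(s_rev, 2 * w.sum() - s_fwd, atol=1e-12)


class TestAdjustAndStandardize:
    def test_pc_span_annihilated(self):
        rng = np.random.default_rng(7)
        pcs = rng.standard_normal((200, 5))
        score = ScoreVector(
            sample_ids=np.arange(200).astype(str),
            values=pcs @ rng.standard_normal(5) + 3.0,
        )
        out = adjust_for_pcs(score, pcs)
        assert np.max(np.abs(out.values)) < 1e-8

    def test_residuals_match_normal_equations(self):
        rng = np.random.default_rng(8)
        pcs = rng.standard_normal((300, 5))
        v = rng.standard_normal(300)
        score = ScoreVector(sample_ids=np.arange(300).astype(str), values=v)
        out = adjust_for_pcs(score, pcs)
        X = np.column_stack([np.ones(300), pcs])
        theta = np.linalg.solve(X.T @ X, X.T @ v)
        np.testing.assert_allclose(out.values, v - X @ theta, atol=1e-10)
        for k in range(5):
            assert abs(np.corrcoef(out.values, pcs[:, k])[0, 1]) < 1e-10

    def test_orthogonal_score_only_demeaned(self):
        rng = np.random.default_rng(9)
        n = 400
        pcs = rng.standard_normal((n, 2))
        pcs -= pcs.mean(axis=0)
        v = rng.standard_normal(n)
        # orthogonalize v against the (centered) PCs, keep its mean
        v -= pcs @ np.linalg.lstsq(pcs, v, rcond=None)[0]
        out = adjust_for_pcs(ScoreVector(np.arange(n).astype(str), v), pcs)
        np.testing.assert_allclose(out.values, v - v.mean(), atol=1e-10)

    def test_standardize_idempotent_and_replayable(self):
        rng = np.random.default_rng(10)
        v = rng.standard_normal(500) * 3 + 7
        s1 = standardize(ScoreVector(np.arange(500).astype(str), v))
        assert abs(s1.values.mean()) < 1e-8 and abs(s1.values.std(ddof=1) - 1) < 1e-8
        s2 = standardize(s1)
        assert np.max(np.abs(s2.values - s1.values)) < 1e-12
        # replay stored parameters on a disjoint cohort
        v_new = rng.standard_normal(100) * 3 + 7
        replayed = standardize(
            ScoreVector(np.arange(100).astype(str), v_new), mean=s1.mean_, sd=s1.sd_
        )
        np.testing.assert_allclose(replayed.values, (v_new - s1.mean_) / s1.sd_)

    def test_constant_score_is_error(self):
        with pytest.raises(ContractError):
            standardize(ScoreVector(np.arange(3).astype(str), np.ones(3)))

    def test_adjust_then_standardize_commutes_with_reordering(self):
        rng = np.random.default_rng(12)
        n = 150
        pcs = rng.standard_normal((n, 3))
        v = rng.standard_normal(n)
        ids = np.array([f"s{i}" for i in range(n)])
        direct = standardize(adjust_for_pcs(ScoreVector(ids, v), pcs)).values
        perm = rng.permutation(n)
        permuted = standardize(
            adjust_for_pcs(ScoreVector(ids[perm], v[perm]), pcs[perm])
        ).values
        np.testing.assert_allclose(permuted, direct[perm], atol=1e-10)


class TestBlend:
    def _std(self, values):
        return standardize(ScoreVector(np.arange(len(values)).astype(str), values))

    def test_unit_weight_returns_first(self):
        rng = np.random.default_rng(1)
        a, b = self._std(rng.standard_normal(50)), self._std(rng.standard_normal(50))
        out = blend_scores([a, b], [1.0, 0.0])
        np.testing.assert_array_equal(out.values, a.values)

    def test_blend_variance_matches_quadratic_form(self):
        # fixed-weight blend of three standardized scores: var = w' Sigma w
        rng = np.random.default_rng(2)
        n = 2000
        base = rng.standard_normal((n, 3)) @ np.linalg.cholesky(
            np.array([[1, 0.5, 0.2], [0.5, 1, 0.4], [0.2, 0.4, 1.0]])
        ).T
        scores = [self._std(base[:, j]) for j in range(3)]
        w = np.array([0.531117, 0.5690198, 0.1465538])
        out = blend_scores(scores, list(w))
        Z = np.column_stack([s.values for s in scores])
        sigma = np.cov(Z, rowvar=False)
        assert out.values.var(ddof=1) == pytest.approx(float(w @ sigma @ w), rel=1e-10)

    def test_zero_sum_weights_on_identical_inputs(self):
        rng = np.random.default_rng(3)
        v = rng.standard_normal(100)
        a, b = self._std(v), self._std(v.copy())
        out = blend_scores([a, b], [1.0, -1.0])
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_unstandardized_input_rejected(self):
        raw = ScoreVector(np.arange(10).astype(str), np.arange(10.0))
        with pytest.raises(ContractError):
            blend_scores([raw], [1.0])
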