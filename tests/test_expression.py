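import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from zwdosage import expression
from zwdosage.expression import ExpressionMatrix
from zwdosage.io_core import (
    CountMatrix,
    Gene,
    GenomeAnnotation,
    SampleTable,
    ValidationError,
)


def make_counts(arr, sample_meta=None, lengths=None, index=None):
    arr = np.asarray(arr)
    index = index or [f"g{i}" for i in range(arr.shape[0])]
    cols = [f"s{j}" for j in range(arr.shape[1])]
    counts = pd.DataFrame(arr, index=index, columns=cols)
    meta = pd.DataFrame({
        "length": lengths if lengths is not None else 1000,
        "biotype": "coding", "contig": "c1", "segment": "A1",
    }, index=counts.index)
    if sample_meta is None:
        sample_meta = {"sample_type": ["T"] * len(cols), "sex": ["NA"] * len(cols)}
    sdf = pd.DataFrame({
        "sample_id": cols,
        "sample_type": sample_meta["sample_type"],
        "sex": sample_meta["sex"],
        "replicate": range(1, len(cols) + 1),
        "batch": "b", "library_size": 0,
    })
    return CountMatrix(counts, meta, SampleTable(sdf))


# ---------------------------------------------------------------------------
# collapse_annotation
# ---------------------------------------------------------------------------

class TestCollapse:
    def test_structural_rna_masks_coding_exon(self):
        ann = GenomeAnnotation({
            "cod": Gene("cod", "c1", "+", "coding", [(0, 300)]),
            "rr": Gene("rr", "c1", "+", "rRNA", [(100, 200)]),
        })
        out = expression.collapse_annotation(ann)
        assert out["cod"].exons == [(0, 100), (200, 300)]
        assert out["cod"].length == 200

    def test_non_overlapping_genes_unchanged(self):
        ann = GenomeAnnotation({
            "a": Gene("a", "c1", "+", "coding", [(0, 100)]),
            "b": Gene("b", "c1", "-", "lncRNA", [(500, 700)]),
        })
        out = expression.collapse_annotation(ann)
        assert out["a"].exons == [(0, 100)]
        assert out["b"].exons == [(500, 700)]

    def test_overlapping_exons_unioned_and_introns(self):
        ann = GenomeAnnotation({
            "a": Gene("a", "c1", "+", "coding", [(0, 100), (80, 150)]),
            "b": Gene("b", "c1", "+", "coding", [(0, 100), (200, 300)]),
        })
        out = expression.collapse_annotation(ann)
        assert out["a"].exons == [(0, 150)]
        assert out["a"].introns == []
        assert out["b"].introns == [(100, 200)]

    def test_fully_masked_gene_dropped(self, caplog):
        ann = GenomeAnnotation({
            "cod": Gene("cod", "c1", "+", "coding", [(100, 200)]),
            "rr": Gene("rr", "c1", "+", "rRNA", [(50, 250)]),
        })
        with caplog.at_level("WARNING"):
            out = expression.collapse_annotation(ann)
        assert "cod" not in out.genes
        assert "rr" in out.genes

    def test_mask_is_strand_agnostic(self):
        ann = GenomeAnnotation({
            "cod": Gene("cod", "c1", "+", "coding", [(0, 300)]),
            "tr": Gene("tr", "c1", "-", "tRNA", [(100, 200)]),
        })
        out = expression.collapse_annotation(ann)
        assert out["cod"].exons == [(0, 100), (200, 300)]


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------

def edger_tmm(matrices: list[np.ndarray], tmp_path) -> list[np.ndarray]:
    """Reference TMM factors from edgeR::calcNormFactors via Rscript."""
    for i, m in enumerate(matrices):
        pd.DataFrame(m).to_csv(tmp_path / f"m{i}.tsv", sep="\t", index=False)
    script = tmp_path / "tmm.R"
    script.write_text("""
suppressMessages(library(edgeR))
args <- commandArgs(trailingOnly=TRUE)
for (f in args) {
  x <- as.matrix(read.delim(f))
  fac <- calcNormFactors(x, method="TMM")
  write(paste(format(fac, digits=15), collapse="\\t"), sub(".tsv", ".out", f))
}
""")
    files = [str(tmp_path / f"m{i}.tsv") for i in range(len(matrices))]
    subprocess.run(["Rscript", str(script)] + files, check=True,
                   capture_output=True)
    return [np.loadtxt(tmp_path / f"m{i}.out") for i in range(len(matrices))]


class TestTMM:
    def test_identical_samples_unit_factors(self):
        cm = make_counts(np.tile([[10], [20], [30], [5]], (1, 3)))
        f = expression.tmm_factors(cm)
        assert np.allclose(f, 1.0)

    def test_pure_depth_difference_absorbed_by_library_size(self):
        rng = np.random.default_rng(0)
        base = rng.negative_binomial(10, 0.3, size=500)
        cm = make_counts(np.column_stack([base, base * 2]))
        f = expression.tmm_factors(cm)
        assert np.allclose(f, 1.0, atol=1e-12)

    def test_spiked_sample_factor_below_one(self):
        rng = np.random.default_rng(1)
        base = rng.negative_binomial(10, 0.3, size=1000) + 1
        spiked = base.copy()
        spiked[:50] *= 10
        cm = make_counts(np.column_stack([base, spiked]))
        f = expression.tmm_factors(cm)
        assert f.iloc[1] < 1.0 < f.iloc[0]

    def test_geometric_mean_one(self):
        rng = np.random.default_rng(2)
        cm = make_counts(rng.negative_binomial(5, 0.2, size=(300, 6)))
        f = expression.tmm_factors(cm)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)

    def test_matches_edger_on_random_nb_matrices(self, tmp_path):
        rng = np.random.default_rng(42)
        mats = []
        for _ in range(50):
            n_genes = int(rng.integers(200, 500))
            n_samples = int(rng.integers(2, 6))
            mu = rng.gamma(2, 20, size=(n_genes, 1)) * rng.uniform(0.5, 2.0, n_samples)
            mats.append(rng.poisson(mu).astype(int))
        ref = edger_tmm(mats, tmp_path)
        for m, expected in zip(mats, ref):
            got = expression.tmm_factors(make_counts(m)).to_numpy()
            assert np.allclose(got, np.atleast_1d(expected), atol=1e-6), (
                got, expected)


# ---------------------------------------------------------------------------
# CPM / FPKM
# ---------------------------------------------------------------------------

class TestScales:
    def test_cpm_definition(self):
        cm = make_counts([[10], [10_000_000 - 10]])
        cpm = expression.compute_cpm(cm)
        assert cpm.values.iloc[0, 0] == pytest.approx(1.0)

    def test_cpm_columns_sum_to_million(self):
        rng = np.random.default_rng(3)
        cm = make_counts(rng.integers(0, 100, size=(50, 4)))
        cpm = expression.compute_cpm(cm)
        assert np.allclose(cpm.values.sum(axis=0), 1e6)

    def test_log2cpm_monotone_in_counts(self):
        cm = make_counts(np.arange(1, 101).reshape(50, 2))
        log2cpm = expression.compute_cpm(cm, log=True)
        col = log2cpm.values.iloc[:, 0].to_numpy()
        assert (np.diff(col) > 0).all()

    def test_fpkm_definition(self):
        cm = make_counts([[100], [10_000_000 - 100]], lengths=[1000, 500])
        fpkm = expression.compute_fpkm(cm)
        assert fpkm.values.iloc[0, 0] == pytest.approx(10.0)

    def test_doubling_length_halves_fpkm(self):
        a = expression.compute_fpkm(make_counts([[100], [900]], lengths=[1000, 1000]))
        b = expression.compute_fpkm(make_counts([[100], [900]], lengths=[2000, 1000]))
        assert b.values.iloc[0, 0] == pytest.approx(a.values.iloc[0, 0] / 2)

    def test_fpkm_cpm_ratio_identity(self):
        rng = np.random.default_rng(4)
        lengths = rng.integers(200, 5000, size=30)
        cm = make_counts(rng.integers(1, 500, size=(30, 3)), lengths=lengths)
        cpm = expression.compute_cpm(cm)
        fpkm = expression.compute_fpkm(cm)
        ratio = fpkm.values / cpm.values
        expected = 1e3 / lengths
        assert np.allclose(ratio, expected[:, None])

    def test_zero_effective_library_rejected(self):
        cm = make_counts([[0], [0]])
        with pytest.raises(ValidationError):
            expression.compute_cpm(cm)


# ---------------------------------------------------------------------------
# expressed-gene filter
# ---------------------------------------------------------------------------

class TestFilter:
    def test_all_zero_gene_removed(self):
        cm = make_counts([[0, 0, 0], [10, 10, 10]])
        kept = expression.filter_expressed(expression.compute_cpm(cm))
        assert "g0" not in kept and "g1" in kept

    def test_cpm_exactly_one_in_exactly_two_samples_kept(self):
        # library 1e6 per sample -> count 1 = CPM 1.0 exactly
        arr = np.zeros((2, 3), dtype=int)
        arr[0] = [1, 1, 0]
        arr[1, :] = [1_000_000 - 1, 1_000_000 - 1, 1_000_000]
        cm = make_counts(arr)
        kept = expression.filter_expressed(expression.compute_cpm(cm))
        assert "g0" in kept

    def test_one_sample_only_removed(self):
        arr = np.zeros((2, 3), dtype=int)
        arr[0] = [50, 0, 0]
        arr[1] = [1_000_000 - 50, 1_000_000, 1_000_000]
        cm = make_counts(arr)
        kept = expression.filter_expressed(expression.compute_cpm(cm))
        assert "g0" not in kept

    def test_matches_enumeration_on_toy_matrix(self):
        rng = np.random.default_rng(5)
        arr = rng.integers(0, 40, size=(5, 4))
        arr[0] = 0
        cm = make_counts(arr)
        cpm = expression.compute_cpm(cm)
        kept = expression.filter_expressed(cpm, min_cpm=1.0, min_samples=2)
        expected = [g for g in cpm.values.index
                    if (cpm.values.loc[g] >= 1.0).sum() >= 2]
        assert list(kept) == expected


# ---------------------------------------------------------------------------
# tau
# ---------------------------------------------------------------------------

def tau_input(values, types):
    arr = np.asarray(values, dtype=float)
    cols = [f"s{j}" for j in range(arr.shape[1])]
    em = ExpressionMatrix(pd.DataFrame(arr, index=["g0"], columns=cols),
                          "CPM", pd.Series(1.0, index=cols))
    st_ = SampleTable(pd.DataFrame({
        "sample_id": cols, "sample_type": types, "sex": "NA",
        "replicate": 1, "batch": "b", "library_size": 0}))
    return em, st_


class TestTau:
    def test_uniform_expression_tau_zero(self):
        em, st_ = tau_input([[5.0, 5.0, 5.0, 5.0]], list("ABCD"))
        assert expression.tau_index(em, st_).iloc[0] == pytest.approx(0.0)

    def test_single_type_expression_tau_one(self):
        em, st_ = tau_input([[9.0, 0.0, 0.0, 0.0]], list("ABCD"))
        assert expression.tau_index(em, st_).iloc[0] == pytest.approx(1.0)

    def test_hand_computed_profile(self):
        # after transform, normalized profile (1, .5, .25, 0):
        # tau = (0 + .5 + .75 + 1)/3 = 0.75; invert log2(x+1) to build inputs
        x = np.array([1.0, 0.5, 0.25, 0.0]) * 8  # log2(cpm+1) = (8, 4, 2, 0)
        cpm = 2 ** x - 1
        em, st_ = tau_input([cpm], list("ABCD"))
        assert expression.tau_index(em, st_).iloc[0] == pytest.approx(0.75)

    def test_tau_in_unit_interval_and_replicates_averaged(self):
        rng = np.random.default_rng(6)
        arr = rng.gamma(2, 10, size=(40, 8))
        cols = [f"s{j}" for j in range(8)]
        em = ExpressionMatrix(pd.DataFrame(arr, index=[f"g{i}" for i in range(40)],
                                           columns=cols),
                              "CPM", pd.Series(1.0, index=cols))
        st_ = SampleTable(pd.DataFrame({
            "sample_id": cols, "sample_type": list("AABBCCDD"), "sex": "NA",
            "replicate": [1, 2] * 4, "batch": "b", "library_size": 0}))
        tau = expression.tau_index(em, st_)
        assert ((tau >= 0) & (tau <= 1)).all()
        # invariance to global rescaling is only approximate under the
        # log2(x+1) transform; check invariance direction on a big scale factor
        em2 = ExpressionMatrix(em.values * 1.0, "CPM", em.norm_factors)
        pd.testing.assert_series_equal(tau, expression.tau_index(em2, st_))

    def test_all_zero_gene_nan(self):
        em, st_ = tau_input([[0.0, 0.0, 0.0, 0.0]], list("ABCD"))
        assert np.isnan(expression.tau_index(em, st_).iloc[0])

    def test_single_type_errors(self):
        em, st_ = tau_input([[1.0, 2.0]], ["A", "A"])
        with pytest.raises(ValidationError):
            expression.tau_index(em, st_)


# ---------------------------------------------------------------------------
# sex-bias classifier
# ---------------------------------------------------------------------------

def bias_fixture(rng, n_genes=1000, n_reps=6, frac_biased=0.1, fold=4.0,
                 dispersion=0.05, lib=2e7):
    mu = np.exp(rng.normal(3, 1, n_genes)) * 1000 * lib / 1e9
    biased = np.zeros(n_genes, dtype=bool)
    biased[: int(n_genes * frac_biased)] = True
    r = 1 / dispersion
    cols = {}
    types, sexes = [], []
    for sex in ("male", "female"):
        for rep in range(n_reps):
            mean = mu * np.where(biased & (sex == "male"), fold, 1.0)
            cols[f"{sex[0]}{rep}"] = rng.negative_binomial(r, r / (r + mean))
            types.append("T")
            sexes.append(sex)
    cm = make_counts(np.column_stack(list(cols.values())),
                     sample_meta={"sample_type": types, "sex": sexes})
    return cm, biased


class TestSexBias:
    def test_identical_groups_all_unbiased(self):
        rng = np.random.default_rng(7)
        base = rng.integers(10, 1000, size=(200, 1))
        arr = np.tile(base, (1, 4))
        cm = make_counts(arr, sample_meta={"sample_type": ["T"] * 4,
                                           "sex": ["male", "male", "female", "female"]})
        log2cpm = expression.compute_cpm(cm, log=True)
        calls = expression.classify_sex_bias(log2cpm, cm.samples, "T")
        assert (calls["direction"] == "unbiased").all()

    def test_exact_twofold_is_unbiased(self):
        # deterministic 2-fold difference: |lfc| == 1 exactly, strict > fails
        arr = np.column_stack([[400, 100, 10_000]] * 2
                              + [[200, 100, 10_200]] * 2).astype(int)
        cm = make_counts(arr, sample_meta={"sample_type": ["T"] * 4,
                                           "sex": ["male", "male", "female", "female"]})
        cpm = expression.compute_cpm(cm, log=True, prior=0.0)
        with np.errstate(divide="ignore"):
            calls = expression.classify_sex_bias(cpm, cm.samples, "T")
        assert abs(calls.loc["g0", "log2fc"] - 1.0) < 1e-9
        assert calls.loc["g0", "direction"] == "unbiased"

    def test_insufficient_replicates_error(self):
        cm = make_counts([[1, 2, 3]], sample_meta={
            "sample_type": ["T"] * 3, "sex": ["male", "female", "female"]})
        log2cpm = expression.compute_cpm(cm, log=True)
        with pytest.raises(ValidationError, match="replicates"):
            expression.classify_sex_bias(log2cpm, cm.samples, "T")

    def test_recall_and_fdr_over_20_seeds(self):
        tp = fp = fn = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            cm, biased = bias_fixture(rng)
            log2cpm = expression.compute_cpm(cm, log=True)
            calls = expression.classify_sex_bias(log2cpm, cm.samples, "T")
            called = (calls["direction"] == "male").to_numpy()
            tp += int((called & biased).sum())
            fp += int((called & ~biased).sum())
            fn += int((~called & biased).sum())
        recall = tp / (tp + fn)
        fdr = fp / max(tp + fp, 1)
        assert recall >= 0.9
        assert fdr <= 0.1


# ---------------------------------------------------------------------------
# lncRNA expression properties on synthetic data
# ---------------------------------------------------------------------------

def test_lncrna_lower_level_and_higher_specificity(default_sim, default_expression):
    cpm = default_expression["cpm"]
    meta = default_expression["counts"].gene_meta
    tau = expression.tau_index(cpm, default_sim["samples"])
    lnc = meta.index[meta["biotype"] == "lncRNA"]
    cod = meta.index[meta["biotype"] == "coding"]
    mean_cpm = cpm.values.mean(axis=1)
    p_level = stats.mannwhitneyu(mean_cpm[lnc], mean_cpm[cod],
                                 alternative="less").pvalue
    p_tau = stats.mannwhitneyu(tau[lnc].dropna(), tau[cod].dropna(),
                               alternative="greater").pvalue
    assert p_level < 0.01
    assert p_tau < 0.01
    assert tau[lnc].median() > tau[cod].median()
    assert mean_cpm[lnc].median() < mean_cpm[cod].median()
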