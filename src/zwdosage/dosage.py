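"""Dosage-compensation statistics.

Z:A median expression ratios and female:male equalization with rank
tests under Bonferroni correction, the generalized (general-association)
Cochran-Mantel-Haenszel test over expression-threshold strata, adjusted
standardized residuals, and the two-proportion / Fisher exact tests used
for coding-vs-lncRNA contrasts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from zwdosage.expression import ExpressionMatrix, aggregate_by_type
from zwdosage.io_core import SampleTable, ValidationError
from zwdosage.io_core import SEGMENT_ANC_Z, SEGMENT_NEO_Z, SEGMENT_W, SEGMENT_UNASSIGNED

logger = logging.getLogger("zwdosage.dosage")

DEFAULT_THRESHOLDS = (0.01, 0.1, 0.5, 1.0)


def segment_class(segment: str) -> str | None:
    """Collapse segment labels to the three analysis classes, or None."""
    if segment in (SEGMENT_ANC_Z, SEGMENT_NEO_Z):
        return segment
    if segment in (SEGMENT_W, SEGMENT_UNASSIGNED):
        return None
    return "A"


# ---------------------------------------------------------------------------
# Z:A dosage and F:M equalization
# ---------------------------------------------------------------------------

def _rank_test(x: np.ndarray, a: np.ndarray, mode: str) -> tuple[float, float]:
    """Two-sided rank test of segment genes against autosomal genes.

    mode "ranksum": Mann-Whitney U of the two gene sets (default).
    mode "signed": one-sample Wilcoxon signed-rank of segment genes
    against the autosomal median.
    """
    if mode == "ranksum":
        res = stats.mannwhitneyu(x, a, alternative="two-sided")
    elif mode == "signed":
        diffs = x - np.median(a)
        diffs = diffs[diffs != 0]
        if len(diffs) == 0:
            return 0.0, 1.0
        res = stats.wilcoxon(diffs, alternative="two-sided")
    else:
        raise ValidationError(f"unknown test mode {mode!r}")
    return float(res.statistic), float(res.pvalue)


def za_dosage_analysis(fpkm: ExpressionMatrix, samples: SampleTable,
                       segments: pd.Series, min_fpkm: float = 0.01,
                       thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
                       test_mode: str = "ranksum",
                       min_genes: int = 10) -> pd.DataFrame:
    """Median Z:A expression ratios per (sample type, sex, segment).

    Replicates are averaged on the linear FPKM scale; per threshold,
    genes at or above it are retained independently in each compartment.
    Each Z segment's gene distribution is tested against the pooled
    autosomal distribution (two-sided rank test), and per-autosome
    medians are reported without tests.  Bonferroni is applied over all
    tests emitted by the call.
    """
    if fpkm.scale != "FPKM":
        raise ValidationError("za_dosage_analysis expects an FPKM matrix")
    thr = sorted(set(thresholds) | {min_fpkm})
    meta = samples.df.set_index("sample_id")
    group_of = {sid: (meta.loc[sid, "sample_type"], meta.loc[sid, "sex"])
                for sid in fpkm.values.columns}
    by_group = fpkm.values.T.groupby(fpkm.values.columns.map(group_of)).mean().T
    seg = segments.reindex(fpkm.values.index).map(lambda s: segment_class(s) if pd.notna(s) else None)
    seg_raw = segments.reindex(fpkm.values.index)

    rows = []
    for stype, sex in by_group.columns:
        expr = by_group[(stype, sex)]
        for t in thr:
            a_vals = expr[(seg == "A") & (expr >= t)].to_numpy()
            a_median = float(np.median(a_vals)) if len(a_vals) else np.nan
            for segment in (SEGMENT_ANC_Z, SEGMENT_NEO_Z):
                vals = expr[(seg == segment) & (expr >= t)].to_numpy()
                run_test = len(vals) >= min_genes and len(a_vals) >= min_genes
                stat, p = (_rank_test(vals, a_vals, test_mode) if run_test
                           else (np.nan, np.nan))
                if not run_test:
                    logger.warning("%s/%s/%s at %.3g FPKM: <%d genes, no test",
                                   stype, sex, segment, t, min_genes)
                med = float(np.median(vals)) if len(vals) else np.nan
                rows.append({
                    "sample_type": stype, "sex": sex, "segment": segment,
                    "threshold": t, "n_genes": len(vals),
                    "median_fpkm": med, "a_median_fpkm": a_median,
                    "za_ratio": med / a_median if a_median else np.nan,
                    "statistic": stat, "p": p,
                    "too_few_genes": not run_test,
                })
            # pooled autosomes row plus per-autosome medians (no tests)
            rows.append({
                "sample_type": stype, "sex": sex, "segment": "A",
                "threshold": t, "n_genes": len(a_vals),
                "median_fpkm": a_median, "a_median_fpkm": a_median,
                "za_ratio": 1.0, "statistic": np.nan, "p": np.nan,
                "too_few_genes": len(a_vals) < min_genes,
            })
            for auto in sorted({s for s in seg_raw.unique()
                                if isinstance(s, str) and segment_class(s) == "A" and s != "A"}):
                vals = expr[(seg_raw == auto) & (expr >= t)].to_numpy()
                med = float(np.median(vals)) if len(vals) else np.nan
                rows.append({
                    "sample_type": stype, "sex": sex, "segment": auto,
                    "threshold": t, "n_genes": len(vals),
                    "median_fpkm": med, "a_median_fpkm": a_median,
                    "za_ratio": med / a_median if a_median else np.nan,
                    "statistic": np.nan, "p": np.nan,
                    "too_few_genes": len(vals) < min_genes,
                })
    out = pd.DataFrame(rows)
    n_tests = int(out["p"].notna().sum())
    out["p_bonf"] = np.minimum(out["p"] * max(n_tests, 1), 1.0)
    out.attrs["n_tests"] = n_tests
    out.attrs["min_fpkm"] = min_fpkm
    return out


def fm_equalization(fpkm: ExpressionMatrix, samples: SampleTable,
                    segments: pd.Series, min_fpkm: float = 0.01,
                    min_genes: int = 10) -> pd.DataFrame:
    """Female:male per-gene expression ratios per segment class.

    Sample types are paired by name across the sexes (replicates averaged
    per sex within a type); genes need FPKM >= min_fpkm in both sexes.
    Each Z segment's log2(F/M) distribution is rank-tested against the
    autosomal one; Bonferroni over all tests in the call.
    """
    if fpkm.scale != "FPKM":
        raise ValidationError("fm_equalization expects an FPKM matrix")
    df = samples.df
    seg = segments.reindex(fpkm.values.index).map(lambda s: segment_class(s) if pd.notna(s) else None)

    rows = []
    for stype, sub in df.groupby("sample_type"):
        f_ids = sub.loc[sub["sex"] == "female", "sample_id"].tolist()
        m_ids = sub.loc[sub["sex"] == "male", "sample_id"].tolist()
        if not f_ids or not m_ids:
            raise ValidationError(f"sample type {stype}: both sexes required")
        f = fpkm.values[f_ids].mean(axis=1)
        m = fpkm.values[m_ids].mean(axis=1)
        ok = (f >= min_fpkm) & (m >= min_fpkm)
        log_ratio = np.log2(f[ok] / m[ok])
        seg_ok = seg[ok]
        a_ratios = log_ratio[seg_ok == "A"].to_numpy()
        for segment in (SEGMENT_ANC_Z, SEGMENT_NEO_Z, "A"):
            vals = log_ratio[seg_ok == segment].to_numpy()
            med = float(np.median(vals)) if len(vals) else np.nan
            if segment != "A" and len(vals) >= min_genes and len(a_ratios) >= min_genes:
                stat, p = _rank_test(vals, a_ratios, "ranksum")
            else:
                stat, p = np.nan, np.nan
            rows.append({
                "sample_type": stype, "segment": segment, "n_genes": len(vals),
                "median_log2_fm": med, "statistic": stat, "p": p,
            })
    out = pd.DataFrame(rows)
    n_tests = int(out["p"].notna().sum())
    out["p_bonf"] = np.minimum(out["p"] * max(n_tests, 1), 1.0)
    out.attrs["n_tests"] = n_tests
    return out


# ---------------------------------------------------------------------------
# generalized CMH and residuals
# ---------------------------------------------------------------------------

@dataclass
class CMHResult:
    """Generalized CMH statistic with the pooled-table residuals."""

    statistic: float
    df: int
    p: float
    residuals: pd.DataFrame | None = None
    n_strata: int = 0
    warnings: list[str] = field(default_factory=list)


def cmh_general(tables: list[np.ndarray] | np.ndarray) -> CMHResult:
    """General-association Cochran-Mantel-Haenszel test over K strata.

    For I x J counts n_ijk with row totals R_ik, column totals C_jk and
    stratum totals N_k, the statistic is Q = G' V^-1 G on the reduced
    (I-1)(J-1) cell vector, with G = sum_k (n_k - m_k), m_ijk =
    R_ik C_jk / N_k and the multiple-hypergeometric covariance
    Cov(n_ijk, n_i'j'k) = R_ik (d_ii' N_k - R_i'k) C_jk (d_jj' N_k -
    C_j'k) / (N_k^2 (N_k - 1)).  Q ~ chi2 with (I-1)(J-1) df.
    """
    arrs = [np.asarray(t, dtype=float) for t in tables]
    if not arrs:
        raise ValidationError("no strata supplied")
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs):
        raise ValidationError("strata have differing dimensions")
    I, J = shape
    if I < 2 or J < 2:
        raise ValidationError("need I >= 2 and J >= 2")
    warnings: list[str] = []
    d = (I - 1) * (J - 1)
    G = np.zeros(d)
    V = np.zeros((d, d))
    used = 0
    for k, tab in enumerate(arrs):
        N = tab.sum()
        if N < 2:
            warnings.append(f"stratum {k} dropped (total {int(N)} < 2)")
            logger.warning("CMH: %s", warnings[-1])
            continue
        R = tab.sum(axis=1)
        C = tab.sum(axis=0)
        m = np.outer(R, C) / N
        G += (tab - m)[: I - 1, : J - 1].ravel()
        # covariance of the reduced cell vector
        Vk = np.empty((d, d))
        for a in range(I - 1):
            for b in range(J - 1):
                for a2 in range(I - 1):
                    for b2 in range(J - 1):
                        row_part = R[a] * ((N if a == a2 else 0.0) - R[a2])
                        col_part = C[b] * ((N if b == b2 else 0.0) - C[b2])
                        Vk[a * (J - 1) + b, a2 * (J - 1) + b2] = (
                            row_part * col_part / (N * N * (N - 1)))
        V += Vk
        used += 1
    if used == 0:
        raise ValidationError("all strata empty")
    try:
        Q = float(G @ np.linalg.solve(V, G))
    except np.linalg.LinAlgError:
        warnings.append("singular covariance; pseudo-inverse used")
        logger.warning("CMH: singular covariance; using pseudo-inverse")
        Q = float(G @ np.linalg.pinv(V) @ G)
    Q = max(Q, 0.0)
    p = float(stats.chi2.sf(Q, d))
    pooled = np.sum(arrs, axis=0)
    res = CMHResult(Q, d, p, residuals=adjusted_residuals(pooled),
                    n_strata=used, warnings=warnings)
    return res


def adjusted_residuals(table: np.ndarray | pd.DataFrame) -> pd.DataFrame:
    """Adjusted standardized residuals of an I x J contingency table.

    r_ij = (O - E) / sqrt(E (1 - R_i/N)(1 - C_j/N)); approximately
    standard normal under independence, |r| > 1.96 notable at alpha 0.05.
    Cells in zero rows/columns come back as NaN.
    """
    df_in = isinstance(table, pd.DataFrame)
    tab = np.asarray(table, dtype=float)
    N = tab.sum()
    if N <= 0:
        raise ValidationError("empty table")
    R = tab.sum(axis=1)
    C = tab.sum(axis=0)
    E = np.outer(R, C) / N
    denom = np.sqrt(E * np.outer(1 - R / N, 1 - C / N))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (tab - E) / denom
    r[(E == 0) | (denom == 0)] = np.nan
    if df_in:
        return pd.DataFrame(r, index=table.index, columns=table.columns)
    return pd.DataFrame(r)


# ---------------------------------------------------------------------------
# proportion and exact tests
# ---------------------------------------------------------------------------

def two_prop_test(x1: int, n1: int, x2: int, n2: int,
                  continuity: bool = True) -> tuple[float, int, float]:
    """Chi-square test for equality of two proportions.

    With the continuity correction, |p1 - p2| is shrunk by
    0.5 (1/n1 + 1/n2) (floored at zero) before squaring.  Returns
    (chi2 statistic, df = 1, p).
    """
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2) or n1 == 0 or n2 == 0:
        raise ValidationError("invalid proportion counts")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return 0.0, 1, 1.0
    c = 0.5 * (1 / n1 + 1 / n2) if continuity else 0.0
    diff = max(abs(p1 - p2) - c, 0.0)
    chi2 = diff ** 2 / (pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    return float(chi2), 1, float(stats.chi2.sf(chi2, 1))


def fisher_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact test by the probability-mass method.

    Sums the hypergeometric probabilities of all tables (with the
    observed margins) whose point probability does not exceed the
    observed one.  Returns (odds ratio, p).
    """
    tab = np.asarray(table)
    if tab.shape != (2, 2) or (tab < 0).any() or not np.issubdtype(tab.dtype, np.integer):
        if tab.shape != (2, 2) or (tab < 0).any() or not np.allclose(tab, np.round(tab)):
            raise ValidationError("fisher_2x2 needs a non-negative integer 2x2 table")
        tab = np.round(tab).astype(np.int64)
    a, b = int(tab[0, 0]), int(tab[0, 1])
    c, d = int(tab[1, 0]), int(tab[1, 1])
    N = a + b + c + d
    r1, c1 = a + b, a + c
    if N == 0:
        return np.nan, 1.0
    lo = max(0, r1 + c1 - N)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, N, c1, r1)
    p_obs = stats.hypergeom.pmf(a, N, c1, r1)
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    odds = (a * d) / (b * c) if b * c > 0 else np.inf
    return odds, min(p, 1.0)


# ---------------------------------------------------------------------------
# sex-bias distribution across chromosome classes
# ---------------------------------------------------------------------------

@dataclass
class BiasDistributionResult:
    """Stratified tables and the CMH battery over them."""

    tables: dict[float, pd.DataFrame]          # threshold -> bias x class counts
    cmh_male_female: CMHResult                  # male-/female-biased x (anc-Z, neo-Z, A)
    cmh_biased_vs_unbiased: CMHResult           # biased/unbiased x (anc-Z, neo-Z, A)
    cmh_neo_vs_a: CMHResult                     # biased/unbiased x (neo-Z, A)
    per_threshold: pd.DataFrame                 # single-stratum CMH per threshold
    p_adjusted: dict[str, float] = field(default_factory=dict)


CLASS_ORDER = (SEGMENT_ANC_Z, SEGMENT_NEO_Z, "A")


def build_stratified_tables(bias: pd.Series, segments: pd.Series,
                            expression: pd.Series,
                            thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
                            rows: tuple[str, ...] = ("male", "female"),
                            classes: tuple[str, ...] = CLASS_ORDER) -> dict[float, pd.DataFrame]:
    """One bias-class x chromosome-class count table per expression threshold."""
    seg = segments.map(lambda s: segment_class(s) if pd.notna(s) else None)
    common = bias.index.intersection(seg.dropna().index).intersection(expression.index)
    tables = {}
    for t in thresholds:
        keep = common[expression.loc[common] >= t]
        tab = pd.DataFrame(0, index=list(rows), columns=list(classes))
        sub = pd.DataFrame({"bias": bias.loc[keep], "cls": seg.loc[keep]})
        counts = sub.groupby(["bias", "cls"]).size()
        for (b, c), n in counts.items():
            if b in tab.index and c in tab.columns:
                tab.loc[b, c] = n
        tables[t] = tab
    return tables


def build_disjoint_tables(bias: pd.Series, segments: pd.Series,
                          expression: pd.Series,
                          thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
                          rows: tuple[str, ...] = ("male", "female"),
                          classes: tuple[str, ...] = CLASS_ORDER) -> dict[float, pd.DataFrame]:
    """Stratified tables with disjoint strata: genes binned between
    consecutive thresholds (the last stratum is unbounded above), so each
    gene appears in exactly one stratum and the CMH variance is valid."""
    thr = sorted(thresholds)
    seg = segments.map(lambda s: segment_class(s) if pd.notna(s) else None)
    common = bias.index.intersection(seg.dropna().index).intersection(expression.index)
    tables = {}
    for i, t in enumerate(thr):
        hi = thr[i + 1] if i + 1 < len(thr) else np.inf
        keep = common[(expression.loc[common] >= t) & (expression.loc[common] < hi)]
        tab = pd.DataFrame(0, index=list(rows), columns=list(classes))
        sub = pd.DataFrame({"bias": bias.loc[keep], "cls": seg.loc[keep]})
        for (b, c), n in sub.groupby(["bias", "cls"]).size().items():
            if b in tab.index and c in tab.columns:
                tab.loc[b, c] = n
        tables[t] = tab
    return tables


def bias_distribution_analysis(bias: pd.Series, segments: pd.Series,
                               expression: pd.Series,
                               thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
                               strata: str = "disjoint",
                               ) -> BiasDistributionResult:
    """CMH battery for the distribution of sex-biased genes across
    chromosome classes, stratified by minimum-expression threshold.

    ``strata="disjoint"`` (default) bins genes between consecutive
    thresholds so the CMH independence assumption holds and the test is
    calibrated; ``strata="nested"`` uses cumulative gene sets (one
    stratum per minimum threshold) — those strata share genes, which
    inflates the joint statistic, so the per-threshold results should be
    read instead.

    Runs (a) male- vs female-biased across anc-Z/neo-Z/A, (b) sex-biased
    vs unbiased across the three classes, (c) sex-biased vs unbiased for
    neo-Z vs A, plus a per-threshold single-stratum CMH, with a
    Bonferroni-style adjustment across the three named contrasts.
    """
    if strata == "disjoint":
        builder = build_disjoint_tables
    elif strata == "nested":
        logger.warning("nested strata share genes across thresholds; the joint "
                       "CMH statistic is anticonservative")
        builder = build_stratified_tables
    else:
        raise ValidationError(f"unknown strata mode {strata!r}")
    mf_tables = builder(bias, segments, expression, thresholds)
    biased = bias.isin(["male", "female"]).map({True: "biased", False: "unbiased"})
    bu_tables = builder(biased, segments, expression, thresholds,
                        rows=("biased", "unbiased"))
    neo_tables = {t: tab[[SEGMENT_NEO_Z, "A"]] for t, tab in bu_tables.items()}

    def run(tabs: dict[float, pd.DataFrame]) -> CMHResult:
        arrs = [t.to_numpy() for t in tabs.values()]
        res = cmh_general(arrs)
        pooled = sum(tabs.values())
        res.residuals = adjusted_residuals(pooled)
        return res

    cmh_mf = run(mf_tables)
    cmh_bu = run(bu_tables)
    cmh_neo = run(neo_tables)
    n_contrasts = 3
    padj = {
        "male_female_by_class": min(cmh_mf.p * n_contrasts, 1.0),
        "biased_vs_unbiased_by_class": min(cmh_bu.p * n_contrasts, 1.0),
        "neo_vs_a": min(cmh_neo.p * n_contrasts, 1.0),
    }
    # per-threshold single-stratum tests always use the cumulative (>= t) sets
    cumulative = build_stratified_tables(bias, segments, expression, thresholds)
    per_thr = pd.DataFrame([
        {"threshold": t, "statistic": (r := cmh_general([tab.to_numpy()])).statistic,
         "df": r.df, "p": r.p}
        for t, tab in cumulative.items()
    ])
    return BiasDistributionResult(mf_tables, cmh_mf, cmh_bu, cmh_neo, per_thr, padj)
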