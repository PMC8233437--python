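"""Annotation collapsing, CPM/FPKM/TMM normalization, expression filters,
tau specificity and a minimal two-group sex-bias classifier.

The TMM implementation follows the weighted trimmed-mean-of-M-values
recipe (reference sample by upper-quartile proximity, double trimming of
M and A, precision weights, geometric-mean-1 rescaling).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from zwdosage import _intervals
from zwdosage.io_core import (
    CountMatrix,
    Gene,
    GenomeAnnotation,
    SampleTable,
    ValidationError,
)

logger = logging.getLogger("zwdosage.expression")

STRUCTURAL_BIOTYPES = ("rRNA", "tRNA", "miRNA")
QUANTIFIED_BIOTYPES = ("coding", "lncRNA")


# ---------------------------------------------------------------------------
# annotation collapsing
# ---------------------------------------------------------------------------

def collapse_annotation(ann: GenomeAnnotation) -> GenomeAnnotation:
    """Collapse gene models to unioned exons after masking structural RNAs.

    Exonic coordinates of structural RNAs (rRNA/tRNA/miRNA) are deleted
    from overlapping coding/lncRNA exons; remaining exons are unioned per
    gene, introns being the gaps in the collapsed chain.  Genes left with
    zero exonic length are dropped with a warning.
    """
    mask_by_contig: dict[str, list[tuple[int, int]]] = {}
    for g in ann:
        if g.biotype in STRUCTURAL_BIOTYPES:
            mask_by_contig.setdefault(g.contig, []).extend(g.exons)
    mask_by_contig = {c: _intervals.merge(iv) for c, iv in mask_by_contig.items()}

    out: dict[str, Gene] = {}
    n_dropped = 0
    for g in ann:
        if g.biotype in STRUCTURAL_BIOTYPES:
            exons = _intervals.merge(g.exons)
        else:
            exons = _intervals.subtract(g.exons, mask_by_contig.get(g.contig, []))
        if not exons:
            logger.warning("gene %s: zero exonic length after masking; dropped", g.gene_id)
            n_dropped += 1
            continue
        out[g.gene_id] = Gene(g.gene_id, g.contig, g.strand, g.biotype, exons)
    logger.info("collapsed %d genes (%d dropped)", len(out), n_dropped)
    return GenomeAnnotation(out)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """genes x samples expression values on a named scale."""

    values: pd.DataFrame
    scale: str                     # "CPM", "log2CPM" or "FPKM"
    norm_factors: pd.Series
    prior: float = 0.0

    def __post_init__(self) -> None:
        if self.scale not in ("CPM", "log2CPM", "FPKM"):
            raise ValidationError(f"unknown scale {self.scale!r}")
        if (self.norm_factors <= 0).any():
            raise ValidationError("normalization factors must be > 0")
        if self.scale != "log2CPM" and (self.values.values < 0).any():
            raise ValidationError(f"negative values on linear scale {self.scale}")


def tmm_factors(counts: CountMatrix, trim_m: float = 0.30,
                trim_a: float = 0.05) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, geometric mean 1."""
    x = counts.counts.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise ValidationError("TMM needs >= 2 samples")
    lib = x.sum(axis=0)
    if (lib == 0).any():
        raise ValidationError("zero library size")

    f75 = np.array([np.quantile(x[:, j] / lib[j], 0.75) for j in range(x.shape[1])])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))

    factors = np.ones(x.shape[1])
    xr, nr = x[:, ref], lib[ref]
    for j in range(x.shape[1]):
        if j == ref:
            continue
        xs, ns = x[:, j], lib[j]
        keep = (xs > 0) & (xr > 0)
        if not keep.any():
            logger.warning("sample %s shares no expressed genes with reference; factor 1",
                           counts.counts.columns[j])
            continue
        ps, pr = xs[keep] / ns, xr[keep] / nr
        m = np.log2(ps / pr)
        a = 0.5 * np.log2(ps * pr)
        if np.max(np.abs(m)) < 1e-6:
            continue
        w = (ns - xs[keep]) / (ns * xs[keep]) + (nr - xr[keep]) / (nr * xr[keep])
        n = len(m)
        lo_m = np.floor(n * trim_m) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * trim_a) + 1
        hi_a = n + 1 - lo_a
        rm = stats.rankdata(m)
        ra = stats.rankdata(a)
        sel = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if not sel.any():
            continue
        f = 2 ** (np.sum(m[sel] / w[sel]) / np.sum(1.0 / w[sel]))
        if np.isfinite(f) and f > 0:
            factors[j] = f
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.counts.columns, name="tmm_factor")


def compute_cpm(counts: CountMatrix, factors: pd.Series | None = None,
                log: bool = False, prior: float = 0.5) -> ExpressionMatrix:
    """Counts per million on the effective (factor-scaled) library sizes.

    The log variant uses a prior count scaled by relative effective
    library size, so log2CPM is finite and monotone in counts.
    """
    lib = counts.library_sizes
    if factors is None:
        factors = pd.Series(1.0, index=counts.counts.columns)
    eff = lib * factors.reindex(lib.index)
    if (eff <= 0).any():
        raise ValidationError("zero effective library size")
    if not log:
        vals = counts.counts / eff * 1e6
        return ExpressionMatrix(vals, "CPM", factors)
    pc = prior * eff / eff.mean()
    vals = np.log2((counts.counts + pc) / (eff + 2 * pc) * 1e6)
    return ExpressionMatrix(vals, "log2CPM", factors, prior=prior)


def compute_fpkm(counts: CountMatrix, factors: pd.Series | None = None,
                 lengths: pd.Series | None = None) -> ExpressionMatrix:
    """Fragments per kilobase of (collapsed) exon model per million reads."""
    lib = counts.library_sizes
    if factors is None:
        factors = pd.Series(1.0, index=counts.counts.columns)
    if lengths is None:
        lengths = counts.gene_meta["length"]
    lengths = lengths.reindex(counts.counts.index)
    if (lengths <= 0).any() or lengths.isna().any():
        raise ValidationError("FPKM requires positive gene lengths for all genes")
    eff = lib * factors.reindex(lib.index)
    vals = counts.counts.div(eff, axis=1).div(lengths, axis=0) * 1e9
    return ExpressionMatrix(vals, "FPKM", factors)


def filter_expressed(cpm: ExpressionMatrix, min_cpm: float = 1.0,
                     min_samples: int = 2) -> pd.Index:
    """Genes with CPM >= min_cpm in at least min_samples samples."""
    if cpm.scale != "CPM":
        raise ValidationError("filter_expressed expects a linear CPM matrix")
    kept = cpm.values.index[(cpm.values >= min_cpm).sum(axis=1) >= min_samples]
    logger.info("expressed-gene filter: kept %d / %d genes", len(kept), len(cpm.values))
    return kept


# ---------------------------------------------------------------------------
# specificity and bias
# ---------------------------------------------------------------------------

def aggregate_by_type(values: pd.DataFrame, samples: SampleTable) -> pd.DataFrame:
    """Arithmetic mean of linear expression across replicates per sample type."""
    type_of = samples.type_of()
    return values.T.groupby(values.columns.map(type_of)).mean().T


def tau_index(cpm: ExpressionMatrix, samples: SampleTable) -> pd.Series:
    """Expression-specificity index in [0, 1] per gene.

    Replicates are averaged on the linear CPM scale per sample type, then
    log2(x + 1)-transformed; tau = sum(1 - x_i / max) / (N - 1).  Genes
    with zero maximum are returned as NaN.
    """
    if cpm.scale != "CPM":
        raise ValidationError("tau_index expects a linear CPM matrix")
    by_type = aggregate_by_type(cpm.values, samples)
    if by_type.shape[1] < 2:
        raise ValidationError("tau requires >= 2 sample types")
    x = np.log2(by_type.to_numpy() + 1.0)
    mx = x.max(axis=1)
    n = x.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        tau = (1.0 - x / mx[:, None]).sum(axis=1) / (n - 1)
    tau[mx == 0] = np.nan
    return pd.Series(tau, index=by_type.index, name="tau")


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def classify_sex_bias(log2cpm: ExpressionMatrix, samples: SampleTable,
                      sample_type: str, min_fold: float = 2.0,
                      fdr: float = 0.05) -> pd.DataFrame:
    """Per-gene Welch t-test between sexes within one sample type.

    Direction is called only when |mean log2 fold change| strictly
    exceeds log2(min_fold) and the BH-adjusted p is below ``fdr``.
    This is a deliberately minimal classifier for synthetic data; calls
    from a dedicated DE engine can be supplied instead.
    """
    if log2cpm.scale != "log2CPM":
        raise ValidationError("classify_sex_bias expects a log2CPM matrix")
    df = samples.df
    sub = df[df["sample_type"] == sample_type]
    males = sub.loc[sub["sex"] == "male", "sample_id"].tolist()
    females = sub.loc[sub["sex"] == "female", "sample_id"].tolist()
    if len(males) < 2 or len(females) < 2:
        raise ValidationError(
            f"sample type {sample_type}: need >= 2 replicates per sex "
            f"(got {len(males)} male, {len(females)} female)")
    xm = log2cpm.values[males].to_numpy()
    xf = log2cpm.values[females].to_numpy()
    lfc = xm.mean(axis=1) - xf.mean(axis=1)  # male minus female
    t, p = stats.ttest_ind(xm, xf, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    padj = bh_adjust(p)
    cut = np.log2(min_fold)
    direction = np.where(
        (np.abs(lfc) > cut) & (padj < fdr),
        np.where(lfc > 0, "male", "female"), "unbiased")
    return pd.DataFrame({
        "gene_id": log2cpm.values.index,
        "sample_type": sample_type,
        "direction": direction,
        "log2fc": lfc,
        "p": p,
        "padj": padj,
    }).set_index("gene_id")
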