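"""Contig-to-chromosome anchoring, coverage-based sex linkage and QC.

Contigs are anchored to the reference chromosome holding the plurality
of their 1-to-1 orthologs; DNA coverage normalized per sample gives
male:female ratios that classify contigs as autosomal, Z-linked or
W-candidates, and drives the sample-QC / sex-mislabel rules.  A separate
alignment-span rule flags chimeric scaffolds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from zwdosage import _intervals
from zwdosage.io_core import CoverageTable, SampleTable, ValidationError

logger = logging.getLogger("zwdosage.assignment")

UNANCHORED = "unanchored"


# ---------------------------------------------------------------------------
# ortholog-majority anchoring
# ---------------------------------------------------------------------------

def anchor_contigs(orthologs: pd.DataFrame, min_votes: int = 1,
                   contig_lengths: pd.Series | None = None) -> pd.DataFrame:
    """Assign each contig to the reference chromosome with the plurality
    of its ortholog votes.

    Ties or fewer than ``min_votes`` total votes leave the contig
    unanchored.  Returns a frame indexed by contig with columns
    ``chromosome``, ``n_votes`` (total), ``top_votes`` and ``support``
    (= top/total); the global ortholog concordance is attached as
    ``result.attrs["concordance"]``.
    """
    if len(orthologs) == 0:
        raise ValidationError("empty ortholog table")
    if contig_lengths is not None:
        unknown = set(orthologs["contig"]) - set(contig_lengths.index)
        if unknown:
            raise ValidationError(f"orthologs on unknown contigs: {sorted(unknown)[:5]}")

    votes = (orthologs.groupby(["contig", "ref_chrom"]).size()
             .rename("votes").reset_index())
    rows = []
    for contig, sub in votes.groupby("contig"):
        total = int(sub["votes"].sum())
        top = int(sub["votes"].max())
        winners = sub.loc[sub["votes"] == top, "ref_chrom"].tolist()
        if total < min_votes or len(winners) > 1:
            chrom = UNANCHORED
        else:
            chrom = winners[0]
        rows.append({"contig": contig, "chromosome": chrom,
                     "n_votes": total, "top_votes": top,
                     "support": top / total})
    out = pd.DataFrame(rows).set_index("contig")

    assigned = out["chromosome"]
    concordant = sum(
        assigned.get(c, UNANCHORED) == r
        for c, r in zip(orthologs["contig"], orthologs["ref_chrom"])
    )
    out.attrs["concordance"] = concordant / len(orthologs)
    logger.info("anchored %d/%d contigs; ortholog concordance %.4f",
                int((out["chromosome"] != UNANCHORED).sum()), len(out),
                out.attrs["concordance"])
    return out


def detect_fusions(assignments: pd.DataFrame, orthologs: pd.DataFrame,
                   scaffold_map: pd.DataFrame, min_support: float = 0.8,
                   min_votes: int = 3) -> pd.DataFrame:
    """Report scaffolds whose contigs anchor confidently to >= 2 reference
    chromosomes (candidate fusion events).

    ``scaffold_map`` needs columns contig, scaffold, scaffold_start.  The
    breakpoint interval is the gap between the last ortholog of one
    reference chromosome and the first of the next along the scaffold.
    """
    smap = scaffold_map.set_index("contig")
    rows = []
    joined = assignments.join(smap, how="inner")
    for scaffold, sub in joined.groupby("scaffold"):
        confident = sub[(sub["chromosome"] != UNANCHORED)
                        & (sub["support"] >= min_support)]
        chrom_votes = confident.groupby("chromosome")["top_votes"].sum()
        chroms = chrom_votes[chrom_votes >= min_votes].index.tolist()
        if len(chroms) < 2:
            continue
        # order orthologs along the scaffold
        ortho = orthologs[orthologs["contig"].isin(sub.index)].copy()
        ortho["scaffold_pos"] = (
            ortho["contig"].map(smap["scaffold_start"]) + ortho["contig_pos"])
        ortho["assigned"] = ortho["contig"].map(assignments["chromosome"])
        ortho = ortho[ortho["assigned"].isin(chroms)
                      & (ortho["ref_chrom"] == ortho["assigned"])]
        ortho = ortho.sort_values("scaffold_pos")
        # breakpoints between consecutive runs of distinct reference chroms
        breakpoints = []
        prev_chrom, prev_pos = None, None
        for _, r in ortho.iterrows():
            if prev_chrom is not None and r["ref_chrom"] != prev_chrom:
                breakpoints.append((int(prev_pos), int(r["scaffold_pos"])))
            prev_chrom, prev_pos = r["ref_chrom"], r["scaffold_pos"]
        rows.append({
            "scaffold": scaffold,
            "ref_chroms": "+".join(sorted(chroms)),
            "breakpoint_start": breakpoints[0][0] if breakpoints else -1,
            "breakpoint_end": breakpoints[0][1] if breakpoints else -1,
            "n_breakpoints": len(breakpoints),
        })
    return pd.DataFrame(rows, columns=["scaffold", "ref_chroms", "breakpoint_start",
                                       "breakpoint_end", "n_breakpoints"])


# ---------------------------------------------------------------------------
# coverage normalization and QC
# ---------------------------------------------------------------------------

@dataclass
class NormalizedCoverage:
    """Raw medians plus per-sample normalized coverage (weighted mean 1)."""

    raw: pd.DataFrame         # contigs x samples median coverage
    normalized: pd.DataFrame  # contigs x samples, per-sample mean 1 (read-weighted)
    weights: pd.DataFrame     # contigs x samples mapped reads
    contig_lengths: pd.Series
    samples: SampleTable


def normalize_coverage(cov: CoverageTable) -> NormalizedCoverage:
    """Divide each sample's contig medians by that sample's read-weighted
    mean median coverage, so the weighted mean normalized coverage is 1."""
    w = cov.mapped_reads.astype(float)
    norm_const = (w * cov.medians).sum(axis=0) / w.sum(axis=0)
    if (norm_const <= 0).any() or norm_const.isna().any():
        bad = norm_const.index[(norm_const <= 0) | norm_const.isna()].tolist()
        raise ValidationError(f"zero/undefined coverage normalizer for samples: {bad}")
    normalized = cov.medians / norm_const
    return NormalizedCoverage(cov.medians, normalized, w, cov.contig_lengths, cov.samples)


def sample_qc_coverage(norm: NormalizedCoverage, min_mean_cov: float = 5.0,
                       het_cv_cutoff: float = 0.5) -> pd.DataFrame:
    """Flag low-coverage and heterogeneous samples.

    low_coverage: length-weighted mean *raw* coverage < ``min_mean_cov``.
    heterogeneous: coefficient of variation of normalized contig coverage
    > ``het_cv_cutoff``.
    """
    lengths = norm.contig_lengths.reindex(norm.raw.index).astype(float)
    mean_cov = (norm.raw.mul(lengths, axis=0)).sum(axis=0) / lengths.sum()
    cv = norm.normalized.std(axis=0, ddof=1) / norm.normalized.mean(axis=0)
    out = pd.DataFrame({
        "sample_id": norm.raw.columns,
        "mean_coverage": mean_cov.values,
        "heterogeneity_cv": cv.values,
    })
    out["low_coverage"] = out["mean_coverage"] < min_mean_cov
    out["heterogeneous"] = out["heterogeneity_cv"] > het_cv_cutoff
    for _, r in out.iterrows():
        if r["low_coverage"] or r["heterogeneous"]:
            logger.info("sample %s flagged: low_coverage=%s heterogeneous=%s",
                        r["sample_id"], r["low_coverage"], r["heterogeneous"])
    return out


def detect_sex_mislabels(norm: NormalizedCoverage, z_contigs: list[str],
                         high_cut: float = 0.98, frac: float = 0.5,
                         female_like_cut: float = 0.75) -> pd.DataFrame:
    """Flag samples whose Z-coverage profile contradicts their sex label.

    A female-labeled sample is male-like when the length-weighted
    fraction of Z contigs with normalized coverage > ``high_cut`` is
    strictly greater than ``frac``; a male-labeled sample is female-like
    when the fraction with normalized coverage < ``female_like_cut``
    exceeds ``frac``.  Fractions are weighted by contig length.
    """
    z_contigs = [c for c in z_contigs if c in norm.normalized.index]
    if not z_contigs:
        raise ValidationError("no Z-linked contigs available for mislabel detection")
    zcov = norm.normalized.loc[z_contigs]
    zlen = norm.contig_lengths.reindex(z_contigs).astype(float)
    total = zlen.sum()
    sex = norm.samples.sex_of()

    rows = []
    for sid in zcov.columns:
        frac_high = float((zlen * (zcov[sid] > high_cut)).sum() / total)
        frac_low = float((zlen * (zcov[sid] < female_like_cut)).sum() / total)
        label = sex.get(sid, "NA")
        mislabel = ((label == "female" and frac_high > frac)
                    or (label == "male" and frac_low > frac))
        rows.append({"sample_id": sid, "sex": label,
                     "frac_z_high": frac_high, "frac_z_female_like": frac_low,
                     "sex_mislabel": bool(mislabel)})
    return pd.DataFrame(rows)


def classify_linkage(norm: NormalizedCoverage, z_cut: float = 0.5,
                     a_band: float = 0.25, w_floor: float = 0.1) -> pd.DataFrame:
    """Classify contigs from the log2 male:female normalized-coverage ratio.

    W-candidate: mean male coverage below ``w_floor`` with female above
    it; Z-linked: log2 ratio >= ``z_cut``; autosomal: |log2 ratio| <
    ``a_band``; otherwise undetermined.  Mean coverage is averaged per
    sex before the log transform.
    """
    sex = norm.samples.sex_of()
    males = [s for s in norm.normalized.columns if sex.get(s) == "male"]
    females = [s for s in norm.normalized.columns if sex.get(s) == "female"]
    if not males or not females:
        raise ValidationError("need at least one QC-passing sample of each sex")
    m = norm.normalized[males].mean(axis=1)
    f = norm.normalized[females].mean(axis=1)
    ratio = np.log2(np.maximum(m, w_floor) / np.maximum(f, w_floor))

    def classify(mi, fi, r):
        if mi < w_floor and fi >= w_floor:
            return "W-candidate"
        if r >= z_cut:
            return "Z-linked"
        if abs(r) < a_band:
            return "autosomal"
        return "undetermined"

    classes = [classify(mi, fi, r) for mi, fi, r in zip(m, f, ratio)]
    return pd.DataFrame({
        "mean_male": m, "mean_female": f, "log2_mf": ratio,
        "linkage_class": classes,
    }, index=norm.normalized.index)


# ---------------------------------------------------------------------------
# chimeric scaffolds
# ---------------------------------------------------------------------------

def flag_chimeric_scaffolds(spans: pd.DataFrame, contig_lengths: pd.Series,
                            min_block: int = 10_000, min_span: int = 100_000,
                            min_span_frac: float = 0.05) -> pd.DataFrame:
    """Flag scaffolds aligning substantially to >= 2 distinct contigs.

    Per (scaffold, contig) pair: total aligned length must reach
    ``min_block``, and the covered span (union of contig intervals) must
    strictly exceed both ``min_span`` and ``min_span_frac`` x contig
    length.  A scaffold is chimeric when >= 2 contigs qualify.  The rule
    is invariant to row order and to splitting blocks into abutting
    sub-blocks (union-based).
    """
    over = spans["contig_end"] > spans["contig"].map(contig_lengths).fillna(-1)
    if over.any():
        bad = spans.loc[over, "contig"].unique().tolist()
        raise ValidationError(f"alignment spans exceed contig length: {bad[:5]}")

    rows = []
    for (scaffold, contig), sub in spans.groupby(["scaffold", "contig"]):
        ivs = list(zip(sub["contig_start"], sub["contig_end"]))
        covered = _intervals.total_length(ivs)
        aligned = int(sub["aligned_length"].sum()) if "aligned_length" in sub else covered
        clen = int(contig_lengths[contig])
        ok = (aligned >= min_block and covered > min_span
              and covered > min_span_frac * clen)
        rows.append({"scaffold": scaffold, "contig": contig,
                     "aligned_total": aligned, "covered_span": covered,
                     "contig_length": clen, "qualifies": ok})
    per_pair = pd.DataFrame(rows)
    if per_pair.empty:
        return pd.DataFrame(columns=["scaffold", "contigs", "n_contigs"])
    chim = []
    for scaffold, sub in per_pair.groupby("scaffold"):
        good = sub[sub["qualifies"]]
        if len(good) >= 2:
            chim.append({"scaffold": scaffold,
                         "contigs": ",".join(sorted(good["contig"])),
                         "n_contigs": len(good)})
    return pd.DataFrame(chim, columns=["scaffold", "contigs", "n_contigs"])
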