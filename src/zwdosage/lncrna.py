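"""Structural lncRNA acceptance rules and coding-vs-lncRNA contrasts.

Candidates are assumed pre-screened for coding potential; this module
applies only structural rules: mature (spliced) length > 200 nt, at
least one splice junction, and positional classification against coding
gene models (sense exon overlap rejects; antisense, intronic and
intergenic are accepted categories).
"""

from __future__ import annotations

import logging

import pandas as pd

from zwdosage import _intervals
from zwdosage.dosage import fisher_2x2, two_prop_test
from zwdosage.io_core import GenomeAnnotation, ValidationError

logger = logging.getLogger("zwdosage.lncrna")

CLASSES = ("intergenic", "antisense", "intronic", "rejected")


def classify_lncrna(candidates: GenomeAnnotation, coding: GenomeAnnotation,
                    repeats: dict[str, list[tuple[int, int]]] | None = None,
                    min_length: int = 200,
                    contigs: set[str] | None = None) -> pd.DataFrame:
    """Classify candidate transcript models into lncRNA categories.

    Rejection rules: mature length <= ``min_length`` nt, fewer than two
    (merged) exons, or exon overlap with a coding gene's collapsed exons
    on the same strand.  Accepted candidates are antisense (opposite-
    strand exon overlap), intronic (inside a coding gene's span with no
    exon overlap, strand ignored) or intergenic.  ``repeat_overlap`` is
    set on >= 1 bp exon overlap with the repeat intervals.
    """
    coding_models = [g for g in coding if g.biotype == "coding"]
    by_contig: dict[str, list] = {}
    for g in coding_models:
        by_contig.setdefault(g.contig, []).append(g)
    rows = []
    for cand in candidates:
        if contigs is not None and cand.contig not in contigs:
            raise ValidationError(f"candidate {cand.gene_id} on unknown contig {cand.contig}")
        exons = _intervals.merge(cand.exons)
        length = _intervals.total_length(exons)
        cls, reason = None, ""
        if length <= min_length:
            cls, reason = "rejected", "too_short"
        elif len(exons) < 2:
            cls, reason = "rejected", "monoexonic"
        else:
            sense = antisense = intronic = False
            for g in by_contig.get(cand.contig, []):
                g_exons = _intervals.merge(g.exons)
                if _intervals.overlaps(exons, g_exons):
                    if g.strand == cand.strand:
                        sense = True
                        break
                    antisense = True
                else:
                    span = [g.span]
                    if _intervals.contains(span, exons):
                        intronic = True
            if sense:
                cls, reason = "rejected", "sense_overlap"
            elif antisense:
                cls = "antisense"
            elif intronic:
                cls = "intronic"
            else:
                cls = "intergenic"
        rep = False
        if repeats is not None:
            rep = _intervals.intersect_length(exons, repeats.get(cand.contig, [])) > 0
        rows.append({
            "transcript_id": cand.gene_id, "contig": cand.contig,
            "strand": cand.strand, "mature_length": length,
            "n_exons": len(exons), "lnc_class": cls,
            "rejection_reason": reason, "repeat_overlap": rep,
        })
    out = pd.DataFrame(rows)
    if not out.empty:
        accepted = out[out["lnc_class"] != "rejected"]
        logger.info("lncRNA classification: %d accepted (%d intergenic, %d antisense, "
                    "%d intronic), %d rejected",
                    len(accepted), (accepted["lnc_class"] == "intergenic").sum(),
                    (accepted["lnc_class"] == "antisense").sum(),
                    (accepted["lnc_class"] == "intronic").sum(),
                    (out["lnc_class"] == "rejected").sum())
    return out


def lncrna_contrast_tests(in_set: pd.Series, biotypes: pd.Series,
                          method: str = "fisher") -> dict:
    """Compare lncRNA vs coding membership in a named gene set.

    ``in_set`` is a boolean Series per gene; ``biotypes`` maps gene ->
    biotype.  Builds the 2x2 (biotype x membership) table and dispatches
    to the Fisher exact test or the continuity-corrected two-proportion
    chi-square test.
    """
    common = in_set.index.intersection(biotypes.index)
    bt = biotypes.loc[common]
    member = in_set.loc[common].astype(bool)
    lnc = bt == "lncRNA"
    cod = bt == "coding"
    if lnc.sum() == 0 or cod.sum() == 0:
        raise ValidationError("both lncRNA and coding genes required for contrast")
    x1, n1 = int((lnc & member).sum()), int(lnc.sum())
    x2, n2 = int((cod & member).sum()), int(cod.sum())
    out = {
        "lnc_in": x1, "lnc_total": n1, "coding_in": x2, "coding_total": n2,
        "lnc_prop": x1 / n1, "coding_prop": x2 / n2,
    }
    if method == "fisher":
        odds, p = fisher_2x2([[x1, n1 - x1], [x2, n2 - x2]])
        out.update({"odds_ratio": odds, "p": p, "method": "fisher"})
    elif method == "two_prop":
        chi2, df, p = two_prop_test(x1, n1, x2, n2, continuity=True)
        out.update({"chi2": chi2, "df": df, "p": p, "method": "two_prop"})
    else:
        raise ValidationError(f"unknown method {method!r}")
    return out
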