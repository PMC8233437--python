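"""Domain types and readers/writers for all external formats.

Internal coordinates are 0-based half-open everywhere.  GFF3 (1-based
closed) and BED (0-based half-open) conversions happen at this boundary
only.  All tables travel as pandas objects wrapped in light dataclasses
that validate their invariants on construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from zwdosage import _intervals

logger = logging.getLogger("zwdosage")

SEGMENT_ANC_Z = "anc-Z"
SEGMENT_NEO_Z = "neo-Z"
SEGMENT_W = "W"
SEGMENT_UNASSIGNED = "unassigned"

BIOTYPES = ("coding", "lncRNA", "miRNA", "rRNA", "tRNA")

#: feature types mapped to biotypes when no explicit attribute is present
_FEATURE_BIOTYPE = {
    "mRNA": "coding",
    "CDS": "coding",
    "lnc_RNA": "lncRNA",
    "lncRNA": "lncRNA",
    "miRNA": "miRNA",
    "rRNA": "rRNA",
    "tRNA": "tRNA",
}


class ParseError(ValueError):
    """Raised when an input file cannot be parsed."""


class ValidationError(ValueError):
    """Raised when parsed data violates a documented invariant."""


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

@dataclass
class Gene:
    """A gene model with 0-based half-open exon intervals on one contig."""

    gene_id: str
    contig: str
    strand: str
    biotype: str
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValidationError(f"gene {self.gene_id} has no exons")
        for s, e in self.exons:
            if s >= e:
                raise ValidationError(
                    f"gene {self.gene_id}: empty or inverted exon [{s}, {e})"
                )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand {self.strand!r}")
        if self.biotype not in BIOTYPES:
            raise ValidationError(f"gene {self.gene_id}: biotype {self.biotype!r}")

    @property
    def length(self) -> int:
        """Sum of collapsed (unioned) exon lengths in bp."""
        return _intervals.total_length(self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return min(s for s, _ in self.exons), max(e for _, e in self.exons)

    @property
    def introns(self) -> list[tuple[int, int]]:
        return _intervals.gaps(self.exons)


@dataclass
class GenomeAnnotation:
    """Ordered collection of gene models keyed by gene id."""

    genes: dict[str, Gene] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.genes.values())

    def __len__(self) -> int:
        return len(self.genes)

    def __getitem__(self, gene_id: str) -> Gene:
        return self.genes[gene_id]

    def subset(self, biotypes: tuple[str, ...]) -> "GenomeAnnotation":
        return GenomeAnnotation(
            {g.gene_id: g for g in self if g.biotype in biotypes}
        )

    def lengths(self) -> pd.Series:
        return pd.Series({g.gene_id: g.length for g in self}, name="length")


def _parse_gff_attributes(text: str) -> dict[str, str]:
    attrs = {}
    for part in text.strip().strip(";").split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            key, _, val = part.partition("=")
            attrs[key.strip()] = val.strip()
    return attrs


def load_annotation(path, contig_lengths: pd.Series | None = None) -> GenomeAnnotation:
    """Parse a GFF3 file into a :class:`GenomeAnnotation`.

    GFF3 1-based closed coordinates are converted to 0-based half-open.
    Biotype resolution order: explicit ``gene_biotype``/``biotype``
    attribute on the gene, else the feature type of its transcripts, else
    "coding" with a warning.
    """
    gene_rows: dict[str, dict] = {}
    tx_to_gene: dict[str, str] = {}
    tx_type: dict[str, str] = {}
    exons: dict[str, list[tuple[int, int]]] = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}: line {lineno}: expected 9 fields, got {len(fields)}")
            contig, _, ftype, start, end, _, strand, _, attr_text = fields
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if start_i < 1 or end_i < start_i:
                raise ParseError(f"{path}: line {lineno}: bad coordinates {start}..{end}")
            iv = (start_i - 1, end_i)  # to 0-based half-open
            attrs = _parse_gff_attributes(attr_text)

            if ftype == "gene":
                gid = attrs.get("ID")
                if gid is None:
                    raise ParseError(f"{path}: line {lineno}: gene without ID")
                gene_rows[gid] = {
                    "contig": contig,
                    "strand": strand,
                    "biotype": attrs.get("gene_biotype") or attrs.get("biotype"),
                }
            elif ftype == "exon":
                parent = attrs.get("Parent")
                if parent is None:
                    raise ParseError(f"{path}: line {lineno}: exon without Parent")
                for p in parent.split(","):
                    exons.setdefault(p, []).append(iv)
            elif ftype in _FEATURE_BIOTYPE or ftype in ("transcript", "mRNA"):
                tid = attrs.get("ID")
                parent = attrs.get("Parent")
                if tid and parent:
                    tx_to_gene[tid] = parent
                    tx_type[tid] = ftype

    genes: dict[str, Gene] = {}
    for gid, row in gene_rows.items():
        gene_exons: list[tuple[int, int]] = list(exons.get(gid, []))
        tx_types = set()
        for tid, parent in tx_to_gene.items():
            if parent == gid:
                gene_exons.extend(exons.get(tid, []))
                tx_types.add(tx_type[tid])
        if not gene_exons:
            raise ValidationError(f"gene {gid} has no exon rows")
        biotype = row["biotype"]
        if biotype is None:
            for t in tx_types:
                if t in _FEATURE_BIOTYPE:
                    biotype = _FEATURE_BIOTYPE[t]
                    break
        if biotype is None:
            logger.warning("gene %s: no biotype attribute or feature clue; assuming coding", gid)
            biotype = "coding"
        if contig_lengths is not None and row["contig"] in contig_lengths.index:
            clen = int(contig_lengths[row["contig"]])
            for s, e in gene_exons:
                if e > clen:
                    raise ValidationError(
                        f"gene {gid}: exon [{s}, {e}) exceeds contig "
                        f"{row['contig']} length {clen}"
                    )
        genes[gid] = Gene(gid, row["contig"], row["strand"], biotype, sorted(gene_exons))
    return GenomeAnnotation(genes)


def write_annotation(ann: GenomeAnnotation, path) -> None:
    """Write a GenomeAnnotation as GFF3 (gene + transcript + exon rows)."""
    tx_feature = {
        "coding": "mRNA", "lncRNA": "lnc_RNA", "miRNA": "miRNA",
        "rRNA": "rRNA", "tRNA": "tRNA",
    }
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in ann:
            s, e = g.span
            fh.write(
                f"{g.contig}\tzwdosage\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id};gene_biotype={g.biotype}\n"
            )
            tid = f"{g.gene_id}.t1"
            fh.write(
                f"{g.contig}\tzwdosage\t{tx_feature[g.biotype]}\t{s + 1}\t{e}\t.\t"
                f"{g.strand}\t.\tID={tid};Parent={g.gene_id}\n"
            )
            for xs, xe in g.exons:
                fh.write(
                    f"{g.contig}\tzwdosage\texon\t{xs + 1}\t{xe}\t.\t{g.strand}\t.\t"
                    f"Parent={tid}\n"
                )


# ---------------------------------------------------------------------------
# samples
# ---------------------------------------------------------------------------

@dataclass
class SampleTable:
    """Per-sample metadata: type, sex, replicate, batch, library size."""

    df: pd.DataFrame

    COLUMNS = ("sample_id", "sample_type", "sex", "replicate", "batch", "library_size")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.df.columns]
        if missing:
            raise ValidationError(f"sample table missing columns: {missing}")
        if self.df["sample_id"].duplicated().any():
            dups = self.df.loc[self.df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        if (self.df["library_size"] < 0).any():
            raise ValidationError("negative library size")
        bad_sex = set(self.df["sex"]) - {"male", "female", "NA"}
        if bad_sex:
            raise ValidationError(f"invalid sex labels: {sorted(bad_sex)}")
        self.df = self.df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.df["sample_id"].tolist()

    def sex_of(self) -> pd.Series:
        return self.df.set_index("sample_id")["sex"]

    def type_of(self) -> pd.Series:
        return self.df.set_index("sample_id")["sample_type"]


def load_samples(path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "batch": str})
    return SampleTable(df)


def write_samples(samples: SampleTable, path) -> None:
    samples.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """genes x samples raw counts plus per-gene metadata.

    ``gene_meta`` carries length (bp), biotype, contig and chromosome
    segment label per gene, indexed identically to ``counts``.
    """

    counts: pd.DataFrame
    gene_meta: pd.DataFrame
    samples: SampleTable

    def __post_init__(self) -> None:
        if list(self.counts.columns) != self.samples.sample_ids:
            raise ValidationError("count columns do not match sample table order")
        if (self.counts.values < 0).any():
            raise ValidationError("negative counts")
        if not self.gene_meta.index.equals(self.counts.index):
            raise ValidationError("gene_meta index does not match counts")
        if (self.gene_meta["length"] <= 0).any():
            bad = self.gene_meta.index[self.gene_meta["length"] <= 0].tolist()
            raise ValidationError(f"non-positive gene lengths: {bad[:5]}")
        self.counts.index.name = "gene_id"
        self.counts.columns.name = None
        self.gene_meta.index.name = "gene_id"

    @property
    def library_sizes(self) -> pd.Series:
        """Declared library sizes; falls back to column sums when absent (0)."""
        declared = self.samples.df.set_index("sample_id")["library_size"]
        colsums = self.counts.sum(axis=0)
        out = declared.where(declared > 0, colsums)
        return out.reindex(self.counts.columns).astype(float)

    def subset_genes(self, gene_ids) -> "CountMatrix":
        return CountMatrix(
            self.counts.loc[gene_ids], self.gene_meta.loc[gene_ids], self.samples
        )


def load_counts(path, samples: SampleTable, gene_meta: pd.DataFrame | None = None) -> CountMatrix:
    """Read a gene x sample TSV of raw counts.

    Float cells are accepted only when integral.  Genes missing from
    ``gene_meta`` get segment "unassigned" and must have a length there;
    with no metadata at all a length of 1 kb placeholder is refused —
    callers must supply lengths.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    extra = [c for c in df.columns if c not in set(samples.sample_ids)]
    missing = [s for s in samples.sample_ids if s not in df.columns]
    if extra or missing:
        raise ValidationError(
            f"count columns mismatch sample table; extra={extra} missing={missing}"
        )
    df = df[samples.sample_ids]
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValidationError("non-numeric cells in count matrix")
    if (values < 0).any():
        raise ValidationError("negative counts in count matrix")
    if not np.allclose(values, np.round(values)):
        raise ValidationError("non-integral counts in count matrix")
    counts = pd.DataFrame(np.round(values).astype(np.int64), index=df.index, columns=df.columns)

    if gene_meta is None:
        raise ValidationError("gene metadata (lengths) required to build a CountMatrix")
    meta = gene_meta.reindex(counts.index)
    if meta["length"].isna().any():
        raise ValidationError("genes missing length metadata")
    meta["segment"] = meta["segment"].fillna(SEGMENT_UNASSIGNED)
    return CountMatrix(counts, meta, samples)


def write_counts(cm: CountMatrix, counts_path, meta_path=None) -> None:
    cm.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
    if meta_path is not None:
        cm.gene_meta.to_csv(meta_path, sep="\t", index_label="gene_id")


def load_gene_meta(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------

@dataclass
class CoverageTable:
    """Per (contig, sample) median DNA coverage and mapped-read weights."""

    medians: pd.DataFrame      # contigs x samples, median coverage
    mapped_reads: pd.DataFrame  # contigs x samples, read counts
    contig_lengths: pd.Series   # bp per contig
    samples: SampleTable

    def __post_init__(self) -> None:
        if (self.medians.values < 0).any():
            raise ValidationError("negative median coverage")
        if not self.medians.index.equals(self.mapped_reads.index):
            raise ValidationError("coverage/read contig sets differ")
        if list(self.medians.columns) != list(self.mapped_reads.columns):
            raise ValidationError("coverage/read sample sets differ")
        missing = set(self.medians.index) - set(self.contig_lengths.index)
        if missing:
            raise ValidationError(f"contigs missing lengths: {sorted(missing)[:5]}")
        for df in (self.medians, self.mapped_reads):
            df.index.name = "contig"
            df.columns.name = None

    @property
    def contigs(self) -> pd.Index:
        return self.medians.index


def load_coverage(path, samples: SampleTable, contig_lengths: pd.Series) -> CoverageTable:
    """Read a long-format TSV: sample_id, contig, median_coverage, mapped_reads."""
    df = pd.read_csv(path, sep="\t")
    need = {"sample_id", "contig", "median_coverage", "mapped_reads"}
    if not need.issubset(df.columns):
        raise ValidationError(f"coverage table needs columns {sorted(need)}")
    med = df.pivot(index="contig", columns="sample_id", values="median_coverage")
    reads = df.pivot(index="contig", columns="sample_id", values="mapped_reads")
    if med.isna().any().any():
        raise ValidationError("contig set not identical across samples")
    order = [s for s in samples.sample_ids if s in med.columns]
    return CoverageTable(med[order], reads[order], contig_lengths, samples)


def write_coverage(cov: CoverageTable, path) -> None:
    long = (
        cov.medians.stack().rename("median_coverage").to_frame()
        .join(cov.mapped_reads.stack().rename("mapped_reads"))
        .reset_index()
    )
    long.columns = ["contig", "sample_id", "median_coverage", "mapped_reads"]
    long = long[["sample_id", "contig", "median_coverage", "mapped_reads"]]
    long.to_csv(path, sep="\t", index=False)


def load_contig_lengths(path) -> pd.Series:
    """FAI-style TSV: first column contig name, second column length (bp)."""
    df = pd.read_csv(path, sep="\t", header=None)
    lengths = pd.Series(df[1].values, index=df[0].values, name="length")
    if (lengths <= 0).any():
        raise ValidationError("non-positive contig length")
    return lengths.astype(np.int64)


def write_contig_lengths(lengths: pd.Series, path) -> None:
    lengths.to_frame().to_csv(path, sep="\t", header=False)


# ---------------------------------------------------------------------------
# orthologs
# ---------------------------------------------------------------------------

ORTHOLOG_COLUMNS = ["gene_id", "contig", "contig_pos", "ref_chrom", "ref_pos"]


def load_orthologs(path, contig_lengths: pd.Series | None = None) -> pd.DataFrame:
    """1-to-1 ortholog table: gene_id, contig, contig_pos, ref_chrom, ref_pos."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ORTHOLOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"ortholog table missing columns: {missing}")
    if df["gene_id"].duplicated().any():
        raise ValidationError("ortholog table has duplicated gene ids (not 1-to-1)")
    if contig_lengths is not None:
        unknown = set(df["contig"]) - set(contig_lengths.index)
        if unknown:
            raise ValidationError(f"ortholog contigs not in contig set: {sorted(unknown)[:5]}")
    return df[ORTHOLOG_COLUMNS]


def write_orthologs(orthologs: pd.DataFrame, path) -> None:
    orthologs.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# alignment spans
# ---------------------------------------------------------------------------

SPAN_COLUMNS = ["scaffold", "scaffold_start", "scaffold_end", "contig", "contig_start", "contig_end"]


def load_alignment_spans(path) -> pd.DataFrame:
    """Read alignment spans from PAF or the 6-column TSV fallback.

    PAF is detected by column count (>=12, tab-separated, no header).
    Coordinates are 0-based half-open on both axes in either dialect.
    """
    with open(path) as fh:
        first = fh.readline()
    n_fields = len(first.rstrip("\n").split("\t"))
    if n_fields >= 12:
        df = pd.read_csv(path, sep="\t", header=None, usecols=range(11))
        df = df.rename(columns={
            0: "scaffold", 2: "scaffold_start", 3: "scaffold_end",
            5: "contig", 7: "contig_start", 8: "contig_end",
        })[SPAN_COLUMNS]
    else:
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in SPAN_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"alignment span table missing columns: {missing}")
        df = df[SPAN_COLUMNS]
    bad = (df["scaffold_end"] <= df["scaffold_start"]) | (df["contig_end"] <= df["contig_start"])
    if bad.any():
        raise ValidationError(f"{int(bad.sum())} alignment spans with non-positive length")
    df["aligned_length"] = df["contig_end"] - df["contig_start"]
    return df


def write_alignment_spans(spans: pd.DataFrame, path) -> None:
    spans[SPAN_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# repeats (BED)
# ---------------------------------------------------------------------------

def load_repeats(path) -> dict[str, list[tuple[int, int]]]:
    """BED intervals (0-based half-open) grouped per contig."""
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: BED needs >=3 columns")
            contig, start, end = fields[0], int(fields[1]), int(fields[2])
            if end <= start:
                raise ValidationError(f"{path}: line {lineno}: empty BED interval")
            out.setdefault(contig, []).append((start, end))
    return {c: _intervals.merge(ivs) for c, ivs in out.items()}


def write_repeats(repeats: dict[str, list[tuple[int, int]]], path) -> None:
    with open(path, "w") as fh:
        for contig in sorted(repeats):
            for s, e in repeats[contig]:
                fh.write(f"{contig}\t{s}\t{e}\n")


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(level=getattr(logging, level.upper()),
                        format="%(asctime)s %(levelname)s %(name)s: %(message)s")
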