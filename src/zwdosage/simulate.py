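"""Synthetic ZW-system genomes, coverage tables and RNA-seq counts.

Everything downstream of the generator is testable against the emitted
ground truth: contig/chromosome membership, sample sexes, per-gene
segments, dosage factors and planted sex-bias directions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from zwdosage import io_core
from zwdosage.io_core import (
    CountMatrix,
    CoverageTable,
    Gene,
    GenomeAnnotation,
    SampleTable,
    SEGMENT_ANC_Z,
    SEGMENT_NEO_Z,
    SEGMENT_W,
)

logger = logging.getLogger("zwdosage.simulate")

GENE_SPACING = 10_000   # bp between gene starts
GENE_SPAN = 2_000       # genomic span of each two-exon gene model
_MEAN_CAP = 1e8


@dataclass
class SimulationConfig:
    """Full parameterization of the synthetic generator.

    Dosage factors are multiplicative on per-gene expression and encode
    the compensation regime directly: on the Z in females, 0.5 means no
    compensation (one copy, no upregulation) and 1.0 complete
    compensation; in males 1.0 means no downregulation.  Keys of
    ``dosage_factors`` are (segment, sex) or (segment, sex, sample_type);
    the most specific match wins; missing keys mean 1.0.
    """

    n_autosomes: int = 29
    anc_z_genes: int = 120
    neo_z_genes: int = 80
    w_genes: int = 10
    genes_per_autosome: int = 40
    ortholog_density: float = 0.85
    transposition_rate: float = 0.03
    breakpoints_per_chromosome: int = 2
    # DNA coverage
    depth_per_copy: float = 15.0
    coverage_noise_sd: float = 0.1
    n_male_dna: int = 8
    n_female_dna: int = 8
    read_length: int = 150
    n_mislabeled: int = 0        # female-labeled samples drawn from the male model
    n_low_coverage: int = 0      # samples scaled to mean raw coverage < 5
    n_heterogeneous: int = 0     # samples with extra per-contig lognormal noise
    # RNA design: (sample_type, sex, n_replicates)
    rna_design: list[tuple[str, str, int]] = field(default_factory=lambda: [
        ("WB", "female", 2), ("WB", "male", 2),
        ("HD", "female", 2), ("HD", "male", 2),
        ("TX", "female", 2), ("TX", "male", 2),
        ("AB", "female", 2), ("AB", "male", 2),
    ])
    baseline_meanlog: float = 3.0   # natural-log scale of per-gene base expression
    baseline_sdlog: float = 1.0
    dosage_factors: dict = field(default_factory=dict)
    nb_dispersion: float = 0.1
    library_size: float = 2e7
    sex_biased_fraction: float = 0.0
    sex_bias_fold: float = 4.0
    lncrna_fraction: float = 0.0
    lncrna_level_factor: float = 0.25
    lncrna_concentration: float = 0.3
    coding_concentration: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ortholog_density", "transposition_rate",
                     "sex_biased_fraction", "lncrna_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        for key, f in self.dosage_factors.items():
            if f <= 0:
                raise ValueError(f"dosage factor {key} must be > 0")
        for n in (self.anc_z_genes, self.neo_z_genes, self.w_genes,
                  self.genes_per_autosome):
            if n < 0:
                raise ValueError("gene counts must be >= 0")

    def dosage_factor(self, segment: str, sex: str, sample_type: str) -> float:
        for key in ((segment, sex, sample_type), (segment, sex)):
            if key in self.dosage_factors:
                return float(self.dosage_factors[key])
        return 1.0


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    contigs: pd.DataFrame      # contig, chromosome, segment, scaffold, scaffold_start, length
    genes: pd.DataFrame        # gene_id, contig, segment, biotype, bias_direction
    sample_flags: pd.DataFrame | None = None  # sample_id, true_sex, planted flag
    ref_chrom_of_segment: dict[str, str] = field(default_factory=dict)

    def z_contigs(self) -> list[str]:
        mask = self.contigs["segment"].isin([SEGMENT_ANC_Z, SEGMENT_NEO_Z])
        return self.contigs.loc[mask, "contig"].tolist()


def _segments_of_config(config: SimulationConfig) -> list[tuple[str, str, int]]:
    """(chromosome, segment label, n genes) in genomic order."""
    out = [("Z", SEGMENT_ANC_Z, config.anc_z_genes),
           ("Z", SEGMENT_NEO_Z, config.neo_z_genes)]
    for i in range(1, config.n_autosomes + 1):
        out.append((f"A{i}", f"A{i}", config.genes_per_autosome))
    if config.w_genes > 0:
        out.append(("W", SEGMENT_W, config.w_genes))
    return out


def simulate_genome_map(config: SimulationConfig):
    """Generate contig lengths, an ortholog table, annotation and truth.

    Each chromosome is laid out as equally spaced two-exon genes and cut
    into ``breakpoints + 1`` contigs at random gene boundaries; the
    anc-Z/neo-Z junction is forced to be a contig boundary so each Z
    contig has a single true segment.  Ortholog rows carry the true
    reference chromosome except for a ``transposition_rate`` fraction,
    which get a uniformly random wrong one.  anc-Z and neo-Z map to two
    distinct reference chromosomes.
    """
    rng = np.random.default_rng(config.seed)
    segments = _segments_of_config(config)

    # reference chromosome names: anc-Z -> ref1, neo-Z -> ref21 (fused pair)
    ref_of_segment: dict[str, str] = {SEGMENT_ANC_Z: "ref1", SEGMENT_NEO_Z: "ref21"}
    ref_pool = [f"ref{i}" for i in range(2, 2 + config.n_autosomes + 25)
                if f"ref{i}" != "ref21"]
    for i in range(1, config.n_autosomes + 1):
        ref_of_segment[f"A{i}"] = ref_pool[i - 1]
    all_refs = sorted(set(ref_of_segment.values()))

    contig_rows = []
    gene_rows = []
    ortho_rows = []
    genes: dict[str, Gene] = {}
    contig_lengths: dict[str, int] = {}

    # group segments by chromosome to lay out genes contiguously
    by_chrom: dict[str, list[tuple[str, int]]] = {}
    for chrom, seg, n in segments:
        by_chrom.setdefault(chrom, []).append((seg, n))

    for chrom, segs in by_chrom.items():
        gene_segments: list[str] = []
        for seg, n in segs:
            gene_segments.extend([seg] * n)
        n_genes = len(gene_segments)
        if n_genes == 0:
            if config.breakpoints_per_chromosome > 0:
                raise ValueError(f"chromosome {chrom}: breakpoints requested but no genes")
            continue
        chrom_len = n_genes * GENE_SPACING + GENE_SPACING // 2

        # contig boundaries at gene boundaries; force the segment junction
        n_breaks = min(config.breakpoints_per_chromosome, n_genes - 1)
        candidates = np.arange(1, n_genes)
        forced = []
        if chrom == "Z" and len(segs) == 2 and all(n > 0 for _, n in segs):
            forced = [segs[0][1]]  # gene index where neo-Z starts
        free = [c for c in candidates if c not in forced]
        n_random = max(n_breaks - len(forced), 0)
        chosen = sorted(forced + list(
            rng.choice(free, size=min(n_random, len(free)), replace=False)))
        bounds = [0] + chosen + [n_genes]

        scaffold = f"scf_{chrom}"
        for ci in range(len(bounds) - 1):
            g_lo, g_hi = bounds[ci], bounds[ci + 1]
            start_bp = g_lo * GENE_SPACING
            end_bp = g_hi * GENE_SPACING if g_hi < n_genes else chrom_len
            contig = f"ctg_{chrom}_{ci}"
            contig_lengths[contig] = end_bp - start_bp
            seg_label = gene_segments[g_lo]  # pure by construction for Z
            contig_rows.append({
                "contig": contig, "chromosome": chrom, "segment": seg_label,
                "scaffold": scaffold, "scaffold_start": start_bp,
                "length": end_bp - start_bp,
            })
            for gi in range(g_lo, g_hi):
                seg = gene_segments[gi]
                gid = f"g_{chrom}_{gi}"
                pos = gi * GENE_SPACING - start_bp  # contig-local gene start
                strand = "+" if rng.random() < 0.5 else "-"
                exons = [(pos, pos + 600), (pos + 1400, pos + GENE_SPAN)]
                genes[gid] = Gene(gid, contig, strand, "coding", exons)
                gene_rows.append({
                    "gene_id": gid, "contig": contig, "segment": seg,
                    "biotype": "coding", "bias_direction": "unbiased",
                })
                if seg != SEGMENT_W and rng.random() < config.ortholog_density:
                    true_ref = ref_of_segment[seg]
                    if rng.random() < config.transposition_rate:
                        wrong = [r for r in all_refs if r != true_ref]
                        ref = wrong[rng.integers(len(wrong))]
                    else:
                        ref = true_ref
                    ortho_rows.append({
                        "gene_id": gid, "contig": contig, "contig_pos": pos,
                        "ref_chrom": ref, "ref_pos": gi * GENE_SPACING,
                    })

    truth = GroundTruth(
        contigs=pd.DataFrame(contig_rows),
        genes=pd.DataFrame(gene_rows).set_index("gene_id", drop=False),
        ref_chrom_of_segment=ref_of_segment,
    )
    lengths = pd.Series(contig_lengths, name="length")
    orthologs = pd.DataFrame(ortho_rows, columns=io_core.ORTHOLOG_COLUMNS)
    annotation = GenomeAnnotation(genes)
    return lengths, orthologs, annotation, truth


# copy number per (segment kind, sex)
def _copy_number(segment: str, sex: str) -> int:
    if segment == SEGMENT_W:
        return 0 if sex == "male" else 1
    if segment in (SEGMENT_ANC_Z, SEGMENT_NEO_Z):
        return 2 if sex == "male" else 1
    return 2


def simulate_dna_coverage(config: SimulationConfig, truth: GroundTruth) -> CoverageTable:
    """Per (sample, contig) median coverage under the ZW copy-number model.

    coverage ~ depth_per_copy x copy_number x lognormal(0, sd_c);
    mapped reads proportional to coverage x contig length.  The noise sd
    is length-attenuated, sd_c = coverage_noise_sd x sqrt(1 kb / L_c):
    the median over a longer contig is a more precise estimator, and the
    configured sd applies to a 1 kb contig.  Planted anomalies (sex
    mislabels, low-coverage, heterogeneous samples) are recorded in
    ``truth.sample_flags``.
    """
    rng = np.random.default_rng(config.seed + 1)
    contigs = truth.contigs
    sample_rows = []
    flags = []
    for i in range(config.n_male_dna):
        sample_rows.append((f"M{i + 1}", "male", "male"))
    for i in range(config.n_female_dna):
        sample_rows.append((f"F{i + 1}", "female", "female"))

    # plant anomalies on extra samples so the clean design stays intact
    for i in range(config.n_mislabeled):
        sample_rows.append((f"F_mis{i + 1}", "female", "male"))  # labeled F, truly M
    low_ids = []
    for i in range(config.n_low_coverage):
        sid = f"M_low{i + 1}"
        sample_rows.append((sid, "male", "male"))
        low_ids.append(sid)
    het_ids = []
    for i in range(config.n_heterogeneous):
        sid = f"F_het{i + 1}"
        sample_rows.append((sid, "female", "female"))
        het_ids.append(sid)

    seg = contigs.set_index("contig")["segment"]
    lengths = contigs.set_index("contig")["length"].astype(float)
    med = {}
    reads = {}
    sd_per_contig = config.coverage_noise_sd * np.sqrt(1_000.0 / lengths.values)
    for sid, label, true_sex in sample_rows:
        copies = np.array([_copy_number(seg[c], true_sex) for c in seg.index], dtype=float)
        noise = (np.exp(rng.normal(0.0, sd_per_contig))
                 if config.coverage_noise_sd > 0 else 1.0)
        cov = config.depth_per_copy * copies * noise
        if sid in low_ids:
            cov = cov * (2.0 / (config.depth_per_copy * 2))  # mean raw coverage ~2 << 5
        if sid in het_ids:
            cov = cov * np.exp(rng.normal(0.0, 1.0, size=len(cov)))
        med[sid] = cov
        reads[sid] = np.round(cov * lengths.values / config.read_length).astype(np.int64)
        flag = ("sex_mislabel" if label != true_sex
                else "low_coverage" if sid in low_ids
                else "heterogeneous" if sid in het_ids
                else "")
        flags.append({"sample_id": sid, "labeled_sex": label,
                      "true_sex": true_sex, "planted_flag": flag})

    medians = pd.DataFrame(med, index=seg.index)
    mapped = pd.DataFrame(reads, index=seg.index)
    sample_df = pd.DataFrame({
        "sample_id": [s for s, _, _ in sample_rows],
        "sample_type": "DNA",
        "sex": [label for _, label, _ in sample_rows],
        "replicate": range(1, len(sample_rows) + 1),
        "batch": "sim",
        "library_size": mapped.sum(axis=0).values,
    })
    truth.sample_flags = pd.DataFrame(flags)
    return CoverageTable(medians, mapped, lengths.astype(np.int64), SampleTable(sample_df))


def simulate_expression_counts(config: SimulationConfig, truth: GroundTruth,
                               annotation: GenomeAnnotation):
    """Negative-binomial RNA counts under the configured dosage regime.

    count ~ NB(mean = mu_g x dosage(segment, sex, type) x profile_g(type)
    x bias_g(sex) x L_g x libsize / 1e9, dispersion phi); dispersion 0
    degenerates to Poisson.  lncRNA genes (a configured fraction) get a
    level factor < 1 and Dirichlet sample-type profiles with low
    concentration (restricted expression).  W genes are absent in males.
    """
    rng = np.random.default_rng(config.seed + 2)
    genes = truth.genes
    gene_ids = genes["gene_id"].tolist()
    n_genes = len(gene_ids)
    lengths = np.array([annotation[g].length for g in gene_ids], dtype=float)

    sample_types = sorted({t for t, _, _ in config.rna_design})
    n_types = len(sample_types)
    type_index = {t: i for i, t in enumerate(sample_types)}

    # biotypes and per-gene baselines
    is_lnc = rng.random(n_genes) < config.lncrna_fraction
    genes = genes.copy()
    genes.loc[is_lnc, "biotype"] = "lncRNA"
    mu = np.exp(rng.normal(config.baseline_meanlog, config.baseline_sdlog, n_genes))
    mu[is_lnc] *= config.lncrna_level_factor

    # sample-type profiles: rows sum to n_types (mean multiplier 1)
    conc = np.where(is_lnc, config.lncrna_concentration, config.coding_concentration)
    profiles = np.empty((n_genes, n_types))
    for i in range(n_genes):
        profiles[i] = rng.dirichlet(np.full(n_types, conc[i])) * n_types

    # planted sex-biased genes: half male-up, half female-up
    bias_dir = np.array(["unbiased"] * n_genes, dtype=object)
    if config.sex_biased_fraction > 0:
        biased = rng.random(n_genes) < config.sex_biased_fraction
        male_up = rng.random(n_genes) < 0.5
        bias_dir[biased & male_up] = "male"
        bias_dir[biased & ~male_up] = "female"
    genes["bias_direction"] = bias_dir

    sample_rows = []
    col_counts = {}
    for stype, sex, n_reps in config.rna_design:
        for rep in range(1, n_reps + 1):
            sid = f"{stype}_{sex[0].upper()}{rep}"
            segs = genes["segment"].values
            dose = np.array([config.dosage_factor(s, sex, stype) for s in segs])
            dose = np.where(segs == SEGMENT_W,
                            0.0 if sex == "male" else dose, dose)
            bias_mult = np.where(
                (bias_dir == "male") & (sex == "male"), config.sex_bias_fold,
                np.where((bias_dir == "female") & (sex == "female"),
                         config.sex_bias_fold, 1.0))
            mean = (mu * dose * bias_mult * profiles[:, type_index[stype]]
                    * lengths * config.library_size / 1e9)
            if (mean > _MEAN_CAP).any():
                logger.warning("capping %d NB means above %g",
                               int((mean > _MEAN_CAP).sum()), _MEAN_CAP)
                mean = np.minimum(mean, _MEAN_CAP)
            if config.nb_dispersion > 0:
                r = 1.0 / config.nb_dispersion
                counts = rng.negative_binomial(r, r / (r + mean))
            else:
                counts = rng.poisson(mean)
            col_counts[sid] = counts.astype(np.int64)
            sample_rows.append({
                "sample_id": sid, "sample_type": stype, "sex": sex,
                "replicate": rep, "batch": "sim", "library_size": 0,
            })

    counts = pd.DataFrame(col_counts, index=gene_ids)
    sample_df = pd.DataFrame(sample_rows)
    sample_df["library_size"] = counts.sum(axis=0).reindex(sample_df["sample_id"]).values
    samples = SampleTable(sample_df)

    gene_meta = pd.DataFrame({
        "length": lengths.astype(np.int64),
        "biotype": genes["biotype"].values,
        "contig": genes["contig"].values,
        "segment": genes["segment"].values,
    }, index=pd.Index(gene_ids, name="gene_id"))
    truth.genes = genes
    return CountMatrix(counts, gene_meta, samples), samples


def simulate_all(config: SimulationConfig):
    """Run all three generators; returns (lengths, orthologs, annotation,
    coverage, counts, samples, truth)."""
    lengths, orthologs, annotation, truth = simulate_genome_map(config)
    coverage = simulate_dna_coverage(config, truth)
    counts, samples = simulate_expression_counts(config, truth, annotation)
    return lengths, orthologs, annotation, coverage, counts, samples, truth


def write_fixtures(config: SimulationConfig, out_dir) -> None:
    """Emit every table in io_core formats plus truth tables."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lengths, orthologs, annotation, coverage, counts, samples, truth = simulate_all(config)
    io_core.write_contig_lengths(lengths, out / "contigs.fai")
    io_core.write_orthologs(orthologs, out / "orthologs.tsv")
    io_core.write_annotation(annotation, out / "genes.gff3")
    io_core.write_coverage(coverage, out / "coverage.tsv")
    io_core.write_samples(coverage.samples, out / "dna_samples.tsv")
    io_core.write_counts(counts, out / "counts.tsv", out / "gene_meta.tsv")
    io_core.write_samples(samples, out / "rna_samples.tsv")
    truth.contigs.to_csv(out / "truth_contigs.tsv", sep="\t", index=False)
    truth.genes.to_csv(out / "truth_genes.tsv", sep="\t", index=False)
    if truth.sample_flags is not None:
        truth.sample_flags.to_csv(out / "truth_samples.tsv", sep="\t", index=False)
    import json
    cfg = asdict(config)
    cfg["rna_design"] = [list(x) for x in cfg["rna_design"]]
    cfg["dosage_factors"] = {"|".join(k): v for k, v in cfg["dosage_factors"].items()}
    (out / "sim_config.json").write_text(json.dumps(cfg, indent=2))
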