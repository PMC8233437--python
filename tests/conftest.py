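import numpy as np
import pandas as pd
import pytest

from zwdosage import assignment, expression
from zwdosage.simulate import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def default_sim():
    """One default-config simulation with planted anomalies, shared read-only."""
    cfg = SimulationConfig(
        seed=7, n_mislabeled=2, n_low_coverage=2, n_heterogeneous=1,
        dosage_factors={("anc-Z", "female"): 0.5},
        lncrna_fraction=0.15,
    )
    lengths, orthologs, annotation, coverage, counts, samples, truth = simulate_all(cfg)
    return {
        "config": cfg, "lengths": lengths, "orthologs": orthologs,
        "annotation": annotation, "coverage": coverage, "counts": counts,
        "samples": samples, "truth": truth,
    }


@pytest.fixture(scope="session")
def default_expression(default_sim):
    counts = default_sim["counts"]
    factors = expression.tmm_factors(counts)
    cpm = expression.compute_cpm(counts, factors)
    kept = expression.filter_expressed(cpm)
    sub = counts.subset_genes(kept)
    f2 = expression.tmm_factors(sub)
    return {
        "kept": kept, "counts": sub,
        "cpm": expression.compute_cpm(sub, f2),
        "log2cpm": expression.compute_cpm(sub, f2, log=True),
        "fpkm": expression.compute_fpkm(sub, f2),
        "factors": f2,
    }


@pytest.fixture(scope="session")
def normcov(default_sim):
    return assignment.normalize_coverage(default_sim["coverage"])


def make_coverage_table(medians: dict, lengths: dict, sexes: dict,
                        reads: dict | None = None):
    """Small CoverageTable from plain dicts (samples -> contig -> value)."""
    from zwdosage.io_core import CoverageTable, SampleTable

    med = pd.DataFrame(medians)
    if reads is None:
        lens = pd.Series(lengths).reindex(med.index).astype(float)
        rd = med.mul(lens, axis=0).round().astype(np.int64)
    else:
        rd = pd.DataFrame(reads)
    sdf = pd.DataFrame({
        "sample_id": list(med.columns),
        "sample_type": "DNA",
        "sex": [sexes[s] for s in med.columns],
        "replicate": range(1, len(med.columns) + 1),
        "batch": "fix",
        "library_size": rd.sum(axis=0).values,
    })
    return CoverageTable(med, rd, pd.Series(lengths), SampleTable(sdf))
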