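import numpy as np
import pandas as pd
import pytest

from ffpe_concord.synthetic_data import SimulationConfig


@pytest.fixture
def clean_config() -> SimulationConfig:
    """Idealized error-free conditions: no artifacts, no sequencing
    error, Poisson coverage deep enough that filters always pass."""
    return SimulationConfig(
        genome_length=100_000,
        seed=42,
        seq_error_rate=0.0,
        deamination_rate_cpg=0.0,
        deamination_rate_noncpg=0.0,
        coverage_dispersion=0.0,
        mapq_mean_ff=58.0,
        mapq_mean_ffpe=58.0,
        mapq_sd=2.0,
    )


@pytest.fixture
def artifact_config(clean_config) -> SimulationConfig:
    """CpG-island-like substrate with strong FFPE deamination."""
    return clean_config.with_(
        cpg_enrichment=4.0,
        deamination_rate_cpg=0.02,
        deamination_rate_noncpg=0.002,
        mean_coverage_ff=100.0,
        mean_coverage_ffpe=100.0,
    )


def make_pileup(pos, ref, counts, depth=None, mapq=55.0, chrom="chr1",
                n_ins=0, n_del=0, indel_seq="."):
    """Small pileup DataFrame builder for hand-written fixtures."""
    counts = np.atleast_2d(np.asarray(counts, dtype=np.int64))
    pos = np.atleast_1d(np.asarray(pos, dtype=np.int64))
    ref = np.atleast_1d(np.asarray(ref, dtype=object))
    n = pos.size
    depth = (counts.sum(axis=1) if depth is None
             else np.broadcast_to(np.asarray(depth), (n,)))
    return pd.DataFrame({
        "chrom": chrom,
        "pos": pos,
        "ref": ref,
        "depth": np.asarray(depth, dtype=np.int64),
        "nA": counts[:, 0], "nC": counts[:, 1],
        "nG": counts[:, 2], "nT": counts[:, 3],
        "n_ins": np.broadcast_to(np.asarray(n_ins), (n,)).astype(np.int64),
        "n_del": np.broadcast_to(np.asarray(n_del), (n,)).astype(np.int64),
        "mapq": np.broadcast_to(np.asarray(mapq, dtype=float), (n,)),
        "indel_seq": np.broadcast_to(np.asarray(indel_seq, dtype=object),
                                     (n,)),
    })


def make_variants(rows, chrom="chr1"):
    """rows: iterable of (pos, ref, alt[, vaf[, genotype]])."""
    out = []
    for row in rows:
        pos, ref, alt = row[:3]
        vaf = row[3] if len(row) > 3 else 0.5
        genotype = row[4] if len(row) > 4 else "het"
        out.append((chrom, pos, ref, alt, genotype, vaf, 50, 55.0))
    return pd.DataFrame(out, columns=["chrom", "pos", "ref", "alt",
                                      "genotype", "vaf", "depth", "mapq"])
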