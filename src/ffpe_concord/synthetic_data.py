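"""Synthetic matched FF/FFPE data generator.

Emulates a pair of sequencing libraries prepared from the same tissue:
one fresh-frozen (FF) and one formalin-fixed paraffin-embedded (FFPE).
Both observe the same underlying truth (reference, germline and somatic
variants, INDELs, copy-number segments); the FFPE member additionally
carries cytosine-deamination artifacts — reads over a reference C (or G,
handled on the complementary strand) flipped to T (A) at a rate that is
elevated when the C sits in a CpG dinucleotide.

Observation channels:

* per-position pileups (depth, base counts, INDEL support, per-position
  mean mapping quality) for deep sequencing,
* low-pass binned read counts with a smooth GC bias for copy-number
  profiling,
* an array-style genotype table at germline sites as an orthogonal
  genotyping platform.

Coverage is negative-binomial with mean/dispersion parameterisation
(Poisson as dispersion -> 0).  All randomness flows from named
substreams of a single seed: identical config => bit-identical outputs.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import _seq
from .seeding import substream

SAMPLE_KINDS = ("ff_normal", "ff_tumor", "ffpe_normal", "ffpe_tumor")

PILEUP_COLUMNS = [
    "chrom", "pos", "ref", "depth",
    "nA", "nC", "nG", "nT", "n_ins", "n_del", "mapq", "indel_seq",
]


class ConfigurationError(ValueError):
    """Raised for invalid simulation parameters."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one matched FF/FFPE simulation.

    Coverage and error defaults follow what a matched-pair exome
    comparison typically looks like: mean depth 79x (FF) / 61x (FFPE),
    human-like GC of 0.41, heterozygosity 1e-3.  Deamination rates apply
    only to FFPE sample kinds.
    """

    genome_length: int = 1_000_000
    gc_fraction: float = 0.41
    cpg_enrichment: float = 1.0
    germline_het_rate: float = 1e-3
    somatic_rate: float = 1e-5
    tumor_vaf_mean: float = 0.4
    tumor_vaf_concentration: float = 30.0
    indel_rate: float = 1e-4
    mean_insertion_size: float = 6.0
    mean_deletion_size: float = 9.0
    mean_coverage_ff: float = 79.0
    mean_coverage_ffpe: float = 61.0
    coverage_dispersion: float = 0.1
    seq_error_rate: float = 5e-4
    deamination_rate_cpg: float = 0.01
    deamination_rate_noncpg: float = 0.001
    mapq_mean_ff: float = 55.0
    mapq_mean_ffpe: float = 50.0
    mapq_sd: float = 5.0
    lowpass_mean_coverage: float = 0.2
    read_length: int = 100
    bin_size: int = 15_000
    gc_bias_strength: float = 0.3
    cnv_segments: tuple = ()
    chrom: str = "chr1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ConfigurationError("genome_length must be positive")
        for name in ("gc_fraction", "germline_het_rate", "somatic_rate",
                     "seq_error_rate", "deamination_rate_cpg",
                     "deamination_rate_noncpg", "indel_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if not 0.0 < self.tumor_vaf_mean <= 1.0:
            raise ConfigurationError("tumor_vaf_mean must be in (0, 1]")
        if self.cpg_enrichment < 0:
            raise ConfigurationError("cpg_enrichment must be >= 0")
        if self.coverage_dispersion < 0:
            raise ConfigurationError("coverage_dispersion must be >= 0")
        if self.mapq_sd < 0:
            raise ConfigurationError("mapq_sd must be >= 0")
        if self.bin_size <= 0 or self.read_length <= 0:
            raise ConfigurationError("bin_size and read_length must be positive")
        object.__setattr__(self, "cnv_segments",
                           tuple(tuple(s) for s in self.cnv_segments))
        for start, end, copy_state in self.cnv_segments:
            if not (1 <= start <= end <= self.genome_length):
                raise ConfigurationError(
                    f"cnv segment ({start},{end}) outside genome")
            if copy_state < 0:
                raise ConfigurationError("copy_state must be >= 0")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass
class TruthSet:
    """Shared ground truth observed by both members of a pair.

    germline: columns pos, ref, alt, genotype ('het')
    somatic:  columns pos, ref, alt, vaf (tumor-only truth VAF)
    indels:   columns pos, kind ('ins'|'del'), seq, vaf
    """

    reference: str
    germline: pd.DataFrame
    somatic: pd.DataFrame
    indels: pd.DataFrame
    cnv_segments: tuple

    def __post_init__(self) -> None:
        n = len(self.reference)
        for df in (self.germline, self.somatic, self.indels):
            if len(df) and not ((df["pos"] >= 1) & (df["pos"] <= n)).all():
                raise ConfigurationError("truth position outside genome")
        overlap = set(self.germline["pos"]) & set(self.somatic["pos"])
        if overlap:
            raise ConfigurationError("germline/somatic positions overlap")
        if len(self.indels) and (self.indels["seq"].str.len() == 0).any():
            raise ConfigurationError("empty indel sequence")


# ---------------------------------------------------------------------------
# reference
# ---------------------------------------------------------------------------

def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def generate_reference(config: SimulationConfig) -> str:
    """Generate a random reference with target GC and tunable CpG density.

    Enrichment > 1 plants explicit "CG" dinucleotide units while
    compensating the single-base pool so expected composition stays at
    gc_fraction exactly; enrichment < 1 breaks a fraction of chance CG
    occurrences with composition-preserving swaps.  Enrichment 1 is iid.
    """
    rng = substream(config.seed, "reference")
    L = config.genome_length
    p = _base_probs(config.gc_fraction)
    enr = config.cpg_enrichment
    p_cg = p[_seq.C] * p[_seq.G]

    if enr == 1.0 or p_cg == 0.0:
        codes = rng.choice(4, size=L, p=p).astype(np.uint8)
        return _seq.decode(codes)

    if enr > 1.0:
        # per-unit planting probability w: fraction of planted CG pairs
        # w/(1+w) plus residual chance pairs approximates the target.
        w_max = min(p[_seq.C], p[_seq.G]) / (1 - min(p[_seq.C], p[_seq.G]))
        target = min(enr * p_cg, 0.95 * w_max / (1 + 0.95 * w_max))
        # solve w/(1+w) = target - residual chance CG (small); one-step
        # correction is ample at the precision the contract requires
        w = target / (1 - target)
        w = min(w, 0.95 * w_max)
        # residual single-base distribution keeping overall composition
        # each planted unit contributes one C and one G
        p_single = (p * (1 + w) - w * np.array([0, 1.0, 1.0, 0])) / (1 - w)
        p_single = np.clip(p_single, 0, None)
        p_single /= p_single.sum()
        n_units = int(L / (1 + w) * 1.05) + 16
        planted = rng.random(n_units) < w
        singles = rng.choice(4, size=n_units, p=p_single).astype(np.uint8)
        lengths = np.where(planted, 2, 1)
        total = int(lengths.sum())
        while total < L:  # pragma: no cover - overshoot is near certain
            extra = rng.choice(4, size=L, p=p_single).astype(np.uint8)
            singles = np.concatenate([singles, extra])
            planted = np.concatenate([planted, np.zeros(L, bool)])
            lengths = np.where(planted, 2, 1)
            total = int(lengths.sum())
        out = np.empty(total, dtype=np.uint8)
        starts = np.concatenate([[0], np.cumsum(lengths)[:-1]])
        out[starts] = np.where(planted, _seq.C, singles)
        out[starts[planted] + 1] = _seq.G
        return _seq.decode(out[:L])

    # enr < 1: iid draft, then break a fraction (1 - enr) of CG pairs by
    # swapping the G with a random other position (composition preserved)
    codes = rng.choice(4, size=L, p=p).astype(np.uint8)
    cg = np.flatnonzero((codes[:-1] == _seq.C) & (codes[1:] == _seq.G))
    chosen = cg[rng.random(cg.size) < (1.0 - enr)]
    partners = rng.integers(0, L, size=chosen.size)
    for i, j in zip(chosen + 1, partners):
        codes[i], codes[j] = codes[j], codes[i]
    return _seq.decode(codes)


# ---------------------------------------------------------------------------
# truth
# ---------------------------------------------------------------------------

def _draw_alts(rng: np.random.Generator, ref_codes: np.ndarray) -> np.ndarray:
    """Uniform alternate allele different from the reference base."""
    shift = rng.integers(1, 4, size=ref_codes.size)
    return ((ref_codes.astype(np.int64) + shift) % 4).astype(np.uint8)


def generate_truth(reference: str, config: SimulationConfig) -> TruthSet:
    """Draw germline het SNVs, somatic SNVs with truth VAF, and INDELs."""
    if not reference:
        raise ConfigurationError("reference is empty")
    rng = substream(config.seed, "truth")
    codes = _seq.encode(reference)
    L = codes.size
    usable = codes != _seq.N

    taken = np.zeros(L, dtype=bool)

    def _sample_positions(rate: float) -> np.ndarray:
        mask = (rng.random(L) < rate) & usable & ~taken
        taken[mask] = True
        return np.flatnonzero(mask)

    g_idx = _sample_positions(config.germline_het_rate)
    germline = pd.DataFrame({
        "pos": g_idx + 1,
        "ref": [_seq.BASES[c] for c in codes[g_idx]],
        "alt": [_seq.BASES[c] for c in _draw_alts(rng, codes[g_idx])],
        "genotype": "het",
    })

    s_idx = _sample_positions(config.somatic_rate)
    m, k = config.tumor_vaf_mean, config.tumor_vaf_concentration
    if m >= 1.0:
        vafs = np.ones(s_idx.size)
    else:
        vafs = rng.beta(m * k, (1 - m) * k, size=s_idx.size)
        vafs = np.clip(vafs, 1e-3, 1.0)
    somatic = pd.DataFrame({
        "pos": s_idx + 1,
        "ref": [_seq.BASES[c] for c in codes[s_idx]],
        "alt": [_seq.BASES[c] for c in _draw_alts(rng, codes[s_idx])],
        "vaf": vafs,
    })

    i_idx = _sample_positions(config.indel_rate)
    kinds = np.where(rng.random(i_idx.size) < 0.5, "ins", "del")
    seqs = []
    for pos0, kind in zip(i_idx, kinds):
        if kind == "ins":
            size = int(rng.geometric(1.0 / config.mean_insertion_size))
            seqs.append(_seq.decode(
                rng.choice(4, size=size).astype(np.uint8)))
        else:
            size = int(rng.geometric(1.0 / config.mean_deletion_size))
            size = max(1, min(size, L - (pos0 + 1)))
            if pos0 + 1 >= L:  # deletion needs downstream sequence
                size = 0
            seqs.append(reference[pos0 + 1:pos0 + 1 + size] or "N")
    indels = pd.DataFrame({
        "pos": i_idx + 1,
        "kind": pd.array(kinds, dtype="str"),
        "seq": pd.array(seqs, dtype="str"),
        "vaf": 0.5,
    })
    if len(indels):
        indels = indels[indels["seq"].str.len() > 0].reset_index(drop=True)

    return TruthSet(reference=reference, germline=germline, somatic=somatic,
                    indels=indels, cnv_segments=config.cnv_segments)


# ---------------------------------------------------------------------------
# pileups
# ---------------------------------------------------------------------------

def _check_kind(sample_kind: str) -> tuple[bool, bool]:
    if sample_kind not in SAMPLE_KINDS:
        raise ConfigurationError(f"unknown sample_kind {sample_kind!r}")
    is_ffpe = sample_kind.startswith("ffpe")
    is_tumor = sample_kind.endswith("tumor")
    return is_ffpe, is_tumor


def _copy_factor(config: SimulationConfig, L: int) -> np.ndarray:
    """Per-position copy_state/2 (diploid baseline 1.0)."""
    factor = np.ones(L, dtype=np.float64)
    for start, end, copy_state in config.cnv_segments:
        factor[start - 1:end] = copy_state / 2.0
    return factor


def _negbin(rng: np.random.Generator, mean: np.ndarray | float, disp: float,
            size: int) -> np.ndarray:
    """Negative binomial with var = mean + disp * mean^2 (Poisson if disp=0)."""
    mean = np.broadcast_to(np.asarray(mean, dtype=np.float64), (size,))
    if disp <= 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / disp, scale=mean * disp)
    return rng.poisson(lam)


def simulate_pileup(reference: str, truth: TruthSet,
                    config: SimulationConfig, sample_kind: str,
                    ) -> pd.DataFrame:
    """Per-position pileup for one sample of the pair.

    Read bases follow the truth genotype (het 0.5, somatic truth VAF in
    tumor kinds), then sequencing error flips each read base to a
    uniform other base, then — FFPE kinds only — reads showing C at a
    reference C (G at a reference G) are deaminated C->T (G->A) at the
    CpG rate when the 3' neighbour is G (5' neighbour is C), else at the
    non-CpG rate.  Tumor depth scales with the covering CNV segment.
    """
    is_ffpe, is_tumor = _check_kind(sample_kind)
    rng = substream(config.seed, "pileup", sample_kind)
    codes = _seq.encode(reference)
    L = codes.size

    mean_cov = config.mean_coverage_ffpe if is_ffpe else config.mean_coverage_ff
    mean = np.full(L, float(mean_cov))
    if is_tumor:
        mean *= _copy_factor(config, L)
    depth = _negbin(rng, mean, config.coverage_dispersion, L).astype(np.int64)

    # variant allele layer
    p_alt = np.zeros(L, dtype=np.float64)
    alt_code = np.full(L, 255, dtype=np.uint8)
    g_idx = truth.germline["pos"].to_numpy() - 1
    p_alt[g_idx] = 0.5
    alt_code[g_idx] = _seq.encode("".join(truth.germline["alt"]))
    if is_tumor and len(truth.somatic):
        s_idx = truth.somatic["pos"].to_numpy() - 1
        p_alt[s_idx] = truth.somatic["vaf"].to_numpy()
        alt_code[s_idx] = _seq.encode("".join(truth.somatic["alt"]))

    alt_n = rng.binomial(depth, p_alt)
    ref_n = depth - alt_n

    counts = np.zeros((L, 4), dtype=np.int64)
    valid_ref = codes < 4
    idx = np.flatnonzero(valid_ref)
    counts[idx, codes[idx]] += ref_n[idx]
    v = np.flatnonzero(alt_code < 4)
    counts[v, alt_code[v]] += alt_n[v]

    # uniform sequencing error: each read base flips to one of the
    # other three with probability seq_error_rate
    e = config.seq_error_rate
    if e > 0:
        third = np.array([1 / 3, 1 / 3, 1 / 3])
        others = [[b for b in range(4) if b != src] for src in range(4)]
        moved = np.zeros((L, 4), dtype=np.int64)
        for src in range(4):
            err = rng.binomial(counts[:, src], e)
            counts[:, src] -= err
            dist = rng.multinomial(err, third)
            for j, dst in enumerate(others[src]):
                moved[:, dst] += dist[:, j]
        counts += moved

    # FFPE deamination: C->T on reads at reference C, G->A at reference G
    if is_ffpe and (config.deamination_rate_cpg > 0
                    or config.deamination_rate_noncpg > 0):
        nxt = np.concatenate([codes[1:], [_seq.N]])
        prv = np.concatenate([[_seq.N], codes[:-1]])
        rate = np.zeros(L)
        is_c = codes == _seq.C
        is_g = codes == _seq.G
        rate[is_c] = np.where(nxt[is_c] == _seq.G,
                              config.deamination_rate_cpg,
                              config.deamination_rate_noncpg)
        rate[is_g] = np.where(prv[is_g] == _seq.C,
                              config.deamination_rate_cpg,
                              config.deamination_rate_noncpg)
        flips_c = rng.binomial(counts[:, _seq.C], np.where(is_c, rate, 0.0))
        counts[:, _seq.C] -= flips_c
        counts[:, _seq.T] += flips_c
        flips_g = rng.binomial(counts[:, _seq.G], np.where(is_g, rate, 0.0))
        counts[:, _seq.G] -= flips_g
        counts[:, _seq.A] += flips_g

    # INDEL support (independent of deamination by design)
    n_ins = np.zeros(L, dtype=np.int32)
    n_del = np.zeros(L, dtype=np.int32)
    indel_seq = np.full(L, ".", dtype=object)
    if len(truth.indels):
        ii = truth.indels["pos"].to_numpy() - 1
        support = rng.binomial(depth[ii], truth.indels["vaf"].to_numpy())
        ins_mask = (truth.indels["kind"] == "ins").to_numpy()
        n_ins[ii[ins_mask]] = support[ins_mask]
        n_del[ii[~ins_mask]] = support[~ins_mask]
        tags = np.where(ins_mask, "+", "-") + truth.indels["seq"].to_numpy()
        indel_seq[ii] = tags

    mapq_mean = config.mapq_mean_ffpe if is_ffpe else config.mapq_mean_ff
    mapq = np.clip(rng.normal(mapq_mean, config.mapq_sd, size=L), 0.0, 60.0)

    df = pd.DataFrame({
        "chrom": pd.Categorical([config.chrom] * L),
        "pos": np.arange(1, L + 1, dtype=np.int64),
        "ref": pd.Categorical.from_codes(
            codes.astype(np.int8), categories=list(_seq.BASES)),
        "depth": depth.astype(np.int32),
        "nA": counts[:, 0].astype(np.int32),
        "nC": counts[:, 1].astype(np.int32),
        "nG": counts[:, 2].astype(np.int32),
        "nT": counts[:, 3].astype(np.int32),
        "n_ins": n_ins,
        "n_del": n_del,
        "mapq": mapq.astype(np.float32),
        "indel_seq": pd.Categorical(indel_seq),
    })
    return df


# ---------------------------------------------------------------------------
# low-pass counts
# ---------------------------------------------------------------------------

def _bin_edges(L: int, bin_size: int) -> tuple[np.ndarray, np.ndarray]:
    starts = np.arange(1, L + 1, bin_size)
    ends = np.minimum(starts + bin_size - 1, L)
    return starts, ends


def simulate_lowpass_counts(reference: str, truth: TruthSet,
                            config: SimulationConfig, sample_kind: str,
                            ) -> pd.DataFrame:
    """Binned low-pass read-start counts with GC bias.

    Expected bin count = lowpass_mean_coverage * width / read_length,
    scaled by copy_state/2 in tumor kinds and by a linear GC-bias factor
    1 + gc_bias_strength * (gc - 0.5) floored at 0.05.
    """
    is_ffpe, is_tumor = _check_kind(sample_kind)
    L = len(reference)
    if L < config.bin_size:
        raise ConfigurationError("genome shorter than one bin")
    rng = substream(config.seed, "lowpass", sample_kind)
    codes = _seq.encode(reference)
    starts, ends = _bin_edges(L, config.bin_size)
    n_bins = starts.size

    gc_cum = np.concatenate([[0], np.cumsum((codes == _seq.C)
                                            | (codes == _seq.G))])
    widths = ends - starts + 1
    gc = (gc_cum[ends] - gc_cum[starts - 1]) / widths

    expected = config.lowpass_mean_coverage * widths / config.read_length
    if is_tumor:
        factor = _copy_factor(config, L)
        cum = np.concatenate([[0.0], np.cumsum(factor)])
        expected = expected * (cum[ends] - cum[starts - 1]) / widths
    bias = np.maximum(1.0 + config.gc_bias_strength * (gc - 0.5), 0.05)
    expected = expected * bias

    count = _negbin(rng, expected, config.coverage_dispersion, n_bins)
    return pd.DataFrame({
        "chrom": config.chrom,
        "start": starts.astype(np.int64),
        "end": ends.astype(np.int64),
        "gc": gc,
        "count": count.astype(np.int64),
    })


# ---------------------------------------------------------------------------
# array genotypes
# ---------------------------------------------------------------------------

def simulate_array_genotypes(truth: TruthSet, error_rate: float, seed: int,
                             site_fraction: float = 1.0) -> pd.DataFrame:
    """Orthogonal array-style genotype table at germline sites.

    Each emitted genotype equals the truth class ('het') and is
    corrupted to a uniform one of the other two classes with probability
    error_rate.
    """
    if not 0.0 <= error_rate <= 1.0:
        raise ConfigurationError("error_rate outside [0, 1]")
    rng = substream(seed, "array")
    g = truth.germline
    keep = rng.random(len(g)) < site_fraction
    pos = g["pos"].to_numpy()[keep]
    geno = np.full(pos.size, "het", dtype=object)
    corrupt = rng.random(pos.size) < error_rate
    # uniform choice among the two wrong classes
    wrong = np.where(rng.random(pos.size) < 0.5, "ref", "hom")
    geno[corrupt] = wrong[corrupt]
    return pd.DataFrame({"pos": pos, "genotype": geno})


def simulate_pair(config: SimulationConfig, tumor: bool = False,
                  ) -> tuple[TruthSet, pd.DataFrame, pd.DataFrame]:
    """Convenience: one truth, matched FF and FFPE pileups."""
    ref = generate_reference(config)
    truth = generate_truth(ref, config)
    kind = "tumor" if tumor else "normal"
    ff = simulate_pileup(ref, truth, config, f"ff_{kind}")
    fp = simulate_pileup(ref, truth, config, f"ffpe_{kind}")
    return truth, ff, fp
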