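"""Hard-filtered consensus base calling and threshold SNV/INDEL calling.

The caller reproduces a simple, deterministic pileup-based pipeline:
a position is callable when depth >= min_coverage and per-position mean
MAPQ >= min_mapq (defaults 13 and 43; targeted panels use 20x).  The
consensus base is the majority base (exact tie => NO_CALL).  A variant
is emitted when the best non-reference allele fraction strictly exceeds
min_vaf (default 0.2); the genotype class is het below the hom boundary
(default 0.8) and hom_alt at or above it.
"""
from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import _seq
from .io_formats import PileupRecord, VariantCall

logger = logging.getLogger(__name__)


class CallStatus(enum.Enum):
    NO_CALL = "no_call"
    NO_VARIANT = "no_variant"


NO_CALL = CallStatus.NO_CALL
NO_VARIANT = CallStatus.NO_VARIANT

_MODES = {"wgs": 13, "wxs": 13, "tes": 20}


@dataclass(frozen=True)
class FilterConfig:
    """Hard-filter thresholds for callable positions and variant calls."""

    min_coverage: int = 13
    min_mapq: float = 43.0
    min_vaf: float = 0.2       # strict: a call needs vaf > min_vaf
    het_hom_boundary: float = 0.8

    def __post_init__(self) -> None:
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")
        if not 0.0 <= self.min_vaf < self.het_hom_boundary <= 1.0:
            raise ValueError("need 0 <= min_vaf < het_hom_boundary <= 1")

    @classmethod
    def for_mode(cls, mode: str, **kwargs) -> "FilterConfig":
        """WGS/WXS use 13x; TES requires 20 unique reads."""
        try:
            cov = _MODES[mode.lower()]
        except KeyError:
            raise ValueError(f"unknown mode {mode!r}; one of {sorted(_MODES)}")
        return cls(min_coverage=cov, **kwargs)

    def with_(self, **kwargs) -> "FilterConfig":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# scalar (per-record) operations
# ---------------------------------------------------------------------------

def _passes(record: PileupRecord, filt: FilterConfig) -> bool:
    return record.depth >= filt.min_coverage and record.mapq >= filt.min_mapq


def consensus_base_call(record: PileupRecord, filt: FilterConfig):
    """Majority base, or NO_CALL on filter failure or an exact tie."""
    if not _passes(record, filt):
        return NO_CALL
    counts = (record.nA, record.nC, record.nG, record.nT)
    top = max(counts)
    winners = [i for i, c in enumerate(counts) if c == top]
    if len(winners) != 1:
        return NO_CALL
    return _seq.BASES[winners[0]]


def call_snv(record: PileupRecord, filt: FilterConfig):
    """Threshold SNV call: best non-reference allele with vaf > min_vaf."""
    if record.ref == "N":
        logger.warning("skipping position %s:%d with reference N",
                       record.chrom, record.pos)
        return NO_CALL
    if not _passes(record, filt):
        return NO_CALL
    counts = {"A": record.nA, "C": record.nC, "G": record.nG, "T": record.nT}
    # first base in A,C,G,T order wins count ties (matches the table path)
    alt = max((b for b in "ACGT" if b != record.ref),
              key=lambda b: counts[b])
    vaf = counts[alt] / record.depth if record.depth else 0.0
    if vaf <= filt.min_vaf:
        return NO_VARIANT
    genotype = "hom_alt" if vaf >= filt.het_hom_boundary else "het"
    return VariantCall(chrom=record.chrom, pos=record.pos, ref=record.ref,
                       alt=alt, genotype=genotype, vaf=vaf,
                       depth=record.depth, mapq=record.mapq)


def call_indel(record: PileupRecord, filt: FilterConfig):
    """Threshold INDEL call from ins/del support counts.

    The higher-supported event wins; an exact ins/del tie is NO_CALL.
    Event sequence comes from the pileup's truth channel (indel_seq).
    """
    if not _passes(record, filt):
        return NO_CALL
    if record.n_ins == record.n_del == 0:
        return NO_VARIANT
    if record.n_ins == record.n_del:
        return NO_CALL
    kind = "ins" if record.n_ins > record.n_del else "del"
    support = record.n_ins if kind == "ins" else record.n_del
    vaf = support / record.depth if record.depth else 0.0
    if vaf <= filt.min_vaf:
        return NO_VARIANT
    seq = record.indel_seq.lstrip("+-")
    if not seq or seq == ".":
        seq = "N"
    anchor = record.ref
    if kind == "ins":
        ref_allele, alt_allele = anchor, anchor + seq
    else:
        ref_allele, alt_allele = anchor + seq, anchor
    genotype = "hom_alt" if vaf >= filt.het_hom_boundary else "het"
    return VariantCall(chrom=record.chrom, pos=record.pos, ref=ref_allele,
                       alt=alt_allele, genotype=genotype, vaf=vaf,
                       depth=record.depth, mapq=record.mapq)


# ---------------------------------------------------------------------------
# vectorised (table) operations
# ---------------------------------------------------------------------------

def _pass_mask(pileup: pd.DataFrame, filt: FilterConfig) -> np.ndarray:
    return ((pileup["depth"].to_numpy() >= filt.min_coverage)
            & (pileup["mapq"].to_numpy() >= filt.min_mapq))


def _count_matrix(pileup: pd.DataFrame) -> np.ndarray:
    return pileup[["nA", "nC", "nG", "nT"]].to_numpy()


def _ref_codes(pileup: pd.DataFrame) -> np.ndarray:
    ref = pileup["ref"]
    if isinstance(ref.dtype, pd.CategoricalDtype):
        cats = _seq.encode("".join(ref.cat.categories))
        return cats[ref.cat.codes.to_numpy()]
    return _seq.encode("".join(ref.astype(str)))


def consensus_base_calls(pileup: pd.DataFrame, filt: FilterConfig,
                         ) -> pd.Series:
    """Consensus base per position as a Series pos -> base code (0..3).

    NO_CALL positions are absent from the result.  Codes follow
    ``ffpe_concord._seq.BASES``.
    """
    counts = _count_matrix(pileup)
    top = counts.max(axis=1)
    winner = counts.argmax(axis=1)
    tie = (counts == top[:, None]).sum(axis=1) != 1
    ok = _pass_mask(pileup, filt) & ~tie
    pos = pileup["pos"].to_numpy()[ok]
    if np.unique(pos).size != pos.size:
        raise ValueError("duplicated positions in pileup")
    return pd.Series(winner[ok].astype(np.int8), index=pos, name="call")


def call_snv_table(pileup: pd.DataFrame, filt: FilterConfig) -> pd.DataFrame:
    """All SNV calls from a pileup table (variant rows only)."""
    counts = _count_matrix(pileup).copy()
    ref = _ref_codes(pileup)
    valid = ref < 4
    if not valid.all():
        logger.warning("skipping %d positions with reference N",
                       int((~valid).sum()))
    rows = np.arange(len(pileup))
    counts[rows[valid], ref[valid]] = -1  # mask the reference column
    alt = counts.argmax(axis=1)
    alt_n = counts[rows, alt]
    depth = pileup["depth"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        vaf = np.where(depth > 0, alt_n / np.maximum(depth, 1), 0.0)
    called = _pass_mask(pileup, filt) & valid & (vaf > filt.min_vaf)
    idx = np.flatnonzero(called)
    out = pd.DataFrame({
        "chrom": np.asarray(pileup["chrom"])[idx],
        "pos": pileup["pos"].to_numpy()[idx],
        "ref": np.array(list(_seq.BASES))[ref[idx]],
        "alt": np.array(list(_seq.BASES))[alt[idx]],
        "genotype": np.where(vaf[idx] >= filt.het_hom_boundary,
                             "hom_alt", "het"),
        "vaf": vaf[idx],
        "depth": depth[idx],
        "mapq": pileup["mapq"].to_numpy()[idx].astype(float),
    })
    return out


def call_indel_table(pileup: pd.DataFrame, filt: FilterConfig) -> pd.DataFrame:
    """All INDEL calls from a pileup table."""
    sub = pileup[(pileup["n_ins"] > 0) | (pileup["n_del"] > 0)]
    calls = []
    for row in sub.itertuples(index=False):
        rec = PileupRecord(chrom=str(row.chrom), pos=int(row.pos),
                           ref=str(row.ref), depth=int(row.depth),
                           nA=int(row.nA), nC=int(row.nC), nG=int(row.nG),
                           nT=int(row.nT), n_ins=int(row.n_ins),
                           n_del=int(row.n_del), mapq=float(row.mapq),
                           indel_seq=str(row.indel_seq))
        call = call_indel(rec, filt)
        if isinstance(call, VariantCall):
            calls.append(call)
    from .io_formats import calls_to_frame
    return calls_to_frame(calls)


def genotype_classes(pileup: pd.DataFrame, filt: FilterConfig) -> pd.Series:
    """Genotype class per callable position: 'ref' | 'het' | 'hom'.

    Derived from the SNV caller (NO_VARIANT => 'ref'); used for the
    comparison against array genotypes.
    """
    counts = _count_matrix(pileup).copy()
    ref = _ref_codes(pileup)
    valid = ref < 4
    rows = np.arange(len(pileup))
    counts[rows[valid], ref[valid]] = -1
    alt_n = counts[rows, counts.argmax(axis=1)]
    depth = pileup["depth"].to_numpy()
    vaf = np.where(depth > 0, alt_n / np.maximum(depth, 1), 0.0)
    ok = _pass_mask(pileup, filt) & valid
    cls = np.where(vaf > filt.min_vaf,
                   np.where(vaf >= filt.het_hom_boundary, "hom", "het"),
                   "ref")
    return pd.Series(cls[ok], index=pileup["pos"].to_numpy()[ok],
                     name="genotype")
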