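"""On-disk formats: FASTA, VCF, BED, pileup TSV, genotype and bin tables.

Conventions
-----------
* Internal coordinates are 1-based inclusive everywhere (VCF style).
* BED files are 0-based half-open on disk; conversion happens here and
  only here.
* The pileup dialect is tab-separated with header
  ``chrom pos ref depth nA nC nG nT n_ins n_del mapq [indel_seq]``;
  the optional last column carries the INDEL event sequence ("." none,
  "+SEQ" insertion, "-SEQ" deletion).
* Readers reject malformed input instead of coercing it.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """Malformed or invalid on-disk data."""


class PileupRecord(NamedTuple):
    chrom: str
    pos: int
    ref: str
    depth: int
    nA: int
    nC: int
    nG: int
    nT: int
    n_ins: int
    n_del: int
    mapq: float
    indel_seq: str = "."


@dataclass(frozen=True)
class VariantCall:
    chrom: str
    pos: int
    ref: str
    alt: str
    genotype: str  # 'het' | 'hom_alt'
    vaf: float
    depth: int
    mapq: float

    def __post_init__(self) -> None:
        if self.alt == self.ref:
            raise FormatError(f"alt equals ref at {self.chrom}:{self.pos}")
        if not 0.0 <= self.vaf <= 1.0:
            raise FormatError(f"vaf {self.vaf} outside [0,1]")
        if self.depth < 1:
            raise FormatError(f"depth {self.depth} < 1")

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)


PILEUP_HEADER = ["chrom", "pos", "ref", "depth", "nA", "nC", "nG", "nT",
                 "n_ins", "n_del", "mapq"]


# ---------------------------------------------------------------------------
# pileup TSV
# ---------------------------------------------------------------------------

def write_pileup(records, path) -> None:
    """Write pileups (DataFrame or iterable of PileupRecord) as TSV."""
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(
        records, columns=PILEUP_HEADER + ["indel_seq"])
    cols = PILEUP_HEADER + (["indel_seq"] if "indel_seq" in df.columns else [])
    df.to_csv(path, sep="\t", index=False, columns=cols,
              float_format="%.4f")


def read_pileup(path, as_records: bool = False):
    """Read the pileup dialect; returns a DataFrame (or PileupRecord list)."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if header[:11] != PILEUP_HEADER:
        raise FormatError(f"{path}: unexpected pileup header {header!r}")
    has_seq = len(header) == 12 and header[11] == "indel_seq"
    if len(header) > 11 and not has_seq:
        raise FormatError(f"{path}: unexpected trailing columns {header[11:]}")
    dtypes = {"chrom": str, "pos": np.int64, "ref": str, "depth": np.int64,
              "nA": np.int64, "nC": np.int64, "nG": np.int64, "nT": np.int64,
              "n_ins": np.int64, "n_del": np.int64, "mapq": float}
    if has_seq:
        dtypes["indel_seq"] = str
    try:
        df = pd.read_csv(path, sep="\t", dtype=dtypes)
    except (ValueError, pd.errors.ParserError) as exc:
        raise FormatError(f"{path}: malformed pileup row ({exc})") from exc
    if not has_seq:
        df["indel_seq"] = "."
    _validate_pileup(df, path)
    if as_records:
        return [PileupRecord(**row) for row in df.to_dict("records")]
    return df


def _validate_pileup(df: pd.DataFrame, path) -> None:
    counts = df[["depth", "nA", "nC", "nG", "nT", "n_ins", "n_del"]]
    bad = (counts < 0).any(axis=1)
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
        raise FormatError(f"{path}: negative count at line {line}")
    if not df["ref"].isin(list("ACGTN")).all():
        raise FormatError(f"{path}: invalid reference base")
    sums = df[["nA", "nC", "nG", "nT"]].sum(axis=1)
    if (sums > df["depth"]).any():
        line = int(np.flatnonzero((sums > df["depth"]).to_numpy())[0]) + 2
        raise FormatError(f"{path}: base counts exceed depth at line {line}")
    if ((df["mapq"] < 0) | (df["mapq"] > 60)).any():
        raise FormatError(f"{path}: mapq outside [0, 60]")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=ffpe-concord
##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##INFO=<ID=MQ,Number=1,Type=Float,Description="Mean mapping quality">
##INFO=<ID=AF,Number=A,Type=Float,Description="Variant allele fraction">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_vcf(calls: Iterable[VariantCall], path, sample: str = "sample",
              contigs: dict[str, int] | None = None) -> None:
    calls = list(calls)
    if contigs is None:
        contigs = {}
        for c in calls:
            contigs[c.chrom] = max(contigs.get(c.chrom, 0), c.pos + 1000)
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{sample}\n")
        for c in sorted(calls, key=lambda v: (v.chrom, v.pos, v.alt)):
            gt = "0/1" if c.genotype == "het" else "1/1"
            info = f"DP={c.depth};MQ={c.mapq:.2f};AF={c.vaf:.6f}"
            fh.write(f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t.\tPASS\t"
                     f"{info}\tGT\t{gt}\n")


def read_vcf(path) -> list[VariantCall]:
    """Read a single-sample VCF; multi-allelic records are split."""
    from cyvcf2 import VCF

    out: list[VariantCall] = []
    vcf = VCF(str(path))
    for rec in vcf:
        dp = rec.INFO.get("DP")
        if dp is None:
            raise FormatError(f"{path}: missing DP at {rec.CHROM}:{rec.POS}")
        mq = rec.INFO.get("MQ")
        af = rec.INFO.get("AF")
        alts = rec.ALT
        afs = (list(af) if isinstance(af, tuple) else [af] * len(alts))
        # genotype class from GT when present, else from AF
        if len(rec.genotypes):
            g = rec.genotypes[0]
            genotype = "hom_alt" if g[0] == g[1] == 1 or (
                len(alts) > 1 and g[0] >= 1 and g[1] >= 1) else "het"
        else:  # pragma: no cover - our writer always emits GT
            genotype = "het"
        for alt, vaf in zip(alts, afs):
            # floats come back as float32; round to the written precision
            out.append(VariantCall(
                chrom=rec.CHROM, pos=rec.POS, ref=rec.REF, alt=alt,
                genotype=genotype,
                vaf=round(float(vaf if vaf is not None else 0.5), 6),
                depth=int(dp),
                mapq=round(float(mq if mq is not None else 60.0), 2)))
    vcf.close()
    return out


def calls_to_frame(calls: Iterable[VariantCall]) -> pd.DataFrame:
    rows = [(c.chrom, c.pos, c.ref, c.alt, c.genotype, c.vaf, c.depth, c.mapq)
            for c in calls]
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                       "genotype", "vaf", "depth", "mapq"])


def frame_to_calls(df: pd.DataFrame) -> list[VariantCall]:
    return [VariantCall(chrom=str(r.chrom), pos=int(r.pos), ref=str(r.ref),
                        alt=str(r.alt), genotype=str(r.genotype),
                        vaf=float(r.vaf), depth=int(r.depth),
                        mapq=float(r.mapq))
            for r in df.itertuples(index=False)]


# ---------------------------------------------------------------------------
# BED and BED-like
# ---------------------------------------------------------------------------

def read_bed(path) -> pd.DataFrame:
    """Read 0-based half-open BED into 1-based inclusive intervals."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED fields")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start < 0:
                raise FormatError(f"{path}:{lineno}: negative start")
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end")
            rows.append((chrom, start + 1, end, fields[3:]))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "extra"])


def write_bed(intervals: pd.DataFrame, path) -> None:
    """Write 1-based inclusive intervals as 0-based half-open BED."""
    with open(path, "w") as fh:
        for r in intervals.itertuples(index=False):
            extra = getattr(r, "extra", None) or []
            fields = [str(r.chrom), str(int(r.start) - 1), str(int(r.end))]
            fields += [str(x) for x in extra]
            fh.write("\t".join(fields) + "\n")


def write_segments_bed(segments, path, chrom: str = "chr1") -> None:
    """(start, end, copy_state) tuples, 1-based inclusive, to BED-like."""
    df = pd.DataFrame(
        [(chrom, s, e, [c]) for s, e, c in segments],
        columns=["chrom", "start", "end", "extra"])
    write_bed(df, path)


def read_segments_bed(path) -> list[tuple[int, int, int]]:
    df = read_bed(path)
    return [(int(r.start), int(r.end), int(r.extra[0]))
            for r in df.itertuples(index=False)]


# ---------------------------------------------------------------------------
# bin counts (BED-like with gc and count)
# ---------------------------------------------------------------------------

def write_bin_counts(bins: pd.DataFrame, path) -> None:
    out = bins.copy()
    out["start"] = out["start"] - 1  # to 0-based half-open
    out.to_csv(path, sep="\t", index=False,
               columns=["chrom", "start", "end", "gc", "count"],
               float_format="%.6f")


def read_bin_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t",
                     dtype={"chrom": str, "start": np.int64, "end": np.int64,
                            "gc": float, "count": np.int64})
    if (df["count"] < 0).any():
        raise FormatError(f"{path}: negative bin count")
    if (df["start"] >= df["end"]).any():
        raise FormatError(f"{path}: start >= end in bin table")
    df["start"] = df["start"] + 1
    return df


# ---------------------------------------------------------------------------
# genotype table
# ---------------------------------------------------------------------------

def write_genotype_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, columns=["pos", "genotype"])


def read_genotype_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"pos": np.int64, "genotype": str})
    valid = {"ref", "het", "hom"}
    if not set(df["genotype"]) <= valid:
        bad = sorted(set(df["genotype"]) - valid)
        raise FormatError(f"{path}: invalid genotype classes {bad}")
    return df
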