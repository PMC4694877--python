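"""Germline subtraction, paired somatic overlap, recurrence filtering.

Somatic calls are tumor variants whose (chrom, pos, alt) key is absent
from the matched normal: subtraction is allele-aware, so a tumor call
at a position where the normal carries a *different* alternate allele
is retained.  The paired overlap accounting mirrors a tumor/normal
quad design: the same tumor sequenced from FF and FFPE tissue, each
with its own matched normal.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_KEY = ["chrom", "pos"]
_AKEY = ["chrom", "pos", "alt"]


@dataclass
class SomaticOverlap:
    n_normal: int
    n_tumor: int
    n_same_positions: int
    n_concordant_nt: int
    n_somatic: int
    n_overlap_pair: int | None = None
    n_concordant_pair: int | None = None
    n_discordant_pair: int | None = None

    def __post_init__(self) -> None:
        if self.n_somatic > self.n_tumor:
            raise ValueError("somatic count exceeds tumor count")
        if self.n_concordant_nt > self.n_same_positions:
            raise ValueError("concordant exceeds shared positions")
        if self.n_overlap_pair is not None:
            if (self.n_concordant_pair + self.n_discordant_pair
                    != self.n_overlap_pair):
                raise ValueError("pair counts inconsistent")


def subtract_germline(tumor_variants: pd.DataFrame,
                      normal_variants: pd.DataFrame) -> pd.DataFrame:
    """Tumor variants whose (pos, alt) pair is absent from the normal."""
    if len(normal_variants) == 0:
        return tumor_variants.copy()
    normal_keys = set(map(tuple, normal_variants[_AKEY].to_numpy()))
    keep = np.fromiter((tuple(k) not in normal_keys
                        for k in tumor_variants[_AKEY].to_numpy()),
                       dtype=bool, count=len(tumor_variants))
    return tumor_variants[keep].reset_index(drop=True)


def normal_tumor_overlap(normal_variants: pd.DataFrame,
                         tumor_variants: pd.DataFrame) -> SomaticOverlap:
    """Normal/tumor accounting for one sample: shared positions,
    concordant alleles, and the somatic remainder."""
    merged = normal_variants[_AKEY].merge(
        tumor_variants[_AKEY], on=_KEY, how="inner",
        suffixes=("_n", "_t"))
    n_same = merged[_KEY].drop_duplicates().shape[0]
    n_conc = int((merged["alt_n"] == merged["alt_t"]).sum())
    somatic = subtract_germline(tumor_variants, normal_variants)
    return SomaticOverlap(
        n_normal=len(normal_variants), n_tumor=len(tumor_variants),
        n_same_positions=n_same, n_concordant_nt=n_conc,
        n_somatic=len(somatic))


def paired_somatic_overlap(ff_somatic: pd.DataFrame,
                           ffpe_somatic: pd.DataFrame,
                           ) -> tuple[int, int, int]:
    """(n_overlap, n_concordant, n_discordant) between two somatic sets.

    Overlap is on position; concordant means equal alternate alleles.
    """
    merged = ff_somatic[_AKEY].merge(ffpe_somatic[_AKEY], on=_KEY,
                                     how="inner", suffixes=("_ff", "_ffpe"))
    merged = merged.drop_duplicates(subset=_KEY)
    n_overlap = len(merged)
    n_conc = int((merged["alt_ff"] == merged["alt_ffpe"]).sum())
    return n_overlap, n_conc, n_overlap - n_conc


def recurrence_table(somatic_sets_by_sample: dict[str, pd.DataFrame],
                     annotation_table: pd.DataFrame,
                     normal_sets: list[pd.DataFrame] | None = None,
                     min_samples: int = 2, max_popfreq: float = 0.10,
                     drop_synonymous: bool = True) -> pd.DataFrame:
    """Variants recurring across samples after annotation-based filtering.

    A variant survives when it is (i) not synonymous (if requested),
    (ii) absent from every supplied normal call set, and (iii) at
    population frequency <= max_popfreq (strictly-more-common variants
    are dropped, so a variant at exactly the boundary is kept).
    Variants lacking an annotation row are dropped with a logged count.
    Rows are sorted by carrier count (descending) then gene name.
    """
    required = {"chrom", "pos", "alt", "gene", "consequence", "popfreq"}
    missing = required - set(annotation_table.columns)
    if missing:
        raise ValueError(f"annotation table missing columns {sorted(missing)}")
    if annotation_table["popfreq"].isna().any():
        raise ValueError("annotation table has missing popfreq values")

    normal_keys: set[tuple] = set()
    for n in normal_sets or []:
        normal_keys |= set(map(tuple, n[_AKEY].to_numpy()))

    carriers: dict[tuple, set[str]] = {}
    n_unannotated = 0
    annot = annotation_table.set_index(_AKEY)
    for sample, variants in somatic_sets_by_sample.items():
        for key in map(tuple, variants[_AKEY].to_numpy()):
            if key not in annot.index:
                n_unannotated += 1
                continue
            carriers.setdefault(key, set()).add(sample)
    if n_unannotated:
        logger.warning("%d variant observations lacked annotation; dropped",
                       n_unannotated)

    rows = []
    for key, samples in carriers.items():
        if len(samples) < min_samples:
            continue
        if key in normal_keys:
            continue
        info = annot.loc[key]
        if isinstance(info, pd.DataFrame):
            raise ValueError(f"duplicate annotation rows for {key}")
        if drop_synonymous and info["consequence"] == "synonymous":
            continue
        if info["popfreq"] > max_popfreq:
            continue
        rows.append((key[0], key[1], key[2], info["gene"],
                     info["consequence"], float(info["popfreq"]),
                     len(samples), ",".join(sorted(samples))))
    out = pd.DataFrame(rows, columns=["chrom", "pos", "alt", "gene",
                                      "consequence", "popfreq", "count",
                                      "samples"])
    return out.sort_values(["count", "gene"], ascending=[False, True],
                           kind="stable").reset_index(drop=True)
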