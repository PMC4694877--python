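"""Matched-pair concordance classification.

Base level: positions with a consensus call in both samples are
concordant when the bases agree, discordant otherwise.  Variant level:
positions called variant in both samples are concordant when the
alternate alleles agree (genotype class ignored); positions called only
in FFPE are false positives, only in FF false negatives — FF is the
reference sample by convention.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ConcordanceTable:
    n_intersect: int
    n_concordant: int
    n_discordant: int
    n_false_positive: int | None = None
    n_false_negative: int | None = None
    n_not_assessed: int = 0
    detail: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.n_concordant + self.n_discordant != self.n_intersect:
            raise ValueError("concordant + discordant != intersect")
        counts = [self.n_intersect, self.n_concordant, self.n_discordant]
        if any(c < 0 for c in counts):
            raise ValueError("negative count")

    @property
    def concordance_rate(self) -> float:
        if self.n_intersect == 0:
            return float("nan")
        return self.n_concordant / self.n_intersect

    def to_frame(self) -> pd.DataFrame:
        rows = [("n_intersect", self.n_intersect),
                ("n_concordant", self.n_concordant),
                ("n_discordant", self.n_discordant),
                ("concordance_rate", self.concordance_rate)]
        if self.n_false_positive is not None:
            rows.append(("n_false_positive", self.n_false_positive))
        if self.n_false_negative is not None:
            rows.append(("n_false_negative", self.n_false_negative))
        if self.n_not_assessed:
            rows.append(("n_not_assessed", self.n_not_assessed))
        return pd.DataFrame(rows, columns=["metric", "value"])


def _region_mask(pos: np.ndarray, regions) -> np.ndarray:
    """Membership of 1-based positions in a list of (start, end) intervals."""
    if regions is None:
        return np.ones(pos.size, dtype=bool)
    mask = np.zeros(pos.size, dtype=bool)
    for interval in regions:
        start, end = int(interval[0]), int(interval[1])
        mask |= (pos >= start) & (pos <= end)
    return mask


def _check_unique(pos: np.ndarray, label: str) -> None:
    if np.unique(pos).size != pos.size:
        raise ValueError(f"duplicated positions in {label} input")


def classify_base_calls(ff_calls: pd.Series, ffpe_calls: pd.Series,
                        regions=None) -> ConcordanceTable:
    """Base-level concordance between two position -> base maps.

    Inputs are Series indexed by position (as produced by
    ``consensus_base_calls``; values may be base codes or letters).
    The ``detail`` frame carries the discordant positions only, with the
    two calls, so that artifact spectra can be computed over them.
    """
    if isinstance(ff_calls, dict):
        ff_calls = pd.Series(ff_calls)
    if isinstance(ffpe_calls, dict):
        ffpe_calls = pd.Series(ffpe_calls)
    _check_unique(ff_calls.index.to_numpy(), "FF")
    _check_unique(ffpe_calls.index.to_numpy(), "FFPE")

    # intersect on position via sorted alignment
    common = ff_calls.index.intersection(ffpe_calls.index)
    a = ff_calls.loc[common].to_numpy()
    b = ffpe_calls.loc[common].to_numpy()
    keep = _region_mask(common.to_numpy(), regions)
    a, b = a[keep], b[keep]
    pos = common.to_numpy()[keep]
    agree = a == b
    detail = pd.DataFrame({"pos": pos[~agree], "ff_call": a[~agree],
                           "ffpe_call": b[~agree]})
    n = int(agree.size)
    n_conc = int(agree.sum())
    return ConcordanceTable(n_intersect=n, n_concordant=n_conc,
                            n_discordant=n - n_conc, detail=detail)


def classify_variants(ff_variants: pd.DataFrame, ffpe_variants: pd.DataFrame,
                      regions=None) -> ConcordanceTable:
    """Variant-level classification keyed by (chrom, pos).

    ``detail`` has one row per union position: pos, class in
    {concordant, discordant, false_positive, false_negative}, and both
    sides' alleles where called.
    """
    key = ["chrom", "pos"]
    ff = ff_variants[key + ["ref", "alt", "vaf"]].copy()
    fp = ffpe_variants[key + ["ref", "alt", "vaf"]].copy()
    for df, label in ((ff, "FF"), (fp, "FFPE")):
        if df.duplicated(subset=key).any():
            raise ValueError(f"duplicated positions in {label} variants")
    merged = ff.merge(fp, on=key, how="outer", suffixes=("_ff", "_ffpe"))
    if regions is not None:
        merged = merged[_region_mask(merged["pos"].to_numpy(), regions)]
    in_ff = merged["alt_ff"].notna()
    in_fp = merged["alt_ffpe"].notna()
    cls = np.where(in_ff & in_fp,
                   np.where(merged["alt_ff"] == merged["alt_ffpe"],
                            "concordant", "discordant"),
                   np.where(in_fp, "false_positive", "false_negative"))
    merged = merged.assign(cls=cls)
    n_conc = int((cls == "concordant").sum())
    n_disc = int((cls == "discordant").sum())
    return ConcordanceTable(
        n_intersect=n_conc + n_disc,
        n_concordant=n_conc,
        n_discordant=n_disc,
        n_false_positive=int((cls == "false_positive").sum()),
        n_false_negative=int((cls == "false_negative").sum()),
        detail=merged,
    )


def compare_to_array(seq_classes: pd.Series, array_genotypes: pd.DataFrame,
                     ) -> ConcordanceTable:
    """Sequencing genotype classes vs an orthogonal array table.

    ``seq_classes`` maps position -> {'ref','het','hom'} at callable
    positions (see ``calling.genotype_classes``).  Array sites without a
    sequencing call are excluded and counted as n_not_assessed.
    """
    arr = array_genotypes.set_index("pos")["genotype"]
    if arr.index.duplicated().any():
        raise ValueError("duplicated positions in array table")
    common = arr.index.intersection(seq_classes.index)
    n_not = int(len(arr) - len(common))
    a = seq_classes.loc[common].to_numpy()
    b = arr.loc[common].to_numpy()
    agree = a == b
    n = int(agree.size)
    n_conc = int(agree.sum())
    detail = pd.DataFrame({"pos": common.to_numpy(), "seq": a, "array": b})
    return ConcordanceTable(n_intersect=n, n_concordant=n_conc,
                            n_discordant=n - n_conc, n_not_assessed=n_not,
                            detail=detail)
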