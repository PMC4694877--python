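"""Sensitivity of pair concordance to coverage, MAPQ and VAF thresholds.

One-dimensional sweeps: one threshold varies over a grid while the
other filter fields stay fixed; calls and the pair classification are
recomputed at every grid value.  Also provides the coverage comparison
between agreeing and disagreeing positions that motivates a minimum
coverage filter: calls lost or gained between the members of a pair
concentrate where depth is low.
"""
from __future__ import annotations

import logging
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .calling import FilterConfig, call_snv_table
from .concordance import classify_variants

logger = logging.getLogger(__name__)

SWEEP_COLUMNS = ["threshold_name", "threshold_value", "n_intersect",
                 "n_concordant", "n_discordant", "n_false_positive",
                 "n_false_negative"]


def _classify_at(ff_pileup: pd.DataFrame, ffpe_pileup: pd.DataFrame,
                 filt: FilterConfig):
    ff = call_snv_table(ff_pileup, filt)
    fp = call_snv_table(ffpe_pileup, filt)
    return classify_variants(ff, fp)


def coverage_mapq_sweep(ff_pileup: pd.DataFrame, ffpe_pileup: pd.DataFrame,
                        coverage_grid=(), mapq_grid=(), vaf_grid=(),
                        filt: FilterConfig | None = None) -> pd.DataFrame:
    """Recompute the pair classification along threshold grids.

    Each grid is swept independently with the other FilterConfig fields
    held at ``filt``'s values.  Grids must be non-empty-able ascending
    sequences; at least one grid must be given.
    """
    filt = filt or FilterConfig()
    grids = [("coverage", coverage_grid), ("mapq", mapq_grid),
             ("vaf", vaf_grid)]
    if all(len(g) == 0 for _, g in grids):
        raise ValueError("no sweep grid given")
    rows = []
    for name, grid in grids:
        values = list(grid)
        if values != sorted(values):
            raise ValueError(f"{name} grid must be ascending")
        for value in values:
            if name == "coverage":
                f = filt.with_(min_coverage=int(value))
            elif name == "mapq":
                f = filt.with_(min_mapq=float(value))
            else:
                f = filt.with_(min_vaf=float(value))
            table = _classify_at(ff_pileup, ffpe_pileup, f)
            rows.append((name, value, table.n_intersect, table.n_concordant,
                         table.n_discordant, table.n_false_positive,
                         table.n_false_negative))
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


def intersect_positions(ff_pileup: pd.DataFrame, ffpe_pileup: pd.DataFrame,
                        filt: FilterConfig) -> np.ndarray:
    """Positions callable (depth/MAPQ pass) in both samples."""
    from .calling import _pass_mask
    a = ff_pileup["pos"].to_numpy()[_pass_mask(ff_pileup, filt)]
    b = ffpe_pileup["pos"].to_numpy()[_pass_mask(ffpe_pileup, filt)]
    return np.intersect1d(a, b)


class CoverageComparison(NamedTuple):
    mean_disagree: float
    mean_concordant: float
    n_disagree: int
    n_concordant: int
    t: float
    p_one_sided: float


def coverage_by_agreement(ff_pileup: pd.DataFrame, ffpe_pileup: pd.DataFrame,
                          filt: FilterConfig | None = None,
                          ) -> CoverageComparison:
    """Mean pair coverage at disagreeing vs concordant variant positions.

    Disagreement pools discordant, false-positive and false-negative
    classes — the calls that differ between the members of a pair.  The
    one-sided Welch t-test is for mean(disagree) < mean(concordant).
    """
    filt = filt or FilterConfig()
    table = _classify_at(ff_pileup, ffpe_pileup, filt)
    detail = table.detail
    depth = (ff_pileup.set_index("pos")["depth"].astype(float)
             + ffpe_pileup.set_index("pos")["depth"].astype(float)) / 2.0
    pos = detail["pos"].to_numpy()
    cov = depth.reindex(pos).to_numpy()
    agree = (detail["cls"] == "concordant").to_numpy()
    cov_dis, cov_con = cov[~agree], cov[agree]
    cov_dis = cov_dis[~np.isnan(cov_dis)]
    cov_con = cov_con[~np.isnan(cov_con)]
    if len(cov_dis) < 2 or len(cov_con) < 2:
        raise ValueError("too few positions in one class for the comparison")
    res = stats.ttest_ind(cov_dis, cov_con, equal_var=False,
                          alternative="less")
    return CoverageComparison(
        mean_disagree=float(cov_dis.mean()),
        mean_concordant=float(cov_con.mean()),
        n_disagree=int(cov_dis.size), n_concordant=int(cov_con.size),
        t=float(res.statistic), p_one_sided=float(res.pvalue))


def vaf_relationship(ff_variants: pd.DataFrame, ffpe_variants: pd.DataFrame,
                     classification, ff_pileup: pd.DataFrame,
                     ffpe_pileup: pd.DataFrame) -> pd.DataFrame:
    """Per-position (vaf_ff, vaf_ffpe, class) over the union of call sets.

    For the side without a call the VAF is recomputed from that sample's
    pileup (0 when no read supports the other side's alternate allele),
    so false positives/negatives carry both VAFs.  Positions absent from
    both pileups are dropped with a warning.
    """
    detail = classification.detail
    if detail is None or "cls" not in detail.columns:
        raise ValueError("classification must come from classify_variants")
    base_cols = {"A": "nA", "C": "nC", "G": "nG", "T": "nT"}
    ff_by_pos = ff_pileup.set_index("pos")
    fp_by_pos = ffpe_pileup.set_index("pos")

    def _vaf_from_pileup(table: pd.DataFrame, pos: int, alt: str) -> float:
        if pos not in table.index:
            return float("nan")
        row = table.loc[pos]
        depth = int(row["depth"])
        if depth == 0:
            return 0.0
        return float(row[base_cols[alt]]) / depth

    rows = []
    for r in detail.itertuples(index=False):
        alt = r.alt_ff if isinstance(r.alt_ff, str) else r.alt_ffpe
        vaf_ff = (r.vaf_ff if isinstance(r.alt_ff, str)
                  else _vaf_from_pileup(ff_by_pos, r.pos, alt))
        vaf_fp = (r.vaf_ffpe if isinstance(r.alt_ffpe, str)
                  else _vaf_from_pileup(fp_by_pos, r.pos, alt))
        if np.isnan(vaf_ff) and np.isnan(vaf_fp):
            logger.warning("position %d absent from both pileups; dropped",
                           r.pos)
            continue
        rows.append((r.pos, vaf_ff, vaf_fp, r.cls))
    return pd.DataFrame(rows, columns=["pos", "vaf_ff", "vaf_ffpe", "class"])
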