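"""FFPE artifact signatures: substitution spectra, context C>T rates,
global mismatch rate, and the study's statistical comparisons.

Substitutions are collapsed onto the reference pyrimidine strand: a
G>A change is counted as C>T on the complement, so the six classes are
C>T, C>A, C>G, T>C, T>A, T>G (written C·G>T·A etc. in the two-strand
notation).  Cytosine deamination artifacts appear as an excess of the
C>T class, concentrated at CpG dinucleotides.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from . import _seq
from .calling import FilterConfig, _pass_mask, _ref_codes, _count_matrix

CLASSES = ("C>T", "C>A", "C>G", "T>C", "T>A", "T>G")
TRANSITIONS = {"C>T", "T>C"}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def collapse_substitution(ref: str, alt: str) -> str:
    """Map a substitution to its pyrimidine-strand class."""
    if ref in "AG":
        ref, alt = _COMP[ref], _COMP[alt]
    key = f"{ref}>{alt}"
    if key not in CLASSES:
        raise ValueError(f"not a substitution: {ref}>{alt}")
    return key


@dataclass
class SpectrumResult:
    class_counts: dict[str, int]
    n_snvs: int
    ct_rate_all: float | None
    tstv: float | None
    ct_rate_discordant: float | None = None
    global_mismatch_rate: float | None = None
    cpn_rates: dict[str, float] | None = None
    npc_rates: dict[str, float] | None = None


def substitution_spectrum(variants: pd.DataFrame, reference: str,
                          ) -> SpectrumResult:
    """Collapsed 6-class spectrum, C·G>T·A rate and Ts/Tv over SNVs.

    Every variant's reference allele must match the supplied reference.
    """
    counts = dict.fromkeys(CLASSES, 0)
    snvs = variants[(variants["ref"].str.len() == 1)
                    & (variants["alt"].str.len() == 1)]
    for row in snvs.itertuples(index=False):
        ref_base = reference[row.pos - 1] if row.pos - 1 < len(reference) else None
        if ref_base != row.ref:
            raise ValueError(
                f"reference mismatch at pos {row.pos}: "
                f"variant says {row.ref}, reference has {ref_base}")
        counts[collapse_substitution(row.ref, row.alt)] += 1
    n = int(sum(counts.values()))
    ts = sum(counts[c] for c in CLASSES if c in TRANSITIONS)
    tv = n - ts
    return SpectrumResult(
        class_counts=counts,
        n_snvs=n,
        ct_rate_all=(counts["C>T"] / n) if n else None,
        tstv=(ts / tv) if tv else None,
    )


class DiscordantCtRates(NamedTuple):
    ffpe_rate: float
    ff_rate: float
    n_discordant: int


def _is_ct_side(ref_bases: np.ndarray, calls: np.ndarray) -> np.ndarray:
    """True where call vs reference is a C·G>T·A substitution."""
    return ((ref_bases == "C") & (calls == "T")) | \
           ((ref_bases == "G") & (calls == "A"))


def discordant_ct_rate(detail: pd.DataFrame, reference: str,
                       ) -> DiscordantCtRates | None:
    """Fraction of discordant positions whose call is C·G>T·A vs reference.

    ``detail`` is the per-position detail of either classify_base_calls
    (columns pos, ff_call, ffpe_call; discordant rows) or
    classify_variants (columns pos, cls, alt_ff, alt_ffpe).  Returns
    None when there are no discordant positions (a missing value, not
    zero).
    """
    if "cls" in detail.columns:
        disc = detail[detail["cls"] == "discordant"]
        ff_call = disc["alt_ff"].to_numpy(dtype=object)
        ffpe_call = disc["alt_ffpe"].to_numpy(dtype=object)
        pos = disc["pos"].to_numpy()
    else:
        disc = detail
        pos = disc["pos"].to_numpy()
        ff_call, ffpe_call = (disc["ff_call"].to_numpy(),
                              disc["ffpe_call"].to_numpy())
        if ff_call.dtype.kind in "iu":  # base codes from the table caller
            letters = np.array(list(_seq.BASES))
            ff_call = letters[ff_call]
            ffpe_call = letters[ffpe_call]
    n = len(disc)
    if n == 0:
        return None
    raw = np.frombuffer(reference.encode("ascii"), dtype=np.uint8)[pos - 1]
    letters = np.array(list(_seq.BASES))
    ref_bases = letters[_seq._ENCODE[raw]]
    return DiscordantCtRates(
        ffpe_rate=float(_is_ct_side(ref_bases, ffpe_call).mean()),
        ff_rate=float(_is_ct_side(ref_bases, ff_call).mean()),
        n_discordant=n,
    )


def ct_side_counts(detail: pd.DataFrame, reference: str,
                   ) -> tuple[int, int, int]:
    """(ffpe C·G>T·A count, ff count, n discordant) at discordant positions."""
    rates = discordant_ct_rate(detail, reference)
    if rates is None:
        return 0, 0, 0
    n = rates.n_discordant
    return round(rates.ffpe_rate * n), round(rates.ff_rate * n), n


def global_mismatch_rate(pileup: pd.DataFrame, reference: str,
                         variant_positions, filt: FilterConfig,
                         ) -> float | None:
    """Mismatching read bases / total read bases at filtered positions.

    Called-variant positions are excluded so true variants do not count
    as mismatch; the denominator is the summed SNV base counts at the
    remaining filter-passing positions.
    """
    ok = _pass_mask(pileup, filt)
    pos = pileup["pos"].to_numpy()
    if variant_positions is not None and len(variant_positions):
        ok &= ~np.isin(pos, np.asarray(list(variant_positions)))
    counts = _count_matrix(pileup)[ok]
    ref = _ref_codes(pileup)[ok]
    valid = ref < 4
    counts, ref = counts[valid], ref[valid]
    total = counts.sum()
    if total == 0:
        return None
    match = counts[np.arange(len(ref)), ref].sum()
    return float((total - match) / total)


# ---------------------------------------------------------------------------
# sequence-context C>T rates
# ---------------------------------------------------------------------------

CPN_CONTEXTS = ("CpA", "CpC", "CpG", "CpT")
NPC_CONTEXTS = ("ApC", "CpC", "GpC", "TpC")


def _c_site_contexts(reference: str) -> pd.DataFrame:
    """All internal C sites (reference G complemented) with their
    3' (CpN) and 5' (NpC) neighbour contexts on the pyrimidine strand."""
    if len(reference) < 3:
        raise ValueError("contig shorter than 3 bases")
    codes = _seq.encode(reference)
    inner = np.arange(1, codes.size - 1)
    here = codes[inner]
    is_c = here == _seq.C
    is_g = here == _seq.G
    keep = is_c | is_g
    idx = inner[keep]
    here = codes[idx]
    nxt = codes[idx + 1]
    prv = codes[idx - 1]
    # on the complement strand of a G site, the 3' neighbour is the
    # complement of the 5' genomic neighbour and vice versa
    three = np.where(here == _seq.C, nxt, _seq.COMPLEMENT[prv])
    five = np.where(here == _seq.C, prv, _seq.COMPLEMENT[nxt])
    letters = np.array(list(_seq.BASES))
    return pd.DataFrame({
        "pos": idx + 1,
        "strand_ref": np.where(here == _seq.C, "C", "G"),
        "cpn": np.char.add("Cp", letters[three]),
        "npc": np.char.add(letters[five], "pC"),
    })


def context_ct_rates(data: pd.DataFrame, reference: str,
                     mode: str = "call_level",
                     ) -> tuple[dict[str, float], dict[str, float]]:
    """C>T rates stratified by 3' (CpN) and 5' (NpC) neighbour.

    call_level: ``data`` is a variant table; the rate is (C sites with a
    C·G>T·A call) / (eligible C sites) per context.
    read_level: ``data`` is a pileup table; the rate is (T reads at
    reference C, A reads at reference G) / (read bases at those sites).
    First and last positions of the contig are excluded.
    """
    sites = _c_site_contexts(reference)
    if mode == "call_level":
        snvs = data[(data["ref"].str.len() == 1)
                    & (data["alt"].str.len() == 1)]
        ct = snvs[((snvs["ref"] == "C") & (snvs["alt"] == "T"))
                  | ((snvs["ref"] == "G") & (snvs["alt"] == "A"))]
        hit = sites["pos"].isin(set(ct["pos"])).to_numpy()
        num = pd.Series(hit, index=None).groupby(
            [sites["cpn"].to_numpy()]).sum()
        den = sites.groupby("cpn").size()
        cpn = {c: float(num.get(c, 0) / den.get(c, np.nan))
               for c in CPN_CONTEXTS}
        num5 = pd.Series(hit).groupby(sites["npc"].to_numpy()).sum()
        den5 = sites.groupby("npc").size()
        npc = {c: float(num5.get(c, 0) / den5.get(c, np.nan))
               for c in NPC_CONTEXTS}
        return cpn, npc
    if mode != "read_level":
        raise ValueError("mode must be 'call_level' or 'read_level'")

    pileup = data.set_index("pos")
    sub = pileup.loc[sites["pos"].to_numpy()]
    is_c = (sites["strand_ref"] == "C").to_numpy()
    mut = np.where(is_c, sub["nT"].to_numpy(), sub["nA"].to_numpy())
    tot = sub[["nA", "nC", "nG", "nT"]].sum(axis=1).to_numpy()
    frame = pd.DataFrame({"cpn": sites["cpn"].to_numpy(),
                          "npc": sites["npc"].to_numpy(),
                          "mut": mut, "tot": tot})
    g3 = frame.groupby("cpn")[["mut", "tot"]].sum()
    g5 = frame.groupby("npc")[["mut", "tot"]].sum()
    cpn = {c: float(g3["mut"].get(c, 0) / g3["tot"].get(c, np.nan))
           for c in CPN_CONTEXTS}
    npc = {c: float(g5["mut"].get(c, 0) / g5["tot"].get(c, np.nan))
           for c in NPC_CONTEXTS}
    return cpn, npc


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

class PairedTResult(NamedTuple):
    t: float
    df: int
    p: float


def paired_t_test(ff_values, ffpe_values) -> PairedTResult:
    """Two-tailed paired t test with an explicit degenerate rule.

    All-zero differences give t=0, p=1; a constant non-zero difference
    (zero variance) is an error.
    """
    a = np.asarray(ff_values, dtype=float)
    b = np.asarray(ffpe_values, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length vectors with n >= 2")
    d = b - a
    if np.allclose(d.var(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return PairedTResult(t=0.0, df=a.size - 1, p=1.0)
        raise ValueError("zero difference variance with non-zero mean")
    res = stats.ttest_rel(b, a)  # t is signed as mean(ffpe - ff)
    return PairedTResult(t=float(res.statistic), df=int(a.size - 1),
                         p=float(res.pvalue))


@dataclass
class DunnettResult:
    f: float
    p_anova: float
    t_values: list[float]
    p_adjusted: list[float]
    flagged: list[bool] = field(default_factory=list)


def anova_dunnett(groups, control_index: int = 0, seed: int = 0,
                  n_draws: int = 100_000, alpha: float = 0.05,
                  ) -> DunnettResult:
    """One-way ANOVA plus Dunnett many-to-one comparisons.

    The Dunnett adjustment is estimated by seeded Monte Carlo of the
    null max-|t| distribution (groups share the pooled within-group
    variance), which is deterministic given the seed and accurate to
    Monte-Carlo error ~1/sqrt(n_draws).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with n >= 2 each")
    k = len(groups) - 1
    ns = np.array([g.size for g in groups])
    means = np.array([g.mean() for g in groups])
    df_within = int(ns.sum() - len(groups))
    sse = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if sse == 0:
        # all groups constant: F undefined or 0; nothing significant
        return DunnettResult(f=0.0, p_anova=1.0,
                             t_values=[0.0] * k, p_adjusted=[1.0] * k,
                             flagged=[False] * k)
    mse = sse / df_within
    f_res = stats.f_oneway(*groups)

    order = [control_index] + [i for i in range(len(groups))
                               if i != control_index]
    n0 = ns[order[0]]
    t_obs = []
    for i in order[1:]:
        se = math.sqrt(mse * (1.0 / ns[i] + 1.0 / n0))
        t_obs.append((means[i] - means[order[0]]) / se)

    rng = np.random.default_rng(int(seed))
    z = rng.standard_normal((n_draws, len(groups))) / np.sqrt(ns[order])
    s2 = rng.chisquare(df_within, size=n_draws) / df_within
    scale = np.sqrt(1.0 / ns[order[1:]] + 1.0 / n0)
    t_null = (z[:, 1:] - z[:, [0]]) / (np.sqrt(s2)[:, None] * scale)
    max_abs = np.abs(t_null).max(axis=1)
    p_adj = [float((max_abs >= abs(t)).mean()) for t in t_obs]
    return DunnettResult(
        f=float(f_res.statistic), p_anova=float(f_res.pvalue),
        t_values=[float(t) for t in t_obs], p_adjusted=p_adj,
        flagged=[p < alpha for p in p_adj],
    )


def two_proportion_test(x1: int, n1: int, x2: int, n2: int,
                        alternative: str = "greater") -> tuple[float, float]:
    """Pooled two-proportion z test; returns (z, p)."""
    if min(n1, n2) == 0:
        return float("nan"), float("nan")
    p1, p2 = x1 / n1, x2 / n2
    pool = (x1 + x2) / (n1 + n2)
    se = math.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
    if se == 0:
        return 0.0, 1.0
    z = (p1 - p2) / se
    if alternative == "greater":
        p = float(stats.norm.sf(z))
    elif alternative == "less":
        p = float(stats.norm.cdf(z))
    else:
        p = float(2 * stats.norm.sf(abs(z)))
    return float(z), p
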