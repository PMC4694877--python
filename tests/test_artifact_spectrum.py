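"""Spectrum collapsing, context rates, and the statistical kernels."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ffpe_concord.artifact_spectrum import (anova_dunnett,
                                            collapse_substitution,
                                            context_ct_rates,
                                            discordant_ct_rate,
                                            global_mismatch_rate,
                                            paired_t_test,
                                            substitution_spectrum,
                                            two_proportion_test)
from ffpe_concord.calling import FilterConfig

from conftest import make_pileup, make_variants

FILT = FilterConfig()


class TestSpectrum:
    def test_complement_collapsing(self):
        ref = "ACGTCAGT"
        variants = make_variants([(2, "C", "T"), (3, "G", "A"),
                                  (1, "A", "G")])
        spec = substitution_spectrum(variants, ref)
        assert spec.class_counts["C>T"] == 2
        assert spec.class_counts["T>C"] == 1
        assert spec.n_snvs == 3
        assert spec.ct_rate_all == pytest.approx(2 / 3)

    def test_tstv(self):
        ref = "ACGT"
        variants = make_variants([(2, "C", "T"), (3, "G", "A"),
                                  (1, "A", "T")])
        spec = substitution_spectrum(variants, ref)
        assert spec.tstv == pytest.approx(2.0)

    def test_empty_variants(self):
        spec = substitution_spectrum(make_variants([]), "ACGT")
        assert sum(spec.class_counts.values()) == 0
        assert spec.ct_rate_all is None and spec.tstv is None

    def test_reference_mismatch_names_position(self):
        with pytest.raises(ValueError, match="pos 3"):
            substitution_spectrum(make_variants([(3, "C", "T")]), "AAAA")

    def test_counts_conserve_snvs(self):
        rng = np.random.default_rng(5)
        ref = "".join(rng.choice(list("ACGT"), size=500))
        rows = []
        for pos in rng.choice(500, size=60, replace=False) + 1:
            r = ref[pos - 1]
            alt = rng.choice([b for b in "ACGT" if b != r])
            rows.append((pos, r, alt))
        spec = substitution_spectrum(make_variants(rows), ref)
        assert sum(spec.class_counts.values()) == 60

    def test_strand_collapse_invariance(self):
        """Complementing the reference and all alleles leaves every
        spectrum field unchanged."""
        comp = str.maketrans("ACGT", "TGCA")
        rng = np.random.default_rng(8)
        ref = "".join(rng.choice(list("ACGT"), size=300))
        rows = []
        for pos in rng.choice(300, size=40, replace=False) + 1:
            r = ref[pos - 1]
            rows.append((pos, r, rng.choice([b for b in "ACGT" if b != r])))
        spec1 = substitution_spectrum(make_variants(rows), ref)
        ref_c = ref.translate(comp)
        rows_c = [(p, r.translate(comp), a.translate(comp))
                  for p, r, a in rows]
        spec2 = substitution_spectrum(make_variants(rows_c), ref_c)
        assert spec1.class_counts == spec2.class_counts
        assert spec1.tstv == spec2.tstv


class TestDiscordantCt:
    def _detail(self, rows):
        return pd.DataFrame(rows, columns=["pos", "ff_call", "ffpe_call"])

    def test_fraction_of_ffpe_side_ct(self):
        ref = "CCCCG"
        detail = self._detail([(1, "C", "T"), (2, "C", "T"), (3, "C", "T"),
                               (4, "C", "A")])
        rates = discordant_ct_rate(detail, ref)
        assert rates.ffpe_rate == pytest.approx(0.75)
        assert rates.ff_rate == 0.0
        assert rates.n_discordant == 4

    def test_g_sites_complemented(self):
        rates = discordant_ct_rate(self._detail([(5, "G", "A")]), "CCCCG")
        assert rates.ffpe_rate == 1.0

    def test_no_discordant_positions_is_missing(self):
        assert discordant_ct_rate(self._detail([]), "ACGT") is None

    def test_variant_detail_accepted(self):
        detail = pd.DataFrame({
            "pos": [1, 2], "cls": ["discordant", "concordant"],
            "alt_ff": ["A", "T"], "alt_ffpe": ["T", "T"]})
        rates = discordant_ct_rate(detail, "CC")
        assert rates.n_discordant == 1
        assert rates.ffpe_rate == 1.0 and rates.ff_rate == 0.0


class TestGlobalMismatch:
    def test_error_free_is_zero(self):
        pileup = make_pileup([1, 2], ["A", "C"], [[50, 0, 0, 0],
                                                  [0, 40, 0, 0]])
        assert global_mismatch_rate(pileup, "AC", [], FILT) == 0.0

    def test_single_mismatch_rate(self):
        pileup = make_pileup([1], ["A"], [[99, 0, 0, 1]])
        assert global_mismatch_rate(pileup, "A", [], FILT) == \
            pytest.approx(0.01)

    def test_variant_positions_excluded(self):
        pileup = make_pileup([1, 2], ["A", "C"], [[50, 0, 0, 0],
                                                  [0, 20, 0, 20]])
        assert global_mismatch_rate(pileup, "AC", [2], FILT) == 0.0

    def test_zero_denominator_missing(self):
        pileup = make_pileup([1], ["A"], [[5, 0, 0, 0]])  # depth < 13
        assert global_mismatch_rate(pileup, "A", [], FILT) is None

    def test_recovers_error_rate(self, clean_config):
        from ffpe_concord.synthetic_data import (generate_reference,
                                                 generate_truth,
                                                 simulate_pileup)
        cfg = clean_config.with_(genome_length=20_000, seq_error_rate=1e-3,
                                 germline_het_rate=0.0, somatic_rate=0.0,
                                 indel_rate=0.0)
        ref = generate_reference(cfg)
        truth = generate_truth(ref, cfg)
        for kind in ("ff_normal", "ffpe_normal"):
            pileup = simulate_pileup(ref, truth, cfg, kind)
            rate = global_mismatch_rate(pileup, ref, [], FILT)
            n = pileup[["nA", "nC", "nG", "nT"]].to_numpy().sum()
            assert n > 1e6
            sd = np.sqrt(1e-3 / n)
            assert abs(rate - 1e-3) < 3 * sd


class TestContextRates:
    def test_cpg_context_classification(self):
        # reference "ACGT": the C at pos 2 has 3' neighbour G => CpG; the
        # G at pos 3 is the same CpG seen from the complementary strand
        cpn, npc = context_ct_rates(make_variants([(2, "C", "T")]), "ACGT",
                                    mode="call_level")
        assert cpn["CpG"] == pytest.approx(0.5)
        assert all(np.isnan(v) for c, v in cpn.items() if c != "CpG")
        assert npc["ApC"] == pytest.approx(0.5)

    def test_call_level_rate(self):
        ref = "ACG" * 100  # 100 internal CpG cytosines (pos 2 mod 3)
        calls = make_variants([(2, "C", "T"), (5, "C", "T")])
        cpn, _ = context_ct_rates(calls, ref, mode="call_level")
        # G sites complemented also land in CpG denominator
        assert cpn["CpG"] == pytest.approx(2 / 199)

    def test_short_contig_rejected(self):
        with pytest.raises(ValueError):
            context_ct_rates(make_variants([]), "AC", mode="call_level")

    def test_read_level_recovers_rates(self, artifact_config):
        from ffpe_concord.synthetic_data import (generate_reference,
                                                 generate_truth,
                                                 simulate_pileup)
        cfg = artifact_config.with_(genome_length=60_000,
                                    deamination_rate_cpg=0.01,
                                    deamination_rate_noncpg=0.001,
                                    seq_error_rate=0.0,
                                    germline_het_rate=0.0, somatic_rate=0.0,
                                    indel_rate=0.0)
        ref = generate_reference(cfg)
        truth = generate_truth(ref, cfg)
        pileup = simulate_pileup(ref, truth, cfg, "ffpe_normal")
        cpn, npc = context_ct_rates(pileup, ref, mode="read_level")
        assert abs(cpn["CpG"] - 0.01) < 0.001
        for ctx in ("CpA", "CpC", "CpT"):
            assert cpn[ctx] < cpn["CpG"] / 3
        # the model has no 5' dependence: NpC rates are all intermediate
        for ctx, rate in npc.items():
            assert 0.001 < rate < 0.01


class TestPairedT:
    def test_closed_form_example(self):
        res = paired_t_test([1, 2, 3], [2, 3, 5])
        assert res.t == pytest.approx(4.0)
        assert res.df == 2
        assert res.p == pytest.approx(
            2 * stats.t.sf(4.0, 2), rel=1e-12)

    def test_antisymmetry(self):
        a, b = [1.0, 2.0, 4.0, 3.0], [2.0, 2.5, 5.0, 2.0]
        r1 = paired_t_test(a, b)
        r2 = paired_t_test(b, a)
        assert r1.t == pytest.approx(-r2.t)
        assert r1.p == pytest.approx(r2.p)

    def test_all_zero_differences(self):
        res = paired_t_test([1, 2, 3], [1, 2, 3])
        assert res.t == 0.0 and res.p == 1.0

    def test_constant_nonzero_difference_rejected(self):
        with pytest.raises(ValueError):
            paired_t_test([1, 2, 3], [2, 3, 4])


class TestDunnett:
    def test_identical_constant_groups(self):
        res = anova_dunnett([[1, 1, 1], [1, 1, 1], [1, 1, 1]], seed=0)
        assert res.f == 0.0
        assert not any(res.flagged)

    def test_two_groups_reduce_to_t_test(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.5, 1, 30)
        res = anova_dunnett([a, b], seed=1, n_draws=200_000)
        t_res = stats.ttest_ind(b, a)
        assert res.t_values[0] == pytest.approx(t_res.statistic, rel=1e-9)
        assert res.p_adjusted[0] == pytest.approx(t_res.pvalue, abs=0.01)

    def test_matches_scipy_dunnett(self):
        """Monte-Carlo adjustment vs scipy's closed-form Dunnett."""
        rng = np.random.default_rng(11)
        control = rng.normal(0, 1, 40)
        g1 = rng.normal(0.6, 1, 40)
        g2 = rng.normal(0.0, 1, 40)
        ours = anova_dunnett([control, g1, g2], seed=2, n_draws=200_000)
        ref = stats.dunnett(g1, g2, control=control)
        assert ours.p_adjusted[0] == pytest.approx(ref.pvalue[0], abs=0.02)
        assert ours.p_adjusted[1] == pytest.approx(ref.pvalue[1], abs=0.02)

    def test_shifted_group_flagged(self):
        rng = np.random.default_rng(9)
        for rep in range(5):
            groups = [rng.normal(0, 1, 50) for _ in range(3)]
            groups.append(rng.normal(3.0, 1, 50))  # shifted by 3 SD
            res = anova_dunnett(groups, control_index=0, seed=rep,
                                n_draws=50_000)
            assert res.flagged[-1]
            assert not any(res.flagged[:-1])

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            anova_dunnett([[1.0]])


class TestTwoProportion:
    def test_known_direction(self):
        z, p = two_proportion_test(60, 100, 40, 100, alternative="greater")
        assert z > 0 and p < 0.01
        _, p2 = two_proportion_test(40, 100, 60, 100, alternative="greater")
        assert p2 > 0.99
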