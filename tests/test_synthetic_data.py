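"""Generator contracts: composition, truth draws, artifact asymmetry."""
import numpy as np
import pytest

from ffpe_concord import _seq
from ffpe_concord.artifact_spectrum import two_proportion_test
from ffpe_concord.synthetic_data import (ConfigurationError, SimulationConfig,
                                         generate_reference, generate_truth,
                                         simulate_array_genotypes,
                                         simulate_lowpass_counts,
                                         simulate_pileup)


class TestReference:
    def test_length_contract(self):
        cfg = SimulationConfig(genome_length=1000, gc_fraction=0.5, seed=1)
        assert len(generate_reference(cfg)) == 1000

    def test_pure_gc_composition(self):
        cfg = SimulationConfig(genome_length=500, gc_fraction=1.0, seed=1)
        assert set(generate_reference(cfg)) <= {"G", "C"}

    def test_gc_within_binomial_noise(self):
        cfg = SimulationConfig(genome_length=200_000, gc_fraction=0.41,
                               seed=7)
        gc = _seq.gc_fraction(_seq.encode(generate_reference(cfg)))
        sd = np.sqrt(0.41 * 0.59 / 200_000)
        assert abs(gc - 0.41) < 3 * sd

    def test_gc_preserved_under_cpg_enrichment(self):
        cfg = SimulationConfig(genome_length=300_000, gc_fraction=0.41,
                               cpg_enrichment=4.0, seed=7)
        gc = _seq.gc_fraction(_seq.encode(generate_reference(cfg)))
        assert abs(gc - 0.41) < 0.01

    def test_cpg_frequency_scales_with_enrichment(self):
        freqs = []
        for enr in (0.25, 1.0, 2.0, 4.0):
            cfg = SimulationConfig(genome_length=200_000, cpg_enrichment=enr,
                                   seed=3)
            codes = _seq.encode(generate_reference(cfg))
            freqs.append(np.mean((codes[:-1] == _seq.C)
                                 & (codes[1:] == _seq.G)))
        assert freqs == sorted(freqs)
        assert freqs[-1] > 3 * freqs[1]

    def test_deterministic(self):
        cfg = SimulationConfig(genome_length=5000, cpg_enrichment=2.0, seed=9)
        assert generate_reference(cfg) == generate_reference(cfg)

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(genome_length=0)
        with pytest.raises(ConfigurationError):
            SimulationConfig(gc_fraction=1.5)


class TestTruth:
    def test_zero_rates_give_empty_sets(self):
        cfg = SimulationConfig(genome_length=10_000, germline_het_rate=0.0,
                               somatic_rate=0.0, indel_rate=0.0, seed=2)
        truth = generate_truth(generate_reference(cfg), cfg)
        assert len(truth.germline) == 0
        assert len(truth.somatic) == 0
        assert len(truth.indels) == 0

    def test_deterministic(self):
        cfg = SimulationConfig(genome_length=20_000, seed=5)
        ref = generate_reference(cfg)
        t1, t2 = generate_truth(ref, cfg), generate_truth(ref, cfg)
        assert t1.germline.equals(t2.germline)
        assert t1.somatic.equals(t2.somatic)
        assert t1.indels.equals(t2.indels)

    def test_germline_count_binomial(self):
        cfg = SimulationConfig(genome_length=1_000_000,
                               germline_het_rate=1e-3, somatic_rate=0.0,
                               indel_rate=0.0, seed=2)
        truth = generate_truth(generate_reference(cfg), cfg)
        sd = np.sqrt(1_000_000 * 1e-3 * (1 - 1e-3))
        assert abs(len(truth.germline) - 1000) < 3 * sd

    def test_positions_disjoint_and_alts_differ(self):
        cfg = SimulationConfig(genome_length=100_000, germline_het_rate=5e-3,
                               somatic_rate=5e-3, indel_rate=1e-3, seed=4)
        ref = generate_reference(cfg)
        truth = generate_truth(ref, cfg)
        g = set(truth.germline["pos"])
        s = set(truth.somatic["pos"])
        i = set(truth.indels["pos"])
        assert not (g & s) and not (g & i) and not (s & i)
        assert (truth.germline["ref"] != truth.germline["alt"]).all()
        for r in truth.germline.itertuples(index=False):
            assert ref[r.pos - 1] == r.ref


class TestPileup:
    def test_error_free_reads_match_truth(self, clean_config):
        cfg = clean_config.with_(genome_length=20_000)
        ref = generate_reference(cfg)
        truth = generate_truth(ref, cfg)
        pileup = simulate_pileup(ref, truth, cfg, "ff_normal")
        variant_pos = set(truth.germline["pos"])
        counts = pileup[["nA", "nC", "nG", "nT"]].to_numpy()
        codes = _seq.encode(ref)
        non_var = ~pileup["pos"].isin(variant_pos).to_numpy()
        rows = np.arange(len(pileup))
        ref_counts = counts[rows, codes]
        # at non-variant positions every read base equals the reference
        assert (ref_counts[non_var] == pileup["depth"].to_numpy()[non_var]
                ).all()
        # at het sites only ref and alt alleles appear
        for r in truth.germline.itertuples(index=False):
            row = counts[r.pos - 1]
            seen = {b for b, c in zip("ACGT", row) if c > 0}
            assert seen <= {r.ref, r.alt}

    def test_ff_never_deaminated(self, clean_config):
        cfg = clean_config.with_(genome_length=20_000,
                                 deamination_rate_cpg=1.0,
                                 deamination_rate_noncpg=1.0,
                                 germline_het_rate=0.0, somatic_rate=0.0,
                                 indel_rate=0.0)
        ref = generate_reference(cfg)
        truth = generate_truth(ref, cfg)
        pileup = simulate_pileup(ref, truth, cfg, "ff_tumor")
        codes = _seq.encode(ref)
        c_sites = codes == _seq.C
        assert (pileup["nT"].to_numpy()[c_sites] == 0).all()

    def test_deamination_rate_recovered(self, clean_config):
        cfg = clean_config.with_(genome_length=100_000, cpg_enrichment=4.0,
                                 deamination_rate_cpg=0.01,
                                 deamination_rate_noncpg=0.0,
                                 germline_het_rate=0.0, somatic_rate=0.0,
                                 indel_rate=0.0, mean_coverage_ffpe=50.0)
        ref = generate_reference(cfg)
        truth = generate_truth(ref, cfg)
        pileup = simulate_pileup(ref, truth, cfg, "ffpe_normal")
        codes = _seq.encode(ref)
        cpg_c = (codes[:-1] == _seq.C) & (codes[1:] == _seq.G)
        sub = pileup.iloc[:-1][cpg_c]
        n_t = sub["nT"].sum()
        n_obs = sub[["nA", "nC", "nG", "nT"]].to_numpy().sum()
        assert n_obs > 1e5
        sd = np.sqrt(0.01 * 0.99 / n_obs)
        assert abs(n_t / n_obs - 0.01) < 3 * sd

    def test_tumor_depth_scales_with_copy_state(self, clean_config):
        cfg = clean_config.with_(genome_length=40_000,
                                 cnv_segments=((1, 20_000, 4),),
                                 germline_het_rate=0.0, somatic_rate=0.0,
                                 indel_rate=0.0)
        ref = generate_reference(cfg)
        truth = generate_truth(ref, cfg)
        pileup = simulate_pileup(ref, truth, cfg, "ff_tumor")
        depth = pileup["depth"].to_numpy()
        ratio = depth[:20_000].mean() / depth[20_000:].mean()
        assert abs(ratio - 2.0) < 0.05

    def test_deterministic_and_kind_specific(self, clean_config):
        cfg = clean_config.with_(genome_length=5_000)
        ref = generate_reference(cfg)
        truth = generate_truth(ref, cfg)
        a = simulate_pileup(ref, truth, cfg, "ff_normal")
        b = simulate_pileup(ref, truth, cfg, "ff_normal")
        assert a.equals(b)
        c = simulate_pileup(ref, truth, cfg, "ffpe_normal")
        assert not a["depth"].equals(c["depth"])

    def test_artifact_asymmetry(self, clean_config):
        """FFPE CpG C>T read rate exceeds FF when deamination > 0;
        indistinguishable when deamination = 0 (two-proportion z test)."""
        def rates(deam):
            cfg = clean_config.with_(
                genome_length=50_000, cpg_enrichment=4.0,
                deamination_rate_cpg=deam, deamination_rate_noncpg=0.0,
                seq_error_rate=0.001, germline_het_rate=0.0,
                somatic_rate=0.0, indel_rate=0.0)
            ref = generate_reference(cfg)
            truth = generate_truth(ref, cfg)
            codes = _seq.encode(ref)
            cpg_c = np.flatnonzero((codes[:-1] == _seq.C)
                                   & (codes[1:] == _seq.G))
            out = []
            for kind in ("ff_normal", "ffpe_normal"):
                p = simulate_pileup(ref, truth, cfg, kind).iloc[cpg_c]
                out.append((int(p["nT"].sum()),
                            int(p[["nA", "nC", "nG", "nT"]].sum().sum())))
            return out

        (ff_x, ff_n), (fp_x, fp_n) = rates(0.01)
        _, p = two_proportion_test(fp_x, fp_n, ff_x, ff_n)
        assert p < 0.01
        (ff_x, ff_n), (fp_x, fp_n) = rates(0.0)
        _, p = two_proportion_test(fp_x, fp_n, ff_x, ff_n)
        assert p > 0.01


class TestLowpassAndArray:
    def test_copy_state_doubles_expected_counts(self, clean_config):
        cfg = clean_config.with_(genome_length=3_000_000, bin_size=15_000,
                                 gc_bias_strength=0.0,
                                 cnv_segments=((1, 1_500_000, 4),),
                                 lowpass_mean_coverage=2.0,
                                 germline_het_rate=0.0, somatic_rate=0.0,
                                 indel_rate=0.0)
        ref = generate_reference(cfg)
        truth = generate_truth(ref, cfg)
        bins = simulate_lowpass_counts(ref, truth, cfg, "ffpe_tumor")
        amp = bins[bins["end"] <= 1_500_000]["count"].mean()
        dip = bins[bins["start"] > 1_500_000]["count"].mean()
        assert abs(amp / dip - 2.0) < 0.25

    def test_deletion_region_ratio(self, clean_config):
        cfg = clean_config.with_(genome_length=4_000_000, bin_size=2_000,
                                 gc_bias_strength=0.0,
                                 cnv_segments=((1, 1_000_000, 1),),
                                 lowpass_mean_coverage=2.0,
                                 germline_het_rate=0.0, somatic_rate=0.0,
                                 indel_rate=0.0)
        ref = generate_reference(cfg)
        truth = generate_truth(ref, cfg)
        bins = simulate_lowpass_counts(ref, truth, cfg, "ff_tumor")
        inside = bins[bins["end"] <= 1_000_000]["count"]
        outside = bins[bins["start"] > 1_000_000]["count"]
        ratio = inside.mean() / outside.mean()
        sd = ratio * np.sqrt(1 / inside.sum() + 1 / outside.sum())
        assert abs(ratio - 0.5) < 3 * max(sd, 0.01)

    def test_genome_shorter_than_bin_rejected(self, clean_config):
        cfg = clean_config.with_(genome_length=1_000, bin_size=15_000)
        ref = generate_reference(cfg)
        truth = generate_truth(ref, cfg)
        with pytest.raises(ConfigurationError):
            simulate_lowpass_counts(ref, truth, cfg, "ff_normal")

    def test_array_error_rate_contracts(self, clean_config):
        cfg = clean_config.with_(genome_length=50_000, germline_het_rate=0.2)
        truth = generate_truth(generate_reference(cfg), cfg)
        exact = simulate_array_genotypes(truth, 0.0, seed=1)
        assert (exact["genotype"] == "het").all()
        flipped = simulate_array_genotypes(truth, 1.0, seed=1)
        assert (flipped["genotype"] != "het").all()
        n = len(truth.germline)
        assert n > 5_000
        noisy = simulate_array_genotypes(truth, 0.02, seed=1)
        mism = int((noisy["genotype"] != "het").sum())
        sd = np.sqrt(n * 0.02 * 0.98)
        assert abs(mism - 0.02 * n) < 3 * sd
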