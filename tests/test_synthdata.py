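import numpy as np
import pytest

from coderep.cohort import logrank_test
from coderep.errors import SizingError, ValidationError
from coderep.synergy import hsa_score
from coderep.synthdata import (
    SyntheticConfig,
    generate_annotation,
    generate_cohort,
    generate_dose_matrix,
    generate_expression,
    generate_peaksets,
    plant_truth,
)
from conftest import SMALL


def _overlap(a_start, a_end, b_start, b_end):
    return a_start < b_end and b_start < a_end


class TestAnnotation:
    def test_fixed_seed_is_deterministic(self, small_config):
        a = generate_annotation(small_config)
        b = generate_annotation(small_config)
        assert a.df.equals(b.df)

    def test_genome_too_small_names_required_length(self):
        cfg = SyntheticConfig(
            n_genes=4,
            n_planted_cooperative=1,
            n_planted_ezh2i_only=0,
            n_planted_hdaci_only=0,
            n_planted_additive=0,
            chrom_length=10_000,
            tss_window_halfwidth=10_000,
        )
        with pytest.raises(SizingError, match="chrom_length >="):
            generate_annotation(cfg)

    def test_gene_count_and_biotype_split(self):
        cfg = SyntheticConfig(**{**SMALL, "n_genes": 100})
        ann = generate_annotation(cfg)
        assert len(ann.gene_ids) == 100
        coding_frac = (ann.df["biotype"] == "protein_coding").mean()
        assert coding_frac >= 0.9

    def test_tss_spacing_at_least_three_halfwidths(self, small_config):
        ann = generate_annotation(small_config)
        hw = small_config.tss_window_halfwidth
        for _, grp in ann.df.groupby("chrom"):
            tss = np.sort(grp["tss"].to_numpy())
            assert (np.diff(tss) >= 3 * hw).all()


class TestPeaks:
    def test_planted_loss_structure(self, small_bundle):
        b = small_bundle
        hw = b.config.tss_window_halfwidth
        by_tid = b.annotation.df.set_index("transcript_id")
        for tid in b.truth.lost_transcripts:
            row = by_tid.loc[tid]
            w0, w1 = max(0, row.tss - hw), row.tss + hw
            in_dmso = [
                p for p in b.peaksets["DMSO"]
                if p.chrom == row.chrom and _overlap(p.start, p.end, w0, w1)
            ]
            assert in_dmso, f"no DMSO peak in window of {tid}"
        assert b.peaksets["HDACi"] == b.peaksets["DMSO"]
        assert b.peaksets["Combo"] == b.peaksets["EZH2i"]

    def test_lost_peak_count_matches_truth_by_brute_force(self, small_bundle):
        b = small_bundle
        treated = list(b.peaksets["EZH2i"])
        lost = [
            p
            for p in b.peaksets["DMSO"]
            if not any(
                p.chrom == t.chrom and _overlap(p.start, p.end, t.start, t.end)
                for t in treated
            )
        ]
        assert len(lost) == len(b.truth.lost_transcripts)

    def test_single_planted_gene_no_background(self):
        cfg = SyntheticConfig(
            **{
                **SMALL,
                "n_genes": 1,
                "n_planted_cooperative": 1,
                "n_planted_ezh2i_only": 0,
                "n_planted_hdaci_only": 0,
                "n_planted_additive": 0,
                "n_background_peaks": 0,
                "stable_peak_fraction": 0.0,
                "noncoding_fraction": 0.0,
                "second_transcript_fraction": 0.0,
            }
        )
        ann = generate_annotation(cfg)
        truth = plant_truth(cfg, ann)
        peaks = generate_peaksets(cfg, ann, truth)
        assert len(peaks["DMSO"]) == 1
        assert len(peaks["EZH2i"]) == 0

    def test_same_seed_identical_peaksets(self, small_config):
        ann = generate_annotation(small_config)
        truth = plant_truth(small_config, ann)
        assert generate_peaksets(small_config, ann, truth) == generate_peaksets(
            small_config, ann, truth
        )


class TestExpression:
    def test_noiseless_planted_means_exact(self, noiseless_bundle):
        b = noiseless_bundle
        expr = b.expression
        eff = b.config.effect_log2fc

        def cond_mean(gene, cond):
            return expr.values.loc[gene, expr.samples_for(cond)].mean()

        coop = sorted(b.truth.genes_of_class("cooperative_prc2"))[0]
        assert cond_mean(coop, "Combo") - cond_mean(coop, "DMSO") == pytest.approx(eff)
        assert cond_mean(coop, "EZH2i") - cond_mean(coop, "DMSO") == 0
        ez = sorted(b.truth.genes_of_class("ezh2i_only"))[0]
        assert cond_mean(ez, "EZH2i") - cond_mean(ez, "DMSO") == pytest.approx(eff)
        assert cond_mean(ez, "Combo") - cond_mean(ez, "EZH2i") == 0

    def test_null_gene_noise_sd_recovered(self):
        # 2500 replicates x 4 conditions = 10000 observations per gene
        cfg = SyntheticConfig(
            **{
                **SMALL,
                "n_genes": 5,
                "n_planted_cooperative": 0,
                "n_planted_ezh2i_only": 0,
                "n_planted_hdaci_only": 0,
                "n_planted_additive": 0,
                "n_replicates_per_condition": 2500,
            }
        )
        ann = generate_annotation(cfg)
        truth = plant_truth(cfg, ann)
        expr = generate_expression(cfg, truth)
        sd = expr.values.iloc[0].std(ddof=1)
        assert sd == pytest.approx(cfg.noise_sd, rel=0.03)

    def test_single_replicate_rejected(self):
        cfg = SyntheticConfig(**{**SMALL, "n_replicates_per_condition": 1})
        ann = generate_annotation(cfg)
        truth = plant_truth(cfg, ann)
        with pytest.raises(ValidationError, match="replicates"):
            generate_expression(cfg, truth)


class TestCohort:
    def test_class_gradients(self, small_bundle):
        cohort = small_bundle.cohort
        means = cohort.df.groupby("tissue")[["EZH2", "ATF3"]].mean()
        assert means.loc["metastatic", "EZH2"] > means.loc["primary", "EZH2"]
        assert means.loc["primary", "EZH2"] > means.loc["normal", "EZH2"]
        assert means.loc["metastatic", "ATF3"] < means.loc["normal", "ATF3"]

    def test_null_hazard_ratio_gives_null_logrank(self):
        pvals = []
        for seed in range(30):
            cfg = SyntheticConfig(
                **{
                    **SMALL,
                    "seed": seed,
                    "hazard_ratio_atf3_low": 1.0,
                    "censor_rate": 0.0,
                    "n_signature_genes": 2,
                    "n_cohort_null_genes": 0,
                }
            )
            cohort, truth = generate_cohort(cfg)
            merged = cohort.df.merge(truth, on="sample")
            low = merged[merged["atf3_low"]]
            high = merged[~merged["atf3_low"] & (merged["tissue"] != "normal")]
            _, p = logrank_test(
                (low["time"], low["event"]), (high["time"], high["event"])
            )
            pvals.append(p)
        # under the null ~5% of seeds reject at alpha = 0.05
        assert np.mean(np.array(pvals) < 0.05) <= 0.2

    def test_hazard_ratio_recovered_from_median_times(self):
        ratios = []
        for seed in range(50):
            cfg = SyntheticConfig(
                seed=seed,
                n_genes=10,
                n_planted_cooperative=0,
                n_planted_ezh2i_only=0,
                n_planted_hdaci_only=0,
                n_planted_additive=0,
                cohort_n_normal=0,
                cohort_n_primary=200,
                cohort_n_metastatic=200,
                hazard_ratio_atf3_low=3.0,
                censor_rate=0.0,
                n_signature_genes=2,
                n_cohort_null_genes=0,
            )
            cohort, truth = generate_cohort(cfg)
            merged = cohort.df.merge(truth, on="sample")
            med_high = merged.loc[~merged["atf3_low"], "time"].median()
            med_low = merged.loc[merged["atf3_low"], "time"].median()
            ratios.append(med_high / med_low)
        # exponential median = ln2 / rate, so the ratio estimates the hazard ratio
        assert np.mean(ratios) == pytest.approx(3.0, rel=0.2)

    def test_invalid_hazard_ratio_rejected(self):
        with pytest.raises(ValidationError):
            SyntheticConfig(**{**SMALL, "hazard_ratio_atf3_low": 0.0})


class TestDose:
    def test_vehicle_well_is_zero(self, small_config):
        m = generate_dose_matrix(small_config)
        assert m.response[0, 0] == 0.0

    def test_planted_excess_recovered_exactly(self):
        for excess in (0.0, 15.0):
            cfg = SyntheticConfig(**{**SMALL, "planted_hsa_excess": excess})
            assert hsa_score(generate_dose_matrix(cfg)).score == pytest.approx(excess)

    def test_single_agent_curves_monotone(self, small_config):
        m = generate_dose_matrix(small_config)
        assert (np.diff(m.response[:, 0]) >= 0).all()
        assert (np.diff(m.response[0, :]) >= 0).all()
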