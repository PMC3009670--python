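"""Validation statistics: linearity, correlations, twins, genotype, populations."""

import numpy as np
import pandas as pd
import pytest

from mescreen import simulate as sim
from mescreen.methstats import (
    assay_linearity,
    genotype_association,
    inter_tissue_correlation,
    population_compare,
    twin_concordance,
)


def _measurements(rows):
    return pd.DataFrame(
        rows, columns=["sample_id", "population", "tissue", "locus", "replicate", "percent"]
    )


class TestLinearity:
    def test_perfect_standards(self):
        std = pd.DataFrame({"expected_fraction": [0, 0.5, 1], "measured_percent": [0, 50, 100]})
        fit = assay_linearity(std)
        assert fit.slope == pytest.approx(100.0)
        assert fit.intercept == pytest.approx(0.0)
        assert fit.r == pytest.approx(1.0)

    def test_constant_response_slope_zero(self):
        std = pd.DataFrame({"expected_fraction": [0, 0.5, 1], "measured_percent": [40, 40, 40]})
        assert assay_linearity(std).slope == 0.0

    def test_matches_closed_form_least_squares(self):
        rng = np.random.default_rng(2)
        x = np.repeat([0, 0.25, 0.5, 0.75, 1.0], 3)
        y = 95 * x + 2 + rng.normal(0, 2, len(x))
        fit = assay_linearity(pd.DataFrame({"expected_fraction": x, "measured_percent": y}))
        # normal equations, computed independently
        sxx = ((x - x.mean()) ** 2).sum()
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        slope = sxy / sxx
        intercept = y.mean() - slope * x.mean()
        r = sxy / np.sqrt(sxx * ((y - y.mean()) ** 2).sum())
        assert fit.slope == pytest.approx(slope, abs=1e-10)
        assert fit.intercept == pytest.approx(intercept, abs=1e-10)
        assert fit.r == pytest.approx(r, abs=1e-10)

    def test_too_few_levels_errors(self):
        std = pd.DataFrame({"expected_fraction": [0, 1], "measured_percent": [0, 100]})
        with pytest.raises(ValueError, match="distinct"):
            assay_linearity(std)


class TestInterTissue:
    def _paired(self, pbl, hf):
        rows = []
        for i, (a, b) in enumerate(zip(pbl, hf)):
            rows.append((f"s{i}", "Caucasian", "PBL", "BOLA3", 1, a))
            rows.append((f"s{i}", "Caucasian", "HF", "BOLA3", 1, b))
        return _measurements(rows)

    def test_identical_vectors(self):
        v = [10.0, 30.0, 50.0, 70.0]
        r = inter_tissue_correlation(self._paired(v, v), "BOLA3", ("PBL", "HF"))
        assert r.r == pytest.approx(1.0)

    def test_negated_vector(self):
        v = np.array([10.0, 30.0, 50.0, 70.0])
        r = inter_tissue_correlation(self._paired(v, 100 - v), "BOLA3", ("PBL", "HF"))
        assert r.r == pytest.approx(-1.0)

    def test_systemic_simulation_matches_closed_form(self):
        rng = np.random.default_rng(3)
        shared = rng.normal(50, 10, 8)
        pbl = shared + rng.normal(0, 2, 8)
        hf = shared + rng.normal(0, 2, 8)
        r = inter_tissue_correlation(self._paired(pbl, hf), "BOLA3", ("PBL", "HF"))
        assert r.r > 0.8
        # closed-form Pearson on the same vectors
        expected = np.corrcoef(pbl, hf)[0, 1]
        assert r.r == pytest.approx(expected, abs=1e-12)

    def test_replicates_averaged_before_correlation(self):
        rows = [
            ("s0", "Caucasian", "PBL", "BOLA3", 1, 10.0),
            ("s0", "Caucasian", "PBL", "BOLA3", 2, 30.0),  # mean 20
            ("s0", "Caucasian", "HF", "BOLA3", 1, 20.0),
            ("s1", "Caucasian", "PBL", "BOLA3", 1, 40.0),
            ("s1", "Caucasian", "HF", "BOLA3", 1, 40.0),
            ("s2", "Caucasian", "PBL", "BOLA3", 1, 60.0),
            ("s2", "Caucasian", "HF", "BOLA3", 1, 60.0),
        ]
        r = inter_tissue_correlation(_measurements(rows), "BOLA3", ("PBL", "HF"))
        assert r.r == pytest.approx(1.0)

    def test_zero_variance_flagged(self):
        v = [50.0, 50.0, 50.0]
        r = inter_tissue_correlation(self._paired(v, [10.0, 20.0, 30.0]), "BOLA3", ("PBL", "HF"))
        assert r.degenerate and np.isnan(r.r)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(4)
        pbl, hf = rng.uniform(20, 80, 10), rng.uniform(20, 80, 10)
        base = inter_tissue_correlation(self._paired(pbl, hf), "BOLA3", ("PBL", "HF"))
        scaled = inter_tissue_correlation(
            self._paired(pbl * 0.5 + 10, hf), "BOLA3", ("PBL", "HF")
        )
        assert scaled.r == pytest.approx(base.r, abs=1e-12)


class TestTwins:
    def test_duplicated_members_fully_concordant(self):
        tw = sim.gen_twins(sim.TwinsConfig(seed=1, intra_pair_r=(("PAX8", 1.0),), technical_sd=0.0))
        c = twin_concordance(tw["pair_measurements"], tw["replicate_measurements"], "PAX8")
        assert c.intra_pair_r == pytest.approx(1.0)
        assert c.nonshared_fraction == pytest.approx(0.0)

    def test_independent_members_near_zero(self):
        rs = []
        for seed in range(15):
            tw = sim.gen_twins(sim.TwinsConfig(seed=seed, intra_pair_r=(("PAX8", 0.0),), n_pairs=30))
            c = twin_concordance(tw["pair_measurements"], tw["replicate_measurements"], "PAX8", seed=seed)
            rs.append(c.intra_pair_r)
        assert abs(np.mean(rs)) < 0.12
        assert np.mean([1 - np.clip(r, 0, 1) for r in rs]) > 0.8

    def test_planted_correlation_recovered(self):
        rs = [
            twin_concordance(
                (tw := sim.gen_twins(sim.TwinsConfig(seed=s)))["pair_measurements"],
                tw["replicate_measurements"], "PAX8", seed=s,
            ).intra_pair_r
            for s in range(15)
        ]
        assert np.mean(rs) == pytest.approx(0.5, abs=0.15)

    def test_member_order_seed_stability(self):
        tw = sim.gen_twins(sim.TwinsConfig(seed=6, intra_pair_r=(("PAX8", 0.6),), n_pairs=30))
        rs = [
            twin_concordance(
                tw["pair_measurements"], tw["replicate_measurements"], "PAX8", seed=s
            ).intra_pair_r
            for s in range(100)
        ]
        assert np.std(rs) < 0.05

    def test_incomplete_pair_excluded(self, caplog):
        tw = sim.gen_twins(sim.TwinsConfig(seed=2, intra_pair_r=(("PAX8", 0.5),), n_pairs=6))
        pm = tw["pair_measurements"]
        pm = pm[~((pm["pair_id"] == "T001") & (pm["sample_id"] == "T001_2"))]
        with caplog.at_level("WARNING"):
            c = twin_concordance(pm, tw["replicate_measurements"], "PAX8")
        assert c.n_pairs == 5
        assert "excluded" in caplog.text


class TestGenotypeAssociation:
    def _data(self, means, sizes, sd, seed=0):
        rng = np.random.default_rng(seed)
        rows_m, rows_g = [], []
        i = 0
        for geno, mu, n in zip(("AA", "AB", "BB"), means, sizes):
            for _ in range(n):
                sid = f"s{i}"
                rows_m.append((sid, "Gambian", "PBL", "ZNF696", 1, float(np.clip(rng.normal(mu, sd), 0, 100))))
                rows_g.append((sid, "rs1", geno))
                i += 1
        return _measurements(rows_m), pd.DataFrame(rows_g, columns=["sample_id", "snp_id", "genotype"])

    def test_equal_means_no_effect(self):
        m, g = self._data((50, 50, 50), (10, 10, 10), sd=3)
        r = genotype_association(m, g, "ZNF696", "rs1")
        assert r.r_squared < 0.2

    def test_planted_separation_explains_variance(self):
        # group sizes as in the genotype-predicts-methylation example: 25/10/5
        m, g = self._data((20, 40, 60), (25, 10, 5), sd=3, seed=1)
        r = genotype_association(m, g, "ZNF696", "rs1")
        assert r.r_squared > 0.7
        assert r.p_value < 1e-6

    def test_hand_computed_anova_table(self):
        rows_m = [
            ("a1", "x", "PBL", "L", 1, 10.0), ("a2", "x", "PBL", "L", 1, 20.0),
            ("b1", "x", "PBL", "L", 1, 30.0), ("b2", "x", "PBL", "L", 1, 40.0),
            ("c1", "x", "PBL", "L", 1, 50.0), ("c2", "x", "PBL", "L", 1, 60.0),
        ]
        rows_g = [("a1", "rs1", "AA"), ("a2", "rs1", "AA"), ("b1", "rs1", "AB"),
                  ("b2", "rs1", "AB"), ("c1", "rs1", "BB"), ("c2", "rs1", "BB")]
        r = genotype_association(
            _measurements(rows_m), pd.DataFrame(rows_g, columns=["sample_id", "snp_id", "genotype"]),
            "L", "rs1",
        )
        # by hand: grand mean 35; SSB = 2*(400+0+400) = 1600; SSW = 3*50 = 150
        # F = (1600/2) / (150/3) = 16
        assert r.f_statistic == pytest.approx(16.0, rel=1e-12)
        assert r.r_squared == pytest.approx(1600 / 1750, rel=1e-12)

    def test_single_group_errors(self):
        m, g = self._data((50, 50, 50), (6, 0, 0), sd=1)
        with pytest.raises(ValueError, match="genotype groups"):
            genotype_association(m, g, "ZNF696", "rs1")


class TestPopulations:
    def test_single_value_quantiles(self):
        m = _measurements([("s0", "Gambian", "PBL", "PAX8", 1, 42.0)])
        row = population_compare(m, "PAX8").iloc[0]
        assert row["p5"] == row["median"] == row["p95"] == 42.0

    def test_uniform_median_near_fifty(self):
        rng = np.random.default_rng(11)
        rows = [(f"s{i}", "Gambian", "PBL", "PAX8", 1, float(v))
                for i, v in enumerate(rng.uniform(0, 100, 4000))]
        row = population_compare(_measurements(rows), "PAX8").iloc[0]
        assert row["median"] == pytest.approx(50, abs=3)

    def test_quantiles_match_percentile_oracle(self):
        rng = np.random.default_rng(12)
        values = rng.uniform(10, 90, 37)
        rows = [(f"s{i}", "Asian", "PBL", "PAX8", 1, float(v)) for i, v in enumerate(values)]
        row = population_compare(_measurements(rows), "PAX8").iloc[0]
        for col, q in (("p5", 5), ("q1", 25), ("median", 50), ("q3", 75), ("p95", 95)):
            assert row[col] == pytest.approx(np.percentile(values, q))
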