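"""Variant annotation, the exclusion cascade, and enrichment arithmetic."""

import numpy as np
import pandas as pd
import pytest

from mescreen import simulate as sim
from mescreen.digest import DigestConfig, enumerate_intervals, find_sites, intervals_to_frame
from mescreen.variants import (
    SequenceVariant,
    StructuralRegion,
    empty_annotations,
    enrichment_test,
    filter_candidates,
    flag_creating_snps,
    flag_site_snps,
    flag_structural_overlap,
    variant_creates_motif,
)


def _toy_genome(n_between=70):
    """Two CCCGGG sites separated by an A-run: one 70+6 bp interval (cut-to-cut 76)."""
    seq = "T" * 10 + "CCCGGG" + "A" * n_between + "CCCGGG" + "T" * 10
    return {"c": seq}


def _toy_intervals(genome):
    seq = genome["c"]
    return intervals_to_frame(enumerate_intervals(find_sites(seq, "c"), DigestConfig(10, 5000)))


class TestSiteSnps:
    def test_variant_inside_flank_motif_flags(self):
        genome = _toy_genome()
        ivs = _toy_intervals(genome)
        # left motif starts at 10; position 12 is motif_start + 2 (ref C)
        ann = flag_site_snps(ivs, [SequenceVariant("c", 12, "C", "T")], genome)
        assert ann["disrupts_site"].tolist() == [True]

    def test_variant_one_bp_left_of_motif_does_not_flag(self):
        genome = _toy_genome()
        ivs = _toy_intervals(genome)
        ann = flag_site_snps(ivs, [SequenceVariant("c", 9, "T", "A")], genome)
        assert ann["disrupts_site"].tolist() == [False]

    def test_ref_mismatch_skipped(self, caplog):
        genome = _toy_genome()
        ivs = _toy_intervals(genome)
        with caplog.at_level("WARNING"):
            ann = flag_site_snps(ivs, [SequenceVariant("c", 12, "G", "T")], genome)
        assert ann["disrupts_site"].tolist() == [False]
        assert "ref mismatch" in caplog.text

    def test_planted_variants_match_generator_truth(self):
        genome, truth = sim.gen_genome(sim.GenomeConfig(seed=21, n_eligible=30))
        seq = genome["chr_sim"]
        ivs = intervals_to_frame(
            enumerate_intervals(find_sites(seq, "chr_sim"), DigestConfig())
        )
        rng = np.random.default_rng(0)
        flagged_truth, variants = set(), []
        for row in ivs.sample(10, random_state=1).itertuples(index=False):
            offset = int(rng.integers(0, 6))
            pos = row.start - 3 + offset
            ref = seq[pos]
            alt = "T" if ref != "T" else "A"
            variants.append(SequenceVariant("chr_sim", pos, ref, alt))
            flagged_truth.add(row.interval_id)
            # the shared cut site also flags the adjacent interval
            left_neighbor = ivs[ivs["end"] == row.start]
            flagged_truth.update(left_neighbor["interval_id"])
        ann = flag_site_snps(ivs, variants, genome)
        got = set(ann.loc[ann["disrupts_site"], "interval_id"])
        assert got == flagged_truth


class TestCreatingSnps:
    def test_near_motif_completion_flags(self):
        # interval body contains CCCGGA; A->G completes the motif
        seq = "T" * 10 + "CCCGGG" + "A" * 20 + "CCCGGA" + "A" * 20 + "CCCGGG" + "T" * 10
        genome = {"c": seq}
        ivs = _toy_intervals(genome)
        pos = seq.index("CCCGGA") + 5
        ann = flag_creating_snps(ivs, [SequenceVariant("c", pos, "A", "G")], genome)
        assert ann["creates_site"].tolist() == [True]
        ann2 = flag_creating_snps(ivs, [SequenceVariant("c", pos, "A", "T")], genome)
        assert ann2["creates_site"].tolist() == [False]

    def test_exhaustive_substitutions_match_rescan_oracle(self):
        # every single-base substitution of a 30-bp sequence, vs full rescan
        seq = "ACCCGGATCCCGGGTACCGGGCCCTGGGAT"
        genome = {"c": seq}
        for pos in range(len(seq)):
            for alt in "ACGT":
                if alt == seq[pos]:
                    continue
                mutated = seq[:pos] + alt + seq[pos + 1 :]
                ref_starts = {i for i in range(len(seq) - 5) if seq[i : i + 6] == "CCCGGG"}
                mut_starts = {
                    i for i in range(len(mutated) - 5) if mutated[i : i + 6] == "CCCGGG"
                }
                expected = sorted(mut_starts - ref_starts)
                got = variant_creates_motif(SequenceVariant("c", pos, seq[pos], alt), genome)
                assert got == expected, (pos, alt)


class TestStructuralOverlap:
    IVS = pd.DataFrame(
        {"interval_id": ["iv1"], "contig": ["c"], "start": [100], "end": [200], "length": [100]}
    )

    def test_partial_overlap_flags(self):
        ann = flag_structural_overlap(self.IVS, [StructuralRegion("c", 150, 160, "CNV")])
        assert ann["in_cnv"].tolist() == [True]

    def test_half_open_abutment_does_not_flag(self):
        ann = flag_structural_overlap(self.IVS, [StructuralRegion("c", 200, 300, "CNV")])
        assert ann["in_cnv"].tolist() == [False]

    def test_containment_flags_segdup(self):
        ann = flag_structural_overlap(self.IVS, [StructuralRegion("c", 0, 1000, "segdup")])
        assert ann["in_segdup"].tolist() == [True]
        assert ann["in_cnv"].tolist() == [False]

    def test_full_containment_mode(self):
        region = [StructuralRegion("c", 150, 400, "CNV")]
        any_mode = flag_structural_overlap(self.IVS, region, containment="any")
        full_mode = flag_structural_overlap(self.IVS, region, containment="full")
        assert any_mode["in_cnv"].tolist() == [True]
        assert full_mode["in_cnv"].tolist() == [False]


def _historical_scale_annotations():
    """107 candidates: 34 SNP-flagged, then 35 of the remaining 73 in CNV/segdup."""
    ids = [f"iv{i:03d}" for i in range(107)]
    ann = empty_annotations(ids)
    ann.loc[:33, "disrupts_site"] = True
    ann.loc[34 : 34 + 34, "in_cnv"] = True  # 35 of the SNP-clean ones
    return ids, ann


class TestCascade:
    def test_historical_stage_counts(self):
        ids, ann = _historical_scale_annotations()
        # one rescued candidate from each stage, mirroring ZNF696 and FLJ20433
        result = filter_candidates(ids, ann, retain_ids=["iv000", "iv034"])
        assert result.n_input == 107
        assert result.n_after_snp == 73
        assert result.n_after_structural == 38
        assert result.n_final == 40
        assert set(result.rescued) == {"iv000", "iv034"}

    def test_identity_without_flags(self):
        ids = ["a", "b", "c"]
        result = filter_candidates(ids, empty_annotations(ids))
        assert result.surviving == ids

    def test_idempotent_on_own_output(self):
        ids, ann = _historical_scale_annotations()
        first = filter_candidates(ids, ann)
        second = filter_candidates(first.surviving, ann)
        assert second.surviving == first.surviving

    def test_unknown_retain_id_errors(self):
        ids = ["a"]
        with pytest.raises(ValueError, match="retain"):
            filter_candidates(ids, empty_annotations(ids), retain_ids=["zzz"])

    def test_removes_all_planted_artifacts_and_no_clean_loci(self, small_msam):
        data, _ = small_msam
        truth = data["truth"]
        ann = empty_annotations(truth["interval_id"])
        ann = ann.set_index("interval_id")
        snp_ids = truth.loc[truth["planted_class"] == "snp_artifact", "interval_id"]
        cnv_ids = truth.loc[truth["planted_class"] == "cnv_artifact", "interval_id"]
        ann.loc[snp_ids, "disrupts_site"] = True
        ann.loc[cnv_ids, "in_cnv"] = True
        ann = ann.reset_index()
        candidates = list(truth["interval_id"])
        result = filter_candidates(candidates, ann)
        flagged = set(snp_ids) | set(cnv_ids)
        assert set(result.removed_snp) | set(result.removed_structural) == flagged
        assert set(result.surviving) == set(candidates) - flagged


def _chi2_oracle(table):
    """Independent Pearson chi-square: sum (O-E)^2 / E over the 2x2 table."""
    table = np.asarray(table, dtype=float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    return float(((table - expected) ** 2 / expected).sum())


class TestEnrichment:
    def test_against_independent_oracle(self):
        r = enrichment_test(10, 100, 100, 10_000)
        chi2 = _chi2_oracle([[10, 90], [100, 9900]])
        assert r.chi_square == pytest.approx(chi2, rel=1e-12)
        from scipy.stats import chi2 as chi2_dist

        assert r.p_value == pytest.approx(chi2_dist.sf(chi2, 1), rel=1e-12)

    def test_equal_fractions_give_null(self):
        r = enrichment_test(10, 100, 100, 1000)
        assert r.chi_square == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_historical_counts_give_order_e8(self):
        # 34 of 107 screen hits carried site SNPs vs 11,943 of 90,807 intervals
        r = enrichment_test(34, 107, 11_943, 90_807)
        assert 1e-9 < r.p_value < 1e-7

    def test_transpose_invariance(self):
        a = enrichment_test(10, 100, 100, 10_000)
        b = _chi2_oracle([[10, 100], [90, 9900]])
        assert a.chi_square == pytest.approx(b, rel=1e-12)

    def test_zero_margin_errors(self):
        with pytest.raises(ValueError, match="margin"):
            enrichment_test(0, 100, 0, 1000)
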