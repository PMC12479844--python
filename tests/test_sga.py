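import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pombescreen import (
    SGAExperiment,
    StrainAnnotation,
    annotation_map,
    classify_interaction,
    control_size_filter,
    interaction_counts,
    interaction_score,
    linkage_filter,
    physical_map,
    replicate_cv,
    rowcol_normalize,
    score_sga,
    variability_filter,
)
from pombescreen.config import ScreenConfig
from pombescreen.simulate import gen_genome, gen_sga_experiment

from conftest import make_plate


class TestLinkageFilter:
    def test_inclusive_30kb_boundary(self):
        anns = [
            StrainAnnotation("near", "I", 100_000 - 29_999),
            StrainAnnotation("edge", "I", 100_000 + 30_000),
            StrainAnnotation("far", "I", 100_000 + 30_001),
            StrainAnnotation("other_chr", "II", 100_000),
        ]
        excluded = linkage_filter(anns, ("I", 100_000))
        assert excluded == {"near", "edge"}

    def test_matches_bruteforce_scan(self):
        genome = gen_genome(100, seed=7)
        qpos = ("I", 2_000_000)
        brute = {
            a.strain_id
            for a in genome
            if a.chromosome == qpos[0] and abs(a.position_bp - qpos[1]) <= 30_000
        }
        assert linkage_filter(genome, qpos) == brute


class TestControlSizeFilter:
    def test_strict_50px_boundary(self):
        medians = {"tiny": 49.0, "edge": 50.0, "ok": 51.0}
        assert control_size_filter(medians) == {"tiny"}


class TestRowColNormalize:
    def test_separable_gradient_removed_exactly(self):
        r = np.exp(0.4 * np.linspace(-0.5, 0.5, 8))
        c = np.exp(-0.3 * np.linspace(-0.5, 0.5, 12))
        plate = make_plate(np.outer(r, c))
        out = rowcol_normalize(plate)
        assert np.nanmax(np.abs(out.sizes - 1.0)) < 1e-9

    def test_constant_plate_unchanged(self):
        out = rowcol_normalize(make_plate(np.full((6, 6), 1.0)))
        assert np.allclose(out.sizes, 1.0)

    def test_all_missing_row_warns_factor_one(self):
        sizes = np.ones((4, 4))
        sizes[2, :] = np.nan
        with pytest.warns(UserWarning, match="rows"):
            out = rowcol_normalize(make_plate(sizes))
        assert np.allclose(out.sizes[~np.isnan(out.sizes)], 1.0)

    def test_polish_also_exact_on_separable(self):
        r = np.exp(0.5 * np.linspace(-0.5, 0.5, 10))
        c = np.exp(0.2 * np.linspace(-0.5, 0.5, 10))
        out = rowcol_normalize(make_plate(np.outer(r, c)), method="polish")
        assert np.nanmax(np.abs(out.sizes - 1.0)) < 1e-9


class TestInteractionScore:
    @pytest.mark.parametrize(
        "q,c,expected",
        [(0.8, 0.8, 0.0), (10.0, 1.0, 100.0), (1.4125, 1.0, 15.0)],
    )
    def test_score_values(self, q, c, expected, config):
        assert interaction_score(q, c, config) == pytest.approx(expected, abs=0.01)

    def test_zero_median_is_error(self, config):
        with pytest.raises(ValueError, match="> 0"):
            interaction_score(1.0, 0.0, config)

    @given(st.floats(min_value=0.05, max_value=20.0), st.floats(min_value=0.05, max_value=20.0))
    def test_antisymmetric_in_arguments(self, q, c):
        cfg = ScreenConfig()
        assert interaction_score(q, c, cfg) == pytest.approx(-interaction_score(c, q, cfg))


class TestVariabilityFilter:
    def test_identical_replicates_retained(self):
        assert variability_filter(np.array([100.0, 100, 100, 100])) == ""

    def test_outlier_quadruplicate_flagged(self):
        assert variability_filter(np.array([100.0, 100, 100, 1000])) == "high_variability"

    def test_single_replicate_insufficient(self):
        assert variability_filter(np.array([100.0])) == "insufficient_replicates"

    @pytest.mark.parametrize("seed", range(4))
    def test_cv_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.uniform(50, 500, 4)
        mean = sum(v) / 4
        sd = (sum((x - mean) ** 2 for x in v) / 3) ** 0.5
        assert replicate_cv(v) == pytest.approx(sd / mean)


class TestClassifyInteraction:
    @pytest.mark.parametrize(
        "score,label",
        [(-16, "negative"), (16, "positive"), (0, "none"), (-15, "none"), (15, "none")],
    )
    def test_cutoffs(self, score, label, config):
        assert classify_interaction(score, config) == label


def _small_sga(seed=21, **kwargs):
    genome = gen_genome(400, seed=seed)
    amap = annotation_map(genome)
    query = genome[50].strain_id
    qp, cp, truth = gen_sga_experiment(genome, query, seed=seed, **kwargs)
    exp = SGAExperiment(query, qp, cp, amap, truth.control_query_id)
    return genome, amap, exp, truth


class TestScoreSga:
    def test_antisymmetry_under_array_swap(self):
        genome, amap, exp, truth = _small_sga()
        fwd = score_sga(exp).set_index("library_gene")
        swapped = SGAExperiment(
            truth.control_query_id, exp.control_plates, exp.query_plates, amap, exp.query_id
        )
        rev = score_sga(swapped).set_index("library_gene")
        both = fwd.join(rev, lsuffix="_f", rsuffix="_r")
        ok = both[(both.qc_f == "") & (both.qc_r == "")]
        assert len(ok) > 200
        assert np.allclose(ok.score_f, -ok.score_r)

    def test_flagged_records_carry_no_label(self):
        _, _, exp, _ = _small_sga()
        rec = score_sga(exp)
        flagged = rec[rec.qc != ""]
        assert (flagged.label == "").all()
        counts = interaction_counts(rec)
        assert counts["scored"] == (rec.qc == "").sum()

    def test_linked_genes_flagged_not_classified(self):
        _, _, exp, truth = _small_sga()
        rec = score_sga(exp).set_index("library_gene")
        for gene in truth.linked_set:
            assert "linked" in rec.loc[gene, "qc"]

    def test_filter_composition_is_order_independent(self, config):
        genome, amap, exp, truth = _small_sga()
        q_ann = amap[exp.query_id]
        c_ann = amap[exp.control_query_id]
        linked = linkage_filter(amap, (q_ann.chromosome, q_ann.position_bp)) | linkage_filter(
            amap, (c_ann.chromosome, c_ann.position_bp)
        )
        from pombescreen.sga import _gene_values

        raw = {
            g: float(np.nanmedian(v)) for g, v in _gene_values(exp.control_plates).items()
        }
        small = control_size_filter(raw, config.min_control_colony_px)
        highvar = {
            g
            for g, v in _gene_values(exp.query_plates).items()
            if variability_filter(v[np.isfinite(v)], config.cv_max) == "high_variability"
        }
        # union in any order is the same set
        assert (linked | small) | highvar == highvar | (small | linked)
        rec = score_sga(exp, config)
        flagged_any = set(rec[rec.qc != ""].library_gene)
        assert (linked | small | highvar) <= flagged_any


class TestPhysicalMap:
    def test_empty_records_give_empty_track(self):
        pm = physical_map(
            pd.DataFrame(columns=["library_gene", "score", "chromosome", "position_bp"]),
            [StrainAnnotation("g", "I", 10)],
            {"g": ("I", 10)},
        )
        assert pm.track.empty

    def test_track_is_genome_ordered(self):
        _, amap, exp, truth = _small_sga()
        rec = score_sga(exp)
        pm = physical_map(rec, amap)
        for _, grp in pm.track.groupby("chromosome"):
            assert grp["position_bp"].is_monotonic_increasing

    def test_no_scored_gene_inside_window_after_filtering(self, config):
        _, amap, exp, truth = _small_sga()
        rec = score_sga(exp, config)
        scored = rec[rec.label != ""]
        q = amap[exp.query_id]
        scored_pos = scored.merge(
            pd.DataFrame(
                [(a.strain_id, a.chromosome, a.position_bp) for a in amap.values()],
                columns=["library_gene", "chrom", "pos"],
            ),
            on="library_gene",
        )
        near = (scored_pos.chrom == q.chromosome) & (
            (scored_pos.pos - q.position_bp).abs() <= config.linkage_window_bp
        )
        assert not near.any()
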