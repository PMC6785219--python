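"""hairpin_rf: product naming, the 71-feature vector, training, prediction."""

import numpy as np
import pytest

from mirstack.folding import fold
from mirstack.hairpin import (
    HPRF_FEATURES,
    build_hprf_training_set,
    distribution_features,
    hairpin_feature_vector,
    name_products,
    neighbor_count,
    overlap_shift_features,
    predict,
    variance_features,
    _compute_candidate_duplex,
)
from mirstack.io import (
    SampleLibrary,
    annotate_hit_counts,
    group_read_regions,
    revcomp,
)
from mirstack.spans import HairpinCandidate, duplex_focused_span

from conftest import read

MIR = "ACGTACGGATCGTACGTACGTC"
LOOP = "TTCGTTAATTCG"


def hairpin_setup(star_reads=True, mor_reads=False, loop_reads=False):
    """A planted hairpin genome plus read stacks; returns (genome, regions,
    candidate) with the candidate's duplex computed."""
    genome = {"chr1": "T" * 100 + MIR + LOOP + revcomp(MIR) + "T" * 100}
    star_start = 100 + len(MIR) + len(LOOP)
    reads = [read(chrom="chr1", start=100, seq=MIR, dup=10, rid="mir_x10")]
    if star_reads:
        reads.append(
            read(chrom="chr1", start=star_start,
                 seq=genome["chr1"][star_start : star_start + len(MIR)],
                 dup=3, rid="star_x3")
        )
    if mor_reads:
        reads.append(
            read(chrom="chr1", start=80, seq=genome["chr1"][80:100], dup=2,
                 rid="mor_x2")
        )
    if loop_reads:
        loop_span = (100 + len(MIR) - 2, 100 + len(MIR) + len(LOOP) + 2)
        reads.append(
            read(chrom="chr1", start=loop_span[0],
                 seq=genome["chr1"][loop_span[0] : loop_span[1]], dup=1,
                 rid="loop_x1")
        )
    reads = annotate_hit_counts(reads)
    regions = group_read_regions(reads)
    major = max(regions, key=lambda g: g.dup_total)
    cand = duplex_focused_span(major, genome)
    assert cand is not None
    _compute_candidate_duplex(cand, genome)
    return genome, regions, cand


class TestNameProducts:
    def test_duplex_register_pair_named_mir_5p_and_3p(self):
        _, regions, cand = hairpin_setup(star_reads=True)
        products = name_products(cand, regions)
        labels = sorted(p.label for p in products)
        assert labels == ["miR-3p", "miR-5p"]
        majors = [p for p in products if p.is_major]
        assert len(majors) == 1 and majors[0].label == "miR-5p"

    def test_upstream_stack_on_same_arm_is_mor(self):
        _, regions, cand = hairpin_setup(star_reads=True, mor_reads=True)
        products = name_products(cand, regions)
        by_label = {p.label: p for p in products}
        assert "moR-5p" in by_label

    def test_loop_spanning_stack_labeled_loop(self):
        _, regions, cand = hairpin_setup(star_reads=True, loop_reads=True)
        products = name_products(cand, regions)
        assert any(p.label == "loop" for p in products)

    def test_exactly_one_major_and_reads_partitioned(self):
        _, regions, cand = hairpin_setup(True, True, True)
        products = name_products(cand, regions)
        assert sum(p.is_major for p in products) == 1
        in_span = [
            g for g in regions if g.overlaps(cand.start, cand.end)
            and g.strand == cand.strand
        ]
        # cut products partition the member regions' reads
        assert sum(len(p.region.reads) for p in products) == sum(
            len(g.reads) for g in in_span
        )


class TestDistributionFeatures:
    def test_unique_reads_give_unit_hit_count(self):
        _, regions, cand = hairpin_setup()
        products = name_products(cand, regions)
        lib = SampleLibrary("s", 13.0)
        feats = distribution_features(products, cand, lib, [])
        assert feats["ahc"] == 1.0
        assert feats["urf"] == pytest.approx(1.0)

    def test_average_hit_count_hand_value(self):
        reads = [
            read(chrom="chr1", start=100, seq=MIR, dup=2, nh=1, rid="a"),
            read(chrom="chr1", start=101, seq=MIR[1:] + "A", dup=2, nh=1, rid="b"),
            read(chrom="chr1", start=102, seq=MIR[2:] + "AA", dup=2, nh=3, rid="c"),
        ]
        genome = {"chr1": "T" * 100 + MIR + LOOP + revcomp(MIR) + "T" * 100}
        regions = group_read_regions(reads)
        cand = duplex_focused_span(regions[0], genome)
        _compute_candidate_duplex(cand, genome)
        products = name_products(cand, regions)
        feats = distribution_features(
            products, cand, SampleLibrary("s", 100.0), []
        )
        assert feats["ahc"] == pytest.approx(5 / 3)

    def test_locus_holding_all_sense_reads_is_one_million_arpm(self):
        _, regions, cand = hairpin_setup()
        products = name_products(cand, regions)
        total = sum(r.dup_count / r.hit_count for p in products
                    for r in p.region.reads)
        lib = SampleLibrary("s", total)
        feats = distribution_features(products, cand, lib, [])
        assert feats["totalSenseRPM"] == pytest.approx(1e6)

    def test_product_fractions_sum_to_one_within_locus(self):
        _, regions, cand = hairpin_setup(True, True, True)
        products = name_products(cand, regions)
        feats = distribution_features(
            products, cand, SampleLibrary("s", 100.0), []
        )
        frac_sum = sum(
            feats[k] for k in feats if k.endswith("Frac")
        )
        assert frac_sum == pytest.approx(1.0)


class TestOverlapShiftFeatures:
    def test_disjoint_products_have_zero_overlaps(self):
        _, regions, cand = hairpin_setup(star_reads=True)
        products = name_products(cand, regions)
        feats = overlap_shift_features(products, cand, [])
        assert feats["totalOverlap"] == 0.0
        assert feats["miR5pmiR3pOverlap"] == 0.0
        assert feats["tapd"] == 0.0 and feats["aapd"] == 0.0

    def test_mir_mor_overlap_interval_arithmetic(self):
        genome = {"chr1": "T" * 100 + MIR + LOOP + revcomp(MIR) + "T" * 100}
        reads = [
            read(chrom="chr1", start=100, seq=MIR, dup=10, rid="mir"),
            # moR overlapping the miR 5' end by 2 nt
            read(chrom="chr1", start=82, seq=genome["chr1"][82:102], dup=2,
                 rid="mor"),
        ]
        reads = annotate_hit_counts(reads)
        regions = group_read_regions(reads)
        major = max(regions, key=lambda g: g.dup_total)
        cand = duplex_focused_span(major, genome)
        _compute_candidate_duplex(cand, genome)
        products = name_products(cand, regions)
        feats = overlap_shift_features(products, cand, [])
        assert feats["miR5pmoR5pOverlap"] == 2.0
        assert feats["totalOverlap"] == 2.0

    def test_antisense_displacement_zero_without_antisense_reads(self):
        _, regions, cand = hairpin_setup()
        products = name_products(cand, regions)
        feats = overlap_shift_features(products, cand, [])
        assert feats["tapd"] == 0.0 and feats["aapd"] == 0.0


class TestVarianceFeatures:
    def test_single_distinct_read_products_have_zero_variance(self):
        _, regions, cand = hairpin_setup()
        products = name_products(cand, regions)
        feats = variance_features(products)
        assert feats["APV"] == 0.0 and feats["ARV"] == 0.0

    def test_population_variance_of_counts(self):
        reads = [
            read(chrom="chr1", start=100, seq=MIR, dup=4, rid="a"),
            read(chrom="chr1", start=100, seq=MIR[:-1] + "A", dup=2, rid="b"),
        ]
        genome = {"chr1": "T" * 100 + MIR + LOOP + revcomp(MIR) + "T" * 100}
        regions = group_read_regions(annotate_hit_counts(reads))
        cand = duplex_focused_span(regions[0], genome)
        _compute_candidate_duplex(cand, genome)
        products = name_products(cand, regions)
        feats = variance_features(products)
        assert feats["APV"] == pytest.approx(1.0)  # var({4,2}) population

    def test_warv_equals_arv_for_equal_length_products(self):
        _, regions, cand = hairpin_setup(star_reads=True)
        products = name_products(cand, regions)
        if len({p.local_span[1] - p.local_span[0] for p in products}) == 1:
            feats = variance_features(products)
            assert feats["wARV"] == pytest.approx(feats["ARV"])


class TestNeighborCount:
    def _candidate(self):
        genome = {"chr1": "T" * 100 + MIR + LOOP + revcomp(MIR) + "T" * 5000}
        (g,) = group_read_regions(
            [read(chrom="chr1", start=100, seq=MIR, dup=5)]
        )
        cand = duplex_focused_span(g, genome)
        return cand

    def test_isolated_candidate_has_no_neighbors(self):
        cand = self._candidate()
        assert neighbor_count(cand, []) == 0

    @pytest.mark.parametrize("distance,expected", [(400, 1), (999, 1), (1001, 0)])
    def test_window_is_inclusive_at_1000(self, distance, expected):
        cand = self._candidate()
        (far,) = group_read_regions(
            [read(chrom="chr1", start=cand.end + distance, seq="C" * 22)]
        )
        assert neighbor_count(cand, [far]) == expected


class TestFeatureVector:
    def test_71_features_all_finite(self):
        genome, regions, cand = hairpin_setup(True, True, True)
        products = name_products(cand, regions)
        lib = SampleLibrary("s", 100.0)
        vec = hairpin_feature_vector(
            cand, products, lib, {}, regions, [], genome
        )
        assert vec.shape == (71,)
        assert np.all(np.isfinite(vec))
        assert len(HPRF_FEATURES) == len(set(HPRF_FEATURES)) == 71

    def test_single_product_candidate_zero_overlaps_and_own_score(self):
        genome, regions, cand = hairpin_setup(star_reads=False)
        products = name_products(cand, regions)
        scores = {id(products[0].parent): 0.87}
        vec = hairpin_feature_vector(
            cand, products, SampleLibrary("s", 100.0), scores, regions, [],
            genome,
        )
        assert vec[HPRF_FEATURES.index("totalOverlap")] == 0.0
        assert vec[HPRF_FEATURES.index("RFProductAvg")] == pytest.approx(0.87)


class TestTraining:
    def test_best_reciprocal_overlap_candidate_is_positive(self, small_fixture,
                                                           trained_models):
        from mirstack import pipeline

        mprf, hprf, cfg = trained_models
        reads, regions = pipeline.prepare_regions(list(small_fixture.reads))
        lib = SampleLibrary.from_reads(reads)
        X, ms, passing = pipeline._mprf_pass(
            regions, small_fixture.genome, mprf, cfg.mprf_threshold
        )
        mprf_scores = {id(g): float(s) for g, s in zip(regions, ms)}
        cands = pipeline.generate_candidates(passing, small_fixture.genome, cfg)
        cands, vecs = pipeline._candidate_vectors(
            cands, regions, reads, small_fixture.genome, lib, mprf_scores, cfg
        )
        Xh, yh, order = build_hprf_training_set(
            cands, vecs, small_fixture.annotations, ratio_x=25, seed=1
        )
        assert (yh == 1).sum() >= 1
        assert (yh == 0).sum() <= 25 * (yh == 1).sum()
        # every positive overlaps an annotated precursor on its strand
        precursors = [
            a for a in small_fixture.annotations if a.kind == "precursor"
        ]
        for idx, label in zip(order, yh):
            if label == 1:
                c = cands[idx]
                assert any(
                    a.chrom == c.chrom and a.strand == c.strand
                    and a.overlaps(c.start, c.end)
                    for a in precursors
                )

    def test_no_overlapping_candidates_is_an_error(self):
        with pytest.raises(ValueError):
            build_hprf_training_set([], [], [], 25, 0)


class _StubForest:
    """Deterministic stand-in forest emitting preset decision values."""

    classes_ = [0, 1]

    def __init__(self, scores):
        self._scores = scores

    def predict_proba(self, X):
        s = np.asarray(self._scores[: len(X)], dtype=float)
        return np.c_[1 - s, s]


class TestPredictThresholds:
    def _cand_and_vec(self, rpm):
        genome, regions, cand = hairpin_setup()
        products = name_products(cand, regions)
        lib = SampleLibrary("s", 13.0 * 1e6 / rpm)  # locus adj = 13 -> rpm
        vec = hairpin_feature_vector(
            cand, products, lib, {}, regions, [], genome
        )
        return cand, vec, lib

    def test_passing_score_and_expression_kept(self):
        from mirstack.mature import ForestModel

        cand, vec, lib = self._cand_and_vec(rpm=0.2)
        model = ForestModel(_StubForest([0.30]), list(HPRF_FEATURES))
        preds = predict(model, [cand], [vec], lib)
        assert len(preds) == 1
        assert preds[0].hprf_score == pytest.approx(0.30)

    def test_score_below_decision_threshold_dropped(self):
        from mirstack.mature import ForestModel

        cand, vec, lib = self._cand_and_vec(rpm=0.2)
        model = ForestModel(_StubForest([0.27]), list(HPRF_FEATURES))
        assert predict(model, [cand], [vec], lib) == []

    def test_expression_below_arpm_threshold_dropped(self):
        from mirstack.mature import ForestModel

        cand, vec, lib = self._cand_and_vec(rpm=0.05)
        model = ForestModel(_StubForest([0.9]), list(HPRF_FEATURES))
        assert predict(model, [cand], [vec], lib) == []
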