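"""Consistency ratios, map reproduction, corr3d, D2, territories, radial stats."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

import rp3d
from rp3d.contacts_io import Allele, ContactRecord, SegmentID, segment_for
from rp3d.evaluate import (
    DETECTION_LIMIT,
    align_similarity,
    consistency_ratios,
    contact_map_reproduction,
    corr3d,
    correlation_dimension,
    radial_metrics,
    structure_metrics,
    territory_ratio,
)
from rp3d.reconstruct import Embedding3D


def _relabel(contacts):
    """Swap maternal and paternal labels on every leg."""
    flip = {Allele.MATERNAL: Allele.PATERNAL,
            Allele.PATERNAL: Allele.MATERNAL,
            Allele.UNKNOWN: Allele.UNKNOWN}
    return [ContactRecord(c.chrom_a, c.pos_a, flip[c.allele_a],
                          c.chrom_b, c.pos_b, flip[c.allele_b], c.cell_id)
            for c in contacts]


def _relabel_embedding(emb):
    flip = {Allele.MATERNAL: Allele.PATERNAL,
            Allele.PATERNAL: Allele.MATERNAL}
    segs = [SegmentID(s.chrom, flip[s.allele], s.bin, s.resolution)
            for s in emb.segments]
    return Embedding3D(segments=segs, coords=emb.coords.copy(),
                       resolution=emb.resolution)


@pytest.fixture(scope="module")
def masked_experiment(small_truth):
    """Contacts with a realistic sparse phasing mask (5% per leg)."""
    thr = rp3d.threshold_for_recurrence_rate(small_truth, 0.08)
    return rp3d.derive_contacts(small_truth, thr, q_detect=1.0,
                                phasing_rate=0.3, seed=23)


class TestConsistencyRatios:
    def test_matches_exhaustive_oracle(self, small_embedding,
                                       masked_experiment):
        emb = small_embedding
        contacts = masked_experiment.contacts
        report = consistency_ratios(emb, contacts)
        # brute-force recomputation, independent loop over assignments
        index = emb.index
        res = emb.resolution
        from rp3d.contacts_io import classify_phasing
        tallies = {}
        for c in contacts:
            pc = classify_phasing(c)
            cand_a = ([c.allele_a] if c.allele_a != Allele.UNKNOWN
                      else [Allele.MATERNAL, Allele.PATERNAL])
            cand_b = ([c.allele_b] if c.allele_b != Allele.UNKNOWN
                      else [Allele.MATERNAL, Allele.PATERNAL])
            dists = []
            for aa in cand_a:
                for ab in cand_b:
                    sa = segment_for(c.chrom_a, c.pos_a, aa, res)
                    sb = segment_for(c.chrom_b, c.pos_b, ab, res)
                    if sa in index and sb in index:
                        dists.append(np.linalg.norm(
                            emb.coords[index[sa]] - emb.coords[index[sb]]))
            sat, tot = tallies.get(pc, (0, 0))
            if dists:
                tallies[pc] = (sat + (min(dists) <= DETECTION_LIMIT), tot + 1)
        for pc, (sat, tot) in tallies.items():
            assert report.per_class[pc].satisfied == sat
            assert report.per_class[pc].total == tot

    def test_zero_limit_satisfies_nothing(self, small_embedding,
                                          masked_experiment):
        report = consistency_ratios(small_embedding,
                                    masked_experiment.contacts, limit=0.0)
        for pc, cc in report.per_class.items():
            if cc.total:
                assert cc.ratio == 0.0

    def test_backbone_adjacent_phased_contact_is_satisfied(
            self, small_embedding):
        # two adjacent segments of a dense reconstruction sit close together
        s0, s1 = small_embedding.segments[0], small_embedding.segments[1]
        res = small_embedding.resolution
        c = ContactRecord(s0.chrom, s0.bin * res + 1, s0.allele,
                          s1.chrom, s1.bin * res + 1, s1.allele)
        report = consistency_ratios(small_embedding, [c])
        assert report.per_class[rp3d.PhasingClass.PHASED].satisfied == 1

    def test_global_allele_relabeling_leaves_ratios_unchanged(
            self, small_embedding, masked_experiment):
        base = consistency_ratios(small_embedding, masked_experiment.contacts)
        flipped = consistency_ratios(_relabel_embedding(small_embedding),
                                     _relabel(masked_experiment.contacts))
        for pc in rp3d.PhasingClass:
            assert base.per_class[pc].satisfied == flipped.per_class[pc].satisfied
            assert base.per_class[pc].total == flipped.per_class[pc].total
            assert base.per_class[pc].ratio == flipped.per_class[pc].ratio

    def test_out_of_embedding_contacts_are_excluded_not_failed(
            self, small_embedding):
        c = ContactRecord("chrZZ", 1, Allele.MATERNAL,
                          "chrZZ", 10**9, Allele.PATERNAL)
        report = consistency_ratios(small_embedding, [c])
        cc = report.per_class[rp3d.PhasingClass.PHASED]
        assert (cc.excluded, cc.total) == (1, 0)


class TestContactMapReproduction:
    def test_true_coordinates_reproduce_truth_with_full_recall(
            self, small_experiment, small_truth):
        truth_map = small_experiment.true_map()
        _, precision, recall = contact_map_reproduction(
            small_truth.as_embedding(), truth_map,
            threshold=small_experiment.contact_threshold)
        assert recall == 1.0
        # adjacent pairs are in the reproduced map but excluded from the
        # truth map (backbone), so precision is high but not 1
        assert precision > 0.85

    def test_recurrence_rate_rule_controls_pair_count(self, rng):
        # generic coordinates: pairwise distances are all distinct, so the
        # reproduced pair count equals rate * (number of pairs) up to 1
        segs = [SegmentID("chr1", Allele.MATERNAL, b, 1) for b in range(150)]
        emb = Embedding3D(segments=segs, coords=rng.normal(size=(150, 3)),
                          resolution=1)
        n_pairs = 150 * 149 // 2
        for rate in (0.02, 0.1):
            repro, _, _ = contact_map_reproduction(
                emb, rp3d.RecurrenceMap(resolution=1), recurrence_rate=rate)
            assert abs(len(repro.pairs) - rate * n_pairs) <= 1

    def test_subsampled_reconstruction_scores_against_oracle(
            self, small_truth):
        thr = rp3d.threshold_for_recurrence_rate(small_truth, 0.08)
        exp = rp3d.derive_contacts(small_truth, thr, q_detect=0.5, seed=9)
        emb = rp3d.reconstruct_cell(exp.contacts,
                                    resolution=small_truth.resolution)
        truth_map = exp.true_map()
        repro, precision, recall = contact_map_reproduction(
            emb, truth_map, recurrence_rate=exp.recurrence_rate)
        # independent recomputation from raw distances
        idx = {s: k for k, s in enumerate(emb.segments)}
        d_thr = repro.diagnostics["threshold"]
        pred = set()
        coords = emb.coords
        segs = emb.segments
        for i in range(len(segs)):
            for j in range(i + 1, len(segs)):
                if np.linalg.norm(coords[i] - coords[j]) <= d_thr:
                    a, b = segs[i], segs[j]
                    pred.add((a, b) if a <= b else (b, a))
        truth_pairs = {p for p in truth_map.pairs
                       if p[0] in idx and p[1] in idx}
        hit = len(pred & truth_pairs)
        assert precision == pytest.approx(hit / len(pred))
        assert recall == pytest.approx(hit / len(truth_pairs))


class TestCorr3D:
    def test_identity_gives_one(self, rng):
        pts = rng.normal(size=(30, 3))
        assert corr3d(pts, pts) == pytest.approx(1.0)

    def test_similarity_transform_invariance(self, rng):
        pts = rng.normal(size=(30, 3))
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0],
                      [0, 0, 1.0]])
        moved = 2.5 * pts @ R + np.array([5.0, -3.0, 1.0])
        assert corr3d(moved, pts) == pytest.approx(1.0)
        reflected = pts * np.array([-1.0, 1.0, 1.0])
        assert corr3d(reflected, pts) == pytest.approx(1.0)

    def test_noisy_configuration_matches_independent_procrustes_oracle(
            self, rng):
        pts = rng.normal(size=(50, 3))
        noisy = pts + 0.3 * rng.normal(size=(50, 3))
        ours = corr3d(noisy, pts)
        from scipy.spatial import procrustes as scipy_procrustes
        m1, m2, _ = scipy_procrustes(pts, noisy)
        oracle = np.corrcoef(m2.ravel(), m1.ravel())[0, 1]
        assert ours == pytest.approx(oracle, abs=1e-10)

    def test_too_few_points_raise(self):
        with pytest.raises(ValueError):
            corr3d(np.zeros((3, 3)), np.zeros((3, 3)))


class TestCorrelationDimension:
    @pytest.mark.parametrize("maker, expected, tol", [
        ("line", 1.0, 0.1), ("sphere", 2.0, 0.15), ("ball", 3.0, 0.15),
    ])
    def test_known_dimensions_recovered(self, maker, expected, tol):
        rng = np.random.default_rng(7)
        n = 2000
        if maker == "line":
            pts = np.zeros((n, 3))
            pts[:, 0] = rng.random(n)
        elif maker == "sphere":
            v = rng.normal(size=(n, 3))
            pts = v / np.linalg.norm(v, axis=1, keepdims=True)
        else:
            v = rng.normal(size=(n, 3))
            u = rng.random(n) ** (1 / 3)
            pts = v / np.linalg.norm(v, axis=1, keepdims=True) * u[:, None]
        d2, (r_lo, r_hi) = correlation_dimension(pts)
        assert d2 == pytest.approx(expected, abs=tol)
        assert 0 < r_lo < r_hi

    def test_scale_invariance(self, rng):
        pts = rng.normal(size=(500, 3))
        d2a, _ = correlation_dimension(pts)
        d2b, _ = correlation_dimension(pts * 1000.0)
        assert d2a == pytest.approx(d2b, rel=1e-9)

    def test_degenerate_input_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            correlation_dimension(np.zeros((200, 3)))

    def test_few_points_warn(self, rng):
        with pytest.warns(UserWarning, match="noisy"):
            correlation_dimension(rng.normal(size=(50, 3)))


def _labeled_embedding(coords_by_chain, resolution=1):
    segs, coords = [], []
    for (chrom, allele), pts in coords_by_chain.items():
        for k, p in enumerate(pts):
            segs.append(SegmentID(chrom, allele, k, resolution))
            coords.append(p)
    return Embedding3D(segments=segs, coords=np.array(coords),
                       resolution=resolution)


class TestTerritoryRatio:
    def test_disjoint_far_apart_chromosomes_are_pure_territories(self, rng):
        a = rng.normal(size=(40, 3)) * 0.3
        b = rng.normal(size=(40, 3)) * 0.3 + np.array([100.0, 0, 0])
        emb = _labeled_embedding({("chr1", Allele.MATERNAL): a,
                                  ("chr2", Allele.MATERNAL): b})
        intra, shuffled = territory_ratio(emb, closeness=5.0, seed=0)
        assert intra == 1.0

    def test_single_chain_shuffles_equal_observed(self, rng):
        emb = _labeled_embedding({("chr1", Allele.MATERNAL):
                                  rng.normal(size=(50, 3))})
        intra, shuffled = territory_ratio(emb, closeness=2.0, seed=0)
        assert intra == 1.0
        assert all(s == intra for s in shuffled)

    def test_clustered_mixture_beats_all_twenty_shuffles(self, rng):
        chains = {}
        for k, chrom in enumerate(["chr1", "chr2", "chr3"]):
            center = np.array([4.0 * k, 0, 0])
            chains[(chrom, Allele.MATERNAL)] = (
                rng.normal(size=(30, 3)) * 0.5 + center)
        emb = _labeled_embedding(chains)
        intra, shuffled = territory_ratio(emb, closeness=1.5,
                                          n_shuffles=20, seed=17)
        assert len(shuffled) == 20
        assert intra > max(shuffled)


class TestRadialMetrics:
    def test_spherical_shell_has_unit_hole_radius(self, rng):
        v = rng.normal(size=(300, 3))
        R = 4.0
        pts = R * v / np.linalg.norm(v, axis=1, keepdims=True)
        emb = _labeled_embedding({("chr1", Allele.MATERNAL): pts})
        m = radial_metrics(emb)
        assert m.hole_radius_normalized == pytest.approx(1.0, abs=0.05)
        np.testing.assert_allclose(m.radial, R, rtol=0.1)

    def test_uniform_ball_has_vanishing_hole(self, rng):
        v = rng.normal(size=(3000, 3))
        u = rng.random(3000) ** (1 / 3)
        pts = v / np.linalg.norm(v, axis=1, keepdims=True) * u[:, None]
        emb = _labeled_embedding({("chr1", Allele.MATERNAL): pts})
        m = radial_metrics(emb)
        assert m.hole_radius_normalized < 0.1

    def test_planted_offset_shifts_per_allele_medians(self, rng):
        base = rng.normal(size=(200, 3))
        offset = base + np.array([6.0, 0, 0])
        emb = _labeled_embedding({("chr1", Allele.MATERNAL): base,
                                  ("chr1", Allele.PATERNAL): offset})
        m = radial_metrics(emb)
        df = m.by_allele.set_index("allele")
        # brute-force check against direct recomputation
        center = emb.coords.mean(axis=0)
        r_mat = np.linalg.norm(base - center, axis=1)
        r_pat = np.linalg.norm(offset - center, axis=1)
        assert df.loc["mat", "median"] == pytest.approx(np.median(r_mat))
        assert df.loc["pat", "median"] == pytest.approx(np.median(r_pat))


def test_structure_metrics_bundles_everything(small_embedding):
    sm = structure_metrics(small_embedding, seed=3)
    assert len(sm.shuffled_intra_ratios) == 20
    assert np.isfinite(sm.correlation_dimension)
    assert 0 <= sm.intra_ratio <= 1
    assert sm.hole_radius_normalized >= 0
    assert {"chrom", "allele", "median"} <= set(sm.radial_by_allele.columns)
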