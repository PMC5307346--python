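"""Template merging, voxel classification and sub-parcellation."""

import numpy as np
import pytest

import tractprint as tp
from conftest import make_samples, mini_spec


class TestMergedTemplate:
    @pytest.fixture()
    def pieces(self, phantom):
        atlas = phantom.label_volume
        primary = {atlas.label_of("Piriform_L"), atlas.label_of("Amygdala_L")}
        return (phantom.templates["sOCN_L"], phantom.templates["fOCN_L"],
                atlas, primary)

    def test_primary_grey_functional_voxels_kept(self, pieces):
        soc, foc, atlas, primary = pieces
        merged = tp.build_merged_template(soc, foc, atlas, primary)
        amygdala_part = foc.mask & atlas.mask_of(atlas.label_of("Amygdala_L"))
        assert amygdala_part.any()
        assert (merged.mask[amygdala_part]).all()

    def test_non_primary_functional_voxels_removed(self, pieces):
        soc, foc, atlas, primary = pieces
        merged = tp.build_merged_template(soc, foc, atlas, primary)
        hippo_part = foc.mask & atlas.mask_of(atlas.label_of("Hippocampus_L"))
        assert hippo_part.any()
        assert not merged.mask[hippo_part].any()
        white = np.isin(atlas.data, atlas.labels_with_tissue("white"))
        assert not (merged.mask & white).any()

    def test_merged_superset_of_structural(self, pieces):
        soc, foc, atlas, primary = pieces
        merged = tp.build_merged_template(soc, foc, atlas, primary)
        assert (merged.mask >= soc.mask).all()
        assert merged.provenance == "merged"

    def test_unknown_primary_label_rejected(self, pieces):
        soc, foc, atlas, _ = pieces
        with pytest.raises(ValueError, match="missing from atlas"):
            tp.build_merged_template(soc, foc, atlas, {99999})

    def test_unlabelled_grey_voxels_kept_when_mask_supplied(self, pieces):
        soc, foc, atlas, primary = pieces
        unlabelled_func = foc.mask & (atlas.data == 0)
        assert unlabelled_func.any()
        grey_everywhere = np.ones(atlas.grid_shape, dtype=bool)
        merged = tp.build_merged_template(
            soc, foc, atlas, primary, keep_unlabelled_grey=grey_everywhere)
        assert merged.mask[unlabelled_func].all()


class TestClassifyVoxels:
    def test_quarter_of_samples_is_the_boundary(self, config):
        s = make_samples([[1250, 0], [1249, 0]], S=5000)
        sp = tp.classify_seed_voxels(s, [0, 1], [1], config)
        assert sp.connected_mask.tolist() == [True, False]
        assert sp.cutoff == 1250

    def test_fraction_rule_scales_with_s(self):
        cfg = tp.PipelineConfig(S=1000)
        s = make_samples([[250, 0]], S=1000)
        sp = tp.classify_seed_voxels(s, [0], [1], cfg)
        assert sp.connected_mask.tolist() == [True]

    def test_counts_pooled_over_target_labels(self, config):
        s = make_samples([[700, 600]], S=5000)
        sp = tp.classify_seed_voxels(s, [0], [1, 2], config)
        assert sp.connected_mask.tolist() == [True]      # 700+600 >= 1250

    def test_fractional_cutoff_rounds_up(self):
        cfg = tp.PipelineConfig(S=999, voxel_class_frac=0.25)   # 249.75
        s = make_samples([[250, 0]], S=999)
        sp = tp.classify_seed_voxels(s, [0], [1], cfg)
        assert sp.cutoff == 250
        assert sp.connected_mask.tolist() == [True]

    def test_invariant_under_count_rescaling(self, config):
        """(S, counts) -> (kS, k*counts) leaves the classification fixed."""
        rng = np.random.default_rng(6)
        counts = rng.integers(0, 2000, size=(8, 3))
        for k in (1, 2, 5):
            s = make_samples(counts * k, S=5000 * k)
            cfg = tp.PipelineConfig(S=5000 * k)
            sp = tp.classify_seed_voxels(s, list(range(8)), [1, 2], cfg)
            base = tp.classify_seed_voxels(
                make_samples(counts, S=5000), list(range(8)), [1, 2], config)
            assert sp.connected_mask.tolist() == base.connected_mask.tolist()

    def test_connected_mask_within_candidates(self, config):
        s = make_samples([[5000, 0], [0, 5000], [0, 0]], S=5000)
        sp = tp.classify_seed_voxels(s, [0, 1], [1], config)
        assert sp.n_voxels == 2


class TestSubparcellate:
    def _merged(self, n, grid=(6, 6, 6)):
        mask = np.zeros(int(np.prod(grid)), dtype=bool)
        mask[:n] = True
        return tp.SeedTemplate(mask=mask.reshape(grid), name="m",
                               provenance="merged")

    def test_assigned_to_largest_count(self, config):
        s = make_samples([[2000, 500, 0]], S=5000)
        sp = tp.subparcellate_by_targets(s, self._merged(1), [1, 2], config)
        assert sp.assigned_target.tolist() == [1]

    def test_exact_tie_goes_to_lowest_label(self, config):
        s = make_samples([[1300, 1300, 0]], S=5000)
        sp = tp.subparcellate_by_targets(s, self._merged(1), [2, 1], config)
        assert sp.assigned_target.tolist() == [1]

    def test_subthreshold_voxel_unassigned(self, config):
        s = make_samples([[1249, 1100, 0]], S=5000)
        sp = tp.subparcellate_by_targets(s, self._merged(1), [1, 2], config)
        assert sp.assigned_target.tolist() == [tp.merge.UNASSIGNED]
        assert not sp.connected_mask[0]

    def test_no_targets_rejected(self, config):
        s = make_samples([[100, 100]], S=5000)
        with pytest.raises(ValueError, match="no secondary targets"):
            tp.subparcellate_by_targets(s, self._merged(1), [], config)

    def test_target_masks_partition_connected_voxels(self, config):
        rng = np.random.default_rng(13)
        counts = rng.multinomial(5000, [0.4, 0.35, 0.25], size=20)
        s = make_samples(counts, S=5000)
        sp = tp.subparcellate_by_targets(s, self._merged(20), [1, 2, 3],
                                         config)
        masks = sp.target_masks()
        union = np.zeros(s.grid_shape, dtype=bool)
        for lab, mask in masks.items():
            assert not (union & mask).any()               # disjoint
            union |= mask
        connected = np.zeros(int(np.prod(s.grid_shape)), dtype=bool)
        connected[sp.voxel_index[sp.connected_mask]] = True
        assert np.array_equal(union.ravel(), connected)   # covering


class TestGroupSubparcellation:
    def _assigned(self, labels, targets=(1, 2), n_vox=None):
        labels = np.asarray(labels, dtype=np.int64)
        n = labels.size if n_vox is None else n_vox
        return tp.SubParcellation(
            grid_shape=(6, 6, 6),
            voxel_index=np.arange(n),
            target_labels=np.asarray(targets, dtype=np.int64),
            connected_mask=labels != tp.merge.UNASSIGNED,
            assigned_target=labels,
        )

    def test_majority_assignment_wins(self, config):
        subs = [self._assigned([1]) for _ in range(9)] + \
               [self._assigned([tp.merge.UNASSIGNED]) for _ in range(7)]
        cons = tp.group_subparcellation(subs, config)
        assert cons.assigned_target.tolist() == [1]

    def test_exact_half_split_goes_to_lowest_label(self, config):
        subs = [self._assigned([1]) for _ in range(8)] + \
               [self._assigned([2]) for _ in range(8)]
        cons = tp.group_subparcellation(subs, config)
        assert cons.assigned_target.tolist() == [1]

    def test_no_qualifying_target_leaves_unassigned(self, config):
        subs = [self._assigned([1]), self._assigned([2]),
                self._assigned([tp.merge.UNASSIGNED]),
                self._assigned([tp.merge.UNASSIGNED])]
        cons = tp.group_subparcellation(subs, config)
        assert cons.assigned_target.tolist() == [tp.merge.UNASSIGNED]

    def test_matches_per_voxel_majority_oracle(self, config):
        rng = np.random.default_rng(21)
        n_vox, n_subj, labels = 30, 10, (1, 2, 3)
        assignments = rng.choice(
            [tp.merge.UNASSIGNED, 1, 2, 3], size=(n_subj, n_vox))
        subs = [self._assigned(a, targets=labels) for a in assignments]
        cons = tp.group_subparcellation(subs, config)
        for v in range(n_vox):
            votes = {lab: int((assignments[:, v] == lab).sum())
                     for lab in labels}
            qual = [lab for lab, c in votes.items()
                    if c >= config.group_frac * n_subj]
            if qual:
                best = max(votes[l] for l in qual)
                expect = min(l for l in qual if votes[l] == best)
            else:
                expect = tp.merge.UNASSIGNED
            assert cons.assigned_target[v] == expect

    def test_mismatched_voxel_sets_rejected(self, config):
        a = self._assigned([1, 2])
        b = self._assigned([1])
        with pytest.raises(ValueError, match="different voxel"):
            tp.group_subparcellation([a, b], config)


class TestPlantedRecovery:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_anterior_posterior_profiles_recovered(self, seed, config):
        """Winner-take-all on the merged seed recovers the planted
        anterior (orbitofrontal) vs posterior (hippocampal) split."""
        spec = tp.default_phantom_spec(n_subjects=1, rng_seed=100 + seed)
        phantom = tp.make_phantom(spec)
        atlas = phantom.label_volume
        merged = tp.build_merged_template(
            phantom.templates["sOCN_L"], phantom.templates["fOCN_L"], atlas,
            {atlas.label_of("Piriform_L"), atlas.label_of("Amygdala_L")})
        targets = [atlas.label_of(n) for n in
                   ("Frontal_Sup_Orb_L", "Cingulum_Ant_L", "Hippocampus_L")]
        samples = tp.simulate_tractography(phantom, 0)
        sp = tp.subparcellate_by_targets(samples, merged, targets, config)

        names = {atlas.label_table[l].name: l for l in targets}
        truth = phantom.truth
        expected = []
        for v in np.sort(merged.voxel_indices()):
            cls = truth.class_by_voxel[
                np.searchsorted(truth.seed_voxels, v)]
            dom = truth.dominant_target(cls, among=list(names))
            expected.append(names[dom] if dom else tp.merge.UNASSIGNED)
        accuracy = np.mean(sp.assigned_target == np.asarray(expected))
        assert accuracy >= 0.95
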