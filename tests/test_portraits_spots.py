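import warnings

import numpy as np
import pytest

from conftest import make_model
from episom.datamodel_io import SampleAnnotation, centralize, match_genes
from episom.portraits_spots import (
    DEFAULT_MIN_UNITS,
    DEFAULT_SPOT_QUANTILE,
    class_mean_portrait,
    cross_map,
    detect_spots,
    overview_spot_map,
    spot_profile,
    variance_map,
)
from episom.som_core import train_som


@pytest.fixture(scope="module")
def bundle_ann(default_bundle):
    return default_bundle.met_ann


class TestClassMeanPortrait:
    def test_single_sample_class_identity(self, dmet_model, bundle_ann):
        gcb = bundle_ann.samples_of("GCB")[0]
        single = SampleAnnotation({gcb: "solo"})
        portrait = class_mean_portrait(dmet_model, single, "solo")
        j = dmet_model.sample_index(gcb)
        assert np.array_equal(
            portrait.ravel(), dmet_model.codebook[:, j]
        )

    def test_size_weighted_mean_equals_global(self, dmet_model, bundle_ann):
        total = np.zeros(dmet_model.n_units)
        n = 0
        for label in bundle_ann.classes():
            k = len(bundle_ann.samples_of(label))
            total += k * class_mean_portrait(
                dmet_model, bundle_ann, label
            ).ravel()
            n += k
        global_mean = dmet_model.codebook.mean(axis=1)
        assert np.allclose(total / n, global_mean, atol=1e-12)

    def test_unknown_class(self, dmet_model, bundle_ann):
        with pytest.raises(ValueError):
            class_mean_portrait(dmet_model, bundle_ann, "nope")

    def test_planted_region_extreme(self, dmet_model, bundle_ann,
                                    default_bundle):
        # the class carrying a planted module shows that region above the
        # grid's 90th percentile in its class-mean portrait
        portrait = class_mean_portrait(dmet_model, bundle_ann, "MM")
        genes = default_bundle.truth.module_genes("mod_iv")
        idx = [default_bundle.met.gene_index(g) for g in genes]
        units = {int(dmet_model.bmu[i]) for i in idx}
        q90 = np.quantile(portrait.ravel(), 0.90)
        vals = [portrait.ravel()[u] for u in units]
        assert min(vals) > q90


class TestVarianceMap:
    def test_constant_prototype_zero(self):
        codebook = np.vstack([np.full(4, 0.3), np.arange(4.0),
                              np.zeros(4), np.ones(4)])
        model = make_model(codebook, np.zeros((1, 4)), [0], 2, 2)
        vm = variance_map(model)
        assert vm[0, 0] == 0.0

    def test_oracle_recompute(self, dmet_model):
        vm = variance_map(dmet_model).ravel()
        for u in range(0, dmet_model.n_units, 37):
            x = dmet_model.codebook[u]
            expected = float(np.mean((x - x.mean()) ** 2))
            assert vm[u] == pytest.approx(expected, abs=1e-12)

    def test_planted_regions_high_variance(self, dmet_model, default_bundle):
        vm = variance_map(dmet_model).ravel()
        med = np.median(vm)
        for name in ("mod_i", "mod_iii", "mod_iv"):
            genes = default_bundle.truth.module_genes(name)
            idx = [default_bundle.met.gene_index(g) for g in genes]
            units = {int(dmet_model.bmu[i]) for i in idx}
            assert np.mean([vm[u] > med for u in units]) > 0.9


class TestOverviewSpotMap:
    def test_quantile_validation(self, dmet_model):
        with pytest.raises(ValueError):
            overview_spot_map(dmet_model, "high", 0.4)
        with pytest.raises(ValueError):
            overview_spot_map(dmet_model, "middle", 0.98)

    def test_constant_model_empty_mask(self):
        codebook = np.full((9, 3), 0.5)
        model = make_model(codebook, np.full((5, 3), 0.5),
                           [0] * 5, 3, 3)
        mask = overview_spot_map(model, "high", 0.98)
        assert not mask.any()

    def test_high_q_single_unit_per_sample(self, rng):
        # continuous data: strictly above the q->1 quantile leaves only
        # each sample's maximal unit
        codebook = rng.normal(size=(25, 4))
        model = make_model(codebook, np.zeros((2, 4)), [0, 1], 5, 5)
        mask = overview_spot_map(model, "high", 0.9999)
        expect = set(np.argmax(codebook, axis=0).tolist())
        assert set(np.flatnonzero(mask.ravel()).tolist()) == expect

    def test_mask_covers_planted_modules(self, dmet_model, default_bundle):
        # coverage measured per gene: stray single genes can fall into
        # background-dominated units whose diluted prototypes miss the
        # per-sample tail, but >=90% of each module must be inside the mask
        mask = overview_spot_map(dmet_model, "high", DEFAULT_SPOT_QUANTILE)
        flat = mask.ravel()
        for name, info in default_bundle.truth.modules.items():
            if info["beta_shift"] == 0:
                continue
            idx = [default_bundle.met.gene_index(g) for g in info["genes"]]
            covered = np.mean([flat[int(dmet_model.bmu[i])] for i in idx])
            assert covered >= 0.9, name


class TestDetectSpots:
    def _blank_model(self, rows=6, cols=6, n_genes=4):
        codebook = np.zeros((rows * cols, 2))
        data = np.zeros((n_genes, 2))
        return make_model(codebook, data, [0] * n_genes, rows, cols)

    def test_single_block(self):
        model = self._blank_model()
        mask = np.zeros((6, 6), dtype=bool)
        mask[1:4, 1:4] = True
        spots = detect_spots(mask, model, min_units=4)
        assert len(spots) == 1
        assert spots[0].n_units == 9

    def test_two_separated_blocks(self):
        model = self._blank_model()
        mask = np.zeros((6, 6), dtype=bool)
        mask[0:2, 0:2] = True
        mask[4:6, 4:6] = True
        spots = detect_spots(mask, model, min_units=4)
        assert len(spots) == 2

    def test_diagonal_touch_is_8_connected(self):
        model = self._blank_model()
        mask = np.zeros((6, 6), dtype=bool)
        mask[0:2, 0:2] = True
        mask[2:4, 2:4] = True  # touches at the corner (1,1)-(2,2)
        spots = detect_spots(mask, model, min_units=4)
        assert len(spots) == 1

    def test_empty_mask(self):
        model = self._blank_model()
        spots = detect_spots(np.zeros((6, 6), dtype=bool), model)
        assert spots == []

    def test_min_units_filter(self):
        model = self._blank_model()
        mask = np.zeros((6, 6), dtype=bool)
        mask[0, 0:3] = True  # 3 units < min_units=4
        assert detect_spots(mask, model, min_units=4) == []

    def test_unit_in_at_most_one_spot(self, dmet_model):
        mask = overview_spot_map(dmet_model, "high")
        spots = detect_spots(mask, dmet_model)
        seen = set()
        for spot in spots:
            assert not (spot.units & seen)
            seen |= spot.units

    def test_spot_genes_subset_of_mask_genes(self, dmet_model):
        mask = overview_spot_map(dmet_model, "high")
        spots = detect_spots(mask, dmet_model)
        mask_units = {
            dmet_model.unit_index(r, c)
            for r, c in zip(*np.where(mask))
        }
        mask_genes = {
            g for g, u in zip(dmet_model.gene_ids, dmet_model.bmu)
            if int(u) in mask_units
        }
        union = set()
        for spot in spots:
            assert set(spot.gene_ids) <= mask_genes
            union |= set(spot.gene_ids)
        assert union <= mask_genes

    def test_five_planted_modules_recovered(self, dmet_model,
                                            default_bundle):
        mask = overview_spot_map(dmet_model, "high")
        spots = detect_spots(mask, dmet_model, min_units=DEFAULT_MIN_UNITS)
        for name, info in default_bundle.truth.modules.items():
            if info["beta_shift"] == 0:
                continue
            truth_genes = set(info["genes"])
            best = max(
                len(truth_genes & set(s.gene_ids))
                / len(truth_genes | set(s.gene_ids))
                for s in spots
            )
            assert best >= 0.7, name


class TestSpotProfile:
    def test_one_gene_spot_equals_raw_values(self):
        data = np.array([[0.1, 0.5, 0.9]])
        model = make_model(np.zeros((4, 3)), data, [0], 2, 2,
                           gene_ids=["G0"], sample_ids=["S0", "S1", "S2"])
        spots = detect_spots(
            np.array([[True, False], [False, False]]), model, min_units=1
        )
        ann = SampleAnnotation({"S0": "a", "S1": "b", "S2": "c"})
        prof = spot_profile(spots[0], ann)
        assert prof.loc["a", "mean"] == 0.1
        assert prof.loc["c", "mean"] == 0.9

    def test_brute_force_oracle(self, dmet_model, bundle_ann):
        mask = overview_spot_map(dmet_model, "high")
        spot = detect_spots(mask, dmet_model)[0]
        prof = spot_profile(spot, bundle_ann)
        idx = [dmet_model.gene_ids.index(g) for g in spot.gene_ids]
        for label in bundle_ann.classes():
            vals = []
            for s in bundle_ann.samples_of(label):
                j = dmet_model.sample_index(s)
                vals.append(
                    sum(dmet_model.data[i, j] for i in idx) / len(idx)
                )
            assert prof.loc[label, "mean"] == pytest.approx(
                float(np.mean(vals)), abs=1e-12
            )

    def test_planted_shift_visible_in_profile(self, default_bundle,
                                              bundle_ann, dmet_model):
        # mod_iv: +0.3 beta in MM only; profile on raw beta scale
        met = default_bundle.met
        genes = default_bundle.truth.module_genes("mod_iv")
        idx = [met.gene_index(g) for g in genes]
        per_sample = met.values[idx, :].mean(axis=0)
        from episom.portraits_spots import SpotModule

        spot = SpotModule("x", "high", {(0, 0)}, genes,
                          list(met.sample_ids), per_sample)
        prof = spot_profile(spot, bundle_ann)
        shift = prof.loc["MM", "mean"] - prof.loc["B", "mean"]
        assert shift == pytest.approx(0.3, abs=0.05)


class TestCrossMap:
    def test_self_map_recovers_own_region(self, dmet_model):
        mask = overview_spot_map(dmet_model, "high")
        spot = detect_spots(mask, dmet_model)[0]
        pairs = [(g, g) for g in dmet_model.gene_ids]
        res = cross_map(spot, dmet_model, pairs)
        member_units = {
            dmet_model.unit_coord(dmet_model.bmu[dmet_model.gene_ids.index(g)])
            for g in spot.gene_ids
        }
        assert set(res.occupancy) == member_units
        assert res.fraction_mapped == 1.0

    def test_empty_pairing_rejected(self, dmet_model):
        mask = overview_spot_map(dmet_model, "high")
        spot = detect_spots(mask, dmet_model)[0]
        with pytest.raises(ValueError, match="empty"):
            cross_map(spot, dmet_model, [])

    def test_coupled_module_concentrates_in_expression_som(
        self, default_bundle, dmet_model, rng
    ):
        dex = centralize(default_bundle.exp)
        exp_model = train_som(dex, 20, 20, epochs=20, seed=7,
                              variant="DexSOM")
        mask = overview_spot_map(dmet_model, "high")
        spots = detect_spots(mask, dmet_model)
        truth_genes = set(default_bundle.truth.module_genes("mod_i"))
        spot = max(
            spots, key=lambda s: len(truth_genes & set(s.gene_ids))
        )
        pairs = match_genes(default_bundle.met, default_bundle.exp)
        res = cross_map(spot, exp_model, pairs)
        assert res.concentration < 0.2
        # random same-size gene sets are less concentrated
        from episom.portraits_spots import SpotModule

        wins = 0
        n_draws = 100
        for _ in range(n_draws):
            random_genes = list(
                rng.choice(default_bundle.met.gene_ids, spot.n_genes,
                           replace=False)
            )
            fake = SpotModule("rnd", "high", spot.units, random_genes,
                              spot.sample_ids, spot.per_sample_profile)
            r = cross_map(fake, exp_model, pairs)
            wins += r.concentration > res.concentration
        assert wins >= 95
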