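"""Model assembly, training determinism, ablation ladder and persistence."""

import numpy as np
import pytest

from sleepgcn.features import Standardizer
from sleepgcn.model import ModelConfig, build_model
from sleepgcn.synthetic import SyntheticSpec, cohort_windows, generate_cohort, ring_montage


def fast_config(**kw):
    base = dict(epochs=3, seed=11, patience=0, val_fraction=0.0)
    base.update(kw)
    return ModelConfig(**base)


@pytest.fixture(scope="module")
def std_windows(tiny_windows):
    return Standardizer().fit(tiny_windows).transform(tiny_windows)


class TestBuild:
    def test_variant_a_has_only_dc_cheb_parameters(self, montage6):
        model = build_model(ModelConfig.variant("a", seed=0), montage6)
        names = set(model.params)
        assert "Theta_dc" in names
        assert not any(n.startswith(("Vp", "Vq", "Phi", "w_graph", "wd")) for n in names)

    def test_parameter_count_strictly_increases_along_ladder(self, montage6):
        counts = [
            build_model(ModelConfig.variant(v, seed=0), montage6, n_domains=3).n_parameters
            for v in "abcde"
        ]
        assert counts == sorted(counts)
        assert len(set(counts)) == 5

    def test_same_seed_same_initial_parameters(self, montage6):
        m1 = build_model(ModelConfig(seed=42), montage6, n_domains=3)
        m2 = build_model(ModelConfig(seed=42), montage6, n_domains=3)
        for k in m1.params:
            assert np.array_equal(m1.params[k].data, m2.params[k].data)

    def test_dg_with_single_domain_rejected(self, montage6):
        with pytest.raises(ValueError, match="R_d"):
            build_model(ModelConfig(seed=0), montage6, n_domains=1)

    def test_disabling_both_views_rejected(self):
        with pytest.raises(ValueError, match="view"):
            ModelConfig(use_fc_view=False, use_dc_view=False)


class TestTraining:
    def test_beta_zero_trajectory_bit_identical_to_no_dg(self, montage6, std_windows):
        cfg_b0 = fast_config(beta=0.0)
        cfg_off = fast_config(use_domain_generalization=False)
        m_b0 = build_model(cfg_b0, montage6, n_domains=4).fit(std_windows)
        m_off = build_model(cfg_off, montage6, n_domains=4).fit(std_windows)
        shared = set(m_b0.params) & set(m_off.params)
        assert "wy" in shared and "Theta_dc" in shared
        for k in shared:
            assert np.array_equal(m_b0.params[k].data, m_off.params[k].data), k
        ly_b0 = [h["loss_y"] for h in m_b0.history]
        ly_off = [h["loss_y"] for h in m_off.history]
        assert ly_b0 == ly_off

    def test_converges_on_separable_features_without_dg(self, montage6):
        spec = SyntheticSpec(
            n_subjects=2, epochs_per_subject=60, n_channels=6,
            class_effect_size=4.0, subject_effect_size=0.0, seed=5,
        )
        windows = cohort_windows(generate_cohort(spec), d=1)
        std = Standardizer().fit(windows).transform(windows)
        cfg = fast_config(epochs=200, d=1, use_domain_generalization=False, gamma=0.0)
        model = build_model(cfg, ring_montage(6)).fit(std)
        assert model.history[-1]["loss_y"] < 0.05

    def test_graph_loss_decreases_with_positive_gamma(self, montage6, std_windows):
        cfg = fast_config(epochs=25, gamma=1e-2)
        model = build_model(cfg, montage6, n_domains=4).fit(std_windows)
        lg = [h["loss_graph"] for h in model.history]
        assert lg[-1] < lg[0]

    def test_single_subject_with_dg_raises(self, montage6, std_windows):
        one_subject = [w for w in std_windows if w.subject_id == "S00"]
        model = build_model(fast_config(), montage6, n_domains=4)
        with pytest.raises(ValueError, match="R_d"):
            model.fit(one_subject)


class TestPrediction:
    @pytest.fixture(scope="class")
    def trained(self, montage6, std_windows):
        return build_model(fast_config(epochs=5), montage6, n_domains=4).fit(std_windows)

    def test_predict_is_deterministic(self, trained, std_windows):
        p1 = trained.predict(std_windows[:50])
        p2 = trained.predict(std_windows[:50])
        assert np.array_equal(p1["labels"], p2["labels"])
        assert np.array_equal(p1["proba"], p2["proba"])

    def test_uniform_posterior_ties_break_to_stage_zero(self, trained, std_windows):
        saved = (trained.params["wy"].data.copy(), trained.params["by"].data.copy())
        trained.params["wy"].data[:] = 0.0
        trained.params["by"].data[:] = 0.0
        try:
            pred = trained.predict(std_windows[:10])
            assert np.all(pred["labels"] == 0)
            assert np.allclose(pred["proba"], 0.2)
        finally:
            trained.params["wy"].data, trained.params["by"].data = saved

    def test_exports_adjacency_and_attention_per_window(self, trained, std_windows):
        pred = trained.predict(std_windows[:8])
        n = trained.montage.n_channels
        tn = trained.config.tn
        assert pred["A_fc"].shape == (8, n, n)
        assert np.allclose(pred["A_fc"].sum(axis=2), 1.0, atol=1e-9)
        assert pred["P_fc"].shape == (8, n, n)
        assert pred["Q_dc"].shape == (8, tn, tn)

    def test_channel_mismatch_rejected(self, trained, std_windows):
        bad = [
            type(w)(w.features[:4], w.label, w.subject_id, w.center_index)
            for w in std_windows[:4]
        ]
        with pytest.raises(ValueError, match="channel"):
            trained.predict(bad)


class TestPersistence:
    def test_save_load_predict_bit_identical(self, tmp_path, montage6, std_windows):
        model = build_model(fast_config(epochs=4), montage6, n_domains=4).fit(std_windows)
        before = model.predict(std_windows[:20])
        path = tmp_path / "model.npz"
        model.save(path)
        reloaded = type(model).load(path)
        for k in model.params:
            assert np.array_equal(model.params[k].data, reloaded.params[k].data)
        after = reloaded.predict(std_windows[:20])
        assert np.array_equal(before["proba"], after["proba"])
        assert np.array_equal(before["labels"], after["labels"])
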