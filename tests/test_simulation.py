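import numpy as np
import pytest

from scbn.simulation import SimConfig, simulate_dataset, study_configs


SMALL = dict(
    n_orth=2000,
    n_unique=(200, 400),
    n_unmapped=(100, 200),
    m_conserved=300,
    depth=(1e6, 2e6),
)


def test_seed_fixes_dataset_bit_exactly():
    cfg = SimConfig(seed=5, **SMALL)
    t1, c1, tr1 = simulate_dataset(cfg)
    t2, c2, tr2 = simulate_dataset(cfg)
    assert t1.data.equals(t2.data)
    assert c1.ids == c2.ids
    assert tr1.c_true == tr2.c_true
    t3, _, _ = simulate_dataset(SimConfig(seed=6, **SMALL))
    assert not t1.data.equals(t3.data)


def test_true_factor_recomputable_from_parameters():
    _, _, tr = simulate_dataset(SimConfig(seed=1, **SMALL))
    table, _, _ = simulate_dataset(SimConfig(seed=1, **SMALL))
    S1 = np.sum(tr.mu1 * table.data["L1"].to_numpy())
    S2 = np.sum(tr.mu2 * table.data["L2"].to_numpy())
    assert tr.c_true == pytest.approx(S2 / S1, abs=1e-12)
    assert tr.c_true > 0


def test_realized_depths_match_configuration():
    cfg = SimConfig(seed=2, **SMALL)
    table, _, _ = simulate_dataset(cfg)
    for total, target in ((table.n1, cfg.depth[0]), (table.n2, cfg.depth[1])):
        assert abs(total - target) < 3 * np.sqrt(target)


def test_row_layout_and_unique_genes():
    cfg = SimConfig(seed=3, **SMALL)
    table, _, tr = simulate_dataset(cfg)
    assert len(table) == 2000 + 200 + 400
    assert tr.unique_mask.sum() == 600
    x1 = table.data["x1"].to_numpy()
    x2 = table.data["x2"].to_numpy()
    sp1_only = tr.unique_mask & (tr.mu2 == 0)
    sp2_only = tr.unique_mask & (tr.mu1 == 0)
    assert sp1_only.sum() == 200 and sp2_only.sum() == 400
    assert np.all(x2[sp1_only] == 0) and np.all(x1[sp2_only] == 0)
    # unmapped genes exist but never enter the table
    assert len(tr.unmapped_counts[0]) == 100
    assert len(tr.unmapped_counts[1]) == 200


def test_de_assignment_and_direction_balance():
    cfg = SimConfig(seed=4, n_orth=5000, prop_de=0.2, fold=2.0, prop_up_sp2=0.9,
                    n_unique=(0, 0), n_unmapped=(0, 0), m_conserved=500,
                    depth=(1e6, 2e6))
    _, _, tr = simulate_dataset(cfg)
    de = tr.de_mask & ~tr.unique_mask
    assert de.sum() == 1000
    up = (tr.direction == 1) & de
    # binomial sampling band around prop_up_sp2
    assert abs(up.sum() / de.sum() - 0.9) < 3 * np.sqrt(0.9 * 0.1 / de.sum())
    np.testing.assert_allclose(tr.mu2[up], tr.mu1[up] * 2.0)
    down = (tr.direction == -1) & de
    np.testing.assert_allclose(tr.mu2[down], tr.mu1[down] / 2.0)


def test_conserved_set_composition_under_noise():
    cfg = SimConfig(seed=5, n_orth=2000, prop_de=0.3, fold=1.5, noise_rate=0.4,
                    n_unique=(0, 0), n_unmapped=(0, 0), m_conserved=200,
                    depth=(1e6, 2e6))
    _, cons, tr = simulate_dataset(cfg)
    assert cons.m == 200
    idx = {g: i for i, g in enumerate(tr.gene_id)}
    labels = np.array([tr.de_mask[idx[g]] for g in cons.ids])
    assert labels.sum() == 80  # round(0.4 * 200) contaminants, rest clean


def test_fold_one_is_degenerate():
    cfg = SimConfig(seed=6, fold=1.0, prop_de=0.1, **{k: v for k, v in SMALL.items()})
    _, _, tr = simulate_dataset(cfg)
    keep = ~tr.unique_mask
    np.testing.assert_array_equal(tr.mu1[keep], tr.mu2[keep])


def test_infeasible_noise_config_errors():
    cfg = SimConfig(n_orth=1000, prop_de=0.01, noise_rate=0.5, m_conserved=100)
    with pytest.raises(ValueError, match="noise"):
        cfg.validate()


def test_invalid_fractions_error():
    with pytest.raises(ValueError):
        SimConfig(prop_de=1.5).validate()
    with pytest.raises(ValueError):
        SimConfig(fold=0.5).validate()


class TestStudyConfigs:
    def test_all_seven_present(self):
        designs = study_configs()
        assert set(designs) == {f"study{i}" for i in range(1, 8)}
        for d in designs.values():
            d.config.validate()

    def test_base_conditions(self):
        base = study_configs()["study1"].config
        assert base.prop_de == 0.1
        assert base.fold == 1.2
        assert base.prop_up_sp2 == 0.9
        assert base.n_unique == (1000, 2000)
        assert base.n_unmapped == (2000, 4000)

    def test_study1_sweeps_conserved_set_size(self):
        d = study_configs()["study1"]
        assert d.sweep_param == "m_conserved"
        assert min(d.sweep_values) == 50 and max(d.sweep_values) == 1000

    @pytest.mark.parametrize("name", ["study2", "study5", "study6"])
    def test_noise_sweep_studies_use_fold_15(self, name):
        d = study_configs()[name]
        assert d.config.fold == 1.5
        assert d.config.m_conserved == 1000
        assert d.sweep_param == "noise_rate"
        assert d.sweep_values[0] == 0.0

    def test_study2_noise_grid(self):
        d = study_configs()["study2"]
        np.testing.assert_allclose(d.sweep_values, np.arange(0.0, 0.61, 0.1))

    def test_study3_strong_fold(self):
        d = study_configs()["study3"]
        assert d.config.prop_de == 0.2
        assert d.config.fold == 8.0
        assert d.config.prop_up_sp2 == 0.7
        assert tuple(d.sweep_values) == (0.0, 0.4)

    def test_study4_cutoff_sweep(self):
        d = study_configs()["study4"]
        assert d.config.prop_de == 0.4
        assert d.sweep_param == "cutoff"
        assert min(d.sweep_values) == 0.0001 and max(d.sweep_values) == 0.6

    def test_study6_cutoff(self):
        assert study_configs()["study6"].cutoff == 0.01

    def test_study7_de_rate_sweep(self):
        d = study_configs()["study7"]
        assert d.config.noise_rate == 0.2
        assert d.config.fold == 1.5
        assert tuple(d.sweep_values) == (0.1, 0.2, 0.3, 0.4, 0.5, 0.6)
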