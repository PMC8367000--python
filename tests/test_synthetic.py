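"""Synthetic ground truth: CPT generators, forward sampling, continuous
emulation, and the end-to-end recovery property."""

import numpy as np
import pytest

from droughtbn import (
    EmulationParams,
    binarize_by_mean,
    continuous_emulation,
    fit_cpts,
    forward_sample_dataset,
    min_max_normalize,
    random_cpts,
)


class TestRandomCpts:
    @pytest.mark.parametrize("mode", ["uniform", "strong"])
    def test_thetas_strictly_inside_unit_interval(self, drought_net, mode):
        cpts = random_cpts(drought_net, seed=0, mode=mode)
        for node in drought_net.nodes:
            th = cpts[node].theta
            assert (th > 0).all() and (th < 1).all()

    def test_same_seed_same_cpts(self, drought_net):
        a = random_cpts(drought_net, seed=7)
        b = random_cpts(drought_net, seed=7)
        for node in drought_net.nodes:
            np.testing.assert_array_equal(a[node].theta, b[node].theta)

    def test_different_seed_different_cpts(self, drought_net):
        a = random_cpts(drought_net, seed=7)
        b = random_cpts(drought_net, seed=8)
        assert any(
            not np.array_equal(a[n].theta, b[n].theta) for n in drought_net.nodes
        )

    def test_strong_mode_respects_activating_sign(self, drought_net):
        cpts = random_cpts(drought_net, seed=0, mode="strong")
        # WRKY18 -> RD29A is activating: flipping WRKY18 on (others fixed off)
        # must raise theta
        tab = cpts["RD29A"]
        i = tab.parents.index("WRKY18")
        off = {p: 0 for p in tab.parents}
        on = dict(off, WRKY18=1)
        assert tab.theta_for(on) > tab.theta_for(off)
        # WRKY40 -> RD29A is inhibiting: the opposite
        off2 = {p: 0 for p in tab.parents}
        assert tab.theta_for(dict(off2, WRKY40=1)) < tab.theta_for(off2)

    def test_unknown_mode_rejected(self, drought_net):
        with pytest.raises(ValueError, match="mode"):
            random_cpts(drought_net, seed=0, mode="exotic")


class TestForwardSampling:
    def test_shape(self, drought_net):
        cpts = random_cpts(drought_net, seed=1)
        data = forward_sample_dataset(drought_net, cpts, n=50, seed=2)
        assert data.data.shape == (50, drought_net.n_nodes)
        assert list(data.data.columns) == list(drought_net.nodes)

    def test_root_frequency_within_binomial_bound(self, example_net, example_cpts):
        n = 10_000
        data = forward_sample_dataset(example_net, example_cpts, n=n, seed=3)
        theta = 0.6  # root A
        freq = data.data["A"].mean()
        assert abs(freq - theta) <= 3 * np.sqrt(theta * (1 - theta) / n)

    def test_conditional_frequency_matches_cpt(self, example_net, example_cpts):
        n = 10_000
        data = forward_sample_dataset(example_net, example_cpts, n=n, seed=4)
        stratum = data.data[data.data["A"] == 1]
        theta = 0.9  # P(B=1 | A=1)
        freq = stratum["B"].mean()
        assert abs(freq - theta) <= 3 * np.sqrt(theta * (1 - theta) / len(stratum))


class TestContinuousEmulation:
    def test_dimensions_and_finiteness(self, drought_net):
        cpts = random_cpts(drought_net, seed=5)
        emu = continuous_emulation(drought_net, cpts, EmulationParams(n=30, seed=6))
        assert emu.expression.shape == (30, drought_net.n_nodes)
        assert np.isfinite(emu.expression.to_numpy()).all()
        assert emu.latent.data.shape == emu.expression.shape

    def test_tiny_sigma_recovery_is_exact(self, example_net, example_cpts):
        params = EmulationParams(n=104, mu0=0.0, mu1=1.0, sigma=1e-9, seed=7)
        emu = continuous_emulation(example_net, example_cpts, params)
        recovered = binarize_by_mean(min_max_normalize(emu.expression))
        for col in emu.expression.columns:
            if emu.latent.data[col].nunique() == 2:  # both states present
                assert (recovered.data[col] == emu.latent.data[col]).all()

    def test_six_sigma_separation_recovers_latent_states(self, drought_net):
        # balanced columns: theta = 0.5 everywhere keeps every marginal at 1/2
        from conftest import make_cpts
        cpts = make_cpts(drought_net, {n: 0.5 for n in drought_net.nodes})
        params = EmulationParams(n=104, mu0=6.0, mu1=12.0, sigma=1.0, seed=9)
        emu = continuous_emulation(drought_net, cpts, params)
        recovered = binarize_by_mean(min_max_normalize(emu.expression))
        agree = (recovered.data.to_numpy() == emu.latent.data.to_numpy()).mean()
        assert agree >= 0.99

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            EmulationParams(n=1)
        with pytest.raises(ValueError):
            EmulationParams(mu0=2.0, mu1=1.0)
        with pytest.raises(ValueError):
            EmulationParams(sigma=0.0)


def test_end_to_end_parameter_recovery(example_net):
    """continuous emulation → preprocessing → CPT fit recovers ground truth
    on well-observed strata at n = 5,000 under strong separation.

    Ground-truth θ are kept in (0.3, 0.7): the mean-threshold decoder needs
    roughly balanced columns, since the threshold approaches the majority
    cluster as min(p, 1−p) → 0 and starts flipping its tail.
    """
    from conftest import make_cpts
    rng = np.random.default_rng(10)
    truth = make_cpts(example_net, {
        node: {
            tuple((idx >> i) & 1 for i in range(len(example_net.parents(node)))):
            float(rng.uniform(0.3, 0.7))
            for idx in range(1 << len(example_net.parents(node)))
        }
        for node in example_net.nodes
    })
    params = EmulationParams(n=5_000, mu0=6.0, mu1=16.0, sigma=1.0, seed=11)
    emu = continuous_emulation(example_net, truth, params)
    binary = binarize_by_mean(min_max_normalize(emu.expression))
    fitted = fit_cpts(example_net, binary.data)
    for node in example_net.nodes:
        ft, tt = fitted[node], truth[node]
        for idx in range(ft.n_configs):
            if ft.n[idx] >= 200:
                assert abs(ft.theta[idx] - tt.theta[idx]) < 0.05
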