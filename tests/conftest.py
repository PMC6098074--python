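import numpy as np
import pytest

from crtuning import syngen


@pytest.fixture(scope="session")
def tuned_cell():
    """A well-tuned model cell used across forward-model tests."""
    return syngen.GroundTruthCell(
        cell_id=0, marked=True, depth_um=200.0, pref_direction=30.0,
        kappa_ori=2.0, dir_bias=0.4, rf_x=0.0, rf_y=0.0,
        sigma_exc=9.0, sigma_inh=25.0, inh_weight=0.3,
        sf_sigma=0.12, sf_inh_ratio=0.5, sf_inh_scale=0.3,
        tf_sigma=6.0, tf_inh_ratio=0.3, tf_inh_scale=0.3,
        c50_true=15.0, nr_exponent=2.0, rate_max=10.0, rate_baseline=1.5)


@pytest.fixture(scope="session")
def flat_cell():
    """An untuned cell (zero concentration, symmetric lobes)."""
    return syngen.GroundTruthCell(
        cell_id=1, marked=False, depth_um=250.0, pref_direction=0.0,
        kappa_ori=0.0, dir_bias=1.0, rf_x=0.0, rf_y=0.0,
        sigma_exc=9.0, sigma_inh=25.0, inh_weight=0.3,
        sf_sigma=0.12, sf_inh_ratio=0.5, sf_inh_scale=0.3,
        tf_sigma=6.0, tf_inh_ratio=0.3, tf_inh_scale=0.3,
        c50_true=15.0, nr_exponent=2.0, rate_max=10.0, rate_baseline=1.5)


@pytest.fixture(scope="session")
def ori_protocol():
    return syngen.build_protocol("orientation", 300.0, seed=11)


@pytest.fixture(scope="session")
def small_population():
    return syngen.generate_population(7, dict(n_marked=10, n_unmarked=20))


def make_curve(values, means):
    from crtuning.tuning import TuningCurve
    values = np.asarray(values, float)
    return TuningCurve(values, np.asarray(means, float),
                       np.zeros(len(values)), np.ones(len(values), int))
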