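"""Folding-time CDF, folding characteristic, hump detection."""

import numpy as np
import pytest

import ssafold as sf
from ssafold.analysis import (exponential_characteristic,
                              mixture_characteristic)
from ssafold.errors import DegenerateSampleError


def test_empirical_cdf():
    sample = sf.FoldingTimeSample(np.array([1.0, 10.0, 100.0]))
    grid = np.array([0.5, 1.0, 10.0, 150.0])
    assert np.allclose(sf.folding_time_cdf(sample, grid),
                       [0, 1 / 3, 2 / 3, 1.0])


def test_censored_molecules_never_fold():
    sample = sf.FoldingTimeSample(np.array([5.0]), censored=[3, 2, 4])
    grid = sf.log_time_grid(sample)
    P = sf.folding_time_cdf(sample, grid)
    assert P[-1] == pytest.approx(1 / 4)


def test_cdf_invariant_to_order_and_grid_refinement():
    rng = np.random.default_rng(0)
    times = rng.exponential(1.0, 500)
    grid = np.logspace(-3, 2, 101)
    a = sf.folding_time_cdf(sf.FoldingTimeSample(times), grid)
    b = sf.folding_time_cdf(sf.FoldingTimeSample(times[::-1]), grid)
    fine = np.logspace(-3, 2, 201)  # shares every coarse point
    c = sf.folding_time_cdf(sf.FoldingTimeSample(times), fine)
    assert np.array_equal(a, b)
    assert np.array_equal(a, c[::2])


def test_empty_sample_rejected():
    with pytest.raises(ValueError):
        sf.folding_time_cdf(sf.FoldingTimeSample(np.array([])),
                            np.array([1.0]))


def test_exponential_characteristic_closed_form_shape():
    """lambda*t*exp(-lt)/(1-exp(-lt)): monotone decreasing from 1."""
    grid = np.logspace(-3, 2, 200)
    curve = exponential_characteristic(1.0, grid)
    assert curve[0] == pytest.approx(1.0, abs=1e-3)
    assert (np.diff(curve) < 1e-12).all()


def test_single_exponential_has_no_humps():
    rng = np.random.default_rng(8)
    fc = sf.folding_characteristic(
        sf.FoldingTimeSample(rng.exponential(1.0, 2000)))
    assert fc.n_humps == 0
    assert sf.count_humps(fc) == 0


def test_two_timescale_mixture_has_two_humps():
    """Rates three decades apart produce one hump per timescale."""
    fc = sf.folding_characteristic(
        sf.FoldingTimeSample(sf.two_timescale_sample()))
    assert fc.n_humps == 2
    (t1, _), (t2, _) = fc.humps
    assert 2.5 < np.log10(t2 / t1) < 3.5


def test_hump_count_stable_to_bandwidth():
    """Halving/doubling the bandwidth keeps the mixture at 2 humps."""
    sample = sf.FoldingTimeSample(sf.two_timescale_sample())
    base = sf.folding_characteristic(sample).bandwidth
    for factor in (0.5, 2.0):
        fc = sf.folding_characteristic(sample, bandwidth=base * factor)
        assert fc.n_humps == 2


def test_characteristic_tail_vanishes():
    rng = np.random.default_rng(3)
    fc = sf.folding_characteristic(
        sf.FoldingTimeSample(rng.exponential(1.0, 2000)))
    # where P = 1 and the density has died, t*P'/P ~ 0
    assert fc.characteristic[-1] < 1e-3
    assert fc.P[-1] == 1.0


def test_characteristic_nan_only_where_P_zero():
    rng = np.random.default_rng(4)
    fc = sf.folding_characteristic(
        sf.FoldingTimeSample(rng.exponential(1.0, 200)))
    nan = ~np.isfinite(fc.characteristic)
    assert (fc.P[nan] == 0).all()
    finite = fc.characteristic[~nan]
    assert (finite >= 0).all()


def test_density_integrates_back_to_cdf():
    """Trapezoid-integrating the estimated P' recovers P within 2%
    where P > 0.1."""
    rng = np.random.default_rng(5)
    sample = sf.FoldingTimeSample(rng.exponential(1.0, 5000))
    fc = sf.folding_characteristic(sample)
    integral = np.concatenate(
        [[0.0], np.cumsum(0.5 * (fc.dPdt[1:] + fc.dPdt[:-1])
                          * np.diff(fc.grid))])
    mask = fc.P > 0.1
    assert np.abs(integral[mask] - fc.P[mask]).max() < 0.02


def test_degenerate_sample_rejected():
    with pytest.raises(DegenerateSampleError):
        sf.folding_characteristic(sf.FoldingTimeSample(np.full(100, 2.0)))


def test_small_sample_warns():
    rng = np.random.default_rng(6)
    with pytest.warns(UserWarning, match="unstable"):
        sf.folding_characteristic(
            sf.FoldingTimeSample(rng.exponential(1.0, 20)))


def test_plot_characteristic_writes_file(tmp_path):
    pytest.importorskip("matplotlib")
    fc = sf.folding_characteristic(
        sf.FoldingTimeSample(sf.two_timescale_sample(n=500)))
    out = tmp_path / "characteristic.png"
    sf.analysis.plot_characteristic(fc, path=out)
    assert out.stat().st_size > 0


def test_mixture_characteristic_limits():
    grid = np.logspace(-4, 5, 300)
    curve = mixture_characteristic((1.0, 1e-3), (0.5, 0.5), grid)
    assert curve[0] == pytest.approx(1.0, abs=1e-2)
    assert curve[-1] < 1e-2
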