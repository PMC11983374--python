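"""Synthetic sample generator: occurrence statistics and mass closure."""

import numpy as np
import pytest
from scipy import stats

from cmxrf import samples
from cmxrf.samples import Composition, OccurrenceTable, TARGET_ELEMENTS


def _table(rates, mus=None, sigmas=None):
    n = len(TARGET_ELEMENTS)
    rates = np.asarray(rates, dtype=float)
    mus = np.full(n, np.log(1e-3)) if mus is None else np.asarray(mus)
    sigmas = np.full(n, 1.0) if sigmas is None else np.asarray(sigmas)
    return OccurrenceTable(TARGET_ELEMENTS, rates, mus, sigmas)


def test_target_element_list():
    assert len(TARGET_ELEMENTS) == 53
    assert 36 not in TARGET_ELEMENTS and 54 not in TARGET_ELEMENTS  # Kr, Xe
    assert TARGET_ELEMENTS[0] == 19 and TARGET_ELEMENTS[-1] == 83  # K .. Bi


def test_all_rates_zero_gives_pure_dark_matrix():
    comp = samples.draw_composition(_table(np.zeros(53)), rng=0)
    assert comp.mass_fractions == {}
    assert comp.dark_matrix_fraction == 1.0


def test_forced_draw_with_degenerate_lognormal():
    rates = np.zeros(53)
    i_fe = TARGET_ELEMENTS.index(26)
    rates[i_fe] = 1.0
    mus = np.full(53, np.log(1e-3))
    mus[i_fe] = np.log(0.05)
    tab = _table(rates, mus, np.full(53, 1e-9))
    comp = samples.draw_composition(tab, rng=1)
    assert set(comp.mass_fractions) == {26}
    assert comp.mass_fractions[26] == pytest.approx(0.05, rel=1e-6)
    assert comp.dark_matrix_fraction == pytest.approx(0.95, rel=1e-6)


def test_presence_frequency_matches_rate():
    rates = np.zeros(53)
    i_zn = TARGET_ELEMENTS.index(30)
    rates[i_zn] = 0.3
    tab = _table(rates)
    rng = np.random.default_rng(42)
    n = 10_000
    hits = sum(30 in samples.draw_composition(tab, rng).mass_fractions for _ in range(n))
    se = np.sqrt(0.3 * 0.7 / n)
    assert abs(hits / n - 0.3) < 3 * se


def test_mass_closure_exact():
    tab = samples.default_occurrence_table()
    rng = np.random.default_rng(7)
    for _ in range(200):
        comp = samples.draw_composition(tab, rng)
        total = sum(comp.mass_fractions.values()) + comp.dark_matrix_fraction
        assert total == pytest.approx(1.0, abs=1e-12)
        assert all(w >= 0 for w in comp.mass_fractions.values())


def test_detectable_cap_rescales_proportionally():
    rates = np.zeros(53)
    mus = np.full(53, np.log(1e-3))
    for z, w in ((26, 0.4), (20, 0.2)):
        i = TARGET_ELEMENTS.index(z)
        rates[i] = 1.0
        mus[i] = np.log(w)
    tab = _table(rates, mus, np.full(53, 1e-9))
    comp = samples.draw_composition(tab, rng=3)
    total = sum(comp.mass_fractions.values())
    assert total == pytest.approx(samples.DETECTABLE_CAP, rel=1e-6)
    # proportions preserved: Fe:Ca stays 2:1
    assert comp.mass_fractions[26] / comp.mass_fractions[20] == pytest.approx(2.0, rel=1e-5)


def test_drawn_concentrations_follow_the_lognormal():
    """KS comparison of 10^4 draws against the configured log-normal."""
    rates = np.zeros(53)
    i = TARGET_ELEMENTS.index(30)
    rates[i] = 1.0
    mu, sigma = np.log(2e-4), 0.8
    mus = np.full(53, np.log(1e-6))
    mus[i] = mu
    sigmas = np.full(53, 1e-9)
    sigmas[i] = sigma
    tab = _table(rates, mus, sigmas)
    rng = np.random.default_rng(5)
    draws = np.array(
        [samples.draw_composition(tab, rng).mass_fractions[30] for _ in range(10_000)]
    )
    res = stats.kstest(np.log(draws), stats.norm(loc=mu, scale=sigma).cdf)
    assert res.pvalue > 0.01


def test_density_bounds_and_mean():
    rng = np.random.default_rng(11)
    draws = np.array([samples.draw_density(rng) for _ in range(10_000)])
    assert draws.min() >= 0.5 and draws.max() <= 3.5
    se = (3.5 - 0.5) / np.sqrt(12) / np.sqrt(len(draws))
    assert abs(draws.mean() - 2.0) < 3 * se


def test_density_degenerate_interval():
    assert samples.draw_density(0, lo=2.0, hi=2.0) == 2.0
    with pytest.raises(ValueError):
        samples.draw_density(0, lo=3.0, hi=1.0)


def test_identical_seed_identical_stream():
    tab = samples.default_occurrence_table()
    a = samples.draw_batch(20, tab, seed=9)
    b = samples.draw_batch(20, tab, seed=9)
    for ca, cb in zip(a, b):
        assert ca.mass_fractions == cb.mass_fractions
        assert ca.density == cb.density


def test_build_table_counts_occurrences():
    refs = [Composition({26: 0.01}, 2.0) for _ in range(3)]
    refs += [Composition({20: 0.02}, 2.0) for _ in range(7)]
    tab = samples.build_occurrence_table(refs)
    assert tab.rate[TARGET_ELEMENTS.index(26)] == pytest.approx(0.3)
    assert tab.rate[TARGET_ELEMENTS.index(20)] == pytest.approx(0.7)
    assert tab.rate[TARGET_ELEMENTS.index(82)] == 0.0


def test_build_table_degenerate_fit_uses_sigma_floor():
    refs = [Composition({26: 0.01}, 2.0) for _ in range(5)]
    tab = samples.build_occurrence_table(refs)
    i = TARGET_ELEMENTS.index(26)
    assert tab.rate[i] == 1.0
    assert tab.lognorm_sigma[i] == pytest.approx(1e-6)
    assert tab.lognorm_mu[i] == pytest.approx(np.log(0.01))


def test_build_table_recovers_lognormal_parameters():
    mu, sigma = np.log(5e-3), 0.9
    rng = np.random.default_rng(21)
    refs = [Composition({26: float(np.exp(rng.normal(mu, sigma)))}, 2.0) for _ in range(500)]
    tab = samples.build_occurrence_table(refs)
    i = TARGET_ELEMENTS.index(26)
    assert tab.lognorm_mu[i] == pytest.approx(mu, rel=0.1)
    assert tab.lognorm_sigma[i] == pytest.approx(sigma, rel=0.1)


def test_occurrence_table_csv_roundtrip(tmp_path):
    tab = samples.default_occurrence_table()
    path = tmp_path / "table.csv"
    tab.to_csv(path)
    back = OccurrenceTable.from_csv(path)
    assert back.elements == tab.elements
    np.testing.assert_allclose(back.rate, tab.rate)
    np.testing.assert_allclose(back.lognorm_mu, tab.lognorm_mu)


def test_composition_jsonl_roundtrip(tmp_path):
    comps = samples.draw_batch(10, seed=2)
    path = tmp_path / "comps.jsonl"
    samples.save_compositions(comps, path)
    back = samples.load_compositions(path)
    assert len(back) == 10
    for a, b in zip(comps, back):
        assert a.mass_fractions == b.mass_fractions
        assert a.density == b.density


def test_composition_validation():
    with pytest.raises(ValueError):
        Composition({26: -0.1}, 2.0)
    with pytest.raises(ValueError):
        Composition({26: 0.5}, 2.0, dark_matrix_fraction=0.2)
    with pytest.raises(ValueError):
        Composition({26: 0.1}, -1.0)
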