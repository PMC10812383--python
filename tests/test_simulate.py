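"""Synthetic-cohort generator: determinism, truth recovery, mixtures."""

import numpy as np
import pytest

import polestrat as ps
from polestrat.simulate import (
    GroupSpec,
    SyntheticCohortConfig,
    _DEFAULT_GROUPS,
    default_config,
    simulate_variants_from_signature,
)


def test_same_seed_identical_cohorts(catalog):
    config = default_config(123, catalog)
    p1, t1 = ps.simulate_cohort(config, catalog=catalog)
    p2, t2 = ps.simulate_cohort(config, catalog=catalog)
    assert p1 == p2
    assert t1.group_labels == t2.group_labels
    assert t1.variant_components == t2.variant_components


def test_different_seeds_differ(catalog):
    p1, _ = ps.simulate_cohort(default_config(1, catalog), catalog=catalog)
    p2, _ = ps.simulate_cohort(default_config(2, catalog), catalog=catalog)
    assert p1 != p2


def test_group_labels_recovered_exactly(small_cohort, catalog):
    """The taxonomy is deterministic, so truth labels reproduce exactly."""
    profiles, truth = small_cohort
    assignments = ps.assign_groups(profiles, catalog)
    for p in profiles:
        assert assignments[p.tumor_id].group == truth.group_labels[p.tumor_id]


def test_group_structure_by_construction(small_cohort, catalog):
    profiles, truth = small_cohort
    for p in profiles:
        drivers = [v for v in ps.flag_drivers(p.pole_variants, catalog) if v.is_exod_driver]
        g = truth.group_labels[p.tumor_id]
        if g == "G1":
            assert p.tmb < 10 and not drivers
        elif g == "G2":
            assert p.tmb >= 10 and len(drivers) == len(p.pole_variants) >= 1
        elif g == "G3":
            assert p.tmb >= 10 and drivers and len(p.pole_variants) > len(drivers)
        else:
            assert p.tmb >= 10 and not drivers


def test_infeasible_g1_tmb_config_rejected(catalog):
    groups = dict(_DEFAULT_GROUPS)
    groups[("CRC", "G1")] = GroupSpec(10, 8, 3, 15)  # mass above threshold
    with pytest.raises(ValueError, match="TMB-low"):
        SyntheticCohortConfig(
            seed=0, groups=groups,
            driver_frequencies=default_config(0, catalog).driver_frequencies,
        )


def test_target_median_recovered_ec_g3(catalog):
    """EC Group-3 TMB median (target 219) recovered within 15% over replicates."""
    groups = {("EC", "G3"): _DEFAULT_GROUPS[("EC", "G3")]}
    base = default_config(0, catalog)
    medians = []
    for seed in range(20):
        config = SyntheticCohortConfig(
            seed=seed, groups=groups, driver_frequencies=base.driver_frequencies
        )
        profiles, _ = ps.simulate_cohort(config, catalog=catalog)
        assert len(profiles) == 57
        med, _, _ = ps.median_range([p.tmb for p in profiles])
        medians.append(med)
    assert abs(np.mean(medians) - 219) / 219 < 0.15


def test_pure_signature_mixture_matches_closed_form(
    signatures, transcript, channel_index, context_sets
):
    """100% SBS10b draws land in the context-set union at the rate the
    vector itself predicts, within 3 binomial standard errors."""
    rng = np.random.default_rng(2024)
    k = 1000
    variants, comps = simulate_variants_from_signature(
        k, {"SBS10b": 1.0}, signatures, transcript, rng,
        channel_index=channel_index, require_protein_altering=False,
    )
    assert set(comps) == {"SBS10b"}
    union = set().union(*(s.included_channels for s in context_sets))
    expected = sum(
        p for ch, p in signatures["SBS10b"].probs.items() if ch in union
    )
    calls = [ps.classify_variant_context(v, context_sets, transcript) for v in variants]
    frac = ps.fraction_in_context(calls).fraction
    se = np.sqrt(expected * (1 - expected) / k)
    assert abs(frac - expected) <= 3 * se


def test_uniform_noise_matches_channel_census(
    signatures, transcript, channel_index, context_sets
):
    rng = np.random.default_rng(77)
    k = 1000
    variants, comps = simulate_variants_from_signature(
        k, {"uniform_noise": 1.0}, signatures, transcript, rng,
        channel_index=channel_index, require_protein_altering=False,
    )
    union = set().union(*(s.included_channels for s in context_sets))
    realizable = [ch for ch, sites in channel_index.items() if sites]
    expected = sum(1 for ch in realizable if ch in union) / len(realizable)
    calls = [ps.classify_variant_context(v, context_sets, transcript) for v in variants]
    frac = ps.fraction_in_context(calls).fraction
    se = np.sqrt(expected * (1 - expected) / k)
    assert abs(frac - expected) <= 3 * se


def test_channel_distribution_chi_square_goodness_of_fit(
    signatures, transcript, channel_index
):
    """Empirical channel counts fit the mixture-weighted distribution."""
    from scipy.stats import chisquare

    from polestrat.signatures import all_channels

    mixture = {"SBS10a": 0.5, "SBS10b": 0.5}
    channels = all_channels()
    expected_p = np.array(
        [
            0.5 * signatures["SBS10a"].probs[c] + 0.5 * signatures["SBS10b"].probs[c]
            for c in channels
        ]
    )
    rejections = 0
    n_seeds, k = 5, 5000
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        variants, _ = simulate_variants_from_signature(
            k, mixture, signatures, transcript, rng,
            channel_index=channel_index, require_protein_altering=False,
        )
        counts = {c: 0 for c in channels}
        for v in variants:
            ch = ps.channel_of(v.coding_change, transcript)
            counts[ch] += 1
        observed = np.array([counts[c] for c in channels], dtype=float)
        # pool low-expectation channels to keep the chi-square valid
        big = expected_p * k >= 5
        obs, exp = observed[big], expected_p[big] * k
        if (~big).any():
            obs = np.append(obs, observed[~big].sum())
            exp = np.append(exp, expected_p[~big].sum() * k)
        _, p = chisquare(obs, exp * obs.sum() / exp.sum())
        assert np.isfinite(p)
        if p < 0.01:
            rejections += 1
    assert rejections <= 1


def test_zero_draws_give_empty_list(signatures, transcript, channel_index):
    rng = np.random.default_rng(0)
    variants, comps = simulate_variants_from_signature(
        0, {"SBS10b": 1.0}, signatures, transcript, rng, channel_index=channel_index
    )
    assert variants == [] and comps == []


def test_driver_prevalence_concentrated_on_p286r_v411l(small_cohort, catalog):
    profiles, truth = small_cohort
    driver_tumors = [
        p for p in profiles if truth.group_labels[p.tumor_id] in {"G2", "G3"}
    ]
    top = 0
    for p in driver_tumors:
        labels = {
            v.raw_label for v in ps.flag_drivers(p.pole_variants, catalog)
            if v.is_exod_driver
        }
        if labels & {"P286R", "V411L"}:
            top += 1
    share = top / len(driver_tumors)
    assert 0.55 <= share <= 0.80  # ~67% by construction
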