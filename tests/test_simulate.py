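"""Synthetic campaign generator: determinism, ground truth, boundary builder."""

import io as _stdio

import numpy as np
import pytest

from olfrisk import (
    DEFAULT_SCENARIOS,
    GeneratorParams,
    assess_campaign,
    generate_campaign,
    mixture_inhalation_risk,
    minimum_dilution,
    perturb_to_boundary,
    write_sample_table,
)
from olfrisk.cancer import cdi_multiplier
from olfrisk.hazard import assess_noncarcinogenic
from olfrisk.simulate import (
    DEFAULT_PALETTE,
    expected_method1_hi,
    expected_mixture_ir,
)
from olfrisk.types import ValidationError


def _campaign_csv(campaign):
    buf = _stdio.StringIO()
    write_sample_table(campaign.samples, buf)
    return buf.getvalue()


def test_same_seed_byte_identical():
    a = generate_campaign(GeneratorParams(n_samples=18, seed=42))
    b = generate_campaign(GeneratorParams(n_samples=18, seed=42))
    assert _campaign_csv(a) == _campaign_csv(b)
    assert a.truth.equals(b.truth)


def test_different_seed_differs():
    a = generate_campaign(GeneratorParams(n_samples=5, seed=1))
    b = generate_campaign(GeneratorParams(n_samples=5, seed=2))
    assert _campaign_csv(a) != _campaign_csv(b)


def test_sample_count_and_sources():
    campaign = generate_campaign(GeneratorParams(n_samples=18, seed=3))
    assert len(campaign.samples) == 18
    areas = {s.area for s in campaign.samples}
    assert areas == {"Wastewater treatment", "Vapour recovery unit system", "Tanks"}


def test_invalid_params_rejected_before_drawing():
    with pytest.raises(ValidationError):
        GeneratorParams(n_samples=0)
    with pytest.raises(ValidationError):
        GeneratorParams(palette=())
    with pytest.raises(ValidationError):
        GeneratorParams(uncovered_fraction_target=1.5)


def test_zero_uncovered_fraction_gives_full_method1_coverage():
    campaign = generate_campaign(
        GeneratorParams(n_samples=6, seed=11, uncovered_fraction_target=0.0)
    )
    assert campaign.uncovered == ()
    t = campaign.truth
    np.testing.assert_allclose(t.hi_m1, t.hi_m2, rtol=1e-12)
    np.testing.assert_allclose(t.hi_m1, t.hi_m3, rtol=1e-12)
    assert (t.nc_count_m1 == 0).all()


def test_carcinogen_only_palette_two_term_risk():
    palette = tuple(
        t for t in DEFAULT_PALETTE if t.name in ("benzene", "naphthalene")
    )
    campaign = generate_campaign(GeneratorParams(n_samples=3, seed=5, palette=palette))
    scen = campaign.scenarios[0]
    m = cdi_multiplier(scen)
    for sample, (_, truth_row) in zip(campaign.samples, campaign.truth.iterrows()):
        by_name = {c.name: c.concentration for c in sample.compounds}
        expected = (
            by_name["benzene"] * 1000 * m * 7.8e-6
            + by_name["naphthalene"] * 1000 * m * 3.4e-5
        )
        assert truth_row[f"ir_{scen.label}"] == pytest.approx(expected, rel=1e-12)


def test_pipeline_matches_ground_truth_on_one_campaign():
    campaign = generate_campaign(GeneratorParams(n_samples=18, seed=77))
    t = campaign.truth
    for method, col in ((1, "hi_m1"), (2, "hi_m2"), (3, "hi_m3")):
        a = assess_campaign(
            campaign.samples, campaign.catalogues, campaign.scenarios,
            campaign.criteria, method=method,
        )
        np.testing.assert_allclose(a.risk.hi, t[col], rtol=1e-9)
    a1 = assess_campaign(
        campaign.samples, campaign.catalogues, campaign.scenarios,
        campaign.criteria, method=1,
    )
    for scen in campaign.scenarios:
        np.testing.assert_allclose(a1.risk[f"ir_{scen.label}"], t[f"ir_{scen.label}"],
                                   rtol=1e-9)
    np.testing.assert_allclose(a1.risk.d_min, t.d_min, rtol=1e-9)


class TestPerturbToBoundary:
    def test_boundary_sample_has_unit_dilution(self, default_campaign, criteria):
        campaign = default_campaign
        scen = campaign.scenarios[0]
        sample = perturb_to_boundary(
            campaign.samples[0], campaign.catalogues, criteria, scen
        )
        nc = assess_noncarcinogenic(sample, campaign.catalogues, 1)
        carc = mixture_inhalation_risk(sample, campaign.catalogues, scen)
        rec = minimum_dilution(nc, carc, criteria)
        assert rec.d_min == pytest.approx(1.0, rel=1e-9)

    @pytest.mark.parametrize("k", [1.78, 0.5])
    def test_rescaling_from_boundary_is_linear(self, default_campaign, criteria, k):
        campaign = default_campaign
        scen = campaign.scenarios[0]
        boundary = perturb_to_boundary(
            campaign.samples[2], campaign.catalogues, criteria, scen
        )
        moved = boundary.scaled(k)
        nc = assess_noncarcinogenic(moved, campaign.catalogues, 1)
        carc = mixture_inhalation_risk(moved, campaign.catalogues, scen)
        rec = minimum_dilution(nc, carc, criteria)
        if k > 1:
            assert rec.d_min == pytest.approx(k, rel=1e-9)
        else:
            assert not rec.necessary

    def test_requires_a_carcinogen_with_iur(self, criteria):
        palette = tuple(t for t in DEFAULT_PALETTE if t.carcinogen_class == "none")
        campaign = generate_campaign(GeneratorParams(n_samples=1, seed=9,
                                                     palette=palette))
        with pytest.raises(ValidationError, match="carcinogen"):
            perturb_to_boundary(campaign.samples[0], campaign.catalogues,
                                criteria, campaign.scenarios[0])


def test_mean_risk_matches_analytic_expectation():
    """Empirical mean HI and IR over many campaigns sit within Monte-Carlo
    error of the palette's lognormal-moment expectation."""
    params = GeneratorParams(n_samples=18, seed=0)
    e_hi = expected_method1_hi(params)
    e_ir = expected_mixture_ir(params, DEFAULT_SCENARIOS[0])
    his, irs = [], []
    for seed in range(40):
        c = generate_campaign(GeneratorParams(n_samples=18, seed=seed))
        his.extend(c.truth.hi_m1)
        irs.extend(c.truth.ir_commercial)
    n = len(his)
    hi_mean, hi_sem = np.mean(his), np.std(his, ddof=1) / np.sqrt(n)
    ir_mean, ir_sem = np.mean(irs), np.std(irs, ddof=1) / np.sqrt(n)
    assert abs(hi_mean - e_hi) < 4 * hi_sem
    assert abs(ir_mean - e_ir) < 4 * ir_sem
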