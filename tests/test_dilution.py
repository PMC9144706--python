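"""Minimum-dilution derivation, ladder snapping and the campaign table."""

import numpy as np
import pytest

from olfrisk import (
    AcceptabilityCriteria,
    CarcRisk,
    LadderExceededError,
    NonCarcRisk,
    OlfactometerLadder,
    dilution_table,
    minimum_dilution,
    snap_to_ladder,
)
from olfrisk.datasets import published_campaign
from olfrisk.types import ValidationError


def _nc(hi, sample_id="S1"):
    return NonCarcRisk(sample_id=sample_id, method=1, hi=hi, hq_by_compound={},
                       nc_percent_count=0.0, nc_percent_mass=0.0)


def _carc(ir, sample_id="S1", label="commercial", singles=None):
    return CarcRisk(
        sample_id=sample_id, scenario_label=label, ir_mixture=ir,
        ir_by_compound=singles, cdi_multiplier=float("nan"),
    )


class TestMinimumDilution:
    def test_mixture_criterion_binding(self):
        # HI 0.227 acceptable; mixture IR 1.78e-5 needs dilution 1.78
        rec = minimum_dilution(_nc(0.227), _carc(1.78e-5))
        assert rec.d_min == pytest.approx(1.78)
        assert rec.d_min_2dp == 1.78
        assert rec.binding_criterion == "ir_mixture[commercial]"
        assert rec.necessary

    def test_sample_within_all_criteria_not_necessary(self):
        rec = minimum_dilution(_nc(0.152), _carc(9.38e-6))
        assert not rec.necessary
        assert rec.d_min == 1.0
        assert rec.binding_criterion == "none"

    def test_hi_criterion_binding(self):
        rec = minimum_dilution(_nc(2.0), _carc(5e-6))
        assert rec.d_min == pytest.approx(2.0)
        assert rec.binding_criterion == "hi"

    def test_single_compound_criterion(self):
        rec = minimum_dilution(
            _nc(0.1), _carc(5e-6, singles={"benzene": 3e-6, "naphthalene": 2e-6})
        )
        assert rec.d_min == pytest.approx(3.0)  # 3e-6 / 1e-6
        assert rec.binding_criterion == "ir_single[commercial]"

    def test_d_min_is_max_over_criteria(self):
        rec = minimum_dilution(
            _nc(1.5),
            [_carc(2.3e-5, label="commercial"), _carc(4e-6, label="institutional")],
        )
        assert rec.d_min == pytest.approx(
            max(rec.d_hi, *rec.d_ir_mixture.values(), *rec.d_ir_single.values())
        )
        assert rec.d_min == pytest.approx(2.3)

    def test_mixed_sample_ids_rejected(self):
        with pytest.raises(ValidationError):
            minimum_dilution(_nc(0.1, "S1"), _carc(2e-5, "S2"))


class TestSnapToLadder:
    def test_snaps_up_to_first_step(self):
        assert snap_to_ladder(1.78, OlfactometerLadder()) == 4.0

    def test_no_dilution_needed(self):
        assert snap_to_ladder(1.0, OlfactometerLadder()) is None

    def test_linear_scan(self):
        assert snap_to_ladder(5.0, OlfactometerLadder()) == 8.0
        assert snap_to_ladder(4.0, OlfactometerLadder()) == 4.0

    def test_above_top_step_flagged(self):
        with pytest.raises(LadderExceededError):
            snap_to_ladder(10.0, OlfactometerLadder(steps=(4.0, 8.0)))


@pytest.fixture(scope="module")
def random_risks():
    rng = np.random.default_rng(99)
    out = []
    for i in range(1000):
        hi = float(rng.lognormal(-1.2, 1.0))
        ir_c = float(rng.lognormal(np.log(1.5e-5), 1.0))
        singles = {"benzene": ir_c * float(rng.uniform(0.3, 0.9))}
        out.append((_nc(hi, f"S{i}"), _carc(ir_c, f"S{i}", singles=singles)))
    return out


class TestPolicyInvariants:
    """Correctness, minimality and monotonicity of d_min by linearity."""

    def test_diluting_by_d_min_restores_acceptability(self, random_risks, criteria):
        for nc, carc in random_risks:
            rec = minimum_dilution(nc, carc, criteria)
            d = rec.d_min
            assert nc.hi / d <= criteria.hi_max * (1 + 1e-12)
            assert carc.ir_mixture / d <= criteria.ir_mixture_max * (1 + 1e-12)
            assert carc.ir_single_max / d <= criteria.ir_single_max * (1 + 1e-12)

    def test_minimality(self, random_risks, criteria):
        for nc, carc in random_risks:
            rec = minimum_dilution(nc, carc, criteria)
            if not rec.necessary:
                continue
            d_short = rec.d_min / (1 + 1e-6)
            violated = (
                nc.hi / d_short > criteria.hi_max
                or carc.ir_mixture / d_short > criteria.ir_mixture_max
                or carc.ir_single_max / d_short > criteria.ir_single_max
            )
            assert violated

    def test_monotone_in_concentration(self, random_risks, criteria):
        for nc, carc in random_risks[:200]:
            rec = minimum_dilution(nc, carc, criteria)
            scaled = minimum_dilution(
                _nc(nc.hi * 1.3, nc.sample_id),
                _carc(carc.ir_mixture * 1.3, carc.sample_id,
                      singles={k: v * 1.3 for k, v in carc.ir_by_compound.items()}),
                criteria,
            )
            assert scaled.d_min >= rec.d_min - 1e-12


class TestCampaignTable:
    def test_published_campaign_reproduced(self):
        """Published per-sample mixture IRs: 16 of 18 commercial-scenario
        samples need dilution (1.01-5.00), none institutional, and 78% of
        samples fall in the (1, 4] dilution band."""
        df = published_campaign()
        recs = []
        for _, row in df.iterrows():
            nc = _nc(row.hi, row.sample_id)
            carcs = [
                CarcRisk.from_mixture_value(row.sample_id, "commercial", row.ir_commercial),
                CarcRisk.from_mixture_value(row.sample_id, "institutional", row.ir_institutional),
            ]
            recs.append(minimum_dilution(nc, carcs, AcceptabilityCriteria(),
                                         OlfactometerLadder()))
        table, dist = dilution_table(recs)
        assert dist["n_samples"] == 18
        assert sum(r.necessary for r in recs) == 16
        assert dist["not_necessary"]["count"] == 2
        assert dist["dilution_1_to_4"]["count"] == 14
        assert dist["dilution_1_to_4"]["percent"] == pytest.approx(77.78, abs=0.01)
        needed = sorted(r.d_min_2dp for r in recs if r.necessary)
        assert needed[0] == 1.01
        assert needed[-1] == 5.00
        # every binding criterion is the commercial mixture criterion
        assert {r.binding_criterion for r in recs if r.necessary} == {
            "ir_mixture[commercial]"
        }
        # institutional column alone would require no dilution at all
        inst_only = [
            minimum_dilution(
                _nc(row.hi, row.sample_id),
                CarcRisk.from_mixture_value(row.sample_id, "institutional",
                                            row.ir_institutional),
            )
            for _, row in df.iterrows()
        ]
        assert not any(r.necessary for r in inst_only)

    def test_ladder_steps_recorded(self):
        recs = [
            minimum_dilution(_nc(0.3, "A"), _carc(1.78e-5, "A"),
                             ladder=OlfactometerLadder()),
            minimum_dilution(_nc(0.3, "B"), _carc(9e-6, "B"),
                             ladder=OlfactometerLadder()),
        ]
        assert recs[0].ladder_step == 4.0
        assert recs[1].ladder_step is None
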