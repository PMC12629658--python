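"""Label-pool accounting and conversion efficiencies along the omega-3 and
omega-6 chains."""

import numpy as np
import pytest

from conftest import make_measurement
from oracle_ce import brute_force_ce
from pufatrace import (
    ALA, DHA, DPA, EPA, OMEGA3, OMEGA6,
    LabelPool,
    Treatment,
    UndefinedConversionError,
    atom_percent_to_delta,
    bird_profile,
    control_reference,
    conversion_efficiency,
    delta_to_atom_percent,
    parse_fatty_acid,
    pathway_total,
    summarize_group,
    total_label,
)


class TestTotalLabel:
    @pytest.mark.parametrize(
        "pct, ape, expect",
        [(0.0, 0.5, 0.0), (10.0, 0.19, 1.9), (25.0, 0.0, 0.0)],
    )
    def test_product_of_share_and_excess(self, pct, ape, expect):
        assert total_label(pct, ape) == pytest.approx(expect)

    def test_negative_share_rejected(self):
        with pytest.raises(ValueError):
            total_label(-1.0, 0.5)


class TestConversionEfficiency:
    def _pools(self, labels):
        return [LabelPool(fa, ape, 1.0) for fa, ape in labels.items()]

    def test_pool_share_of_pathway_sum(self):
        pools = self._pools({ALA: 3.0, EPA: 1.0, DPA: 0.0, DHA: 6.0})
        assert conversion_efficiency(pools[3], pools) == pytest.approx(60.0)

    def test_all_label_in_precursor_means_no_conversion(self):
        pools = self._pools({ALA: 5.0, EPA: 0.0, DPA: 0.0, DHA: 0.0})
        for p in pools[1:]:
            assert conversion_efficiency(p, pools) == 0.0

    def test_total_conversion(self):
        pools = self._pools({ALA: 0.0, EPA: 0.0, DPA: 0.0, DHA: 5.0})
        assert conversion_efficiency(pools[3], pools) == pytest.approx(100.0)

    def test_zero_pathway_sum_is_undefined(self):
        pools = self._pools({ALA: 0.0, EPA: 0.0, DPA: 0.0, DHA: 0.0})
        with pytest.raises(UndefinedConversionError):
            conversion_efficiency(pools[0], pools)


def _bird(deltas, fames, species="barn_swallow", bird_id="b1", treatment=Treatment.LABELLED_ALA):
    return [
        make_measurement(bird_id, species, treatment, fa, d, f)
        for fa, d, f in zip(deltas.keys(), deltas.values(), fames)
    ]


@pytest.fixture
def ala_bird_and_control():
    deltas = {"18:3n-3": 800.0, "20:5n-3": 150.0, "22:5n-3": 40.0, "22:6n-3": 300.0}
    bird = _bird(deltas, [1.2, 1.0, 0.9, 7.5])
    control = {
        parse_fatty_acid(fa): delta_to_atom_percent(-30.0) for fa in deltas
    }
    return bird, control


class TestBirdProfile:
    def test_ce_sums_to_100_and_total_excludes_precursor(self, ala_bird_and_control):
        bird, control = ala_bird_and_control
        prof = bird_profile(bird, control, OMEGA3)
        assert sum(prof.per_product_ce.values()) == pytest.approx(100.0, abs=1e-9)
        assert prof.total_ce == pytest.approx(
            sum(prof.per_product_ce[fa] for fa in OMEGA3.products)
        )
        assert pathway_total(prof) == pytest.approx(prof.total_ce)

    def test_matches_brute_force_oracle(self, ala_bird_and_control):
        bird, control = ala_bird_and_control
        prof = bird_profile(bird, control, OMEGA3)
        expect = brute_force_ce(
            OMEGA3.members,
            {m.fatty_acid: (m.delta13c, m.pct_fame) for m in bird},
            {fa: atom_percent_to_delta(ap) for fa, ap in control.items()},
        )
        for fa in OMEGA3.members:
            assert prof.per_product_ce[fa] == pytest.approx(expect[fa], abs=1e-9)

    def test_missing_precursor_is_hard_error(self, ala_bird_and_control):
        bird, control = ala_bird_and_control
        with pytest.raises(ValueError, match="precursor"):
            bird_profile(bird[1:], control, OMEGA3)

    def test_missing_control_for_measured_fa_is_hard_error(self, ala_bird_and_control):
        bird, control = ala_bird_and_control
        control = {fa: ap for fa, ap in control.items() if fa != DHA}
        with pytest.raises(ValueError, match="control"):
            bird_profile(bird, control, OMEGA3)

    def test_missing_product_contributes_zero_with_warning(self, ala_bird_and_control, caplog):
        bird, control = ala_bird_and_control
        bird = [m for m in bird if m.fatty_acid != DPA]
        with caplog.at_level("WARNING"):
            prof = bird_profile(bird, control, OMEGA3)
        assert prof.per_product_ce[DPA] == 0.0
        assert any("zero label" in r.message for r in caplog.records)

    def test_bird_identical_to_control_is_undefined(self):
        deltas = {fa: -30.0 for fa in ["18:3n-3", "20:5n-3", "22:5n-3", "22:6n-3"]}
        bird = _bird(deltas, [1.2, 1.0, 0.9, 7.5])
        control = {parse_fatty_acid(fa): delta_to_atom_percent(-30.0) for fa in deltas}
        with pytest.raises(UndefinedConversionError):
            bird_profile(bird, control, OMEGA3)

    def test_negative_ape_floor_policy(self, ala_bird_and_control):
        bird, control = ala_bird_and_control
        bird[2] = make_measurement("b1", "barn_swallow", Treatment.LABELLED_ALA,
                                   "22:5n-3", -35.0, 0.9)  # below baseline
        kept = bird_profile(bird, control, OMEGA3, negative_ape="keep")
        floored = bird_profile(bird, control, OMEGA3, negative_ape="floor")
        assert kept.per_product_ce[DPA] < 0
        assert floored.per_product_ce[DPA] == 0.0
        assert sum(floored.per_product_ce.values()) == pytest.approx(100.0, abs=1e-9)


class TestInvariants:
    def _random_bird(self, rng, pathway):
        deltas = {str(fa): float(rng.uniform(-25, 3000)) for fa in pathway.members}
        fames = rng.uniform(0.3, 15.0, size=len(pathway.members))
        bird = _bird(deltas, fames)
        control = {
            parse_fatty_acid(fa): delta_to_atom_percent(float(rng.uniform(-35, -25)))
            for fa in deltas
        }
        return bird, control

    @pytest.mark.parametrize("pathway", [OMEGA3, OMEGA6], ids=lambda p: p.name)
    def test_normalization_scale_and_control_invariance(self, rng, pathway):
        """Randomized birds: CE sums to 100, is invariant to rescaling all
        %FAME (it is a ratio), and to a common additive shift of control
        and labelled atom percents."""
        for _ in range(150):
            bird, control = self._random_bird(rng, pathway)
            try:
                prof = bird_profile(bird, control, pathway)
            except UndefinedConversionError:
                continue
            assert sum(prof.per_product_ce.values()) == pytest.approx(100.0, abs=1e-9)

            scaled = [
                make_measurement(m.bird_id, m.species, m.treatment, str(m.fatty_acid),
                                 m.delta13c, m.pct_fame * 3.7)
                for m in bird
            ]
            prof2 = bird_profile(scaled, control, pathway)
            for fa in pathway.members:
                assert prof2.per_product_ce[fa] == pytest.approx(
                    prof.per_product_ce[fa], rel=1e-9, abs=1e-9
                )

            shift = 0.05
            shifted_bird = [
                make_measurement(m.bird_id, m.species, m.treatment, str(m.fatty_acid),
                                 atom_percent_to_delta(delta_to_atom_percent(m.delta13c) + shift),
                                 m.pct_fame)
                for m in bird
            ]
            shifted_control = {fa: ap + shift for fa, ap in control.items()}
            prof3 = bird_profile(shifted_bird, shifted_control, pathway)
            for fa in pathway.members:
                assert prof3.per_product_ce[fa] == pytest.approx(
                    prof.per_product_ce[fa], rel=1e-7, abs=1e-7
                )


class TestControlReferenceAndSummaries:
    def test_multiple_controls_average(self):
        c1 = [make_measurement("c1", treatment=Treatment.CONTROL, delta13c=-30.0)]
        c2 = [make_measurement("c2", treatment=Treatment.CONTROL, delta13c=-26.0)]
        ref = control_reference(c1 + c2)
        expect = (delta_to_atom_percent(-30.0) + delta_to_atom_percent(-26.0)) / 2
        assert ref[ALA] == pytest.approx(expect)

    def test_summary_mean_and_sample_sd(self, ala_bird_and_control):
        bird, control = ala_bird_and_control
        base = bird_profile(bird, control, OMEGA3)
        profs = []
        for i, total in enumerate([40.0, 50.0, 60.0]):
            # rescale one synthetic profile to hit the target total exactly
            scale = total / base.total_ce
            ce = {fa: v * scale if fa != OMEGA3.precursor else v
                  for fa, v in base.per_product_ce.items()}
            profs.append(base.__class__(f"b{i}", base.species, base.pathway, base.pools,
                                        ce, total, base.corrected))
        (cell,) = summarize_group(profs)
        assert (cell.mean, cell.n) == (50.0, 3)
        assert cell.sd == pytest.approx(10.0)

    def test_identical_profiles_have_zero_sd(self, ala_bird_and_control):
        bird, control = ala_bird_and_control
        profs = [bird_profile(bird, control, OMEGA3) for _ in range(3)]
        (cell,) = summarize_group(profs)
        assert cell.sd == 0.0 and cell.n == 3
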