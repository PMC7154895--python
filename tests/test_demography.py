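import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from loliumsim.demography import (
    adult_plants,
    allocate_cohorts,
    annual_step,
    cohort_seed_return,
    emerged_seedlings,
    seeds_per_plant,
    total_seed_return,
    update_seedbank,
)
from loliumsim.stochastics import RealizedParams

rates = st.floats(0.0, 1.0)


def make_params(**overrides) -> RealizedParams:
    """Susceptible-population means with optional overrides."""
    base = dict(
        sm=0.49, e=0.73, sdls=(0.02, 0.03, 0.11), fr=(0.07, 0.0, 0.46),
        f=20300.0, b=0.17, lp=0.88, sl=0.19,
        rc_post_early=0.98, rc_post_late=0.91,
        cr={"wheat_soybean": 0.89, "oat_soybean": 0.48, "oat_corn": 0.89},
    )
    base.update(overrides)
    return RealizedParams(**base)


class TestLifeCycleEquations:
    def test_emerged_seedlings(self):
        assert emerged_seedlings(2000.0, 0.73) == pytest.approx(1460.0)
        assert emerged_seedlings(0.0, 0.73) == 0.0
        assert emerged_seedlings(2000.0, 0.0) == 0.0
        with pytest.raises(ValueError):
            emerged_seedlings(-1.0, 0.73)

    def test_allocate_cohorts_conserves_seedlings(self):
        sdl_i = allocate_cohorts(1460.0, (1 / 3, 1 / 3, 1 / 3))
        assert sdl_i == pytest.approx([486.667, 486.667, 486.667], abs=1e-3)
        assert sum(sdl_i) == pytest.approx(1460.0)
        assert allocate_cohorts(1460.0, (1, 0, 0)) == pytest.approx([1460.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="sum"):
            allocate_cohorts(10.0, (0.6, 0.6, 0.2))

    def test_adult_plants(self):
        assert adult_plants(1000.0, 0.11, 0.0) == pytest.approx(110.0)
        assert adult_plants(1000.0, 0.5, 1.0) == 0.0
        assert adult_plants(1000.0, 0.03, 0.91) == pytest.approx(2.7)

    def test_seeds_per_plant_hyperbolic(self):
        isolated = seeds_per_plant(20300.0, 0.0, 0.88, 0.0, 0.17, 0.0)
        assert isolated == pytest.approx(2436.0)
        # half saturation at density AP = 1/b
        half = seeds_per_plant(20300.0, 0.0, 0.88, 0.0, 0.17, 1 / 0.17)
        assert half == pytest.approx(isolated / 2)
        assert seeds_per_plant(20300.0, 1.0, 0.88, 0.0, 0.17, 5.0) == 0.0

    def test_cohort_seed_return(self):
        assert cohort_seed_return(100.0, 10.0, 0.19) == pytest.approx(810.0)
        assert cohort_seed_return(100.0, 10.0, 1.0) == 0.0
        assert cohort_seed_return(100.0, 0.0, 0.19) == 0.0

    def test_total_seed_return(self):
        assert total_seed_return((810.0, 0.0, 0.0)) == 810.0
        assert total_seed_return((1.0, 2.0, 3.0)) == 6.0
        assert total_seed_return((3.0, 1.0, 2.0)) == 6.0

    def test_update_seedbank(self):
        assert update_seedbank(2000.0, 0.73, 0.49, 0.0, 0.0) == pytest.approx(275.4)
        assert update_seedbank(2000.0, 0.73, 0.49, 1000.0, 0.89) == pytest.approx(385.4)
        assert update_seedbank(5000.0, 1.0, 0.49, 777.0, 1.0) == 0.0


class TestAnnualStep:
    # frozen values hand-chained through the five life-cycle equations with
    # susceptible means, SB=2000, equal cohort fractions, no management
    EXPECTED_AP = (9.733333333333334, 14.6, 53.53333333333334)
    EXPECTED_SP = (853.3952787543947, 699.5979322228604, 130.2329879215893)
    EXPECTED_TSP_I = (6728.168377699649, 8273.445146467548, 5647.162822255957)
    EXPECTED_TSP = 20648.776346423154
    EXPECTED_SB_NEXT = 20924.176346423155

    def test_matches_hand_chained_oracle(self):
        state = annual_step(2000.0, (1 / 3, 1 / 3, 1 / 3), make_params())
        assert state.sdl == pytest.approx(1460.0)
        assert state.ap_i == pytest.approx(self.EXPECTED_AP)
        assert state.sp_i == pytest.approx(self.EXPECTED_SP)
        assert state.tsp_i == pytest.approx(self.EXPECTED_TSP_I)
        assert state.tsp == pytest.approx(self.EXPECTED_TSP)
        assert state.sb_next == pytest.approx(self.EXPECTED_SB_NEXT)

    def test_total_kill_leaves_only_the_dormant_bank(self):
        state = annual_step(2000.0, (1 / 3, 1 / 3, 1 / 3), make_params(),
                            rc=(1.0, 1.0, 1.0))
        assert state.tsp == 0.0
        assert state.sb_next == pytest.approx(2000.0 * 0.27 * 0.51)

    def test_single_cohort_allocation(self):
        state = annual_step(2000.0, (0.0, 0.0, 1.0), make_params())
        assert state.tsp_i[0] == 0.0
        assert state.tsp_i[1] == 0.0
        assert state.tsp_i[2] > 0.0

    def test_rotation_discounts_seed_return(self):
        none = annual_step(2000.0, (1 / 3, 1 / 3, 1 / 3), make_params())
        rotated = annual_step(2000.0, (1 / 3, 1 / 3, 1 / 3), make_params(), cr=0.48)
        assert rotated.sb_next == pytest.approx(
            none.sb_next - 0.48 * none.tsp
        )

    def test_rc_applies_switches(self):
        p = make_params()
        rc = (0.91, 0.0, 0.0)
        both = annual_step(2000.0, (1, 0, 0), p, rc=rc, rc_applies="both")
        surv = annual_step(2000.0, (1, 0, 0), p, rc=rc, rc_applies="survival_only")
        fec = annual_step(2000.0, (1, 0, 0), p, rc=rc, rc_applies="fecundity_only")
        # survival term identical between both and survival_only
        assert surv.ap_i[0] == both.ap_i[0]
        # but survivors reproduce at full per-plant rate
        assert surv.sp_i[0] == pytest.approx(both.sp_i[0] / (1 - 0.91))
        # fecundity_only keeps all plants but discounts their output
        assert fec.ap_i[0] > both.ap_i[0]
        assert both.sb_next <= surv.sb_next
        assert both.sb_next <= fec.sb_next
        with pytest.raises(ValueError, match="rc_applies"):
            annual_step(2000.0, (1, 0, 0), p, rc=rc, rc_applies="never")

    def test_extinction_floor_snaps_to_zero(self):
        state = annual_step(1e-7, (1 / 3, 1 / 3, 1 / 3), make_params(),
                            rc=(1.0, 1.0, 1.0))
        assert state.sb_next == 0.0

    @given(sb=st.floats(0, 1e6), rc1=rates, rc2=rates, rc3=rates, cr=rates)
    @settings(max_examples=100, deadline=None)
    def test_seed_bank_respects_saturation_bound(self, sb, rc1, rc2, rc3, cr):
        p = make_params()
        state = annual_step(sb, (1 / 3, 1 / 3, 1 / 3), p, rc=(rc1, rc2, rc3), cr=cr)
        cap = sum(
            p.f * (1 - p.fr[i]) * (1 - p.lp) / p.b * (1 - p.sl) * (1 - cr)
            for i in range(3)
        )
        assert state.sb_next <= sb * (1 - p.e) * (1 - p.sm) + cap + 1e-6

    @given(sb=st.floats(0, 1e6), lo=rates, hi=rates)
    @settings(max_examples=100, deadline=None)
    def test_next_bank_non_increasing_in_each_control_rate(self, sb, lo, hi):
        lo, hi = min(lo, hi), max(lo, hi)
        p = make_params()
        fr = (0.2, 0.5, 0.3)
        for which in range(3):
            rc_lo = tuple(lo if i == which else 0.0 for i in range(3))
            rc_hi = tuple(hi if i == which else 0.0 for i in range(3))
            assert (annual_step(sb, fr, p, rc=rc_hi).sb_next
                    <= annual_step(sb, fr, p, rc=rc_lo).sb_next + 1e-9)
        assert (annual_step(sb, fr, p, cr=hi).sb_next
                <= annual_step(sb, fr, p, cr=lo).sb_next + 1e-9)

    @given(sb=st.floats(0, 1e6), f_lo=st.floats(1, 30000), f_hi=st.floats(1, 30000))
    @settings(max_examples=50, deadline=None)
    def test_next_bank_non_decreasing_in_fecundity(self, sb, f_lo, f_hi):
        f_lo, f_hi = min(f_lo, f_hi), max(f_lo, f_hi)
        fr = (0.25, 0.5, 0.25)
        low = annual_step(sb, fr, make_params(f=f_lo)).sb_next
        high = annual_step(sb, fr, make_params(f=f_hi)).sb_next
        assert high >= low - 1e-9
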