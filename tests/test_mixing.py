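"""Dietary-water compounding and the two-endmember terrestrial index."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from terrsub.mixing import (
    DegenerateEndmembersError,
    EndmemberSet,
    MixingParameters,
    build_endmembers,
    correct_source_for_water,
    indices_for_consumers,
    sensitivity_scan,
    terrestrial_index,
    water_compounding,
)


class TestWaterCompounding:
    @pytest.mark.parametrize(
        "omega, tl, expected",
        [
            (0.5, 1.0, 0.0),          # no trophic steps, no water
            (0.28, 2.0, 0.28),        # one step
            (0.28, 2.5, 1 - 0.72**1.5),  # default parameters, ~0.3891
        ],
    )
    def test_examples(self, omega, tl, expected):
        assert water_compounding(omega, tl) == pytest.approx(expected, abs=1e-12)

    def test_default_value(self):
        assert water_compounding(0.28, 2.5) == pytest.approx(0.3891, abs=5e-5)

    @settings(max_examples=100, derandomize=True)
    @given(
        omega=st.floats(0.01, 0.95),
        tl=st.floats(1.0, 5.0),
        d_omega=st.floats(0.001, 0.04),
        d_tl=st.floats(0.01, 0.5),
    )
    def test_monotone_in_omega_and_tl(self, omega, tl, d_omega, d_tl):
        base = water_compounding(omega, tl)
        if omega + d_omega < 1 and tl > 1:
            assert water_compounding(omega + d_omega, tl) > base
        assert water_compounding(omega, tl + d_tl) > base

    def test_invalid_trophic_level(self):
        with pytest.raises(ValueError, match="trophic_level"):
            water_compounding(0.28, 0.5)


class TestSourceCorrection:
    def test_water_is_a_fixed_point(self):
        p = MixingParameters()
        assert correct_source_for_water(p.d2h_water, p) == pytest.approx(p.d2h_water)

    def test_zero_omega_is_identity(self):
        p = MixingParameters(omega=0.0)
        assert correct_source_for_water(-80.0, p) == pytest.approx(-80.0)

    def test_worked_example(self):
        p = MixingParameters(omega=0.28, d2h_water=-55.06)
        got = correct_source_for_water(-80.0, p, trophic_level=2.0)
        assert got == pytest.approx((-80.0 + 0.28 * 55.06) / 0.72, abs=1e-9)
        assert got == pytest.approx(-89.70, abs=0.005)

    @settings(max_examples=100, derandomize=True)
    @given(source=st.floats(-250, 0), omega=st.floats(0, 0.9), tl=st.floats(1, 4))
    def test_inverts_forward_mixture(self, source, omega, tl):
        p = MixingParameters(omega=omega)
        wc = water_compounding(omega, tl)
        measured = wc * p.d2h_water + (1 - wc) * source
        assert correct_source_for_water(measured, p, tl) == pytest.approx(
            source, abs=1e-8 + 1e-9 * abs(source)
        )


class TestEndmembers:
    def test_no_water_contribution_returns_sources(self):
        p = MixingParameters(omega=0.0)
        e = build_endmembers([-150.0], [-90.0], p, "upstream")
        assert e.d2h_c_100_aquatic == pytest.approx(-150.0)
        assert e.d2h_c_100_terrestrial == pytest.approx(-90.0)

    def test_worked_example(self):
        """Seston mean −150 ‰, water-corrected insect source −90 ‰."""
        p = MixingParameters()  # omega 0.28, consumer TL 2.5, water −55.06
        insect_measured = 0.28 * p.d2h_water + 0.72 * (-90.0)
        e = build_endmembers([-150.0], [insect_measured], p, "upstream")
        assert e.d2h_terrestrial_source == pytest.approx(-90.0, abs=1e-9)
        assert e.d2h_c_100_aquatic == pytest.approx(-113.06, abs=0.005)
        assert e.d2h_c_100_terrestrial == pytest.approx(-76.41, abs=0.005)

    def test_apply_mode_re_mixes_instead_of_inverting(self):
        p = MixingParameters(source_correction="apply")
        e = build_endmembers([-150.0], [-90.0], p, "upstream")
        src = 0.28 * p.d2h_water + 0.72 * (-90.0)
        assert e.d2h_terrestrial_source == pytest.approx(src)

    def test_empty_sources_rejected(self):
        with pytest.raises(ValueError, match="seston"):
            build_endmembers([], [-90.0], MixingParameters(), "upstream")

    def test_coincident_endmembers_rejected(self):
        with pytest.raises(DegenerateEndmembersError):
            p = MixingParameters(omega=0.0)
            build_endmembers([-90.0], [-90.0], p, "upstream")


class TestTerrestrialIndex:
    ENDS = EndmemberSet(
        section="upstream",
        d2h_aquatic_source=-150.0,
        d2h_terrestrial_source=-90.0,
        d2h_c_100_aquatic=-113.06,
        d2h_c_100_terrestrial=-76.41,
        omega_compound=0.3891,
    )

    @pytest.mark.parametrize(
        "consumer, expected",
        [(-113.06, 0.0), (-76.41, 1.0), ((-113.06 - 76.41) / 2, 0.5)],
    )
    def test_endpoint_and_midpoint(self, consumer, expected):
        res = terrestrial_index(consumer, self.ENDS)
        assert res.index == pytest.approx(expected, abs=1e-12)
        assert not res.clipped

    def test_out_of_range_kept_raw_and_flagged(self):
        res = terrestrial_index(-60.0, self.ENDS)
        assert res.index > 1
        assert res.clipped
        assert res.index_clipped == 1.0

    @settings(max_examples=100, derandomize=True)
    @given(t=st.floats(-0.5, 1.5))
    def test_forward_inverse_recovers_fraction(self, t):
        c = t * self.ENDS.d2h_c_100_terrestrial + (1 - t) * self.ENDS.d2h_c_100_aquatic
        assert terrestrial_index(c, self.ENDS).index == pytest.approx(t, abs=1e-9)

    @settings(max_examples=50, derandomize=True)
    @given(t=st.floats(0, 1), shift=st.floats(-50, 50))
    def test_invariant_to_common_affine_shift(self, t, shift):
        """Shifting consumer, sources and water together leaves T unchanged."""
        p0 = MixingParameters()
        p1 = MixingParameters(d2h_water=p0.d2h_water + shift)
        e0 = build_endmembers([-150.0], [-85.0], p0, "s")
        e1 = build_endmembers([-150.0 + shift], [-85.0 + shift], p1, "s")
        c0 = t * e0.d2h_c_100_terrestrial + (1 - t) * e0.d2h_c_100_aquatic
        assert terrestrial_index(c0 + shift, e1).index == pytest.approx(t, abs=1e-9)


def _noiseless_tables():
    """Consumers at exact mixtures of the section endmembers, two sections."""
    p = MixingParameters()
    rows_c, rows_s, rows_i = [], [], []
    for sec, (seston, insect) in {
        "upstream": (-150.0, -80.0),
        "downstream": (-155.0, -82.0),
    }.items():
        e = build_endmembers([seston], [insect], p, sec)
        for i, t in enumerate({"upstream": (0.6, 0.7), "downstream": (0.1, 0.2)}[sec]):
            c = t * e.d2h_c_100_terrestrial + (1 - t) * e.d2h_c_100_aquatic
            rows_c.append(
                {"sample_id": f"{sec}{i}", "taxon": "roach", "section": sec,
                 "d2h_nonexchangeable": c}
            )
        rows_s.append({"sample_id": f"s{sec}", "taxon": "seston", "section": sec,
                       "d2h_nonexchangeable": seston})
        rows_i.append({"sample_id": f"i{sec}", "taxon": "insect", "section": sec,
                       "d2h_nonexchangeable": insect})
    return pd.DataFrame(rows_c), pd.DataFrame(rows_s), pd.DataFrame(rows_i), p


class TestSensitivityScan:
    def test_single_cell_matches_single_run(self):
        consumers, seston, insects, p = _noiseless_tables()
        scan = sensitivity_scan(consumers, seston, insects, [0.28], [2.5], p)
        idx, _ = indices_for_consumers(consumers, seston, insects, p)
        direct = idx.groupby(["species", "section"])["index"].mean()
        for row in scan.itertuples():
            assert row.mean_index == pytest.approx(
                direct[(row.species, row.section)], abs=1e-12
            )

    def test_section_contrast_keeps_sign_across_grid(self):
        """Upstream minus downstream mean index stays positive over ω, TL."""
        consumers, seston, insects, p = _noiseless_tables()
        scan = sensitivity_scan(
            consumers, seston, insects, [0.17, 0.22, 0.28, 0.30], [2.0, 2.5, 3.0], p
        )
        wide = scan.pivot_table(
            index=["omega", "trophic_level"], columns="section", values="mean_index"
        )
        assert ((wide["upstream"] - wide["downstream"]) > 0).all()

    def test_mean_index_continuous_in_omega(self):
        consumers, seston, insects, p = _noiseless_tables()
        grid = list(np.linspace(0.17, 0.30, 14))
        scan = sensitivity_scan(consumers, seston, insects, grid, [2.5], p)
        up = scan[scan["section"] == "upstream"].sort_values("omega")["mean_index"]
        assert np.abs(np.diff(up)).max() < 0.02  # smooth, no jumps

    def test_empty_grid_rejected(self):
        consumers, seston, insects, p = _noiseless_tables()
        with pytest.raises(ValueError, match="non-empty"):
            sensitivity_scan(consumers, seston, insects, [], [2.5], p)
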