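"""Disclosure-risk model and k-anonymity endpoint masking."""

import numpy as np
import pytest

from pedtraj.geomask import (
    GeomaskPolicy,
    GeomaskStripper,
    apply_geomask,
    average_disclosure_risk,
    disclosure_risk,
    housing_density,
    infer_direction,
    load_districts,
    load_school_coords,
)
from pedtraj.records import Direction

from conftest import SCHOOL, commute_track

# printed district table values: (density per km², 1/k at v=1.5, t=50)
PRINTED = {
    "Sarrià": (12240.62, 4.62e-3),
    "Ciutat Vella": (42949.85, 1.32e-3),
    "Horta-Guinardó": (27041.75, 2.09e-3),
    "Sant Andreu": (36755.51, 1.54e-3),
    "L'Eixample": (38559.55, 1.47e-3),
    "L'Hospitalet": (36997.67, 1.53e-3),
    "Sants-Montjuïc": (35949.52, 1.57e-3),
    "Sant Martí": (38607.13, 1.47e-3),
    "Viladecans": (6355.95, 8.90e-3),
}


class TestDisclosureRisk:
    @pytest.mark.parametrize(
        "units, surface, density",
        [(74729, 6.105, 12240.62), (24221, 3.811, 6355.95), (0, 1.0, 0.0)],
    )
    def test_housing_density(self, units, surface, density):
        # printed densities carry last-digit rounding of the published
        # surfaces, hence the relative tolerance
        assert housing_density(units, surface) == pytest.approx(density, rel=1e-4)

    def test_density_zero_surface_raises(self):
        with pytest.raises(ValueError):
            housing_density(100, 0.0)

    @pytest.mark.parametrize("density, risk", [(12240.62, 4.62e-3), (6355.95, 8.90e-3)])
    def test_printed_risks(self, density, risk):
        got = disclosure_risk(density, GeomaskPolicy(), t=50.0)
        assert float(f"{got:.3g}") == pytest.approx(risk)

    def test_doubling_t_quarters_risk(self):
        r1 = disclosure_risk(30000.0, t=25.0)
        r2 = disclosure_risk(30000.0, t=50.0)
        assert r1 / r2 == pytest.approx(4.0)

    def test_monotone_decreasing_in_density_and_t(self):
        ts = np.linspace(10, 100, 12)
        risks_t = [disclosure_risk(30000.0, t=t) for t in ts]
        assert all(a > b for a, b in zip(risks_t, risks_t[1:]))
        dens = np.linspace(5000, 50000, 12)
        risks_d = [disclosure_risk(d, t=50.0) for d in dens]
        assert all(a > b for a, b in zip(risks_d, risks_d[1:]))

    def test_zero_density_or_t_errors(self):
        with pytest.raises(ValueError):
            disclosure_risk(0.0, t=50.0)
        with pytest.raises(ValueError):
            disclosure_risk(10000.0, t=0.0)

    def test_packaged_table_reconstruction(self):
        districts = load_districts()
        assert len(districts) == 9
        for d in districts:
            density, risk = PRINTED[d.name]
            assert d.density == pytest.approx(density, rel=1e-4)
            got = disclosure_risk(d.density, t=50.0)
            assert float(f"{got:.3g}") == pytest.approx(risk)

    def test_average_risk_equals_brute_force_mean(self):
        districts = load_districts()
        avg = average_disclosure_risk(districts, t=50.0)
        brute = sum(disclosure_risk(d.density, t=50.0) for d in districts) / len(districts)
        assert avg == pytest.approx(brute, rel=1e-12)
        assert round(avg * 1e3, 2) == 2.72
        assert average_disclosure_risk(districts[:1], t=50.0) == pytest.approx(
            disclosure_risk(districts[0].density, t=50.0)
        )

    def test_empty_district_list_errors(self):
        with pytest.raises(ValueError):
            average_disclosure_risk([])


class TestApplyGeomask:
    def test_home_to_school_removes_prefix(self, rng):
        traj = commute_track(home_dist=750.0, to_school=True)  # 1 Hz, 501 records
        policy = GeomaskPolicy(t_min=50, t_max=50)
        masked, rep = apply_geomask(traj, policy, rng, Direction.HOME_TO_SCHOOL)
        assert rep["t"] == 50
        assert rep["n_removed"] == 50
        assert len(masked) == len(traj) - 50
        # contiguous prefix removed; last record untouched
        assert list(masked.df.index) == list(traj.df.index[50:])

    def test_school_to_home_removes_suffix(self, rng):
        traj = commute_track(home_dist=750.0, to_school=False)
        policy = GeomaskPolicy(t_min=30, t_max=30)
        masked, rep = apply_geomask(traj, policy, rng, Direction.SCHOOL_TO_HOME)
        assert list(masked.df.index) == list(traj.df.index[:-30])
        assert masked.df["time"].iloc[0] == traj.df["time"].iloc[0]

    def test_too_short_after_mask_discarded(self, rng):
        traj = commute_track(home_dist=90.0)  # 61 records
        masked, rep = apply_geomask(
            traj, GeomaskPolicy(t_min=50, t_max=50), rng, Direction.HOME_TO_SCHOOL
        )
        assert masked is None
        assert rep["reason"] == "too_short_after_mask"

    def test_direction_inference(self):
        to_school = commute_track(to_school=True)
        from_school = commute_track(to_school=False)
        assert infer_direction(to_school, SCHOOL) is Direction.HOME_TO_SCHOOL
        assert infer_direction(from_school, SCHOOL) is Direction.SCHOOL_TO_HOME


class TestGeomaskStripper:
    def _cohort(self, n=40):
        return [
            commute_track(
                home_dist=600.0,
                to_school=(i % 2 == 0),
                nickname=f"zaf_{i:04d}_walk",
            )
            for i in range(n)
        ]

    def test_determinism(self):
        cohort = self._cohort()
        coords = load_school_coords()
        a = GeomaskStripper(random_state=3, school_coords=coords).fit(cohort)
        out1 = a.transform(cohort)
        b = GeomaskStripper(random_state=3, school_coords=coords).fit(cohort)
        out2 = b.transform(cohort)
        assert [len(t) for t in out1] == [len(t) for t in out2]
        assert a.mask_report_ == b.mask_report_
        for t1, t2 in zip(out1, out2):
            assert t1.df.equals(t2.df)

    def test_mask_is_prefix_xor_suffix(self):
        cohort = self._cohort()
        step = GeomaskStripper(random_state=5, school_coords=load_school_coords()).fit(cohort)
        for before, after in zip(cohort, step.transform(cohort)):
            idx_b, idx_a = list(before.df.index), list(after.df.index)
            # kept rows are a contiguous slice anchored at one end
            assert idx_a == idx_b[: len(idx_a)] or idx_a == idx_b[-len(idx_a):]
            assert len(idx_a) < len(idx_b)
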