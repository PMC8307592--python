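"""Belt geometry: TM selection, density peak, radii, volume conservation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from detbelt import (
    BeltOptions,
    BeltSpec,
    FixtureParams,
    belt_height,
    build_belt,
    density_estimate,
    inner_radius,
    make_ring_fixture,
    outer_radius,
    radial_distances,
    rightmost_peak,
    select_exposed_tm_atoms,
    stack_mixture,
)
from detbelt.beltcore import RadialProfile
from detbelt.errors import (
    BeltComputationError,
    NoExposedAtomsError,
    SpecValidationError,
    ThicknessUnavailableError,
)
from detbelt.pdb_io import OrientedStructure
from detbelt.sasa import SasaResult

from conftest import carbon_atoms


def fake_sasa(areas):
    return SasaResult(
        per_atom_area=np.asarray(areas, dtype=float), probe_radius=1.4, n_points=960
    )


class TestBeltHeight:
    @pytest.mark.parametrize("half,expected", [(15.2, 30.4), (14.0, 28.0)])
    def test_doubles_half_thickness(self, half, expected):
        assert belt_height(half) == pytest.approx(expected)

    def test_missing_thickness_raises(self):
        with pytest.raises(ThicknessUnavailableError):
            belt_height(None)

    def test_nonpositive_thickness_rejected(self):
        with pytest.raises(ValueError):
            belt_height(0.0)


class TestExposedSelection:
    def make(self, zs):
        return OrientedStructure(
            atoms=carbon_atoms([(10.0, 0.0, z) for z in zs]), half_thickness=15.0
        )

    def test_slab_and_cutoff_rules(self):
        s = self.make([0.0, 20.0, 5.0])
        kept = select_exposed_tm_atoms(s, fake_sasa([10.0, 10.0, 10.0]))
        assert [a.z for a in kept] == [0.0, 5.0]  # z = 20 outside the slab

    def test_cutoff_is_strict(self):
        s = self.make([0.0, 1.0, 2.0])
        kept = select_exposed_tm_atoms(s, fake_sasa([3.0, 3.5, 2.9]))
        assert [a.z for a in kept] == [1.0]  # exactly 3.0 is excluded

    def test_slab_boundary_inclusive(self):
        s = self.make([15.0, -15.0, 15.001])
        kept = select_exposed_tm_atoms(s, fake_sasa([10.0, 10.0, 10.0]))
        assert [a.z for a in kept] == [15.0, -15.0]

    def test_empty_selection_raises(self):
        s = self.make([0.0])
        with pytest.raises(NoExposedAtomsError):
            select_exposed_tm_atoms(s, fake_sasa([1.0]))


class TestRadialDistances:
    def test_known_triangles(self):
        atoms = carbon_atoms([(3, 4, 7), (0, 0, 1), (-20, 0, 2)])
        assert list(radial_distances(atoms)) == pytest.approx([5.0, 0.0, 20.0])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            radial_distances([])


class TestDensityAndPeak:
    def test_point_mass_short_circuits(self):
        prof = density_estimate(np.full(500, 20.0))
        assert prof.point_mass == 20.0
        assert rightmost_peak(prof) == 20.0

    def test_unimodal_mode_recovered(self):
        rng = np.random.default_rng(1)
        prof = density_estimate(rng.normal(15.0, 1.0, 1000))
        assert rightmost_peak(prof) == pytest.approx(15.0, abs=0.3)
        # proper density: integrates to ~1 on the padded grid
        assert np.trapezoid(prof.density, prof.grid) == pytest.approx(1.0, abs=0.01)

    def test_bimodal_prefers_rightmost_not_tallest(self):
        rng = np.random.default_rng(1)
        d = np.concatenate([rng.normal(10, 0.5, 300), rng.normal(22, 0.5, 200)])
        peak = rightmost_peak(density_estimate(d))
        assert peak == pytest.approx(22.0, abs=0.3)

    def test_minor_right_mode_below_guard_ignored(self):
        grid = np.linspace(0, 30, 512)
        density = np.exp(-0.5 * ((grid - 10) / 1.0) ** 2)
        density += 0.05 * np.exp(-0.5 * ((grid - 25) / 1.0) ** 2)
        density /= np.trapezoid(density, grid)
        prof = RadialProfile(grid=grid, density=density, bandwidth=1.0, n_samples=500)
        assert rightmost_peak(prof) == pytest.approx(10.0, abs=0.1)
        # the same mode above the guard fraction wins as rightmost
        density2 = np.exp(-0.5 * ((grid - 10) / 1.0) ** 2)
        density2 += 0.30 * np.exp(-0.5 * ((grid - 25) / 1.0) ** 2)
        prof2 = RadialProfile(grid=grid, density=density2, bandwidth=1.0, n_samples=500)
        assert rightmost_peak(prof2) == pytest.approx(25.0, abs=0.1)

    def test_explicit_bandwidth_honoured(self):
        rng = np.random.default_rng(2)
        d = rng.normal(15.0, 1.0, 500)
        prof = density_estimate(d, BeltOptions(kde_bandwidth=0.7))
        assert prof.bandwidth == pytest.approx(0.7, rel=1e-9)


class TestRadii:
    def test_inner_radius_offset(self):
        assert inner_radius(20.0) == pytest.approx(21.66)
        assert inner_radius(0.0) == pytest.approx(1.66)

    def test_inner_radius_override_wins(self):
        opts = BeltOptions(inner_radius_override=25.0)
        assert inner_radius(7.0, opts) == 25.0

    @pytest.mark.parametrize(
        "V,h,r,expected",
        [
            (0.0, 30.0, 10.0, 10.0),
            (math.pi * 30 * 100, 30.0, 0.0, 10.0),
            (172_000.0, 30.0, 20.0, math.sqrt(172_000 / (math.pi * 30) + 400)),
        ],
    )
    def test_outer_radius_closed_form(self, V, h, r, expected):
        R = outer_radius(V, h, r)
        assert R == pytest.approx(expected, rel=1e-12)
        assert math.pi * h * (R**2 - r**2) == pytest.approx(V, rel=1e-9, abs=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        V=st.floats(0.0, 1e6),
        h=st.floats(1.0, 100.0),
        r=st.floats(0.0, 100.0),
    )
    def test_volume_conservation_property(self, V, h, r):
        R = outer_radius(V, h, r)
        assert R >= r or R == pytest.approx(r, abs=1e-300)  # r**2 may underflow
        assert math.pi * h * (R**2 - r**2) == pytest.approx(V, rel=1e-6, abs=1e-6)


class TestStacks:
    def test_single_stack_spans_belt(self):
        stacks = stack_mixture(30.0, 20.0, 45.0, [("DDM", 172_000.0)])
        assert len(stacks) == 1
        assert (stacks[0].z_lo, stacks[0].z_hi) == (-15.0, 15.0)

    def test_proportional_tiling(self):
        stacks = stack_mixture(30.0, 20.0, 45.0, [("A", 2000.0), ("B", 1000.0)])
        assert [(s.z_lo, s.z_hi) for s in stacks] == pytest.approx(
            [(-15.0, 5.0), (5.0, 15.0)]
        )

    def test_three_equal_volumes_conserve_each(self):
        h, r = 30.0, 20.0
        V = 60_000.0
        R = outer_radius(3 * V, h, r)
        stacks = stack_mixture(h, r, R, [("A", V), ("B", V), ("C", V)])
        for s in stacks:
            vol = math.pi * (s.z_hi - s.z_lo) * (R**2 - r**2)
            assert vol == pytest.approx(V, rel=1e-9)
        assert stacks[0].z_lo == -15.0 and stacks[-1].z_hi == 15.0

    def test_all_zero_volumes_rejected(self):
        with pytest.raises(ValueError):
            stack_mixture(30.0, 20.0, 45.0, [("A", 0.0)])


class TestBuildBelt:
    def test_end_to_end_ring_fixture(self, db, ring_fixture):
        structure, _ = ring_fixture
        spec = BeltSpec([("DDM", 400)])
        g = build_belt(structure, spec, db, volume_overrides={"DDM": 430.0})
        assert g.h == 30.0
        assert g.V_total == pytest.approx(172_000.0)
        assert g.r == pytest.approx(20.0 + 1.66, abs=0.1)
        assert g.R == pytest.approx(math.sqrt(172_000 / (math.pi * 30) + g.r**2))
        assert math.pi * g.h * (g.R**2 - g.r**2) == pytest.approx(
            g.V_total, rel=1e-6
        )
        assert sum(s.volume for s in g.stacks) == pytest.approx(g.V_total, rel=1e-12)

    def test_inner_radius_override_recomputes_R_not_V(self, db, ring_fixture):
        structure, _ = ring_fixture
        spec = BeltSpec([("DDM", 400)])
        base = build_belt(structure, spec, db)
        over = build_belt(
            structure, spec, db, BeltOptions(inner_radius_override=25.0)
        )
        assert over.r == 25.0 and over.r_source == "override"
        assert over.V_total == base.V_total
        assert over.R != base.R
        assert math.pi * over.h * (over.R**2 - over.r**2) == pytest.approx(
            over.V_total, rel=1e-6
        )

    def test_outer_radius_increases_with_count(self, db, ring_fixture):
        structure, _ = ring_fixture
        radii = [
            build_belt(structure, BeltSpec([("DDM", n)]), db).R
            for n in (100, 400, 800)
        ]
        assert radii[0] < radii[1] < radii[2]

    def test_mixture_order_permutes_stacks_only(self, db, ring_fixture):
        structure, _ = ring_fixture
        g1 = build_belt(structure, BeltSpec([("DDM", 400), ("CHOLATE", 150)]), db)
        g2 = build_belt(structure, BeltSpec([("CHOLATE", 150), ("DDM", 400)]), db)
        assert (g1.h, g1.r, g1.R, g1.V_total) == (g2.h, g2.r, g2.R, g2.V_total)
        assert [s.detergent_id for s in g1.stacks] == ["DDM", "CHOLATE"]
        assert [s.detergent_id for s in g2.stacks] == ["CHOLATE", "DDM"]

    def test_zero_count_rejected(self):
        with pytest.raises(SpecValidationError, match="positive"):
            BeltSpec([("DDM", 0)])

    def test_stage_labelled_error(self, db):
        structure = OrientedStructure(
            atoms=carbon_atoms([(10, 0, 0)]), half_thickness=None
        )
        with pytest.raises(BeltComputationError, match="belt height"):
            build_belt(structure, BeltSpec([("DDM", 400)]), db)

    def test_decoy_shell_does_not_shift_peak(self, db):
        structure, _ = make_ring_fixture(FixtureParams(decoy_inner_radius=8.0))
        g = build_belt(structure, BeltSpec([("DDM", 400)]), db)
        assert g.peak_radius == pytest.approx(20.0, abs=0.5)
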