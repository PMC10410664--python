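"""SLE, LLE and phase-diagram assembly tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from saftscreen import phase_equilibria as pe
from saftscreen.parameters import API_FUSION, R_GAS, FusionProperties
from saftscreen.phase_equilibria import (BinaryContext, P_DEFAULT,
                                         aaps_scan, build_phase_diagram,
                                         ideal_solubility,
                                         mole_weight_convert,
                                         read_phase_diagram, solve_lle_point,
                                         solve_sle_point, solubility_curve,
                                         write_phase_diagram)
from saftscreen.saft_core import ComponentModel, SegmentParameters


@pytest.fixture(scope="module")
def critical_pair(toy_api):
    """Pair whose miscibility gap closes between 460 and 500 K."""
    seg = SegmentParameters(0.032, 3.6, 250.0)
    poly = ComponentModel("PCRIT", 2000.0, ((seg, 1.0),), role="polymer")
    return toy_api, poly


class TestMoleWeightConvert:
    def test_unity(self):
        assert mole_weight_convert(1.0, 300.0, 5000.0) == 1.0

    def test_equal_masses(self):
        assert mole_weight_convert(0.5, 200.0, 200.0) == pytest.approx(0.5)

    def test_gsf_in_eud(self):
        w = mole_weight_convert(0.5, 352.77, 212000.0)
        assert w == pytest.approx(1.661245106433036e-3, rel=1e-12)

    @given(x=st.floats(1e-12, 1.0 - 1e-12),
           Ma=st.floats(50.0, 500.0), Mp=st.floats(500.0, 5e5))
    @settings(max_examples=200, deadline=None)
    def test_round_trip_identity(self, x, Ma, Mp):
        w = mole_weight_convert(x, Ma, Mp, "x_to_w")
        back = mole_weight_convert(w, Ma, Mp, "w_to_x")
        assert back == pytest.approx(x, abs=1e-14, rel=1e-12)

    def test_domain_checks(self):
        with pytest.raises(ValueError):
            mole_weight_convert(1.5, 300.0, 5000.0)
        with pytest.raises(ValueError):
            mole_weight_convert(0.5, -1.0, 5000.0)


class TestIdealSolubility:
    def test_npx_closed_form(self):
        """Frozen from exp(-dG_fus/(R T)) with the built-in constants."""
        x = ideal_solubility(API_FUSION["NPX"], 400.0)
        assert x == pytest.approx(0.5307897804093799, rel=1e-12)

    def test_unity_at_melting(self):
        for fus in API_FUSION.values():
            assert ideal_solubility(fus, fus.T_m) == pytest.approx(1.0)


class TestSlePoint:
    def test_melting_point_limit(self, toy_api, toy_polymer_acceptor,
                                 toy_fusion):
        pt = solve_sle_point(toy_api, toy_polymer_acceptor, toy_fusion,
                             toy_fusion.T_m)
        assert pt.x_api == pytest.approx(1.0)
        assert pt.w_api == pytest.approx(1.0)

    def test_ideal_mode_closed_form(self, toy_api, toy_polymer_acceptor):
        fus = API_FUSION["NPX"]
        pt = solve_sle_point(toy_api, toy_polymer_acceptor, fus, 400.0,
                             ideal=True)
        assert pt.x_api == pytest.approx(0.5307897804093799, rel=1e-12)

    def test_self_consistency_from_scratch(self, toy_api,
                                           toy_polymer_acceptor, toy_fusion):
        """The stored root must re-satisfy the solubility equation when the
        activity coefficient is recomputed independently."""
        from saftscreen.saft_core import (activity_coefficient,
                                          binary_mixture)
        T = 380.0
        pt = solve_sle_point(toy_api, toy_polymer_acceptor, toy_fusion, T)
        mix = binary_mixture(toy_api, toy_polymer_acceptor, pt.x_api)
        gamma = activity_coefficient(mix, 0, T, P_DEFAULT)
        from saftscreen.parameters import fusion_gibbs_energy
        resid = (math.log(pt.x_api * gamma)
                 + fusion_gibbs_energy(toy_fusion, T) / (R_GAS * T))
        assert abs(resid) < 1e-10

    def test_cross_association_raises_solubility(self, toy_api, toy_fusion,
                                                 toy_polymer_plain):
        """Acceptor sites on the polymer (stronger attraction) must raise
        the predicted solubility versus an identical polymer without them."""
        seg = toy_polymer_plain.segments[0][0]
        seg_acc = SegmentParameters(
            seg.segment_count_ratio, seg.sigma, seg.u_over_kB,
            0.0, 0.02, 0, 8)
        poly_acc = ComponentModel("TPOLY+HB", toy_polymer_plain.molar_mass,
                                  ((seg_acc, 1.0),), role="polymer")
        T = 390.0
        x_plain = solve_sle_point(toy_api, toy_polymer_plain, toy_fusion,
                                  T).x_api
        x_assoc = solve_sle_point(toy_api, poly_acc, toy_fusion, T).x_api
        assert x_assoc > x_plain

    def test_kij_monotonicity(self, toy_api, toy_polymer_acceptor,
                              toy_fusion):
        T = 390.0
        xs = [solve_sle_point(toy_api, toy_polymer_acceptor, toy_fusion, T,
                              kij=k).x_api for k in (-0.02, 0.0, 0.02, 0.05)]
        assert all(a >= b - 1e-12 for a, b in zip(xs, xs[1:]))


class TestSolubilityCurve:
    def test_single_point_at_melting(self, toy_api, toy_polymer_acceptor,
                                     toy_fusion):
        curve = solubility_curve(toy_api, toy_polymer_acceptor, toy_fusion,
                                 T_grid=[toy_fusion.T_m])
        assert len(curve.points) == 1
        assert curve.points[0].x_api == pytest.approx(1.0)

    def test_ideal_mode_monotone(self, toy_api, toy_polymer_acceptor,
                                 toy_fusion):
        grid = np.linspace(330.0, toy_fusion.T_m, 12)
        curve = solubility_curve(toy_api, toy_polymer_acceptor, toy_fusion,
                                 T_grid=grid, ideal=True)
        xs = [q.x_api for q in curve.points]
        assert np.all(np.diff(xs) > 0)  # increasing with T

    def test_default_pressure(self):
        assert P_DEFAULT == 1e5  # 0.1 MPa

    def test_bad_grid_rejected(self, toy_api, toy_polymer_acceptor,
                               toy_fusion):
        with pytest.raises(ValueError):
            solubility_curve(toy_api, toy_polymer_acceptor, toy_fusion,
                             T_grid=[400.0, 390.0])
        with pytest.raises(ValueError):
            solubility_curve(toy_api, toy_polymer_acceptor, toy_fusion,
                             T_grid=[toy_fusion.T_m + 5.0])


def _lower_hull_gap(xs, G):
    """Widest gap of the lower convex hull (Andrew monotone chain)."""
    hull = []
    for i in range(len(xs)):
        while len(hull) >= 2:
            (x1, g1), (x2, g2) = hull[-2], hull[-1]
            if (x2 - x1) * (G[i] - g1) - (xs[i] - x1) * (g2 - g1) <= 0:
                hull.pop()
            else:
                break
        hull.append((xs[i], G[i]))
    gaps = [(hull[i + 1][0] - hull[i][0], hull[i][0], hull[i + 1][0])
            for i in range(len(hull) - 1)]
    return max(gaps)


def brute_force_common_tangent(ctx, n_mid=400):
    """Independent dense-grid lower-convex-hull construction of the
    mixing Gibbs energy; returns the widest hull gap (binodal pair),
    refined once around the detected gap edges."""
    xs = np.unique(np.concatenate([
        np.geomspace(1e-8, 0.05, 60), np.linspace(0.05, 0.95, n_mid),
        1.0 - np.geomspace(1e-8, 0.05, 60)]))
    G = np.array([ctx.gibbs_mix(float(x)) for x in xs])
    width, lo, hi = _lower_hull_gap(xs, G)
    grid_step = np.max(np.diff(xs))
    if width < 3.0 * grid_step:
        return None
    # refine around both edges to push the construction error well below
    # the comparison tolerance
    step = np.median(np.diff(xs))
    extra = np.concatenate([
        np.linspace(max(lo - 3 * step, xs[0]),
                    min(lo + 3 * step, xs[-1]), 120),
        np.linspace(max(hi - 3 * step, xs[0]),
                    min(hi + 3 * step, xs[-1]), 120)])
    xs2 = np.unique(np.concatenate([xs, extra]))
    G2 = np.array([ctx.gibbs_mix(float(x)) for x in xs2])
    _, lo2, hi2 = _lower_hull_gap(xs2, G2)
    return lo2, hi2


class TestLle:
    def test_identical_components_no_split(self, toy_api):
        twin = ComponentModel("TWIN", toy_api.molar_mass, toy_api.segments)
        assert solve_lle_point(toy_api, twin, 350.0) is None

    def test_split_passes_independent_activity_check(self, critical_pair):
        api, poly = critical_pair
        T = 380.0
        pt = solve_lle_point(api, poly, T)
        assert pt is not None
        ctx = BinaryContext(api, poly, T)
        la1 = ctx.ln_activities(pt.x_L1)
        la2 = ctx.ln_activities_pair(pt.x_L2, math.exp(pt.ln_x_poly_L2))
        assert np.max(np.abs(la1 - la2)) < 1e-8

    def test_split_matches_brute_force_hull(self, critical_pair):
        api, poly = critical_pair
        T = 420.0
        pt = solve_lle_point(api, poly, T)
        ctx = BinaryContext(api, poly, T)
        lohi = brute_force_common_tangent(ctx)
        assert lohi is not None
        lo, hi = lohi
        assert pt.x_L1 == pytest.approx(lo, abs=1e-3)
        assert pt.x_L2 == pytest.approx(hi, abs=1e-3)

    def test_no_split_agrees_with_convexity_oracle(self, toy_api,
                                                   toy_polymer_acceptor):
        T = 390.0
        assert solve_lle_point(toy_api, toy_polymer_acceptor, T) is None
        ctx = BinaryContext(toy_api, toy_polymer_acceptor, T)
        xs = np.linspace(1e-4, 1.0 - 1e-4, 1000)
        G = np.array([ctx.gibbs_mix(float(x)) for x in xs])
        d2 = np.diff(G, 2)
        assert np.all(d2 > -1e-9)  # convex within numerical noise


class TestAapsScan:
    def test_identical_components_empty(self, toy_api):
        twin = ComponentModel("TWIN", toy_api.molar_mass, toy_api.segments)
        curve = aaps_scan(toy_api, twin, (300.0, 400.0), step=50.0)
        assert not curve.has_split
        assert curve.points == []

    def test_demixing_pair_contiguous(self, critical_pair):
        api, poly = critical_pair
        curve = aaps_scan(api, poly, (300.0, 460.0), step=40.0)
        assert curve.has_split
        Ts = [q.T for q in curve.points]
        assert Ts == sorted(Ts)
        assert len(Ts) == 5  # split at every scanned temperature

    def test_gap_narrows_toward_critical_point(self, critical_pair):
        api, poly = critical_pair
        curve = aaps_scan(api, poly, (300.0, 500.0), step=40.0)
        widths = [q.x_L2 - q.x_L1 for q in curve.points]
        assert np.all(np.diff(widths) < 0)
        assert curve.points[-1].T < 500.0  # gap closed before the scan end


class TestAapsSleConsistency:
    def test_sle_root_outside_unstable_region(self, critical_pair):
        """When a binodal straddles the solubility composition, the
        reported solubility root must sit in a locally stable or
        metastable region (non-negative Gibbs curvature)."""
        api, poly = critical_pair
        fus = pe.FusionProperties(T_m=420.0, dH_fus=30.0, dCp_a=100.0)
        T = 400.0
        bp = solve_lle_point(api, poly, T)
        assert bp is not None
        pt = solve_sle_point(api, poly, fus, T)
        if bp.x_L1 < pt.x_api < bp.x_L2:
            ctx = BinaryContext(api, poly, T)
            h = 1e-4
            curv = (ctx.dgibbs_mix(pt.x_api + h)
                    - ctx.dgibbs_mix(pt.x_api - h)) / (2 * h)
            assert curv > -1e-6


class TestPhaseDiagram:
    def test_miscible_system_empty_binodal(self, toy_api,
                                           toy_polymer_acceptor, toy_fusion):
        diagram = build_phase_diagram(
            toy_api, toy_polymer_acceptor, toy_fusion,
            sle_grid=np.linspace(370.0, toy_fusion.T_m, 6),
            aaps_range=(350.0, 410.0), aaps_step=30.0)
        assert diagram.solubility.points
        assert not diagram.binodal.has_split

    def test_demixing_system_both_curves(self, critical_pair, toy_fusion,
                                         tmp_path):
        api, poly = critical_pair
        diagram = build_phase_diagram(
            api, poly, toy_fusion,
            sle_grid=np.linspace(380.0, toy_fusion.T_m, 5),
            aaps_range=(340.0, 420.0), aaps_step=40.0)
        assert diagram.solubility.points
        assert diagram.binodal.has_split

        path = tmp_path / "diagram.tsv"
        write_phase_diagram(diagram, path)
        back = read_phase_diagram(path)
        assert back.api == diagram.api
        assert back.kij == diagram.kij
        assert len(back.solubility.points) == len(diagram.solubility.points)
        assert len(back.binodal.points) == len(diagram.binodal.points)
        for a, b in zip(diagram.solubility.points, back.solubility.points):
            assert b.x_api == pytest.approx(a.x_api, rel=1e-9)
        # serialization is deterministic
        path2 = tmp_path / "diagram2.tsv"
        write_phase_diagram(diagram, path2)
        assert path.read_text() == path2.read_text()
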