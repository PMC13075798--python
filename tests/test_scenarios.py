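import numpy as np
import pytest

from lanmm import _fast
from lanmm.params import ModelParams
from lanmm.scenarios import (
    TwoColumnParams,
    pv_scan,
    two_column_branch,
    two_column_integrate,
    two_column_jacobian,
    two_column_observables,
    two_column_rhs,
)


@pytest.fixture(scope="module")
def scan():
    return pv_scan(ModelParams(), c7_values=(550.0, 300.0, 150.0),
                   phi2_grid=np.linspace(0.0, 350.0, 8))


class TestPvScan:
    def test_baseline_matches_direct_branch(self, scan, table1):
        # same code path: the C7=550 loci at phi_e2=0 equal the equilibrium
        # module's own detections exactly
        from lanmm.equilibria import _select_locus_point, continue_branch

        branch = continue_branch(table1.with_inputs(0.0, 0.0), "phi_e1", (0.0, 600.0))
        base = scan.entry(550.0)
        for kind, arr in (("SNIC", base.snic), ("HB1", base.hb1), ("HB2", base.hb2)):
            hit = _select_locus_point(branch.bifurcations, kind, window=(-150.0, 600.0))
            assert arr[0] == hit.theta

    def test_loci_left_shift_at_zero_drive(self, scan):
        base, reduced = scan.entry(550.0), scan.entry(300.0)
        assert reduced.snic[0] < base.snic[0]
        assert reduced.hb1[0] < base.hb1[0]
        assert reduced.hb2[0] < base.hb2[0]

    def test_coexistence_area_enlarged_at_300(self, scan):
        assert scan.entry(300.0).coexistence_fraction > scan.entry(550.0).coexistence_fraction

    def test_gamma_extinct_at_small_coupling(self, scan):
        # no gamma Hopf anywhere in the window: fast oscillations abolished
        assert np.all(np.isnan(scan.entry(150.0).hb2))
        assert scan.entry(150.0).coexistence_fraction == 0.0


class TestTwoColumnModel:
    def test_decoupled_rhs_equals_two_single_columns(self, table1):
        tc = TwoColumnParams(phi=120.0, k_ff=0.0, k_fb_p11=0.0, k_fb_p12=0.0, k_fb_sst=0.0)
        rng = np.random.default_rng(5)
        z = rng.normal(scale=0.1, size=20)
        d = two_column_rhs(z, tc)
        p = table1.with_inputs(120.0, 120.0).as_vector()
        expected = np.concatenate([_fast.rhs10(z[:10].copy(), p),
                                   _fast.rhs10(z[10:].copy(), p)])
        np.testing.assert_array_equal(d, expected)

    def test_jacobian_matches_complex_step(self):
        # chain-rule Jacobian against complex-step differentiation of a
        # mirror implementation of the coupled vector field
        tc = TwoColumnParams(phi=120.0)
        p = tc.as_vector()
        g = tc.gains()
        rng = np.random.default_rng(6)

        def sig(v, v0, phi0=p[19], r=p[20]):
            return 2 * phi0 / (1 + np.exp(r * (v0 - v)))

        def rhs20_c(z):
            AA, AGs, AGf, aA, aGs, aGf = p[:6]
            C = p[6:19]
            q = AA / aA
            F1, F2 = C[2] * q * p[26], C[7] * q * p[27]
            a1_2 = C[0] * z[11] + C[1] * z[12] + F1 + C[10] * z[13]
            s21 = sig(a1_2, p[21])
            a1_1 = C[0] * z[1] + C[1] * z[2] + F1 + C[10] * z[3] + g[1] * q * s21
            a2_1 = C[3] * z[0]
            a3_1 = C[4] * z[0] + g[3] * q * s21
            a4_1 = C[5] * z[3] + C[6] * z[4] + F2 + C[11] * z[0] + g[2] * q * s21
            a5_1 = C[8] * z[3] + C[9] * z[4] + C[12] * z[0]
            s12 = sig(a4_1, p[24])
            a2_2 = C[3] * z[10]
            a3_2 = C[4] * z[10]
            a4_2 = C[5] * z[13] + C[6] * z[14] + F2 + C[11] * z[10] + g[0] * q * s12
            a5_2 = C[8] * z[13] + C[9] * z[14] + C[12] * z[10]
            d = np.empty(20, dtype=complex)
            d[:5] = z[5:10]
            d[10:15] = z[15:20]
            d[5] = aA * AA * sig(a1_1, p[21]) - 2 * aA * z[5] - aA**2 * z[0]
            d[6] = aA * AA * sig(a2_1, p[22]) - 2 * aA * z[6] - aA**2 * z[1]
            d[7] = aGs * AGs * sig(a3_1, p[23]) - 2 * aGs * z[7] - aGs**2 * z[2]
            d[8] = aA * AA * sig(a4_1, p[24]) - 2 * aA * z[8] - aA**2 * z[3]
            d[9] = aGf * AGf * sig(a5_1, p[25]) - 2 * aGf * z[9] - aGf**2 * z[4]
            d[15] = aA * AA * sig(a1_2, p[21]) - 2 * aA * z[15] - aA**2 * z[10]
            d[16] = aA * AA * sig(a2_2, p[22]) - 2 * aA * z[16] - aA**2 * z[11]
            d[17] = aGs * AGs * sig(a3_2, p[23]) - 2 * aGs * z[17] - aGs**2 * z[12]
            d[18] = aA * AA * sig(a4_2, p[24]) - 2 * aA * z[18] - aA**2 * z[13]
            d[19] = aGf * AGf * sig(a5_2, p[25]) - 2 * aGf * z[19] - aGf**2 * z[14]
            return d

        h = 1e-30
        worst = 0.0
        for _ in range(20):
            z = rng.normal(scale=0.15, size=20)
            J = two_column_jacobian(z, tc)
            for i in range(20):
                e = np.zeros(20)
                e[i] = 1.0
                col = rhs20_c(z.astype(complex) + 1j * h * e).imag / h
                worst = max(worst, np.max(np.abs(J[:, i] - col)))
        assert worst < 1e-6

    def test_coupled_dynamics_bounded_and_rhythmic(self):
        tc = TwoColumnParams(phi=125.0)
        _, states = two_column_integrate(tc, t_transient=10.0, t_record=10.0)
        v11, v12, v21, v22 = two_column_observables(states, tc)
        for v in (v11, v12, v21, v22):
            assert np.max(np.abs(v)) < 500.0
            assert np.ptp(v) > 0.5  # all four populations oscillate

    def test_superficial_layers_carry_gamma(self):
        # with default gains the superficial (PING) populations show a
        # gamma-band spectral component absent from a slow-only signal
        from lanmm.metrics import psd
        from lanmm.simulate import TimeSeries

        tc = TwoColumnParams(phi=125.0)
        t, states = two_column_integrate(tc, t_transient=10.0, t_record=30.0)
        v11, v12, v21, v22 = two_column_observables(states, tc)
        ts = TimeSeries(t=t, vP1=v11, vP2=v12, sample_rate=1000.0)
        s = psd(ts, "vP2")
        mask_gamma = (s.freqs >= 30) & (s.freqs <= 60)
        mask_slow = s.freqs < 12
        assert np.max(s.power[mask_gamma]) > 1e-4 * np.max(s.power[mask_slow])


class TestTwoColumnBranch:
    def test_decoupled_branch_reproduces_single_column(self, table1, branch_phi2_0):
        # with zero gains the coupled system is a duplicated single column at
        # phi_e1 = phi_e2 = phi, so its detected events must match a single
        # column driven identically
        tc = TwoColumnParams(k_ff=0.0, k_fb_p11=0.0, k_fb_p12=0.0, k_fb_sst=0.0)
        br2 = two_column_branch(tc, (0.0, 400.0))
        from lanmm.equilibria import continue_branch

        br1 = continue_branch(table1.with_inputs(0.0, 0.0).with_inputs(phi_e2=0.0),
                              "phi_e1", (0.0, 400.0))
        # compare against single column with phi_e2 = phi_e1 = theta:
        # rebuild with coupled inputs via the two-column problem on 10 dims
        # -> instead compare fold/Hopf sets of br2 with a single column where
        # both drives vary together
        from lanmm.equilibria import (ContinuationProblem, EquilibriumBranch,
                                      EquilibriumPoint, continue_problem,
                                      detect_codim1)

        p0 = table1.as_vector()

        def f(y, th):
            q = p0.copy()
            q[26] = q[27] = th
            return _fast.rhs10(y, q)

        def jac(y, th):
            q = p0.copy()
            q[26] = q[27] = th
            return _fast.jac10(y, q)

        prob1 = ContinuationProblem(f, jac, 10)
        pts = continue_problem(prob1, 0.0, 400.0, step=0.5)
        ref = EquilibriumBranch(vary="phi", points=[
            EquilibriumPoint(theta=p.theta, state=p.state, eigenvalues=p.eigenvalues)
            for p in pts])
        ref.bifurcations = detect_codim1(ref, prob1)

        ref_events = sorted((b.kind, round(b.theta, 1)) for b in ref.bifurcations)
        got_events = sorted(set((b.kind, round(b.theta, 1)) for b in br2.bifurcations))
        assert got_events == ref_events

    def test_coupled_branch_detects_hopf_points(self):
        tc = TwoColumnParams()
        br = two_column_branch(tc, (0.0, 400.0))
        hopfs = [b for b in br.bifurcations if b.kind.startswith("hopf")]
        assert hopfs, "coupled columns should retain oscillation onset via Hopf"
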