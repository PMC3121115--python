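import numpy as np
import pytest

from conftest import (
    EQ_HIGH_C2,
    EQ_LOW_C2,
    EQ_MID_C2,
    SPECTRUM_STABLE,
    SPECTRUM_UNSTABLE,
)
from ssimod.io_cli import fixture, random_module, random_parameters
from ssimod.model_build import ParameterSet, build_rate_model
from ssimod.multieq import (
    cauchy_binet_det,
    determinant_sign_certificate,
    find_equilibria,
    find_singular_point,
    stability_analysis,
)
from ssimod.ssi_graph import KineticParams, Reaction, SSIModule


def _kp(**kw):
    kw.setdefault("v_max", 1.0)
    kw.setdefault("k_m", 1.0)
    return KineticParams(**kw)


def _decay_model(v_max=1.0, k_m=0.5, v_in=0.3):
    """input -> S1 -> output with a constant inflow rate v_in."""
    module = SSIModule(
        ["X", "S1", "Y"],
        [Reaction("vin", "X", "S1", (), _kp(v_max=1.0, k_m=1.0)),
         Reaction("vout", "S1", "Y", (), _kp(v_max=v_max, k_m=k_m))],
        allow_ssn=True,
    )
    # choose the input level so the inflow rate equals v_in exactly:
    # v_in = C_X/(1+C_X)  =>  C_X = v_in/(1-v_in)
    c_x = v_in / (1.0 - v_in)
    return build_rate_model(module, ParameterSet(inputs={"X": c_x}))


class TestCertificate:
    def test_bistable_example_is_inconclusive(self, fig4):
        module, _ = fig4
        verdict = determinant_sign_certificate(module)
        assert verdict.status == "inconclusive_mixed_signs"
        assert verdict.n_positive > 0 and verdict.n_negative > 0

    def test_uninhibited_chain_is_certified(self):
        module, _ = fixture("chain_ssn")
        verdict = determinant_sign_certificate(module)
        assert verdict.status == "certified_unique"
        assert verdict.n_positive + verdict.n_negative >= 1
        assert verdict.n_positive == 0 or verdict.n_negative == 0

    def test_two_inhibitors_unsupported(self):
        kp = _kp(k_c={"S2": 1, "S3": 1}, k_u={"S2": 1, "S3": 1})
        module = SSIModule(
            ["X", "S1", "S2", "S3", "Y"],
            [Reaction("v1", "X", "S1", ("S2", "S3"), kp),
             Reaction("v2", "S1", "S2", (), _kp()),
             Reaction("v3", "S2", "S3", (), _kp()),
             Reaction("v4", "S3", "Y", (), _kp())],
        )
        assert determinant_sign_certificate(module).status == "unsupported"

    def test_closed_cycle_is_degenerate(self):
        # a closed cycle conserves total mass: the stoichiometric columns
        # sum to zero, so every determinant term vanishes structurally and
        # no isolated equilibrium is guaranteed
        module = SSIModule(
            ["S1", "S2", "S3"],
            [Reaction("v1", "S1", "S2", ("S3",),
                      _kp(k_c={"S3": 1}, k_u={"S3": 1})),
             Reaction("v2", "S2", "S3", (), _kp()),
             Reaction("v3", "S3", "S1", (), _kp())],
        )
        verdict = determinant_sign_certificate(module)
        assert verdict.status == "degenerate"
        assert verdict.n_positive == verdict.n_negative == 0


    def test_refuses_oversized_modules(self):
        n = 9
        nodes = ["X"] + [f"S{i}" for i in range(1, n + 1)] + ["Y"]
        reactions = [Reaction("v0", "X", "S1", (), _kp())]
        for i in range(1, n):
            inh = f"S{(i + 1) % n + 1}"
            kw = {}
            if inh not in (f"S{i}", f"S{i + 1}"):
                kw = dict(k_c={inh: 1.0}, k_u={inh: 1.0})
                reactions.append(
                    Reaction(f"v{i}", f"S{i}", f"S{i + 1}", (inh,), _kp(**kw))
                )
            else:
                reactions.append(
                    Reaction(f"v{i}", f"S{i}", f"S{i + 1}", (), _kp())
                )
        reactions.append(Reaction(f"v{n}", f"S{n}", "Y", (), _kp()))
        module = SSIModule(nodes, reactions)
        with pytest.raises(ValueError, match="refusing"):
            determinant_sign_certificate(module)

    def test_cauchy_binet_matches_direct_determinant(self, fig4_model):
        rng = np.random.default_rng(17)
        for _ in range(50):
            c = np.exp(rng.uniform(-2, 2, size=3))
            direct = float(np.linalg.det(fig4_model.jacobian(c)))
            expanded = cauchy_binet_det(fig4_model, c)
            assert expanded == pytest.approx(direct, rel=1e-8)

    def test_witness_attached_when_model_supplied(self, fig4, fig4_model):
        module, _ = fig4
        verdict = determinant_sign_certificate(module, model=fig4_model)
        assert verdict.status == "inconclusive_mixed_signs"
        assert verdict.witness is not None
        det = np.linalg.det(fig4_model.jacobian(verdict.witness))
        assert abs(det) < 1e-10


class TestFindEquilibria:
    def test_bistable_example_has_exactly_three(self, fig4_equilibria):
        assert len(fig4_equilibria) == 3
        found = np.array([rec.c for rec in fig4_equilibria])
        expected = np.array([EQ_LOW_C2, EQ_MID_C2, EQ_HIGH_C2])
        assert np.max(np.abs(found - expected)) <= 1e-3

    def test_all_residuals_tiny(self, fig4_equilibria):
        for rec in fig4_equilibria:
            assert rec.residual < 1e-10

    def test_ssn_chain_closed_form(self):
        v_in, v_max, k_m = 0.3, 1.0, 0.5
        model = _decay_model(v_max=v_max, k_m=k_m, v_in=v_in)
        records = find_equilibria(model, seed=0)
        assert len(records) == 1
        r = v_in / v_max
        assert records[0].c[0] == pytest.approx(k_m * r / (1 - r), rel=1e-9)

    def test_no_equilibria_when_inflow_exceeds_efflux_capacity(self):
        module, params = fixture("fig4_noeq")
        model = build_rate_model(module, params)
        records = find_equilibria(model, seed=0)
        assert records == []

    def test_seed_independence_of_root_set(self, fig4_model, fig4_equilibria):
        other = find_equilibria(fig4_model, seed=20_240_517)
        assert len(other) == len(fig4_equilibria)
        for a, b in zip(other, fig4_equilibria):
            assert np.allclose(a.c, b.c, rtol=1e-6)

    def test_invalid_bounds_rejected(self, fig4_model):
        with pytest.raises(ValueError):
            find_equilibria(fig4_model, bounds=(-1.0, 10.0))


class TestStability:
    def test_stable_equilibrium_spectrum(self, fig4_model, fig4_equilibria):
        rec = fig4_equilibria[1]  # median C_2: the asymptotically stable one
        assert rec.stability == "asymptotically_stable"
        assert np.allclose(
            np.sort(rec.eigenvalues.real), np.sort(SPECTRUM_STABLE), atol=2e-3
        )
        assert np.max(np.abs(rec.eigenvalues.imag)) < 1e-12

    def test_unstable_equilibrium_spectrum(self, fig4_equilibria):
        rec = fig4_equilibria[0]  # smallest C_2: the unstable saddle
        assert rec.stability == "unstable"
        assert np.allclose(
            np.sort(rec.eigenvalues.real), np.sort(SPECTRUM_UNSTABLE), atol=2e-3
        )

    def test_largest_c2_equilibrium_is_also_unstable(self, fig4_equilibria):
        # no reference spectrum exists for this one; computed and labeled only
        assert fig4_equilibria[2].stability == "unstable"

    def test_eigenvalue_product_equals_determinant(self, fig4_model,
                                                   fig4_equilibria):
        for rec in fig4_equilibria:
            det = np.linalg.det(fig4_model.jacobian(rec.c))
            prod = np.prod(rec.eigenvalues).real
            assert prod == pytest.approx(det, rel=1e-8)

    def test_one_dimensional_decay_closed_form(self):
        model = _decay_model(v_max=1.0, k_m=0.5, v_in=0.3)
        [rec] = find_equilibria(model, seed=0)
        c_star = rec.c[0]
        expected = -1.0 * 0.5 / (0.5 + c_star) ** 2
        assert rec.eigenvalues[0].real == pytest.approx(expected, rel=1e-9)
        assert rec.stability == "asymptotically_stable"


class TestFindSingularPoint:
    def test_bracket_between_low_and_mid_equilibria(self, fig4_model,
                                                    fig4_equilibria):
        # det J is positive at the smallest-C_2 equilibrium and negative at
        # the stable median-C_2 one: bisection must find |det| < 1e-10
        c_a, c_b = fig4_equilibria[0].c, fig4_equilibria[1].c
        witness = find_singular_point(fig4_model, c_a, c_b)
        assert witness is not None
        assert abs(np.linalg.det(fig4_model.jacobian(witness))) < 1e-10

    def test_no_witness_for_certified_chain(self, chain_model):
        witness = find_singular_point(
            chain_model, seed=4, n_samples=10_000, bounds=(1e-3, 1e3)
        )
        assert witness is None

    def test_no_witness_for_one_dimensional_decay(self):
        model = _decay_model()
        assert find_singular_point(model, seed=1, n_samples=2_000) is None


class TestCertificateSoundnessSmall:
    """Small-scale version of the soundness property (the full 200-module
    sweep lives in the acceptance suite)."""

    # seeds chosen so the generated module is actually certified
    @pytest.mark.parametrize("seed", [1, 2, 3, 9, 10, 14, 17, 24, 29, 30])
    def test_certified_modules_have_at_most_one_equilibrium(self, seed):
        module, _ = random_module(2, 4, p_inhibit=0.5, seed=seed)
        verdict = determinant_sign_certificate(module)
        assert verdict.certified
        for draw in range(3):
            params = random_parameters(module, seed=100 * seed + draw)
            model = build_rate_model(module, params)
            records = find_equilibria(
                model, bounds=(1e-2, 1e2), n_starts=0, lattice_points=5
            )
            assert len(records) <= 1
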