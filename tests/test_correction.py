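"""Natural-abundance correction: matrix construction and inversion."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tracemet.correction import (
    P13_NATURAL,
    correct_dataset,
    correct_mid,
    correction_matrix_empirical,
    correction_matrix_theoretical,
    parse_formula,
)
from tracemet.network import METABOLITES


def binomial_column(n, p):
    """Independent expansion: P(k of n carbons heavy) via explicit enumeration."""
    from itertools import product

    col = np.zeros(n + 1)
    for combo in product((0, 1), repeat=n):
        col[sum(combo)] += np.prod([p if c else 1 - p for c in combo]) if n else 1.0
    return col


class TestTheoretical:
    def test_columns_match_enumerated_binomial(self):
        p = P13_NATURAL
        for met in ("accoa", "aspartate", "glutamate"):
            n = METABOLITES[met].n_carbons
            C = correction_matrix_theoretical(met, p13=p).matrix
            for j in range(n + 1):
                expected = np.concatenate([np.zeros(j), binomial_column(n - j, p)])
                np.testing.assert_allclose(C[:, j], expected, atol=1e-12, err_msg=f"{met} col {j}")

    def test_p13_zero_gives_identity(self):
        C = correction_matrix_theoretical("malate", p13=0.0).matrix
        np.testing.assert_allclose(C, np.eye(5), atol=1e-15)

    def test_fully_labeled_column_is_unit_vector(self):
        C = correction_matrix_theoretical("glutamate", p13=0.0107).matrix
        np.testing.assert_allclose(C[:, 5], np.eye(6)[5], atol=1e-15)

    def test_formula_mode_adds_heteroatom_envelope(self):
        carbon_only = correction_matrix_theoretical("accoa").matrix
        # two backbone carbons, formula with extra Si shifts mass upward
        with_si = correction_matrix_theoretical(
            "accoa", elemental_formula={"C": 2, "Si": 1}
        ).matrix
        assert with_si[1, 0] > carbon_only[1, 0]
        assert np.all(with_si.sum(axis=0) <= 1.0 + 1e-9)

    def test_formula_parser(self):
        assert parse_formula("C6H12O6") == {"C": 6, "H": 12, "O": 6}
        assert parse_formula("C4H5NO3Si2") == {"C": 4, "H": 5, "N": 1, "O": 3, "Si": 2}
        with pytest.raises(ValueError):
            parse_formula("not-a-formula!")

    def test_bad_p13_rejected(self):
        with pytest.raises(ValueError):
            correction_matrix_theoretical("malate", p13=0.6)


class TestEmpirical:
    def test_shift_construction_by_hand(self):
        std = np.array([0.979, 0.021, 0.0])
        C = correction_matrix_empirical("accoa", std).matrix
        np.testing.assert_allclose(C[:, 1], [0.0, 0.979, 0.021], atol=1e-12)
        np.testing.assert_allclose(C[:, 2], [0.0, 0.0, 0.979], atol=1e-12)

    def test_delta_standard_gives_identity(self):
        C = correction_matrix_empirical("malate", np.array([1.0, 0, 0, 0, 0])).matrix
        np.testing.assert_allclose(C, np.eye(5), atol=1e-15)

    def test_self_correction_recovers_m0(self):
        std = correction_matrix_theoretical("glutamate").matrix[:, 0] * 1e6
        C = correction_matrix_empirical("glutamate", std)
        mid, _ = correct_mid(std, C)
        assert mid[0] >= 0.999

    def test_zero_standard_rejected(self):
        with pytest.raises(ValueError, match="[Zz]ero"):
            correction_matrix_empirical("accoa", np.zeros(3))

    def test_agreement_with_theoretical_carbon_mode(self):
        """Standard generated at natural abundance: the unlabeled column is
        exact, and the shift-invariance approximation error of column j is
        bounded by the envelope of the j carbons it wrongly re-varies,
        i.e. about j * p13 per entry."""
        for met in ("accoa", "malate", "glutamate"):
            n = METABOLITES[met].n_carbons
            theo = correction_matrix_theoretical(met).matrix
            emp = correction_matrix_empirical(met, theo[:, 0]).matrix
            np.testing.assert_allclose(emp[:, 0], theo[:, 0], atol=1e-12)
            for j in range(1, n + 1):
                assert np.abs(theo[:, j] - emp[:, j]).max() <= j * P13_NATURAL + 1e-6, (met, j)


@st.composite
def random_mid(draw, n):
    raw = draw(
        st.lists(st.floats(0.0, 1.0), min_size=n + 1, max_size=n + 1).filter(
            lambda v: sum(v) > 1e-6
        )
    )
    arr = np.array(raw)
    return arr / arr.sum()


class TestCorrectMid:
    @pytest.mark.parametrize("mode", ["theoretical", "empirical"])
    @pytest.mark.parametrize("method", ["nnls", "solve_clip"])
    def test_round_trip_random_mids(self, mode, method, rng):
        """correct(convolve(m)) == m for 100 random MIDs per metabolite."""
        for met in ("accoa", "lactate", "malate", "glutamate"):
            n = METABOLITES[met].n_carbons
            theo = correction_matrix_theoretical(met)
            C = (
                theo
                if mode == "theoretical"
                else correction_matrix_empirical(met, theo.matrix[:, 0])
            )
            for _ in range(100):
                m = rng.dirichlet(np.ones(n + 1))
                obs = C.matrix @ m * 1e5
                est, total = correct_mid(obs, C, method=method)
                np.testing.assert_allclose(est, m, atol=1e-8)
                assert total == pytest.approx(1e5, rel=1e-6)

    @given(random_mid(n=4), st.integers(0, 2**31 - 1))
    def test_nnls_never_negative_under_noise(self, m, seed):
        rng = np.random.default_rng(seed)
        C = correction_matrix_theoretical("malate")
        obs = (C.matrix @ m) * rng.lognormal(0, 0.1, 5)
        if obs.sum() == 0:
            return
        est, _ = correct_mid(obs, C, method="nnls")
        assert np.all(est >= 0)
        assert est.sum() == pytest.approx(1.0, abs=1e-9)

    def test_noisy_recovery_within_monte_carlo_band(self):
        """nnls under cv=5% noise stays within 3x the empirical replicate SD."""
        rng = np.random.default_rng(2024)
        C = correction_matrix_theoretical("glutamate")
        truth = np.array([0.55, 0.02, 0.25, 0.05, 0.08, 0.05])
        ests = []
        for _ in range(100):
            obs = (C.matrix @ truth) * rng.lognormal(0, 0.05, 6)
            est, _ = correct_mid(obs, C)
            ests.append(est)
        ests = np.asarray(ests)
        sd = ests.std(axis=0)
        assert np.all(np.abs(ests.mean(axis=0) - truth) <= 3 * sd / np.sqrt(100) + 1e-3)

    def test_all_zero_observation_rejected(self):
        C = correction_matrix_theoretical("accoa")
        with pytest.raises(ValueError):
            correct_mid(np.zeros(3), C)


def test_correct_dataset_round_trip_noiseless(control_params, glucose_cfg):
    """Noiseless cohort tables correct back to the simulator's true MIDs."""
    from tracemet.measure import NoiseModel, simulate_cohort
    from tracemet.presets import default_cohort_design
    from tracemet.propagate import simulate_experiment

    design = default_cohort_design(n_replicates=2, tracers=[glucose_cfg])
    cohort = simulate_cohort(design, NoiseModel(0.0, 0.0, 0))
    corrected = correct_dataset(
        cohort["samples"], cohort["standards"], mode="theoretical_carbon"
    )
    truth = {
        "FTD3": simulate_experiment(glucose_cfg, design.lines[0][2]),
        "isogenic_control": simulate_experiment(glucose_cfg, control_params),
    }
    for (grp, met), sub in corrected.groupby(["group", "metabolite"]):
        rep = sub[sub["replicate"] == 1].sort_values("isotopologue")
        line = rep["line"].iloc[0]
        frac = rep[rep["line"] == line]["fraction"].to_numpy()
        np.testing.assert_allclose(frac, truth[grp][met], atol=1e-8, err_msg=f"{grp}/{met}")
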