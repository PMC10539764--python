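import math

import numpy as np
import pytest

import rdcalign as ra
from rdcalign import tensor_fit
from rdcalign.fixtures import consecutive_pairs

from conftest import random_saupe


def _two_atom(element_a, element_b, r):
    atoms = (
        ra.Atom("A", element_a, [0.0, 0.0, 0.0], 1.5),
        ra.Atom("B", element_b, [0.0, 0.0, r], 1.5),
    )
    return ra.Molecule("pair", atoms)


# ---------------------------------------------------------------------------
# dipolar prefactor
# ---------------------------------------------------------------------------


def test_dmax_ch_closed_form():
    # independent closed-form evaluation of mu0*gC*gH*h/(16 pi^3 r^3)
    mu0, h = 4e-7 * math.pi, 6.62607015e-34
    gh, gc = 2.6752218744e8, 6.728284e7
    r = 1.09e-10
    expected = mu0 * gh * gc * h / (16 * math.pi**3 * r**3)
    mol = _two_atom("C", "H", 1.09)
    assert ra.dmax("A", "B", mol) == pytest.approx(expected, rel=1e-12)
    assert expected == pytest.approx(23.3e3, rel=0.01)  # the familiar one-bond CH scale


def test_dmax_inverse_cube():
    assert ra.dmax("A", "B", _two_atom("C", "H", 2.18)) == pytest.approx(
        ra.dmax("A", "B", _two_atom("C", "H", 1.09)) / 8.0, rel=1e-12
    )


def test_dmax_hh_over_ch_is_gamma_ratio():
    r = 1.8
    ratio = ra.dmax("A", "B", _two_atom("H", "H", r)) / ra.dmax("A", "B", _two_atom("C", "H", r))
    assert ratio == pytest.approx(2.6752218744e8 / 6.728284e7, rel=1e-9)


def test_dmax_unsupported_nucleus():
    with pytest.raises(KeyError, match="unsupported"):
        ra.dmax("A", "B", _two_atom("O", "H", 1.0))


# ---------------------------------------------------------------------------
# back-calculation
# ---------------------------------------------------------------------------


def test_rdc_zero_tensor_gives_zero(bent_molecule, bent_pairs):
    zero = ra.SaupeTensor(np.zeros((3, 3)))
    for pair in bent_pairs:
        assert ra.rdc_from_tensor(zero, bent_molecule, pair) == 0.0


def test_rdc_axial_tensor_along_z():
    szz = 1e-3
    t = ra.SaupeTensor(np.diag([-szz / 2, -szz / 2, szz]))
    mol = _two_atom("C", "H", 1.09)  # internuclear vector along z
    assert ra.rdc_from_tensor(t, mol, ("A", "B")) == pytest.approx(
        ra.dmax("A", "B", mol) * szz, rel=1e-10
    )


def test_rdc_matches_eigen_expansion(bent_molecule, bent_pairs):
    # independent route: D = Dmax * sum_k lambda_k (u . v_k)^2
    t = random_saupe(5)
    vals, vecs, _ = ra.eigen_frame(t)
    for pair in bent_pairs[:4]:
        a, b = bent_molecule.atom(pair[0]), bent_molecule.atom(pair[1])
        u = b.position - a.position
        u = u / np.linalg.norm(u)
        expected = ra.dmax(*pair, bent_molecule) * sum(
            vals[k] * float(u @ vecs[:, k]) ** 2 for k in range(3)
        )
        assert ra.rdc_from_tensor(t, bent_molecule, pair) == pytest.approx(expected, rel=1e-10)


# ---------------------------------------------------------------------------
# SVD fitting
# ---------------------------------------------------------------------------


def test_svd_fit_exact_recovery(bent_molecule, bent_pairs):
    truth = random_saupe(11)
    rdcs = ra.make_synthetic_rdcs(bent_molecule, truth, bent_pairs)
    fit = ra.svd_fit(rdcs, bent_molecule)
    np.testing.assert_allclose(fit.tensor.matrix, truth.matrix, atol=1e-9 * 1e-3)
    assert fit.r == pytest.approx(1.0)


def test_svd_fit_equals_normal_equations(bent_molecule, bent_pairs):
    pairs = bent_pairs[:6]
    rdcs = ra.make_synthetic_rdcs(bent_molecule, random_saupe(12), pairs, noise_sigma=0.8, seed=9)
    fit = ra.svd_fit(rdcs, bent_molecule)
    A = tensor_fit.design_matrix(bent_molecule, pairs)
    params = np.linalg.solve(A.T @ A, A.T @ rdcs.values)  # brute-force normal equations
    syy, szz, sxy, sxz, syz = params
    expected = np.array([[-syy - szz, sxy, sxz], [sxy, syy, syz], [sxz, syz, szz]])
    np.testing.assert_allclose(fit.tensor.matrix, expected, atol=1e-10 * np.abs(expected).max())


def test_svd_fit_noise_residual_scale(bent_molecule, bent_pairs):
    sigma = 1.5
    rms_resids = []
    for seed in range(12):
        rdcs = ra.make_synthetic_rdcs(
            bent_molecule, random_saupe(20), bent_pairs, noise_sigma=sigma, seed=seed
        )
        fit = ra.svd_fit(rdcs, bent_molecule)
        rms_resids.append(np.sqrt(np.mean((rdcs.values - fit.d_calc) ** 2)))
    # residual rms tracks the injected noise (5 dof absorbed out of 13 couplings)
    expected = sigma * np.sqrt(1 - 5 / len(bent_pairs))
    assert np.mean(rms_resids) == pytest.approx(expected, rel=0.35)


def test_svd_fit_too_few_rdcs(bent_molecule, bent_pairs):
    rdcs = ra.make_synthetic_rdcs(bent_molecule, random_saupe(1), bent_pairs[:4])
    with pytest.raises(ValueError, match=">= 5"):
        ra.svd_fit(rdcs, bent_molecule)


def test_svd_fit_rank_deficient():
    # all internuclear vectors parallel: only one independent orientation
    atoms = tuple(
        ra.Atom(f"{'C' if i % 2 == 0 else 'H'}{i}", "C" if i % 2 == 0 else "H",
                [float(i), 0.0, 0.0], 1.5)
        for i in range(8)
    )
    mol = ra.Molecule("line", atoms)
    pairs = [(atoms[i].name, atoms[i + 1].name) for i in range(7)]
    rdcs = ra.make_synthetic_rdcs(mol, random_saupe(3), pairs)
    with pytest.raises(ValueError, match="rank"):
        ra.svd_fit(rdcs, mol)


# ---------------------------------------------------------------------------
# quality statistics
# ---------------------------------------------------------------------------


def test_quality_stats_perfect_fit():
    d = np.array([1.0, -2.0, 3.0, 0.5])
    r, q, slope, qs, rq = ra.quality_stats(d, d)
    assert (r, q, slope, qs) == pytest.approx((1.0, 0.0, 1.0, 0.0), abs=1e-12)
    assert rq == pytest.approx(4.0 / tensor_fit.QS_FLOOR)


def test_quality_stats_published_value_formula():
    # direct formula on R = 0.996, QS = 0.076: RQ = (1.996)^2 / 0.076
    assert (0.996 + 1) ** 2 / 0.076 == pytest.approx(52.42, abs=0.01)


def test_quality_stats_anticorrelation():
    d = np.array([1.0, -2.0, 3.0, 0.5])
    r, q, slope, qs, rq = ra.quality_stats(d, -d)
    assert r == pytest.approx(-1.0)
    assert slope == pytest.approx(-1.0)
    assert rq == pytest.approx(0.0, abs=1e-12)


def test_qs_invariant_to_prediction_rescaling():
    rng = np.random.default_rng(4)
    d_exp = rng.normal(0, 10, 9)
    d_pred = d_exp + rng.normal(0, 1, 9)
    _, _, _, qs1, rq1 = ra.quality_stats(d_exp, d_pred)
    _, _, _, qs2, rq2 = ra.quality_stats(d_exp, 7.3 * d_pred)
    assert qs2 == pytest.approx(qs1, rel=1e-12)
    assert rq2 == pytest.approx(rq1, rel=1e-12)


def test_rq_monotonicity():
    # decreasing in qs at fixed r, increasing in r at fixed qs
    rq = lambda r, qs: (r + 1) ** 2 / max(qs, tensor_fit.QS_FLOOR)
    assert rq(0.9, 0.1) > rq(0.9, 0.2)
    assert rq(0.95, 0.1) > rq(0.85, 0.1)


def test_quality_stats_all_zero_prediction_is_error():
    with pytest.raises(ValueError, match="slope"):
        ra.quality_stats(np.array([1.0, 2.0]), np.zeros(2))


# ---------------------------------------------------------------------------
# Monte Carlo errors
# ---------------------------------------------------------------------------


def _stat_fn(noisy):
    d = noisy.values
    ref = np.arange(1, len(d) + 1, dtype=float)
    r, _, _, qs, rq = ra.quality_stats(d, ref)
    return r, qs, rq


def _noisy_set(sigma):
    rng = np.random.default_rng(8)
    records = tuple(
        ra.RDCRecord(f"C{i}", f"H{i}", float(i + 1 + rng.normal(0, 0.2)), sigma)
        for i in range(8)
    )
    return ra.RDCSet("m", "x", records)


def test_monte_carlo_zero_sigma_zero_errors():
    errs = ra.monte_carlo_errors(_stat_fn, _noisy_set(0.0), n_rep=10, seed=0)
    assert errs == pytest.approx((0.0, 0.0, 0.0), abs=1e-12)


def test_monte_carlo_deterministic_with_seed():
    a = ra.monte_carlo_errors(_stat_fn, _noisy_set(0.5), n_rep=50, seed=42)
    b = ra.monte_carlo_errors(_stat_fn, _noisy_set(0.5), n_rep=50, seed=42)
    assert a == b  # bitwise


def test_monte_carlo_error_grows_with_sigma():
    lo = ra.monte_carlo_errors(_stat_fn, _noisy_set(0.5), n_rep=200, seed=7)
    hi = ra.monte_carlo_errors(_stat_fn, _noisy_set(1.0), n_rep=200, seed=7)
    assert hi[0] > lo[0]


# ---------------------------------------------------------------------------
# eigen frame
# ---------------------------------------------------------------------------


def test_eigen_frame_axial_along_z():
    t = ra.SaupeTensor(1e-3 * np.diag([-0.5, -0.5, 1.0]))
    vals, vecs, _ = ra.eigen_frame(t)
    assert abs(vals[2]) >= abs(vals[1]) >= abs(vals[0])
    np.testing.assert_allclose(np.abs(vecs[:, 2]), [0, 0, 1], atol=1e-12)


def test_eigen_frame_reconstruction():
    t = random_saupe(31)
    vals, vecs, _ = ra.eigen_frame(t)
    np.testing.assert_allclose(vecs @ np.diag(vals) @ vecs.T, t.matrix, atol=1e-12 * 1e-3)
    np.testing.assert_allclose(vecs.T @ vecs, np.eye(3), atol=1e-10)


def test_eigen_frame_degenerate_pair_no_exception():
    # |Sxx| = |Syy|: deterministic tie-break by descending signed value
    t = ra.SaupeTensor(1e-3 * np.diag([0.5, -0.5, 0.0])[[2, 0, 1]][:, [2, 0, 1]])
    vals, vecs, _ = ra.eigen_frame(t)
    assert abs(abs(vals[1]) - abs(vals[2])) < 1e-15
    assert vals[1] >= vals[2]  # tie-break: positive eigenvalue first
    assert np.all(vecs[2, :] > -1e-12)  # hemisphere canonicalization


def test_eigen_ordering_after_fit(bent_molecule, bent_pairs):
    for seed in range(5):
        rdcs = ra.make_synthetic_rdcs(
            bent_molecule, random_saupe(seed + 40), bent_pairs, noise_sigma=0.5, seed=seed
        )
        vals = ra.svd_fit(rdcs, bent_molecule).tensor.eigenvalues
        assert abs(vals[2]) >= abs(vals[1]) >= abs(vals[0])
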