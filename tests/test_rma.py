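"""RMA stages against independent brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from tempotome import ProbeIntensityMatrix, background_correct, median_polish, median_polish_summarize, quantile_normalize, rma
from tempotome.rma import estimate_background_parameters, exp_normal_posterior_mean


# --- independent oracles -------------------------------------------------

def quantile_oracle(X):
    """Naive sort/average/unsort quantile normalization with tie averaging."""
    X = np.asarray(X, float)
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = sorted(X[:, j])
        for i, v in enumerate(X[:, j]):
            ranks = [k for k, s in enumerate(col) if s == v]
            out[i, j] = np.mean([ref[k] for k in ranks])
    return out


def median_polish_oracle(X, tol=1e-8, max_iter=20):
    """Scalar-loop re-implementation of the alternating median sweeps."""
    X = [list(map(float, row)) for row in X]
    nr, nc = len(X), len(X[0])
    overall, row, col = 0.0, [0.0] * nr, [0.0] * nc
    med = lambda v: float(np.median(v))
    for _ in range(max_iter):
        rm = [med(X[i]) for i in range(nr)]
        for i in range(nr):
            for j in range(nc):
                X[i][j] -= rm[i]
            row[i] += rm[i]
        d = med(row)
        row = [v - d for v in row]
        overall += d
        cm = [med([X[i][j] for i in range(nr)]) for j in range(nc)]
        for j in range(nc):
            for i in range(nr):
                X[i][j] -= cm[j]
            col[j] += cm[j]
        d = med(col)
        col = [v - d for v in col]
        overall += d
        if max(max(abs(v) for v in rm), max(abs(v) for v in cm)) < tol:
            break
    return overall, row, col


def posterior_mean_quadrature(observed, mu, sigma, alpha):
    """Numerical integration of E[S | O] over the truncated-normal posterior."""
    a = observed - mu - sigma * sigma * alpha
    lo, hi = max(0.0, a - 12 * sigma), a + 12 * sigma
    f = lambda s: np.exp(-alpha * s) * stats.norm.pdf(observed - s, mu, sigma)
    num = integrate.quad(lambda s: s * f(s), lo, hi, limit=200)[0]
    den = integrate.quad(f, lo, hi, limit=200)[0]
    return num / den


# --- background correction ----------------------------------------------

def test_posterior_mean_matches_quadrature():
    mu, sigma, alpha = 100.0, 10.0, 0.001
    for observed in (500.0, 150.0, 90.0, 50.0):
        closed = exp_normal_posterior_mean(np.array([observed]), mu, sigma, alpha)[0]
        numeric = posterior_mean_quadrature(observed, mu, sigma, alpha)
        assert closed == pytest.approx(numeric, rel=1e-6)


def test_posterior_mean_noise_free_limit():
    # sigma -> 0 and observed >> mu: plain background subtraction
    out = exp_normal_posterior_mean(np.array([500.0]), mu=100.0, sigma=1e-4, alpha=0.001)
    assert out[0] == pytest.approx(400.0, abs=1e-3)


def test_posterior_mean_strictly_positive_below_background():
    out = exp_normal_posterior_mean(
        np.array([1.0, 10.0, 50.0, 99.0]), mu=100.0, sigma=10.0, alpha=0.01
    )
    assert np.all(out > 0)


def test_background_correct_bounds_and_errors(rng):
    signal = rng.exponential(200.0, size=(400, 3))
    bg = rng.normal(100.0, 10.0, size=(400, 3))
    obs = np.clip(signal + bg, 1e-6, None)
    m = ProbeIntensityMatrix(
        intensities=pd.DataFrame(obs, columns=["a", "b", "c"],
                                 index=[f"p{i}" for i in range(400)]),
        probeset=pd.Series([f"ps{i // 4}" for i in range(400)],
                           index=[f"p{i}" for i in range(400)]),
    )
    corrected = background_correct(m)
    vals = corrected.intensities.to_numpy()
    assert np.all(vals > 0)
    assert np.all(vals <= obs + 1e-12)
    with pytest.raises(ValueError):
        estimate_background_parameters(np.full(10, 5.0))


# --- quantile normalization ----------------------------------------------

def test_quantile_hand_example():
    X = np.array([[2.0, 4.0], [5.0, 1.0], [3.0, 6.0]])
    out = quantile_normalize(X)
    np.testing.assert_allclose(out[:, 0], [1.5, 5.5, 3.5])
    np.testing.assert_allclose(out[:, 1], [3.5, 1.5, 5.5])


def test_quantile_idempotent_on_equal_distributions(rng):
    col = rng.normal(size=50)
    X = np.column_stack([col, col, col])
    np.testing.assert_allclose(quantile_normalize(X), X, atol=1e-12)


def test_quantile_matches_oracle_on_random_instances(rng):
    for _ in range(100):
        n, p = rng.integers(2, 12), rng.integers(1, 6)
        X = rng.normal(size=(n, p))
        if rng.random() < 0.5:  # inject ties
            X = np.round(X, 1)
        np.testing.assert_allclose(quantile_normalize(X), quantile_oracle(X), atol=1e-8)


@settings(derandomize=True, max_examples=40)
@given(
    st.integers(2, 20), st.integers(1, 5), st.integers(0, 2**31 - 1)
)
def test_quantile_columns_share_multiset_and_ranks(n, p, seed):
    X = np.random.default_rng(seed).normal(size=(n, p))
    out = quantile_normalize(X)
    ref = np.sort(out[:, 0])
    for j in range(p):
        np.testing.assert_allclose(np.sort(out[:, j]), ref, atol=1e-12)
        # rank order preserved within columns (no ties in continuous draws)
        assert np.array_equal(np.argsort(X[:, j]), np.argsort(out[:, j]))


def test_quantile_rejects_empty():
    with pytest.raises(ValueError):
        quantile_normalize(np.empty((0, 0)))


# --- median polish --------------------------------------------------------

def test_median_polish_additive_2x2():
    overall, row, col, resid, converged = median_polish(np.array([[1.0, 2.0], [3.0, 4.0]]))
    assert converged
    np.testing.assert_allclose(resid, 0.0, atol=1e-12)
    np.testing.assert_allclose(overall + col, [2.0, 3.0])


def test_median_polish_matches_oracle_random_blocks(rng):
    for _ in range(100):
        X = rng.normal(size=(5, 4))
        overall, row, col, _, _ = median_polish(X)
        o_overall, o_row, o_col = median_polish_oracle(X)
        assert overall == pytest.approx(o_overall, abs=1e-8)
        np.testing.assert_allclose(row, o_row, atol=1e-8)
        np.testing.assert_allclose(col, o_col, atol=1e-8)


def test_summarize_single_probe_identity():
    vals = pd.DataFrame([[1.0, 2.0, 3.0]], index=["p0"], columns=["a", "b", "c"])
    out = median_polish_summarize(vals, pd.Series(["ps0"], index=["p0"]))
    np.testing.assert_allclose(out.loc["ps0"], [1.0, 2.0, 3.0])


def test_summarize_matches_per_block_polish(rng):
    # grouped 3-D sweeps must agree with polishing each block alone
    n_sets, k, n_arrays = 7, 5, 4
    X = rng.normal(size=(n_sets * k, n_arrays))
    probes = [f"s{s}_p{i}" for s in range(n_sets) for i in range(k)]
    probeset = pd.Series([p.split("_")[0] for p in probes], index=probes)
    vals = pd.DataFrame(X, index=probes, columns=list("abcd"))
    out = median_polish_summarize(vals, probeset)
    for s in range(n_sets):
        overall, _, col, _, _ = median_polish(X[s * k:(s + 1) * k])
        np.testing.assert_allclose(out.loc[f"s{s}"], overall + col, atol=1e-10)


def test_summarize_rejects_mismatched_probes():
    vals = pd.DataFrame([[1.0]], index=["p0"], columns=["a"])
    with pytest.raises(Exception):
        median_polish_summarize(vals, pd.Series(["ps0"], index=["other"]))


# --- full chain -----------------------------------------------------------

def test_rma_chain_deterministic(zero_noise_run):
    again = rma(zero_noise_run.probes, bgcorrect=False)
    pd.testing.assert_frame_equal(zero_noise_run.expr, again)
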