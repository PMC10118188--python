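import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from streambaci import (
    compare_cells,
    letter_display,
    wild_bootstrap,
    wu_jackknife,
)
from streambaci.inference import CellEstimate, WildBootstrapReport


# --- independent OLS oracles --------------------------------------------

def _ols_coefs(X, y):
    Xi = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(Xi, y, rcond=None)
    return beta  # intercept first


def _ols_hat_diag(X):
    Xi = np.column_stack([np.ones(X.shape[0]), X])
    return np.diag(Xi @ np.linalg.inv(Xi.T @ Xi) @ Xi.T)


def _ols_wu_variance(X, y):
    """Delete-one OLS Wu jackknife with (1 - h_i) weights."""
    n = len(y)
    beta = _ols_coefs(X, y)[1:]
    h = _ols_hat_diag(X)
    dev = np.zeros((n, X.shape[1]))
    for i in range(n):
        mask = np.arange(n) != i
        dev[i] = _ols_coefs(X[mask], y[mask])[1:] - beta
    return ((1 - h)[:, None] * dev**2).sum(axis=0)


def _ols_wild_cis(X, y, n_resamples, seed, alpha=0.05):
    """Wild bootstrap HC3 on OLS, replicating the package's sign stream."""
    n = len(y)
    full = _ols_coefs(X, y)
    Xi = np.column_stack([np.ones(n), X])
    fitted = Xi @ full
    resid = y - fitted
    h = _ols_hat_diag(X)
    scaled = resid / (1 - h)
    rng = np.random.default_rng(seed)
    boot = np.zeros((n_resamples, X.shape[1]))
    for b in range(n_resamples):
        v = rng.choice((-1.0, 1.0), size=n)
        boot[b] = _ols_coefs(X, fitted + v * scaled)[1:]
    return np.percentile(boot, [100 * alpha / 2, 100 * (1 - alpha / 2)], axis=0)


# --- Wu jackknife --------------------------------------------------------

class TestWuJackknife:
    def test_zero_noise_degenerate(self, rng):
        X = rng.normal(size=(15, 3))
        y = X @ [1.0, 2.0, -1.0] + 4.0
        rep = wu_jackknife(X, y, k=3)
        assert np.all(rep.degenerate)
        np.testing.assert_allclose(rep.variance, 0.0, atol=1e-16)
        np.testing.assert_allclose(rep.p, 0.0)

    def test_ols_equivalence_at_full_rank(self, rng):
        X = rng.normal(size=(25, 3))
        y = X @ [1.0, 0.0, -0.5] + rng.normal(scale=0.8, size=25)
        rep = wu_jackknife(X, y, k=3, weighted=True)
        ref = _ols_wu_variance(X, y)
        np.testing.assert_allclose(rep.variance, ref, atol=1e-8)
        np.testing.assert_allclose(rep.coef, _ols_coefs(X, y)[1:], atol=1e-8)

    def test_null_calibration_matches_ols_oracle(self):
        # y independent of X at k = rank: decisions must agree with the
        # independently coded delete-one OLS Wu jackknife replicate by
        # replicate, and the rejection rate must stay near alpha.
        # (300 replicates instead of 1000 to stay inside the test budget;
        # agreement is exact so the MC size only affects the sanity band.)
        reps = 300
        n, p = 40, 3
        r = np.random.default_rng(100)
        rej = rej_ref = 0
        from scipy import stats as ss

        for _ in range(reps):
            X = r.normal(size=(n, p))
            y = r.normal(size=n)
            rep = wu_jackknife(X, y, k=p)
            rej += int(np.any(rep.p <= 0.05))
            var_ref = _ols_wu_variance(X, y)
            t_ref = _ols_coefs(X, y)[1:] / np.sqrt(var_ref)
            p_ref = 2 * ss.t.sf(np.abs(t_ref), rep.df)
            rej_ref += int(np.any(p_ref <= 0.05))
            np.testing.assert_allclose(rep.variance, var_ref, atol=1e-8)
        assert rej == rej_ref
        # any-of-3 coefficients at alpha=.05: familywise rate well below 0.3
        assert rej / reps < 0.3

    def test_unweighted_variant(self, rng):
        X = rng.normal(size=(20, 2))
        y = X @ [1.0, -1.0] + rng.normal(size=20)
        w = wu_jackknife(X, y, k=2, weighted=True)
        u = wu_jackknife(X, y, k=2, weighted=False)
        assert not np.allclose(w.variance, u.variance)
        assert np.all(u.variance >= 0)

    def test_needs_enough_rows(self, rng):
        X = rng.normal(size=(4, 3))
        with pytest.raises(ValueError, match="n >"):
            wu_jackknife(X, rng.normal(size=4), k=2)


# --- wild bootstrap ------------------------------------------------------

class TestWildBootstrap:
    def test_default_resamples_is_2000(self):
        import inspect

        sig = inspect.signature(wild_bootstrap)
        assert sig.parameters["n_resamples"].default == 2000

    def test_zero_residual_zero_width(self, rng):
        X = rng.normal(size=(15, 2))
        y = X @ [2.0, -1.0] + 3.0
        cells = {"a": np.array([1.0, 0.0]), "b": np.array([0.0, 1.0])}
        rep = wild_bootstrap(X, y, k=2, cells=cells, n_resamples=50, seed=0)
        np.testing.assert_allclose(rep.coef_lower, rep.coef_upper, atol=1e-10)
        for est in rep.cells.values():
            assert est.upper - est.lower < 1e-10

    def test_ols_equivalence_on_shared_streams(self, rng):
        n, p = 30, 3
        X = rng.normal(size=(n, p))
        noise = rng.normal(size=n) * (0.5 + np.abs(X[:, 0]))  # heteroscedastic
        y = X @ [1.0, -0.5, 0.0] + noise
        rep = wild_bootstrap(X, y, k=p, n_resamples=400, seed=77)
        lo_ref, hi_ref = _ols_wild_cis(X, y, 400, seed=77)
        np.testing.assert_allclose(rep.coef_lower, lo_ref, atol=1e-8)
        np.testing.assert_allclose(rep.coef_upper, hi_ref, atol=1e-8)

    def test_seeded_determinism(self, rng):
        X = rng.normal(size=(20, 2))
        y = X @ [1.0, 1.0] + rng.normal(size=20)
        cells = {"c": np.array([1.0, 1.0])}
        a = wild_bootstrap(X, y, k=2, cells=cells, n_resamples=200, seed=5)
        b = wild_bootstrap(X, y, k=2, cells=cells, n_resamples=200, seed=5)
        np.testing.assert_array_equal(a.coef_lower, b.coef_lower)
        assert a.cells["c"].lower == b.cells["c"].lower

    def test_mammen_weights_supported(self, rng):
        X = rng.normal(size=(15, 2))
        y = X @ [1.0, 0.5] + rng.normal(size=15)
        rep = wild_bootstrap(X, y, k=2, n_resamples=100, seed=1, aux="mammen")
        assert np.all(rep.coef_lower <= rep.coef_upper)

    def test_coef_significance_rule(self, rng):
        X = rng.normal(size=(40, 2))
        y = 5.0 * X[:, 0] + rng.normal(scale=0.2, size=40)
        rep = wild_bootstrap(X, y, k=2, n_resamples=300, seed=2)
        sig = rep.coef_significant()
        assert sig[0]  # strong effect: CI excludes zero
        assert not sig[1]

    def test_back_transform_attached(self, rng):
        from streambaci import BoxCoxSpec

        X = rng.normal(size=(20, 2))
        z = 1.0 + 0.3 * X[:, 0] + rng.normal(scale=0.1, size=20)
        cells = {"c": np.array([1.0, 0.0])}
        spec = BoxCoxSpec(lam=0.0, shift=0.0)
        rep = wild_bootstrap(X, z, k=2, cells=cells, n_resamples=100, seed=3, transform=spec)
        est = rep.cells["c"]
        assert est.pred_back == pytest.approx(np.exp(est.pred))
        assert est.lower_back == pytest.approx(np.exp(est.lower))


# --- cell comparisons and letters ---------------------------------------

def _report(intervals):
    """Build a report with given {cell: (pred, lo, hi)}."""
    rep = WildBootstrapReport(columns=[], coef=np.array([]),
                              coef_lower=np.array([]), coef_upper=np.array([]))
    for cid, (pred, lo, hi) in intervals.items():
        rep.cells[cid] = CellEstimate(cell=cid, pred=pred, lower=lo, upper=hi)
    return rep


class TestCompareCells:
    def test_disjoint(self):
        rep = _report({"a": (1.5, 1, 2), "b": (3.5, 3, 4)})
        assert compare_cells(rep, "a", "b") is True

    def test_overlap(self):
        rep = _report({"a": (2, 1, 3), "b": (3, 2, 4)})
        assert compare_cells(rep, "a", "b") is False

    def test_shared_endpoint_counts_as_intersecting(self):
        rep = _report({"a": (1.5, 1, 2), "b": (2.5, 2, 3)})
        assert compare_cells(rep, "a", "b") is False


class TestLetterDisplay:
    def test_all_overlapping_single_letter(self):
        rep = _report({c: (i, 0, 10) for i, c in enumerate("wxyz")})
        disp = letter_display(rep)
        assert all(v == "A" for v in disp.letters.values())

    def test_all_disjoint_ordered_letters(self):
        rep = _report({"hi": (9, 8, 10), "mid": (5, 4, 6), "lo": (1, 0, 2)})
        disp = letter_display(rep)
        assert disp.letters == {"hi": "A", "mid": "B", "lo": "C"}

    def test_chain_case(self):
        # x > y > z; (x,y) overlap, (y,z) overlap, (x,z) disjoint
        rep = _report({"x": (10, 8, 12), "y": (7, 5, 9), "z": (4, 2, 6)})
        assert compare_cells(rep, "x", "z")
        assert not compare_cells(rep, "x", "y")
        disp = letter_display(rep)
        assert disp.letters == {"x": "A", "y": "AB", "z": "B"}

    def test_alphabet_extends_past_26(self):
        rep = _report({f"c{i}": (float(-i), -i - 0.4, -i + 0.4) for i in range(30)})
        disp = letter_display(rep)
        values = list(disp.letters.values())
        assert len(set(values)) == 30
        assert disp.letters["c0"] == "A"
        assert disp.letters["c29"] == "AD"

    @settings(max_examples=60, deadline=None)
    @given(st.integers(0, 10_000), st.integers(2, 8))
    def test_soundness_on_random_intervals(self, seed, n_cells):
        r = np.random.default_rng(seed)
        rep = _report(
            {i: (float(c), float(c - w), float(c + w))
             for i, (c, w) in enumerate(zip(r.normal(size=n_cells) * 3,
                                            r.uniform(0.1, 3, size=n_cells)))}
        )
        disp = letter_display(rep)  # internal soundness assertion runs
        for a in rep.cells:
            assert disp.letters[a]
            for b in rep.cells:
                if a != b:
                    assert disp.share_letter(a, b) == (not compare_cells(rep, a, b))

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_widening_never_creates_significance(self, seed):
        r = np.random.default_rng(seed)
        centers = r.normal(size=5) * 3
        widths = r.uniform(0.1, 2, size=5)
        narrow = _report({i: (float(c), float(c - w), float(c + w))
                          for i, (c, w) in enumerate(zip(centers, widths))})
        wide = _report({i: (float(c), float(c - 2 * w), float(c + 2 * w))
                        for i, (c, w) in enumerate(zip(centers, widths))})
        for a in range(5):
            for b in range(a + 1, 5):
                if not compare_cells(narrow, a, b):
                    assert not compare_cells(wide, a, b)

    def test_largest_prediction_carries_a(self, rng):
        X = rng.normal(size=(40, 2))
        y = X @ [2.0, 1.0] + rng.normal(scale=0.5, size=40)
        cells = {i: np.array([float(i), 0.0]) for i in range(4)}
        rep = wild_bootstrap(X, y, k=2, cells=cells, n_resamples=300, seed=8)
        disp = letter_display(rep)
        top = max(rep.cells, key=lambda c: rep.cells[c].pred)
        assert "A" in disp.letters[top]
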