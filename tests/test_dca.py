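import numpy as np
import pytest
from scipy.optimize import minimize

from defold import dca
from defold import msa as M
from defold.synthetic import PlantedPotts, sample_potts_msa


def uniform_weights(m):
    return M.SeqWeights(np.ones(m.n_rows), 1.0)


# ---------------------------------------------------------------------------
# Independent oracles


def naive_pseudo_nll(x, arr, lam_h, lam_e, q):
    """Straight-loop pseudo-likelihood for a 2-column alignment (oracle)."""
    h = x[: 2 * q].reshape(2, q)
    e = x[2 * q:].reshape(q, q)
    n = arr.shape[0]
    total = 0.0
    for row in arr:
        a0, a1 = row
        z0 = np.log(sum(np.exp(h[0][b] + e[b][a1]) for b in range(q)))
        total -= (h[0][a0] + e[a0][a1] - z0) / n
        z1 = np.log(sum(np.exp(h[1][b] + e[a0][b]) for b in range(q)))
        total -= (h[1][a1] + e[a0][a1] - z1) / n
    return total + lam_h * (h**2).sum() + lam_e * (e**2).sum()


def bruteforce_plm_q2(msa, lam=(0.1, 0.1)):
    """Derivative-free minimization of the independently coded objective."""
    arr = msa.to_array()
    res = minimize(naive_pseudo_nll, np.zeros(8), args=(arr, lam[0], lam[1], 2),
                   method="Nelder-Mead",
                   options={"maxiter": 5000, "fatol": 1e-12, "xatol": 1e-8})
    res = minimize(naive_pseudo_nll, res.x, args=(arr, lam[0], lam[1], 2),
                   method="BFGS", options={"gtol": 1e-10})
    return dca.to_zero_sum_gauge(res.x[:4].reshape(2, 2),
                                 res.x[4:].reshape(1, 2, 2))


def closed_form_di_2x2(e):
    """DI for a single q=2 pair with uniform marginals, by direct summation.

    With uniform marginals the direct distribution is the unique 2x2 table
    with margins (1/2, 1/2) and odds ratio exp(e00 + e11 - e01 - e10).
    """
    sr = np.sqrt(np.exp(e[0, 0] + e[1, 1] - e[0, 1] - e[1, 0]))
    p = 0.5 * sr / (1 + sr)
    P = np.array([[p, 0.5 - p], [0.5 - p, p]])
    return float((P * np.log(P / 0.25)).sum())


# ---------------------------------------------------------------------------
# Frequencies


class TestSiteFrequencies:
    def test_identical_rows_are_indicators(self):
        m = M.Msa(["AC"] * 5)
        f = dca.site_frequencies(m, uniform_weights(m), lam=0.0)
        assert f.f_i[0, 0] == pytest.approx(1.0)   # A at site 0
        assert f.f_i[1, 1] == pytest.approx(1.0)   # C at site 1

    def test_two_point_split(self):
        m = M.Msa(["AA", "CC"])
        f = dca.site_frequencies(m, uniform_weights(m), lam=0.0)
        assert f.f_i[0, 0] == pytest.approx(0.5)
        assert f.f_i[0, 1] == pytest.approx(0.5)

    def test_pseudocount_mixing_formula(self):
        m = M.Msa(["AC"] * 3)
        f = dca.site_frequencies(m, uniform_weights(m), lam=0.5)
        assert f.f_i[0, 0] == pytest.approx(0.5 + 0.5 / 21)

    def test_normalization_and_symmetry(self):
        m = M.Msa(["ACD", "A-D", "CCD", "AC-"])
        f = dca.site_frequencies(m, uniform_weights(m), lam=0.2)
        assert np.allclose(f.f_i.sum(axis=1), 1.0)
        assert np.allclose(f.f_ij.sum(axis=(2, 3)), 1.0)
        assert np.allclose(f.f_ij[0, 2], f.f_ij[2, 0].T)


# ---------------------------------------------------------------------------
# Pseudo-likelihood fitting


class TestFitPlm:
    def test_matches_bruteforce_on_tiny_system(self):
        rows = ["AA"] * 5 + ["AC"] * 2 + ["CA"] * 1 + ["CC"] * 4
        m = M.Msa(rows)
        fit = dca.fit_plm(m, uniform_weights(m), reg=(0.1, 0.1), q=2, tol=1e-15)
        h_bf, e_bf = bruteforce_plm_q2(m)
        assert np.abs(fit.h - h_bf).max() < 1e-3
        assert np.abs(fit.e - e_bf).max() < 1e-3

    def test_zero_sum_gauge_and_determinism(self):
        m = M.Msa(["ACDA", "CADC", "AACD", "CCDA", "ADCA"])
        w = uniform_weights(m)
        fit1 = dca.fit_plm(m, w, q=21)
        fit2 = dca.fit_plm(m, w, q=21)
        assert np.array_equal(fit1.h, fit2.h)
        assert np.array_equal(fit1.e, fit2.e)
        assert np.abs(fit1.e.sum(axis=1)).max() < 1e-8
        assert np.abs(fit1.e.sum(axis=2)).max() < 1e-8
        assert np.abs(fit1.h.sum(axis=1)).max() < 1e-8

    def test_gauge_shift_of_fields_regauges_to_same_model(self):
        m = M.Msa(["AC", "CA", "AA", "CC", "AC"])
        fit = dca.fit_plm(m, uniform_weights(m), q=2)
        h_shift = fit.h + 3.7  # constant per site: absorbed by Z
        h2, e2 = dca.to_zero_sum_gauge(h_shift, fit.e)
        assert np.allclose(h2, fit.h)
        assert np.allclose(e2, fit.e)

    def test_independent_columns_have_no_significant_couplings(self):
        # columns sampled from independent fields: coupling norms should be
        # statistically indistinguishable from a column-permuted null
        fields = np.zeros((6, 2))
        fields[:, 0] = np.linspace(-0.5, 0.5, 6)
        model = PlantedPotts(L=6, q=2, planted_pairs=[], fields=fields)
        msa = sample_potts_msa(model, 500, seed=11)
        fit = dca.fit_plm(msa, uniform_weights(msa), q=2)
        norms = np.linalg.norm(fit.e, axis=(1, 2))

        rng = np.random.default_rng(0)
        arr = msa.to_array()
        null_max = []
        for _ in range(3):
            perm = np.column_stack([rng.permutation(arr[:, c])
                                    for c in range(arr.shape[1])])
            letters = "AC"
            null = M.Msa(["".join(letters[a] for a in row) for row in perm])
            nfit = dca.fit_plm(null, uniform_weights(null), q=2)
            null_max.append(np.linalg.norm(nfit.e, axis=(1, 2)).max())
        assert norms.max() <= 2.0 * max(null_max)

    def test_stronger_coupling_regularization_shrinks_couplings(self):
        m = M.Msa(["AACA", "CCAC", "AACA", "ACCA", "CAAC", "AACC"])
        w = uniform_weights(m)
        norms = [
            np.linalg.norm(dca.fit_plm(m, w, reg=(0.01, lam_e), q=2).e)
            for lam_e in (0.01, 0.1, 1.0)
        ]
        assert norms[0] > norms[1] > norms[2]


# ---------------------------------------------------------------------------
# Direct information


class TestDirectInformation:
    def test_zero_couplings_give_zero_di(self):
        m = M.Msa(["ACA", "CAC", "AAA", "CCC"])
        f = dca.site_frequencies(m, uniform_weights(m), lam=0.1, q=2)
        model = dca.PottsModel(h=np.zeros((3, 2)), e=np.zeros((3, 2, 2)))
        di = dca.direct_information(model, f)
        assert np.abs(di.di).max() < 1e-12

    def test_symmetry_and_zero_diagonal(self):
        model = PlantedPotts(L=5, q=2, planted_pairs=[(0, 3, 1.0)])
        msa = sample_potts_msa(model, 400, seed=3)
        w = uniform_weights(msa)
        fit = dca.fit_plm(msa, w, q=2)
        di = dca.direct_information(fit, dca.site_frequencies(msa, w, q=2))
        assert np.allclose(di.di, di.di.T)
        assert np.all(np.diag(di.di) == 0)
        assert np.all(di.di >= 0)

    def test_matches_direct_summation_on_known_pair(self):
        e = np.array([[0.8, -0.3], [-0.5, 0.2]])
        model = dca.PottsModel(h=np.zeros((2, 2)), e=e[None].copy())
        freqs = dca.SiteFrequencies(
            f_i=np.full((2, 2), 0.5), f_ij=np.zeros((2, 2, 2, 2)),
            lam=0.0, q=2,
        )
        di = dca.direct_information(model, freqs)
        assert di.di[0, 1] == pytest.approx(closed_form_di_2x2(e), abs=1e-9)

    def test_gauge_invariance(self):
        model = PlantedPotts(L=4, q=3, planted_pairs=[(0, 2, 1.5)])
        msa = sample_potts_msa(model, 500, seed=5)
        w = uniform_weights(msa)
        freqs = dca.site_frequencies(msa, w, q=3)
        fit = dca.fit_plm(msa, w, q=3)
        di1 = dca.direct_information(fit, freqs)
        # gauge transform: shift couplings by row function, compensate fields
        e2 = fit.e.copy()
        h2 = fit.h.copy()
        phi = np.array([0.4, -0.2, 0.6])
        e2[0] += phi[:, None]          # pair (0,1): e_01(a,b) + phi(a)
        h2[0] -= phi
        di2 = dca.direct_information(
            dca.PottsModel(h=h2, e=e2), freqs)
        assert np.allclose(di1.di, di2.di, atol=1e-6)


# ---------------------------------------------------------------------------
# Contact ranking and I/O


class TestRankContacts:
    def _di(self, L, rng=None):
        d = np.zeros((L, L))
        if rng is not None:
            u = rng.uniform(size=(L, L))
            d = (u + u.T) / 2
            np.fill_diagonal(d, 0)
        return dca.DiMatrix(di=d)

    def test_top_2l_count(self, rng):
        ranked = dca.rank_contacts(self._di(10, rng), L=10, min_separation=1)
        assert len(ranked) == 20

    def test_unique_maximum_ranks_first(self):
        d = np.zeros((12, 12))
        d[3, 9] = d[9, 3] = 5.0
        ranked = dca.rank_contacts(dca.DiMatrix(di=d), min_separation=2, k=5)
        assert ranked.pairs[0][:2] == (3, 9)

    def test_all_equal_scores_break_ties_lexicographically(self):
        d = np.ones((8, 8))
        np.fill_diagonal(d, 0)
        ranked = dca.rank_contacts(dca.DiMatrix(di=d), min_separation=5, k=3)
        assert ranked.indices() == [(0, 5), (0, 6), (0, 7)]

    def test_min_separation_respected(self, rng):
        ranked = dca.rank_contacts(self._di(10, rng), min_separation=4, k=10)
        assert all(j - i >= 4 for i, j in ranked.indices())

    def test_too_few_pairs_warns_and_returns_all(self, rng):
        with pytest.warns(UserWarning):
            ranked = dca.rank_contacts(self._di(5, rng), min_separation=3, k=10)
        assert len(ranked) == 3  # (0,3),(0,4),(1,4)


class TestContactIO:
    def test_round_trip_preserves_order_and_scores(self, tmp_path):
        cs = dca.ContactSet(pairs=[(1, 9, 1.5), (0, 7, 1.2)], min_separation=5)
        p = tmp_path / "c.rr"
        dca.write_contacts(cs, p)
        back = dca.read_contacts(p)
        assert back.indices() == cs.indices()
        assert [s for _, _, s in back.pairs] == pytest.approx([1.5, 1.2])

    def test_invalid_ordering_rejected(self, tmp_path):
        cs = dca.ContactSet(pairs=[(9, 1, 1.5)], min_separation=1)
        with pytest.raises(ValueError):
            dca.write_contacts(cs, tmp_path / "bad.rr")

    def test_empty_set_header_only(self, tmp_path):
        p = tmp_path / "empty.rr"
        dca.write_contacts(dca.ContactSet(pairs=[], min_separation=1), p)
        assert p.read_text().strip() == "PFRMAT RR"

    def test_model_save_load(self, tmp_path):
        m = M.Msa(["AC", "CA", "AA"])
        fit = dca.fit_plm(m, uniform_weights(m), q=2)
        path = tmp_path / "model.npz"
        fit.save(path)
        back = dca.PottsModel.load(path)
        assert np.array_equal(back.h, fit.h)
        assert np.array_equal(back.e, fit.e)
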