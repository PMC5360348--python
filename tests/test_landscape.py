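"""Distribution pairs, fitness landscape, selection strength, decomposition."""

import math

import numpy as np
import pytest

from linsel import (
    Lineage,
    attach_phenotypes,
    bin_sweep,
    decompose_response,
    division_selection_strength,
    enumerate_lineages,
    estimate_distributions,
    fitness_landscape,
    growth_rate,
    make_edges,
    select_bin_width,
    selection_strength,
)
from linsel.landscape import weighted_quantile

LN2 = math.log(2)


def iid_lineages(D, x, name="x"):
    """Fabricated lineage set from i.i.d. chronological draws of (D, x).

    Chronological weights are uniform; retrospective weights are the exact
    2^D tilt, as in the infinite-tree limit.
    """
    D = np.asarray(D)
    x = np.asarray(x, dtype=float)
    w_cl = np.ones(len(D)) / len(D)
    w_rs = w_cl * 2.0**D
    w_rs = w_rs / w_rs.sum()
    return [
        Lineage(str(i), (str(i),), int(D[i]), float(w_cl[i]), float(w_rs[i]),
                {name: float(x[i])})
        for i in range(len(D))
    ]


class TestBinWidth:
    def test_freedman_diaconis_hand_value(self):
        # values 1..8, uniform weights: IQR = 4, width = 2*4*8^(-1/3) = 4
        vals = np.arange(1, 9, dtype=float)
        w = np.ones(8)
        assert select_bin_width(vals, w) == pytest.approx(4.0)

    def test_degenerate_iqr_falls_back(self):
        vals = np.array([1.0] * 9 + [2.0])
        w = np.ones(10)
        # IQR = 0 but range > 0: range / ceil(sqrt(10)) = 1/4
        assert select_bin_width(vals, w) == pytest.approx(0.25)

    def test_all_equal_values_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            select_bin_width(np.ones(10), np.ones(10))

    def test_width_shrinks_with_duplicated_sample(self):
        vals = np.arange(1, 9, dtype=float)
        w1 = select_bin_width(vals, np.ones(8))
        w2 = select_bin_width(np.repeat(vals, 2), np.ones(16))
        assert w2 == pytest.approx(w1 * 2 ** (-1 / 3))

    def test_weighted_quantile_inverted_cdf(self):
        v = np.array([1.0, 2.0, 3.0])
        w = np.array([0.25, 0.25, 0.5])
        assert weighted_quantile(v, w, 0.25) == 1.0
        assert weighted_quantile(v, w, 0.5) == 2.0
        assert weighted_quantile(v, w, 0.75) == 3.0


class TestTwoTreeExample:
    """Hand-enumerable ensemble: tree A divides once (both leaves x=a), tree B not."""

    @pytest.fixture
    def analysis(self, two_tree_ensemble):
        lineages = enumerate_lineages(two_tree_ensemble)
        for lin in lineages:
            lin.phenotypes["x"] = 1.0 if lin.leaf_id.startswith("A") else 2.0
        edges = np.array([0.5, 1.5, 2.5])
        pair = estimate_distributions(lineages, "x", edges)
        lam = growth_rate(two_tree_ensemble)
        scape = fitness_landscape(pair, lam, two_tree_ensemble.tau)
        report = selection_strength(pair, scape, lineages)
        return pair, scape, report, lam

    def test_distributions(self, analysis):
        pair = analysis[0]
        assert pair.p_cl == pytest.approx([0.5, 0.5])
        assert pair.p_rs == pytest.approx([2 / 3, 1 / 3])

    def test_landscape_values(self, analysis):
        _, scape, _, lam = analysis
        assert lam == pytest.approx(math.log(1.5))
        assert scape.h == pytest.approx([LN2, 0.0])

    def test_selection_strength_values(self, analysis):
        report = analysis[2]
        assert report.S == pytest.approx(LN2 / 6)
        assert report.S_D == pytest.approx(LN2 / 6)
        assert report.S_rel == pytest.approx(1.0)
        assert report.jeffreys_check < 1e-10


class TestDistributionPair:
    def test_equal_D_gives_equal_distributions(self, balanced_tree):
        lineages = enumerate_lineages(balanced_tree)
        for i, lin in enumerate(lineages):
            lin.phenotypes["x"] = float(i % 2)
        pair = estimate_distributions(lineages, "x", np.array([-0.5, 0.5, 1.5]))
        assert pair.p_cl == pytest.approx(pair.p_rs)

    def test_empty_bins_trimmed_and_reported(self):
        lins = iid_lineages([0, 0, 1, 1], [0.1, 0.1, 0.9, 0.9])
        edges = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
        pair = estimate_distributions(lins, "x", edges)
        assert len(pair.p_cl) == 2
        assert pair.excluded_mass_cl == 0.0  # empty bins carried no mass
        assert pair.p_cl.sum() == pytest.approx(1.0)
        assert pair.p_rs.sum() == pytest.approx(1.0)

    def test_out_of_support_mass_reported_and_escalated(self):
        """Values outside shared edges are trimmed; excess trimming raises."""
        rng = np.random.default_rng(0)
        D = np.array([0] * 50 + [8] * 2)
        x = np.concatenate([rng.uniform(0, 1, 50), [5.0, 5.1]])
        lins = iid_lineages(D, x)
        # the heavy-D lineages fall outside the edges: nearly all the
        # retrospective mass is trimmed away
        edges = np.array([0.0, 0.5, 1.0])
        with pytest.raises(ValueError, match="trim"):
            estimate_distributions(lins, "x", edges)
        pair = estimate_distributions(lins, "x", edges, allow_excess_trim=True)
        assert pair.p_cl.sum() == pytest.approx(1.0)
        assert pair.p_rs.sum() == pytest.approx(1.0)
        assert pair.excluded_mass_rs > 0.9
        assert 0 < pair.excluded_mass_cl < 0.1


class TestLandscape:
    def test_flat_when_distributions_match(self):
        lins = iid_lineages([1, 1, 1, 1], [0.1, 0.4, 0.6, 0.9])
        pair = estimate_distributions(lins, "x", np.array([0.0, 0.5, 1.0]))
        scape = fitness_landscape(pair, Lambda=0.7, tau=2.0)
        assert scape.h == pytest.approx([0.7, 0.7])

    def test_reconstruction_identity(self):
        """p_rs = exp(tau*(h - Lambda)) * p_cl exactly on the retained support."""
        rng = np.random.default_rng(5)
        D = rng.binomial(20, 0.1, 200)
        x = D + rng.standard_normal(200)
        lins = iid_lineages(D, x)
        edges = make_edges(x, 0.8)
        pair = estimate_distributions(lins, "x", edges, allow_excess_trim=True)
        scape = fitness_landscape(pair, Lambda=0.33, tau=1.7)
        rebuilt = np.exp(1.7 * (scape.h - 0.33)) * pair.p_cl
        assert rebuilt == pytest.approx(pair.p_rs, rel=1e-12)


class TestSelectionStrength:
    def test_zero_for_identical_distributions(self):
        lins = iid_lineages([2] * 6, [0.1, 0.2, 0.4, 0.6, 0.8, 0.9])
        pair = estimate_distributions(lins, "x", np.array([0.0, 0.5, 1.0]))
        scape = fitness_landscape(pair, 0.5, 1.0)
        rep = selection_strength(pair, scape, lins)
        assert rep.S == pytest.approx(0.0, abs=1e-15)
        assert rep.S_D == pytest.approx(0.0, abs=1e-15)

    def test_phenotype_equal_to_D_saturates_bound(self):
        rng = np.random.default_rng(11)
        D = rng.binomial(12, 0.3, 500)
        lins = iid_lineages(D, D.astype(float))
        edges = np.arange(D.max() + 2) - 0.5
        pair = estimate_distributions(lins, "x", edges)
        tau = 3.0
        scape = fitness_landscape(pair, 0.4, tau)
        rep = selection_strength(pair, scape, lins)
        assert rep.S == pytest.approx(rep.S_D, rel=1e-10)
        assert rep.S_rel == pytest.approx(1.0, rel=1e-10)
        # on integer bins the landscape *is* the lineage fitness up to Lambda
        d_vals = 0.5 * (pair.bin_lo + pair.bin_hi)
        assert scape.h - scape.h[0] == pytest.approx(d_vals * LN2 / tau - d_vals[0] * LN2 / tau)

    def test_jeffreys_identity_randomized(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            D = rng.binomial(15, rng.uniform(0.05, 0.3), 120)
            x = D + rng.uniform(0.5, 2.0) * rng.standard_normal(120)
            lins = iid_lineages(D, x)
            pair = estimate_distributions(
                lins, "x", make_edges(x, rng.uniform(0.5, 2.0)), allow_excess_trim=True
            )
            scape = fitness_landscape(pair, 0.1, 2.0)
            rep = selection_strength(pair, scape, lins)
            assert rep.jeffreys_check < 1e-10
            assert -1e-12 <= rep.S <= rep.S_D + 1e-12

    def test_relative_strength_tracks_squared_correlation(self):
        """Near-Gaussian joint: S_rel sits between (and near) the two corr^2."""
        rng = np.random.default_rng(3)
        m, T, p = 20000, 50, 0.05
        D = rng.binomial(T, p, size=m)
        x = D + 1.5 * rng.standard_normal(m)
        lins = iid_lineages(D, x)
        width = select_bin_width(x, np.full(m, 1 / m))
        pair = estimate_distributions(lins, "x", make_edges(x, width),
                                      allow_excess_trim=True)
        scape = fitness_landscape(pair, 0.6, 250 / 60)
        rep = selection_strength(pair, scape, lins)
        lo, hi = sorted([rep.corr2_cl, rep.corr2_rs])
        assert lo - 0.05 <= rep.S_rel <= hi + 0.05
        assert abs(rep.S_rel - 0.5 * (lo + hi)) < 0.1

    def test_division_selection_strength_matches_tilted_mean(self):
        # S[D] = (ln2/tau) * (E_rs[D] - E_cl[D]) with the empirical tilt
        D = np.array([0, 1, 1, 2, 3])
        lins = iid_lineages(D, D.astype(float))
        tau = 2.0
        w_cl = np.full(5, 0.2)
        w_rs = w_cl * 2.0**D / (w_cl * 2.0**D).sum()
        expected = (LN2 / tau) * ((w_rs * D).sum() - (w_cl * D).sum())
        assert division_selection_strength(lins, tau) == pytest.approx(expected)


class TestDecomposition:
    def _report(self, seed, shift=0.0):
        rng = np.random.default_rng(seed)
        D = rng.binomial(15, 0.15 + shift, 300)
        x = D + rng.standard_normal(300)
        lins = iid_lineages(D, x)
        pair = estimate_distributions(lins, "x", make_edges(x, 1.0),
                                      allow_excess_trim=True)
        scape = fitness_landscape(pair, 0.4 + shift, 2.0)
        return selection_strength(pair, scape, lins)

    def test_identical_environments_give_zero(self):
        r = self._report(1)
        d = decompose_response(r, r)
        assert d.delta_mean_h_rs == d.delta_mean_h_cl == d.delta_S == 0.0

    def test_identity_holds_exactly(self):
        d = decompose_response(self._report(1), self._report(2, shift=0.1))
        assert d.delta_mean_h_rs == pytest.approx(
            d.delta_mean_h_cl + d.delta_S, abs=1e-14
        )

    def test_phenotype_mismatch_rejected(self):
        r1, r2 = self._report(1), self._report(2)
        object.__setattr__(r2, "phenotype_name", "other")
        with pytest.raises(ValueError, match="mismatch"):
            decompose_response(r1, r2)


def test_bin_sweep_returns_tidy_table():
    rng = np.random.default_rng(8)
    D = rng.binomial(15, 0.2, 400)
    x = D + rng.standard_normal(400)
    lins = iid_lineages(D, x)
    df = bin_sweep(lins, "x", widths=[0.5, 1.0, 2.0], Lambda=0.5, tau=2.0)
    assert list(df.columns) == ["width", "n_bins", "S", "excluded_mass_cl",
                                "excluded_mass_rs"]
    assert (df.n_bins.diff().dropna() <= 0).all()  # wider bins, fewer of them
    assert (df.S >= 0).all()
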