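"""Reliable components: recovery, projections, explained summaries, pooling."""

import numpy as np
import pytest
from scipy import stats as sstats

import sweepvep as sv
from sweepvep.rca import RCAInput, RCAResults, ReliableComponents, TrialBlock


def component_cohort(rng, topo, n_participants=15, n_trials=20, noise=0.5, n_bins=10):
    """Single phase-locked component + independent sensor noise."""
    n_ch = topo.size
    base = rng.standard_normal(2 * n_bins) * 2.0
    blocks = []
    for pid in range(n_participants):
        scale = 1 + 0.1 * rng.standard_normal()
        for tr in range(n_trials):
            X = np.outer(base * scale, topo) + noise * rng.standard_normal((2 * n_bins, n_ch))
            blocks.append(TrialBlock(X=X, condition="c", participant=f"P{pid}", trial=tr))
    return RCAInput(blocks=blocks)


class TestFit:
    def test_recovers_planted_topography(self, montage128):
        rng = np.random.default_rng(42)
        topo = sv.default_ground_truth(
            sv.ConditionSpec(), montage128, sv.SweepProtocol.adult()
        ).components[2].topography
        inp = component_cohort(rng, topo)
        res = ReliableComponents(inp, n_components=3, rank=60).fit()
        r = abs(np.corrcoef(res.W[:, 0], topo)[0, 1])
        assert r > 0.95

    def test_rank1_noiseless_perfect_reliability(self):
        rng = np.random.default_rng(1)
        topo = rng.standard_normal(24)
        base = rng.standard_normal(20)
        blocks = [
            TrialBlock(X=np.outer(base, topo), condition="c", participant="P0", trial=t)
            for t in range(5)
        ]
        res = ReliableComponents(RCAInput(blocks=blocks), n_components=2, rank=10).fit()
        assert res.eigenvalues[0] == pytest.approx(1.0, abs=1e-9)
        assert res.rank == 1  # no second direction exists
        assert res.reliability_explained[0] == pytest.approx(1.0)
        assert res.variance_explained[0] == pytest.approx(1.0)

    def test_channel_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        topo = rng.standard_normal(16)
        inp = component_cohort(rng, topo, n_participants=4, n_trials=6)
        perm = rng.permutation(16)
        blocks_p = [
            TrialBlock(X=b.X[:, perm], condition=b.condition, participant=b.participant,
                       trial=b.trial)
            for b in inp.blocks
        ]
        res = ReliableComponents(inp, n_components=1, rank=16).fit()
        res_p = ReliableComponents(RCAInput(blocks=blocks_p), n_components=1, rank=16).fit()
        assert np.allclose(res_p.W[:, 0], res.W[perm, 0], atol=1e-8)

    def test_gevd_residual_small(self):
        rng = np.random.default_rng(4)
        inp = component_cohort(rng, rng.standard_normal(20), n_participants=5, n_trials=8)
        res = ReliableComponents(inp, n_components=3, rank=18).fit()
        assert res.gevd_residual() < 1e-8

    def test_single_trial_condition_rejected(self):
        X = np.random.default_rng(5).standard_normal((20, 8))
        with pytest.raises(ValueError):
            ReliableComponents(RCAInput(blocks=[TrialBlock(X=X, condition="c",
                                                           participant="P0", trial=0)]))

    def test_recovery_degrades_monotonically_with_noise(self):
        # isotonic trend: mean topography correlation is non-increasing in
        # sensor noise (Spearman trend over a sigma grid, 20 seeds each)
        sigmas = [0.2, 1.0, 4.0, 16.0]
        topo_rng = np.random.default_rng(7)
        topo = topo_rng.standard_normal(16)
        means = []
        for sig in sigmas:
            rs = []
            for seed in range(20):
                rng = np.random.default_rng(1000 + seed)
                inp = component_cohort(rng, topo, n_participants=4, n_trials=5, noise=sig)
                res = ReliableComponents(inp, n_components=1, rank=16).fit()
                rs.append(abs(np.corrcoef(res.W[:, 0], topo)[0, 1]))
            means.append(np.mean(rs))
        rho, _ = sstats.spearmanr(sigmas, means)
        assert rho < 0
        assert means[0] > means[-1]


class TestProjection:
    def _selector_results(self, n_ch=8, col=2):
        W = np.zeros((n_ch, 1))
        W[col, 0] = 1.0
        eye = np.eye(n_ch)
        return RCAResults(
            model=None, W=W, A=W.copy(), eigenvalues=np.ones(1), W_full=W,
            A_forward_full=W.copy(), subspace=eye[:, :1], rank=1,
            reliability_explained=np.ones(1), variance_explained=np.ones(1),
            rxy=eye, rpool=eye,
        )

    def test_unit_weight_selects_channel(self):
        res = self._selector_results(col=2)
        rng = np.random.default_rng(0)
        coefs = rng.standard_normal((10, 8)) + 1j * rng.standard_normal((10, 8))
        out = res.project(coefs)
        assert np.allclose(out, coefs[:, 2])

    def test_rank1_projection_proportional_to_series(self, montage32):
        rng = np.random.default_rng(1)
        topo = rng.standard_normal(32)
        series = rng.standard_normal(40)
        blocks = [
            TrialBlock(X=np.outer(series, topo), condition="c", participant="P0", trial=t)
            for t in range(3)
        ]
        res = ReliableComponents(RCAInput(blocks=blocks), n_components=1, rank=8).fit()
        proj = res.project(np.outer(series, topo))
        r = abs(np.corrcoef(proj, series)[0, 1])
        assert r > 0.999

    def test_dimension_mismatch_raises(self):
        res = self._selector_results()
        with pytest.raises(ValueError):
            res.project(np.zeros((5, 9)))

    def test_sidebands_share_signal_weights(self, montage32):
        # the projection is one linear map: projecting signal and sideband
        # coefficient arrays uses the identical weight column
        res = self._selector_results(n_ch=32, col=5)
        sig = np.random.default_rng(2).standard_normal((10, 32))
        sb = np.random.default_rng(3).standard_normal((10, 32))
        assert np.allclose(res.project(sig), sig[:, 5])
        assert np.allclose(res.project(sb), sb[:, 5])


class TestExplained:
    def test_two_orthogonal_components_variance_ratio(self):
        rng = np.random.default_rng(11)
        n_ch, n_rows = 24, 40
        t1 = rng.standard_normal(n_ch)
        t1 /= np.linalg.norm(t1)
        t2 = rng.standard_normal(n_ch)
        t2 -= t1 * (t1 @ t2)
        t2 /= np.linalg.norm(t2)
        s1 = rng.standard_normal(n_rows)
        s2 = rng.standard_normal(n_rows)
        s2 -= s1 * (s1 @ s2) / (s1 @ s1)  # sample-orthogonal series
        s1 *= np.sqrt(3.0) / s1.std()
        s2 *= 1.0 / s2.std()
        blocks = [
            TrialBlock(X=np.outer(s1, t1) + np.outer(s2, t2), condition="c",
                       participant="P0", trial=t)
            for t in range(4)
        ]
        res = ReliableComponents(RCAInput(blocks=blocks), n_components=2, rank=8).fit()
        # both components are perfectly reliable (rho = 1) so their order is
        # arbitrary; the variance split must still be 3:1
        hi, lo = np.sort(res.variance_explained[:2])[::-1]
        assert hi / lo == pytest.approx(3.0, rel=0.05)

    def test_reliability_fractions_sum_at_most_one(self):
        rng = np.random.default_rng(12)
        inp = component_cohort(rng, rng.standard_normal(16), n_participants=4, n_trials=5)
        res = ReliableComponents(inp, n_components=3, rank=16).fit()
        assert res.reliability_explained[: res.n_components].sum() <= 1.0 + 1e-12
        assert np.all(res.reliability_explained >= 0)


class TestPooling:
    def _ds(self, participants, cond="c", session=0, harmonic=2):
        rng = np.random.default_rng(hash(tuple(participants)) % 2**31)
        blocks = [
            TrialBlock(X=rng.standard_normal((4, 6)), condition=cond,
                       participant=p, trial=t, session=session)
            for p in participants
            for t in range(2)
        ]
        return RCAInput(blocks=blocks, harmonic=harmonic)

    def test_duplicate_participant_keeps_first_session(self):
        d1 = self._ds(["A", "B"], session=0)
        d2 = self._ds(["B", "C"], session=1)
        pooled = sv.pool_participants([d1, d2])
        assert pooled.participants() == {"A", "B", "C"}
        b_blocks = [b for b in pooled.blocks if b.participant == "B"]
        assert all(b.session == 0 for b in b_blocks)

    def test_disjoint_participants_concatenate(self):
        d1 = self._ds(["A", "B"])
        d2 = self._ds(["C", "D"])
        pooled = sv.pool_participants([d1, d2])
        assert len(pooled.blocks) == len(d1.blocks) + len(d2.blocks)

    def test_pooled_count_matches_set_union(self):
        # meta-analysis fixture: four experiments with overlapping cohorts
        sets = [["A", "B", "C"], ["B", "D"], ["C", "E", "F"], ["A", "F", "G"]]
        datasets = [self._ds(s, session=i) for i, s in enumerate(sets)]
        pooled = sv.pool_participants(datasets)
        brute = set().union(*sets)
        assert pooled.participants() == brute
        # one session per participant
        per_part = {}
        for b in pooled.blocks:
            per_part.setdefault(b.participant, set()).add(b.session)
        assert all(len(s) == 1 for s in per_part.values())
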