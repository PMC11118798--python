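import numpy as np
import pytest
from conftest import make_net

from sapm import synth
from sapm.model import (
    LatentSignal,
    SAPMFit,
    StabilityError,
    derived_D,
    fit_null_reference,
    fit_sapm,
    forward_model,
    select_subregions,
    signal_decomposition,
)
from sapm.synth import PAIN, GroundTruth, build_paradigm, generate_participant


def standardized(rng, n):
    x = rng.standard_normal(n)
    x = x - x.mean()
    return x / x.std()


class TestForwardModel:
    def test_decoupled_limit(self, chain3_net, rng):
        L = standardized(rng, 40)
        db = {("a", "b"): 0.0, ("b", "c"): 0.0, ("int1", "a"): 1.0}
        out = forward_model(chain3_net, db, [("int1", L)])
        assert np.allclose(out[0], L)
        assert np.all(out[1:] == 0)

    def test_two_region_chain(self, two_region_net, rng):
        L = standardized(rng, 40)
        db = {("a", "b"): 0.5, ("int1", "a"): 1.0}
        out = forward_model(two_region_net, db, [("int1", L)])
        assert np.allclose(out[1], 0.5 * L)

    def test_two_cycle_geometric_series(self, rng):
        # closed form: O_a = L / (1 - 0.2), O_b = 0.4 L / (1 - 0.2)
        net = make_net(["a", "b"], [("a", "b"), ("b", "a")], [("int1", ["a"])])
        L = standardized(rng, 40)
        db = {("a", "b"): 0.4, ("b", "a"): 0.5, ("int1", "a"): 1.0}
        out = forward_model(net, db, [("int1", L)])
        assert np.allclose(out[0], L / 0.8)
        assert np.allclose(out[1], 0.4 * L / 0.8)

    def test_unstable_raises_with_radius(self, rng):
        net = make_net(["a", "b"], [("a", "b"), ("b", "a")], [("int1", ["a"])])
        db = {("a", "b"): 1.1, ("b", "a"): 1.0, ("int1", "a"): 1.0}
        with pytest.raises(StabilityError, match=r"radius 1\.0"):
            forward_model(net, db, [("int1", standardized(rng, 40))])

    def test_scale_identifiability(self, chain3_net, rng):
        L = standardized(rng, 40)
        db = {("a", "b"): 0.5, ("b", "c"): -0.3, ("int1", "a"): 0.8}
        out1 = forward_model(chain3_net, db, [("int1", L)])
        c = 2.5
        db2 = dict(db)
        db2[("int1", "a")] = 0.8 / c
        out2 = forward_model(chain3_net, db2, [("int1", c * L)])
        assert np.allclose(out1, out2)

    def test_excitatory_semantics(self, two_region_net, rng):
        L = standardized(rng, 60)
        covs = []
        for w in (0.2, 0.5, 0.8):
            out = forward_model(
                two_region_net, {("a", "b"): w, ("int1", "a"): 1.0}, [("int1", L)]
            )
            covs.append(np.cov(out[0], out[1])[0, 1])
        assert covs[0] < covs[1] < covs[2]


class TestFitSapm:
    def test_noiseless_self_consistency(self, chain3_net):
        p = build_paradigm(PAIN)
        db = {("a", "b"): 0.5, ("b", "c"): -0.3, ("int1", "a"): 1.0}
        L = synth.paradigm_latents(p, 1)
        obs = forward_model(chain3_net, db, [("int1", L[0])])
        fit = fit_sapm(obs, chain3_net, latents_init=L, n_restarts=1)
        for k, v in db.items():
            assert fit.db[k] == pytest.approx(v, abs=1e-6)
        assert fit.r2_total > 1 - 1e-9

    def test_grid_oracle_two_region(self, two_region_net, rng):
        p = build_paradigm(PAIN)
        L = synth.paradigm_latents(p, 1)[0]
        true_w = 0.43
        obs_a = L + 0.1 * rng.standard_normal(40)
        obs_b = true_w * obs_a + 0.1 * rng.standard_normal(40)
        obs = np.vstack([obs_a, obs_b])
        obs = obs - obs.mean(axis=1, keepdims=True)
        # brute-force SSE grid: region a is latent-absorbed, so total SSE
        # is minimized over the single edge weight
        grid = np.arange(-1.0, 1.0 + 1e-12, 1e-3)
        sse = ((obs[1][None, :] - grid[:, None] * obs[0][None, :]) ** 2).sum(axis=1)
        w_star = grid[np.argmin(sse)]
        fit = fit_sapm(obs, two_region_net, seed=0)
        assert fit.db[("a", "b")] == pytest.approx(w_star, abs=1e-3)
        assert fit.sse <= sse.min() + 1e-9

    def test_monotone_sse(self, default_net):
        gt = synth.table2_ground_truth("FM", PAIN, net=default_net)
        ds = generate_participant(
            default_net, gt, build_paradigm(PAIN), noise_sd=0.1, seed=5
        )
        fit = fit_sapm(ds.region_series(PAIN), default_net, n_restarts=1, seed=1)
        hist = np.array(fit.sse_history)
        assert np.all(np.diff(hist) <= 1e-9)

    def test_determinism(self, default_net):
        gt = synth.table2_ground_truth("FM", PAIN, net=default_net)
        ds = generate_participant(
            default_net, gt, build_paradigm(PAIN), noise_sd=0.1, seed=6
        )
        obs = ds.region_series(PAIN)
        f1 = fit_sapm(obs, default_net, seed=3)
        f2 = fit_sapm(obs, default_net, seed=3)
        assert f1.db == f2.db

    def test_latent_sign_convention(self, chain3_net, rng):
        p = build_paradigm(PAIN)
        db = {("a", "b"): 0.5, ("b", "c"): -0.3, ("int1", "a"): 1.0}
        L = synth.paradigm_latents(p, 1)
        obs = forward_model(chain3_net, db, [("int1", L[0])])
        obs = obs + 0.01 * rng.standard_normal(obs.shape)
        fit = fit_sapm(obs, chain3_net, seed=0)
        assert fit.db[("int1", "a")] >= 0

    def test_input_validation(self, chain3_net):
        with pytest.raises(ValueError, match="non-finite"):
            fit_sapm(np.full((3, 40), np.nan), chain3_net)
        with pytest.raises(ValueError, match="volumes"):
            fit_sapm(np.zeros((3, 5)), chain3_net)
        with pytest.raises(ValueError):
            fit_sapm(np.zeros((2, 40)), chain3_net)

    def test_save_load_round_trip(self, chain3_net, tmp_path):
        p = build_paradigm(PAIN)
        db = {("a", "b"): 0.5, ("b", "c"): -0.3, ("int1", "a"): 1.0}
        L = synth.paradigm_latents(p, 1)
        obs = forward_model(chain3_net, db, [("int1", L[0])])
        fit = fit_sapm(obs, chain3_net, seed=0)
        path = fit.save(tmp_path / "fit.json")
        loaded = SAPMFit.load(path)
        assert loaded.db == fit.db
        assert loaded.subregion_choice == fit.subregion_choice
        assert np.allclose(loaded.latents[0].series, fit.latents[0].series)


class TestParameterRecovery:
    @pytest.mark.parametrize(
        "group,cond,key,target",
        [
            ("FM", synth.PAIN, ("PBN", "Thalamus"), 0.166),
            ("FM", synth.NO_PAIN, ("LC", "DRt"), -0.438),
            ("FM", synth.PAIN, ("LC", "Thalamus"), 0.286),
            ("HC", synth.PAIN, ("LC", "Thalamus"), 0.528),
        ],
    )
    def test_group_mean_recovery(self, default_net, group, cond, key, target):
        gt = synth.table2_ground_truth(group, cond, net=default_net)
        p = build_paradigm(cond)
        means = []
        for s in range(6):
            ests = []
            for i in range(15):
                seed = synth.stage_seed(s, f"rec:{cond}", i)
                rng = np.random.default_rng(seed)
                db = synth._draw_db(default_net, gt, rng)
                ds = generate_participant(
                    default_net, gt, p, noise_sd=0.1, seed=seed + 1, db=db
                )
                fit = fit_sapm(
                    ds.region_series(cond), default_net, seed=seed + 2, n_restarts=2
                )
                ests.append(fit.db[key])
            means.append(np.mean(ests))
        assert np.mean(means) == pytest.approx(target, abs=0.05)
        # sign recovery per seed
        assert np.mean(np.sign(means) == np.sign(target)) >= 0.95


class TestSelectSubregions:
    def _candidates(self, net, signal_idx, noise_sd, seed):
        p = build_paradigm(PAIN)
        db = {("a", "b"): 0.6, ("b", "c"): -0.4, ("int1", "a"): 1.0}
        ds = generate_participant(
            net,
            GroundTruth(db_mean=dict(db)),
            p,
            noise_sd=noise_sd,
            seed=seed,
            db=db,
            signal_subregion={r: signal_idx for r in net.region_abbrevs},
        )
        return ds.data[PAIN]

    def test_exhaustive_recovers_signal_subregion(self, chain3_net):
        cube = self._candidates(chain3_net, 2, 0.05, 31)
        fit = select_subregions(cube, chain3_net, method="auto", fit_opts={"n_restarts": 2})
        assert fit.subregion_choice == {"a": 2, "b": 2, "c": 2}

    def test_greedy_matches_exhaustive(self, chain3_net):
        cube = self._candidates(chain3_net, 4, 0.05, 32)
        ex = select_subregions(cube, chain3_net, method="exhaustive", fit_opts={"n_restarts": 2})
        gr = select_subregions(cube, chain3_net, method="greedy", fit_opts={"n_restarts": 2})
        assert gr.subregion_choice == ex.subregion_choice
        assert gr.mean_region_r2 == pytest.approx(ex.mean_region_r2, abs=1e-9)

    def test_identical_candidates_lowest_index(self, chain3_net, rng):
        base = self._candidates(chain3_net, 1, 0.0, 33)
        cube = np.repeat(base[:, :1, :], 5, axis=1)
        fit = select_subregions(cube, chain3_net, method="exhaustive", fit_opts={"n_restarts": 1})
        assert fit.subregion_choice == {"a": 1, "b": 1, "c": 1}

    def test_greedy_at_least_baseline(self, chain3_net):
        cube = self._candidates(chain3_net, 3, 0.2, 34)
        gr = select_subregions(cube, chain3_net, method="greedy", fit_opts={"n_restarts": 2})
        baseline = fit_sapm(
            np.array([cube[r, 0] for r in range(3)]), chain3_net, n_restarts=2,
            seed=synth.stage_seed(0, "subregion-fit"),
        )
        assert gr.mean_region_r2 >= baseline.mean_region_r2 - 1e-12


class TestNullReference:
    def test_requires_two_samples(self, chain3_net):
        with pytest.raises(ValueError):
            fit_null_reference(np.zeros((3, 40)), chain3_net, n_null=1)

    def test_deterministic(self, chain3_net):
        p = build_paradigm(PAIN)
        db = {("a", "b"): 0.5, ("b", "c"): -0.3, ("int1", "a"): 1.0}
        ds = generate_participant(
            chain3_net, GroundTruth(db_mean=dict(db)), p, noise_sd=0.1, seed=2, db=db
        )
        obs = ds.region_series(PAIN)
        n1 = fit_null_reference(obs, chain3_net, n_null=3, seed=5)
        n2 = fit_null_reference(obs, chain3_net, n_null=3, seed=5)
        for k in n1.mean:
            assert n1.mean[k] == n2.mean[k]

    def test_null_means_near_zero(self, chain3_net):
        p = build_paradigm(PAIN)
        db = {("a", "b"): 0.5, ("b", "c"): -0.3, ("int1", "a"): 1.0}
        ds = generate_participant(
            chain3_net, GroundTruth(db_mean=dict(db)), p, noise_sd=0.1, seed=7, db=db
        )
        ref = fit_null_reference(
            ds.region_series(PAIN), chain3_net, n_null=25, seed=11,
            fit_opts={"n_restarts": 2},
        )
        for k in [("a", "b"), ("b", "c")]:
            se = ref.sd[k] / np.sqrt(25)
            assert abs(ref.mean[k]) < 2 * se + 1e-12


class TestDerivedD:
    def test_single_target_share(self, two_region_net):
        fit = _toy_fit(two_region_net, {("a", "b"): 0.7, ("int1", "a"): 1.0})
        d = derived_D(fit, two_region_net)
        assert d.shares[("a", "b")] == 1.0

    def test_arithmetic_shares(self):
        net = make_net(["a", "b", "c"], [("a", "b"), ("a", "c")], [("int1", ["a"])])
        fit = _toy_fit(net, {("a", "b"): 0.3, ("a", "c"): 0.1, ("int1", "a"): 1.0})
        d = derived_D(fit, net)
        assert d.shares[("a", "b")] == pytest.approx(0.75)
        assert d.shares[("a", "c")] == pytest.approx(0.25)

    def test_zero_weights_uniform(self):
        net = make_net(["a", "b", "c"], [("a", "b"), ("a", "c")], [("int1", ["a"])])
        fit = _toy_fit(net, {("a", "b"): 0.0, ("a", "c"): 0.0, ("int1", "a"): 1.0})
        d = derived_D(fit, net)
        assert d.shares[("a", "b")] == pytest.approx(0.5)

    def test_shares_sum_to_one_default_net(self, default_net):
        gt = synth.table2_ground_truth("FM", PAIN, net=default_net)
        ds = generate_participant(
            default_net, gt, build_paradigm(PAIN), noise_sd=0.1, seed=13
        )
        fit = fit_sapm(ds.region_series(PAIN), default_net, n_restarts=2, seed=0)
        d = derived_D(fit, default_net)
        for r in default_net.region_abbrevs:
            targets = default_net.targets_of(r)
            if targets:
                total = sum(d.shares[(r, t)] for t in targets)
                assert total == pytest.approx(1.0, abs=1e-9)


class TestSignalDecomposition:
    def test_contributions_sum_to_total(self, default_net):
        gt = synth.table2_ground_truth("FM", PAIN, net=default_net)
        ds = generate_participant(
            default_net, gt, build_paradigm(PAIN), noise_sd=0.1, seed=17
        )
        fit = fit_sapm(ds.region_series(PAIN), default_net, n_restarts=2, seed=0)
        dec = signal_decomposition(fit, default_net, "LC")
        total = sum(dec["contributions"].values())
        assert np.allclose(total, dec["total_input"], atol=1e-12)

    def test_lc_sources_listed(self, default_net):
        gt = synth.table2_ground_truth("FM", PAIN, net=default_net)
        ds = generate_participant(
            default_net, gt, build_paradigm(PAIN), noise_sd=0.1, seed=18
        )
        fit = fit_sapm(ds.region_series(PAIN), default_net, n_restarts=2, seed=0)
        dec = signal_decomposition(fit, default_net, "LC")
        assert {"PAG", "PBN", "Hypothalamus", "int2"} <= set(dec["contributions"])

    def test_latent_only_region(self, rng):
        net = make_net(["a", "b"], [("a", "b")], [("int1", ["a"])])
        fit = _toy_fit(net, {("a", "b"): 0.5, ("int1", "a"): 1.0})
        dec = signal_decomposition(fit, net, "a")
        assert list(dec["contributions"]) == ["int1"]
        assert np.allclose(dec["contributions"]["int1"], dec["total_input"])
        assert np.allclose(dec["total_input"], dec["output"])

    def test_unknown_region(self, two_region_net):
        fit = _toy_fit(two_region_net, {("a", "b"): 0.5, ("int1", "a"): 1.0})
        with pytest.raises(KeyError):
            signal_decomposition(fit, two_region_net, "zzz")


def _toy_fit(net, db):
    rng = np.random.default_rng(0)
    L = rng.standard_normal(40)
    L = (L - L.mean()) / L.std()
    latents = [LatentSignal(l.name, L) for l in net.latents]
    return SAPMFit(
        db=dict(db),
        latents=latents,
        subregion_choice={r: 1 for r in net.region_abbrevs},
        r2_total=1.0,
        r2_by_region={r: 1.0 for r in net.region_abbrevs},
        sse=0.0,
        n_iter=1,
        converged=True,
    )
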