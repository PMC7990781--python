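import numpy as np
import pytest

from flornet.data_model import ConditionKey
from flornet.nn_models import (
    INPUT_GENES,
    OUTPUT_GENES,
    build_training_pairs,
    evaluation_pairs,
    expand_dataset,
    load_ensemble,
    protocol_conditions,
    rollout,
    save_ensemble,
    split_train_test,
    train_regressor,
)

WT_LD = ConditionKey("WT", "LD")


@pytest.fixture(scope="module")
def expanded(pheno_dataset):
    return expand_dataset(pheno_dataset, n_samples=100, seed=0)


def test_expand_counts_and_moments(pheno_dataset):
    exp = expand_dataset(pheno_dataset, n_samples=1000, seed=1)
    for key, (times, samples) in exp.entries.items():
        assert samples.shape == (times.size, 1000)
    # empirical mean within 3 standard errors of the record mean
    key = ("PIM", "apex", "WT", "LD")
    times, samples = exp.entries[key]
    sub = pheno_dataset.frame.query(
        "gene=='PIM' and genotype=='WT' and photoperiod=='LD'").sort_values("time")
    for k, (m, sd) in enumerate(zip(sub["mean"], sub["sd"])):
        if sd == 0:
            assert np.all(samples[k] == m)
        else:
            assert abs(samples[k].mean() - m) <= 3 * sd / np.sqrt(1000)


def test_expand_zero_sd_gives_copies(tiny_dataset):
    frame = tiny_dataset.frame.assign(sd=0.0)
    from flornet.data_model import ExpressionDataset
    exp = expand_dataset(ExpressionDataset(frame), n_samples=50, seed=0)
    _, samples = exp.entries[("DET", "apex", "WT", "LD")]
    assert np.all(samples == np.array([[2.0], [4.0], [8.0]]))


def test_expand_deterministic(pheno_dataset):
    a = expand_dataset(pheno_dataset, n_samples=20, seed=5)
    b = expand_dataset(pheno_dataset, n_samples=20, seed=5)
    for key in a.entries:
        assert np.array_equal(a.entries[key][1], b.entries[key][1])


def test_training_pairs_shapes(expanded):
    X, Y = build_training_pairs(expanded, [WT_LD])
    times = expanded.times(WT_LD)
    assert X.shape == ((times.size - 1) * expanded.n_samples, len(INPUT_GENES))
    assert Y.shape == (X.shape[0], len(OUTPUT_GENES))


def test_pairs_do_not_cross_conditions(expanded):
    X_all, _ = build_training_pairs(expanded)
    per_cond = 0
    for c in expanded.conditions():
        Xc, _ = build_training_pairs(expanded, [c])
        per_cond += Xc.shape[0]
    assert X_all.shape[0] == per_cond  # no extra cross-boundary pairs


def test_veg1_not_in_panel():
    assert "VEG1" not in INPUT_GENES and "VEG1" not in OUTPUT_GENES
    assert "FTb2" in INPUT_GENES and "FTb2" not in OUTPUT_GENES


def test_split_nn_sddata_counts(expanded):
    train, test = split_train_test(expanded, "NN_SDdata")
    # exactly one held-out time point per SD condition
    for c in protocol_conditions("NN_SDdata"):
        all_times = expanded.times(c)
        assert test.times(c).tolist() == [all_times[-1]]
        assert train.times(c).tolist() == all_times[:-1].tolist()


def test_split_nn_lddata_holds_out_late1(expanded):
    train, test = split_train_test(expanded, "NN_LDdata")
    train_genotypes = {k[2] for k in train.entries}
    assert "late1-2" not in train_genotypes
    assert {k[2] for k in test.entries} == {"late1-2"}


def test_split_partition(expanded):
    train, test = split_train_test(expanded, "NN")
    for key, (times, _) in expanded.entries.items():
        if key[0] == "VEG1":
            continue
        tr = train.entries.get(key, (np.array([]), None))[0]
        te = test.entries.get(key, (np.array([]), None))[0]
        assert sorted(np.concatenate([tr, te]).tolist()) == times.tolist()
        assert not set(tr) & set(te)


def test_evaluation_pairs_target_last_days(expanded):
    X, Y = evaluation_pairs(expanded, "NN_SDdata")
    n_cond = len(protocol_conditions("NN_SDdata"))
    assert X.shape[0] == n_cond * expanded.n_samples


def _identity_pairs(n=600, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.uniform(0, 4, size=(n, len(INPUT_GENES)))
    Y = np.zeros((n, len(OUTPUT_GENES)))
    Y[:, 0] = X[:, 0]  # DET passes through; all other targets 0
    return X, Y


def test_regressor_learns_identity_map():
    X, Y = _identity_pairs()
    ens = train_regressor((X, Y), topology=(16,), n_members=2, seed=0, max_iter=800)
    rng = np.random.default_rng(1)
    X_new = rng.uniform(0, 4, size=(200, len(INPUT_GENES)))
    pred = ens.predict(X_new)
    ss_res = np.sum((pred[:, 0] - X_new[:, 0]) ** 2)
    ss_tot = np.sum((X_new[:, 0] - X_new[:, 0].mean()) ** 2)
    assert 1 - ss_res / ss_tot > 0.95


def test_regressor_constant_targets():
    rng = np.random.default_rng(2)
    X = rng.uniform(0, 4, size=(400, len(INPUT_GENES)))
    Y = np.full((400, len(OUTPUT_GENES)), 2.0)
    ens = train_regressor((X, Y), topology=(8,), n_members=1, seed=0, max_iter=600)
    pred = ens.predict(X[:50])
    assert np.allclose(pred, 2.0, atol=0.1)


def test_regressor_deterministic():
    X, Y = _identity_pairs(n=300)
    a = train_regressor((X, Y), topology=(8,), n_members=2, seed=4, max_iter=200)
    b = train_regressor((X, Y), topology=(8,), n_members=2, seed=4, max_iter=200)
    assert a.cv_scores == b.cv_scores


def test_save_load_round_trip(tmp_path):
    X, Y = _identity_pairs(n=300)
    ens = train_regressor((X, Y), topology=(8,), n_members=2, seed=0, max_iter=200)
    path = tmp_path / "model.json"
    save_ensemble(ens, path)
    again = load_ensemble(path)
    Xp = X[:20]
    assert np.allclose(ens.predict(Xp), again.predict(Xp), rtol=1e-10)
    assert again.cv_scores == ens.cv_scores


def test_rollout_single_step_equals_prediction():
    X, Y = _identity_pairs(n=300)
    ens = train_regressor((X, Y), topology=(8,), n_members=2, seed=0, max_iter=200)
    init = np.full(len(OUTPUT_GENES), 1.5)
    ftb2 = np.array([0.5, 0.5])
    mean, members = rollout(ens, init, ftb2, times=[7.0, 14.0])
    per_member = ens.predict_members(np.append(init, ftb2[0])[None, :])[:, 0, :]
    direct = np.clip(per_member, 0.0, None).mean(axis=0)
    assert np.allclose(mean[1], direct)
    # ensemble mean lies within the member envelope
    assert np.all(mean[1] >= members[:, 1, :].min(axis=0) - 1e-12)
    assert np.all(mean[1] <= members[:, 1, :].max(axis=0) + 1e-12)


def test_rollout_tracks_linear_system():
    """One-step pairs from a contracting linear system: the learned rollout
    stays close to the analytic trajectory over 5 steps."""
    rng = np.random.default_rng(8)
    n_out, n_in = len(OUTPUT_GENES), len(INPUT_GENES)
    A = 0.6 * np.eye(n_out, n_in)  # x' = 0.6 x (FTb2 column unused)
    X = rng.uniform(0.5, 3, size=(3000, n_in))
    Y = X @ A.T + 0.5
    ens = train_regressor((X, Y), topology=(16,), n_members=2, seed=0, max_iter=800)
    x0 = np.full(n_out, 2.0)
    times = 7.0 * np.arange(1, 7)
    mean, _ = rollout(ens, x0, np.full(times.size, 1.0), times)
    truth = np.empty((times.size, n_out))
    truth[0] = x0
    for k in range(times.size - 1):
        truth[k + 1] = 0.6 * truth[k] + 0.5
    rng_range = truth.max() - truth.min()
    nrmse = np.sqrt(np.mean((mean - truth) ** 2)) / rng_range
    assert nrmse < 0.1
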