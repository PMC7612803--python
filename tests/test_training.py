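"""Target construction and the training regimes (end-to-end, sequential,
leapfrog): degeneracies, freezing contracts and the activation ledger."""

import numpy as np
import pytest

import fbsempet as fp
from fbsempet import autodiff as ad
from fbsempet.fbsem_net import FBSEMConfig, ModuleChain
from fbsempet.training import (TrainingConfig, build_iteration_targets,
                               train_end_to_end, train_leapfrog,
                               train_sequential)


@pytest.fixture()
def micro_dataset(small_setup, small_system, counts_small):
    """2/1/1 dataset with 12-module targets (fast training tests)."""
    proj = small_setup[2]
    cl, ch = counts_small
    ds = fp.build_dataset(2, 1, 1, small_system, count_low=cl, count_high=ch,
                          seed=3, geo_projector=proj)
    for s in ds["train"] + ds["val"]:
        build_iteration_targets(s, n_iters=2, n_subsets=6)
    return ds


@pytest.fixture()
def dataset_1sub(small_setup, counts_small):
    grid, geom, proj, psf, norm = small_setup
    cl, ch = counts_small
    sys1 = fp.assemble_system(proj, psf, np.ones(geom.n_bins), norm, 1, grid, geom)
    ds = fp.build_dataset(6, 2, 2, sys1, seed=1, count_low=cl, count_high=ch,
                          geo_projector=proj)
    for s in ds["train"]:
        build_iteration_targets(s, n_iters=1, n_subsets=1)
    return ds


class TestTargets:
    def test_length_matches_module_count(self, tiny_dataset):
        assert len(tiny_dataset["train"][0].targets) == 12

    def test_first_target_is_first_em_update(self, micro_dataset):
        s = micro_dataset["train"][0]
        y_nf = s.high.ybar * (s.scale_low / s.scale_high)
        first = fp.em_update(np.ones(s.sys.n_voxels), y_nf, s.sys, 0)
        np.testing.assert_allclose(s.targets.images[0], first, rtol=1e-12)

    def test_deterministic(self, micro_dataset):
        s = micro_dataset["train"][0]
        t2 = build_iteration_targets(s, n_iters=2, n_subsets=6)
        for a, b in zip(s.targets.images, t2.images):
            np.testing.assert_array_equal(a, b)

    def test_targets_nonnegative(self, tiny_dataset):
        for img in tiny_dataset["train"][0].targets.images:
            assert np.all(img >= 0)


class TestRegimeDegeneracy:
    def test_one_module_sequential_equals_end_to_end(self, dataset_1sub):
        """All regimes coincide for a 1-module chain under a fixed seed."""
        cfg = FBSEMConfig(n_iters=1, n_subsets=1, n_channels=4)
        results = []
        for regime in ("sequential_IS", "end_to_end_final", "end_to_end_IS"):
            chain = ModuleChain(cfg, seed=42)
            tc = TrainingConfig(lr=0.01, epochs=1, batch_size=5, regime=regime,
                                seed=9, epochs_per_module=1)
            if regime == "sequential_IS":
                chain, _ = train_sequential(dataset_1sub["train"], chain, tc)
            else:
                chain, _ = train_end_to_end(dataset_1sub["train"], chain, tc)
            results.append(chain.state_dict())
        ref = results[0]
        for other in results[1:]:
            assert all(np.array_equal(ref[k], other[k]) for k in ref)

    def test_zero_lr_leaves_parameters_unchanged(self, micro_dataset):
        cfg = FBSEMConfig(n_iters=2, n_subsets=6, n_channels=4)
        chain = ModuleChain(cfg, seed=1)
        before = chain.state_dict()
        tc = TrainingConfig(lr=0.0, epochs=1, batch_size=2,
                            regime="sequential_IS", seed=0, epochs_per_module=1)
        chain, _ = train_sequential(micro_dataset["train"], chain, tc)
        after = chain.state_dict()
        for k in before:
            if "running" in k:        # BN statistics still update
                continue
            assert np.array_equal(before[k], after[k]), k


class TestSequential:
    def test_frozen_prefix_untouched_bit_for_bit(self, micro_dataset):
        cfg = FBSEMConfig(n_iters=1, n_subsets=6, n_channels=4)
        chain = ModuleChain(cfg, seed=2)
        tc = TrainingConfig(lr=0.01, epochs=1, batch_size=2,
                            regime="sequential_IS", seed=0, epochs_per_module=1)
        # capture module 0 parameters after its own training by re-running
        # with a hook: train fully, then retrain a fresh chain for 1 module
        import copy
        chain_full = ModuleChain(cfg, seed=2)
        chain_full, _ = train_sequential(micro_dataset["train"], chain_full, tc)
        # training modules 1..5 must not have altered module 0:
        chain_prefix = ModuleChain(FBSEMConfig(n_iters=1, n_subsets=6,
                                               n_channels=4), seed=2)
        # a 6-module chain truncated after module 0's training equals
        # training just that module with the same seeds
        tc1 = TrainingConfig(lr=0.01, epochs=1, batch_size=2,
                             regime="sequential_IS", seed=0, epochs_per_module=1)
        s_full = chain_full.nets[0].state_dict()
        # independent single-module training with identical rng consumption
        chain_one = ModuleChain(cfg, seed=2)
        chain_one, _ = train_sequential(micro_dataset["train"], chain_one, tc1)
        s_one = chain_one.nets[0].state_dict()
        assert all(np.array_equal(s_full[k], s_one[k]) for k in s_full)

    def test_training_reduces_module_loss(self, tiny_dataset):
        from fbsempet.training import _Batch, _module_forward_batch, _mse
        from fbsempet.autodiff import Tensor
        cfg = FBSEMConfig(n_iters=1, n_subsets=6, n_channels=8)
        chain = ModuleChain(cfg, seed=3)
        batch = _Batch(tiny_dataset["train"])

        def loss_module0():
            with ad.no_grad():
                out = _module_forward_batch(chain, 0,
                                            Tensor(np.ones((batch.sys.n_voxels,
                                                            batch.n))),
                                            batch, training=True)
            return float(np.mean((out.data - batch.targets[0]) ** 2))

        before = loss_module0()
        tc = TrainingConfig(lr=0.01, epochs=2, batch_size=5,
                            regime="sequential_IS", seed=0, epochs_per_module=2)
        chain, _ = train_sequential(tiny_dataset["train"], chain, tc)
        assert loss_module0() < before

    def test_activation_ledger_independent_of_depth(self, micro_dataset,
                                                    small_setup, small_system,
                                                    counts_small):
        proj = small_setup[2]
        cl, ch = counts_small

        def peak(n_iters):
            ds = fp.build_dataset(2, 1, 1, small_system, count_low=cl,
                                  count_high=ch, seed=3, geo_projector=proj)
            for s in ds["train"]:
                build_iteration_targets(s, n_iters=n_iters, n_subsets=6)
            chain = ModuleChain(FBSEMConfig(n_iters=n_iters, n_subsets=6,
                                            n_channels=4), seed=0)
            tc = TrainingConfig(lr=0.01, epochs=1, batch_size=2,
                                regime="sequential_IS", seed=0,
                                epochs_per_module=1)
            ad.ledger.reset()
            train_sequential(ds["train"], chain, tc)
            return ad.ledger.peak

        assert peak(2) == peak(10)

    def test_end_to_end_ledger_grows_with_depth(self, small_setup, small_system,
                                                counts_small):
        proj = small_setup[2]
        cl, ch = counts_small

        def peak(n_iters):
            ds = fp.build_dataset(2, 1, 1, small_system, count_low=cl,
                                  count_high=ch, seed=3, geo_projector=proj)
            for s in ds["train"]:
                build_iteration_targets(s, n_iters=n_iters, n_subsets=6)
            chain = ModuleChain(FBSEMConfig(n_iters=n_iters, n_subsets=6,
                                            n_channels=4), seed=0)
            tc = TrainingConfig(lr=0.01, epochs=1, batch_size=2,
                                regime="end_to_end_final", seed=0)
            ad.ledger.reset()
            train_end_to_end(ds["train"], chain, tc)
            return ad.ledger.peak

        p6, p12 = peak(1), peak(2)
        assert p12 > 1.8 * p6


class TestLeapfrog:
    def test_factor_and_k60_equivalence(self, micro_dataset):
        cfg = FBSEMConfig(n_iters=1, n_subsets=6, n_channels=4)
        chain = ModuleChain(cfg, seed=1)
        tc = TrainingConfig(lr=0.01, epochs=1, batch_size=2, regime="leapfrog",
                            seed=0)
        chain, _, factor = train_leapfrog(micro_dataset["train"], chain, tc,
                                          n_targets=12)
        assert factor == 12 / 6
        # k = n_targets: leapfrog loss == end_to_end_final loss definition
        chain_a = ModuleChain(FBSEMConfig(n_iters=2, n_subsets=6,
                                          n_channels=4), seed=7)
        chain_b = ModuleChain(FBSEMConfig(n_iters=2, n_subsets=6,
                                          n_channels=4), seed=7)
        chain_a, _, f = train_leapfrog(micro_dataset["train"], chain_a, tc,
                                       n_targets=12)
        tc_e2e = TrainingConfig(lr=0.01, epochs=1, batch_size=2,
                                regime="end_to_end_final", seed=0)
        chain_b, _ = train_end_to_end(micro_dataset["train"], chain_b, tc_e2e)
        assert f == 1.0
        sa, sb = chain_a.state_dict(), chain_b.state_dict()
        assert all(np.array_equal(sa[k], sb[k]) for k in sa)

    def test_deeper_than_targets_rejected(self, micro_dataset):
        chain = ModuleChain(FBSEMConfig(n_iters=3, n_subsets=6, n_channels=4),
                            seed=0)
        tc = TrainingConfig(lr=0.01, epochs=1, batch_size=2, regime="leapfrog",
                            seed=0)
        with pytest.raises(ValueError):
            train_leapfrog(micro_dataset["train"], chain, tc, n_targets=12)


class TestEndToEnd:
    def test_is_loss_trains_without_error_and_logs(self, micro_dataset):
        cfg = FBSEMConfig(n_iters=1, n_subsets=6, n_channels=4)
        chain = ModuleChain(cfg, seed=0)
        tc = TrainingConfig(lr=0.01, epochs=2, batch_size=2,
                            regime="end_to_end_IS", seed=0)
        chain, log = train_end_to_end(micro_dataset["train"], chain, tc,
                                      val_samples=micro_dataset["val"])
        assert len(log) == 2
        assert np.isfinite(log[-1]["train_loss"])
        assert np.isfinite(log[-1]["val_loss"])

    def test_loss_csv_written(self, tmp_path, micro_dataset):
        from fbsempet.training import save_loss_log
        log = [{"epoch": 0, "module": 1, "train_loss": 0.5, "val_loss": 0.6}]
        path = tmp_path / "log.csv"
        save_loss_log(str(path), log)
        lines = path.read_text().strip().split("\n")
        assert lines[0] == "epoch,module,train_loss,val_loss"
        assert lines[1].startswith("0,1,0.5")


def test_training_config_validation():
    with pytest.raises(ValueError):
        TrainingConfig(regime="nonsense")
    with pytest.raises(ValueError):
        TrainingConfig(epochs=0)
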