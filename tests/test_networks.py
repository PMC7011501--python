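"""Model assembly and training: pair scoring, composition equalities,
early stopping, determinism, masked multi-task pre-training and
per-block transfer."""

import numpy as np
import pytest

from chemodti import _autodiff as ad
from chemodti._autodiff import Tensor
from chemodti.featurize import ATOM_FEATURE_DIM, atom_features
from chemodti.graph_encoder import GNNParams, encode_molecule
from chemodti.networks import (
    MLP,
    CNFeaMLPModel,
    CNModel,
    CNOneStepModel,
    FNNModel,
    FeatureCache,
    NetworkError,
    TrainingConfig,
    build_labeled_split,
    cn_feamlp_predict,
    cn_onestep_predict,
    cn_predict,
    comb_concat,
    fnn_predict,
    load_checkpoint,
    mlp_forward,
    multitask_loss,
    pretrain_multitask,
    save_checkpoint,
    train,
    transfer_load,
)
from chemodti.sequence_encoder import CNNParams, encode_protein
from chemodti.synthetic_data import MultiTaskLabels, generate_multitask_bioassays


def zero_params(block):
    for p in block.parameters():
        p.data[:] = 0.0


def small_cn(seed=0, hidden=6, filters=5):
    rng = np.random.default_rng(seed)
    gnn = GNNParams(ATOM_FEATURE_DIM, hidden_dim=hidden, n_layers=2, rng=rng)
    cnn = CNNParams(in_channels=20, n_filters=filters, n_layers=2,
                    filter_size=4, stride=2, rng=rng)
    mlp = MLP(hidden + filters, hidden=(8,), out_dim=1, rng=rng)
    return CNModel(gnn, cnn, mlp)


def small_feamlp(cache, seed=0, hidden=6, filters=5):
    rng = np.random.default_rng(seed)
    gnn = GNNParams(ATOM_FEATURE_DIM, hidden_dim=hidden, n_layers=2, rng=rng)
    cnn = CNNParams(in_channels=20, n_filters=filters, n_layers=2,
                    filter_size=4, stride=2, rng=rng)
    mol_id = cache.dataset.molecule_ids[0]
    prot_id = cache.dataset.protein_ids[0]
    desc_dim = (len(cache.mol_descriptor(mol_id))
                + len(cache.prot_descriptor(prot_id)))
    raw = MLP(hidden + filters, hidden=(8,), out_dim=4, rng=rng)
    fea = MLP(desc_dim, hidden=(8,), out_dim=4, rng=rng)
    joint = MLP(8, hidden=(50,), out_dim=1, rng=rng)
    return CNFeaMLPModel(gnn, cnn, raw, fea, joint)


class TestCombAndMLP:
    def test_concat_order_molecule_first(self):
        out = comb_concat(Tensor(np.array([[1.0, 2.0]])), Tensor(np.array([[3.0]])))
        assert out.data.tolist() == [[1.0, 2.0, 3.0]]

    def test_concat_dims_additive(self):
        out = comb_concat(Tensor(np.zeros((1, 100))), Tensor(np.zeros((1, 100))))
        assert out.data.shape == (1, 200)

    def test_zero_mlp_scores_half(self):
        mlp = MLP(4, hidden=(3,), out_dim=1)
        zero_params(mlp)
        assert mlp_forward(np.ones(4), mlp) == 0.5

    def test_single_layer_equals_logistic_regression(self):
        mlp = MLP(3, hidden=(), out_dim=1)
        mlp.weights[0].data = np.array([[0.5], [-1.0], [2.0]])
        mlp.biases[0].data = np.array([0.25])
        x = np.array([1.0, 2.0, 3.0])
        z = 0.5 * 1 - 1.0 * 2 + 2.0 * 3 + 0.25
        assert mlp_forward(x, mlp) == pytest.approx(1 / (1 + np.exp(-z)))

    def test_dropout_zero_is_deterministic(self):
        rng = np.random.default_rng(0)
        mlp = MLP(4, hidden=(5,), out_dim=1, dropout=0.0, rng=rng)
        x = Tensor(np.ones((1, 4)))
        a = mlp.forward(x, training=True, rng=np.random.default_rng(1))
        b = mlp.forward(x, training=True, rng=np.random.default_rng(2))
        assert (a.data == b.data).all()

    def test_width_mismatch(self):
        mlp = MLP(4)
        with pytest.raises(NetworkError):
            mlp.forward(Tensor(np.ones((1, 3))))


class TestCNModel:
    def test_zero_model_scores_half(self, tiny_generated):
        _, dataset, _ = tiny_generated
        cache = FeatureCache(dataset)
        model = small_cn()
        for block in model.blocks.values():
            zero_params(block)
        m, p = dataset.molecule_ids[0], dataset.protein_ids[0]
        assert cn_predict(m, p, model, cache) == 0.5

    def test_pipeline_equals_stage_composition(self, tiny_generated):
        _, dataset, _ = tiny_generated
        cache = FeatureCache(dataset)
        model = small_cn(seed=3)
        m, p = dataset.molecule_ids[2], dataset.protein_ids[1]
        emb = encode_molecule(dataset.molecule(m), cache.node_features(m),
                              model.molecule_encoder)
        prot = encode_protein(dataset.protein(p), model.protein_encoder,
                              onehot=cache.onehot(p))
        manual = mlp_forward(comb_concat(emb, prot), model.pair_mlp)
        assert cn_predict(m, p, model, cache) == manual

    def test_pair_mlp_width_checked(self):
        rng = np.random.default_rng(0)
        gnn = GNNParams(ATOM_FEATURE_DIM, hidden_dim=6, n_layers=1, rng=rng)
        cnn = CNNParams(in_channels=20, n_filters=5, n_layers=1, rng=rng)
        with pytest.raises(NetworkError, match="input width"):
            CNModel(gnn, cnn, MLP(7, hidden=(4,), out_dim=1, rng=rng))


class TestFNN:
    def test_default_hidden_widths(self):
        model = FNNModel.default()
        assert model.pair_mlp.hidden == (2000, 1000, 100)
        assert model.pair_mlp.in_dim == 1021 + 567

    def test_zero_weights_half_and_deterministic(self):
        mlp = MLP(10, hidden=(4,), out_dim=1)
        zero_params(mlp)
        assert fnn_predict(np.ones(6), np.ones(4), mlp) == 0.5
        a = fnn_predict(np.ones(6), np.zeros(4), mlp)
        assert a == fnn_predict(np.ones(6), np.zeros(4), mlp)


class TestMultiView:
    def test_feamlp_zero_model_half(self, tiny_generated):
        _, dataset, _ = tiny_generated
        cache = FeatureCache(dataset)
        model = small_feamlp(cache)
        for block in model.blocks.values():
            zero_params(block)
        m, p = dataset.molecule_ids[0], dataset.protein_ids[0]
        assert cn_feamlp_predict(m, p, model, cache) == 0.5

    def test_silencing_expert_branch_reproduces_learnt_composition(self, tiny_generated):
        _, dataset, _ = tiny_generated
        cache = FeatureCache(dataset)
        model = small_feamlp(cache, seed=5)
        model.silence_branch("expert")
        m, p = dataset.molecule_ids[1], dataset.protein_ids[2]
        # manual CN-equivalent composition through the learnt branch only
        learnt, _ = model.branch_outputs(m, p, cache)
        joint_in = ad.concat([ad.relu(learnt), Tensor(np.zeros((1, 4)))], axis=1)
        expected = float(ad.sigmoid(model.mlp_pair_pair.forward(joint_in)).data.ravel()[0])
        assert cn_feamlp_predict(m, p, model, cache) == expected
        # and the output no longer depends on the descriptors
        cache._mol_desc[m] = cache.mol_descriptor(m) * 0 + 7.0
        cache._prot_desc[p] = cache.prot_descriptor(p) * 0 - 3.0
        assert cn_feamlp_predict(m, p, model, cache) == expected

    def test_silencing_learnt_branch_reproduces_expert_composition(self, tiny_generated):
        _, dataset, _ = tiny_generated
        cache = FeatureCache(dataset)
        model = small_feamlp(cache, seed=6)
        model.silence_branch("learnt")
        m, p = dataset.molecule_ids[3], dataset.protein_ids[1]
        _, expert = model.branch_outputs(m, p, cache)
        joint_in = ad.concat([Tensor(np.zeros((1, 4))), ad.relu(expert)], axis=1)
        expected = float(ad.sigmoid(model.mlp_pair_pair.forward(joint_in)).data.ravel()[0])
        assert cn_feamlp_predict(m, p, model, cache) == expected
        # FNN-equivalence: swapping the encoders' weights cannot change it
        for block in (model.molecule_encoder, model.protein_encoder):
            for t in block.parameters():
                t.data[:] = np.random.default_rng(0).normal(size=t.data.shape)
        assert cn_feamlp_predict(m, p, model, cache) == expected

    def test_onestep_zero_model_half_and_dims(self, tiny_generated):
        _, dataset, _ = tiny_generated
        cache = FeatureCache(dataset)
        rng = np.random.default_rng(7)
        gnn = GNNParams(ATOM_FEATURE_DIM, hidden_dim=6, n_layers=1, rng=rng)
        cnn = CNNParams(in_channels=20, n_filters=5, n_layers=1, rng=rng)
        m, p = dataset.molecule_ids[0], dataset.protein_ids[0]
        fea_mol = MLP(len(cache.mol_descriptor(m)), hidden=(), out_dim=3, rng=rng)
        fea_prot = MLP(len(cache.prot_descriptor(p)), hidden=(), out_dim=2, rng=rng)
        pair = MLP(6 + 5 + 3 + 2, hidden=(4,), out_dim=1, rng=rng)
        model = CNOneStepModel(gnn, cnn, fea_mol, fea_prot, pair)
        for block in model.blocks.values():
            zero_params(block)
        assert cn_onestep_predict(m, p, model, cache) == 0.5
        with pytest.raises(NetworkError, match="input width"):
            CNOneStepModel(gnn, cnn, fea_mol, fea_prot,
                           MLP(15, hidden=(4,), out_dim=1, rng=rng))


class TestTraining:
    def test_constant_validation_aupr_stops_at_eleven(self, tiny_generated):
        _, dataset, _ = tiny_generated
        model = small_cn()
        trn, val = build_labeled_split(dataset, ratio="1:2", seed=0)
        config = TrainingConfig(seed=0, learning_rate=0.0, max_epochs=100, patience=10)
        _, history = train(model, dataset, trn, val, config)
        assert history.stopped_epoch == 11
        assert history.best_epoch == 1
        assert len(set(history.val_aupr)) == 1

    def test_same_seed_identical_history_and_parameters(self, tiny_generated):
        _, dataset, _ = tiny_generated
        trn, val = build_labeled_split(dataset, ratio="1:2", seed=1)
        config = TrainingConfig(seed=3, max_epochs=3, patience=3)
        m1, h1 = train(small_cn(seed=2), dataset, trn, val, config)
        m2, h2 = train(small_cn(seed=2), dataset, trn, val, config)
        assert h1.train_loss == h2.train_loss
        assert h1.val_aupr == h2.val_aupr
        for p1, p2 in zip(m1.all_parameters(), m2.all_parameters()):
            assert (p1.data == p2.data).all()

    def test_best_epoch_within_patience_window(self, tiny_generated):
        _, dataset, _ = tiny_generated
        trn, val = build_labeled_split(dataset, ratio="1:2", seed=2)
        config = TrainingConfig(seed=0, max_epochs=8, patience=4)
        _, history = train(small_cn(seed=4), dataset, trn, val, config)
        assert history.best_epoch <= history.stopped_epoch <= history.best_epoch + 4
        assert history.stopped_epoch <= 8

    def test_overlapping_split_rejected(self, tiny_generated):
        _, dataset, _ = tiny_generated
        trn, val = build_labeled_split(dataset, ratio="1:1", seed=0)
        with pytest.raises(NetworkError, match="overlap"):
            train(small_cn(), dataset, trn, trn, TrainingConfig())

    def test_empty_split_rejected(self, tiny_generated):
        _, dataset, _ = tiny_generated
        with pytest.raises(NetworkError):
            train(small_cn(), dataset, [], [("M00000", "P00000", 1)], TrainingConfig())


class TestTransfer:
    def test_checkpoint_roundtrip_reproduces_predictions(self, tmp_path, tiny_generated):
        _, dataset, _ = tiny_generated
        cache = FeatureCache(dataset)
        trn, val = build_labeled_split(dataset, ratio="1:2", seed=0)
        config = TrainingConfig(seed=0, max_epochs=2, patience=2)
        source, _ = train(small_cn(seed=8), dataset, trn, val, config)
        save_checkpoint(tmp_path / "cn.npz", source)
        target = small_cn(seed=99)  # different random init
        transfer_load(target, tmp_path / "cn.npz",
                      blocks=["molecule_encoder", "protein_encoder", "pair_mlp"])
        pairs = [(m, p) for m in dataset.molecule_ids[:4]
                 for p in dataset.protein_ids[:4]]
        src_scores = [cn_predict(m, p, source, cache) for m, p in pairs]
        tgt_scores = [cn_predict(m, p, target, cache) for m, p in pairs]
        assert src_scores == tgt_scores  # bit-for-bit

    def test_partial_load_leaves_other_blocks_fresh(self, tmp_path):
        source = small_cn(seed=1)
        save_checkpoint(tmp_path / "cn.npz", source)
        target = small_cn(seed=2)
        before_cnn = [p.data.copy() for p in target.protein_encoder.parameters()]
        transfer_load(target, tmp_path / "cn.npz", blocks=["molecule_encoder"])
        for a, b in zip(source.molecule_encoder.parameters(),
                        target.molecule_encoder.parameters()):
            assert (a.data == b.data).all()
        for a, b in zip(before_cnn, target.protein_encoder.parameters()):
            assert (a == b.data).all()

    def test_frozen_blocks_unchanged_by_training(self, tmp_path, tiny_generated):
        _, dataset, _ = tiny_generated
        source = small_cn(seed=3)
        save_checkpoint(tmp_path / "cn.npz", source)
        target = small_cn(seed=4)
        transfer_load(target, tmp_path / "cn.npz", blocks=["molecule_encoder"],
                      freeze=["molecule_encoder"])
        frozen_before = [p.data.copy() for p in target.molecule_encoder.parameters()]
        mlp_before = [p.data.copy() for p in target.pair_mlp.parameters()]
        trn, val = build_labeled_split(dataset, ratio="1:2", seed=0)
        train(target, dataset, trn, val, TrainingConfig(seed=0, max_epochs=2, patience=2))
        for a, b in zip(frozen_before, target.molecule_encoder.parameters()):
            assert (a == b.data).all()
        assert any((a != b.data).any()
                   for a, b in zip(mlp_before, target.pair_mlp.parameters()))

    def test_shape_mismatch_names_block(self, tmp_path):
        source = small_cn(seed=1, hidden=6)
        save_checkpoint(tmp_path / "cn.npz", source)
        target = small_cn(seed=1, hidden=7)
        with pytest.raises(NetworkError, match="molecule_encoder"):
            transfer_load(target, tmp_path / "cn.npz", blocks=["molecule_encoder"])

    def test_checkpoint_meta(self, tmp_path):
        model = small_cn(seed=5)
        save_checkpoint(tmp_path / "cn.npz", model, config={"note": "x"})
        states, meta = load_checkpoint(tmp_path / "cn.npz")
        assert set(states) == {"molecule_encoder", "protein_encoder", "pair_mlp"}
        assert meta["schema_version"] == 1
        assert meta["config"] == {"note": "x"}


class TestMultitaskPretraining:
    @pytest.fixture
    def molecules(self, tiny_generated):
        _, dataset, _ = tiny_generated
        return dataset.molecules[:10]

    def test_fully_masked_labels_zero_loss_zero_gradient(self, molecules):
        rng = np.random.default_rng(0)
        encoder = GNNParams(ATOM_FEATURE_DIM, hidden_dim=5, n_layers=1, rng=rng)
        head = MLP(5, hidden=(), out_dim=4, rng=rng)
        labels = MultiTaskLabels(matrix=np.full((10, 4), -1, dtype=np.int8),
                                 molecule_ids=[m.id for m in molecules])
        feats = [atom_features(m) for m in molecules]
        loss = multitask_loss(encoder, head, molecules, feats, labels, range(10))
        assert loss.item() == 0.0
        loss.backward()
        for p in [*encoder.parameters(), *head.parameters()]:
            assert p.grad is None or (p.grad == 0).all()

    def test_masked_gradient_equals_observed_only_oracle(self, molecules):
        # the gradient with unknown entries masked must match finite
        # differences of an independent loss computed over observed
        # entries only (no autodiff)
        rng = np.random.default_rng(1)
        encoder = GNNParams(ATOM_FEATURE_DIM, hidden_dim=4, n_layers=1, rng=rng)
        head = MLP(4, hidden=(), out_dim=3, rng=rng)
        matrix = rng.integers(-1, 2, size=(10, 3)).astype(np.int8)
        matrix[0, 0] = 1  # ensure something observed
        labels = MultiTaskLabels(matrix=matrix, molecule_ids=[m.id for m in molecules])
        feats = [atom_features(m) for m in molecules]

        def observed_only_loss():
            total, count = 0.0, 0
            for i, mol in enumerate(molecules):
                h = np.asarray(feats[i], dtype=float)
                w0, w1 = encoder.W0[0].data, encoder.W1[0].data
                adj = np.zeros((mol.n_atoms, mol.n_atoms))
                for a, b in mol.edges:
                    adj[a, b] = adj[b, a] = 1.0
                h = 1 / (1 + np.exp(-(h @ w0 + adj @ h @ w1)))
                z = h.sum(axis=0) @ head.weights[0].data + head.biases[0].data
                for t in range(3):
                    if matrix[i, t] < 0:
                        continue
                    y = float(matrix[i, t])
                    total += max(z[t], 0) - z[t] * y + np.log1p(np.exp(-abs(z[t])))
                    count += 1
            return total / count

        loss = multitask_loss(encoder, head, molecules, feats, labels, range(10))
        assert loss.item() == pytest.approx(observed_only_loss(), abs=1e-12)
        loss.backward()
        eps = 1e-6
        param = encoder.W0[0]
        for idx in [(0, 0), (3, 2), (10, 1)]:
            orig = param.data[idx]
            param.data[idx] = orig + eps
            up = observed_only_loss()
            param.data[idx] = orig - eps
            down = observed_only_loss()
            param.data[idx] = orig
            assert param.grad[idx] == pytest.approx((up - down) / (2 * eps), abs=1e-5)

    def test_all_unknown_task_skipped_with_warning(self, molecules, caplog):
        rng = np.random.default_rng(2)
        encoder = GNNParams(ATOM_FEATURE_DIM, hidden_dim=4, n_layers=1, rng=rng)
        matrix = rng.integers(0, 2, size=(10, 3)).astype(np.int8)
        matrix[:, 1] = -1
        labels = MultiTaskLabels(matrix=matrix, molecule_ids=[m.id for m in molecules])
        config = TrainingConfig(seed=0, max_epochs=1, patience=1, batch_size=5)
        with caplog.at_level("WARNING"):
            state, head, losses = pretrain_multitask(encoder, molecules, labels,
                                                     config=config)
        assert "all-unknown" in caplog.text
        assert len(losses) == 1
        assert set(state) == {f"{n}.{l}" for n in ("W0", "W1") for l in (0,)}

    def test_pretraining_improves_downstream_at_small_train_size(self):
        # paired comparison over 3 seeds: initialise the molecule
        # encoder from 90-task bioassay pre-training vs fresh random,
        # train on a small positive subsample, compare validation AUPR
        from chemodti.synthetic_data import GeneratorConfig, generate_dataset
        from chemodti.networks import smoke_cn_model

        config = GeneratorConfig(seed=0)
        dataset, _ = generate_dataset(config)
        cache = FeatureCache(dataset)
        labels = generate_multitask_bioassays(dataset.molecules, n_tasks=90,
                                              unknown_fraction=0.4, seed=0)
        diffs = []
        for seed in (0, 1, 2):
            rng = np.random.default_rng(seed)
            pos = [dataset.positives[i]
                   for i in rng.permutation(len(dataset.positives))[:40]]
            trn, val = build_labeled_split(dataset, ratio="1:5", seed=seed,
                                           positives=pos)
            t_config = TrainingConfig(seed=seed, max_epochs=20, patience=10)
            base = smoke_cn_model(ATOM_FEATURE_DIM, seed=seed)
            _, h_base = train(base, dataset, trn, val, t_config, cache=cache)
            pre = smoke_cn_model(ATOM_FEATURE_DIM, seed=seed)
            pretrain_multitask(pre.molecule_encoder, dataset.molecules, labels,
                               config=TrainingConfig(seed=seed, max_epochs=10,
                                                     patience=10, batch_size=20))
            _, h_pre = train(pre, dataset, trn, val, t_config, cache=cache)
            diffs.append(max(h_pre.val_aupr) - max(h_base.val_aupr))
        assert np.mean(diffs) > 0.0

    def test_pretraining_runs_and_reduces_loss(self, molecules):
        rng = np.random.default_rng(3)
        encoder = GNNParams(ATOM_FEATURE_DIM, hidden_dim=6, n_layers=1, rng=rng)
        labels = generate_multitask_bioassays(molecules, n_tasks=12,
                                              unknown_fraction=0.2, seed=0)
        config = TrainingConfig(seed=0, max_epochs=6, patience=6, batch_size=5,
                                learning_rate=5e-3)
        _, _, losses = pretrain_multitask(encoder, molecules, labels, config=config)
        assert losses[-1] < losses[0]
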