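import numpy as np
import pytest

import drtransfer as dt


@pytest.fixture(scope="session")
def fixture_ds():
    """Tiny deterministic dataset: 40 source / 20 target / 20 pool samples,
    30 genes of which 3 carry signal."""
    return dt.make_fixture()


@pytest.fixture(scope="session")
def fixture_run(fixture_ds):
    """Small trained model + normalized cohorts on the tiny fixture, shared
    across tests that only need *a* trained model, not a good one."""
    ds = fixture_ds
    cfg = dt.PipelineConfig(hidden=(32, 16, 8), ensemble_size=2,
                            batch_sizes=(16,), learning_rates=(1e-3,),
                            base_seed=11)
    src_norm, tgt_norm = dt.normalize_cohorts(cfg, ds.source, ds.target, ds.pool)
    y, label_norm = dt.normalize_labels(ds.source_response.values, cfg.drug)
    model = dt.train_ensemble(src_norm.values, y,
                              {"epochs": 60, "batch_size": 16,
                               "learning_rate": 1e-3},
                              K=2, base_seed=11, hidden=cfg.hidden,
                              gene_ids=list(src_norm.gene_ids),
                              label_normalizer=label_norm)
    labels = ds.target_labels.aligned_to(tgt_norm).labels
    return {"ds": ds, "config": cfg, "src_norm": src_norm, "tgt_norm": tgt_norm,
            "y": y, "model": model, "labels": labels}


def linear_predictor(weights, gene_ids=None):
    """Transparent single-member 'ensemble' computing yhat = w . x exactly."""
    w = np.asarray(weights, dtype=float)
    from drtransfer.nn import DenseNet
    from drtransfer.predictor import TrainedPredictor

    m = DenseNet(n_in=w.size, hidden=(), n_out=1, dropout=0.0, seed=0)
    m.set_weights({"W0": w[:, None], "b0": np.zeros(1)})
    return TrainedPredictor(
        members=[m],
        gene_ids=gene_ids or [f"g{i}" for i in range(w.size)],
        hyperparams={})
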