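"""Train the deep belief network, with elephant-herding tuning.

Pretrains stacked RBMs by CD-1, fine-tunes with dropout/L2/early
stopping, and lets EHO pick (learning rate, momentum, weight decay,
width) against the inner-CV mean squared error.
"""

import numpy as np

from spiralselect import SyntheticSpec, generate_dataset
from spiralselect.dbnn import DBNNClassifier, TrainConfig
from spiralselect.eho import EHOConfig, HyperVector, mse_objective, run_eho
from spiralselect.evaluate import PredictionSet, roc_auc
from spiralselect.preprocess import preprocess_fold

spec = SyntheticSpec(seed=4)
ds = generate_dataset(spec)
train, test = ds.subset(np.arange(0, 320)), ds.subset(np.arange(320, 400))
tr, te, _ = preprocess_fold(train, test)
origin = np.asarray(tr.origin)
cols = np.isin(origin, sorted(spec.informative_idx))  # oracle mask here
X, y = tr.X.to_numpy(float)[:, cols], tr.y
Xt, yt = te.X.to_numpy(float)[:, cols], te.y

base = TrainConfig(epochs=5, finetune_epochs=120, patience=12,
                   learning_rate=0.02, seed=0)


def objective(pos):
    return mse_objective(X, y, HyperVector.from_position(pos),
                         n_folds=3, base_cfg=base, seed=0)


best_pos, best_mse, trace = run_eho(
    objective, EHOConfig(n_clans=2, clan_size=4, max_iter=3, seed=0))
hyper = HyperVector.from_position(best_pos)
print(f"tuned: eta={hyper.learning_rate:.4g} momentum={hyper.momentum:.3f}"
      f" decay={hyper.weight_decay:.2g} layers={hyper.layer_sizes}")
print(f"inner-CV MSE: {trace[0]:.4f} -> {best_mse:.4f}")

cfg = TrainConfig(epochs=10, finetune_epochs=300, patience=30,
                  learning_rate=hyper.learning_rate,
                  momentum=hyper.momentum,
                  weight_decay=hyper.weight_decay, seed=0)
clf = DBNNClassifier(hyper.layer_sizes, cfg).fit(X, y)
p = clf.predict_proba(Xt)[:, 1]
print(f"held-out AUC: {roc_auc(PredictionSet(yt, p)):.4f}")
print(f"held-out accuracy: {((p >= 0.5) == yt).mean():.4f}")
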