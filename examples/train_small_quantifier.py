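"""Train a small quantification model on synthetic depth profiles.

Desk-scale demonstration: a few hundred profiles and a handful of
epochs, enough to watch the loss fall and get rough predictions.  The
full-accuracy configuration (thousands of profiles, more epochs) is the
ModelConfig default; see the pipeline runner or `cmxrf train`.
"""

import numpy as np

from cmxrf import datasets, model

train_set = datasets.generate_dataset(400, seed=1)
val_set = datasets.generate_dataset(80, seed=2)

cfg = model.ModelConfig(epochs=6, learning_rate=1e-3)
m = model.build_model(cfg)
print(f"model: {m.n_parameters():,} parameters")

model.train(m, train_set, val_set, verbose=True)

# predict on a noisy realization of the held-out profiles
rng = np.random.default_rng(3)
noisy = rng.poisson(val_set.X.astype(np.float64)).astype(np.float64)
preds = model.predict(m, noisy)

dens_err = [
    abs(p.density - y) / y for p, y in zip(preds, val_set.Y[:, 53])
]
x0_err = [abs(p.x0 - y) for p, y in zip(preds, val_set.Y[:, 54])]
print(f"\nmedian density deviation: {np.median(dens_err):.1%}")
print(f"median |x0 error|: {np.median(x0_err):.1f} um")
print("(accuracy improves substantially at the full training scale)")

m.save("small_model.npz")
print("checkpoint written to small_model.npz")
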