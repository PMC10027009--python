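"""Train the inverse network on a small synthetic corpus and evaluate it.

Generates randomized tissue models, computes their noisy squared contrast
curves K²(T) and true speed-resolved perfusion, trains the 7-25-3 tanh
network with the perfusion-weighted MSE loss, and reports the evaluation
metrics: wMAPE per speed band (error relative to each sample's total
perfusion), unweighted MAPE for total perfusion, and R².

This demo uses 3000 training models for speed; `melsci.experiments.
headline_experiment` runs the full desk-scale protocol (10k + 10k models,
restricted ablation, single-exposure baseline).
"""

import numpy as np

from melsci.config import Config
from melsci.experiments import single_exposure_mapes
from melsci.perfusion_ann import Dataset, evaluate_model, train_ann
from melsci.pipeline import ForwardModel

cfg = Config()
cfg.mc.grid_t_epi = (0.05, 0.12, 0.3, 0.8)
cfg.mc.grid_musp = (0.3, 0.8, 1.6, 3.5)
cfg.mc.n_photons = 30_000
cfg.ann.restarts = 3

print("simulating photon path-length grid ...")
fm = ForwardModel(None, cfg, seed=10)
print("generating 3000 training + 2000 evaluation models ...")
train_sim = fm.generate_dataset(3000, seed=11)
eval_sim = fm.generate_dataset(2000, seed=12)

ds = Dataset.from_arrays(train_sim.K2, train_sim.targets,
                         np.random.default_rng(13))
print("training 3 restarts with early stopping ...")
model = train_ann(ds, cfg.ann, seed=14)
print("restart test-split wMSE scores:",
      [round(s, 5) for s in model.meta["restart_scores"]])

metrics = evaluate_model(model, eval_sim.K2, eval_sim.targets)
print("\nevaluation on held-out models:")
print("  wMAPE [0-1, 1-10, >10 mm/s] %:", np.round(metrics["wmape"], 1))
print(f"  total-perfusion MAPE %: {metrics['mape_total']:.1f}")
print("  R2 [low, mid, high, total]:", np.round(metrics["r2"], 2))

pse = single_exposure_mapes(eval_sim.K2, eval_sim.targets.sum(axis=1))
print("\nsingle-exposure baseline MAPE % per exposure (1..64 ms):",
      np.round(pse, 1))
print("  -> best single-exposure error "
      f"{pse.min():.1f}% at T={[1,2,4,8,16,32,64][int(pse.argmin())]} ms; "
      "the network's total-perfusion error is "
      f"{metrics['mape_total']:.1f}%")
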