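"""Prediction-evaluation statistics on a toy validation set.

Shows RMSE / R-squared / Bias for regression and Accuracy / Cohen's kappa for
classification, including the imbalanced-data caveat: a majority-class
predictor keeps a decent accuracy but collapses to kappa = 0.
"""

import numpy as np

import canopyfeat as cf

rng = np.random.default_rng(3)
obs = rng.normal(40, 10, size=200)
pred = obs + rng.normal(0, 5, size=200)
reg = cf.regression_metrics(obs, pred)
print("regression :", {k: round(v, 3) for k, v in reg.items()})

labels = rng.choice(["1", "2", "3"], size=200, p=[0.7, 0.2, 0.1]).tolist()
majority = ["1"] * 200
cls = cf.classification_metrics(labels, majority)
print("majority-class classifier :", {k: round(v, 3) for k, v in cls.items()})
# Accuracy equals the majority-class share, but kappa corrects for chance
# agreement and scores the constant predictor at exactly zero.
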