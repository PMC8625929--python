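"""Shared posterior-prediction contract for all probabilistic regressors."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np


@dataclass
class PosteriorPrediction:
    """Predictive mean and standard deviation, optionally with draws.

    ``std`` is the epistemic spread of the model's predictive mean (for
    sampled models, the standard deviation over stochastic forward passes;
    for GPs and mixture density networks, the closed form).  When a draw
    matrix is present its column statistics must agree with mean/std.
    """

    mean: np.ndarray                    # (n_test,)
    std: np.ndarray                     # (n_test,) nonnegative
    samples: Optional[np.ndarray] = None  # (S, n_test)

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float).ravel()
        self.std = np.asarray(self.std, dtype=float).ravel()
        if self.mean.shape != self.std.shape:
            raise ValueError("mean and std lengths differ")
        if np.any(self.std < 0):
            raise ValueError("std must be nonnegative")
        if self.samples is not None:
            self.samples = np.asarray(self.samples, dtype=float)
            if self.samples.shape[1] != self.mean.shape[0]:
                raise ValueError("samples column count must match mean")
            if not (np.allclose(self.samples.mean(axis=0), self.mean,
                                atol=1e-8)
                    and np.allclose(self.samples.std(axis=0), self.std,
                                    atol=1e-8)):
                raise ValueError("samples inconsistent with mean/std")
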