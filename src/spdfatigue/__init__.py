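"""EEG driver-fatigue detection from spatial-temporal covariance structure.

The package classifies 9 s, 30-channel EEG trials as vigilant or drowsy by
fusing three views of the trial's covariance structure: an SPD-network
embedding of the whole-trial covariance, Stein-divergence distances to the
class centers on the SPD manifold, and an LSTM over the sequence of
segment-wise covariances.  A synthetic benchmark generator, reaction-time
labeling, a channel-pair discriminability statistic (zeta) and a
forward-problem brain-state analysis round out the pipeline.
"""

from .fusion import Metrics, TrainConfig
from .model import FatigueFusionModel, FatigueFusionResults
from .synthetic import GenConfig, TrialSet, generate_dataset

__all__ = [
    "FatigueFusionModel",
    "FatigueFusionResults",
    "TrainConfig",
    "Metrics",
    "GenConfig",
    "TrialSet",
    "generate_dataset",
    "__version__",
]

__version__ = "0.1.0"
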