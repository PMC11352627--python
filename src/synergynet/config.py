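"""Configuration dataclasses for featurization, encoders, model and training.

Architecture constants the method fixes (256-bit radius-2 fingerprints, the
3→32→64→128→160 point-cloud channel schedule, the 3/2/1-layer GCN parts,
the halving predictor head ending in one neuron) are hard structure, not
configuration. Everything the method leaves open (hidden widths, pooling
rules, activation choices) lives here, with a "default" and a scaled-down
"small" preset for quick CPU experiments.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

__all__ = [
    "FeaturizerConfig",
    "SequenceEncoderConfig",
    "GraphEncoderConfig",
    "CloudEncoderConfig",
    "CellEncoderConfig",
    "ModelConfig",
    "TrainConfig",
    "small_model_config",
    "load_yaml",
    "save_yaml",
]


@dataclass
class FeaturizerConfig:
    fp_bits: int = 256          # fingerprint length (fixed by the method)
    fp_radius: int = 2
    max_atoms: int = 64         # capacity of the atom-sequence encoder
    cloud_points: int = 100     # padded point-cloud length n
    conformer_seed: int = 2024
    relax_conformer: bool = True
    include_explicit_h: bool = False
    power_mode: str = "cumulative"   # cumulative | exact
    add_self_loops: bool = False


@dataclass
class SequenceEncoderConfig:
    lstm_units: int = 64        # d_l; BiLSTM output width is 2*d_l
    gmlp_layers: int = 3
    gmlp_dim: int = 128         # channel width of Z (split in half by the SGU)
    heads: int = 4
    head_dim: int = 32          # d_q = d_k = d_v
    attn_out: int = 128         # width of W^o output
    gmlp_input: str = "full"    # full | forward_half
    seq_pool: str = "mean"      # mean | max  (positions -> vector)


@dataclass
class GraphEncoderConfig:
    width: int = 64             # per-layer GCN width, all three parts
    share_weights: bool = True  # Siamese: drug-1 / drug-2 / pair share one stack


@dataclass
class CloudEncoderConfig:
    channels: tuple[int, ...] = (32, 64, 128, 160)  # fixed by the method
    kernel_size: int = 3
    pool: str = "max"           # max | mean over cloud positions


@dataclass
class CellEncoderConfig:
    hidden: int = 256
    out: int = 128


@dataclass
class ModelConfig:
    featurizer: FeaturizerConfig = field(default_factory=FeaturizerConfig)
    sequence: SequenceEncoderConfig = field(default_factory=SequenceEncoderConfig)
    graph: GraphEncoderConfig = field(default_factory=GraphEncoderConfig)
    cloud: CloudEncoderConfig = field(default_factory=CloudEncoderConfig)
    cell: CellEncoderConfig = field(default_factory=CellEncoderConfig)
    predictor_width: int = 1024  # second layer is half, final layer is 1
    variant: str = "MMFSyn"
    order_augment: bool = True   # train on both drug orderings, average at predict
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ModelConfig":
        d = dict(d)
        kwargs: dict[str, Any] = {}
        for f in dataclasses.fields(cls):
            if f.name not in d:
                continue
            value = d[f.name]
            if dataclasses.is_dataclass(f.type) or f.name in (
                    "featurizer", "sequence", "graph", "cloud", "cell"):
                sub = {"featurizer": FeaturizerConfig,
                       "sequence": SequenceEncoderConfig,
                       "graph": GraphEncoderConfig,
                       "cloud": CloudEncoderConfig,
                       "cell": CellEncoderConfig}[f.name]
                value = sub(**value) if isinstance(value, dict) else value
                if f.name == "cloud" and isinstance(value.channels, list):
                    value.channels = tuple(value.channels)
            kwargs[f.name] = value
        return cls(**kwargs)


@dataclass
class TrainConfig:
    batch_size: int = 256
    lr0: float = 1e-3
    gamma: float = 0.9
    step_size: int = 20
    epochs: int = 100
    weight_decay: float = 0.01
    patience: int = 20          # early stopping on validation MSE
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.lr0 <= 0:
            raise ValueError("lr0 must be positive")
        if not 0 < self.gamma <= 1:
            raise ValueError("gamma must be in (0, 1]")
        if self.step_size < 1:
            raise ValueError("step_size must be >= 1")


def small_model_config(max_atoms: int = 32, cloud_points: int = 32,
                       seed: int = 0) -> ModelConfig:
    """A scaled-down preset for CPU-sized experiments and fixtures.

    Hidden widths shrink; everything the method pins (fingerprint length,
    cloud channel schedule, GCN part depths, head halving) is untouched.
    """
    return ModelConfig(
        featurizer=FeaturizerConfig(max_atoms=max_atoms,
                                    cloud_points=cloud_points),
        sequence=SequenceEncoderConfig(lstm_units=24, gmlp_layers=2,
                                       gmlp_dim=48, heads=2, head_dim=16,
                                       attn_out=48),
        graph=GraphEncoderConfig(width=24),
        cell=CellEncoderConfig(hidden=96, out=48),
        predictor_width=384,
        seed=seed,
    )


def load_yaml(path) -> ModelConfig:
    with open(path) as fh:
        return ModelConfig.from_dict(yaml.safe_load(fh))


def save_yaml(config: ModelConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
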