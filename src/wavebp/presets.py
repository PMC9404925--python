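"""Canonical experiment presets.

``full_scale`` mirrors the full-scale study configuration (500-epoch
training, 4-level / 32-filter W-Net on 8-min-plus clinical records).
``desk_scale`` is the package's reduced reference experiment, sized to run
on a single CPU: one synthetic 10-minute subject at 125 Hz, a 3-level /
16-filter single-conv-per-level W-Net, trained for 100 epochs.  Tests and
the reproduction script share these presets so results are comparable
across runs.
"""

from __future__ import annotations

from .pipeline import RunConfig
from .synth import SynthConfig
from .train import TrainConfig
from .wnet import ModelConfig


def desk_scale(method: str = "I", seed: int = 0, epochs: int = 100) -> RunConfig:
    """Reduced subject-specific experiment for a single CPU.

    Batch size 64 rather than the full-scale 128: a 10-min subject yields
    ~230 training windows, and the smaller batch doubles the number of Adam
    updates per epoch, which this data size needs to converge in 100 epochs.
    """
    return RunConfig.from_method(
        method,
        seed=seed,
        synth=SynthConfig(duration_s=600.0),
        model=ModelConfig(levels=3, base_filters=16, convs_per_level=1),
        train=TrainConfig(epochs=epochs, batch_size=64),
    )


def full_scale(method: str = "I", seed: int = 0) -> RunConfig:
    """Full-scale configuration (500 epochs, 4-level / 32-filter model)."""
    return RunConfig.from_method(
        method,
        seed=seed,
        synth=SynthConfig(duration_s=600.0),
        model=ModelConfig(),
        train=TrainConfig(),
    )
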