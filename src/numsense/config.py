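"""Experiment configuration: validation, serialization, canonical presets."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from .errors import InvalidArgumentError

__all__ = [
    "StimulusConfig",
    "TrialsConfig",
    "ObserverConfig",
    "DbnConfig",
    "AnalysisConfig",
    "ExperimentConfig",
    "full_scale_config",
    "reduced_config",
]


@dataclass
class StimulusConfig:
    num_range: tuple[float, float] = (7.0, 28.0)
    size_range: tuple[float, float] = (2.6e5, 10.4e5)
    spacing_range: tuple[float, float] = (0.8e7, 3.2e7)
    levels: int = 13
    instances: int = 10
    test_instances: int = 4
    canvas: int = 200
    downscale: int | None = 100
    # unsupervised-learning image set: numerosity range wider than the
    # task space (the task grids are reused when unsup_num_range is None)
    unsup_num_range: tuple[float, float] | None = (5.0, 32.0)
    unsup_num_levels: int = 28
    unsup_instances: int = 14


@dataclass
class TrialsConfig:
    n_comparison_pairs: int = 300
    quotas: dict = field(
        default_factory=lambda: {"0.5-0.6": 0.1, "0.6-0.7": 0.2, "0.7-0.8": 0.3, "0.8-0.9": 0.4}
    )
    n_uniform_pairs: int = 15200
    n_readout_pairs: int = 3000

    def quota_bins(self) -> dict[tuple[float, float], float]:
        out = {}
        for k, v in self.quotas.items():
            lo, hi = (float(x) for x in k.split("-"))
            out[(lo, hi)] = float(v)
        return out


@dataclass
class ObserverConfig:
    betas: tuple[float, float, float, float] = (0.0, 2.0, 0.4, 0.3)
    gamma: float = 0.01
    rt_median_ms: float = 600.0
    rt_sigma: float = 0.3


@dataclass
class DbnConfig:
    arch: tuple[int, int] = (1500, 1000)
    n_seeds: int = 12
    epochs: int = 200
    young_epoch: int = 1
    lr_layer1: float = 0.1
    lr_layer2: float = 0.05
    batch_size: int = 125
    init_sigma: float = 0.01
    init_visible_bias_from_data: bool = True


@dataclass
class AnalysisConfig:
    gamma_mode: float | str = 0.01
    rsa_level_indices: tuple[int, int, int] = (0, 8, 12)
    rsa_instances: int = 10
    fdr_q: float = 0.01


@dataclass
class ExperimentConfig:
    stimulus: StimulusConfig = field(default_factory=StimulusConfig)
    trials: TrialsConfig = field(default_factory=TrialsConfig)
    observer: ObserverConfig = field(default_factory=ObserverConfig)
    dbn: DbnConfig = field(default_factory=DbnConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    seed: int = 0
    scale: str = "reduced"

    def validate(self) -> None:
        s = self.stimulus
        if s.levels < 2 or s.instances < 1:
            raise InvalidArgumentError("need >= 2 levels and >= 1 instance")
        for lo, hi in (s.num_range, s.size_range, s.spacing_range):
            if not 0 < lo < hi:
                raise InvalidArgumentError(f"bad range ({lo}, {hi})")
        if s.downscale is not None and s.downscale > s.canvas:
            raise InvalidArgumentError("downscale target exceeds canvas")
        total = sum(self.trials.quotas.values())
        if abs(total - 1.0) > 1e-9:
            raise InvalidArgumentError(f"quota fractions sum to {total}, expected 1")
        for frac in self.trials.quotas.values():
            c = frac * self.trials.n_comparison_pairs
            if abs(c - round(c)) > 1e-9:
                raise InvalidArgumentError("quota x n_pairs must be integral")
        if not 0 <= self.observer.gamma < 1:
            raise InvalidArgumentError("observer gamma must be in [0, 1)")
        if self.dbn.epochs < 1 or self.dbn.young_epoch < 1:
            raise InvalidArgumentError("epochs must be >= 1")
        if self.dbn.young_epoch > self.dbn.epochs:
            raise InvalidArgumentError("young epoch exceeds total epochs")
        idxs = self.analysis.rsa_level_indices
        if any(i < 0 or i >= s.levels for i in idxs):
            raise InvalidArgumentError(f"RSA level indices {idxs} out of range")

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ExperimentConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        raw = json.loads(text)

        def build(klass, data):
            kwargs = {}
            for f in dataclasses.fields(klass):
                if f.name not in data:
                    continue
                v = data[f.name]
                kwargs[f.name] = tuple(v) if isinstance(v, list) else v
            return klass(**kwargs)

        return cls(
            stimulus=build(StimulusConfig, raw.get("stimulus", {})),
            trials=build(TrialsConfig, raw.get("trials", {})),
            observer=build(ObserverConfig, raw.get("observer", {})),
            dbn=build(DbnConfig, raw.get("dbn", {})),
            analysis=build(AnalysisConfig, raw.get("analysis", {})),
            seed=raw.get("seed", 0),
            scale=raw.get("scale", "reduced"),
        )


def full_scale_config(seed: int = 0) -> ExperimentConfig:
    """The full-scale protocol (cluster-scale; not run in tests)."""
    cfg = ExperimentConfig(seed=seed, scale="full")
    return cfg


def reduced_config(seed: int = 0) -> ExperimentConfig:
    """Desk-scale configuration preserving the qualitative design.

    50 x 50 images, numerosities 5-16 with 5 levels per dimension,
    5^3 x 16 = 2000 training images, architecture (200, 100), 12 seeds,
    Young = 1 vs Mature = 50 epochs, 2000 test pairs.
    """
    return ExperimentConfig(
        stimulus=StimulusConfig(
            num_range=(5.0, 16.0),
            size_range=(5000.0, 10000.0),
            spacing_range=(3.0e5, 6.0e5),
            levels=5,
            instances=8,
            test_instances=8,
            canvas=100,
            downscale=50,
            unsup_num_range=(4.0, 24.0),
            unsup_num_levels=8,
            unsup_instances=10,
        ),
        trials=TrialsConfig(
            n_comparison_pairs=300,
            n_uniform_pairs=2000,
            n_readout_pairs=3000,
        ),
        dbn=DbnConfig(
            arch=(200, 100),
            n_seeds=12,
            epochs=50,
            young_epoch=1,
            batch_size=25,
            init_sigma=0.1,
            init_visible_bias_from_data=True,
        ),
        analysis=AnalysisConfig(rsa_level_indices=(0, 2, 4), rsa_instances=10),
        seed=seed,
        scale="reduced",
    )
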