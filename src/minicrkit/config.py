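"""Run configuration: the CRISPR backbone, pairing rules and tool parameters.

The repeat/leader/backbone-spacer sequences of the source CRISPR locus are
configuration inputs, never hard-coded — users supply them from their organism's
genome or the literature.  A worked default (`RunConfig.example()`) is generated
from a seed so the toolkit is demonstrable without external data; it is labelled
synthetic and is not the sequence of any natural locus.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .assembly import Backbone
from .errors import MiniCRKitError
from .pairing import HandleSpec, PasConfig
from .scan import ScanConfig


@dataclass
class RunConfig:
    """Everything a reproducible run needs, loadable from one YAML file."""

    repeat_seq: str
    leader_seq: str
    backbone_spacers: list[str]
    protospacer_length: int = 37
    criterion_mode: str = "full"
    min_paired: int = 6
    wobble_counts_as_paired: bool = True
    minimal_positions: list[int] = field(default_factory=lambda: [-3, -4, -5])
    min_separation: int | None = None  # defaults to 2x protospacer length downstream
    survey_thresholds: list[int] = field(default_factory=lambda: [1, 5])
    oe_overlap: int = 12
    moe_total_length: int = 50
    qpcr_efficiency: float = 1.0
    rng_seed: int = 0
    out_dir: str = "minicrkit_out"

    def __post_init__(self) -> None:
        # validate sequence fields through the seqio/pairing layer
        self.handle()  # raises on a bad repeat
        self.backbone()  # raises on bad leader/spacers
        self.pas_config()
        self.scan_config()

    def handle(self) -> HandleSpec:
        return HandleSpec.from_repeat(self.repeat_seq)

    def backbone(self) -> Backbone:
        return Backbone.from_sequences(self.leader_seq, self.repeat_seq, self.backbone_spacers)

    def pas_config(self) -> PasConfig:
        return PasConfig(
            min_paired=self.min_paired,
            wobble_counts_as_paired=self.wobble_counts_as_paired,
            minimal_positions=frozenset(self.minimal_positions),
        )

    def scan_config(self) -> ScanConfig:
        return ScanConfig(
            protospacer_length=self.protospacer_length,
            criterion_mode=self.criterion_mode,
            pas_config=self.pas_config(),
        )

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise MiniCRKitError(f"config file {path} is not a mapping")
        try:
            return cls(**data)
        except TypeError as exc:
            raise MiniCRKitError(f"invalid config field: {exc}") from exc

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]

    @classmethod
    def example(cls, seed: int = 7) -> "RunConfig":
        """A synthetic demonstration config: random 24-nt repeat, 100-nt leader,
        six random 37-nt backbone spacers.  Not a natural locus."""
        rng = np.random.default_rng(seed)
        bases = list("ACGT")
        mk = lambda n: "".join(rng.choice(bases, size=n))
        return cls(
            repeat_seq=mk(24),
            leader_seq=mk(100),
            backbone_spacers=[mk(37) for _ in range(6)],
            rng_seed=seed,
        )


def provenance_block(config: RunConfig) -> str:
    """Comment block stamped into text outputs: config hash + seed."""
    return f"# minicrkit config_hash={config.config_hash()} seed={config.rng_seed}\n"
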