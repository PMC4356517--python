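"""Persisted run configuration: one JSON document drives a reproducible
simulate → call → stats pipeline (all seeds explicit)."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import io as aio
from .cassette import (
    AluPair,
    AluSequence,
    IntervalMap,
    ReporterCassette,
    build_cassette,
    build_interval_map,
    generate_diverged_alu,
    synthetic_consensus,
)
from .simulate import MixturePreset


class ConfigError(ValueError):
    """Invalid run configuration (CLI exit code 2)."""


@dataclass
class RunConfig:
    """Everything needed to reproduce a simulated colony set byte-for-byte."""

    consensus_fasta: str | None = None
    consensus_length: int = 300
    consensus_seed: int = 101
    divergence_pct: float = 5.0
    divergence_mode: str = "evenly_spaced"
    divergence_seed: int = 202
    spacer_length: int = 1100
    promoter_length: int = 1200
    reporter_length: int = 600
    detectable_deletion_window: tuple[int, int] = (897, 1881)
    cassette_seed: int = 303
    p_single_crossover: float = 1.0
    p_complex_chimera: float = 0.0
    p_nhej: float = 0.0
    five_prime_bias_weight: float = 0.0
    microhomology_seeking: bool = False
    n_colonies: int = 100
    simulation_seed: int = 404
    segment_length: int = 100
    weighting: str = "per_interval"

    def __post_init__(self) -> None:
        if self.n_colonies < 1:
            raise ConfigError("n_colonies must be >= 1")
        if not 0 <= self.divergence_pct <= 100:
            raise ConfigError("divergence_pct must be in [0, 100]")
        if self.weighting not in ("per_interval", "per_bp"):
            raise ConfigError(f"unknown weighting {self.weighting!r}")
        if self.divergence_mode not in ("evenly_spaced", "random", "scrambled"):
            raise ConfigError(f"unknown divergence mode {self.divergence_mode!r}")
        self.detectable_deletion_window = tuple(self.detectable_deletion_window)

    def preset(self) -> MixturePreset:
        try:
            return MixturePreset(
                p_single_crossover=self.p_single_crossover,
                p_complex_chimera=self.p_complex_chimera,
                p_nhej=self.p_nhej,
                five_prime_bias_weight=self.five_prime_bias_weight,
                microhomology_seeking=self.microhomology_seeking,
            )
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        try:
            data = json.loads(Path(path).read_text())
            return cls(**data)
        except (TypeError, json.JSONDecodeError) as exc:
            raise ConfigError(f"bad config {path}: {exc}") from exc


def build_pair(config: RunConfig) -> AluPair:
    """Consensus + diverged copy, compared positionally (both are equal-length)."""
    if config.consensus_fasta:
        records = aio.read_fasta(config.consensus_fasta)
        if not records:
            raise ConfigError(f"no sequences in {config.consensus_fasta}")
        consensus = records[0]
    else:
        consensus = synthetic_consensus(config.consensus_length, config.consensus_seed)
    diverged = generate_diverged_alu(
        consensus, config.divergence_pct, config.divergence_mode, config.divergence_seed
    )
    return AluPair.from_ungapped(diverged, consensus)


def build_run(config: RunConfig) -> tuple[AluPair, ReporterCassette, IntervalMap]:
    pair = build_pair(config)
    cassette = build_cassette(
        pair,
        spacer_length=config.spacer_length,
        promoter_length=config.promoter_length,
        reporter_length=config.reporter_length,
        window=config.detectable_deletion_window,
        seed=config.cassette_seed,
    )
    interval_map = build_interval_map(pair, config.segment_length)
    return pair, cassette, interval_map
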