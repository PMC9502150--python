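"""Aligner configuration: one flat record of every tunable parameter.

Unknown keys are rejected so typos in YAML config files fail loudly.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import yaml

from .alignment import ScoringScheme
from .chaining import ChainingParams
from .pairing import PairingParams

__all__ = ["AlignConfig"]


@dataclasses.dataclass
class AlignConfig:
    # seeding
    skip: int = 1
    max_occs: int = 1000
    allow_high_multimappers: bool = False
    # chaining
    max_allowed_gap: int = 100
    chain_rounds: Optional[int] = 2
    consensus_fraction: float = 0.65
    subopt_fraction: float = 0.90
    # alignment
    match: int = 2
    mismatch: int = -4
    gap_open: int = -5
    gap_extend: int = -3
    min_score_fraction: float = 0.65
    cache_size: int = 10000
    allow_soft_clip: bool = False
    # pairing
    max_fragment_len: int = 1000
    library_orientation: str = "FR"
    allow_discordant: bool = False
    max_alignments_per_read: int = 20
    best_strata: bool = False

    def __post_init__(self):
        if self.skip < 1:
            raise ValueError("skip must be >= 1")
        if self.max_occs < 1:
            raise ValueError("max_occs must be >= 1")
        if not 0 <= self.min_score_fraction <= 1:
            raise ValueError("min_score_fraction must be in [0, 1]")
        if self.cache_size < 0:
            raise ValueError("cache_size must be >= 0")
        # delegate the rest to the component parameter records
        self.scoring()
        self.pairing_params()

    @classmethod
    def from_dict(cls, d: dict) -> "AlignConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path, overrides: Optional[dict] = None) -> "AlignConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ValueError(f"{path}: config file must contain a mapping")
        # YAML keys use the CLI spelling; accept both spellings
        aliases = {
            "consensusFraction": "consensus_fraction",
            "maxAllowedGap": "max_allowed_gap",
            "chainRounds": "chain_rounds",
            "suboptFraction": "subopt_fraction",
            "gapOpen": "gap_open",
            "gapExtend": "gap_extend",
            "minScoreFraction": "min_score_fraction",
            "cacheSize": "cache_size",
        }
        d = {aliases.get(key, key): v for key, v in d.items()}
        if overrides:
            d.update(overrides)
        return cls.from_dict(d)

    def scoring(self) -> ScoringScheme:
        return ScoringScheme(
            match=self.match,
            mismatch=self.mismatch,
            gap_open=self.gap_open,
            gap_extend=self.gap_extend,
        )

    def chaining_params(self, k: int) -> ChainingParams:
        return ChainingParams(
            max_allowed_gap=self.max_allowed_gap,
            h=self.chain_rounds,
            avg_seed_len=k,
            consensus_fraction=self.consensus_fraction,
            subopt_fraction=self.subopt_fraction,
        )

    def pairing_params(self) -> PairingParams:
        return PairingParams(
            max_fragment_len=self.max_fragment_len,
            library_orientation=self.library_orientation,
            allow_discordant=self.allow_discordant,
            max_alignments_per_read=self.max_alignments_per_read,
            best_strata=self.best_strata,
        )
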