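"""Protocol configuration: one YAML file describing a whole session setup.

The defaults reproduce the pilot protocol — two series of 21 targets at
a 5-second cadence (210 s), easy-level range of motion, lateral
inclination driving the horizontal axis and axial rotation unworked —
so an empty config (or a bare ``simulate``) runs the study's session
structure.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .engine import GameConfig
from .fusion import FusionParams
from .io import game_config_from_dict

__all__ = ["ProtocolConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class ProtocolConfig:
    """A validated run configuration: identifiers, game, fusion, output."""

    subject_id: str = "anonymous"
    session_id: str = "s1"
    out_dir: str = "sessions"
    game: GameConfig = field(default_factory=GameConfig)
    fusion: FusionParams = field(default_factory=FusionParams)

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "session_id": self.session_id,
            "out_dir": self.out_dir,
            "game": asdict(self.game),
            "fusion": asdict(self.fusion),
        }


def _from_dict(d: dict) -> ProtocolConfig:
    d = dict(d or {})
    unknown = set(d) - {"subject_id", "session_id", "out_dir", "game", "fusion"}
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    game = d.get("game", {})
    if not isinstance(game, GameConfig):
        try:
            game = game_config_from_dict(game)
        except TypeError as exc:
            raise ValueError(f"invalid game config: {exc}") from exc
    fusion = d.get("fusion", {})
    if not isinstance(fusion, FusionParams):
        unknown = set(fusion) - set(FusionParams.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown fusion keys: {sorted(unknown)}")
        fusion = FusionParams(**fusion)
    return ProtocolConfig(
        subject_id=str(d.get("subject_id", "anonymous")),
        session_id=str(d.get("session_id", "s1")),
        out_dir=str(d.get("out_dir", "sessions")),
        game=game,
        fusion=fusion,
    )


def load_config(path) -> ProtocolConfig:
    """Read and validate a YAML protocol config.

    Unknown keys are rejected with a field-level message; value
    violations surface the dataclass validation errors.
    """
    text = Path(path).read_text()
    try:
        payload = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ValueError(f"cannot parse config {path}: {exc}") from exc
    if payload is None:
        payload = {}
    if not isinstance(payload, dict):
        raise ValueError("config root must be a mapping")
    return _from_dict(payload)


def save_config(cfg: ProtocolConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
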