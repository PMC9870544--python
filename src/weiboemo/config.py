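"""Run configuration shared by the CLI stages."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .core import DEFAULT_SEPARATORS

__all__ = ["RunConfig", "output_meta"]


@dataclass
class RunConfig:
    """Paths and parameters for a pipeline run.

    Unset lexicon/modifier/stopword paths fall back to the packaged defaults.
    """

    lexicon_path: str | None = None
    degree_path: str | None = None
    negation_path: str | None = None
    stopword_path: str | None = None
    official_keywords_path: str | None = None
    delta: float = 0.5
    separators: str = "".join(sorted(DEFAULT_SEPARATORS))
    window: int = 3
    seed: int = 0
    ndigits: int = 2
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.window < 0:
            raise ValueError("window must be nonnegative")
        for name in (
            "lexicon_path",
            "degree_path",
            "negation_path",
            "stopword_path",
            "official_keywords_path",
        ):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} does not exist: {p}")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load YAML or JSON config; keyword overrides win over file values."""
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in data.items() if k in known}
        kwargs["extra"] = {k: v for k, v in data.items() if k not in known}
        kwargs.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**kwargs)

    def digest(self) -> str:
        """Stable short hash of the configuration, embedded in outputs."""
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def output_meta(config: RunConfig) -> dict:
    """Provenance block every artifact embeds."""
    return {"tool_version": __version__, "config_hash": config.digest()}
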