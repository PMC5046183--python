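"""Run configuration: every tunable of the detection pipeline in one place.

Defaults follow the published operating point for ~0.25 um/pixel tiles:
voting range r_min = 1, r_max = 40 px, kernel sigma = 4 px, 3 voting
passes, 15 px matching radius, threshold-sweep step 0.05. Config files are
flat ``key = value`` text; unknown keys are rejected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import List, Optional

__all__ = ["RunConfig"]


def _parse_value(key: str, raw: str):
    raw = raw.strip()
    if raw.lower() in ("none", ""):
        return None
    if raw.lower() in ("true", "false"):
        return raw.lower() == "true"
    if key == "vote.schedule":
        return [float(x) for x in raw.strip("[]").split(",") if x.strip()]
    try:
        f = float(raw)
        return int(f) if f.is_integer() and "." not in raw and "e" not in raw.lower() else f
    except ValueError:
        return raw


@dataclass
class RunConfig:
    # channel selection
    channel_mode: str = "red"  # red | luminance | snmf
    channel_stain_index: int = 0
    channel_invert: bool = False
    snmf_sparsity: float = 0.1
    snmf_seed: int = 0
    # preprocessing
    preprocess_sigma_gau: float = 1.5
    canny_low: float = 0.1
    canny_high: float = 0.3
    canny_sigma: float = 1.0
    # refinement
    refine_strategy: str = "gs2"  # none | gs1 | gs2
    refine_theta_max: float = math.pi / 2
    refine_min_fragment_size: int = 1
    # voting
    vote_r_min: float = 1.0
    vote_r_max: float = 40.0
    vote_sigma: float = 4.0
    vote_sigma_radial: Optional[float] = None  # None -> (r_max - r_min) / 4
    vote_n_passes: int = 3
    vote_delta_max: float = math.pi / 4
    vote_schedule: Optional[List[float]] = None
    vote_mode: str = "mpv"  # spv (single pass) | mpv
    # seeds / evaluation
    seeds_min_area: int = 1
    eval_radius_px: float = 15.0
    eval_grid_step: float = 0.05

    _KEYMAP = None  # class-level cache, filled lazily

    @classmethod
    def _keymap(cls) -> dict:
        if cls._KEYMAP is None:
            cls._KEYMAP = {
                f.name.replace("_", ".", 1): f.name
                for f in fields(cls)
                if not f.name.startswith("_")
            }
        return cls._KEYMAP

    def validate(self) -> "RunConfig":
        if self.channel_mode not in ("red", "luminance", "snmf"):
            raise ValueError(f"unknown channel.mode {self.channel_mode!r}")
        if self.refine_strategy not in ("none", "gs1", "gs2"):
            raise ValueError(f"unknown refine.strategy {self.refine_strategy!r}")
        if self.vote_mode not in ("spv", "mpv"):
            raise ValueError(f"unknown vote.mode {self.vote_mode!r}")
        return self

    def n_passes(self) -> int:
        """Effective pass count: single-pass voting is the n = 1 special case."""
        return 1 if self.vote_mode == "spv" else self.vote_n_passes

    # ---- flat key=value serialisation -------------------------------------
    def set(self, key: str, value) -> None:
        km = self._keymap()
        if key not in km:
            raise ValueError(f"unknown config key {key!r}")
        if isinstance(value, str):
            value = _parse_value(key, value)
        setattr(self, km[key], value)

    def to_dict(self) -> dict:
        return {k: getattr(self, attr) for k, attr in self._keymap().items()}

    def to_text(self) -> str:
        lines = []
        for k, v in self.to_dict().items():
            if isinstance(v, list):
                v = "[" + ", ".join(str(x) for x in v) + "]"
            lines.append(f"{k} = {v}")
        return "\n".join(lines) + "\n"

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_text())

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        cfg = cls()
        unknown = []
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"malformed config line: {line!r}")
                key, raw = (s.strip() for s in line.split("=", 1))
                try:
                    cfg.set(key, raw)
                except ValueError:
                    unknown.append(key)
        if unknown:
            raise ValueError(f"unknown config keys: {', '.join(sorted(unknown))}")
        return cfg.validate()
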