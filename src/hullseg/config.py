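"""Run configuration: a human-readable TOML file that round-trips
bit-exactly.

The configuration carries everything needed to reproduce a run across a
larger image set: hull vertices/alpha/delta, prior vertices, segmentation
post-processing, layout detection parameters (or a fixed layout), scale
and time metadata.  Floats are written with ``repr``, which round-trips
every IEEE double exactly through decimal text.
"""

from __future__ import annotations

import re
import tomllib
from dataclasses import dataclass, field, asdict
from pathlib import Path

__all__ = ["LayoutConfig", "RunConfig", "load_config", "save_config"]

_REQUIRED = ("hull",)


@dataclass
class LayoutConfig:
    """Circle-detection parameters, or a fixed layout bypassing detection.

    ``fixed`` is a list of (unit_index, row, col, radius[, group]) tuples;
    when present, detection is skipped entirely.
    """

    r_min: int = 10
    r_max: int = 30
    expected_n: int = 0  # 0 = no layout: whole frame is one unit
    cut_distance: float = 200.0
    ordering: str = "row-major"
    dilation: float = 0.0
    fixed: list | None = None


@dataclass
class RunConfig:
    images: str = ""  # glob or directory
    time_regex: str = r"(?P<ts>\d{8}_\d{6})"
    time_format: str = "%Y%m%d_%H%M%S"
    vertices: list = field(default_factory=list)  # hull vertices, [L,a,b]
    priors: list = field(default_factory=list)
    alpha: float = 0.0
    delta: float = 5.0
    min_pixels: int = 20
    fill_area: int = 0
    remove_area: int = 0
    layout: LayoutConfig = field(default_factory=LayoutConfig)
    scale: float | None = None  # physical length per pixel
    background_cuboid: list | None = None  # [[Lmin,amin,bmin],[Lmax,amax,bmax]]
    out_dir: str = "results"
    debug: bool = False
    overlay_color: list = field(default_factory=lambda: [255, 0, 255])

    def hull_spec(self):
        from .hull import HullSpec, merge_priors

        verts = merge_priors(self.vertices, self.priors)
        return HullSpec(vertices=verts, alpha=self.alpha, delta=self.delta)


def _fmt(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)
    if isinstance(value, int):
        return str(value)
    if isinstance(value, str):
        return '"' + value.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(value, (list, tuple)):
        return "[" + ", ".join(_fmt(v) for v in value) + "]"
    raise TypeError(f"cannot serialize {type(value)}")


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write the configuration as TOML (None fields omitted)."""
    lines = ["# hullseg run configuration", ""]
    d = asdict(config)
    layout = d.pop("layout")
    for key, value in d.items():
        if value is None:
            continue
        lines.append(f"{key} = {_fmt(value)}")
    lines.append("")
    lines.append("[layout]")
    for key, value in layout.items():
        if value is None:
            continue
        lines.append(f"{key} = {_fmt(value)}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_config(path: str | Path) -> RunConfig:
    """Parse a TOML configuration, validating structure.

    Missing required sections are reported by name; malformed vertex
    triples are reported with their position in the list.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    for key in ("vertices", "priors"):
        for i, v in enumerate(data.get(key, [])):
            if not (isinstance(v, (list, tuple)) and len(v) == 3):
                raise ValueError(
                    f"{path}: {key}[{i}] is not an L,a,b triple: {v!r}"
                )
    layout = LayoutConfig(**data.pop("layout", {}))
    known = {f for f in RunConfig.__dataclass_fields__} - {"layout"}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"{path}: unknown keys: {sorted(unknown)}")
    cfg = RunConfig(layout=layout, **data)
    return cfg


def apply_overrides(config: RunConfig, **overrides) -> RunConfig:
    """Apply command-line overrides; hull vertices given on the command
    line merge into the priors rather than replacing the file's set."""
    cli_vertices = overrides.pop("vertices", None)
    for key, value in overrides.items():
        if value is None:
            continue
        if not hasattr(config, key):
            raise ValueError(f"unknown config field {key!r}")
        setattr(config, key, value)
    if cli_vertices:
        config.priors = config.priors + [list(map(float, v)) for v in cli_vertices]
    return config


def parse_vertex(text: str) -> list[float]:
    """Parse a command-line 'L,a,b' triple."""
    parts = re.split(r"[,\s]+", text.strip())
    if len(parts) != 3:
        raise ValueError(f"vertex must be 'L,a,b', got {text!r}")
    return [float(p) for p in parts]
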