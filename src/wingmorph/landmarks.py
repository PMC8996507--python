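"""Landmark configurations and their file formats (TPS, CSV)."""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .template import ANCHOR_INDICES, N_POINTS, wing_template


@dataclass
class LandmarkConfiguration:
    """One specimen's ordered 2D point configuration with role tags.

    ``roles`` distinguishes vein landmarks from outline semilandmarks and
    ``zones`` records which of the five outline zones a semilandmark belongs
    to (0 for landmarks).
    """

    coords: np.ndarray                      # (k, 2)
    roles: np.ndarray | None = None         # 'landmark' / 'semilandmark'
    zones: np.ndarray | None = None
    wing_type: str = "forewing"
    metadata: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be a (k, 2) array")
        if self.roles is None or self.zones is None:
            tpl = wing_template(self.wing_type)
            if len(self.coords) == N_POINTS:
                self.roles = tpl.roles.copy() if self.roles is None else self.roles
                self.zones = tpl.zones.copy() if self.zones is None else self.zones

    @property
    def n_points(self) -> int:
        return len(self.coords)

    def centroid_size(self) -> float:
        c = self.coords - self.coords.mean(axis=0)
        return float(np.sqrt((c ** 2).sum()))


def write_tps(path: str | Path, configs: Iterable[LandmarkConfiguration]) -> None:
    """Write configurations in the TPS landmark exchange format."""
    lines = []
    for i, cfg in enumerate(configs):
        lines.append(f"LM={cfg.n_points}")
        for x, y in cfg.coords:
            lines.append(f"{x:.10f} {y:.10f}")
        ident = cfg.metadata.get("id", f"specimen_{i}")
        lines.append(f"ID={ident}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_tps(path: str | Path, wing_type: str = "forewing") -> list[LandmarkConfiguration]:
    """Read a TPS file (LM=, coordinate rows, ID= records)."""
    configs: list[LandmarkConfiguration] = []
    coords: list[list[float]] = []
    expected = 0
    ident = None
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        upper = line.upper()
        if upper.startswith("LM="):
            expected = int(line.split("=", 1)[1])
            coords = []
            ident = None
        elif upper.startswith("ID="):
            ident = line.split("=", 1)[1]
            if len(coords) != expected:
                raise ValueError(
                    f"TPS record {ident!r}: expected {expected} points, got {len(coords)}")
            configs.append(LandmarkConfiguration(
                np.array(coords), wing_type=wing_type, metadata={"id": ident}))
        elif upper.startswith(("SCALE=", "IMAGE=")):
            continue
        else:
            parts = line.split()
            coords.append([float(parts[0]), float(parts[1])])
    return configs


def configs_to_frame(configs: Sequence[LandmarkConfiguration]) -> pd.DataFrame:
    """Long-format CSV table: one row per point per specimen."""
    rows = []
    for i, cfg in enumerate(configs):
        ident = cfg.metadata.get("id", f"specimen_{i}")
        for j, (x, y) in enumerate(cfg.coords):
            rows.append({
                "specimen": ident, "point": j, "x": x, "y": y,
                "role": None if cfg.roles is None else cfg.roles[j],
                "zone": None if cfg.zones is None else int(cfg.zones[j]),
            })
    return pd.DataFrame(rows)


def write_csv(path: str | Path, configs: Sequence[LandmarkConfiguration]) -> None:
    configs_to_frame(configs).to_csv(path, index=False)


def read_csv(path: str | Path, wing_type: str = "forewing") -> list[LandmarkConfiguration]:
    df = pd.read_csv(path)
    configs = []
    for ident, grp in df.groupby("specimen", sort=False):
        grp = grp.sort_values("point")
        configs.append(LandmarkConfiguration(
            grp[["x", "y"]].to_numpy(), wing_type=wing_type,
            metadata={"id": ident}))
    return configs


def stack_coords(configs: Sequence[LandmarkConfiguration]) -> np.ndarray:
    """(n, k, 2) coordinate array from a list of configurations."""
    arr = np.stack([c.coords for c in configs])
    return arr
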