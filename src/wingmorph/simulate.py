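"""Synthetic wing data with the statistical structure the analyses assume.

The generator states a small world modelled on a museum-scale comparative
study of libellulid dragonflies:

* ~27 species with ~10 specimens each, two wing types per specimen;
* species mean shapes evolving by Brownian motion on a pure-birth ultrametric
  tree of depth 10 time units;
* two binary habitat factors — landscape (open/forested) and hunting
  water body (running/standing) — with the landscape factor laid out as
  phylogenetic grades (latent Brownian trait, median split) and the water
  factor copied from it with probability equal to the configured
  concordance (default 0.75);
* a habitat-linked shape effect: open-landscape species are deformed along a
  fixed "narrowing + anal-corner" displacement template, forested species
  along its negation;
* within-species coordinate noise, and (optionally) a proximal pigment patch
  on the wings of standing-water species, emulating the association between
  proximal pigmentation and temporary/standing-water habits.

Everything is deterministic for a given :class:`SimulationConfig` seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Polygon
from skimage.draw import line as draw_line
from skimage.draw import polygon as draw_polygon

from .images import WingImage, default_frame
from .landmarks import LandmarkConfiguration
from .outlines import OutlineTrace
from .template import (ANCHOR_INDICES, NARROWING_TEMPLATE, N_BOUNDARY,
                       N_POINTS, VEIN_EDGES, _ANCHOR_THETA, outline_points,
                       wing_template)
from .trees import Phylogeny, phylo_covariance, simulate_tree


class LabelledDataError(ValueError):
    """Raised when specimen labels are missing or inconsistent."""


class RenderError(ValueError):
    """Raised when a configuration cannot be rendered (degenerate outline)."""


@dataclass
class SimulationConfig:
    """Stated world of the synthetic generator (see module docstring)."""

    n_species: int = 27
    n_per_species: int = 10
    tree_depth: float = 10.0
    bm_sigma2: float = 2.5e-6           # per coordinate per time unit
    habitat_effect_size: float = 0.01   # x unit-max template, wing length 1
    habitat_concordance: float = 0.75
    within_species_sd: float = 0.005
    pigment_intensity_range: tuple[float, float] = (40.0, 100.0)
    frame_forewing: tuple[int, int] = (200, 56)
    frame_hindwing: tuple[int, int] = (200, 81)
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if not 0.0 <= self.habitat_concordance <= 1.0:
            raise ValueError("habitat_concordance must lie in [0, 1]")
        if min(self.frame_forewing) <= 0 or min(self.frame_hindwing) <= 0:
            raise ValueError("frames must be positive")
        if self.tree_depth <= 0:
            raise ValueError("tree_depth must be positive")

    def frame(self, wing_type: str) -> tuple[int, int]:
        return self.frame_forewing if wing_type == "forewing" else self.frame_hindwing


@dataclass
class HabitatTable:
    """Species -> (landscape, water body) assignment."""

    table: pd.DataFrame    # index species; columns landscape, water_body

    def __post_init__(self):
        missing = self.table[["landscape", "water_body"]].isna().any(axis=1)
        if missing.any():
            raise LabelledDataError(
                f"species missing habitat labels: {list(self.table.index[missing])}")

    def landscape(self, species: str) -> str:
        return str(self.table.loc[species, "landscape"])

    def water_body(self, species: str) -> str:
        return str(self.table.loc[species, "water_body"])

    def concordant_fraction(self) -> float:
        """Fraction of species with the concordant pairing
        (forested & running) or (open & standing)."""
        t = self.table
        conc = (((t.landscape == "forested") & (t.water_body == "running"))
                | ((t.landscape == "open") & (t.water_body == "standing")))
        return float(conc.mean())

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index_label="species")

    @classmethod
    def from_csv(cls, path: str | Path) -> "HabitatTable":
        return cls(pd.read_csv(path, index_col="species"))


def simulate_bm_traits(phylogeny: Phylogeny, sigma2: float, p_dims: int,
                       seed: int | None = None,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """Brownian-motion tip values: each trait ~ MVN(0, sigma2 * C), the root
    value fixed at 0.  Rows follow ``phylogeny.tip_names``."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    C = phylo_covariance(phylogeny).C
    # C is PSD; tiny jitter guards the factorization near singularity
    L = np.linalg.cholesky(C + 1e-12 * np.eye(len(C)))
    return np.sqrt(sigma2) * (L @ rng.standard_normal((len(C), p_dims)))


def assign_habitats(phylogeny: Phylogeny, concordance: float = 0.75,
                    seed: int | None = None,
                    rng: np.random.Generator | None = None) -> HabitatTable:
    """Landscape from a latent Brownian trait split at its median (so labels
    form phylogenetic grades); water body copied from the concordant pairing
    with probability ``concordance``, flipped otherwise."""
    if rng is None:
        rng = np.random.default_rng(seed)
    latent = simulate_bm_traits(phylogeny, 1.0, 1, rng=rng)[:, 0]
    open_mask = latent >= np.median(latent)
    landscape = np.where(open_mask, "open", "forested")
    concordant = np.where(open_mask, "standing", "running")
    flipped = np.where(open_mask, "running", "standing")
    keep = rng.random(len(latent)) < concordance
    water = np.where(keep, concordant, flipped)
    return HabitatTable(pd.DataFrame(
        {"landscape": landscape, "water_body": water},
        index=pd.Index(phylogeny.tip_names, name="species")))


def generate_specimens(phylogeny: Phylogeny, habitat_table: HabitatTable,
                       config: SimulationConfig, wing_type: str = "forewing",
                       rng: np.random.Generator | None = None,
                       ) -> tuple[list[LandmarkConfiguration], pd.DataFrame]:
    """Specimen-level 38-point configurations plus a label table.

    specimen shape = species BM mean
                     + (sign by landscape) * habitat_effect_size * template
                     + N(0, within_species_sd^2) coordinate noise
    """
    missing = [sp for sp in phylogeny.tip_names
               if sp not in habitat_table.table.index]
    if missing:
        raise LabelledDataError(f"habitat table missing species: {missing}")
    if rng is None:
        rng = np.random.default_rng([config.seed, 2])
    tpl = wing_template(wing_type)
    bm = simulate_bm_traits(phylogeny, config.bm_sigma2, 2 * N_POINTS, rng=rng)
    configs: list[LandmarkConfiguration] = []
    rows = []
    for i, sp in enumerate(phylogeny.tip_names):
        mean = tpl.base_config + bm[i].reshape(N_POINTS, 2)
        sign = 1.0 if habitat_table.landscape(sp) == "open" else -1.0
        for j in range(config.n_per_species):
            noise = rng.normal(0.0, config.within_species_sd, (N_POINTS, 2)) \
                if config.within_species_sd > 0 else 0.0
            coords = mean + sign * config.habitat_effect_size * NARROWING_TEMPLATE + noise
            ident = f"{sp}_{wing_type[0]}{j + 1:02d}"
            meta = {"id": ident, "species": sp, "wing_type": wing_type,
                    "landscape": habitat_table.landscape(sp),
                    "water_body": habitat_table.water_body(sp)}
            configs.append(LandmarkConfiguration(
                coords=coords, roles=tpl.roles.copy(), zones=tpl.zones.copy(),
                wing_type=wing_type, metadata=meta))
            rows.append(meta)
    labels = pd.DataFrame(rows).set_index("id")
    return configs, labels


def specimen_outline(config: LandmarkConfiguration, n_dense: int = 480) -> OutlineTrace:
    """Dense, smooth outline consistent with a specimen's boundary points.

    The 31 boundary points' displacements from the reference outline are
    interpolated (periodically in the outline parameter) onto a dense
    parameter grid that contains the six anchors exactly, so the trace passes
    through every boundary landmark/semilandmark of the configuration.
    """
    tpl = wing_template(config.wing_type)
    disp = config.coords[:N_BOUNDARY] - tpl.base_config[:N_BOUNDARY]
    spans = np.diff(_ANCHOR_THETA)
    alloc = np.maximum(3, np.round(n_dense * spans / spans.sum()).astype(int))
    thetas = []
    anchor_pos = []
    for k in range(5):
        anchor_pos.append(sum(len(t) for t in thetas))
        thetas.append(np.linspace(_ANCHOR_THETA[k], _ANCHOR_THETA[k + 1],
                                  alloc[k], endpoint=False))
    anchor_pos.append(sum(len(t) for t in thetas))
    theta = np.concatenate(thetas + [np.array([_ANCHOR_THETA[-1]])])
    base = outline_points(config.wing_type, theta)
    bt = tpl.boundary_theta
    dx = np.interp(theta, bt, disp[:, 0])
    dy = np.interp(theta, bt, disp[:, 1])
    boundary = base + np.column_stack([dx, dy])
    # straight root (attachment) edge closing the outline
    root = np.linspace(boundary[-1], boundary[0], 8)[1:-1]
    boundary = np.vstack([boundary, root])
    return OutlineTrace(boundary=boundary, anchor_indices=np.array(anchor_pos),
                        metadata=dict(config.metadata))


def render_wing_image(config: LandmarkConfiguration,
                      frame: tuple[int, int] | None = None,
                      pigment_intensity: float = 0.0) -> WingImage:
    """Render a configuration as an 8-bit greyscale wing image.

    A filled mid-grey wing polygon with darker vein polylines on a white
    (255) background, plus an optional darkened proximal pigment patch.
    Output dimensions equal ``frame`` exactly (width, height); origin
    top-left, row-major.
    """
    if frame is None:
        frame = default_frame(config.wing_type)
    w, h = frame
    if w <= 0 or h <= 0:
        raise ValueError("frame dimensions must be positive")
    trace = specimen_outline(config)
    poly = Polygon(trace.boundary)
    boundary = trace.boundary
    if not poly.is_valid or poly.area <= 0:
        # coordinate noise can fold the outline microscopically at the wing
        # tip; repair hairline folds, but refuse genuinely crossed outlines
        fixed = poly.buffer(0)
        lobes = list(fixed.geoms) if fixed.geom_type == "MultiPolygon" else [fixed]
        total = sum(g.area for g in lobes)
        largest = max(lobes, key=lambda g: g.area, default=None)
        if largest is None or total <= 0 or largest.area < 0.99 * total:
            raise RenderError("degenerate (self-intersecting) wing outline")
        boundary = np.asarray(largest.exterior.coords)[:-1]

    pts = np.vstack([boundary, config.coords[N_BOUNDARY:]])
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    margin = 3.0
    scale = min((w - 2 * margin) / (hi[0] - lo[0]), (h - 2 * margin) / (hi[1] - lo[1]))

    def to_px(xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(xy)
        col = margin + (xy[:, 0] - lo[0]) * scale
        row = margin + (hi[1] - xy[:, 1]) * scale  # flip y: origin top-left
        off_c = (w - 2 * margin - (hi[0] - lo[0]) * scale) / 2
        off_r = (h - 2 * margin - (hi[1] - lo[1]) * scale) / 2
        return np.column_stack([row + off_r, col + off_c])

    canvas = np.full((h, w), 255.0)
    bpx = to_px(boundary)
    rr, cc = draw_polygon(bpx[:, 0], bpx[:, 1], shape=canvas.shape)
    canvas[rr, cc] = 170.0
    wing_mask = np.zeros_like(canvas, dtype=bool)
    wing_mask[rr, cc] = True

    if pigment_intensity > 0:
        # proximal patch, posterior of the wing's long axis
        span = hi - lo
        center = to_px(np.array([lo[0] + 0.18 * span[0], lo[1] + 0.35 * span[1]]))[0]
        rgrid, cgrid = np.mgrid[0:h, 0:w]
        rx = 0.11 * span[0] * scale
        ry = 0.35 * span[1] * scale
        patch = (((rgrid - center[0]) / max(ry, 1.0)) ** 2
                 + ((cgrid - center[1]) / max(rx, 1.0)) ** 2) <= 1.0
        sel = patch & wing_mask
        canvas[sel] = np.clip(canvas[sel] - pigment_intensity, 0, 255)

    cpx = to_px(config.coords)
    for a, b in VEIN_EDGES:
        r0, c0 = np.rint(cpx[a]).astype(int)
        r1, c1 = np.rint(cpx[b]).astype(int)
        rr, cc = draw_line(r0, c0, r1, c1)
        keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        canvas[rr[keep], cc[keep]] = 80.0
    closed = np.vstack([bpx, bpx[0]])
    for k in range(len(closed) - 1):
        r0, c0 = np.rint(closed[k]).astype(int)
        r1, c1 = np.rint(closed[k + 1]).astype(int)
        rr, cc = draw_line(r0, c0, r1, c1)
        keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        canvas[rr[keep], cc[keep]] = 60.0

    meta = dict(config.metadata)
    meta["pigment_intensity"] = float(pigment_intensity)
    return WingImage(pixels=np.clip(np.rint(canvas), 0, 255).astype(np.uint8),
                     frame=frame, wing_type=config.wing_type, metadata=meta)


@dataclass
class SimulatedDataset:
    """Everything the downstream analyses consume, for one simulated world."""

    config: SimulationConfig
    phylogeny: Phylogeny
    habitats: HabitatTable
    configurations: dict = field(default_factory=dict)   # wing -> [LandmarkConfiguration]
    labels: dict = field(default_factory=dict)           # wing -> DataFrame
    images: dict = field(default_factory=dict)           # wing -> [WingImage]


def simulate_dataset(config: SimulationConfig,
                     wings: tuple[str, ...] = ("forewing", "hindwing"),
                     render: bool = True) -> SimulatedDataset:
    """Simulate a full dataset: tree, habitats, landmark configurations and
    (optionally) rendered wing images.  Bitwise deterministic given the
    config seed."""
    tree = simulate_tree(config.n_species, config.tree_depth,
                         seed=np.random.default_rng([config.seed, 0]).integers(2 ** 31))
    habitats = assign_habitats(tree, config.habitat_concordance,
                               rng=np.random.default_rng([config.seed, 1]))
    ds = SimulatedDataset(config=config, phylogeny=tree, habitats=habitats)
    for wi, wing in enumerate(wings):
        rng = np.random.default_rng([config.seed, 2 + wi])
        configs, labels = generate_specimens(tree, habitats, config, wing, rng=rng)
        ds.configurations[wing] = configs
        ds.labels[wing] = labels
        if render:
            prng = np.random.default_rng([config.seed, 10 + wi])
            lo, hi = config.pigment_intensity_range
            imgs = []
            for cfg in configs:
                pig = 0.0
                if cfg.metadata["water_body"] == "standing" and hi > 0:
                    pig = float(prng.uniform(lo, hi))
                imgs.append(render_wing_image(cfg, config.frame(wing), pig))
            ds.images[wing] = imgs
    return ds
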