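"""Seeded synthetic leaf data emulating the field study design.

The original leaf scans behind the model are not deposited, so every test
and example in this package runs on synthetic material generated here:
model-true Gielis outlines perturbed by multiplicative radial measurement
noise and an optional one-sided basal/lateral bulge (a controlled,
parameterized violation of bilateral symmetry used for power testing);
Weibull-distributed leaf-length populations per species; rasterized
scan-like binary masks; and multi-species panels that mirror the sampling
protocol — measure a large length sample per species, pick the leaves
nearest the median length, digitize those.

Everything is driven by a single master seed.  Per-species and per-leaf
generators are derived with ``numpy.random.SeedSequence(master,
spawn_key=(species_index, leaf_index))``, so any leaf can be regenerated
in isolation and identical configurations yield byte-identical manifests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .extraction import LeafImage
from .geometry import (
    TWO_PI,
    BoundaryCurve,
    GielisParams,
    PoseParams,
    _radius_raw,
    leaf_length,
)
from .popstats import select_representative

__all__ = [
    "SpeciesSpec",
    "SynthConfig",
    "sample_lengths",
    "make_leaf",
    "render_mask",
    "make_species_panel",
    "scale_from_target_length",
]


@dataclass(frozen=True)
class SpeciesSpec:
    """True parameters of one synthetic species.

    ``n`` is the leaf-shape parameter shared by all leaves of the species;
    ``weibull_k``/``weibull_lam`` give the species' leaf-length
    distribution (shape, scale in cm).
    """

    species_id: str
    n: float
    weibull_k: float = 2.0
    weibull_lam: float = 15.0

    def __post_init__(self) -> None:
        if self.n <= 0 or self.weibull_k <= 0 or self.weibull_lam <= 0:
            raise ValueError("n, weibull_k, weibull_lam must all be positive")


@dataclass(frozen=True)
class SynthConfig:
    """Study-design configuration for a synthetic multi-species panel.

    Defaults mirror the field protocol the generator emulates: 500
    measured lengths per species, of which the 30 leaves nearest the
    median length are digitized; small multiplicative radial measurement
    noise; no built-in asymmetry.
    """

    species: tuple[SpeciesSpec, ...]
    seed: int = 0
    lengths_per_species: int = 500
    leaves_per_species: int = 30
    noise_sd: float = 0.005
    asymmetry: float = 0.0
    asymmetry_arc: tuple[float, float] = (np.pi / 4, 3 * np.pi / 4)
    num_points: int = 2000
    pose_xy_range: float = 5.0
    pose_theta_range: float = np.pi
    render: bool = False
    render_scale: float = 2.54 / 300  # cm/px, a 300-dpi scan

    def __post_init__(self) -> None:
        if len(self.species) == 0:
            raise ValueError("at least one species is required")
        if self.leaves_per_species < 1:
            raise ValueError("leaves_per_species must be >= 1")
        if self.leaves_per_species > self.lengths_per_species:
            raise ValueError("cannot digitize more leaves than were measured")
        if self.noise_sd < 0 or self.asymmetry < 0:
            raise ValueError("noise_sd and asymmetry must be nonnegative")

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        d = dict(d)
        species = tuple(SpeciesSpec(**s) for s in d.pop("species"))
        if "asymmetry_arc" in d:
            d["asymmetry_arc"] = tuple(d["asymmetry_arc"])
        return cls(species=species, **d)


def sample_lengths(k: float, lam: float, count: int, seed) -> np.ndarray:
    """I.i.d. Weibull(shape k, scale lam) leaf lengths, deterministic per seed."""
    if k <= 0 or lam <= 0:
        raise ValueError("Weibull shape and scale must be positive")
    rng = np.random.default_rng(seed)
    return lam * rng.weibull(k, size=int(count))


def scale_from_target_length(target_length: float, n: float) -> float:
    """Invert the length identity: the ``l`` whose modeled blade has
    tip-to-base length ``target_length``, i.e. ``l = L / (1 + 2^(-1/(2n)))``."""
    return target_length / (1.0 + 2.0 ** (-1.0 / (2.0 * n)))


def _bump(phi: np.ndarray, arc: tuple[float, float]) -> np.ndarray:
    """Raised-cosine window on the arc, restricted to the phi > 0 side."""
    lo, hi = arc
    if not 0.0 <= lo < hi <= np.pi:
        raise ValueError("asymmetry arc must satisfy 0 <= lo < hi <= pi")
    center, width = 0.5 * (lo + hi), hi - lo
    w = 0.5 * (1.0 + np.cos(TWO_PI * (phi - center) / (2 * width)))
    return np.where((phi > lo) & (phi < hi) & (phi > 0), w, 0.0)


def make_leaf(
    params: GielisParams,
    pose: PoseParams | None = None,
    noise_sd: float = 0.0,
    asymmetry: float = 0.0,
    asymmetry_arc: tuple[float, float] = (np.pi / 4, 3 * np.pi / 4),
    num_points: int = 2000,
    seed=None,
) -> BoundaryCurve:
    """One synthetic digitized leaf outline.

    Radii are perturbed multiplicatively, ``r_i = r(phi_i) (1 + eps_i) +
    delta * l * bump(phi_i)`` with ``eps_i ~ N(0, noise_sd^2)`` and
    ``bump`` a raised-cosine window over ``asymmetry_arc`` on the
    ``phi > 0`` side only — a smooth one-sided violation of the model's
    mirror symmetry with amplitude ``asymmetry`` (as a fraction of l).
    The pose is applied last.
    """
    if noise_sd < 0 or asymmetry < 0:
        raise ValueError("noise_sd and asymmetry must be nonnegative")
    phi = -np.pi + TWO_PI * np.arange(num_points) / num_points
    r = _radius_raw(phi, params.l, params.n)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        r = r * (1.0 + rng.normal(0.0, noise_sd, size=num_points))
    if asymmetry > 0:
        r = r + asymmetry * params.l * _bump(phi, asymmetry_arc)
    if np.any(r <= 0):
        raise ValueError("noise drove a radius non-positive; reduce noise_sd")
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi)])
    curve = BoundaryCurve(pts, units="cm", closed=True)
    if pose is not None:
        from .fitting import apply_pose

        curve = apply_pose(curve, pose)
    return curve


def _fill_polygon(rows: np.ndarray, cols: np.ndarray, shape) -> np.ndarray:
    """Even-odd scanline fill: a pixel is foreground iff its *center* lies
    inside the polygon.  Center-based filling keeps the rasterized area
    unbiased (no half-pixel dilation), which the sub-pixel extraction
    round trip relies on.  Vectorized over edges x scanlines."""
    height, width = shape
    r0, c0 = rows, cols
    r1, c1 = np.roll(rows, -1), np.roll(cols, -1)
    yc = np.arange(height, dtype=float)  # pixel-center row coordinates
    crosses = (r0[:, None] <= yc) != (r1[:, None] <= yc)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (yc - r0[:, None]) / (r1 - r0)[:, None]
    xc = c0[:, None] + t * (c1 - c0)[:, None]
    edge_idx, row_idx = np.nonzero(crosses)
    x_at = xc[edge_idx, row_idx]
    start = np.clip(np.ceil(x_at).astype(int), 0, width)
    delta = np.zeros((height, width + 1), dtype=int)
    np.add.at(delta, (row_idx, start), 1)
    return (np.cumsum(delta[:, :-1], axis=1) % 2).astype(bool)


def render_mask(
    curve: BoundaryCurve, scale: float, margin_px: int = 2
) -> LeafImage:
    """Rasterize a closed boundary into a scan-like binary mask.

    The curve is placed with a ``margin_px`` background margin; pixel
    (row, col) maps to physical coordinates consistent with
    :func:`gielisleaf.extraction.extract_boundary` (y up, origin at the
    image's lower-left pixel center).
    """
    if scale <= 0:
        raise ValueError("scale (cm/px) must be positive")
    from .geometry import shoelace_area

    if shoelace_area(curve) == 0.0:
        raise ValueError("degenerate zero-area curve")
    x, y = curve.x, curve.y
    cols = (x - x.min()) / scale + margin_px
    rows_up = (y - y.min()) / scale + margin_px
    height = int(np.ceil(rows_up.max())) + margin_px + 1
    width = int(np.ceil(cols.max())) + margin_px + 1
    rows = (height - 1) - rows_up  # flip to image convention
    mask = _fill_polygon(rows, cols, (height, width))
    if not mask.any():
        raise ValueError("curve rasterized to an empty mask; check scale")
    return LeafImage(mask.astype(float), scale)


def _leaf_seed(master_seed: int, species_idx: int, leaf_idx: int):
    return np.random.SeedSequence(master_seed, spawn_key=(species_idx, leaf_idx))


def make_species_panel(config: SynthConfig, outdir=None) -> dict:
    """Generate a full multi-species dataset.

    Per species: a Weibull length sample; the ``leaves_per_species``
    leaves nearest the median length selected for digitization; one
    boundary per selected leaf whose true scale ``l`` is back-solved from
    its target length through the length identity, with an independently
    seeded pose and noise realization.  Returns (and optionally writes) a
    manifest recording every true parameter and seed.

    When ``outdir`` is given, writes ``lengths.csv`` (species_id,
    length_cm), one ``boundary_<species>_<leaf>.csv`` per leaf, optional
    PNG masks, and ``manifest.json``.
    """
    leaves = []
    lengths_rows = []
    manifest_species = []
    for si, sp in enumerate(config.species):
        len_seed = np.random.SeedSequence(config.seed, spawn_key=(si,))
        lengths = sample_lengths(
            sp.weibull_k, sp.weibull_lam, config.lengths_per_species, len_seed
        )
        lengths_rows.extend((sp.species_id, L) for L in lengths)
        chosen = select_representative(lengths, config.leaves_per_species)
        sp_leaves = []
        for li, idx in enumerate(chosen):
            target_L = float(lengths[idx])
            l = scale_from_target_length(target_L, sp.n)
            seed = _leaf_seed(config.seed, si, li)
            rng = np.random.default_rng(seed)
            pose = PoseParams(
                x0=float(rng.uniform(-config.pose_xy_range, config.pose_xy_range)),
                y0=float(rng.uniform(-config.pose_xy_range, config.pose_xy_range)),
                theta=float(
                    rng.uniform(-config.pose_theta_range, config.pose_theta_range)
                ),
            )
            params = GielisParams(l, sp.n)
            curve = make_leaf(
                params,
                pose,
                noise_sd=config.noise_sd,
                asymmetry=config.asymmetry,
                asymmetry_arc=config.asymmetry_arc,
                num_points=config.num_points,
                seed=rng,
            )
            leaf = {
                "species_id": sp.species_id,
                "leaf_index": li,
                "length_index": int(idx),
                "target_length_cm": target_L,
                "true_l": l,
                "true_n": sp.n,
                "true_pose": {"x0": pose.x0, "y0": pose.y0, "theta": pose.theta},
                "spawn_key": [si, li],
                "curve": curve,
            }
            sp_leaves.append(leaf)
        leaves.extend(sp_leaves)
        manifest_species.append(
            {
                "species_id": sp.species_id,
                "true_n": sp.n,
                "weibull_k": sp.weibull_k,
                "weibull_lam": sp.weibull_lam,
                "median_length_cm": float(np.median(lengths)),
                "n_lengths": len(lengths),
                "n_leaves": len(sp_leaves),
            }
        )

    manifest = {
        "seed": config.seed,
        "noise_sd": config.noise_sd,
        "asymmetry": config.asymmetry,
        "num_points": config.num_points,
        "species": manifest_species,
        "leaves": [{k: v for k, v in leaf.items() if k != "curve"} for leaf in leaves],
    }
    panel = {
        "manifest": manifest,
        "lengths": lengths_rows,
        "leaves": leaves,
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        import pandas as pd

        pd.DataFrame(lengths_rows, columns=["species_id", "length_cm"]).to_csv(
            outdir / "lengths.csv", index=False
        )
        from .fitting import write_boundary_csv

        for leaf in leaves:
            name = f"boundary_{leaf['species_id']}_{leaf['leaf_index']:03d}"
            write_boundary_csv(leaf["curve"], outdir / f"{name}.csv")
            leaf_entry = next(
                e
                for e in manifest["leaves"]
                if e["species_id"] == leaf["species_id"]
                and e["leaf_index"] == leaf["leaf_index"]
            )
            leaf_entry["boundary_csv"] = f"{name}.csv"
            if config.render:
                img = render_mask(leaf["curve"], config.render_scale)
                import imageio.v3 as iio

                png = f"{name}.png"
                iio.imwrite(
                    outdir / png, (img.pixels * 255).astype(np.uint8)
                )
                leaf_entry["mask_png"] = png
                leaf_entry["mask_scale_cm_per_px"] = config.render_scale
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True)
        )
    return panel
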