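"""Seeded synthetic nuclei images with ground-truth masks and truth tables.

Fixture images emulate the two benchmarking regimes: low density (LD,
hard-core spacing between nuclei) and high density (HD, clustered with
overlaps). Nuclei are Gaussian-profile disks on a background with an
optional linear illumination gradient and Gaussian noise; marker
channels light up a Bernoulli subset of cells with lognormal amplitude.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .image_io import ImageStack, write_stack, write_label_mask
from .segmentation import LabelMask

__all__ = ["FixtureSpec", "generate", "write_fixture"]

# a Gaussian skirt A*exp(-d^2 / (2 s^2)) falls to 10% of A at
# d = s * sqrt(2 ln 10); nuclei are flat-core disks with a Gaussian
# skirt whose core radius is chosen so the 10%-amplitude contour (the
# ground-truth footprint boundary) sits exactly at the nominal radius R
_FOOTPRINT_FACTOR = math.sqrt(2.0 * math.log(10.0))


@dataclass
class FixtureSpec:
    width: int = 512
    height: int = 512
    n_cells: int = 100
    mean_radius_px: float = 7.5
    radius_sd: float = 0.75
    density_mode: str = "LD"  # LD: hard-core spacing; HD: clustered, overlaps
    nuclear_amplitude: float = 2000.0
    background_level: float = 100.0
    gradient_amplitude: float = 0.0
    noise_sd: float = 50.0
    edge_sigma_px: float = 1.0  # Gaussian skirt width at the nucleus rim
    # autofluorescence-like background blobs (0 coverage disables them)
    texture_coverage: float = 0.0
    texture_amplitude: float = 800.0
    texture_scale_px: float = 20.0
    texture_edge_sigma_px: float = 2.0
    n_channels: int = 1
    marker_positive_prob: list[float] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.width, self.height, self.n_cells, self.n_channels) <= 0:
            raise ValueError("width, height, n_cells and n_channels must be positive")
        if self.mean_radius_px <= 0:
            raise ValueError("mean_radius_px must be positive")
        if self.edge_sigma_px <= 0:
            raise ValueError("edge_sigma_px must be positive")
        if self.density_mode not in ("LD", "HD"):
            raise ValueError("density_mode must be 'LD' or 'HD'")
        if not self.marker_positive_prob:
            self.marker_positive_prob = [0.5] * (self.n_channels - 1)
        if len(self.marker_positive_prob) != self.n_channels - 1:
            raise ValueError(
                "marker_positive_prob needs one entry per non-nuclear channel"
            )
        if any(not 0 <= p <= 1 for p in self.marker_positive_prob):
            raise ValueError("marker probabilities must lie in [0, 1]")
        if not 0 <= self.texture_coverage < 1:
            raise ValueError("texture_coverage must lie in [0, 1)")


def _sample_centers(spec: FixtureSpec, rng: np.random.Generator) -> np.ndarray:
    margin = spec.mean_radius_px + 1
    lo = np.array([margin, margin])
    hi = np.array([spec.height - margin, spec.width - margin])
    if np.any(hi <= lo):
        raise ValueError("image too small for the requested radius")
    if spec.density_mode == "LD":
        min_dist = 2.5 * spec.mean_radius_px
        centers: list[np.ndarray] = []
        attempts = 0
        max_attempts = 2000 * spec.n_cells
        while len(centers) < spec.n_cells:
            if attempts >= max_attempts:
                raise ValueError(
                    f"cannot place {spec.n_cells} cells with hard-core spacing "
                    f"{min_dist:.1f}px in {spec.width}x{spec.height}; "
                    "reduce n_cells or use HD mode"
                )
            cand = lo + rng.random(2) * (hi - lo)
            attempts += 1
            if all(np.hypot(*(cand - c)) >= min_dist for c in centers):
                centers.append(cand)
        return np.array(centers)
    # HD: clusters of overlapping nuclei
    n_clusters = max(1, spec.n_cells // 8)
    cluster_centers = lo + rng.random((n_clusters, 2)) * (hi - lo)
    idx = rng.integers(0, n_clusters, size=spec.n_cells)
    jitter = rng.normal(0.0, 2.0 * spec.mean_radius_px, size=(spec.n_cells, 2))
    return np.clip(cluster_centers[idx] + jitter, lo, hi)


def generate(spec: FixtureSpec) -> tuple[ImageStack, LabelMask, pd.DataFrame]:
    """Render the fixture: image stack, ground-truth mask, truth table.

    The mask labels connected components of the union of all nuclear
    footprints (profile above 10% of the cell amplitude, i.e. distance
    <= radius): overlapping nuclei therefore merge into one mask object,
    while the truth table keeps one row per generated cell x channel with
    its ``mask_label`` recording the merge. Deterministic given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    centers = _sample_centers(spec, rng)
    radii = np.clip(
        rng.normal(spec.mean_radius_px, spec.radius_sd, size=spec.n_cells),
        2.0, None,
    )

    yy, xx = np.mgrid[0:spec.height, 0:spec.width].astype(np.float64)
    footprint = np.zeros((spec.height, spec.width), dtype=bool)
    profiles = np.zeros((spec.n_cells, spec.height, spec.width), dtype=np.float32)
    for i, ((cy, cx), r) in enumerate(zip(centers, radii)):
        s = min(spec.edge_sigma_px, r / _FOOTPRINT_FACTOR)
        core = r - _FOOTPRINT_FACTOR * s  # 10% contour lands at distance r
        y0, y1 = max(0, int(cy - 4 * r)), min(spec.height, int(cy + 4 * r) + 1)
        x0, x1 = max(0, int(cx - 4 * r)), min(spec.width, int(cx + 4 * r) + 1)
        d = np.sqrt((yy[y0:y1, x0:x1] - cy) ** 2 + (xx[y0:y1, x0:x1] - cx) ** 2)
        profiles[i, y0:y1, x0:x1] = np.exp(
            -np.maximum(d - core, 0.0) ** 2 / (2 * s * s))
        footprint[y0:y1, x0:x1] |= d <= r

    labels, _ = ndimage.label(footprint, structure=np.ones((3, 3), bool))
    mask = LabelMask(labels)
    mask_label = [
        int(labels[int(round(cy)), int(round(cx))]) for cy, cx in centers
    ]

    gradient = (
        spec.gradient_amplitude * (xx + yy) / (spec.width + spec.height)
        if spec.gradient_amplitude else 0.0
    )

    texture = 0.0
    if spec.texture_coverage > 0:
        # sharp-edged autofluorescence blobs outside the footprint union:
        # the structured background that distinguishes narrow from wide
        # band-pass segmentation
        f = ndimage.gaussian_filter(
            rng.standard_normal((spec.height, spec.width)), spec.texture_scale_px)
        blobs = f > np.quantile(f, 1.0 - spec.texture_coverage)
        texture = spec.texture_amplitude * ndimage.gaussian_filter(
            blobs.astype(np.float64), spec.texture_edge_sigma_px)

    channels: list[np.ndarray] = []
    names: list[str] = []
    truth_rows: list[dict] = []

    def render(per_cell_amp: np.ndarray) -> np.ndarray:
        img = np.full((spec.height, spec.width), float(spec.background_level))
        img += gradient
        img += texture
        img += np.einsum("i,ijk->jk", per_cell_amp, profiles.astype(np.float64))
        if spec.noise_sd > 0:
            img += rng.normal(0.0, spec.noise_sd, size=img.shape)
        return np.clip(np.rint(img), 0, 65535).astype(np.uint16)

    nuc_amp = np.full(spec.n_cells, float(spec.nuclear_amplitude))
    channels.append(render(nuc_amp))
    names.append("nuclei")
    for i in range(spec.n_cells):
        truth_rows.append({
            "cell": i + 1, "channel": "nuclei", "x": centers[i, 1],
            "y": centers[i, 0], "radius_px": radii[i],
            "mask_label": mask_label[i], "positive": True,
            "amplitude": nuc_amp[i],
        })

    for c, prob in enumerate(spec.marker_positive_prob, start=2):
        positive = rng.random(spec.n_cells) < prob
        amp = np.where(
            positive,
            rng.lognormal(math.log(max(spec.nuclear_amplitude, 1e-9)), 0.3,
                          size=spec.n_cells),
            0.0,
        )
        name = f"marker{c - 1}"
        channels.append(render(amp))
        names.append(name)
        for i in range(spec.n_cells):
            truth_rows.append({
                "cell": i + 1, "channel": name, "x": centers[i, 1],
                "y": centers[i, 0], "radius_px": radii[i],
                "mask_label": mask_label[i], "positive": bool(positive[i]),
                "amplitude": amp[i],
            })

    stack = ImageStack(channels, names)
    truth = pd.DataFrame(truth_rows)
    return stack, mask, truth


def write_fixture(spec: FixtureSpec, out_dir: str | Path) -> dict[str, Path]:
    """Generate and write the fixture plus a sidecar spec echo."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stack, mask, truth = generate(spec)
    paths = {
        "stack": out_dir / "fixture_stack.tif",
        "mask": out_dir / "fixture_truth_mask.tif",
        "truth": out_dir / "fixture_truth.tsv",
        "spec": out_dir / "fixture_spec.json",
    }
    write_stack(stack, paths["stack"])
    write_label_mask(mask.labels, paths["mask"])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    paths["spec"].write_text(json.dumps(asdict(spec), indent=2))
    return paths
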