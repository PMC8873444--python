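"""Synthetic Ki-67 IHC slide generator with exact ground truth.

Real annotated Ki-67 pROIs are not redistributable, so the test bed renders
slides with the same statistical structure: tumor nuclei grouped in spatial
clusters (the regions a pathologist would score), each nucleus independently
DAB-positive with a configured probability; isolated lymphocytes and
irregular stain-blob artifacts scattered outside the clusters (the content
the ROI stage must reject); and a pale stromal background.

Rendering goes through the inverse HED stain transform, so the colors seen
by the downstream color-deconvolution segmentation are physically consistent
with the optical densities the generator laid down.  Every random draw flows
from the single seed in :class:`SynthesisConfig`; two calls with the same
config are bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.color import hed2rgb
from skimage.draw import disk as disk_coords
from skimage.draw import ellipse as ellipse_coords

from ki67pi.io_annotations import (
    DAB_POSITIVE,
    HEMATOXYLIN_ONLY,
    AnnotationSet,
    GroundTruthPI,
    NucleusAnnotation,
    SlideImage,
    write_annotation_csv,
    write_cellcounter_xml,
    write_image,
)
from ki67pi.roi import ROIMask


class SynthesisError(RuntimeError):
    """Raised when the requested content cannot be placed in the image."""


@dataclass(frozen=True)
class SynthesisConfig:
    """Parameters of one synthetic slide.

    Optical densities are in the normalized units of the HED stain space
    (1.0 corresponds to near-total absorbance): a well-stained nucleus is
    ~0.08-0.13, the white background 0.  The
    ``dab_weak_fraction`` knob renders that fraction of the DAB-positive
    nuclei at ``dab_weak_range`` intensity, emulating slides with
    heterogeneous (partially faint) immunostaining.
    """

    seed: int = 0
    image_height: int = 448
    image_width: int = 448
    n_clusters: int = 2
    nuclei_per_cluster: tuple[int, int] = (40, 70)
    cluster_radius: int = 80
    target_pi: float = 0.2
    nucleus_radius: tuple[int, int] = (5, 8)
    lymphocyte_count: int = 12
    lymphocyte_radius: tuple[int, int] = (2, 3)
    artifact_count: int = 3
    artifact_radius: tuple[int, int] = (10, 16)
    artifact_stain: str = "random"  # random | dab | hema
    artifact_intensity: tuple[float, float] = (0.09, 0.15)
    artifact_min_spacing: int = 140
    dab_intensity: tuple[float, float] = (0.08, 0.13)
    hema_intensity: tuple[float, float] = (0.075, 0.12)
    dab_weak_fraction: float = 0.0
    dab_weak_range: tuple[float, float] = (0.025, 0.038)
    noise_sigma: float = 0.0015
    stroma_level: float = 0.003
    clearance: int = 12  # min gap between cluster footprints and outside objects

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_pi <= 1.0:
            raise ValueError(f"target_pi must be in [0, 1], got {self.target_pi}")
        if not 0.0 <= self.dab_weak_fraction <= 1.0:
            raise ValueError("dab_weak_fraction must be in [0, 1]")
        for name in ("n_clusters", "lymphocyte_count", "artifact_count"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if min(self.image_height, self.image_width) < 48:
            raise ValueError("image must be at least one window (48 px) on a side")


@dataclass
class SyntheticSlide:
    """A rendered slide paired with its exact ground truth."""

    image: SlideImage
    annotations: AnnotationSet
    roi_truth: ROIMask
    true_pi: GroundTruthPI
    config: SynthesisConfig


def render_from_stain_densities(
    dab_density: np.ndarray, hema_density: np.ndarray, slide_id: str = "synthetic"
) -> SlideImage:
    """RGB raster from per-pixel DAB and hematoxylin optical densities.

    Applies the inverse of the standard HED stain-separation transform (zero
    eosin), so forward deconvolution of the result recovers the densities up
    to 8-bit quantization.  Zero density renders near-white.
    """
    dab_density = np.asarray(dab_density, dtype=np.float64)
    hema_density = np.asarray(hema_density, dtype=np.float64)
    if dab_density.shape != hema_density.shape:
        raise ValueError(
            f"density rasters differ in shape: {dab_density.shape} vs {hema_density.shape}"
        )
    if (dab_density < 0).any() or (hema_density < 0).any():
        raise ValueError("stain densities must be non-negative")
    hed = np.stack(
        [hema_density, np.zeros_like(hema_density), dab_density], axis=-1
    )
    rgb = np.clip(hed2rgb(hed), 0.0, 1.0)
    pixels = (rgb * 255.0).round().astype(np.uint8)
    return SlideImage(slide_id=slide_id, pixels=pixels)


def _place_points(
    rng: np.random.Generator,
    n: int,
    sampler,
    min_dist_of,
    accept,
    max_tries: int = 400,
    what: str = "object",
) -> list[tuple[float, float, float]]:
    """Dart-throwing placement of ``n`` (y, x, r) triples with rejection.

    ``sampler`` draws a candidate, ``accept`` validates it against the scene,
    ``min_dist_of`` gives the minimum allowed center distance to each placed
    triple.  Raises :class:`SynthesisError` after ``max_tries`` rejections
    for a single object — never silently truncates.
    """
    placed: list[tuple[float, float, float]] = []
    for _ in range(n):
        for attempt in range(max_tries):
            cand = sampler()
            y, x, r = cand
            if not accept(y, x, r):
                continue
            ok = True
            for py, px, pr in placed:
                if (y - py) ** 2 + (x - px) ** 2 < min_dist_of(r, pr) ** 2:
                    ok = False
                    break
            if ok:
                placed.append(cand)
                break
        else:
            raise SynthesisError(
                f"could not place {what} {len(placed) + 1}/{n} after {max_tries} tries; "
                f"image too small for the requested content"
            )
    return placed


def generate_slide(config: SynthesisConfig) -> SyntheticSlide:
    """Render one synthetic slide with annotations, ROI truth, and true PI.

    Tumor nuclei are placed in ``n_clusters`` circular clusters, each
    nucleus drawn DAB-positive independently with probability ``target_pi``;
    the realized labels are recorded in the emitted annotations, so the
    stored true PI is the count-based PI of what was actually rendered.
    Lymphocytes and artifacts land strictly outside the cluster footprints.
    """
    rng = np.random.default_rng(config.seed)
    H, W = config.image_height, config.image_width
    dab = np.zeros((H, W), dtype=np.float64)
    hema = np.zeros((H, W), dtype=np.float64)
    roi_mask = np.zeros((H, W), dtype=bool)

    R = config.cluster_radius
    margin = R + config.nucleus_radius[1] + 2
    if 2 * margin >= min(H, W) and config.n_clusters > 0:
        raise SynthesisError(
            f"cluster radius {R} does not fit a {H}x{W} image"
        )

    def cluster_sampler():
        y = rng.uniform(margin, H - margin)
        x = rng.uniform(margin, W - margin)
        return (y, x, float(R))

    # retry the whole cluster set: an unlucky first center can make the
    # pairwise-distance constraint infeasible even when a layout exists
    clusters = None
    for _ in range(50):
        try:
            clusters = _place_points(
                rng,
                config.n_clusters,
                cluster_sampler,
                min_dist_of=lambda r, pr: r + pr + 2 * config.clearance,
                accept=lambda y, x, r: True,
                max_tries=100,
                what="tumor cluster",
            )
            break
        except SynthesisError:
            continue
    if clusters is None:
        raise SynthesisError(
            f"could not place {config.n_clusters} clusters of radius {R} "
            f"in a {H}x{W} image"
        )

    footprint_r = R + config.nucleus_radius[1] + 1
    for cy, cx, _ in clusters:
        rr, cc = disk_coords((cy, cx), footprint_r, shape=(H, W))
        roi_mask[rr, cc] = True

    points: list[NucleusAnnotation] = []
    r_lo, r_hi = config.nucleus_radius
    for cy, cx, _ in clusters:
        n_nuclei = int(rng.integers(config.nuclei_per_cluster[0], config.nuclei_per_cluster[1] + 1))

        def nucleus_sampler():
            rho = R * np.sqrt(rng.random())
            theta = rng.uniform(0, 2 * np.pi)
            r = rng.uniform(r_lo, r_hi)
            return (cy + rho * np.sin(theta), cx + rho * np.cos(theta), r)

        nuclei = _place_points(
            rng,
            n_nuclei,
            nucleus_sampler,
            min_dist_of=lambda r, pr: 0.95 * (r + pr),
            accept=lambda y, x, r: r < y < H - r and r < x < W - r,
            what="tumor nucleus",
        )
        for ny, nx, nr in nuclei:
            positive = bool(rng.random() < config.target_pi)
            if positive and config.dab_weak_fraction > 0 and rng.random() < config.dab_weak_fraction:
                intensity = rng.uniform(*config.dab_weak_range)
            elif positive:
                intensity = rng.uniform(*config.dab_intensity)
            else:
                intensity = rng.uniform(*config.hema_intensity)
            _draw_nucleus(rng, dab if positive else hema, ny, nx, nr, intensity)
            points.append(
                NucleusAnnotation(
                    x=int(round(nx)),
                    y=int(round(ny)),
                    label=DAB_POSITIVE if positive else HEMATOXYLIN_ONLY,
                )
            )

    def outside_roi(y: float, x: float, r: float) -> bool:
        if not (r < y < H - r and r < x < W - r):
            return False
        for cy, cx, _ in clusters:
            if (y - cy) ** 2 + (x - cx) ** 2 < (footprint_r + r + config.clearance) ** 2:
                return False
        return True

    # isolated lymphocytes: small, dark, hematoxylin-only, never annotated
    ly_lo, ly_hi = config.lymphocyte_radius
    lymphocytes = _place_points(
        rng,
        config.lymphocyte_count,
        lambda: (rng.uniform(0, H), rng.uniform(0, W), rng.uniform(ly_lo, ly_hi)),
        min_dist_of=lambda r, pr: 6 * (r + pr),
        accept=outside_roi,
        what="lymphocyte",
    )
    for ly, lx, lr in lymphocytes:
        _draw_nucleus(rng, hema, ly, lx, lr, rng.uniform(0.13, 0.18))

    # stain-blob artifacts: irregular unions of disks in either stain
    ar_lo, ar_hi = config.artifact_radius
    artifacts = _place_points(
        rng,
        config.artifact_count,
        lambda: (rng.uniform(0, H), rng.uniform(0, W), rng.uniform(ar_lo, ar_hi)),
        min_dist_of=lambda r, pr: float(config.artifact_min_spacing),
        accept=lambda y, x, r: outside_roi(y, x, 2 * r),
        what="artifact",
    )
    for ay, ax, ar in artifacts:
        if config.artifact_stain == "dab":
            target = dab
        elif config.artifact_stain == "hema":
            target = hema
        else:
            target = dab if rng.random() < 0.5 else hema
        intensity = rng.uniform(*config.artifact_intensity)
        for _ in range(int(rng.integers(3, 6))):
            oy = ay + rng.normal(0, ar * 0.45)
            ox = ax + rng.normal(0, ar * 0.45)
            rr, cc = disk_coords((oy, ox), rng.uniform(0.5, 0.9) * ar, shape=(H, W))
            target[rr, cc] = np.maximum(target[rr, cc], intensity)

    # pale stromal wash (hematoxylin) plus per-pixel sensor noise
    if config.stroma_level > 0:
        stroma = gaussian_filter(rng.normal(0, 1, size=(H, W)), sigma=18)
        stroma = config.stroma_level * (1 + stroma / max(stroma.std(), 1e-9) * 0.4)
        hema += np.clip(stroma, 0, None)
    if config.noise_sigma > 0:
        dab = dab + rng.normal(0, config.noise_sigma, size=(H, W))
        hema = hema + rng.normal(0, config.noise_sigma, size=(H, W))
    dab = np.clip(dab, 0, None)
    hema = np.clip(hema, 0, None)

    slide_id = f"synth-{config.seed:06d}"
    image = render_from_stain_densities(dab, hema, slide_id=slide_id)
    annotations = AnnotationSet(slide_id=slide_id, points=points)
    n_pos = annotations.count(DAB_POSITIVE)
    n_neg = annotations.count(HEMATOXYLIN_ONLY)
    total = n_pos + n_neg
    true_pi = GroundTruthPI(
        n_positive=n_pos, n_negative=n_neg, pi=(n_pos / total) if total else 0.0
    )
    return SyntheticSlide(
        image=image,
        annotations=annotations,
        roi_truth=ROIMask(mask=roi_mask, empty=not roi_mask.any()),
        true_pi=true_pi,
        config=config,
    )


def _draw_nucleus(
    rng: np.random.Generator,
    channel: np.ndarray,
    y: float,
    x: float,
    r: float,
    intensity: float,
) -> None:
    """Filled ellipse with mild eccentricity and slight intensity mottle."""
    ecc = rng.uniform(0.8, 1.0)
    rot = rng.uniform(0, np.pi)
    rr, cc = ellipse_coords(y, x, r, r * ecc, shape=channel.shape, rotation=rot)
    mottle = rng.normal(1.0, 0.05, size=rr.shape)
    channel[rr, cc] = np.maximum(channel[rr, cc], intensity * np.clip(mottle, 0.7, 1.3))


def write_slide(slide: SyntheticSlide, outdir: str | Path) -> dict:
    """Write image, annotations (XML + CSV), ROI-truth mask, and JSON sidecar.

    Returns the sidecar dict (also written as ``<slide_id>.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sid = slide.image.slide_id
    write_image(slide.image, outdir / f"{sid}.png")
    write_cellcounter_xml(slide.annotations, outdir / f"{sid}.xml")
    write_annotation_csv(slide.annotations, outdir / f"{sid}.csv")
    slide.roi_truth.to_png(outdir / f"{sid}_roi.png")
    sidecar = {
        "slide_id": sid,
        "true_pi": slide.true_pi.pi,
        "n_positive": slide.true_pi.n_positive,
        "n_negative": slide.true_pi.n_negative,
        "config": dataclasses.asdict(slide.config),
    }
    (outdir / f"{sid}.json").write_text(json.dumps(sidecar, indent=2))
    return sidecar
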