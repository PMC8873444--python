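"""Image and nucleus-annotation I/O, ground-truth PI, and chunk partitioning.

A *slide* here is one exported rectangular region of interest (pROI) from a
whole-slide Ki-67 IHC image: an 8-bit RGB raster.  Nucleus annotations are
point markers placed by a pathologist on neoplastic nuclei, each labeled as
DAB-positive (brown, Ki-67 expressing) or hematoxylin-only (blue
counterstain).  The count-based proliferation index is

    PI = N_positive / (N_positive + N_negative)

Annotations can be read from ImageJ Cell Counter marker XML (the tool used
to collect the original data) or from a simple CSV dialect that is easier to
author programmatically.
"""

from __future__ import annotations

import csv
import json
import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from PIL import Image
import tifffile

logger = logging.getLogger(__name__)

#: Annotation label for DAB-stained (Ki-67 positive) nuclei.
DAB_POSITIVE = "dab_positive"
#: Annotation label for hematoxylin-only (Ki-67 negative) nuclei.
HEMATOXYLIN_ONLY = "hematoxylin_only"
#: class_map sentinel: markers of this class are dropped on read.
IGNORE = "ignore"

VALID_LABELS = frozenset({DAB_POSITIVE, HEMATOXYLIN_ONLY})

ANNOTATION_CSV_HEADER = ["slide_id", "x", "y", "label"]


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation inputs."""


@dataclass
class SlideImage:
    """An 8-bit RGB raster with an identifier; the unit of analysis."""

    slide_id: str
    pixels: np.ndarray  # (H, W, 3) uint8

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(
                f"slide {self.slide_id!r}: expected (H, W, 3) raster, "
                f"got shape {self.pixels.shape}"
            )
        if self.pixels.dtype != np.uint8:
            raise ValueError(
                f"slide {self.slide_id!r}: expected uint8 pixels, got {self.pixels.dtype}"
            )

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class NucleusAnnotation:
    """A point marker on one nucleus; x is the column, y the row (0-based)."""

    x: int
    y: int
    label: str

    def __post_init__(self) -> None:
        if self.label not in VALID_LABELS:
            raise AnnotationError(f"unknown annotation label {self.label!r}")


@dataclass
class AnnotationSet:
    """All nucleus point annotations for one slide."""

    slide_id: str
    points: list[NucleusAnnotation] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.points)

    def count(self, label: str) -> int:
        return sum(1 for p in self.points if p.label == label)

    def check_bounds(self, image: SlideImage) -> None:
        """Verify every point lies inside the paired image raster."""
        for p in self.points:
            if not (0 <= p.x < image.width and 0 <= p.y < image.height):
                raise AnnotationError(
                    f"annotation ({p.x}, {p.y}) outside image "
                    f"{image.width}x{image.height} for slide {self.slide_id!r}"
                )


@dataclass(frozen=True)
class GroundTruthPI:
    """Count-based proliferation index: n_positive / (n_positive + n_negative)."""

    n_positive: int
    n_negative: int
    pi: float


@dataclass
class ChunkPartition:
    """Random disjoint partition of slide ids into chunks numbered 1..k."""

    assignment: dict[str, int]
    chunk_sizes: list[int]
    seed: int

    @property
    def n_chunks(self) -> int:
        return len(self.chunk_sizes)

    def chunk(self, index: int) -> list[str]:
        """Slide ids in chunk ``index`` (1-based), in sorted order."""
        return sorted(s for s, c in self.assignment.items() if c == index)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"seed": self.seed, "assignment": self.assignment}, indent=2)
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ChunkPartition":
        data = json.loads(Path(path).read_text())
        assignment = {str(k): int(v) for k, v in data["assignment"].items()}
        k = max(assignment.values())
        sizes = [sum(1 for c in assignment.values() if c == i) for i in range(1, k + 1)]
        return cls(assignment=assignment, chunk_sizes=sizes, seed=int(data["seed"]))


# ---------------------------------------------------------------------------
# images


def read_image(path: str | Path, slide_id: str | None = None) -> SlideImage:
    """Read a PNG or TIFF raster into an 8-bit RGB :class:`SlideImage`.

    Alpha channels are dropped; grayscale is promoted to 3 identical
    channels; 16-bit samples are rescaled to 8-bit by keeping the high byte
    (logged, since scanner exports vary in bit depth).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    suffix = path.suffix.lower()
    if suffix in {".tif", ".tiff"}:
        arr = tifffile.imread(str(path))
    elif suffix == ".png":
        arr = np.asarray(Image.open(path))
    else:
        raise ValueError(f"unsupported image format {suffix!r} for {path} (PNG or TIFF only)")

    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim != 3:
        raise ValueError(f"{path}: cannot interpret array of shape {arr.shape} as an image")
    if arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.shape[2] != 3:
        raise ValueError(f"{path}: expected 3 or 4 channels, got {arr.shape[2]}")

    if arr.dtype == np.uint16:
        logger.info("rescaling 16-bit image %s to 8-bit by dropping the low byte", path)
        arr = (arr >> 8).astype(np.uint8)
    elif arr.dtype != np.uint8:
        raise ValueError(f"{path}: unsupported sample dtype {arr.dtype}")

    return SlideImage(slide_id=slide_id or path.stem, pixels=np.ascontiguousarray(arr))


def write_image(image: SlideImage, path: str | Path) -> None:
    """Write an RGB raster losslessly (PNG or TIFF chosen by suffix)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".tif", ".tiff"}:
        tifffile.imwrite(str(path), image.pixels)
    elif suffix == ".png":
        Image.fromarray(image.pixels).save(path)
    else:
        raise ValueError(f"unsupported output format {suffix!r}")


# ---------------------------------------------------------------------------
# annotations


def read_cellcounter_xml(
    path: str | Path, class_map: Mapping[int, str], slide_id: str | None = None
) -> AnnotationSet:
    """Parse an ImageJ Cell Counter marker file into an :class:`AnnotationSet`.

    ``class_map`` maps each Cell Counter marker type number to
    :data:`DAB_POSITIVE`, :data:`HEMATOXYLIN_ONLY` or :data:`IGNORE`.  Marker
    coordinates are 1-based in the file and shifted to the package's 0-based
    pixel convention on read.  Any marker type present in the file but absent
    from ``class_map`` is an error: silently dropping an unknown class would
    bias the ground-truth PI.
    """
    path = Path(path)
    try:
        tree = ET.parse(str(path))
    except ET.ParseError as exc:
        raise AnnotationError(f"malformed Cell Counter XML {path}: {exc}") from exc
    root = tree.getroot()

    points: list[NucleusAnnotation] = []
    unmapped: set[int] = set()
    for marker_type in root.iter("Marker_Type"):
        type_el = marker_type.find("Type")
        if type_el is None or type_el.text is None:
            raise AnnotationError(f"{path}: Marker_Type without a Type element")
        type_id = int(type_el.text)
        markers = marker_type.findall("Marker")
        if not markers:
            continue
        label = class_map.get(type_id)
        if label is None:
            unmapped.add(type_id)
            continue
        if label == IGNORE:
            continue
        if label not in VALID_LABELS:
            raise AnnotationError(f"class_map maps type {type_id} to unknown label {label!r}")
        for m in markers:
            x_el, y_el = m.find("MarkerX"), m.find("MarkerY")
            if x_el is None or y_el is None:
                raise AnnotationError(f"{path}: Marker without MarkerX/MarkerY")
            points.append(
                NucleusAnnotation(x=int(x_el.text) - 1, y=int(y_el.text) - 1, label=label)
            )
    if unmapped:
        raise AnnotationError(
            f"{path}: counter types {sorted(unmapped)} present but not in class_map; "
            f"map them to a label or to 'ignore'"
        )

    if slide_id is None:
        name_el = root.find(".//Image_Filename")
        slide_id = (
            Path(name_el.text).stem if name_el is not None and name_el.text else path.stem
        )
    return AnnotationSet(slide_id=slide_id, points=points)


def write_cellcounter_xml(
    annotations: AnnotationSet,
    path: str | Path,
    class_map: Mapping[int, str] | None = None,
) -> None:
    """Write annotations as Cell Counter marker XML (1-based coordinates).

    By default type 1 holds DAB-positive and type 2 hematoxylin-only markers.
    """
    if class_map is None:
        class_map = {1: DAB_POSITIVE, 2: HEMATOXYLIN_ONLY}
    label_to_type = {v: k for k, v in class_map.items() if v in VALID_LABELS}
    root = ET.Element("CellCounter_Marker_File")
    props = ET.SubElement(root, "Image_Properties")
    ET.SubElement(props, "Image_Filename").text = f"{annotations.slide_id}.png"
    data = ET.SubElement(root, "Marker_Data")
    ET.SubElement(data, "Current_Type").text = "0"
    for label, type_id in sorted(label_to_type.items(), key=lambda kv: kv[1]):
        mt = ET.SubElement(data, "Marker_Type")
        ET.SubElement(mt, "Type").text = str(type_id)
        for p in annotations.points:
            if p.label != label:
                continue
            m = ET.SubElement(mt, "Marker")
            ET.SubElement(m, "MarkerX").text = str(p.x + 1)
            ET.SubElement(m, "MarkerY").text = str(p.y + 1)
            ET.SubElement(m, "MarkerZ").text = "1"
    ET.ElementTree(root).write(str(path), encoding="unicode", xml_declaration=True)


def read_annotation_csv(path: str | Path, slide_id: str | None = None) -> AnnotationSet:
    """Read the ``slide_id,x,y,label`` CSV dialect (0-based coordinates)."""
    path = Path(path)
    points: list[NucleusAnnotation] = []
    seen_ids: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != ANNOTATION_CSV_HEADER:
            raise AnnotationError(
                f"{path}: expected header {ANNOTATION_CSV_HEADER}, got {reader.fieldnames}"
            )
        for row in reader:
            seen_ids.add(row["slide_id"])
            points.append(
                NucleusAnnotation(x=int(row["x"]), y=int(row["y"]), label=row["label"])
            )
    if slide_id is None:
        if len(seen_ids) > 1:
            raise AnnotationError(f"{path}: multiple slide_ids {sorted(seen_ids)}; pass slide_id")
        slide_id = seen_ids.pop() if seen_ids else path.stem
    return AnnotationSet(slide_id=slide_id, points=points)


def write_annotation_csv(annotations: AnnotationSet, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(ANNOTATION_CSV_HEADER)
        for p in annotations.points:
            writer.writerow([annotations.slide_id, p.x, p.y, p.label])


# ---------------------------------------------------------------------------
# ground truth and partitioning


def ground_truth_pi(annotations: AnnotationSet) -> GroundTruthPI:
    """Count-based proliferation index from point annotations.

    Raises :class:`AnnotationError` on an empty set: a slide with no
    annotated nuclei has no defined PI, and returning 0 would silently
    pass a wrong ground truth downstream.
    """
    n_pos = annotations.count(DAB_POSITIVE)
    n_neg = annotations.count(HEMATOXYLIN_ONLY)
    total = n_pos + n_neg
    if total == 0:
        raise AnnotationError(
            f"slide {annotations.slide_id!r}: no annotated nuclei, PI undefined"
        )
    return GroundTruthPI(n_positive=n_pos, n_negative=n_neg, pi=n_pos / total)


def partition_chunks(
    slide_ids: Sequence[str], chunk_sizes: Sequence[int], seed: int
) -> ChunkPartition:
    """Uniformly random disjoint partition of slides into chunks of given sizes.

    Mirrors the study design of splitting a slide collection into k training
    chunks plus a held-out testing chunk.  Deterministic given ``seed``.
    """
    slide_ids = list(slide_ids)
    if len(set(slide_ids)) != len(slide_ids):
        raise ValueError("duplicate slide ids")
    if any(s < 0 for s in chunk_sizes):
        raise ValueError("chunk sizes must be non-negative")
    if sum(chunk_sizes) != len(slide_ids):
        raise ValueError(
            f"chunk sizes sum to {sum(chunk_sizes)} but there are {len(slide_ids)} slides"
        )
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(slide_ids)))
    assignment: dict[str, int] = {}
    pos = 0
    for chunk_index, size in enumerate(chunk_sizes, start=1):
        for i in order[pos : pos + size]:
            assignment[slide_ids[i]] = chunk_index
        pos += size
    return ChunkPartition(assignment=assignment, chunk_sizes=list(chunk_sizes), seed=seed)
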