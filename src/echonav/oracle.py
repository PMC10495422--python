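"""Quality and window-type oracles: the stand-in for the intelligence module.

A quality score is a signed scalar in [-1, 1]: the sign is the good/bad
image classification and the magnitude the classifier's probability (a
'bad' image with probability 0.998 scores -0.998, a 'good' one with
probability 0.986 scores +0.986). The closer to +1, the better. The search
algorithm only ever compares and thresholds these scores, so any backend
honouring the convention can drive it.

Two backends are provided:

* a synthetic quality field — a Gaussian ridge of high quality along a
  short band segment (the apical window) over a low-quality background,
  with optional seeded noise; fully regenerable from its spec, and
* a coordinate-indexed image bank — a directory of pre-acquired images
  named by pixel location, scored at lookup time by a user-supplied
  plugin returning a (label, probability) pair.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field as dc_field
from enum import Enum
from pathlib import Path
from typing import Callable, Optional, Protocol

import numpy as np
from scipy.spatial import cKDTree

from .geometry import GridPosition

__all__ = [
    "WindowLabel",
    "WindowType",
    "SyntheticFieldSpec",
    "QualityField",
    "generate_field",
    "FieldOracle",
    "ImageBank",
    "ImageBankOracle",
    "load_image_bank",
    "QualityOracle",
    "InvalidSpecError",
    "MissingSampleError",
    "PluginContractError",
    "DuplicateEntryError",
    "reference_field_spec",
    "signed_quality",
]

# ---------------------------------------------------------------------------
# score and window-type conventions
# ---------------------------------------------------------------------------


class WindowLabel(Enum):
    A4CH = "A4CH"
    A2CH = "A2CH"
    NONE = "NONE"


@dataclass(frozen=True)
class WindowType:
    """Predicted echo-window view at a position.

    ``NONE`` carries probability 0; apical labels carry the classifier
    probability (1.0 for the deterministic synthetic label map).
    """

    label: WindowLabel
    probability: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(f"window probability must be in [0, 1], got {self.probability}")
        if self.label is WindowLabel.NONE and self.probability != 0.0:
            raise ValueError("NONE window type carries probability 0")


WINDOW_NONE = WindowType(WindowLabel.NONE, 0.0)


def signed_quality(label: str, probability: float) -> float:
    """Convert a (class, probability) classifier output to a signed score.

    'bad' maps to ``-probability``, 'good' to ``+probability``.
    """
    if not 0.0 <= probability <= 1.0:
        raise PluginContractError(f"probability must be in [0, 1], got {probability}")
    label = label.lower()
    if label == "good":
        return float(probability)
    if label == "bad":
        return -float(probability)
    raise PluginContractError(f"label must be 'good' or 'bad', got {label!r}")


class QualityOracle(Protocol):
    """Anything that can score a grid position."""

    def evaluate(self, p: GridPosition) -> tuple[float, WindowType]: ...


# ---------------------------------------------------------------------------
# synthetic quality field
# ---------------------------------------------------------------------------


class InvalidSpecError(ValueError):
    """Raised when a synthetic-field spec violates its invariants."""


@dataclass(frozen=True)
class SyntheticFieldSpec:
    """Parameters of the synthetic quality landscape.

    The high-quality ridge runs along the segment ``band_start`` →
    ``band_end``; quality decays as a Gaussian of the distance to that
    segment, from ``peak_quality`` on the axis down to
    ``background_quality`` far away, plus seeded Gaussian noise:

        q(x, y) = clip(bg + (peak - bg) * exp(-d^2 / (2 sigma^2)) + eps, -1, 1)

    The first ``a4ch_fraction`` of the band's length is labelled A4CH,
    the remainder A2CH; labels apply only where quality exceeds 0.
    """

    canvas_width: int = 1080
    canvas_height: int = 1080
    band_start: tuple[int, int] = (620, 620)
    band_end: tuple[int, int] = (800, 520)
    band_sigma: float = 18.0
    peak_quality: float = 0.98
    background_quality: float = -0.95
    noise_sigma: float = 0.02
    a4ch_fraction: float = 0.5
    seed: int = 20230915

    def __post_init__(self) -> None:
        if not (-1.0 <= self.background_quality < 0.0):
            raise InvalidSpecError("background_quality must lie in [-1, 0)")
        if not (0.0 < self.peak_quality <= 1.0):
            raise InvalidSpecError("peak_quality must lie in (0, 1]")
        if self.peak_quality <= self.background_quality:
            raise InvalidSpecError("peak_quality must exceed background_quality")
        if self.band_sigma <= 0:
            raise InvalidSpecError("band_sigma must be positive")
        if self.noise_sigma < 0:
            raise InvalidSpecError("noise_sigma must be non-negative")
        if not (0.0 <= self.a4ch_fraction <= 1.0):
            raise InvalidSpecError("a4ch_fraction must lie in [0, 1]")
        for px, py in (self.band_start, self.band_end):
            if not (0 <= px < self.canvas_width and 0 <= py < self.canvas_height):
                raise InvalidSpecError("band endpoints must lie on the canvas")
        if self.band_start == self.band_end:
            raise InvalidSpecError("band must have positive length")

    def to_dict(self) -> dict:
        return {
            "canvas_width": self.canvas_width,
            "canvas_height": self.canvas_height,
            "band_start": list(self.band_start),
            "band_end": list(self.band_end),
            "band_sigma": self.band_sigma,
            "peak_quality": self.peak_quality,
            "background_quality": self.background_quality,
            "noise_sigma": self.noise_sigma,
            "a4ch_fraction": self.a4ch_fraction,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticFieldSpec":
        d = dict(d)
        for key in ("band_start", "band_end"):
            if key in d:
                d[key] = tuple(int(v) for v in d[key])
        return cls(**d)


# label-map codes stored in the int8 array
_LABEL_CODES = {0: WindowLabel.NONE, 1: WindowLabel.A4CH, 2: WindowLabel.A2CH}


@dataclass
class QualityField:
    """Dense per-pixel quality array plus window-type label map.

    ``quality`` is float64 with shape (canvas_height, canvas_width), every
    entry in [-1, 1]; ``labels`` is int8 with the same shape (0 = NONE,
    1 = A4CH, 2 = A2CH). Regenerating from the same spec (same seed)
    reproduces the arrays bit for bit.
    """

    quality: np.ndarray
    labels: np.ndarray
    spec: Optional[SyntheticFieldSpec] = None

    def __post_init__(self) -> None:
        self.quality = np.asarray(self.quality, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.quality.shape != self.labels.shape:
            raise ValueError("quality and label arrays must share a shape")
        if self.quality.size and (self.quality.min() < -1.0 or self.quality.max() > 1.0):
            raise ValueError("quality values must lie in [-1, 1]")

    @property
    def canvas_height(self) -> int:
        return self.quality.shape[0]

    @property
    def canvas_width(self) -> int:
        return self.quality.shape[1]

    def quality_at(self, p: GridPosition) -> float:
        return float(self.quality[p.y, p.x])

    def window_type_at(self, p: GridPosition) -> WindowType:
        label = _LABEL_CODES[int(self.labels[p.y, p.x])]
        if label is WindowLabel.NONE:
            return WINDOW_NONE
        return WindowType(label, 1.0)


def _distance_and_projection(spec: SyntheticFieldSpec) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel Euclidean distance to the band segment and the clipped
    projection parameter t in [0, 1] of the nearest segment point."""
    h, w = spec.canvas_height, spec.canvas_width
    ys, xs = np.mgrid[0:h, 0:w]
    ax, ay = spec.band_start
    bx, by = spec.band_end
    ux, uy = bx - ax, by - ay
    seg_len2 = float(ux * ux + uy * uy)
    t = ((xs - ax) * ux + (ys - ay) * uy) / seg_len2
    t = np.clip(t, 0.0, 1.0)
    dx = xs - (ax + t * ux)
    dy = ys - (ay + t * uy)
    return np.hypot(dx, dy), t


def generate_field(spec: SyntheticFieldSpec) -> QualityField:
    """Materialise the quality array and label map for a field spec."""
    d, t = _distance_and_projection(spec)
    ridge = np.exp(-(d * d) / (2.0 * spec.band_sigma**2))
    quality = spec.background_quality + (spec.peak_quality - spec.background_quality) * ridge
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        quality = quality + rng.normal(0.0, spec.noise_sigma, size=quality.shape)
    quality = np.clip(quality, -1.0, 1.0)

    labels = np.zeros(quality.shape, dtype=np.int8)
    above = quality > 0.0
    labels[above & (t <= spec.a4ch_fraction)] = 1
    labels[above & (t > spec.a4ch_fraction)] = 2
    return QualityField(quality=quality, labels=labels, spec=spec)


def reference_field_spec() -> SyntheticFieldSpec:
    """The bundled reference landscape used by the region-comparison study.

    A 1080x1080 canvas (the body camera's frame size) with a thin,
    ~30-degree-slanted high-quality band in the middle of the patient's
    left torso — the apical window — and low-quality background
    everywhere else. The patient's anatomical left is toward increasing
    x (the camera looks down on a supine patient), and the band sits
    well clear of the lower-left torso so that region contains no
    above-threshold position.
    """
    return SyntheticFieldSpec()


class FieldOracle:
    """Quality oracle backed by a dense synthetic field: evaluate() is a lookup."""

    def __init__(self, field: QualityField):
        self.field = field
        self.n_evaluations = 0

    def evaluate(self, p: GridPosition) -> tuple[float, WindowType]:
        if not (0 <= p.x < self.field.canvas_width and 0 <= p.y < self.field.canvas_height):
            raise ValueError(f"position {p} is off the {self.field.canvas_width}x{self.field.canvas_height} canvas")
        self.n_evaluations += 1
        return self.field.quality_at(p), self.field.window_type_at(p)


# ---------------------------------------------------------------------------
# coordinate-indexed image bank
# ---------------------------------------------------------------------------


class MissingSampleError(KeyError):
    """Raised on an image-bank miss under the strict miss policy."""


class PluginContractError(ValueError):
    """Raised when a scoring plugin violates the (label, probability) contract."""


class DuplicateEntryError(ValueError):
    """Raised when two bank files encode the same (x, y) coordinate."""


#: filename grammar, bit-exact: x{XXXX}_y{YYYY}_id{NNNN}.{png|jpg}
_BANK_FILENAME = re.compile(r"^x(\d{4})_y(\d{4})_id(\d{4})\.(png|jpg)$")


@dataclass
class BankEntry:
    position: GridPosition
    image_id: int
    path: Path


@dataclass
class ImageBank:
    """Directory of pre-acquired images indexed by pixel coordinate."""

    root: Path
    entries: dict[GridPosition, BankEntry] = dc_field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def lookup(self, p: GridPosition) -> Optional[BankEntry]:
        """Exact-coordinate lookup; a miss returns None, never raises."""
        return self.entries.get(p)

    def nearest(self, p: GridPosition) -> BankEntry:
        if not self.entries:
            raise MissingSampleError("image bank is empty")
        positions = list(self.entries)
        tree = cKDTree(np.asarray(positions, dtype=float))
        _, idx = tree.query([p.x, p.y])
        return self.entries[positions[int(idx)]]

    def write_manifest(self, path: Path | str) -> None:
        """One tab-delimited record per image: x, y, id, path."""
        lines = ["x\ty\tid\tpath"]
        for pos in sorted(self.entries):
            e = self.entries[pos]
            lines.append(f"{pos.x}\t{pos.y}\t{e.image_id}\t{e.path}")
        Path(path).write_text("\n".join(lines) + "\n")


def load_image_bank(root: Path | str) -> ImageBank:
    """Scan a directory for conforming filenames and build the coordinate map.

    Non-conforming files are ignored; an empty directory yields an empty
    bank (a warning-level situation, not an error); two files encoding the
    same coordinate raise :class:`DuplicateEntryError` naming both.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"image bank root {root} does not exist")
    bank = ImageBank(root=root)
    for f in sorted(root.iterdir()):
        m = _BANK_FILENAME.match(f.name)
        if not m:
            continue
        pos = GridPosition(int(m.group(1)), int(m.group(2)))
        if pos in bank.entries:
            raise DuplicateEntryError(
                f"coordinate {tuple(pos)} encoded by both {bank.entries[pos].path.name} and {f.name}"
            )
        bank.entries[pos] = BankEntry(position=pos, image_id=int(m.group(3)), path=f)
    return bank


class ImageBankOracle:
    """Quality oracle over an image bank plus a user-supplied scoring plugin.

    The plugin receives a PIL image and returns ``(label, probability)``
    with label 'good' or 'bad'; its output is converted to the signed
    quality convention. ``window_plugin`` may additionally classify the
    view, returning ``(label, probability)`` with label 'A4CH', 'A2CH' or
    'NONE'; without one, window type is reported as NONE.

    ``miss_policy`` is 'nearest' (default: fall back to the closest stored
    coordinate, mirroring fetching the image of the corresponding point)
    or 'strict' (a miss raises :class:`MissingSampleError`).
    """

    def __init__(
        self,
        bank: ImageBank,
        quality_plugin: Callable,
        window_plugin: Optional[Callable] = None,
        miss_policy: str = "nearest",
    ):
        if miss_policy not in ("nearest", "strict"):
            raise ValueError("miss_policy must be 'nearest' or 'strict'")
        self.bank = bank
        self.quality_plugin = quality_plugin
        self.window_plugin = window_plugin
        self.miss_policy = miss_policy
        self.n_evaluations = 0

    def _resolve(self, p: GridPosition) -> BankEntry:
        entry = self.bank.lookup(p)
        if entry is None:
            if self.miss_policy == "strict":
                raise MissingSampleError(f"no image stored at {tuple(p)}")
            entry = self.bank.nearest(p)
        return entry

    def evaluate(self, p: GridPosition) -> tuple[float, WindowType]:
        from PIL import Image

        entry = self._resolve(p)
        self.n_evaluations += 1
        with Image.open(entry.path) as img:
            label, prob = self.quality_plugin(img)
            quality = signed_quality(label, prob)
            if self.window_plugin is None:
                return quality, WINDOW_NONE
            wlabel, wprob = self.window_plugin(img)
        wlabel = str(wlabel).upper()
        if wlabel == "NONE":
            return quality, WINDOW_NONE
        if wlabel not in ("A4CH", "A2CH"):
            raise PluginContractError(f"window label must be 'A4CH', 'A2CH' or 'NONE', got {wlabel!r}")
        if not 0.0 <= wprob <= 1.0:
            raise PluginContractError(f"window probability must be in [0, 1], got {wprob}")
        return quality, WindowType(WindowLabel[wlabel], float(wprob))
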