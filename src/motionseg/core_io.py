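"""Volume/label I/O, conforming preprocessing, and label-scheme management.

Internal axis convention
------------------------
Arrays are indexed ``(i, j, k)`` with ``i`` = lateral (left-right), ``j`` =
superior-inferior and ``k`` = anterior-posterior.  The anterior-posterior
axis is the long (184-voxel) axis of the fixed crop box, so the convention is
load-bearing: NIfTI images are reoriented to this canonical layout on read
(RAS+ followed by an axis swap placing A-P last).  Voxel extents are
half-open ``[start, start + length)`` with 0-based indices.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .geometry import FULL_SCALE, Geometry

#: Canonical internal orientation: axis 0 left->Right, axis 1
#: inferior->Superior, axis 2 posterior->Anterior.
CANONICAL_AXCODES = ("R", "S", "A")

# RAS array axes -> internal (R, S, A) array axes.
_RAS_TO_INTERNAL = (0, 2, 1)
_INTERNAL_TO_RAS = (0, 2, 1)


class ShapeError(ValueError):
    """Raised when an image does not have exactly three spatial axes."""


@dataclass(frozen=True)
class LabelScheme:
    """Mapping label id -> (region name, macro-region).

    ``macro_region`` is one of ``{"cortical", "subcortical", "other"}``; the
    cortical/subcortical split drives metric aggregation.  ``unknown_id`` is
    the background / out-of-brain label and is never treated as a region.
    """

    entries: dict[int, tuple[str, str]]
    unknown_id: int = 0

    def __post_init__(self) -> None:
        if self.unknown_id not in self.entries:
            raise ValueError("unknown_id must be an entry of the scheme")
        for lid, (name, macro) in self.entries.items():
            if macro not in ("cortical", "subcortical", "other"):
                raise ValueError(f"bad macro-region {macro!r} for label {lid}")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, label_id: int) -> bool:
        return int(label_id) in self.entries

    @property
    def ids(self) -> list[int]:
        return sorted(self.entries)

    @property
    def n_classes(self) -> int:
        """Number of classes for one-hot encoding (max id + 1)."""
        return max(self.entries) + 1

    def name(self, label_id: int) -> str:
        return self.entries[int(label_id)][0]

    def macro_region(self, label_id: int) -> str:
        return self.entries[int(label_id)][1]

    def ids_of_macro(self, macro: str) -> list[int]:
        return [i for i in self.ids if self.entries[i][1] == macro and i != self.unknown_id]

    def merged(self, merge_map: dict[int, int]) -> "LabelScheme":
        """Scheme obtained by applying ``merge_map`` (old id -> new id)."""
        new_entries: dict[int, tuple[str, str]] = {}
        for old, new in merge_map.items():
            if new in self.entries:
                new_entries[new] = self.entries[new]
            elif old in self.entries and new not in new_entries:
                new_entries[new] = self.entries[old]
        if self.unknown_id in merge_map:
            unknown = merge_map[self.unknown_id]
        else:
            unknown = self.unknown_id
        if unknown not in new_entries:
            new_entries[unknown] = ("Unknown", "other")
        return LabelScheme(entries=new_entries, unknown_id=unknown)


_SUBCORTICAL_AND_OTHER = [
    # (name, macro); left/right structures merged, all ventricles one label
    ("Cerebral-White-Matter", "other"),
    ("Ventricles", "subcortical"),
    ("Cerebellum-White-Matter", "other"),
    ("Cerebellum-Cortex", "other"),
    ("Thalamus", "subcortical"),
    ("Caudate", "subcortical"),
    ("Putamen", "subcortical"),
    ("Pallidum", "subcortical"),
    ("Hippocampus", "subcortical"),
    ("Amygdala", "subcortical"),
    ("Accumbens-Area", "subcortical"),
    ("VentralDC", "subcortical"),
    ("Brain-Stem", "other"),
    ("CSF", "other"),
    ("Choroid-Plexus", "other"),
    ("Corpus-Callosum", "other"),
]

_DK_CORTICAL = [
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "fusiform", "inferiorparietal", "inferiortemporal",
    "isthmuscingulate", "lateraloccipital", "lateralorbitofrontal", "lingual",
    "medialorbitofrontal", "middletemporal", "parahippocampal", "paracentral",
    "parsopercularis", "parsorbitalis", "parstriangularis", "pericalcarine",
    "postcentral", "posteriorcingulate", "precentral", "precuneus",
    "rostralanteriorcingulate", "rostralmiddlefrontal", "superiorfrontal",
    "superiorparietal", "superiortemporal", "supramarginal", "frontalpole",
    "temporalpole", "transversetemporal",
]


def default_scheme() -> LabelScheme:
    """Packaged 50-region Desikan-Killiany-style label scheme.

    50 entries total including Unknown (id 0): 16 hemisphere-merged
    subcortical/other structures (a single label for all ventricles) and 33
    merged cortical parcels.  Fully replaceable via :func:`load_scheme`.
    """
    entries: dict[int, tuple[str, str]] = {0: ("Unknown", "other")}
    next_id = 1
    for name, macro in _SUBCORTICAL_AND_OTHER:
        entries[next_id] = (name, macro)
        next_id += 1
    for name in _DK_CORTICAL:
        entries[next_id] = (f"ctx-{name}", "cortical")
        next_id += 1
    scheme = LabelScheme(entries=entries)
    assert len(scheme) == 50
    return scheme


def load_scheme(path: str | Path, unknown_id: int = 0) -> LabelScheme:
    """Load a label scheme from a plain-text table.

    Accepted line formats (comments ``#`` and blank lines ignored)::

        <id> <name> <macro-region>            # native format
        <id> <name> <R> <G> <B> <A>           # FreeSurfer-LUT column order

    LUT-style rows (numeric third column) get macro-region ``other`` unless
    the name starts with ``ctx`` (cortical).
    """
    entries: dict[int, tuple[str, str]] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ValueError(f"unparseable scheme line: {raw!r}")
        lid, name = int(parts[0]), parts[1]
        if len(parts) >= 3 and not parts[2].lstrip("-").isdigit():
            macro = parts[2]
        else:
            macro = "cortical" if name.lower().startswith("ctx") else "other"
        if lid in entries:
            raise ValueError(f"duplicate label id {lid}")
        entries[lid] = (name, macro)
    return LabelScheme(entries=entries, unknown_id=unknown_id)


def save_scheme(scheme: LabelScheme, path: str | Path) -> None:
    lines = [f"{i} {scheme.name(i)} {scheme.macro_region(i)}" for i in scheme.ids]
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class Volume:
    """3D scalar intensity array with voxel spacing and orientation."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    axcodes: tuple[str, str, str] = CANONICAL_AXCODES

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ShapeError(f"Volume must be 3D, got shape {self.data.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LabelMask:
    """3D integer label array over a :class:`LabelScheme`."""

    labels: np.ndarray
    scheme: LabelScheme

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ShapeError(f"LabelMask must be 3D, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def present_labels(self) -> list[int]:
        return [int(v) for v in np.unique(self.labels)]

    def validate(self) -> None:
        for v in self.present_labels():
            if v not in self.scheme:
                raise ValueError(f"label {v} not in scheme")


def read_nifti(
    path: str | Path, scheme: LabelScheme | None = None
) -> Volume | LabelMask:
    """Read a NIfTI image, reorienting to the internal (R, S, A) layout.

    With ``scheme`` given the file is interpreted as a label mask and read
    without any interpolation or dtype change beyond integer casting.
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - nibabel error text varies
        raise IOError(f"cannot read NIfTI file {path}: {exc}") from exc
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ShapeError(f"expected a 3D image, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    data = np.transpose(data, _RAS_TO_INTERNAL)
    spacing = tuple(float(zooms[a]) for a in _RAS_TO_INTERNAL)
    if scheme is not None:
        return LabelMask(labels=np.rint(data).astype(np.int32), scheme=scheme)
    return Volume(data=np.asarray(data, dtype=np.float32), spacing=spacing)


def write_nifti(obj: Volume | LabelMask, path: str | Path) -> None:
    """Write a Volume or LabelMask as NIfTI in RAS+ orientation."""
    if isinstance(obj, LabelMask):
        data, spacing = obj.labels.astype(np.int16), (1.0, 1.0, 1.0)
    else:
        data, spacing = np.asarray(obj.data, dtype=np.float32), obj.spacing
    ras = np.transpose(data, _INTERNAL_TO_RAS)
    sp = tuple(spacing[a] for a in _INTERNAL_TO_RAS)
    affine = np.diag(list(sp) + [1.0])
    nib.save(nib.Nifti1Image(ras, affine), str(path))


def center_crop_pad(
    arr: np.ndarray, target: tuple[int, int, int], fill: float | int = 0
) -> np.ndarray:
    """Symmetrically crop or zero-pad ``arr`` to ``target`` shape."""
    out = np.full(target, fill, dtype=arr.dtype)
    src_slices, dst_slices = [], []
    for n, t in zip(arr.shape, target):
        if n >= t:
            off = (n - t) // 2
            src_slices.append(slice(off, off + t))
            dst_slices.append(slice(0, t))
        else:
            off = (t - n) // 2
            src_slices.append(slice(0, n))
            dst_slices.append(slice(off, off + n))
    out[tuple(dst_slices)] = arr[tuple(src_slices)]
    return out


def conform(
    obj: Volume | LabelMask, geometry: Geometry = FULL_SCALE
) -> Volume | LabelMask:
    """Resample to 1 mm isotropic and center crop/pad to the conform shape.

    Volumes are resampled with 3rd-order spline interpolation and padded with
    zeros; label masks use nearest-neighbour resampling and are padded with
    the scheme's Unknown label.  Volumes already at 1 mm and the target shape
    pass through unchanged.
    """
    if isinstance(obj, LabelMask):
        data, spacing, order, fill = obj.labels, (1.0, 1.0, 1.0), 0, obj.scheme.unknown_id
    else:
        data, spacing, order, fill = obj.data, obj.spacing, 3, 0
    if any(n == 0 for n in data.shape):
        raise ValueError("degenerate zero-extent input volume")
    if not all(abs(s - 1.0) < 1e-6 for s in spacing):
        data = ndimage.zoom(data, zoom=spacing, order=order, mode="constant", cval=fill)
        if any(n == 0 for n in data.shape):
            raise ValueError("resampling produced a zero-extent volume")
    if data.shape != tuple(geometry.conform_shape):
        data = center_crop_pad(data, tuple(geometry.conform_shape), fill=fill)
    if isinstance(obj, LabelMask):
        return LabelMask(labels=data.astype(obj.labels.dtype), scheme=obj.scheme)
    return Volume(data=data, spacing=(1.0, 1.0, 1.0), axcodes=obj.axcodes)


def normalize_intensity(v: Volume) -> Volume:
    """Standardise intensities to zero mean, unit variance over the array."""
    data = np.asarray(v.data, dtype=np.float64)
    sd = data.std()
    if sd == 0:
        raise ValueError("cannot normalize a constant volume (zero variance)")
    out = (data - data.mean()) / sd
    return Volume(data=out.astype(np.float32), spacing=v.spacing, axcodes=v.axcodes)


def merge_labels(m: LabelMask, merge_map: dict[int, int]) -> LabelMask:
    """Voxelwise relabeling according to ``merge_map`` (old id -> new id)."""
    present = m.present_labels()
    missing = [v for v in present if v not in merge_map]
    if missing:
        raise ValueError(f"merge_map missing entries for labels {missing}")
    lut = np.zeros(max(max(present), max(merge_map)) + 1, dtype=m.labels.dtype)
    for old, new in merge_map.items():
        if old < lut.size:
            lut[old] = new
    merged = lut[m.labels]
    return LabelMask(labels=merged, scheme=m.scheme.merged(merge_map))
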