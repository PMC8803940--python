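"""Pipeline geometry: one object from which every derived shape follows.

All stages (conforming, cropping, subvolume sampling) read their shapes from a
single :class:`Geometry` so that the full-scale and desk-scale pipelines are
structurally identical.  At full scale the conformed volume is 256^3 at 1 mm
isotropic and the fixed crop box is 152 x 152 x 184 voxels (15.2 cm lateral
and superior-inferior, 18.4 cm anterior-posterior); subvolumes are half the
cropped extent and the sampling step is a quarter of it, which yields a
3 x 3 x 3 = 27 overlapping-subvolume grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Geometry:
    """Shared shape configuration for the two-stage pipeline.

    Parameters
    ----------
    conform_shape
        Target shape of conformed volumes (voxels, 1 mm isotropic).
    crop_lengths
        Edge lengths of the fixed bounding box, in voxels, ordered
        (i, j, k) = (lateral, superior-inferior, anterior-posterior).
        Must be divisible by 4 so the half/quarter subvolume grid tiles
        exactly.
    downsample_factor
        Resampling factor applied to the conformed volume before the
        crop-localisation network.
    """

    conform_shape: tuple[int, int, int] = (256, 256, 256)
    crop_lengths: tuple[int, int, int] = (152, 152, 184)
    downsample_factor: float = 0.5

    def __post_init__(self) -> None:
        if len(self.conform_shape) != 3 or len(self.crop_lengths) != 3:
            raise ValueError("conform_shape and crop_lengths must be triples")
        for L, S in zip(self.crop_lengths, self.conform_shape):
            if L <= 0 or S <= 0:
                raise ValueError("shapes must be positive")
            if L % 4 != 0:
                raise ValueError(
                    f"crop length {L} not divisible by 4; the subvolume grid "
                    "(half shape, quarter step) would not tile exactly"
                )
            if L > S:
                raise ValueError("crop box larger than conformed volume")
        if not (0 < self.downsample_factor <= 1):
            raise ValueError("downsample_factor must be in (0, 1]")

    @property
    def sub_shape(self) -> tuple[int, int, int]:
        """Subvolume shape: half the cropped extent per axis."""
        return tuple(L // 2 for L in self.crop_lengths)

    @property
    def step(self) -> tuple[int, int, int]:
        """Subvolume sampling step: a quarter of the cropped extent."""
        return tuple(L // 4 for L in self.crop_lengths)

    @property
    def downsampled_shape(self) -> tuple[int, int, int]:
        return tuple(int(round(s * self.downsample_factor)) for s in self.conform_shape)


#: Full-scale geometry for real 1 mm isotropic T1 volumes.
FULL_SCALE = Geometry()

#: Desk-scale geometry used for CPU-sized phantom studies: the whole pipeline
#: shrunk to a 64^3 conformed volume with a 40 x 40 x 48 fixed box
#: (nearest multiple-of-8 lengths to a 1/4 scaling of the full-scale box),
#: preserving the 27-subvolume grid structure.
DESK_SCALE = Geometry(conform_shape=(64, 64, 64), crop_lengths=(40, 40, 48))
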