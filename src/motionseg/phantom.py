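"""Labeled head phantoms and graded k-space motion-artifact simulation.

The generator stands in for a non-public in-scanner head-motion study: each
"subject" is a layered ellipsoidal head (scalp, skull, CSF, a four-parcel
cortical shell, white-matter core, ventricles, and ellipsoidal deep-gray
nuclei) with tissue-mean intensities plus Gaussian noise.  Head motion during
a segmented acquisition is emulated by corrupting contiguous blocks of
phase-encode lines in k-space with per-block rigid perturbations
(translations become linear phase ramps; rotations resample the corrupted
block from a rotated image), which produces the ghosting/ringing artifacts
characteristic of nodding during a structural scan.  Artifact severity maps
to three quality tiers (HM1 good, HM2 medium, HM3 bad).

Ground-truth label masks are never touched by the motion simulation:
artifacts corrupt intensities only.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .core_io import LabelMask, LabelScheme, Volume, default_scheme, write_nifti
from .geometry import DESK_SCALE, Geometry

QUALITY_TIERS = ("HM1", "HM2", "HM3")

#: Nucleus names drawn from the scheme, in painting order.
_NUCLEUS_NAMES = (
    "Thalamus", "Caudate", "Putamen", "Pallidum",
    "Hippocampus", "Amygdala", "Accumbens-Area", "VentralDC",
)

# Stereotyped nucleus center offsets as fractions of the volume shape.
_NUCLEUS_OFFSETS = (
    (0.10, 0.00, 0.02), (-0.10, 0.00, 0.02),
    (0.08, -0.06, -0.08), (-0.08, -0.06, -0.08),
    (0.06, 0.08, 0.10), (-0.06, 0.08, 0.10),
    (0.00, -0.10, 0.08), (0.00, 0.10, -0.10),
)


def _default_intensities() -> dict[str, float]:
    return {
        "background": 0.0,
        "scalp": 70.0,
        "skull": 25.0,
        "csf": 45.0,
        "cortex": 85.0,
        "white_matter": 115.0,
        "ventricle": 40.0,
        "nucleus_base": 130.0,
    }


@dataclass
class PhantomSpec:
    """Anatomy + acquisition parameters of one synthetic head.

    ``seed`` fixes the anatomy (ellipsoid sizes, jitters); the additive
    Gaussian noise is re-drawn per acquisition via ``noise_seed`` so the same
    head can be "scanned" repeatedly.  ``nucleus_intensity_step`` separates
    the stylized T1 contrast of successive deep-gray nuclei.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    n_subcortical: int = 4
    tissue_intensities: dict[str, float] = field(default_factory=_default_intensities)
    nucleus_intensity_step: float = 12.0
    noise_sd: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 32 for s in self.shape):
            raise ValueError("phantom shape must be >= 32 voxels per axis")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class MotionSpec:
    """Rigid-motion corruption parameters for one acquisition.

    ``n_nods`` is the number of discrete motion events; each event corrupts
    one contiguous block of phase-encode lines with its own random rigid
    perturbation drawn within ``max_translation_mm`` / ``max_rotation_deg``.
    ``corrupted_fraction`` is the fraction of phase-encode lines affected in
    total.
    """

    n_nods: int = 5
    max_translation_mm: float = 1.0
    max_rotation_deg: float = 1.0
    corrupted_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_translation_mm < 0 or self.max_rotation_deg < 0:
            raise ValueError("motion magnitudes must be >= 0")
        if not (0 <= self.corrupted_fraction <= 1):
            raise ValueError("corrupted_fraction must be in [0, 1]")
        if self.n_nods < 1:
            raise ValueError("n_nods must be >= 1")


def _ellipsoid(shape, center, semiaxes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    acc = np.zeros(shape, dtype=np.float64)
    for g, c, a in zip(grids, center, semiaxes):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def generate_phantom(
    spec: PhantomSpec,
    scheme: LabelScheme | None = None,
    noise_seed: int | None = None,
) -> tuple[Volume, LabelMask]:
    """Generate one labeled head phantom.

    Returns a paired intensity volume (1 mm isotropic) and ground-truth
    label mask over ``scheme``.  Deterministic given ``spec.seed`` and
    ``noise_seed`` (defaults to ``spec.seed``).
    """
    scheme = scheme or default_scheme()
    name_to_id = {scheme.name(i): i for i in scheme.ids}
    nucleus_ids = [name_to_id[n] for n in _NUCLEUS_NAMES if n in name_to_id]
    if spec.n_subcortical > len(nucleus_ids):
        raise ValueError(
            f"n_subcortical={spec.n_subcortical} exceeds the "
            f"{len(nucleus_ids)} available subcortical nucleus labels"
        )
    cortical_ids = [i for i in scheme.ids if scheme.macro_region(i) == "cortical"][:4]
    wm_id = name_to_id.get("Cerebral-White-Matter")
    vent_id = name_to_id.get("Ventricles")
    if wm_id is None or vent_id is None or len(cortical_ids) < 4:
        raise ValueError("scheme lacks the tissue labels the phantom requires")

    rng = np.random.default_rng(spec.seed)
    s = np.asarray(spec.shape, dtype=np.float64)
    center = s / 2.0 + rng.uniform(-0.06, 0.06, 3) * s
    head_sem = s * np.array([0.36, 0.38, 0.40]) * rng.uniform(0.95, 1.05)
    brain_sem = s * np.array([0.26, 0.26, 0.30]) * rng.uniform(0.92, 1.03)
    shell_t = max(2.0, 0.14 * float(brain_sem.mean()))

    ti = spec.tissue_intensities
    vol = np.full(spec.shape, ti["background"], dtype=np.float64)
    labels = np.zeros(spec.shape, dtype=np.int32)

    head = _ellipsoid(spec.shape, center, head_sem)
    vol[head] = ti["scalp"]
    skull = _ellipsoid(spec.shape, center, brain_sem * 1.18)
    vol[skull] = ti["skull"]
    csf = _ellipsoid(spec.shape, center, brain_sem * 1.08)
    vol[csf] = ti["csf"]

    brain = _ellipsoid(spec.shape, center, brain_sem)
    wm = _ellipsoid(spec.shape, center, brain_sem - shell_t)
    shell = brain & ~wm
    vol[brain] = ti["cortex"]
    vol[wm] = ti["white_matter"]

    # Cortical shell split into four quadrant parcels (lateral x AP sign).
    gi, _, gk = np.ogrid[tuple(slice(0, n) for n in spec.shape)]
    quadrant = (gi >= center[0]).astype(np.int32) * 2 + (gk >= center[2]).astype(np.int32)
    quadrant = np.broadcast_to(quadrant, spec.shape)
    for q in range(4):
        labels[shell & (quadrant == q)] = cortical_ids[q]
    labels[wm] = wm_id

    for side in (-1.0, 1.0):
        vc = center + np.array([side * 0.05, 0.02, 0.0]) * s
        vmask = _ellipsoid(spec.shape, vc, s * np.array([0.030, 0.045, 0.075]))
        vol[vmask] = ti["ventricle"]
        labels[vmask] = vent_id

    for n in range(spec.n_subcortical):
        off = np.asarray(_NUCLEUS_OFFSETS[n]) + rng.uniform(-0.01, 0.01, 3)
        nc = center + off * s
        nsem = s * 0.045 * rng.uniform(0.9, 1.1)
        nmask = _ellipsoid(spec.shape, nc, nsem)
        vol[nmask] = ti["nucleus_base"] + n * spec.nucleus_intensity_step
        labels[nmask] = nucleus_ids[n]

    if spec.noise_sd > 0:
        nrng = np.random.default_rng(spec.seed if noise_seed is None else noise_seed)
        vol = vol + nrng.normal(0.0, spec.noise_sd, spec.shape)

    return (
        Volume(data=vol.astype(np.float32)),
        LabelMask(labels=labels, scheme=scheme),
    )


def _rotate_volume(data: np.ndarray, angles_deg: np.ndarray) -> np.ndarray:
    """Rigid rotation about the volume center (linear interpolation)."""
    rads = np.deg2rad(angles_deg)
    rot = np.eye(3)
    for axis, a in enumerate(rads):
        c, sn = np.cos(a), np.sin(a)
        ax = np.eye(3)
        idx = [i for i in range(3) if i != axis]
        ax[idx[0], idx[0]], ax[idx[0], idx[1]] = c, -sn
        ax[idx[1], idx[0]], ax[idx[1], idx[1]] = sn, c
        rot = ax @ rot
    center = (np.asarray(data.shape) - 1) / 2.0
    inv = rot.T
    offset = center - inv @ center
    return ndimage.affine_transform(data, inv, offset=offset, order=1, mode="constant")


def apply_motion(v: Volume, m: MotionSpec) -> Volume:
    """Corrupt a conformed volume with segmented-k-space rigid motion.

    The anterior-posterior axis (axis 2) is treated as the phase-encode
    direction.  The corrupted fraction of phase-encode planes is split into
    ``n_nods`` contiguous blocks at random (non-DC) positions; each block is
    replaced by the k-space of the rigidly displaced object (translation as
    an exact linear phase ramp, rotation by resampling).  Returns the
    magnitude image.  Deterministic given ``m.seed``.
    """
    data = np.asarray(v.data, dtype=np.float64)
    K = data.shape[2]
    n_corrupt = int(round(m.corrupted_fraction * (K - 1)))
    if n_corrupt == 0 or (m.max_translation_mm == 0 and m.max_rotation_deg == 0):
        return Volume(data=data.astype(np.float32), spacing=v.spacing, axcodes=v.axcodes)

    rng = np.random.default_rng(m.seed)
    F = np.fft.fftn(data)
    freqs = [np.fft.fftfreq(n, d=sp) for n, sp in zip(data.shape, v.spacing)]

    # Contiguous blocks of phase-encode indices, avoiding the DC plane.
    block_sizes = np.full(m.n_nods, n_corrupt // m.n_nods, dtype=int)
    block_sizes[: n_corrupt % m.n_nods] += 1
    block_sizes = block_sizes[block_sizes > 0]
    taken = np.zeros(K, dtype=bool)
    taken[0] = True  # keep DC
    blocks: list[np.ndarray] = []
    for size in block_sizes:
        for _ in range(200):
            start = int(rng.integers(1, max(K - size, 2)))
            idx = np.arange(start, min(start + size, K))
            if not taken[idx].any():
                taken[idx] = True
                blocks.append(idx)
                break

    for idx in blocks:
        t = rng.uniform(-m.max_translation_mm, m.max_translation_mm, 3)
        angles = rng.uniform(-m.max_rotation_deg, m.max_rotation_deg, 3)
        if m.max_rotation_deg > 0 and np.any(angles != 0):
            Fsrc = np.fft.fftn(_rotate_volume(data, angles))
        else:
            Fsrc = F
        ramp_i = np.exp(-2j * np.pi * freqs[0] * t[0])[:, None, None]
        ramp_j = np.exp(-2j * np.pi * freqs[1] * t[1])[None, :, None]
        ramp_k = np.exp(-2j * np.pi * freqs[2][idx] * t[2])[None, None, :]
        F[:, :, idx] = Fsrc[:, :, idx] * ramp_i * ramp_j * ramp_k

    out = np.abs(np.fft.ifftn(F))
    return Volume(data=out.astype(np.float32), spacing=v.spacing, axcodes=v.axcodes)


def severity_score(m: MotionSpec) -> float:
    """Documented artifact-severity statistic: corrupted fraction times the
    summed rigid magnitudes.  Monotone nondecreasing in every magnitude."""
    return m.corrupted_fraction * (m.max_translation_mm + m.max_rotation_deg)


@dataclass(frozen=True)
class QualityThresholds:
    """Severity cut points between HM1/HM2 and HM2/HM3 (ties break toward
    the better tier: a score exactly at a threshold takes the lower tier)."""

    hm1_max: float = 0.35
    hm2_max: float = 1.5


def grade_quality(m: MotionSpec, thresholds: QualityThresholds | None = None) -> str:
    """Map a motion spec to a quality tier via the severity score."""
    th = thresholds or QualityThresholds()
    s = severity_score(m)
    if s <= th.hm1_max:
        return "HM1"
    if s <= th.hm2_max:
        return "HM2"
    return "HM3"


def _sample_motion(condition: str, seed: int, rng: np.random.Generator) -> MotionSpec:
    if condition == "MOVE1":
        return MotionSpec(
            n_nods=5,
            max_translation_mm=float(rng.uniform(0.2, 2.2)),
            max_rotation_deg=float(rng.uniform(0.2, 2.2)),
            corrupted_fraction=float(rng.uniform(0.05, 0.35)),
            seed=seed,
        )
    if condition == "MOVE2":
        return MotionSpec(
            n_nods=10,
            max_translation_mm=float(rng.uniform(1.0, 4.0)),
            max_rotation_deg=float(rng.uniform(1.0, 4.0)),
            corrupted_fraction=float(rng.uniform(0.20, 0.55)),
            seed=seed,
        )
    raise ValueError(f"unknown motion condition {condition!r}")


@dataclass
class StudyRecord:
    """One acquisition of one subject."""

    record_id: str
    subject: str
    condition: str  # CONV / MOVE1 / MOVE2 / RETEST
    session: int
    tier: str
    severity: float
    volume: Volume
    mask: LabelMask
    volume_path: str = ""
    mask_path: str = ""


def generate_study(
    n_subjects: int,
    seed: int,
    geometry: Geometry = DESK_SCALE,
    n_retest: int = 0,
    scheme: LabelScheme | None = None,
    thresholds: QualityThresholds | None = None,
    phantom_kwargs: dict | None = None,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, list[StudyRecord]]:
    """Generate the motion-study roster: per subject one rest acquisition
    (CONV, no motion), one mild-motion (MOVE1, 5 nods) and one strong-motion
    (MOVE2, 10 nods) acquisition of the same head, plus ``n_retest``
    additional no-motion acquisitions for test-retest emulation.

    Returns the roster table and the records; with ``out_dir`` set, volumes
    and masks are also written as NIfTI and the roster as CSV.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    scheme = scheme or default_scheme()
    phantom_kwargs = dict(phantom_kwargs or {})
    phantom_kwargs.setdefault("shape", tuple(geometry.conform_shape))
    root = np.random.SeedSequence(seed)
    subj_seqs = root.spawn(n_subjects)

    records: list[StudyRecord] = []
    for si, seq in enumerate(subj_seqs):
        subject = f"sub-{si:03d}"
        seeds = seq.generate_state(8 + 2 * n_retest) % (2**31)
        spec = PhantomSpec(seed=int(seeds[0]), **phantom_kwargs)
        rng = np.random.default_rng(int(seeds[1]))
        conv_vol, mask = generate_phantom(spec, scheme, noise_seed=int(seeds[2]))
        records.append(
            StudyRecord(
                record_id=f"{subject}_CONV", subject=subject, condition="CONV",
                session=0, tier="HM1", severity=0.0, volume=conv_vol, mask=mask,
            )
        )
        for ci, condition in enumerate(("MOVE1", "MOVE2")):
            vol, _ = generate_phantom(spec, scheme, noise_seed=int(seeds[3 + ci]))
            mspec = _sample_motion(condition, seed=int(seeds[5 + ci]), rng=rng)
            moved = apply_motion(vol, mspec)
            records.append(
                StudyRecord(
                    record_id=f"{subject}_{condition}", subject=subject,
                    condition=condition, session=1 + ci,
                    tier=grade_quality(mspec, thresholds),
                    severity=severity_score(mspec), volume=moved, mask=mask,
                )
            )
        for ri in range(n_retest):
            vol, _ = generate_phantom(spec, scheme, noise_seed=int(seeds[8 + 2 * ri]))
            records.append(
                StudyRecord(
                    record_id=f"{subject}_RETEST{ri}", subject=subject,
                    condition="RETEST", session=3 + ri, tier="HM1",
                    severity=0.0, volume=vol, mask=mask,
                )
            )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for rec in records:
            vp = out / f"{rec.record_id}_T1.nii.gz"
            write_nifti(rec.volume, vp)
            rec.volume_path = str(vp)
            mp = out / f"{rec.subject}_mask.nii.gz"
            if not mp.exists():
                write_nifti(rec.mask, mp)
            rec.mask_path = str(mp)

    roster = pd.DataFrame(
        [
            {
                "record_id": r.record_id, "subject": r.subject,
                "condition": r.condition, "session": r.session, "tier": r.tier,
                "severity": r.severity, "volume_path": r.volume_path,
                "mask_path": r.mask_path,
            }
            for r in records
        ]
    )
    if out_dir is not None:
        roster.to_csv(Path(out_dir) / "roster.csv", index=False)
    return roster, records
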