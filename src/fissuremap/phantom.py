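"""Synthetic intervertebral-disc phantoms.

Generates cohorts of small sagittal T2-weighted-like image stacks with
the statistical structure the downstream analysis assumes: an elliptical
disc (bright nucleus pulposus, darker annulus fibrosus) replicated over a
few midsagittal slices with mild per-slice shrinkage, degeneration-
dependent nucleus signal decay, and annular fissures rendered as thin
bright streaks running from the nucleus boundary into the outer third of
the annulus on the ventral and/or dorsal side.

Conventions: arrays are ``(slices, rows, cols)``; the column index
increases ventral -> dorsal, so the ventral annulus occupies the left
third of the ROI columns and the dorsal annulus the right third.
Lateral fissures lie outside the imaged midsagittal slab and leave no
in-plane footprint (no streak, empty fissure mask) -- they are invisible
to a sagittal occlusion sweep by construction.

A "severely disrupted" phenotype replaces the delimitable streak with
diffuse brightening of the outer annulus; such discs keep their fissure
label but are not eligible for attention mapping (the disrupted annulus
has no localized fissure to point at).

Default label distributions mirror a lumbar discography cohort of 43
patients / 123 discs with 94 fissure-positive discs; see the per-field
defaults on :class:`PhantomConfig`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "PhantomConfig",
    "DiscPhantom",
    "generate_cohort",
    "render_disc",
    "cohort_manifest",
    "save_cohort",
    "load_cohort",
]

IN_PLANE_POSITIONS = ("ventral", "dorsal")
POSITIONS = ("ventral", "dorsal", "lateral")
LEVELS = ("L1-L2", "L2-L3", "L3-L4", "L4-L5", "L5-S1")

#: nucleus boundary and start of the outer third of the annulus, in
#: normalized elliptical radius
NUCLEUS_RADIUS = 0.55
OUTER_THIRD_RADIUS = 0.85


@dataclass(frozen=True)
class PhantomConfig:
    """Cohort-level generator settings.

    Label-distribution defaults emulate the reference lumbar cohort:
    fissure prevalence 94/123, fissure positions weighted (ventral 4%,
    dorsal 81%, both 12%, lateral 3%), degeneration grades 2-5 at
    (16%, 39%, 41%, 3%), 63% of fissured discs carrying a visible
    high-intensity-zone (HIZ) flag and ~20% of fissured discs severely
    disrupted (excluded from attention mapping).  ``fissure_contrast`` is
    the streak intensity offset in units of the background noise SD.
    """

    n_patients: int = 43
    discs_per_patient: int = 3
    image_shape: Tuple[int, int, int] = (5, 48, 96)
    voxel_spacing: Tuple[float, float, float] = (4.4, 0.59, 0.59)
    fissure_prevalence: float = 94 / 123
    ventral_fraction: float = 0.04
    dorsal_fraction: float = 0.81
    both_fraction: float = 0.12
    lateral_fraction: float = 0.03
    degeneration_grade_probs: Tuple[float, float, float, float] = (
        0.163, 0.390, 0.415, 0.032)
    fissure_contrast: float = 6.0
    noise_sd: float = 1.0
    disrupted_fraction: float = 0.20
    hiz_fraction: float = 0.63
    hiz_visibility_cutoff: float = 3.0
    seed: int = 0

    def __post_init__(self):
        weights = (self.ventral_fraction, self.dorsal_fraction,
                   self.both_fraction, self.lateral_fraction)
        if not np.isclose(sum(weights), 1.0, atol=1e-6):
            raise ValueError("fissure position fractions must sum to 1")
        for name in ("fissure_prevalence", "ventral_fraction",
                     "dorsal_fraction", "both_fraction", "lateral_fraction",
                     "disrupted_fraction", "hiz_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not np.isclose(sum(self.degeneration_grade_probs), 1.0, atol=1e-6):
            raise ValueError("degeneration_grade_probs must sum to 1")
        # the slab is a handful of slices; only in-plane size can degenerate
        if self.image_shape[0] < 1 or min(self.image_shape[1:]) < 8:
            raise ValueError(
                f"degenerate image_shape {self.image_shape}: need >= 1 slice "
                "and in-plane dimensions >= 8")
        if self.n_patients < 1 or self.discs_per_patient < 1:
            raise ValueError("n_patients and discs_per_patient must be >= 1")

    def to_json(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class DiscPhantom:
    """One synthetic disc: image stack, masks and ground-truth labels."""

    disc_id: str
    patient_id: str
    level: str
    image: np.ndarray
    roi_mask: np.ndarray
    fissure_mask: np.ndarray
    position_masks: Dict[str, np.ndarray]
    fissure_present: bool
    fissure_positions: Tuple[str, ...]
    hiz_flag: bool
    degeneration_grade: int
    ddd_grade: int
    attention_eligible: bool
    severely_disrupted: bool
    voxel_spacing: Tuple[float, float, float]

    @property
    def in_plane_positions(self) -> Tuple[str, ...]:
        return tuple(p for p in self.fissure_positions
                     if p in IN_PLANE_POSITIONS)


def _elliptical_radius(shape_rc: Tuple[int, int], scale: float) -> np.ndarray:
    rows, cols = shape_rc
    r0, c0 = (rows - 1) / 2.0, (cols - 1) / 2.0
    a_r, a_c = 0.38 * rows * scale, 0.44 * cols * scale
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    return np.sqrt(((rr - r0) / a_r) ** 2 + ((cc - c0) / a_c) ** 2)


def _slice_scales(n_slices: int) -> np.ndarray:
    mid = (n_slices - 1) / 2.0
    return 1.0 - 0.08 * np.abs(np.arange(n_slices) - mid)


def _streak_voxels(shape_rc: Tuple[int, int], scale: float, side: str,
                   wiggle_phase: float) -> List[Tuple[int, int]]:
    """In-plane voxels of a thin fissure streak on one side of the disc.

    The streak runs radially along the horizontal axis from the nucleus
    boundary into the outer third of the annulus, with a small sinusoidal
    row wiggle, two voxels thick.
    """
    rows, cols = shape_rc
    r0, c0 = (rows - 1) / 2.0, (cols - 1) / 2.0
    a_c = 0.44 * cols * scale
    sign = 1 if side == "dorsal" else -1
    out = []
    for rho in np.linspace(NUCLEUS_RADIUS, 0.97, 40):
        c = int(round(c0 + sign * rho * a_c))
        r = int(round(r0 + 1.5 * np.sin(4.0 * rho + wiggle_phase)))
        for dr in (0, 1):
            rr = min(max(r + dr, 0), rows - 1)
            out.append((rr, min(max(c, 0), cols - 1)))
    return sorted(set(out))


@dataclass(frozen=True)
class DiscSpec:
    """Per-disc rendering parameters drawn by :func:`generate_cohort`."""

    disc_id: str
    patient_id: str
    level: str
    fissure_present: bool
    fissure_positions: Tuple[str, ...]
    degeneration_grade: int
    ddd_grade: int
    hiz_flag: bool
    severely_disrupted: bool
    render_seed: int


def render_disc(spec: DiscSpec, config: PhantomConfig) -> DiscPhantom:
    """Render one disc phantom from its drawn labels.

    Compartment means: background 5, annulus 40, nucleus 100 minus 15 per
    degeneration grade above 2 (signal decay of the degenerating nucleus).
    Streak intensity = annulus mean + ``fissure_contrast`` noise-SD units.
    Additive Gaussian noise of sd ``noise_sd`` everywhere.
    """
    for p in spec.fissure_positions:
        if p not in POSITIONS:
            raise ValueError(f"unknown fissure position {p!r}")
    S, R, C = config.image_shape
    rng = np.random.default_rng(spec.render_seed)
    unit = config.noise_sd if config.noise_sd > 0 else 1.0
    annulus_mean = 40.0
    nucleus_mean = 100.0 - 15.0 * (spec.degeneration_grade - 2)
    streak_value = annulus_mean + config.fissure_contrast * unit

    image = np.full((S, R, C), 5.0)
    roi = np.zeros((S, R, C), dtype=bool)
    fissure_mask = np.zeros((S, R, C), dtype=bool)
    position_masks = {p: np.zeros((S, R, C), dtype=bool)
                      for p in spec.fissure_positions if p in IN_PLANE_POSITIONS}
    scales = _slice_scales(S)
    wiggle_phase = float(rng.uniform(0, 2 * np.pi))

    in_plane = [p for p in spec.fissure_positions if p in IN_PLANE_POSITIONS]
    draw_streaks = (spec.fissure_present and in_plane
                    and not spec.severely_disrupted)

    for s in range(S):
        rho = _elliptical_radius((R, C), scales[s])
        sl_roi = rho <= 1.0
        roi[s] = sl_roi
        image[s][sl_roi] = annulus_mean
        image[s][rho <= NUCLEUS_RADIUS] = nucleus_mean
        if spec.severely_disrupted and spec.fissure_present:
            outer = sl_roi & (rho > NUCLEUS_RADIUS)
            image[s][outer] += config.fissure_contrast * unit * (
                0.3 + 0.4 * rng.random(int(outer.sum())))
        if draw_streaks:
            for p in in_plane:
                for (r, c) in _streak_voxels((R, C), scales[s], p,
                                             wiggle_phase):
                    if sl_roi[r, c] and rho[r, c] >= NUCLEUS_RADIUS - 0.05:
                        image[s, r, c] = streak_value
                        fissure_mask[s, r, c] = True
                        position_masks[p][s, r, c] = True

    if spec.severely_disrupted and spec.fissure_present:
        # diffuse pathology: the fissure "mask" is the outer annulus band
        for s in range(S):
            rho = _elliptical_radius((R, C), scales[s])
            band = roi[s] & (rho > OUTER_THIRD_RADIUS)
            fissure_mask[s] = band
            for p in position_masks:
                half = np.zeros_like(band)
                mid_col = C // 2
                if p == "ventral":
                    half[:, :mid_col] = True
                else:
                    half[:, mid_col:] = True
                position_masks[p][s] = band & half

    if config.noise_sd > 0:
        image += rng.normal(0.0, config.noise_sd, size=image.shape)

    # ">50% continuously intact outer third AF" analogue: only the severely
    # disrupted phenotype is excluded; lateral-only and fissure-free discs
    # stay in the attention-analysis set (lateral fissures are judged
    # incorrect downstream, not excluded).
    eligible = not (spec.fissure_present and spec.severely_disrupted)

    return DiscPhantom(
        disc_id=spec.disc_id,
        patient_id=spec.patient_id,
        level=spec.level,
        image=image,
        roi_mask=roi,
        fissure_mask=fissure_mask,
        position_masks=position_masks,
        fissure_present=bool(spec.fissure_present),
        fissure_positions=tuple(spec.fissure_positions),
        hiz_flag=bool(spec.hiz_flag),
        degeneration_grade=int(spec.degeneration_grade),
        ddd_grade=int(spec.ddd_grade),
        attention_eligible=eligible,
        severely_disrupted=bool(spec.severely_disrupted),
        voxel_spacing=config.voxel_spacing,
    )


def _draw_specs(config: PhantomConfig) -> List[DiscSpec]:
    ss = np.random.SeedSequence(config.seed)
    label_rng = np.random.default_rng(ss.spawn(1)[0])
    n_discs = config.n_patients * config.discs_per_patient
    render_seeds = np.random.SeedSequence((config.seed, 1)).generate_state(
        n_discs).astype(np.int64)
    specs = []
    pos_weights = np.array([config.ventral_fraction, config.dorsal_fraction,
                            config.both_fraction, config.lateral_fraction])
    pos_choices = ("ventral", "dorsal", "both", "lateral")
    i = 0
    for p in range(config.n_patients):
        pid = f"P{p:03d}"
        for d in range(config.discs_per_patient):
            level = LEVELS[(p + d) % len(LEVELS)]
            fissured = bool(label_rng.random() < config.fissure_prevalence)
            if fissured:
                choice = pos_choices[label_rng.choice(4, p=pos_weights /
                                                      pos_weights.sum())]
                positions = (("ventral", "dorsal") if choice == "both"
                             else (choice,))
                ddd = 2 if label_rng.random() < 87 / 94 else 3
                disrupted = bool(label_rng.random() < config.disrupted_fraction)
                has_in_plane = any(q in IN_PLANE_POSITIONS for q in positions)
                hiz = bool(has_in_plane
                           and config.fissure_contrast
                           >= config.hiz_visibility_cutoff
                           and label_rng.random() < config.hiz_fraction)
            else:
                positions = ()
                ddd = 0 if label_rng.random() < 8 / 29 else 1
                disrupted = False
                hiz = False
            grade = int(label_rng.choice(
                (2, 3, 4, 5), p=np.asarray(config.degeneration_grade_probs) /
                sum(config.degeneration_grade_probs)))
            specs.append(DiscSpec(
                disc_id=f"{pid}_D{d}", patient_id=pid, level=level,
                fissure_present=fissured, fissure_positions=positions,
                degeneration_grade=grade, ddd_grade=ddd, hiz_flag=hiz,
                severely_disrupted=disrupted,
                render_seed=int(render_seeds[i]) & 0x7FFFFFFF))
            i += 1
    return specs


def generate_cohort(config: PhantomConfig) -> Tuple[List[DiscPhantom],
                                                    pd.DataFrame]:
    """Generate a full synthetic cohort and its manifest.

    Deterministic given ``config.seed``: labels are drawn per disc from
    the configured distributions, patients form disjoint groups, and the
    manifest records one row per disc (identifiers plus every label).
    """
    discs = [render_disc(spec, config) for spec in _draw_specs(config)]
    return discs, cohort_manifest(discs)


def cohort_manifest(discs: Sequence[DiscPhantom]) -> pd.DataFrame:
    rows = []
    for d in discs:
        rows.append({
            "disc_id": d.disc_id,
            "patient_id": d.patient_id,
            "level": d.level,
            "fissure_present": bool(d.fissure_present),
            "fissure_positions": "+".join(d.fissure_positions),
            "hiz_flag": bool(d.hiz_flag),
            "degeneration_grade": d.degeneration_grade,
            "ddd_grade": d.ddd_grade,
            "attention_eligible": bool(d.attention_eligible),
            "severely_disrupted": bool(d.severely_disrupted),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort I/O (NIfTI images + CSV manifest + JSON config sidecar)
# ---------------------------------------------------------------------------

def _affine(spacing) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    return aff


def save_cohort(discs: Sequence[DiscPhantom], manifest: pd.DataFrame,
                out_dir, config: Optional[PhantomConfig] = None) -> None:
    """Write one NIfTI per disc per channel plus CSV manifest/JSON sidecar."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for d in discs:
        aff = _affine(d.voxel_spacing)
        nib.save(nib.Nifti1Image(d.image.astype(np.float32), aff),
                 out / f"{d.disc_id}_image.nii")
        nib.save(nib.Nifti1Image(d.roi_mask.astype(np.uint8), aff),
                 out / f"{d.disc_id}_roi.nii")
        nib.save(nib.Nifti1Image(d.fissure_mask.astype(np.uint8), aff),
                 out / f"{d.disc_id}_fissure.nii")
    manifest.to_csv(out / "manifest.csv", index=False)
    if config is not None:
        (out / "phantom_config.json").write_text(
            json.dumps(config.to_json(), indent=2, sort_keys=True))


def load_cohort(in_dir):
    """Load images/masks written by :func:`save_cohort`.

    Returns ``(rois, manifest)`` where ``rois`` maps disc_id to a dict
    with ``image``, ``roi_mask``, ``fissure_mask`` and ``voxel_spacing``.
    """
    import nibabel as nib

    in_dir = Path(in_dir)
    manifest = pd.read_csv(in_dir / "manifest.csv")
    rois = {}
    for disc_id in manifest["disc_id"]:
        img = nib.load(in_dir / f"{disc_id}_image.nii")
        roi = nib.load(in_dir / f"{disc_id}_roi.nii")
        fis = in_dir / f"{disc_id}_fissure.nii"
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        rois[disc_id] = {
            "image": np.asarray(img.dataobj, dtype=float),
            "roi_mask": np.asarray(roi.dataobj).astype(bool),
            "fissure_mask": (np.asarray(nib.load(fis).dataobj).astype(bool)
                             if fis.exists() else None),
            "voxel_spacing": spacing,
        }
    return rois, manifest
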