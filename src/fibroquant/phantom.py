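"""Synthetic paired-limb CT phantoms and cohorts.

A phantom slice shows two circular limb cross-sections on an air background,
each built from concentric compartments: a skin band on the outside, a
muscle/water core in the middle, and a subcutaneous fat annulus between
them.  Fibrosis is rendered as a reticulated lattice of strands inside the
fat annulus ("honeycomb" pattern), occupying a requested fraction of the
annulus area per limb.  HU values are sampled as class means plus Gaussian
noise; the generating masks double as exact ground truth.

Default HU means sit inside the physiologic ranges: air −1000, fat −80,
muscle/water 0 (water), skin 20, fibrosis 40 (soft tissue).  Skin at 20 HU
falls inside the −34..26 HU muscle/water window on purpose: it is only
recoverable morphologically, matching the labeling pipeline's ordering
(skin is peeled off before the HU window is applied).

Cohorts link a per-patient fibrosis burden to synthetic BEI/SCDR readings
through configurable linear links with Gaussian noise, planting a known
correlation structure for the statistics layer to recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from fibroquant._constants import AIR, FAT, FIBROSIS, MUSCLE_WATER, SKIN
from fibroquant.ct_io import CTSlice, LabelMap
from fibroquant.indices import LimbPairCounts, aggregate_subindices
from fibroquant.clinical_stats import PatientRecord

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "make_slice_pair",
    "make_patient",
    "make_cohort",
    "noise_sd_for_target_correlation",
]

DEFAULT_HU_MEANS = {
    AIR: -1000.0,
    MUSCLE_WATER: 0.0,
    FAT: -80.0,
    SKIN: 20.0,
    FIBROSIS: 40.0,
}


@dataclass
class PhantomSpec:
    """Geometry and intensity model of one paired-limb phantom slice.

    Radii are in pixels and must nest: muscle_radius < limb_radius −
    skin_thickness.  ``fibrosis_fraction_*`` is the proportion of each
    limb's fat annulus rendered as reticulation.  ``reticulation_period``
    sets the honeycomb lattice spacing.
    """

    image_size: int = 128
    limb_radius: float = 26.0
    skin_thickness: float = 2.0
    muscle_radius: float = 12.0
    fibrosis_fraction_affected: float = 0.2
    fibrosis_fraction_unaffected: float = 0.05
    hu_means: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_HU_MEANS))
    hu_noise_sd: float = 5.0
    reticulation_period: float = 7.0
    seed: int = 0
    affected_side: str = "left"

    def __post_init__(self) -> None:
        if not (0 < self.muscle_radius < self.limb_radius - self.skin_thickness):
            raise ValueError("radii must nest: muscle < limb - skin")
        for f in (self.fibrosis_fraction_affected, self.fibrosis_fraction_unaffected):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fibrosis fractions must lie in [0, 1]")
        if self.hu_noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        # each limb is centered in its image half at width/4 from the edge
        if self.limb_radius + 1 > self.image_size / 4:
            raise ValueError("limbs do not fit the image halves")


def _reticulation_pattern(shape: tuple[int, int], period: float) -> np.ndarray:
    """Distance-to-lattice field whose sublevel sets form a honeycomb-like
    web of strands.  Smaller values = closer to a lattice line."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]].astype(np.float64)
    # two oblique line families plus a horizontal one give a triangular web
    d1 = np.abs(((rr + 0.37 * period) % period) - period / 2)
    d2 = np.abs(((0.5 * rr + 0.866 * cc + 0.11 * period) % period) - period / 2)
    d3 = np.abs(((0.5 * rr - 0.866 * cc + 0.71 * period) % period) - period / 2)
    return np.minimum(np.minimum(d1, d2), d3)


def _limb_masks(
    spec: PhantomSpec, center: tuple[float, float], fraction: float
) -> np.ndarray:
    """Label one limb: concentric skin/fat/muscle with planted fibrosis.

    The fibrosis mask takes exactly round(fraction × annulus area) pixels,
    chosen as the annulus pixels closest to the reticulation lattice — a
    deterministic quantile cut, strictly monotone in ``fraction``.
    """
    n = spec.image_size
    rr, cc = np.mgrid[0:n, 0:n].astype(np.float64)
    dist = np.hypot(rr - center[0], cc - center[1])

    labels = np.full((n, n), AIR, dtype=np.uint8)
    body = dist <= spec.limb_radius
    interior = dist <= spec.limb_radius - spec.skin_thickness
    muscle = dist <= spec.muscle_radius
    annulus = interior & ~muscle

    labels[body & ~interior] = SKIN
    labels[muscle] = MUSCLE_WATER
    labels[annulus] = FAT

    k = int(round(fraction * annulus.sum()))
    if k > 0:
        pattern = _reticulation_pattern((n, n), spec.reticulation_period)
        flat_idx = np.flatnonzero(annulus.ravel())
        order = np.argsort(pattern.ravel()[flat_idx], kind="stable")
        chosen = flat_idx[order[:k]]
        fib = np.zeros(n * n, dtype=bool)
        fib[chosen] = True
        labels[fib.reshape(n, n)] = FIBROSIS
    return labels


def make_slice_pair(
    spec: PhantomSpec, slice_index: int = 0, patient_id: str = "phantom"
) -> tuple[CTSlice, LabelMap]:
    """One paired-limb slice and its exact generating label map.

    The affected limb sits in the image half named by ``affected_side``
    (image-left half for ``"left"`` — phantom coordinates, not radiological).
    """
    n = spec.image_size
    cy = n / 2.0 - 0.5
    cx_left = n / 4.0 - 0.5
    cx_right = 3.0 * n / 4.0 - 0.5
    if spec.affected_side == "left":
        f_left, f_right = spec.fibrosis_fraction_affected, spec.fibrosis_fraction_unaffected
    else:
        f_left, f_right = spec.fibrosis_fraction_unaffected, spec.fibrosis_fraction_affected

    left = _limb_masks(spec, (cy, cx_left), f_left)
    right = _limb_masks(spec, (cy, cx_right), f_right)
    labels = np.where(right != AIR, right, left).astype(np.uint8)

    rng = np.random.default_rng(spec.seed)
    hu = np.empty((n, n), dtype=np.float64)
    for cls, mean in spec.hu_means.items():
        hu[labels == cls] = mean
    if spec.hu_noise_sd > 0:
        hu += rng.normal(0.0, spec.hu_noise_sd, size=hu.shape)

    meta = dict(
        spacing=(0.5, 0.5),
        slice_index=slice_index,
        patient_id=patient_id,
        affected_side=spec.affected_side,
    )
    return CTSlice(hu, **meta), LabelMap(labels, **meta)


def _ground_truth_counts(lm: LabelMap, affected_side: str, region: str) -> LimbPairCounts:
    """Exact per-limb class counts from a generator label map (midline split).

    Phantom coordinates: the affected limb occupies the image half named by
    ``affected_side`` directly (no radiological mirroring).
    """
    mid = lm.shape[1] // 2
    left, right = lm.labels[:, :mid], lm.labels[:, mid:]
    aff, un = (left, right) if affected_side == "left" else (right, left)
    return LimbPairCounts(
        p_fat_aff=int((aff == FAT).sum()),
        p_fib_aff=int((aff == FIBROSIS).sum()),
        p_fat_un=int((un == FAT).sum()),
        p_fib_un=int((un == FIBROSIS).sum()),
        p_limb_un=int((un != AIR).sum()),
        p_limb_aff=int((aff != AIR).sum()),
        region=region,
    )


def make_patient(
    spec: PhantomSpec,
    n_slices: int = 4,
    landmark: int = 2,
    patient_id: str = "phantom",
) -> tuple[list[tuple[CTSlice, LabelMap]], list[LimbPairCounts]]:
    """A stack of slice pairs varying smoothly along the limb axis.

    Slices are ordered distal→proximal; slices with index ≥ ``landmark``
    are tagged proximal.  Limb radius grows ~15% from the most distal to
    the most proximal slice, as real limbs taper.  Returns the rendered
    pairs and the exact per-slice ground-truth counts.
    """
    if n_slices < 2:
        raise ValueError("need at least 2 slices")
    if not 1 <= landmark < n_slices:
        raise ValueError("landmark must satisfy 1 <= landmark < n_slices")
    pairs = []
    counts = []
    for i in range(n_slices):
        scale = 1.0 + 0.15 * i / max(n_slices - 1, 1)
        s = replace(
            spec,
            limb_radius=spec.limb_radius * scale,
            muscle_radius=spec.muscle_radius * scale,
            seed=spec.seed + i,
        )
        sl, lm = make_slice_pair(s, slice_index=i, patient_id=patient_id)
        region = "proximal" if i >= landmark else "distal"
        pairs.append((sl, lm))
        counts.append(_ground_truth_counts(lm, spec.affected_side, region))
    return pairs, counts


def noise_sd_for_target_correlation(target_r: float, signal_sd: float, coef: float = 1.0) -> float:
    """Noise sd that makes corr(coef·x + e, x) equal ``target_r`` in
    expectation, given sd(x) = signal_sd."""
    if not 0 < target_r <= 1:
        raise ValueError("target correlation must be in (0, 1]")
    return abs(coef) * signal_sd * math.sqrt(1.0 / target_r**2 - 1.0)


@dataclass
class CohortSpec:
    """Synthetic cohort with a planted burden → clinical-reference link.

    Per patient: fibrosis burden (the affected fat-annulus fibrosis
    fraction) is drawn from ``burden_distribution``; BEI ratio and both
    SCDRs are generated as intercept + coef·burden + Gaussian noise.
    ``bei_link``/``scdr_link`` are (coef, noise_sd) pairs.
    """

    n_patients: int = 30
    slices_per_patient: int = 4
    burden_distribution: Callable[[np.random.Generator], float] | tuple[float, float] = (0.05, 0.45)
    bei_link: tuple[float, float] = (1.0, 0.05)
    scdr_link: tuple[float, float] = (0.5, 0.15)
    seed: int = 0
    base_spec: PhantomSpec = field(default_factory=PhantomSpec)

    def __post_init__(self) -> None:
        if self.n_patients < 5:
            raise ValueError("cohort needs at least 5 patients")
        if self.bei_link[1] < 0 or self.scdr_link[1] < 0:
            raise ValueError("link noise sd must be non-negative")

    def draw_burden(self, rng: np.random.Generator) -> float:
        if callable(self.burden_distribution):
            return float(self.burden_distribution(rng))
        lo, hi = self.burden_distribution
        return float(rng.uniform(lo, hi))


def make_cohort(
    cspec: CohortSpec,
    render: bool = False,
    keep_stacks: bool = False,
) -> tuple[list[PatientRecord], list[list[tuple[CTSlice, LabelMap]]]]:
    """Generate a cohort of patient records (and optionally the image stacks).

    With ``render`` false the subindices come straight from the generator's
    exact ground-truth counts (fast path).  With ``render`` true every slice
    is rendered and re-labeled by the rule-based pipeline, so the subindices
    carry realistic segmentation noise.  Deterministic per seed.
    """
    from fibroquant.rule_label import RuleParams, label_slice

    rng = np.random.default_rng(cspec.seed)
    records: list[PatientRecord] = []
    stacks: list[list[tuple[CTSlice, LabelMap]]] = []
    landmark = max(1, cspec.slices_per_patient // 2)
    for i in range(cspec.n_patients):
        burden = cspec.draw_burden(rng)
        spec = replace(
            cspec.base_spec,
            fibrosis_fraction_affected=burden,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        pid = f"P{i:03d}"
        pairs, gt_counts = make_patient(
            spec, n_slices=cspec.slices_per_patient, landmark=landmark, patient_id=pid
        )
        if render:
            params = RuleParams(skin_erosion_radius=int(round(spec.skin_thickness)))
            counts = []
            for (sl, _), gt in zip(pairs, gt_counts):
                lm = label_slice(sl, params)
                # phantom coordinates: affected limb is in the half named by
                # affected_side, so count without radiological mirroring
                c = _ground_truth_counts(lm, spec.affected_side, gt.region)
                counts.append(c)
        else:
            counts = gt_counts
        sub = aggregate_subindices(counts)

        bcoef, bsd = cspec.bei_link
        scoef, ssd = cspec.scdr_link
        bei = bcoef * burden + (rng.normal(0.0, bsd) if bsd > 0 else 0.0)
        scdr_p = scoef * burden + (rng.normal(0.0, ssd) if ssd > 0 else 0.0)
        scdr_d = scoef * burden + (rng.normal(0.0, ssd) if ssd > 0 else 0.0)
        records.append(
            PatientRecord(
                patient_id=pid,
                subindices=sub,
                bei_ratio=float(bei),
                scdr_proximal=float(scdr_p),
                scdr_distal=float(scdr_d),
            )
        )
        if keep_stacks:
            stacks.append(pairs)
    return records, stacks
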