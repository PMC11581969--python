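"""Synthetic two-phase CT cohorts with planted tumor habitats.

Each synthetic patient carries an arterial-phase (ACE) and a venous-phase
(VCE) volume, an ellipsoidal tumor ROI partitioned into K spatially
contiguous habitat shells, a binary Tim-3 expression label, an IHC staining
profile, and exponential survival times. The construction is designed so
that the Tim-3 signal lives in one designated habitat: Tim-3-high patients
receive a mean shift and a texture-scale change in that habitat only, with
compensating shifts in the remaining habitats so the whole-ROI mean carries
no class information. Subregion-aware features can therefore separate the
classes where whole-tumor features largely cannot — the property the
habitat-vs-whole-tumor comparison is built to probe.

Everything is deterministic given ``(spec.seed, patient_index)``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging import ImageVolume, RoiMask, write_mask, write_volume

__all__ = [
    "CohortSpec",
    "SyntheticPatient",
    "assign_classes",
    "generate_patient",
    "generate_cohort",
    "generate_ihc_field",
    "sample_survival",
    "write_cohort",
    "CLINICAL_COLUMNS",
]

CLINICAL_COLUMNS = [
    "patient_id",
    "tim3_class",
    "h_score",
    "os_months",
    "os_event",
    "recurrence",
]

#: Dirichlet concentrations over (high positive, positive, low positive,
#: negative) IHC categories. The high-class prior concentrates mass in the
#: strongly stained categories (expected H-score 215 > 92.3), the low-class
#: prior in the weak ones (expected H-score ≈ 85 < 92.3).
IHC_ALPHA = {"high": (6.0, 4.0, 2.0, 1.0), "low": (1.0, 2.0, 4.0, 6.0)}

_HSCORE_WEIGHTS = np.array([3.0, 2.0, 1.0, 0.0])


@dataclasses.dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults emulate a single-center resectable-HCC cohort: 102 analyzed
    patients, three intratumoral habitats per tumor ordered core → rim by
    arterial enhancement, a balanced Tim-3 high/low split, and a hazard
    ratio of ~2.2 for overall survival in the Tim-3-high group.
    """

    n_patients: int = 102
    volume_shape: tuple[int, int, int] = (48, 48, 48)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tumor_radius_range: tuple[float, float] = (8.0, 14.0)
    n_habitats_true: int = 3
    #: mean HU per habitat, per phase; arterial contrast spread exceeds venous
    habitat_intensity_means: dict = dataclasses.field(
        default_factory=lambda: {
            "ACE": (40.0, 110.0, 180.0),
            "VCE": (60.0, 100.0, 145.0),
        }
    )
    #: correlation length (voxels) of the smoothed intensity noise per habitat
    habitat_texture_scale: tuple[float, ...] = (1.0, 1.75, 2.5)
    noise_sd: float = 20.0
    #: between-patient global enhancement variability (HU): one offset per
    #: patient and phase, shared by all habitats (contrast timing, cardiac
    #: output), so between-habitat contrast is preserved
    global_jitter_sd: float = 15.0
    #: residual per-habitat mean variability (HU) on top of the global offset
    habitat_jitter_sd: float = 6.0
    #: between-patient lognormal sd of each habitat's texture scale
    texture_jitter_sd: float = 0.15
    #: habitat (1-based) and phase carrying the Tim-3 signal
    signal_habitat: int = 2
    signal_phase: str = "ACE"
    #: mean HU shift of the signal habitat in Tim-3-high patients; kept small
    #: relative to the jitter scales so the class signal is mostly textural
    effect_size: float = 5.0
    #: texture-scale exchange in Tim-3-high patients: the signal habitat's
    #: correlation length gains this amount and the partner habitat loses it
    #: (with the default scales this swaps the two), so the whole-ROI
    #: mixture of textures is class-invariant while per-habitat texture flips
    texture_effect: float = 0.75
    #: habitat (1-based) giving up texture scale to the signal habitat
    texture_partner_habitat: int = 3
    class_balance: float = 0.5
    survival_hr: float = 2.2
    censor_rate: float = 0.3
    #: median overall survival of the Tim-3-low group, months
    median_survival_low: float = 60.0
    background_noise_sd: float = 10.0
    #: amplitude of the smooth shell-boundary perturbation (normalized radius)
    boundary_perturbation: float = 0.12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if self.n_habitats_true < 1:
            raise ValueError("n_habitats_true must be >= 1")
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError("class_balance must be in (0, 1)")
        for rate in (self.censor_rate,):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        for phase, means in self.habitat_intensity_means.items():
            if len(means) != self.n_habitats_true:
                raise ValueError(
                    f"{phase}: need {self.n_habitats_true} habitat means"
                )
            if len(set(means)) != len(means):
                raise ValueError(f"{phase}: habitat means must be distinct")
        if len(self.habitat_texture_scale) != self.n_habitats_true:
            raise ValueError("need one texture scale per habitat")
        if not 1 <= self.signal_habitat <= self.n_habitats_true:
            raise ValueError("signal_habitat out of range")
        if self.tumor_radius_range[0] > self.tumor_radius_range[1]:
            raise ValueError("invalid tumor_radius_range")


@dataclasses.dataclass
class SyntheticPatient:
    patient_id: str
    ace_volume: ImageVolume
    vce_volume: ImageVolume
    roi: RoiMask
    true_habitats: np.ndarray  # int grid, 0 outside ROI, 1..K inside
    tim3_class: str
    ihc_percent: np.ndarray  # (high+, +, low+, −), sums to 100
    h_score: float
    os_months: float
    os_event: int
    recurrence_flag: int


def _patient_rng(seed: int, patient_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(patient_index,))
    )


def assign_classes(spec: CohortSpec) -> np.ndarray:
    """Deterministic Tim-3 class per patient index.

    Exactly ``round(n * class_balance)`` patients are high, placed by a
    seeded permutation so classes are interleaved but reproducible.
    """
    n_high = int(round(spec.n_patients * spec.class_balance))
    labels = np.array(["high"] * n_high + ["low"] * (spec.n_patients - n_high))
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(2**20,)))
    return rng.permutation(labels)


def generate_ihc_field(
    rng: np.random.Generator | int, tim3_class: str
) -> np.ndarray:
    """Draw one IHC field as four category percentages summing to 100.

    Categories are (high positive, positive, low positive, negative);
    percentages are Dirichlet draws with class-specific concentration.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    alpha = IHC_ALPHA[tim3_class]
    pct = rng.dirichlet(alpha) * 100.0
    # guard the simplex constraint against floating-point drift
    return pct * (100.0 / pct.sum())


def sample_survival(
    rng: np.random.Generator,
    tim3_class: str,
    hr: float,
    censor_rate: float,
    median_low: float = 60.0,
) -> tuple[float, int]:
    """Exponential survival time with group-specific rate, plus censoring.

    The Tim-3-low group has median ``median_low`` months; the high group's
    hazard is multiplied by ``hr``. With probability ``censor_rate`` the
    observation is right-censored at a uniform fraction of the event time.
    """
    rate = np.log(2.0) / median_low
    if tim3_class == "high":
        rate *= hr
    t = rng.exponential(1.0 / rate)
    event = 1
    if rng.uniform() < censor_rate:
        event = 0
        t *= rng.uniform(0.05, 1.0)
    return max(float(t), 1e-3), event


def _smooth_unit_field(
    rng: np.random.Generator, shape: tuple[int, ...], sigma: float
) -> np.ndarray:
    """Gaussian-correlated noise field rescaled to unit global SD."""
    field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    sd = field.std()
    return field / sd if sd > 0 else field


def _make_geometry(
    spec: CohortSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Place an ellipsoidal ROI and partition it into perturbed shells."""
    shape = np.asarray(spec.volume_shape, dtype=int)
    spacing = np.asarray(spec.spacing_mm, dtype=float)
    lo, hi = spec.tumor_radius_range
    semi_mm = rng.uniform(lo, hi, size=3)
    semi_vox = semi_mm / spacing
    margin = 2.0
    for ax in range(3):
        if 2 * semi_vox[ax] + 2 * margin > shape[ax]:
            raise ValueError(
                f"tumor radius {semi_mm[ax]:.1f} mm does not fit along axis "
                f"{ax} of volume_shape {tuple(shape)}"
            )
    center = np.array(
        [
            rng.uniform(semi_vox[ax] + margin, shape[ax] - semi_vox[ax] - margin)
            for ax in range(3)
        ]
    )
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    rho = np.sqrt(
        sum(((g - c) / sv) ** 2 for g, c, sv in zip(grids, center, semi_vox))
    )
    roi = rho <= 1.0
    # perturb the radial coordinate with a smooth field so shell boundaries
    # are irregular but habitats stay contiguous
    rho_p = rho + spec.boundary_perturbation * _smooth_unit_field(rng, tuple(shape), 3.0)
    habitats = np.zeros(tuple(shape), dtype=np.uint8)
    k = spec.n_habitats_true
    vals = rho_p[roi]
    qs = np.quantile(vals, np.linspace(0, 1, k + 1)[1:-1]) if k > 1 else []
    lab = np.digitize(vals, qs) + 1  # 1 = innermost shell
    habitats[roi] = lab
    return roi, habitats


def _render_phase(
    spec: CohortSpec,
    rng: np.random.Generator,
    phase: str,
    roi: np.ndarray,
    habitats: np.ndarray,
    tim3_class: str,
) -> np.ndarray:
    """Draw one phase's intensity volume from the planted habitat model."""
    shape = tuple(spec.volume_shape)
    vol = rng.standard_normal(shape) * spec.background_noise_sd
    vol[roi] = 0.0
    k = spec.n_habitats_true
    global_offset = rng.normal(0.0, spec.global_jitter_sd) if spec.global_jitter_sd > 0 else 0.0
    counts = np.array([(habitats == h).sum() for h in range(1, k + 1)], dtype=float)
    shifts = np.zeros(k)
    if tim3_class == "high" and phase == spec.signal_phase:
        s = spec.signal_habitat - 1
        shifts[s] = spec.effect_size
        others = counts.sum() - counts[s]
        if others > 0:
            for j in range(k):
                if j != s:
                    shifts[j] = -spec.effect_size * counts[s] / others
    for h in range(1, k + 1):
        mask_h = habitats == h
        if not mask_h.any():
            continue
        mean_h = (
            spec.habitat_intensity_means[phase][h - 1]
            + shifts[h - 1]
            + global_offset
            + (rng.normal(0.0, spec.habitat_jitter_sd)
               if spec.habitat_jitter_sd > 0 else 0.0)
        )
        scale = spec.habitat_texture_scale[h - 1]
        if tim3_class == "high" and phase == spec.signal_phase:
            if h == spec.signal_habitat:
                scale += spec.texture_effect
            elif h == spec.texture_partner_habitat:
                scale = max(scale - spec.texture_effect, 0.3)
        if spec.texture_jitter_sd > 0:
            scale *= float(np.exp(rng.normal(0.0, spec.texture_jitter_sd)))
        if spec.noise_sd > 0:
            field = ndimage.gaussian_filter(rng.standard_normal(shape), scale)
            local_sd = field[mask_h].std()
            if local_sd > 0:
                field *= spec.noise_sd / local_sd
            vol[mask_h] = mean_h + field[mask_h]
        else:
            vol[mask_h] = mean_h
    return vol


def generate_patient(spec: CohortSpec, patient_index: int) -> SyntheticPatient:
    """Generate one fully specified synthetic patient.

    Deterministic given ``(spec.seed, patient_index)``; the Tim-3 class is
    taken from the cohort-level assignment so a patient can be regenerated
    in isolation.
    """
    classes = assign_classes(spec)
    tim3 = str(classes[patient_index])
    rng = _patient_rng(spec.seed, patient_index)
    roi, habitats = _make_geometry(spec, rng)
    ace = _render_phase(spec, rng, "ACE", roi, habitats, tim3)
    vce = _render_phase(spec, rng, "VCE", roi, habitats, tim3)
    ihc = generate_ihc_field(rng, tim3)
    h_score = float(_HSCORE_WEIGHTS @ ihc)
    os_months, os_event = sample_survival(
        rng, tim3, spec.survival_hr, spec.censor_rate, spec.median_survival_low
    )
    p_rec = 0.7 if tim3 == "high" else 0.5
    recurrence = int(rng.uniform() < p_rec)
    return SyntheticPatient(
        patient_id=f"P{patient_index:04d}",
        ace_volume=ImageVolume(ace, spec.spacing_mm, phase="ACE"),
        vce_volume=ImageVolume(vce, spec.spacing_mm, phase="VCE"),
        roi=RoiMask(roi.astype(np.uint8), spec.spacing_mm),
        true_habitats=habitats,
        tim3_class=tim3,
        ihc_percent=ihc,
        h_score=h_score,
        os_months=os_months,
        os_event=os_event,
        recurrence_flag=recurrence,
    )


def clinical_table(patients: list[SyntheticPatient]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": p.patient_id,
            "tim3_class": p.tim3_class,
            "h_score": p.h_score,
            "os_months": p.os_months,
            "os_event": p.os_event,
            "recurrence": p.recurrence_flag,
        }
        for p in patients
    ]
    return pd.DataFrame(rows, columns=CLINICAL_COLUMNS)


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[SyntheticPatient], pd.DataFrame]:
    """Generate the full cohort and its clinical table."""
    patients = [generate_patient(spec, i) for i in range(spec.n_patients)]
    return patients, clinical_table(patients)


def write_cohort(
    patients: list[SyntheticPatient],
    clinical: pd.DataFrame,
    out_dir: str | Path,
) -> None:
    """Write the cohort in the on-disk layout.

    ``<out>/<patient_id>/{ace,vce,roi,habitats_true}.nii.gz`` plus
    ``<out>/clinical.csv``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for p in patients:
        pdir = out / p.patient_id
        pdir.mkdir(exist_ok=True)
        write_volume(p.ace_volume, pdir / "ace.nii.gz")
        write_volume(p.vce_volume, pdir / "vce.nii.gz")
        write_mask(p.roi, pdir / "roi.nii.gz")
        img = nib.Nifti1Image(
            p.true_habitats.astype(np.uint8),
            np.diag(list(p.roi.spacing_mm) + [1.0]),
        )
        nib.save(img, str(pdir / "habitats_true.nii.gz"))
    clinical.to_csv(out / "clinical.csv", index=False)
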