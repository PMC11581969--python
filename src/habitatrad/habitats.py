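"""Tumor habitat generation: SLIC superpixels, K-means, ReMap harmonization.

The ROI of each patient is oversegmented into superpixels on the joint
two-phase (ACE, VCE) normalized image, superpixel intensity profiles are
clustered into K habitats with K-means, small connected components are
merged into their largest neighbor, and finally the per-patient cluster
labels — which an unsupervised algorithm assigns arbitrarily — are
harmonized across patients by ranking clusters on mean arterial-phase
intensity (the ReMap step), so habitat k carries comparable physical
meaning in every patient.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.segmentation import slic as _skimage_slic
from sklearn.cluster import KMeans

from .imaging import ImageVolume, RoiMask

__all__ = [
    "SuperpixelMap",
    "HabitatMap",
    "RemapRule",
    "slic_superpixels",
    "kmeans_habitats",
    "filter_small_regions",
    "remap_labels",
    "segment_patient",
]

logger = logging.getLogger(__name__)

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclasses.dataclass
class SuperpixelMap:
    """SLIC oversegmentation of one ROI.

    ``labels`` is 0 outside the ROI and 1..S inside; ``profiles`` holds one
    row per superpixel with mean normalized ACE/VCE intensity, voxel count
    and centroid.
    """

    labels: np.ndarray
    profiles: pd.DataFrame

    @property
    def n_superpixels(self) -> int:
        return len(self.profiles)


@dataclasses.dataclass
class HabitatMap:
    """K-habitat partition of one ROI (0 outside, 1..K inside)."""

    labels: np.ndarray
    k: int
    provenance: dict = dataclasses.field(default_factory=dict)

    def voxel_counts(self) -> dict[int, int]:
        labs, counts = np.unique(self.labels[self.labels > 0], return_counts=True)
        return dict(zip(labs.tolist(), counts.tolist()))

    def present_labels(self) -> list[int]:
        return sorted(self.voxel_counts())


@dataclasses.dataclass
class RemapRule:
    """Raw-cluster → harmonized-label permutation and its ordering statistic."""

    order_stat: dict[int, float]  # raw label -> mean ACE intensity
    permutation: dict[int, int]  # raw label -> harmonized label


def slic_superpixels(
    ace: ImageVolume,
    vce: ImageVolume,
    roi: RoiMask,
    n_segments: int | None = None,
    compactness: float = 0.05,
    seed: int = 0,
) -> SuperpixelMap:
    """Oversegment the ROI into superpixels on the joint (ACE, VCE) image.

    ``compactness`` balances intensity similarity against spatial proximity.
    ``n_segments`` defaults to one superpixel per ~75 ROI voxels (min 60) —
    superpixels must be thinner than the subregions they should tile, and
    habitat shells in cm-scale tumors are only a few mm thick. The
    algorithm itself is deterministic; ``seed`` is kept for interface
    stability.
    """
    mask = roi.as_bool()
    n_roi = int(mask.sum())
    if n_roi == 0:
        raise ValueError("empty ROI")
    if n_segments is None:
        n_segments = max(60, n_roi // 75)
        n_segments = min(n_segments, n_roi)
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    if n_roi < n_segments:
        raise ValueError(
            f"ROI has {n_roi} voxels < n_segments={n_segments}; "
            "lower n_segments"
        )
    if n_segments == 1:
        labels = mask.astype(np.int32)
    else:
        img = np.stack([ace.values, vce.values], axis=-1).astype(np.float64)
        labels = _skimage_slic(
            img,
            n_segments=n_segments,
            compactness=compactness,
            mask=mask,
            channel_axis=-1,
            start_label=1,
            enforce_connectivity=True,
        ).astype(np.int32)
        labels[~mask] = 0
        # relabel densely 1..S
        uniq = np.unique(labels[labels > 0])
        lut = np.zeros(labels.max() + 1, dtype=np.int32)
        lut[uniq] = np.arange(1, len(uniq) + 1)
        labels = lut[labels]
    profiles = _superpixel_profiles(labels, ace.values, vce.values)
    return SuperpixelMap(labels=labels, profiles=profiles)


def _superpixel_profiles(
    labels: np.ndarray, ace: np.ndarray, vce: np.ndarray
) -> pd.DataFrame:
    ids = np.unique(labels[labels > 0])
    mean_ace = ndimage.mean(ace, labels=labels, index=ids)
    mean_vce = ndimage.mean(vce, labels=labels, index=ids)
    counts = ndimage.sum_labels(np.ones_like(labels), labels=labels, index=ids)
    centroids = ndimage.center_of_mass(np.ones_like(labels), labels=labels, index=ids)
    return pd.DataFrame(
        {
            "superpixel": ids.astype(int),
            "mean_ace": mean_ace,
            "mean_vce": mean_vce,
            "voxel_count": counts.astype(int),
            "centroid_x": [c[0] for c in centroids],
            "centroid_y": [c[1] for c in centroids],
            "centroid_z": [c[2] for c in centroids],
        }
    ).set_index("superpixel")


def kmeans_habitats(
    sp: SuperpixelMap, k: int = 3, seed: int = 0, n_init: int = 10
) -> HabitatMap:
    """Cluster superpixel intensity profiles into K raw habitats.

    Profiles (mean ACE, mean VCE) are standardized before Lloyd's
    algorithm; every superpixel's voxels inherit its cluster label (1..K).
    """
    if sp.n_superpixels < k:
        raise ValueError(
            f"{sp.n_superpixels} superpixels < k={k}; cannot cluster"
        )
    x = sp.profiles[["mean_ace", "mean_vce"]].to_numpy(dtype=float)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    xz = (x - x.mean(axis=0)) / sd
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    assign = km.fit_predict(xz) + 1  # clusters 1..K
    lut = np.zeros(int(sp.labels.max()) + 1, dtype=np.int32)
    lut[sp.profiles.index.to_numpy()] = assign
    labels = lut[sp.labels]
    labels[sp.labels == 0] = 0
    return HabitatMap(labels=labels.astype(np.uint8), k=k,
                      provenance={"inertia": float(km.inertia_)})


def filter_small_regions(h: HabitatMap, min_voxels: int = 64) -> HabitatMap:
    """Merge habitat components smaller than ``min_voxels`` into neighbors.

    Each undersized connected component (26-connectivity) is reassigned to
    the habitat label of its largest adjacent region inside the ROI. Total
    ROI voxel count is conserved. If an entire habitat vanishes, K is
    effectively reduced and a log entry records it.
    """
    labels = h.labels.astype(np.int32).copy()
    roi = labels > 0
    for _ in range(100):  # merging can create new undersized components
        changed = False
        comp_labels, sizes = _components(labels, roi)
        small = [c for c in range(1, comp_labels.max() + 1) if sizes[c] < min_voxels]
        # leave the ROI intact if it is one undersized blob
        if len(sizes) - 1 <= 1:
            break
        for c in sorted(small, key=lambda c: sizes[c]):
            comp_mask = comp_labels == c
            if not comp_mask.any():
                continue
            if comp_mask.sum() >= min_voxels:
                continue
            target = _largest_adjacent_label(comp_labels, labels, comp_mask, roi)
            if target is None:
                continue
            labels[comp_mask] = target
            changed = True
        if not changed:
            break
    out = HabitatMap(labels=labels.astype(np.uint8), k=h.k,
                     provenance=dict(h.provenance))
    lost = set(range(1, h.k + 1)) - set(out.present_labels())
    if lost and set(h.present_labels()) >= lost:
        logger.info("small-region filtering removed habitat label(s) %s", lost)
    return out


def _components(labels: np.ndarray, roi: np.ndarray):
    """Connected components of the habitat partition (per habitat label)."""
    comp = np.zeros(labels.shape, dtype=np.int32)
    next_id = 1
    sizes = {0: 0}
    for lab in np.unique(labels[roi]):
        cc, n = ndimage.label(labels == lab, structure=_CONN26)
        for i in range(1, n + 1):
            m = cc == i
            comp[m] = next_id
            sizes[next_id] = int(m.sum())
            next_id += 1
    return comp, sizes


def _largest_adjacent_label(
    comp_labels: np.ndarray,
    labels: np.ndarray,
    comp_mask: np.ndarray,
    roi: np.ndarray,
) -> int | None:
    ring = ndimage.binary_dilation(comp_mask, structure=_CONN26) & roi & ~comp_mask
    if not ring.any():
        return None
    neighbor_comps = np.unique(comp_labels[ring])
    neighbor_comps = neighbor_comps[neighbor_comps > 0]
    if len(neighbor_comps) == 0:
        return None
    best, best_size = None, -1
    for nc in neighbor_comps:
        m = comp_labels == nc
        size = int(m.sum())
        if size > best_size:
            best_size = size
            best = int(labels[m][0])
    return best


def remap_patient(
    h: HabitatMap, ace: ImageVolume, vce: ImageVolume
) -> tuple[HabitatMap, RemapRule]:
    """Harmonize one patient's raw cluster labels by arterial intensity rank.

    Raw clusters are sorted ascending on mean normalized ACE intensity and
    relabeled 1..K, so harmonized label 1 is always the least-enhancing
    habitat. Ties break on mean VCE intensity, then on voxel count
    (descending), deterministically.
    """
    present = h.present_labels()
    stats = []
    for lab in present:
        m = h.labels == lab
        stats.append(
            (
                float(ace.values[m].mean()),
                float(vce.values[m].mean()),
                -int(m.sum()),
                lab,
            )
        )
    order = sorted(stats)
    perm = {rec[3]: new for new, rec in enumerate(order, start=1)}
    order_stat = {rec[3]: rec[0] for rec in stats}
    new_labels = np.zeros_like(h.labels)
    for raw, harm in perm.items():
        new_labels[h.labels == raw] = harm
    rule = RemapRule(order_stat=order_stat, permutation=perm)
    prov = dict(h.provenance)
    prov["remap"] = perm
    return HabitatMap(labels=new_labels, k=h.k, provenance=prov), rule


def remap_labels(
    cohort: list[HabitatMap],
    ace_volumes: list[ImageVolume],
    vce_volumes: list[ImageVolume],
) -> tuple[list[HabitatMap], list[RemapRule]]:
    """Apply the ReMap harmonization to every patient of a cohort."""
    ks = {h.k for h in cohort}
    if len(ks) > 1:
        raise ValueError(f"habitat maps built with different k: {ks}")
    maps, rules = [], []
    for h, a, v in zip(cohort, ace_volumes, vce_volumes):
        hm, rule = remap_patient(h, a, v)
        maps.append(hm)
        rules.append(rule)
    return maps, rules


def segment_patient(
    ace: ImageVolume,
    vce: ImageVolume,
    roi: RoiMask,
    k: int = 3,
    n_segments: int | None = None,
    compactness: float = 0.05,
    min_voxels: int = 64,
    seed: int = 0,
    n_init: int = 10,
) -> tuple[HabitatMap, RemapRule, SuperpixelMap]:
    """Full per-patient habitat pipeline: SLIC → K-means → filter → ReMap."""
    sp = slic_superpixels(ace, vce, roi, n_segments, compactness, seed)
    raw = kmeans_habitats(sp, k=k, seed=seed, n_init=n_init)
    filt = filter_small_regions(raw, min_voxels=min_voxels)
    harmonized, rule = remap_patient(filt, ace, vce)
    return harmonized, rule, sp
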