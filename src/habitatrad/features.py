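"""IBSI-style radiomic features: first-order, 3D shape, and texture matrices.

Implements the classic handcrafted feature families — intensity statistics,
3D geometry, and the four texture matrices (GLCM, GLRLM, GLSZM, NGTDM) —
computed on fixed-bin discretized intensities within an arbitrary region
(whole ROI or a single habitat). Feature vectors are extracted per phase and
per region and fused by column concatenation with
``<phase>__<region>__<family>__<feature>`` names (early fusion).

Gray levels are discretized with a fixed bin width on the normalized [0, 1]
intensity scale (default 0.05, i.e. 25 HU on the 500-HU CT window), so bins
mean the same thing in every patient. Texture matrices use 26-connectivity
and the 13 unique 3D directions at distance 1; directional features are
averaged over directions.

Degenerate regions (a single gray level) yield the standard limiting values
(zero contrast/entropy, correlation 1, ...) rather than NaN; the fallback is
logged.
"""

from __future__ import annotations

import dataclasses
import logging
from collections import OrderedDict

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "FeatureConfig",
    "extract_region_features",
    "extract_rad_table",
    "extract_habitat_table",
    "fused_columns",
    "feature_names",
]

logger = logging.getLogger(__name__)

ALL_FAMILIES = ("firstorder", "shape", "glcm", "glrlm", "glszm", "ngtdm")

#: the 13 unique direction offsets of a 26-connected 3D neighborhood
OFFSETS_3D = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1),
    (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclasses.dataclass(frozen=True)
class FeatureConfig:
    """Extraction configuration (fixed per study).

    ``bin_width`` is on the normalized [0, 1] scale; 0.05 corresponds to a
    25 HU bin on a 500 HU window. ``distance`` is the co-occurrence offset
    length in voxels.
    """

    bin_width: float = 0.05
    distance: int = 1
    families: tuple[str, ...] = ALL_FAMILIES

    @property
    def n_levels(self) -> int:
        return int(np.ceil(1.0 / self.bin_width))


def discretize(values: np.ndarray, config: FeatureConfig) -> np.ndarray:
    """Fixed-bin-width discretization to gray levels 1..n_levels."""
    lev = np.floor(values / config.bin_width).astype(np.int32) + 1
    return np.clip(lev, 1, config.n_levels)


def _crop_to_region(arrays: list[np.ndarray], mask: np.ndarray, pad: int = 1):
    sl = ndimage.find_objects(mask.astype(np.int8))[0]
    sl = tuple(
        slice(max(s.start - pad, 0), min(s.stop + pad, dim))
        for s, dim in zip(sl, mask.shape)
    )
    return [a[sl] for a in arrays], mask[sl]


def _shift(arr: np.ndarray, off: tuple[int, int, int], fill=0) -> np.ndarray:
    """Shift an array by ``off`` with constant fill (no wraparound)."""
    out = np.full_like(arr, fill)
    src = tuple(
        slice(max(0, -o), arr.shape[i] - max(0, o)) for i, o in enumerate(off)
    )
    dst = tuple(
        slice(max(0, o), arr.shape[i] - max(0, -o)) for i, o in enumerate(off)
    )
    out[dst] = arr[src]
    return out


# ---------------------------------------------------------------------------
# first-order


def _first_order(values: np.ndarray, levels: np.ndarray,
                 voxel_volume: float) -> OrderedDict:
    v = values.astype(np.float64)
    n = v.size
    p = np.bincount(levels)[1:].astype(float)
    p = p[p > 0] / n
    mean = v.mean()
    out = OrderedDict()
    out["energy"] = float((v ** 2).sum())
    out["total_energy"] = float((v ** 2).sum() * voxel_volume)
    out["entropy"] = float(-(p * np.log2(p)).sum())
    out["minimum"] = float(v.min())
    out["p10"] = float(np.percentile(v, 10))
    out["p90"] = float(np.percentile(v, 90))
    out["maximum"] = float(v.max())
    out["mean"] = float(mean)
    out["median"] = float(np.median(v))
    out["iqr"] = float(np.percentile(v, 75) - np.percentile(v, 25))
    out["range"] = float(v.max() - v.min())
    out["mad"] = float(np.abs(v - mean).mean())
    out["rms"] = float(np.sqrt((v ** 2).mean()))
    var = float(v.var())
    out["variance"] = var
    sd = np.sqrt(var)
    if sd > 0:
        out["skewness"] = float(((v - mean) ** 3).mean() / sd ** 3)
        out["kurtosis"] = float(((v - mean) ** 4).mean() / sd ** 4)
    else:
        out["skewness"] = 0.0
        out["kurtosis"] = 0.0
    out["uniformity"] = float((p ** 2).sum())
    return out


# ---------------------------------------------------------------------------
# shape


def _shape(mask: np.ndarray, spacing: tuple[float, float, float]) -> OrderedDict:
    from skimage import measure

    spacing = np.asarray(spacing, dtype=float)
    n_vox = int(mask.sum())
    voxel_volume = float(np.prod(spacing))
    volume = n_vox * voxel_volume
    out = OrderedDict()
    out["voxel_count"] = float(n_vox)
    out["volume_mm3"] = volume
    padded = np.pad(mask.astype(np.float64), 1)
    try:
        verts, faces, _, _ = measure.marching_cubes(padded, level=0.5,
                                                    spacing=tuple(spacing))
        area = float(measure.mesh_surface_area(verts, faces))
    except (ValueError, RuntimeError):  # pragma: no cover - degenerate mask
        area = 6.0 * voxel_volume ** (2 / 3) * n_vox
    out["surface_area_mm2"] = area
    out["surface_to_volume"] = area / volume if volume > 0 else 0.0
    out["sphericity"] = (
        float((36.0 * np.pi * volume ** 2) ** (1.0 / 3.0) / area) if area > 0 else 0.0
    )
    coords = np.argwhere(mask) * spacing
    out["max_diameter_mm"] = _max_diameter(coords)
    lam = _pca_eigenvalues(coords)
    out["major_axis_mm"] = float(4.0 * np.sqrt(lam[0]))
    out["minor_axis_mm"] = float(4.0 * np.sqrt(lam[1]))
    out["least_axis_mm"] = float(4.0 * np.sqrt(lam[2]))
    out["elongation"] = float(np.sqrt(lam[1] / lam[0])) if lam[0] > 0 else 1.0
    out["flatness"] = float(np.sqrt(lam[2] / lam[0])) if lam[0] > 0 else 1.0
    bbox = coords.max(axis=0) - coords.min(axis=0) + spacing
    out["extent"] = float(volume / np.prod(bbox)) if np.prod(bbox) > 0 else 1.0
    return out


def _max_diameter(coords: np.ndarray) -> float:
    if len(coords) == 1:
        return 0.0
    pts = coords
    if len(coords) > 10:
        try:
            hull = ConvexHull(coords)
            pts = coords[hull.vertices]
        except QhullError:
            pass
    if len(pts) > 400:  # cap the pairwise scan
        idx = np.linspace(0, len(pts) - 1, 400).astype(int)
        pts = pts[idx]
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def _pca_eigenvalues(coords: np.ndarray) -> np.ndarray:
    if len(coords) < 2:
        return np.zeros(3)
    cov = np.cov(coords, rowvar=False)
    lam = np.sort(np.linalg.eigvalsh(cov))[::-1]
    return np.clip(lam, 0.0, None)


# ---------------------------------------------------------------------------
# GLCM


def _glcm_matrix(levels: np.ndarray, region: np.ndarray, off, n_levels: int,
                 distance: int) -> np.ndarray:
    off = tuple(o * distance for o in off)
    shifted_lev = _shift(levels, off)
    shifted_reg = _shift(region, off, fill=False)
    valid = region & shifted_reg
    if not valid.any():
        return np.zeros((n_levels, n_levels))
    i = levels[valid] - 1
    j = shifted_lev[valid] - 1
    mat = np.zeros((n_levels, n_levels))
    np.add.at(mat, (i, j), 1.0)
    mat += mat.T  # symmetric co-occurrences
    return mat


def _glcm_features(mat: np.ndarray) -> OrderedDict:
    out = OrderedDict()
    total = mat.sum()
    n = mat.shape[0]
    idx = np.arange(1, n + 1, dtype=float)
    if total == 0:
        for k in ("contrast", "dissimilarity", "homogeneity", "inverse_difference",
                  "asm", "joint_entropy", "correlation", "cluster_shade",
                  "cluster_prominence", "max_probability", "sum_average",
                  "difference_entropy", "joint_average"):
            out[k] = 0.0
        out["correlation"] = 1.0
        return out
    p = mat / total
    ii, jj = np.meshgrid(idx, idx, indexing="ij")
    diff = np.abs(ii - jj)
    px = p.sum(axis=1)
    mu_x = (idx * px).sum()
    sig_x = np.sqrt(((idx - mu_x) ** 2 * px).sum())
    out["contrast"] = float((p * (ii - jj) ** 2).sum())
    out["dissimilarity"] = float((p * diff).sum())
    out["homogeneity"] = float((p / (1.0 + (ii - jj) ** 2)).sum())
    out["inverse_difference"] = float((p / (1.0 + diff)).sum())
    asm = float((p ** 2).sum())
    out["asm"] = asm
    nz = p[p > 0]
    out["joint_entropy"] = float(-(nz * np.log2(nz)).sum())
    if sig_x > 0:
        out["correlation"] = float(
            ((ii - mu_x) * (jj - mu_x) * p).sum() / (sig_x * sig_x)
        )
    else:
        out["correlation"] = 1.0  # single-level fallback
    out["cluster_shade"] = float((p * (ii + jj - 2 * mu_x) ** 3).sum())
    out["cluster_prominence"] = float((p * (ii + jj - 2 * mu_x) ** 4).sum())
    out["max_probability"] = float(p.max())
    out["sum_average"] = float((p * (ii + jj)).sum())
    # difference distribution p_{|i-j|}
    pd_ = np.zeros(n)
    for d in range(n):
        pd_[d] = p[diff == d].sum()
    nzd = pd_[pd_ > 0]
    out["difference_entropy"] = float(-(nzd * np.log2(nzd)).sum())
    out["joint_average"] = float(mu_x)
    return out


def _glcm(levels, region, config: FeatureConfig) -> OrderedDict:
    feats = None
    for off in OFFSETS_3D:
        mat = _glcm_matrix(levels, region, off, config.n_levels, config.distance)
        if mat.sum() == 0:  # no voxel pairs along this direction
            continue
        f = _glcm_features(mat)
        if feats is None:
            feats = OrderedDict((k, [v]) for k, v in f.items())
        else:
            for k, v in f.items():
                feats[k].append(v)
    if feats is None:  # single-voxel-thick everywhere: degenerate limits
        return _glcm_features(np.zeros((config.n_levels, config.n_levels)))
    return OrderedDict((k, float(np.mean(v))) for k, v in feats.items())


# ---------------------------------------------------------------------------
# GLRLM


def _glrlm_matrix(levels, region, off, n_levels):
    """Run-length matrix P[g-1, r-1] along one direction."""
    same_next = region & _shift(region, tuple(-o for o in off), fill=False)
    same_next &= levels == _shift(levels, tuple(-o for o in off))
    has_same_prev = region & _shift(region, off, fill=False)
    has_same_prev &= levels == _shift(levels, off)
    front = region & ~has_same_prev  # run starts
    max_run = max(region.shape)
    mat = np.zeros((n_levels, max_run))
    length = 1
    while front.any() and length <= max_run:
        ends = front & ~same_next
        if ends.any():
            g = levels[ends] - 1
            np.add.at(mat, (g, np.full(g.shape, length - 1)), 1.0)
        cont = front & same_next
        front = _shift(cont, tuple(-o for o in off), fill=False)
        length += 1
    return mat


def _rl_zone_features(mat: np.ndarray, n_vox: int, prefix_small: str,
                      prefix_large: str) -> OrderedDict:
    """Shared run-length / size-zone feature formulas.

    ``mat[g-1, s-1]`` counts runs (or zones) of gray level g and length
    (or size) s; features follow the usual small/large emphasis pattern.
    """
    out = OrderedDict()
    nonzero_cols = np.nonzero(mat.any(axis=0))[0]
    if len(nonzero_cols):
        mat = mat[:, : nonzero_cols[-1] + 1]
    total = mat.sum()
    ng, ns = mat.shape
    g = np.arange(1, ng + 1, dtype=float)[:, None]
    s = np.arange(1, ns + 1, dtype=float)[None, :]
    if total == 0:
        for k in (prefix_small, prefix_large, "gl_nonuniformity",
                  "length_nonuniformity", "fraction", "low_gl_emphasis",
                  "high_gl_emphasis", f"{prefix_small}_low_gl",
                  f"{prefix_small}_high_gl", f"{prefix_large}_low_gl",
                  f"{prefix_large}_high_gl", "gl_variance",
                  "length_variance", "entropy"):
            out[k] = 0.0
        return out
    p = mat / total
    out[prefix_small] = float((p / s ** 2).sum())
    out[prefix_large] = float((p * s ** 2).sum())
    out["gl_nonuniformity"] = float((mat.sum(axis=1) ** 2).sum() / total)
    out["length_nonuniformity"] = float((mat.sum(axis=0) ** 2).sum() / total)
    out["fraction"] = float(total / n_vox)
    out["low_gl_emphasis"] = float((p / g ** 2).sum())
    out["high_gl_emphasis"] = float((p * g ** 2).sum())
    out[f"{prefix_small}_low_gl"] = float((p / (g ** 2 * s ** 2)).sum())
    out[f"{prefix_small}_high_gl"] = float((p * g ** 2 / s ** 2).sum())
    out[f"{prefix_large}_low_gl"] = float((p * s ** 2 / g ** 2).sum())
    out[f"{prefix_large}_high_gl"] = float((p * g ** 2 * s ** 2).sum())
    mu_g = float((p * g).sum())
    mu_s = float((p * s).sum())
    out["gl_variance"] = float((p * (g - mu_g) ** 2).sum())
    out["length_variance"] = float((p * (s - mu_s) ** 2).sum())
    nz = p[p > 0]
    out["entropy"] = float(-(nz * np.log2(nz)).sum())
    return out


def _glrlm(levels, region, config: FeatureConfig) -> OrderedDict:
    n_vox = int(region.sum())
    feats = None
    for off in OFFSETS_3D:
        mat = _glrlm_matrix(levels, region, off, config.n_levels)
        f = _rl_zone_features(mat, n_vox, "short_run_emphasis",
                              "long_run_emphasis")
        if feats is None:
            feats = OrderedDict((k, [v]) for k, v in f.items())
        else:
            for k, v in f.items():
                feats[k].append(v)
    return OrderedDict((k, float(np.mean(v))) for k, v in feats.items())


# ---------------------------------------------------------------------------
# GLSZM


def _glszm(levels, region, config: FeatureConfig) -> OrderedDict:
    n_vox = int(region.sum())
    max_size = n_vox
    counts: dict[tuple[int, int], float] = {}
    for gl in np.unique(levels[region]):
        cc, n = ndimage.label((levels == gl) & region, structure=_CONN26)
        if n == 0:
            continue
        sizes = np.bincount(cc.ravel())[1:]
        for sz in sizes:
            key = (int(gl), int(sz))
            counts[key] = counts.get(key, 0.0) + 1.0
    mat = np.zeros((config.n_levels, max_size))
    for (gl, sz), c in counts.items():
        mat[gl - 1, sz - 1] = c
    return _rl_zone_features(mat, n_vox, "small_zone_emphasis",
                             "large_zone_emphasis")


# ---------------------------------------------------------------------------
# NGTDM


def _ngtdm(levels, region, config: FeatureConfig) -> OrderedDict:
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    reg_f = region.astype(np.float64)
    w = ndimage.convolve(reg_f, kernel, mode="constant")
    s_img = ndimage.convolve(levels * reg_f, kernel, mode="constant")
    valid = region & (w > 0)
    lev = levels[valid].astype(float)
    nb_mean = s_img[valid] / w[valid]
    n = lev.size
    ng = config.n_levels
    s_i = np.zeros(ng)
    n_i = np.zeros(ng)
    for i in range(1, ng + 1):
        m = lev == i
        n_i[i - 1] = m.sum()
        if m.any():
            s_i[i - 1] = np.abs(i - nb_mean[m]).sum()
    p_i = n_i / n if n > 0 else n_i
    present = p_i > 0
    ngp = int(present.sum())
    i_vals = np.arange(1, ng + 1, dtype=float)
    out = OrderedDict()
    denom_coarse = float((p_i * s_i).sum())
    out["coarseness"] = float(1.0 / denom_coarse) if denom_coarse > 0 else 1e6
    if ngp > 1 and n > 0:
        pi, pj = np.meshgrid(p_i, p_i, indexing="ij")
        ii, jj = np.meshgrid(i_vals, i_vals, indexing="ij")
        both = (pi > 0) & (pj > 0)
        out["contrast"] = float(
            (pi * pj * (ii - jj) ** 2)[both].sum()
            / (ngp * (ngp - 1))
            * s_i.sum() / n
        )
        denom_busy = float(np.abs(ii * pi - jj * pj)[both].sum())
        out["busyness"] = float((p_i * s_i).sum() / denom_busy) if denom_busy > 0 else 0.0
        with np.errstate(divide="ignore", invalid="ignore"):
            comp = np.abs(ii - jj) * (pi * s_i[:, None] + pj * s_i[None, :]) / (pi + pj)
        out["complexity"] = float(comp[both].sum() / n)
        s_sum = s_i.sum()
        out["strength"] = (
            float(((pi + pj) * (ii - jj) ** 2)[both].sum() / s_sum)
            if s_sum > 0 else 0.0
        )
    else:  # single gray level: textureless limits
        out["contrast"] = 0.0
        out["busyness"] = 0.0
        out["complexity"] = 0.0
        out["strength"] = 0.0
    return out


# ---------------------------------------------------------------------------
# region extraction and tables


def extract_region_features(
    volume,
    region,
    config: FeatureConfig | None = None,
) -> OrderedDict:
    """Extract all configured feature families from one region of one phase.

    Parameters
    ----------
    volume : ImageVolume
        Normalized ([0, 1]) intensity volume.
    region : ndarray of bool, or RoiMask
        Region to extract from; must be non-empty and aligned to ``volume``.

    Returns
    -------
    OrderedDict mapping ``<family>__<feature>`` to float.
    """
    config = config or FeatureConfig()
    mask = region.as_bool() if hasattr(region, "as_bool") else np.asarray(region, bool)
    if mask.shape != volume.values.shape:
        raise ValueError("region and volume shapes differ")
    if not mask.any():
        raise ValueError("empty region")
    (vals_c,), mask_c = _crop_to_region([volume.values], mask)
    levels = discretize(vals_c, config)
    levels_masked = np.where(mask_c, levels, 0)
    region_vals = vals_c[mask_c]
    n_distinct = len(np.unique(levels[mask_c]))
    if n_distinct < 2:
        logger.debug(
            "region has a single gray level; texture features take their "
            "degenerate limiting values"
        )
    voxel_volume = float(np.prod(volume.spacing_mm))
    out: OrderedDict[str, float] = OrderedDict()
    fams = config.families
    if "firstorder" in fams:
        for k, v in _first_order(region_vals, levels[mask_c], voxel_volume).items():
            out[f"firstorder__{k}"] = v
    if "shape" in fams:
        for k, v in _shape(mask_c, volume.spacing_mm).items():
            out[f"shape__{k}"] = v
    if "glcm" in fams:
        for k, v in _glcm(levels_masked, mask_c, config).items():
            out[f"glcm__{k}"] = v
    if "glrlm" in fams:
        for k, v in _glrlm(levels_masked, mask_c, config).items():
            out[f"glrlm__{k}"] = v
    if "glszm" in fams:
        for k, v in _glszm(levels_masked, mask_c, config).items():
            out[f"glszm__{k}"] = v
    if "ngtdm" in fams:
        for k, v in _ngtdm(levels_masked, mask_c, config).items():
            out[f"ngtdm__{k}"] = v
    return out


def feature_names(config: FeatureConfig | None = None) -> list[str]:
    """The ``<family>__<feature>`` names produced by one region extraction."""
    config = config or FeatureConfig()
    vol = np.zeros((4, 4, 4))
    vol[1:3, 1:3, 1:3] = np.linspace(0.1, 0.9, 8).reshape(2, 2, 2)
    from .imaging import ImageVolume

    probe = ImageVolume(vol, (1.0, 1.0, 1.0))
    mask = vol > 0
    return list(extract_region_features(probe, mask, config).keys())


def fused_columns(
    base_names: list[str],
    mode: str = "rad",
    k: int = 3,
    phases: tuple[str, str] = ("ACE", "VCE"),
) -> list[str]:
    """Column names of a fused feature table.

    ``mode='rad'`` → per phase, whole-ROI columns (2F total);
    ``mode='per_habitat'`` → per phase and habitat (2·K·F);
    ``mode='averaged'`` → per phase, habitat-averaged (2F).
    """
    cols = []
    for phase in phases:
        if mode == "rad":
            regions = ["whole"]
        elif mode == "per_habitat":
            regions = [f"habitat{i}" for i in range(1, k + 1)]
        elif mode == "averaged":
            regions = ["habitat_mean"]
        else:
            raise ValueError(f"unknown mode {mode!r}")
        for region in regions:
            cols.extend(f"{phase}__{region}__{name}" for name in base_names)
    return cols


def _phase_volumes(patient) -> dict[str, object]:
    return {"ACE": patient.ace_volume, "VCE": patient.vce_volume}


def extract_rad_table(
    cohort: list,
    config: FeatureConfig | None = None,
) -> pd.DataFrame:
    """Whole-ROI feature table, both phases fused (the Rad path).

    ``cohort`` items need ``patient_id``, ``ace_volume``, ``vce_volume``
    (normalized) and ``roi`` attributes. Patients missing a phase are
    excluded with a log entry.
    """
    config = config or FeatureConfig()
    base = feature_names(config)
    cols = fused_columns(base, mode="rad")
    rows, index = [], []
    for p in cohort:
        vols = _phase_volumes(p)
        if any(v is None for v in vols.values()):
            logger.warning("patient %s missing a phase; excluded", p.patient_id)
            continue
        row = []
        for phase in ("ACE", "VCE"):
            feats = extract_region_features(vols[phase], p.roi, config)
            row.extend(feats.values())
        rows.append(row)
        index.append(p.patient_id)
    return pd.DataFrame(rows, index=pd.Index(index, name="patient_id"), columns=cols)


def extract_habitat_table(
    cohort: list,
    habitat_maps: list,
    mode: str = "per_habitat",
    k: int = 3,
    config: FeatureConfig | None = None,
) -> pd.DataFrame:
    """Per-habitat feature table (the Habitat path).

    ``mode='per_habitat'`` keeps one column block per harmonized habitat
    (2·K·F columns); a habitat lost to small-region filtering yields NaN
    for its block (logged). ``mode='averaged'`` averages each feature over
    the habitats present (2F columns).
    """
    config = config or FeatureConfig()
    base = feature_names(config)
    cols = fused_columns(base, mode=mode, k=k)
    rows, index = [], []
    for p, hmap in zip(cohort, habitat_maps):
        vols = _phase_volumes(p)
        per_phase = {}
        for phase in ("ACE", "VCE"):
            vecs = []
            for hab in range(1, k + 1):
                region = hmap.labels == hab
                if not region.any():
                    logger.warning(
                        "patient %s: habitat %d absent; features missing",
                        p.patient_id, hab,
                    )
                    vecs.append(np.full(len(base), np.nan))
                else:
                    feats = extract_region_features(vols[phase], region, config)
                    vecs.append(np.array(list(feats.values())))
            per_phase[phase] = vecs
        row = []
        for phase in ("ACE", "VCE"):
            if mode == "per_habitat":
                for vec in per_phase[phase]:
                    row.extend(vec)
            elif mode == "averaged":
                stacked = np.vstack(per_phase[phase])
                row.extend(np.nanmean(stacked, axis=0))
            else:
                raise ValueError(f"unknown mode {mode!r}")
        rows.append(row)
        index.append(p.patient_id)
    return pd.DataFrame(rows, index=pd.Index(index, name="patient_id"), columns=cols)
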