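"""PCA/ICA cell detection and rule-based ROI refinement.

Automatic detection follows the spatio-temporal ICA approach used for
one-photon data: PCA reduces the movie, then ICA unmixes a concatenation
of spatial and temporal principal-component loadings weighted by ``mu``
(``mu=1`` purely spatial, ``0`` purely temporal).  Thresholded
independent-component filters become candidate ROIs, which are then
refined by size/roundness filtering, overlap merging, low-fluorescence
exclusion, and correlated-neighbor merging — and can be audited manually.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import ndimage
from skimage.measure import perimeter as _sk_perimeter
from skimage.morphology import disk
from sklearn.decomposition import PCA, FastICA

from .activity import DffMovie
from .io import CalimbaError, Movie

_STRUCT4 = ndimage.generate_binary_structure(2, 1)  # 4-connectivity


class UnknownRoiLabelError(CalimbaError, KeyError):
    """A referenced ROI label does not exist in the set."""


def roundness(mask: np.ndarray) -> float:
    """Isoperimetric roundness 4*pi*A / P^2, clipped to [0, 1].

    The perimeter P is the boundary crack-length estimate of
    ``skimage.measure.perimeter`` (4-neighborhood); a disc scores ~1,
    elongated shapes score low.  Very small compact masks can exceed 1
    with this discrete estimator and are clipped.
    """
    mask = np.asarray(mask, dtype=bool)
    area = int(mask.sum())
    if area == 0:
        return 0.0
    p = _sk_perimeter(mask, neighborhood=4)
    if p == 0:  # single pixel or degenerate
        return 1.0
    return float(min(1.0, 4.0 * np.pi * area / p**2))


@dataclass
class Roi:
    """A labeled binary mask presumed to cover one soma."""

    mask: np.ndarray
    label: int
    source: Literal["auto", "manual", "merged"] = "auto"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2 or not self.mask.any():
            raise ValueError("ROI mask must be a non-empty 2-D binary image")

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    @property
    def roundness(self) -> float:
        return roundness(self.mask)

    @property
    def centroid(self) -> tuple[float, float]:
        rr, cc = np.nonzero(self.mask)
        return float(rr.mean()), float(cc.mean())


@dataclass
class RoiSet:
    """Ordered collection of ROIs on a common movie grid."""

    rois: list[Roi] = field(default_factory=list)
    frame_shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.frame_shape is None and self.rois:
            self.frame_shape = self.rois[0].mask.shape
        for roi in self.rois:
            if roi.mask.shape != self.frame_shape:
                raise ValueError("ROI mask shape differs from frame_shape")

    def __len__(self) -> int:
        return len(self.rois)

    def __iter__(self):
        return iter(self.rois)

    def __getitem__(self, i: int) -> Roi:
        return self.rois[i]

    @property
    def labels(self) -> list[int]:
        return [r.label for r in self.rois]

    def relabeled(self) -> "RoiSet":
        """Copy with labels renumbered 1..N in order."""
        return RoiSet(
            [replace(r, mask=r.mask.copy(), label=i + 1) for i, r in enumerate(self.rois)],
            frame_shape=self.frame_shape,
        )

    def label_image(self) -> np.ndarray:
        """uint16 image with each pixel carrying its ROI label (0 = none).

        Later ROIs overwrite earlier ones where masks overlap.
        """
        img = np.zeros(self.frame_shape, dtype=np.uint16)
        for roi in self.rois:
            img[roi.mask] = roi.label
        return img


@dataclass
class IcaResult:
    """Spatial filters and temporal signals of the independent components."""

    spatial_filters: np.ndarray  # n_components x height x width
    temporal_signals: np.ndarray  # n_components x time
    n_pcs: int
    n_ics: int
    mu: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.spatial_filters)):
            raise ValueError("spatial filters must be finite")
        if self.spatial_filters.shape[0] != self.temporal_signals.shape[0]:
            raise ValueError("component count mismatch between filters and signals")


def pca_ica(
    dff: DffMovie | Movie,
    n_pcs: int,
    n_ics: int,
    mu: float = 0.5,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-5,
) -> IcaResult:
    """Spatio-temporal PCA/ICA cell sorting.

    The T x P movie matrix is reduced to ``n_pcs`` principal components;
    ICA then unmixes the concatenation of (variance-normalized) spatial
    and temporal PC loadings weighted by ``mu`` and ``1-mu``.  The output
    is deterministic for a fixed ``seed``.  Components are sign-flipped
    so their temporal signal has positive skew (calcium transients are
    positive-going).
    """
    if not 0.0 <= mu <= 1.0:
        raise ValueError("mu must be in [0, 1]")
    data = dff.data
    T, H, W = data.shape
    P = H * W
    if not (1 <= n_ics <= n_pcs <= min(T, P)):
        raise ValueError("need 1 <= n_ics <= n_pcs <= min(time, pixels)")
    X = data.reshape(T, P)

    pca = PCA(n_components=n_pcs, svd_solver="full", random_state=seed)
    temporal = pca.fit_transform(X)  # T x n_pcs
    spatial = pca.components_  # n_pcs x P
    if pca.n_components_ < n_pcs:
        raise ValueError("input rank below requested number of components")

    def _unit_rows(m: np.ndarray) -> np.ndarray:
        norm = np.linalg.norm(m, axis=1, keepdims=True)
        return m / np.where(norm == 0, 1.0, norm)

    joint = np.concatenate(
        [mu * _unit_rows(spatial), (1.0 - mu) * _unit_rows(temporal.T)], axis=1
    )  # n_pcs x (P + T)

    ica = FastICA(
        n_components=n_ics,
        random_state=seed,
        whiten="unit-variance",
        max_iter=max_iter,
        tol=tol,
    )
    ica.fit(joint.T)  # samples = P + T observations of n_pcs mixtures
    W_unmix = ica.components_  # n_ics x n_pcs

    filters = W_unmix @ spatial  # n_ics x P
    signals = W_unmix @ temporal.T  # n_ics x T
    # somata are sparse positive spatial structures: orient each component
    # so its spatial filter is positively skewed
    flip = np.where(_skew_rows(filters) < 0, -1.0, 1.0)
    filters *= flip[:, None]
    signals *= flip[:, None]
    return IcaResult(
        spatial_filters=filters.reshape(n_ics, H, W),
        temporal_signals=signals,
        n_pcs=n_pcs,
        n_ics=n_ics,
        mu=mu,
    )


def _skew_rows(m: np.ndarray) -> np.ndarray:
    c = m - m.mean(axis=1, keepdims=True)
    s = c.std(axis=1)
    s = np.where(s == 0, 1.0, s)
    return (c**3).mean(axis=1) / s**3


def filters_to_rois(
    ica: IcaResult, z_thresh: float = 3.0, min_speck_px: int = 5
) -> RoiSet:
    """Binarize IC spatial filters into candidate ROIs.

    Each filter is standardized over pixels, thresholded at ``z_thresh``
    on the positive side, hole-filled, cleaned of specks smaller than
    ``min_speck_px``, and split into 4-connected components; each
    component becomes one ROI with ``source='auto'``.
    """
    rois: list[Roi] = []
    label = 1
    shape = ica.spatial_filters.shape[1:]
    for filt in ica.spatial_filters:
        sd = filt.std()
        if sd == 0:
            continue
        z = (filt - filt.mean()) / sd
        binary = z >= z_thresh
        if not binary.any():
            continue
        binary = ndimage.binary_fill_holes(binary)
        labeled, n = ndimage.label(binary, structure=_STRUCT4)
        for comp in range(1, n + 1):
            mask = labeled == comp
            if mask.sum() < min_speck_px:
                continue
            rois.append(Roi(mask=mask, label=label, source="auto"))
            label += 1
    return RoiSet(rois, frame_shape=shape)


def filter_size_shape(
    rois: RoiSet,
    min_area: int = 30,
    max_area: int = 300,
    roundness_min: float = 0.6,
) -> RoiSet:
    """Remove ROIs outside the size window or below the roundness cutoff.

    Boundary values are kept: an ROI survives iff
    ``min_area <= area <= max_area`` and ``roundness >= roundness_min``.
    Manual ROIs are exempt.
    """
    kept = [
        r
        for r in rois
        if r.source == "manual"
        or (min_area <= r.area_px <= max_area and r.roundness >= roundness_min)
    ]
    return RoiSet(kept, frame_shape=rois.frame_shape)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _merge_groups(rois: RoiSet, uf: _UnionFind) -> RoiSet:
    groups: dict[int, list[Roi]] = {}
    order: list[int] = []
    for i, roi in enumerate(rois):
        root = uf.find(i)
        if root not in groups:
            groups[root] = []
            order.append(root)
        groups[root].append(roi)
    merged: list[Roi] = []
    for root in order:
        members = groups[root]
        if len(members) == 1:
            merged.append(members[0])
        else:
            union_mask = np.logical_or.reduce([m.mask for m in members])
            source = "manual" if any(m.source == "manual" for m in members) else "merged"
            merged.append(Roi(mask=union_mask, label=members[0].label, source=source))
    return RoiSet(merged, frame_shape=rois.frame_shape)


def merge_overlapping(
    rois: RoiSet,
    overlap_frac: float = 0.30,
    denominator: Literal["min", "union"] = "min",
) -> RoiSet:
    """Merge ROI pairs whose shared area exceeds ``overlap_frac``.

    Shared fraction is |A∩B| divided by the smaller ROI's area by
    default (``denominator='union'`` gives IoU instead).  Strictly-above
    comparison; merging is transitive via union-find, merged ROIs get
    ``source='merged'``.  Idempotent: a second pass changes nothing.
    """
    n = len(rois)
    uf = _UnionFind(n)
    areas = [r.area_px for r in rois]
    for i in range(n):
        for j in range(i + 1, n):
            inter = np.logical_and(rois[i].mask, rois[j].mask).sum()
            if inter == 0:
                continue
            if denominator == "min":
                denom = min(areas[i], areas[j])
            else:
                denom = areas[i] + areas[j] - inter
            if inter / denom > overlap_frac:
                uf.union(i, j)
    return _merge_groups(rois, uf)


def merge_correlated_neighbors(
    rois: RoiSet,
    traces: np.ndarray,
    r_merge: float = 0.8,
    neighbor_gap_px: int = 2,
) -> RoiSet:
    """Merge neighboring ROIs whose traces correlate above ``r_merge``.

    Two ROIs are neighbors when their boundary gap is at most
    ``neighbor_gap_px`` pixels (masks within dilation distance).  Pearson
    correlation strictly above ``r_merge`` (default 0.8) triggers a
    merge; merging is transitive.
    """
    traces = np.asarray(traces, dtype=float)
    n = len(rois)
    if traces.shape[0] != n:
        raise ValueError("need exactly one trace per ROI")
    selem = disk(neighbor_gap_px)
    dilated = [ndimage.binary_dilation(r.mask, structure=selem) for r in rois]
    uf = _UnionFind(n)
    for i in range(n):
        for j in range(i + 1, n):
            if not np.logical_and(dilated[i], rois[j].mask).any():
                continue
            ti, tj = traces[i], traces[j]
            if ti.std() == 0 or tj.std() == 0:
                continue
            r = float(np.corrcoef(ti, tj)[0, 1])
            if r > r_merge:
                uf.union(i, j)
    return _merge_groups(rois, uf)


def exclude_low_fluorescence(
    rois: RoiSet,
    movie: Movie,
    quantile: float = 0.05,
    absolute_floor: float | None = None,
) -> RoiSet:
    """Drop ROIs whose mean raw fluorescence is too low.

    Each ROI's brightness is its mean over the movie's temporal-mean
    image.  ROIs strictly below the given quantile of the ROI-brightness
    distribution are removed (when all ROIs tie, none is strictly below
    and none is removed); ``absolute_floor`` switches to an absolute
    threshold instead.  Manual ROIs are exempt.
    """
    if len(rois) == 0:
        return RoiSet([], frame_shape=rois.frame_shape)
    mean_img = movie.data.mean(axis=0)
    brightness = np.array([mean_img[r.mask].mean() for r in rois])
    if absolute_floor is not None:
        cut = absolute_floor
    else:
        cut = np.quantile(brightness, quantile)
    kept = [
        r
        for r, b in zip(rois, brightness)
        if r.source == "manual" or not b < cut
    ]
    return RoiSet(kept, frame_shape=rois.frame_shape)


def audit(
    rois: RoiSet,
    add_masks: Sequence[np.ndarray] = (),
    remove_labels: Iterable[int] = (),
) -> RoiSet:
    """Apply manual removals and additions.

    Additions are appended with ``source='manual'`` and are exempt from
    the automatic filters on re-run; an added mask overlapping an
    existing ROI leaves both (manual audit overrides merge rules).
    """
    remove = set(remove_labels)
    existing = set(rois.labels)
    unknown = remove - existing
    if unknown:
        raise UnknownRoiLabelError(f"labels not in set: {sorted(unknown)}")
    kept = [r for r in rois if r.label not in remove]
    next_label = max(existing, default=0) + 1
    out = list(kept)
    for mask in add_masks:
        out.append(Roi(mask=np.asarray(mask, dtype=bool), label=next_label, source="manual"))
        next_label += 1
    return RoiSet(out, frame_shape=rois.frame_shape or (add_masks[0].shape if len(add_masks) else None))


def refine(
    rois: RoiSet,
    movie: Movie,
    traces: np.ndarray | None = None,
    min_area: int = 30,
    max_area: int = 300,
    roundness_min: float = 0.6,
    overlap_frac: float = 0.30,
    low_fluor_quantile: float = 0.05,
    r_merge: float = 0.8,
) -> RoiSet:
    """Full refinement chain: size/shape -> overlap merge -> low-fluorescence
    -> correlated-neighbor merge (the last only when traces are given).

    Never increases the ROI count.
    """
    out = filter_size_shape(rois, min_area, max_area, roundness_min)
    out = merge_overlapping(out, overlap_frac)
    out = exclude_low_fluorescence(out, movie, low_fluor_quantile)
    if traces is not None and len(out):
        from .traces import extract_traces  # lazy: avoid import cycle

        raw, _ = extract_traces(movie, out)
        out = merge_correlated_neighbors(out, raw, r_merge)
    return out.relabeled()


def save_roiset(rois: RoiSet, tif_path: str | Path, json_path: str | Path) -> None:
    """Serialize as a labeled 16-bit TIFF plus a JSON sidecar of metadata."""
    import tifffile

    tifffile.imwrite(tif_path, rois.label_image())
    meta = [
        {
            "label": r.label,
            "source": r.source,
            "area_px": r.area_px,
            "roundness": round(r.roundness, 6),
            "centroid": [round(c, 3) for c in r.centroid],
        }
        for r in rois
    ]
    Path(json_path).write_text(json.dumps(meta, indent=2))


def load_roiset(tif_path: str | Path, json_path: str | Path | None = None) -> RoiSet:
    """Inverse of :func:`save_roiset` (overlaps collapse to the stored labels)."""
    import tifffile

    img = tifffile.imread(tif_path)
    sources: dict[int, str] = {}
    if json_path is not None and Path(json_path).exists():
        for entry in json.loads(Path(json_path).read_text()):
            sources[int(entry["label"])] = entry.get("source", "auto")
    rois = [
        Roi(mask=img == lab, label=int(lab), source=sources.get(int(lab), "auto"))
        for lab in np.unique(img)
        if lab != 0
    ]
    return RoiSet(rois, frame_shape=img.shape)
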