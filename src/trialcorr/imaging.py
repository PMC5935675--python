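"""Single-cell calling from 4-channel section images.

Nuclei are segmented from the nuclear channel by thresholding plus
connected components with area bounds. FISH spots are local maxima of a
difference-of-Gaussians band-pass response inside a nucleus. Per-cell calls:
pSTAT3 positivity by a per-slide Otsu (or fixed) threshold on mean nuclear
intensity, JAK2 amplification by the conventional spot-count ratio vs. the
CEP9 reference (ratio >= 2 with a floor of one reference spot), or an
absolute-count alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from trialcorr.records import CELL_COLUMNS, CHANNELS, population_label

RATIO_RULE = "ratio"
ABSOLUTE_RULE = "absolute"


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable knobs of segmentation, spot detection, and calling."""

    nuclear_threshold_method: str = "otsu"    # "otsu" | "fixed"
    nuclear_threshold: float = 100.0          # used when fixed
    min_nucleus_area: float = 60.0            # px^2
    max_nucleus_area: float = 4000.0
    spot_sigma_range: tuple[float, float] = (1.0, 2.5)  # DoG band (px)
    spot_min_prominence: float = 40.0         # DoG response threshold
    spot_min_distance: int = 2                # px between maxima
    pstat3_threshold_method: str = "otsu"     # "otsu" | "fixed"
    pstat3_threshold: float = 95.0            # used when fixed
    amp_rule: str = RATIO_RULE                # "ratio" | "absolute"
    amp_ratio: float = 2.0
    amp_min_spots: int = 4                    # absolute-rule cutoff

    def __post_init__(self):
        if not (0 < self.min_nucleus_area < self.max_nucleus_area):
            raise ValueError("need 0 < min_nucleus_area < max_nucleus_area")
        s1, s2 = self.spot_sigma_range
        if not (0 < s1 < s2):
            raise ValueError("spot_sigma_range must be increasing positive")
        if self.amp_rule not in (RATIO_RULE, ABSOLUTE_RULE):
            raise ValueError("amp_rule must be 'ratio' or 'absolute'")


def segment_nuclei(nuclear_channel: np.ndarray,
                   params: SegmentationParams = SegmentationParams()
                   ) -> tuple[np.ndarray, pd.DataFrame]:
    """Threshold + connected components with area filtering.

    Returns (label image, centroid table with columns label, x, y, area).
    A blank (constant) image yields zero nuclei.
    """
    img = np.asarray(nuclear_channel, dtype=float)
    if img.ndim != 2:
        raise ValueError("nuclear channel must be a 2-D image")
    labels = np.zeros(img.shape, dtype=int)
    if np.ptp(img) == 0:
        return labels, pd.DataFrame(columns=["label", "x", "y", "area"])
    if params.nuclear_threshold_method == "otsu":
        thr = threshold_otsu(img)
    else:
        thr = params.nuclear_threshold
    raw = cc_label(img > thr)
    rows = []
    next_id = 1
    for prop in regionprops(raw):
        if params.min_nucleus_area <= prop.area <= params.max_nucleus_area:
            labels[raw == prop.label] = next_id
            cy, cx = prop.centroid
            rows.append({"label": next_id, "x": cx, "y": cy,
                         "area": int(prop.area)})
            next_id += 1
    return labels, pd.DataFrame(rows, columns=["label", "x", "y", "area"])


def _dog_response(channel: np.ndarray, sigma_lo: float,
                  sigma_hi: float) -> np.ndarray:
    img = np.asarray(channel, dtype=float)
    return gaussian(img, sigma_lo, preserve_range=True) - \
        gaussian(img, sigma_hi, preserve_range=True)


def count_spots(channel: np.ndarray, labels: np.ndarray,
                params: SegmentationParams = SegmentationParams()
                ) -> pd.Series:
    """Spots per nucleus: band-pass local maxima assigned to labels.

    Maxima outside any nucleus are discarded. Returns a Series indexed by
    nucleus label (every label present, zero-filled).
    """
    channel = np.asarray(channel)
    labels = np.asarray(labels)
    if channel.shape != labels.shape:
        raise ValueError("channel and label image shapes differ")
    label_ids = np.unique(labels)
    label_ids = label_ids[label_ids > 0]
    counts = pd.Series(0, index=pd.Index(label_ids, name="label"),
                       dtype=int)
    if label_ids.size == 0:
        return counts
    dog = _dog_response(channel, *params.spot_sigma_range)
    peaks = peak_local_max(dog, min_distance=params.spot_min_distance,
                           threshold_abs=params.spot_min_prominence,
                           exclude_border=False)
    if peaks.size:
        owner = labels[peaks[:, 0], peaks[:, 1]]
        inside = owner > 0
        tallied = pd.Series(owner[inside]).value_counts()
        counts.loc[tallied.index] = tallied.to_numpy()
    return counts


def mean_nuclear_intensity(channel: np.ndarray, labels: np.ndarray
                           ) -> pd.Series:
    """Mean intensity of each labelled nucleus."""
    channel = np.asarray(channel, dtype=float)
    labels = np.asarray(labels)
    if channel.shape != labels.shape:
        raise ValueError("channel and label image shapes differ")
    ids = np.unique(labels)
    ids = ids[ids > 0]
    means = ndi.mean(channel, labels=labels, index=ids) if ids.size else []
    return pd.Series(means, index=pd.Index(ids, name="label"), dtype=float)


def call_amplification(jak2_spots, cep9_spots,
                       params: SegmentationParams = SegmentationParams()
                       ) -> np.ndarray:
    """Cell-level JAK2 amplification call.

    Ratio rule (default): jak2 / max(cep9, 1) >= amp_ratio — the reference
    count is floored at 1 so zero-CEP9 cells are retained rather than
    dropped. Absolute rule: jak2 >= amp_min_spots.
    """
    jak2 = np.asarray(jak2_spots, dtype=float)
    cep9 = np.asarray(cep9_spots, dtype=float)
    if params.amp_rule == ABSOLUTE_RULE:
        return jak2 >= params.amp_min_spots
    return jak2 / np.maximum(cep9, 1.0) >= params.amp_ratio


def call_cells(labels: np.ndarray, centroids: pd.DataFrame,
               jak2_counts: pd.Series, cep9_counts: pd.Series,
               pstat3_channel: np.ndarray,
               params: SegmentationParams = SegmentationParams()
               ) -> pd.DataFrame:
    """Assemble the per-cell record table with phenotype/genotype calls.

    pSTAT3 positivity thresholds the per-nucleus mean intensity, by Otsu
    over this slide's nuclei by default (fixed threshold override in
    ``params``). Cells with zero reference (CEP9) spots are flagged in the
    ``cep9_zero`` column but still called via the floored ratio.
    """
    intensity = mean_nuclear_intensity(pstat3_channel, labels)
    if len(intensity) == 0:
        return pd.DataFrame(columns=CELL_COLUMNS)
    if params.pstat3_threshold_method == "otsu" and intensity.nunique() > 1:
        thr = threshold_otsu(intensity.to_numpy())
    else:
        thr = params.pstat3_threshold
    idx = intensity.index
    jak2 = jak2_counts.reindex(idx, fill_value=0).to_numpy()
    cep9 = cep9_counts.reindex(idx, fill_value=0).to_numpy()
    pos = intensity.to_numpy() > thr
    amp = call_amplification(jak2, cep9, params)
    cent = centroids.set_index("label").reindex(idx)
    out = pd.DataFrame({
        "cell_id": idx.to_numpy(),
        "x": cent["x"].to_numpy(),
        "y": cent["y"].to_numpy(),
        "jak2_spots": jak2.astype(int),
        "cep9_spots": cep9.astype(int),
        "pstat3_intensity": intensity.to_numpy(),
        "pstat3_pos": pos,
        "jak2_amp": amp,
        "cd8": False,
        "gzmb": False,
        "population": [population_label(p, a) for p, a in zip(pos, amp)],
    })[CELL_COLUMNS]
    out["cep9_zero"] = cep9 == 0
    return out


def process_slide(image: np.ndarray,
                  params: SegmentationParams = SegmentationParams()
                  ) -> pd.DataFrame:
    """Image stack (DAPI, JAK2, CEP9, pSTAT3) -> cell record table."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[0] != len(CHANNELS):
        raise ValueError(f"expected a ({len(CHANNELS)}, H, W) stack")
    dapi, jak2_ch, cep9_ch, pstat3_ch = (image[i] for i in range(4))
    labels, centroids = segment_nuclei(dapi, params)
    jak2 = count_spots(jak2_ch, labels, params)
    cep9 = count_spots(cep9_ch, labels, params)
    return call_cells(labels, centroids, jak2, cep9, pstat3_ch, params)


def process_slide_file(path,
                       params: SegmentationParams = SegmentationParams()
                       ) -> pd.DataFrame:
    """Read a multi-page TIFF (channel order as written) and call cells."""
    stack = tifffile.imread(path)
    return process_slide(np.asarray(stack), params)
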