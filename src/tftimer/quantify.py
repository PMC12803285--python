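"""Image-side measurement operators.

Mirrors the measurements of the wing-disc study: ImageJ-style intensity
profiles along the A/P axis, compartment partition of channel intensity,
Laplacian-of-Gaussian puncta detection, intensity-weighted (Manders M1)
colocalization, and extraction of the normalized slow/fast ratio at
basolateral membranes.  All operators are deterministic given their seed
and configuration; estimators with uncertainty report seeded bootstrap
confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import dilation, disk, skeletonize

__all__ = [
    "IntensityProfile",
    "PunctaSet",
    "ColocResult",
    "RatioResult",
    "QuantifyError",
    "plot_profile",
    "subtract_background",
    "compartment_partition",
    "detect_puncta",
    "intensity_overlap",
    "membrane_ratio",
    "membrane_mask_from_channel",
]


class QuantifyError(ValueError):
    pass


@dataclass
class IntensityProfile:
    """Column-wise mean intensity along the A/P axis (ImageJ plot-profile)."""

    positions_um: np.ndarray
    values: np.ndarray
    regions: list

    def region_mean(self, label: str) -> float:
        sel = [r == label for r in self.regions]
        if not any(sel):
            raise QuantifyError(f"no profile positions in region {label!r}")
        return float(np.mean(self.values[np.asarray(sel)]))


@dataclass
class PunctaSet:
    """Detected puncta; ``table`` columns: y_um, x_um, radius_um,
    intensity (integrated, background-subtracted), plus region when given."""

    table: pd.DataFrame
    pixel_size: float

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class ColocResult:
    fraction: float
    ci_lo: float
    ci_hi: float
    n_puncta: int
    region: str = ""
    channel_pair: tuple = ()


@dataclass
class RatioResult:
    """Per-region normalized slow/fast membrane ratio.

    ``status`` is "ok" or "undefined" (fast channel at/below the noise
    floor, the regime where the fast chromophore is quenched or absent).
    """

    region: str
    ratio: float
    ci_lo: float
    ci_hi: float
    n_pixels: int
    status: str = "ok"


def plot_profile(
    image: np.ndarray,
    pixel_size: float,
    mask: np.ndarray | None = None,
    region_masks: dict | None = None,
    background: float | None = None,
) -> IntensityProfile:
    """Mean intensity per image column, optionally restricted to a mask.

    The value at column x is the mean over unmasked rows at x; columns with
    no unmasked pixel are NaN.  ``background`` is subtracted if given.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise QuantifyError(f"expected a 2-D channel image, got shape {image.shape}")
    if mask is not None:
        if not mask.any():
            raise QuantifyError("profile mask is empty")
        data = np.where(mask, image, np.nan)
    else:
        data = image
    with np.errstate(invalid="ignore"):
        values = np.nanmean(data, axis=0)
    if background is not None:
        values = values - background
    nx = image.shape[1]
    positions = (np.arange(nx) + 0.5) * pixel_size
    regions = [""] * nx
    if region_masks:
        for label, m in region_masks.items():
            cols = m.any(axis=0)
            for i in np.nonzero(cols)[0]:
                regions[i] = label
    return IntensityProfile(positions_um=positions, values=values, regions=regions)


def subtract_background(
    image: np.ndarray,
    mask: np.ndarray | None = None,
    method: str = "percentile",
    percentile: float = 5.0,
    floor: bool = True,
) -> np.ndarray:
    """Background-subtract a channel image.

    Default: subtract the 5th percentile of the (masked) pixel values and
    floor at 0.  ``method="median"`` subtracts the median instead (useful
    when most pixels are background and unbiased sums matter; no floor by
    default semantics still applies the ``floor`` flag).
    """
    image = np.asarray(image, dtype=float)
    pixels = image[mask] if mask is not None else image.ravel()
    if pixels.size == 0:
        raise QuantifyError("background mask is empty")
    if method == "percentile":
        bg = np.percentile(pixels, percentile)
    elif method == "median":
        bg = np.median(pixels)
    else:
        raise QuantifyError(f"unknown background method {method!r}")
    out = image - bg
    if floor:
        out = np.clip(out, 0.0, None)
    return out


def compartment_partition(image: np.ndarray, masks: dict) -> dict:
    """Fraction of total channel intensity per (disjoint) region mask.

    Fractions sum to 1 over the union of the masks.
    """
    image = np.asarray(image, dtype=float)
    labels = list(masks)
    stack = np.stack([masks[k] for k in labels])
    if (stack.sum(axis=0) > 1).any():
        raise QuantifyError("partition masks overlap")
    sums = {k: float(image[masks[k]].sum()) for k in labels}
    total = sum(sums.values())
    if total <= 0:
        raise QuantifyError("zero total signal over the partition masks")
    return {k: v / total for k, v in sums.items()}


def detect_puncta(
    image: np.ndarray,
    pixel_size: float,
    spot_sigma_um: float = 0.4,
    region_mask: np.ndarray | None = None,
    min_area_px: int = 4,
) -> PunctaSet:
    """Laplacian-of-Gaussian spot detection at a known spot scale.

    The scale-normalized LoG response is thresholded by Otsu (computed on
    the response inside the mask), connected components become puncta, and
    centroids are intensity-weighted.  Detections are sorted by (y, x) for
    determinism; an empty set is a valid result.
    """
    image = np.asarray(image, dtype=float)
    s = spot_sigma_um / pixel_size
    response = -ndimage.gaussian_laplace(image, sigma=s) * s * s
    sel = region_mask if region_mask is not None else np.ones_like(image, dtype=bool)
    vals = response[sel]
    if vals.size == 0 or np.ptp(vals) <= 0:
        return PunctaSet(_empty_puncta(), pixel_size)
    thr = threshold_otsu(vals)
    binary = (response > thr) & sel
    labels, n = ndimage.label(binary)
    if n == 0:
        return PunctaSet(_empty_puncta(), pixel_size)
    rows = []
    bg = np.percentile(image[sel], 5.0)
    for lab in range(1, n + 1):
        comp = labels == lab
        area = int(comp.sum())
        if area < min_area_px:
            continue
        w = np.clip(image * comp, 0.0, None)
        total_w = w.sum()
        if total_w <= 0:
            continue
        yy, xx = np.nonzero(comp)
        cy = float((yy * w[yy, xx]).sum() / total_w)
        cx = float((xx * w[yy, xx]).sum() / total_w)
        intensity = float((image[comp] - bg).clip(0).sum())
        if intensity <= 0:
            continue
        rows.append(
            dict(
                y_um=(cy + 0.5) * pixel_size,
                x_um=(cx + 0.5) * pixel_size,
                radius_um=float(np.sqrt(area / np.pi) * pixel_size),
                intensity=intensity,
                label=lab,
            )
        )
    table = pd.DataFrame(rows) if rows else _empty_puncta()
    table = table.sort_values(["y_um", "x_um"]).reset_index(drop=True)
    return PunctaSet(table, pixel_size)


def _empty_puncta() -> pd.DataFrame:
    return pd.DataFrame(columns=["y_um", "x_um", "radius_um", "intensity", "label"])


def intensity_overlap(
    signal: np.ndarray,
    partner: np.ndarray,
    region_mask: np.ndarray,
    pixel_size: float,
    spot_sigma_um: float = 0.4,
    mask_dilation_px: int = 2,
    n_boot: int = 1000,
    seed: int = 0,
    region: str = "",
    channel_pair: tuple = (),
) -> ColocResult:
    """Manders-style M1: fraction of signal intensity inside the partner mask.

    Both channels are background-subtracted (5th percentile within the
    region).  The partner mask is Otsu-thresholded on intensity and dilated
    ``mask_dilation_px`` to cover the blurred skirt of partner objects (the
    threshold sits near half the object peak, so without dilation the mask
    clips the skirt of perfectly colocalized signal).  The confidence
    interval is
    a seeded bootstrap over detected signal puncta: each punctum contributes
    its integrated intensity and its in-mask intensity, and the diffuse
    (non-punctal) remainder is kept fixed.
    """
    region_mask = np.asarray(region_mask, dtype=bool)
    sig = subtract_background(np.where(region_mask, signal, 0.0), mask=region_mask)
    par = subtract_background(np.where(region_mask, partner, 0.0), mask=region_mask)
    total = sig[region_mask].sum()
    if total <= 0:
        raise QuantifyError("zero total signal intensity in region")
    pvals = par[region_mask]
    if np.ptp(pvals) <= 0:
        pmask = np.zeros_like(region_mask)
    else:
        thr = threshold_otsu(pvals)
        pmask = (par > thr) & region_mask
        if mask_dilation_px > 0:
            pmask = dilation(pmask, disk(mask_dilation_px)) & region_mask
    inside = sig[pmask].sum() if pmask.any() else 0.0
    m1 = float(inside / total)

    # bootstrap over detected signal puncta
    det = detect_puncta(signal, pixel_size, spot_sigma_um, region_mask)
    if len(det):
        lab_img, _ = _relabel(signal, det, region_mask, pixel_size, spot_sigma_um)
        tot_i, in_i = [], []
        for lab in det.table["label"]:
            comp = lab_img == lab
            tot_i.append(sig[comp].sum())
            in_i.append(sig[comp & pmask].sum())
        tot_i = np.asarray(tot_i)
        in_i = np.asarray(in_i)
        rest_tot = total - tot_i.sum()
        rest_in = inside - in_i.sum()
        rng = np.random.default_rng(seed)
        n = len(tot_i)
        idx = rng.integers(0, n, size=(n_boot, n))
        boot_tot = tot_i[idx].sum(axis=1) + rest_tot
        boot_in = in_i[idx].sum(axis=1) + rest_in
        with np.errstate(divide="ignore", invalid="ignore"):
            boot = np.where(boot_tot > 0, boot_in / boot_tot, np.nan)
        lo, hi = np.nanpercentile(boot, [2.5, 97.5])
        lo, hi = min(lo, m1), max(hi, m1)
    else:
        lo = hi = m1
    return ColocResult(
        fraction=m1, ci_lo=float(lo), ci_hi=float(hi), n_puncta=len(det),
        region=region, channel_pair=channel_pair,
    )


def _relabel(signal, det: PunctaSet, region_mask, pixel_size, spot_sigma_um):
    """Recompute the LoG component label image matching ``detect_puncta``."""
    s = spot_sigma_um / pixel_size
    response = -ndimage.gaussian_laplace(np.asarray(signal, float), sigma=s) * s * s
    thr = threshold_otsu(response[region_mask])
    labels, n = ndimage.label((response > thr) & region_mask)
    return labels, n


def membrane_mask_from_channel(
    membrane_channel: np.ndarray, dilate_px: int = 1
) -> np.ndarray:
    """Membrane pixels from the membrane-marker channel.

    Otsu threshold, skeletonize to the lattice midline, dilate 1 px.
    """
    img = np.asarray(membrane_channel, dtype=float)
    thr = threshold_otsu(img)
    skel = skeletonize(img > thr)
    if dilate_px > 0:
        skel = dilation(skel, disk(dilate_px))
    return skel


def membrane_ratio(
    image_slow: np.ndarray,
    image_fast: np.ndarray,
    membrane_mask: np.ndarray,
    region_masks: dict,
    calibration_constant: float = 1.0,
    n_boot: int = 500,
    seed: int = 0,
    noise_floor_sigmas: float = 5.0,
    bg_margin_px: int = 4,
    region_erosion_px: int = 6,
) -> dict:
    """Normalized slow/fast fluorescence ratio on membrane pixels per region.

    Region masks are eroded by ``region_erosion_px`` before measuring, so
    membrane segments shared between adjacent regions (cell outlines
    straddling a region boundary carry mixed signal) do not contaminate the
    per-region ratio.  Per-channel background is the mean over region
    pixels farther than
    ``bg_margin_px`` from the membrane mask (so the blurred membrane skirt
    does not inflate it).  The ratio of background-subtracted membrane-pixel
    means is divided by ``calibration_constant`` (the slow/fast ratio of an
    infinitely old pool) so that 1 means fully matured.  Uncertainty is a
    seeded pixel bootstrap.  A region whose fast-channel signal is below
    ``noise_floor_sigmas`` standard errors is reported with status
    "undefined" (the quenched / undetectable-fast regime) rather than a
    number.
    """
    slow = np.asarray(image_slow, dtype=float)
    fast = np.asarray(image_fast, dtype=float)
    membrane_mask = np.asarray(membrane_mask, dtype=bool)
    far = ndimage.distance_transform_edt(~membrane_mask) > bg_margin_px
    rng = np.random.default_rng(seed)
    out = {}
    for label, region in region_masks.items():
        region = np.asarray(region, dtype=bool)
        if region_erosion_px > 0:
            eroded = ndimage.binary_erosion(
                region, disk(region_erosion_px), border_value=1
            )
            if (eroded & membrane_mask).any():
                region = eroded
        on = membrane_mask & region
        off = far & region
        if not on.any() or not off.any():
            raise QuantifyError(f"region {label!r} has no membrane or background pixels")
        s_on, f_on = slow[on], fast[on]
        s_bg, f_bg = slow[off].mean(), fast[off].mean()
        s_sig = s_on.mean() - s_bg
        f_sig = f_on.mean() - f_bg
        n = on.sum()
        f_se = fast[on].std(ddof=1) / np.sqrt(n) + fast[off].std(ddof=1) / np.sqrt(off.sum())
        if f_sig <= noise_floor_sigmas * f_se:
            out[label] = RatioResult(
                region=label, ratio=np.nan, ci_lo=np.nan, ci_hi=np.nan,
                n_pixels=int(n), status="undefined",
            )
            continue
        ratio = (s_sig / f_sig) / calibration_constant
        idx = rng.integers(0, n, size=(n_boot, n))
        # background means carry their own sampling error; propagate it
        s_bg_se = slow[off].std(ddof=1) / np.sqrt(off.sum())
        f_bg_se = fast[off].std(ddof=1) / np.sqrt(off.sum())
        s_bg_b = s_bg + rng.normal(0.0, s_bg_se, n_boot)
        f_bg_b = f_bg + rng.normal(0.0, f_bg_se, n_boot)
        with np.errstate(divide="ignore", invalid="ignore"):
            boot = (s_on[idx].mean(axis=1) - s_bg_b) / (f_on[idx].mean(axis=1) - f_bg_b)
        boot = boot / calibration_constant
        lo, hi = np.nanpercentile(boot, [2.5, 97.5])
        out[label] = RatioResult(
            region=label, ratio=float(ratio),
            ci_lo=float(min(lo, ratio)), ci_hi=float(max(hi, ratio)),
            n_pixels=int(n), status="ok",
        )
    return out
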