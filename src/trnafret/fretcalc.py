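"""Crosstalk calibration and corrected-FRET (cFRET) quantification.

The raw sensitized-emission FRET channel of a Cy3/Cy5 pair contains, in
addition to true energy transfer, donor bleed-through (fraction ``a`` of
the donor signal) and acceptor cross-excitation (fraction ``b`` of the
acceptor signal).  The coefficients are measured once from single-label
control samples (:func:`estimate_correction_coefficient`) and removed with
the Youvan correction

    Fc = raw_FRET - a * donor - b * acceptor   (clamped at 0)

The corrected intensity is then expressed as the calculated-FRET
percentage

    cFRET(%) = Youvan / ((Cy3 + Cy5) / 2) * 100

evaluated per punctum from region-mean intensities, and summarized per
cell compartment both as the mean of per-punctum values (primary) and as
summed corrected intensity normalized to compartment area.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .synthdata import (COMPARTMENT_NAMES, DENDRITE, GLIA, SOMA, ChannelStack,
                        CompartmentMasks)

__all__ = [
    "CorrectionCoefficients",
    "CfretResult",
    "estimate_correction_coefficient",
    "youvan_correct",
    "cfret_percent",
    "total_intensity",
    "cfret_by_compartment",
]


@dataclass
class CorrectionCoefficients:
    """Crosstalk coefficients estimated from single-label controls.

    ``c_marker_to_donor`` is an optional third coefficient for marker
    (e.g. Alexa-488) bleed-through into the donor channel; it defaults to 0
    and is exposed for completeness but not applied by
    :func:`youvan_correct`.
    """

    a_donor_bleed: float | None = None
    b_acceptor_cross: float | None = None
    c_marker_to_donor: float = 0.0
    n_pixels_used: int = 0
    fit_residual: float = 0.0

    def merged(self, other: "CorrectionCoefficients") -> "CorrectionCoefficients":
        """Combine two one-sided calibrations into one coefficient set."""
        return CorrectionCoefficients(
            a_donor_bleed=self.a_donor_bleed if self.a_donor_bleed is not None else other.a_donor_bleed,
            b_acceptor_cross=self.b_acceptor_cross if self.b_acceptor_cross is not None else other.b_acceptor_cross,
            c_marker_to_donor=max(self.c_marker_to_donor, other.c_marker_to_donor),
            n_pixels_used=self.n_pixels_used + other.n_pixels_used,
            fit_residual=max(self.fit_residual, other.fit_residual),
        )


@dataclass
class CfretResult:
    per_punctum: pd.DataFrame
    per_compartment: dict[str, dict[str, float]]
    soma_dendrite_ratio: float
    n_clamped_pixels: int


def _image_mode(img: np.ndarray) -> float:
    """Background level as the mode of the (rounded) intensity histogram."""
    vals = np.round(np.asarray(img, dtype=float).ravel()).astype(np.int64)
    vals -= vals.min()
    counts = np.bincount(vals)
    return float(np.argmax(counts) + np.round(img).min())


def estimate_correction_coefficient(
    control: ChannelStack,
    role: str,
    foreground_threshold: float | None = None,
) -> CorrectionCoefficients:
    """Estimate one crosstalk coefficient from a single-label control stack.

    Parameters
    ----------
    control:
        Control stack containing only one dye species.
    role:
        ``"donor-only"`` (yields the bleed-through coefficient ``a``) or
        ``"acceptor-only"`` (the cross-excitation coefficient ``b``).
    foreground_threshold:
        Intensity (after background subtraction) above which a pixel of
        the role channel counts as foreground.  Default: 3 robust SDs
        (1.4826 x MAD) of the background-subtracted role channel.

    The coefficient is the slope of a least-squares fit through the origin
    of raw-FRET vs. role-channel intensity over foreground pixels, both
    background-subtracted (background = image mode): leakage scales with
    signal, not with offset.
    """
    if role not in ("donor-only", "acceptor-only"):
        raise ValueError(f"role must be 'donor-only' or 'acceptor-only', got {role!r}")
    x = np.asarray(control.donor if role == "donor-only" else control.acceptor, dtype=float)
    y = np.asarray(control.fret, dtype=float)
    if not np.any(x != 0):
        raise ValueError(f"{role} control has an all-zero role channel")
    xb = x - _image_mode(x)
    yb = y - _image_mode(y)
    if foreground_threshold is None:
        mad = np.median(np.abs(xb - np.median(xb)))
        foreground_threshold = 3.0 * 1.4826 * mad
    fg = xb > foreground_threshold
    n = int(fg.sum())
    if n < 10:
        raise ValueError(f"only {n} foreground pixels (< 10) in {role} control")
    xs, ys = xb[fg], yb[fg]
    slope = float(np.dot(xs, ys) / np.dot(xs, xs))
    resid = float(np.sqrt(np.mean((ys - slope * xs) ** 2)))
    coeff = max(slope, 0.0)
    if role == "donor-only":
        return CorrectionCoefficients(a_donor_bleed=coeff, n_pixels_used=n, fit_residual=resid)
    return CorrectionCoefficients(b_acceptor_cross=coeff, n_pixels_used=n, fit_residual=resid)


def youvan_correct(
    raw_fret: np.ndarray,
    donor: np.ndarray,
    acceptor: np.ndarray,
    coeffs: CorrectionCoefficients,
) -> np.ndarray:
    """Youvan-corrected FRET image: ``raw - a*donor - b*acceptor``, clamped
    at zero pixelwise.  Shapes must match."""
    raw_fret = np.asarray(raw_fret, dtype=float)
    donor = np.asarray(donor, dtype=float)
    acceptor = np.asarray(acceptor, dtype=float)
    if not (raw_fret.shape == donor.shape == acceptor.shape):
        raise ValueError(
            f"shape mismatch: raw {raw_fret.shape}, donor {donor.shape}, "
            f"acceptor {acceptor.shape}")
    a = coeffs.a_donor_bleed or 0.0
    b = coeffs.b_acceptor_cross or 0.0
    out = raw_fret - a * donor - b * acceptor
    return np.clip(out, 0.0, None)


def cfret_percent(youvan_intensity, cy3_intensity, cy5_intensity):
    """Calculated FRET percentage.

    cFRET(%) = Youvan / ((Cy3 + Cy5) / 2) * 100.

    Works on scalars or arrays.  Where the denominator is zero the result
    is NaN (flagged undefined, never silently 0).
    """
    y = np.asarray(youvan_intensity, dtype=float)
    denom = (np.asarray(cy3_intensity, dtype=float) + np.asarray(cy5_intensity, dtype=float)) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom > 0, 100.0 * y / np.where(denom > 0, denom, 1.0), np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def total_intensity(area, mean_intensity):
    """Total intensity of a particle: area x mean intensity."""
    if np.any(np.asarray(area) < 0):
        raise ValueError("area must be >= 0")
    return area * mean_intensity


def _punctum_regions(puncta: pd.DataFrame, shape: tuple[int, int]) -> np.ndarray:
    """Label image of punctum regions: the detection label image when the
    population carries one, else disks of matching area at the centroids."""
    lab = puncta.attrs.get("label_image")
    if lab is not None and lab.shape == shape:
        return lab
    out = np.zeros(shape, dtype=np.int32)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    for rec in puncta.itertuples(index=False):
        r = max(1.0, math.sqrt(max(rec.area_px, 1.0) / math.pi))
        sel = (yy - rec.y) ** 2 + (xx - rec.x) ** 2 <= r ** 2
        out[sel] = rec.id + 1
    return out


def cfret_by_compartment(
    stack: ChannelStack,
    coeffs: CorrectionCoefficients,
    masks: CompartmentMasks,
    puncta: pd.DataFrame,
) -> CfretResult:
    """Per-punctum and per-compartment cFRET summary.

    For every punctum the mean Cy3, Cy5 and Youvan-corrected intensities
    are taken over its pixel region and combined with
    :func:`cfret_percent`.  Each compartment reports the mean of its
    per-punctum cFRET values (primary statistic), the compartment area, and
    the pooled alternative (summed corrected intensity / area).  A
    compartment with no puncta is absent from the result rather than
    reported as zero.  The soma/dendrite ratio of mean cFRET is included
    (NaN when either side is absent).
    """
    if masks.labels.shape != np.asarray(stack.fret).shape:
        raise ValueError("masks do not align with the channel stack")
    corrected = youvan_correct(stack.fret, stack.donor, stack.acceptor, coeffs)
    a = coeffs.a_donor_bleed or 0.0
    b = coeffs.b_acceptor_cross or 0.0
    n_clamped = int(np.sum((np.asarray(stack.fret) - a * np.asarray(stack.donor)
                            - b * np.asarray(stack.acceptor)) < 0))

    regions = _punctum_regions(puncta, masks.labels.shape)
    ids = puncta["id"].to_numpy()
    index = ids + 1
    mean_d = ndimage.mean(stack.donor, labels=regions, index=index)
    mean_a = ndimage.mean(stack.acceptor, labels=regions, index=index)
    mean_y = ndimage.mean(corrected, labels=regions, index=index)
    cf = cfret_percent(mean_y, mean_d, mean_a)
    comp_at = masks.labels[
        np.clip(np.round(puncta["y"]).astype(int), 0, masks.labels.shape[0] - 1),
        np.clip(np.round(puncta["x"]).astype(int), 0, masks.labels.shape[1] - 1),
    ]
    per_punctum = pd.DataFrame({
        "id": ids,
        "cfret_percent": cf,
        "mean_donor": mean_d,
        "mean_acceptor": mean_a,
        "mean_youvan": mean_y,
        "compartment": [COMPARTMENT_NAMES[c] for c in comp_at],
    })

    per_comp: dict[str, dict[str, float]] = {}
    px2 = masks.pixel_size_nm ** 2
    for code in (SOMA, DENDRITE, GLIA):
        name = COMPARTMENT_NAMES[code]
        sub = per_punctum[per_punctum["compartment"] == name]
        sub = sub[np.isfinite(sub["cfret_percent"])]
        if len(sub) == 0:
            continue
        cmask = masks.labels == code
        area_px = int(cmask.sum())
        per_comp[name] = {
            "cfret_mean_percent": float(sub["cfret_percent"].mean()),
            "n_puncta": int(len(sub)),
            "area_px": area_px,
            "area_nm2": area_px * px2,
            "corrected_intensity_per_area": float(corrected[cmask].sum() / area_px)
            if area_px else float("nan"),
        }
    if "soma" in per_comp and "dendrite" in per_comp:
        ratio = per_comp["soma"]["cfret_mean_percent"] / per_comp["dendrite"]["cfret_mean_percent"]
    else:
        ratio = float("nan")
    return CfretResult(per_punctum=per_punctum, per_compartment=per_comp,
                       soma_dendrite_ratio=float(ratio), n_clamped_pixels=n_clamped)
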