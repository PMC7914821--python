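"""The two core per-section statistics and their z-stack aggregation.

* Coefficient of variation (CV): population standard deviation of the
  background-subtracted in-mask pixel intensities of one optical section
  divided by their mean.  A homogeneous cytoplasm gives a small CV; signal
  redistributed into bright foci raises it.  The stack-level value is the
  unweighted mean over included (nucleus-free) sections.

* Above-threshold Pearson correlation (R): Pearson correlation between two
  channels restricted to in-mask pixels exceeding a per-channel threshold
  (by default in either channel — the union rule), computed per section and
  averaged over sections with a defined value.

Undefined sections (too few pixels, zero mean or zero variance) are dropped
and logged, never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from skimage.filters import threshold_otsu

from .image_io import ZStack
from .masking import SectionMaskSet, estimate_background, subtract_background

logger = logging.getLogger(__name__)


@dataclass
class CVProfile:
    """Per-section CV values of one stack/channel with their mean."""

    sample_id: str
    condition: str
    channel: str
    section_cvs: list[float]  # included sections only, in z order
    section_indices: list[int]
    aggregate: float  # unweighted mean over listed sections
    n_sections_included: int


@dataclass
class ColocResult:
    """Per-section above-threshold R values of one channel pair with their mean."""

    sample_id: str
    condition: str
    channel_pair: tuple[str, str]
    section_rs: list[float]
    section_indices: list[int]
    aggregate: float
    thresholds: dict[str, float]
    pixel_rule: str


def section_cv(intensities: np.ndarray) -> float | None:
    """CV of one section: population sd / mean of the in-mask values.

    Returns None (section undefined) for fewer than two values or a
    non-positive mean.
    """
    v = np.asarray(intensities, dtype=np.float64).ravel()
    if v.size < 2:
        return None
    m = v.mean()
    if m <= 0:
        return None
    return float(v.std(ddof=0) / m)


def stack_cv(
    stack: ZStack,
    masks: SectionMaskSet,
    channel: str,
    background: float | None = None,
) -> CVProfile:
    """Per-section CV over the included sections, plus the stack mean.

    ``background`` defaults to the per-channel estimate stored in ``masks``
    (re-estimated if the channel was not part of mask construction).
    """
    if channel not in stack.channels:
        raise KeyError(f"no channel {channel!r} in stack")
    if background is None:
        background = masks.background.get(channel)
        if background is None:
            background = estimate_background(stack, channel)
    sub = subtract_background(stack.channels[channel], background)
    cvs: list[float] = []
    idx: list[int] = []
    for z in np.flatnonzero(masks.included):
        cv = section_cv(sub[z][masks.cytoplasm[z]])
        if cv is None:
            logger.info("%s z=%d: CV undefined, section dropped", stack.sample_id, z)
            continue
        cvs.append(cv)
        idx.append(int(z))
    if not cvs:
        raise ValueError(f"stack {stack.sample_id!r}: no section with a defined CV")
    return CVProfile(
        sample_id=stack.sample_id,
        condition=stack.condition,
        channel=channel,
        section_cvs=cvs,
        section_indices=idx,
        aggregate=float(np.mean(cvs)),
        n_sections_included=len(cvs),
    )


def _sections_for_pcc(masks: SectionMaskSet, policy: str) -> np.ndarray:
    if policy == "all":
        # every section with a usable pollen region, nuclei or not
        min_area = int(masks.params.get("min_pollen_area", 1))
        return np.flatnonzero(masks.pollen.sum(axis=(1, 2)) >= min_area)
    if policy == "nucleus_free":
        return np.flatnonzero(masks.included)
    raise ValueError(f"unknown section policy {policy!r}")


def channel_thresholds(
    stack: ZStack,
    masks: SectionMaskSet,
    pair: tuple[str, str],
    method: str = "otsu",
    percentile: float = 90.0,
    section_policy: str = "all",
) -> dict[str, float]:
    """One threshold per channel from in-mask background-subtracted voxels
    pooled over the analysed sections.

    Thresholds are computed once per stack (not per section) so per-section
    R values stay comparable along z.
    """
    out: dict[str, float] = {}
    zs = _sections_for_pcc(masks, section_policy)
    for ch in pair:
        if ch not in stack.channels:
            raise KeyError(f"no channel {ch!r} in stack")
        b = masks.background.get(ch)
        if b is None:
            b = estimate_background(stack, ch)
        sub = subtract_background(stack.channels[ch], b)
        pooled = np.concatenate([sub[z][masks.pollen[z]] for z in zs])
        if pooled.size < 2 or float(pooled.max()) == float(pooled.min()):
            raise ValueError(f"channel {ch!r}: degenerate intensity distribution")
        if method == "otsu":
            out[ch] = float(threshold_otsu(pooled, nbins=512))
        elif method == "percentile":
            out[ch] = float(np.percentile(pooled, percentile))
        else:
            raise ValueError(f"unknown threshold method {method!r}")
    return out


def section_pcc(
    ch1: np.ndarray,
    ch2: np.ndarray,
    mask: np.ndarray,
    thr1: float,
    thr2: float,
    rule: str = "union",
    min_pixels: int = 20,
) -> float | None:
    """Above-threshold Pearson R of one section, or None when undefined.

    Pixel selection: in-mask pixels above threshold in at least one channel
    ("union", the default) or in both ("intersection").  Sections selecting
    fewer than ``min_pixels`` pixels are undefined: a correlation from a
    handful of threshold-grazing pixels is noise, not colocalization.
    """
    v1 = np.asarray(ch1, dtype=np.float64)[mask]
    v2 = np.asarray(ch2, dtype=np.float64)[mask]
    if rule == "union":
        sel = (v1 > thr1) | (v2 > thr2)
    elif rule == "intersection":
        sel = (v1 > thr1) & (v2 > thr2)
    else:
        raise ValueError(f"unknown pixel rule {rule!r}")
    a, b = v1[sel], v2[sel]
    if a.size < max(2, min_pixels) or a.std() == 0 or b.std() == 0:
        return None
    r = float(np.corrcoef(a, b)[0, 1])
    return float(np.clip(r, -1.0, 1.0))


def stack_pcc(
    stack: ZStack,
    masks: SectionMaskSet,
    pair: tuple[str, str] = ("GFP", "RFP"),
    method: str = "otsu",
    percentile: float = 90.0,
    rule: str = "union",
    section_policy: str = "all",
    thresholds: dict[str, float] | None = None,
    min_pixels: int = 20,
) -> ColocResult:
    """Per-section above-threshold R and the stack mean for a channel pair.

    Colocalization uses all sections with a pollen region by default (set
    ``section_policy="nucleus_free"`` to apply the CV section rule instead).
    """
    if thresholds is None:
        thresholds = channel_thresholds(
            stack, masks, pair, method=method, percentile=percentile, section_policy=section_policy
        )
    subs = {}
    for ch in pair:
        b = masks.background.get(ch)
        if b is None:
            b = estimate_background(stack, ch)
        subs[ch] = subtract_background(stack.channels[ch], b)
    rs: list[float] = []
    idx: list[int] = []
    for z in _sections_for_pcc(masks, section_policy):
        r = section_pcc(
            subs[pair[0]][z],
            subs[pair[1]][z],
            masks.pollen[z],
            thresholds[pair[0]],
            thresholds[pair[1]],
            rule=rule,
            min_pixels=min_pixels,
        )
        if r is None:
            logger.info("%s z=%d: R undefined, section dropped", stack.sample_id, z)
            continue
        rs.append(r)
        idx.append(int(z))
    if not rs:
        raise ValueError(f"stack {stack.sample_id!r}: no section with a defined R")
    return ColocResult(
        sample_id=stack.sample_id,
        condition=stack.condition,
        channel_pair=tuple(pair),
        section_rs=rs,
        section_indices=idx,
        aggregate=float(np.mean(rs)),
        thresholds=dict(thresholds),
        pixel_rule=rule,
    )
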