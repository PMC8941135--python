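"""Region-of-interest statistics on mass-spectrometry-imaging ion images.

An :class:`IonImage` is a stack of per-channel intensity grids sharing a
pixel size and a set of named boolean region masks (organism colonies,
the interaction zone between them, agar control). The operations here
compute region means, transect profiles across the interaction zone, and
co-culture vs mono-culture induction calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ZERO_DENOM_EPS = 1e-9  # floor for mono-culture region means in ratios
RATIO_CAP = 1e6  # reported ratio when the mono-culture region is blank


@dataclass
class IonImage:
    channels: dict[str, np.ndarray]
    pixel_size: float  # micrometres per pixel
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {name: arr.shape for name, arr in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel grids differ in shape: {shapes}")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        for name, arr in self.channels.items():
            if (arr < 0).any():
                raise ValueError(f"channel {name!r} has negative intensities")
        shape = self.shape
        for name, mask in self.masks.items():
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != shape:
                raise ValueError(f"mask {name!r} shape {mask.shape} != grid {shape}")
            self.masks[name] = mask

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass
class InductionCall:
    channel: str
    region: str
    mean_co: float
    mean_mono: float
    ratio: float
    induced: bool
    zero_denominator: bool = False


def tic_normalize(image: IonImage) -> IonImage:
    """Divide each pixel's channel vector by its total across channels.

    Pixels with zero total ion current stay zero (their count is not an
    error; blank agar pixels are expected). Idempotent.
    """
    if not image.channels:
        raise ValueError("image has no channels")
    stack = np.stack(list(image.channels.values()))
    total = stack.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        normed = np.where(total > 0, stack / total, 0.0)
    return IonImage(
        channels={k: normed[i] for i, k in enumerate(image.channels)},
        pixel_size=image.pixel_size,
        masks=dict(image.masks),
    )


def region_mean(image: IonImage, channel: str, region: str) -> float:
    """Arithmetic mean intensity of a channel over a named region mask."""
    if channel not in image.channels:
        raise KeyError(f"no channel {channel!r}")
    if region not in image.masks:
        raise KeyError(f"no region mask {region!r}")
    mask = image.masks[region]
    if not mask.any():
        raise ValueError(f"region mask {region!r} is empty")
    return float(image.channels[channel][mask].mean())


def transect_profile(
    image: IonImage, channel: str, axis: int = 1, bin_width: int = 1
) -> pd.DataFrame:
    """Mean intensity binned along the axis joining the two organism regions.

    ``axis=1`` bins columns (the usual left-organism/right-organism
    layout), ``axis=0`` bins rows. Positions are bin centres in
    micrometres via the pixel size.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    if channel not in image.channels:
        raise KeyError(f"no channel {channel!r}")
    grid = image.channels[channel]
    line = grid.mean(axis=0) if axis == 1 else grid.mean(axis=1)
    rows = []
    for lo in range(0, len(line), bin_width):
        hi = min(lo + bin_width, len(line))
        centre = (lo + hi) / 2.0
        rows.append(
            {"position_um": centre * image.pixel_size, "mean_intensity": float(line[lo:hi].mean())}
        )
    return pd.DataFrame(rows)


def induction_call(
    co: IonImage,
    mono: IonImage,
    channel: str,
    region: str,
    ratio_threshold: float = 2.0,
) -> InductionCall:
    """Is a channel elevated in co-culture relative to mono-culture?

    ratio = region_mean(co) / max(region_mean(mono), eps). A blank
    mono-culture region with positive co-culture signal reports the
    capped ratio with a zero-denominator flag; induced whenever ratio >=
    threshold.
    """
    if co.shape != mono.shape:
        raise ValueError("co- and mono-culture images differ in shape")
    mean_co = region_mean(co, channel, region)
    mean_mono = region_mean(mono, channel, region)
    zero_denom = mean_mono < ZERO_DENOM_EPS
    if zero_denom:
        ratio = RATIO_CAP if mean_co > 0 else 1.0
    else:
        ratio = mean_co / mean_mono
    return InductionCall(
        channel=channel,
        region=region,
        mean_co=mean_co,
        mean_mono=mean_mono,
        ratio=ratio,
        induced=ratio >= ratio_threshold,
        zero_denominator=zero_denom,
    )


def induction_table(
    co: IonImage,
    mono: IonImage,
    region: str,
    ratio_threshold: float = 2.0,
) -> pd.DataFrame:
    """Induction calls for every channel shared by both images."""
    shared = [c for c in co.channels if c in mono.channels]
    rows = []
    for ch in shared:
        call = induction_call(co, mono, ch, region, ratio_threshold)
        rows.append(
            {
                "channel": call.channel,
                "region": call.region,
                "mean_co": call.mean_co,
                "mean_mono": call.mean_mono,
                "ratio": call.ratio,
                "induced": call.induced,
                "zero_denominator": call.zero_denominator,
            }
        )
    return pd.DataFrame(rows)
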