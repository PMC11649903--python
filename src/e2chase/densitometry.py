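"""Gel densitometry arithmetic: band intensities -> species fractions.

Converts per-lane band intensity tables into the fractions consumed by the
kinetic model, including background subtraction and the NaOH partition that
distinguishes alkali-labile oxyester (Ser/Thr) linkages from NaOH-resistant
isopeptide (Lys) linkages.

Every emitted fraction is invariant under uniform rescaling of the lane
intensities, since densitometric signals carry arbitrary units.  Values are
clamped into [0, 1]; each clamp is reported via a :class:`ClampWarning`
rather than silently absorbed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LaneQuant",
    "ClampWarning",
    "fraction_loaded",
    "fraction_modified",
    "naoh_partition",
    "lanes_to_timecourse",
]

_ROLES = {"loaded", "apo", "unmodified", "modified_total", "background"}
_TREATMENTS = {"none", "NaOH", "no_ATP"}


class ClampWarning(UserWarning):
    """A fraction or intensity was clamped to stay in its valid range."""


@dataclass
class LaneQuant:
    """Quantified band intensities for one gel lane.

    ``intensities`` maps band roles (``loaded``, ``apo``, ``unmodified``,
    ``modified_total``, ``background``) to non-negative intensities in
    arbitrary units; ``treatment`` records NaOH or no-ATP handling.
    """

    lane_id: str
    intensities: dict[str, float]
    treatment: str = "none"
    time_min: float | None = None
    condition: str = ""

    def __post_init__(self) -> None:
        unknown = set(self.intensities) - _ROLES
        if unknown:
            raise ValueError(f"unknown band roles: {sorted(unknown)}")
        for role, v in self.intensities.items():
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"intensity for {role!r} must be finite and >= 0, got {v}")
        if self.treatment not in _TREATMENTS:
            raise ValueError(f"treatment must be one of {sorted(_TREATMENTS)}")


def fraction_loaded(lane: LaneQuant) -> float:
    """Loaded fraction: loaded / (loaded + apo)."""
    try:
        loaded = lane.intensities["loaded"]
        apo = lane.intensities["apo"]
    except KeyError as e:
        raise ValueError(f"lane {lane.lane_id!r} missing band role {e}") from None
    total = loaded + apo
    if total <= 0:
        raise ValueError(f"lane {lane.lane_id!r}: loaded + apo intensity is zero")
    return loaded / total


def fraction_modified(lane: LaneQuant, background: "LaneQuant | float" = 0.0) -> float:
    """Modified fraction after per-lane background subtraction.

    The background (a scalar, or a reference lane such as a no-ATP control,
    whose ``modified_total`` — or ``background`` — band is used) is
    subtracted from the modified signal before forming
    ``modified / (modified + unmodified)``.  Over-subtraction clamps the
    modified signal at zero with a :class:`ClampWarning`.
    """
    try:
        unmod = lane.intensities["unmodified"]
        mod = lane.intensities["modified_total"]
    except KeyError as e:
        raise ValueError(f"lane {lane.lane_id!r} missing band role {e}") from None
    if isinstance(background, LaneQuant):
        bg = background.intensities.get(
            "background", background.intensities.get("modified_total", 0.0)
        )
    else:
        bg = float(background)
    if bg < 0:
        raise ValueError(f"background must be >= 0, got {bg}")
    mod_corr = mod - bg
    if mod_corr <= 0 and bg > 0:
        warnings.warn(
            f"lane {lane.lane_id!r}: background {bg:g} consumes the modified "
            f"signal {mod:g}; clamped to 0",
            ClampWarning, stacklevel=2,
        )
        mod_corr = 0.0
    total = mod_corr + unmod
    if total <= 0:
        raise ValueError(f"lane {lane.lane_id!r}: total corrected signal is zero")
    return mod_corr / total


def naoh_partition(mod_with_naoh: float, mod_without: float) -> tuple[float, float]:
    """Partition modification into NaOH-resistant and -sensitive fractions.

    resistant = (modified fraction with NaOH) / (modified fraction without),
    capped at 1; sensitive = 1 - resistant.  The resistant share reports
    isopeptide (Lys) linkages, the sensitive share oxyester (Ser/Thr)
    linkages.
    """
    for name, v in (("mod_with_naoh", mod_with_naoh), ("mod_without", mod_without)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must be a fraction in [0, 1], got {v}")
    if mod_without <= 0:
        raise ValueError("modified fraction without NaOH is zero; partition undefined")
    resistant = mod_with_naoh / mod_without
    if resistant > 1.0:
        warnings.warn(
            f"NaOH-treated fraction {mod_with_naoh:g} exceeds untreated "
            f"{mod_without:g}; resistant fraction capped at 1",
            ClampWarning, stacklevel=2,
        )
        resistant = 1.0
    return resistant, 1.0 - resistant


def lanes_to_timecourse(lanes: list[LaneQuant], observable: str = "modified_fraction",
                        background: "LaneQuant | float" = 0.0, label: str = ""):
    """Convert a list of time-stamped lanes into a :class:`~e2chase.kinetics.TimeCourse`.

    Lanes must carry ``time_min``; the fraction per lane is computed with
    :func:`fraction_loaded` (observable ``mono_band``) or
    :func:`fraction_modified` (observable ``modified_fraction``).
    """
    from .kinetics import TimeCourse

    stamped = [l for l in lanes if l.time_min is not None]
    if not stamped:
        raise ValueError("no lanes carry time_min")
    stamped.sort(key=lambda l: l.time_min)
    if observable == "mono_band":
        fracs = [fraction_loaded(l) for l in stamped]
    elif observable == "modified_fraction":
        fracs = [fraction_modified(l, background) for l in stamped]
    else:
        raise ValueError(f"unsupported observable {observable!r}")
    return TimeCourse(
        times=np.array([l.time_min for l in stamped]),
        signal=np.array(fracs),
        observable=observable,
        label=label or (stamped[0].condition or "lanes"),
    )
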