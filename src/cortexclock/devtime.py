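"""Cross-species developmental-time translation by fractional-FA-decay matching.

A developmental window in a source species is converted to the species-free
pair of decay fractions (f_start, f_end) via the source FA clock and then
projected onto a target species by inverting that species' clock:

    target_age(f) = t_init_target + tau_target * ln(1/f)

Because the fractions carry no species information, translation is exactly
transitive and reduces to the identity when source and target coincide.

Printed reference predictions from the Translating Time model (a published
cross-species event-timing regression; only its outputs are used here, the
model itself is not implemented) ship as immutable constants so FA-based
predictions can be compared against them.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import (
    InvalidInputError,
    SpeciesMismatchError,
    UnrepresentableWindowError,
)
from .rounding import days_to_weeks, round_half_away
from .trajectory import SpeciesFAParams, age_at_fraction, decay_fraction

__all__ = [
    "DevWindow",
    "FractionWindow",
    "TTReference",
    "TT_HUMAN_FROM_RAT",
    "TT_FERRET_FROM_RAT",
    "TT_CAT_EQUIVALENTS_GD",
    "pn_to_pc",
    "pc_to_pn",
    "window_to_fractions",
    "project_window",
    "translate_window",
    "compare_to_translating_time",
    "render_window",
]


@dataclass(frozen=True)
class DevWindow:
    """An age interval in one species, in days post conception."""

    species_name: str
    start_pc: float
    end_pc: float

    def __post_init__(self) -> None:
        if not (0 < self.start_pc < self.end_pc):
            raise InvalidInputError("need 0 < start_pc < end_pc")


@dataclass(frozen=True)
class FractionWindow:
    """Species-free window: remaining decay fractions at the two bounds.

    An earlier age leaves a larger fraction of the FA range, so
    ``f_start >= f_end``.
    """

    f_start: float
    f_end: float

    def __post_init__(self) -> None:
        for f in (self.f_start, self.f_end):
            if not (0 < f <= 1):
                raise InvalidInputError("fractions must lie in (0, 1]")
        if self.f_start < self.f_end:
            raise InvalidInputError("f_start must be >= f_end (earlier age, larger fraction)")


@dataclass(frozen=True)
class TTReference:
    """A printed Translating Time prediction used as a comparison reference."""

    source_species: str
    target_species: str
    window_pc: DevWindow
    note: str = ""


#: Translating Time: rat critical period (P4-P6) mapped to human,
#: PC138-PC150 (19.7-21.4 gestational weeks).
TT_HUMAN_FROM_RAT = TTReference(
    "rat", "human", DevWindow("human", 138.0, 150.0),
    note="rat P4-P6 -> human 138-150 gestational days",
)

#: Translating Time: rat critical period mapped to ferret, P11-P15.5
#: (PC52-PC56.5).
TT_FERRET_FROM_RAT = TTReference(
    "rat", "ferret", DevWindow("ferret", 52.0, 56.5),
    note="rat P4-P6 -> ferret P11-P15.5 (PC52-PC56.5)",
)

#: Translating Time single-age equivalents in the cat, gestational days:
#: rat P6 -> cat GD 61.9; ferret P20 -> cat GD 66.8 (cat gestation 65 d).
TT_CAT_EQUIVALENTS_GD = {"rat_P6": 61.9, "ferret_P20": 66.8}


def pn_to_pc(age_postnatal: float, gestation_days: float) -> float:
    """Postnatal age -> days post conception (add the gestation length)."""
    if age_postnatal < 0:
        raise InvalidInputError("postnatal age must be >= 0")
    if gestation_days <= 0:
        raise InvalidInputError("gestation_days must be > 0")
    return age_postnatal + gestation_days


def pc_to_pn(age_pc: float, gestation_days: float) -> float:
    """Days post conception -> postnatal age; negative values are prenatal
    (report them as gestational days)."""
    if age_pc < 0:
        raise InvalidInputError("age_pc must be >= 0")
    return age_pc - gestation_days


def window_to_fractions(window: DevWindow, params: SpeciesFAParams) -> FractionWindow:
    """Express a window as its FA decay fractions under the species clock.

    The window must lie entirely at or after ``t_init``: earlier ages sit on
    the FA plateau where the fraction saturates at 1 and the mapping cannot
    be inverted.
    """
    if window.species_name != params.species_name:
        raise SpeciesMismatchError(
            f"window is for {window.species_name!r}, params for {params.species_name!r}"
        )
    if window.start_pc < params.t_init:
        raise UnrepresentableWindowError(
            f"window starts at {window.start_pc} dpc, before t_init="
            f"{params.t_init} dpc; decay fraction saturates at 1 on the plateau"
        )
    return FractionWindow(
        f_start=decay_fraction(params, window.start_pc),
        f_end=decay_fraction(params, window.end_pc),
    )


def project_window(fractions: FractionWindow, target: SpeciesFAParams) -> DevWindow:
    """Project species-free decay fractions onto a target species' clock."""
    return DevWindow(
        species_name=target.species_name,
        start_pc=age_at_fraction(target, fractions.f_start),
        end_pc=age_at_fraction(target, fractions.f_end),
    )


def translate_window(
    source_window: DevWindow,
    source: SpeciesFAParams,
    target: SpeciesFAParams,
) -> DevWindow:
    """Translate a developmental window between species by fraction matching."""
    return project_window(window_to_fractions(source_window, source), target)


def compare_to_translating_time(
    predicted: DevWindow, reference: TTReference
) -> dict[str, float | bool]:
    """Signed per-bound offsets (days) of an FA-based window vs a Translating
    Time reference window: positive means the FA-based bound is later."""
    if predicted.species_name != reference.target_species:
        raise SpeciesMismatchError(
            f"predicted window is for {predicted.species_name!r}, reference for "
            f"{reference.target_species!r}"
        )
    start_offset = predicted.start_pc - reference.window_pc.start_pc
    end_offset = predicted.end_pc - reference.window_pc.end_pc
    overlap = not (
        predicted.end_pc < reference.window_pc.start_pc
        or reference.window_pc.end_pc < predicted.start_pc
    )
    return {
        "start_offset_days": start_offset,
        "end_offset_days": end_offset,
        "windows_overlap": overlap,
    }


def render_window(window: DevWindow, gestation_days: float) -> dict:
    """Report-precision rendering of a window.

    PC days round to the nearest whole day; weeks are days/7 at one decimal.
    Bounds before birth are labelled gestational days, after birth postnatal
    days — the idiom used for prenatal predictions (e.g. human windows are
    quoted in gestational days/weeks).
    """
    def bound(age_pc: float) -> dict:
        pn = pc_to_pn(age_pc, gestation_days)
        prenatal = pn < 0
        return {
            "pc_days": round_half_away(age_pc),
            "pc_weeks": days_to_weeks(age_pc),
            "frame": "gestational_day" if prenatal else "postnatal_day",
            "frame_value": round_half_away(age_pc if prenatal else pn, 1),
        }

    return {
        "species": window.species_name,
        "start": bound(window.start_pc),
        "end": bound(window.end_pc),
    }
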