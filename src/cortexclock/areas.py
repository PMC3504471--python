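"""Cortical surface-area reduction arithmetic.

Quantifies the shrinkage of visual cortical areas after early bilateral
enucleation: per-region group means (control vs treated) and the percent
reduction 100*(control - treated)/control.  Negative reductions (treated
larger than control) are allowed and flagged as enlargements.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .errors import InvalidInputError
from .rounding import round_half_away

__all__ = ["AreaMeasure", "GroupSummary", "percent_reduction", "summarize_groups", "read_area_csv"]


@dataclass(frozen=True)
class AreaMeasure:
    """One subject's surface area for one region, in mm^2."""

    region: str
    group: str
    area: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        if not self.area > 0:
            raise InvalidInputError("area must be > 0")


@dataclass(frozen=True)
class GroupSummary:
    """Per-(region, group) means and per-region percent reductions.

    ``reductions`` maps region -> percent reduction (control vs treated);
    regions missing either group are reported in ``incomplete_regions``
    rather than silently treated as zero.
    """

    means: pd.DataFrame
    reductions: dict[str, float]
    incomplete_regions: tuple[str, ...]


def percent_reduction(control_mean: float, treated_mean: float) -> float:
    """Percent reduction of the treated mean relative to control.

    100*(control - treated)/control; a negative result means enlargement.
    """
    if not control_mean > 0:
        raise InvalidInputError("control mean must be > 0")
    return 100.0 * (control_mean - treated_mean) / control_mean


def summarize_groups(
    measures: Iterable[AreaMeasure],
    control_label: str = "control",
    treated_label: str = "treated",
) -> GroupSummary:
    """Group means per (region, group) and percent reduction per region.

    Order-invariant and scale-equivariant: the percentages do not depend on
    the area unit.
    """
    rows = [
        {"region": m.region, "group": m.group, "area": m.area, "subject_id": m.subject_id}
        for m in measures
    ]
    if not rows:
        raise InvalidInputError("no area measures supplied")
    df = pd.DataFrame(rows)
    means = (
        df.groupby(["region", "group"], sort=True)["area"]
        .agg(["mean", "count"])
        .reset_index()
    )
    reductions: dict[str, float] = {}
    incomplete: list[str] = []
    for region, sub in means.groupby("region"):
        by_group = dict(zip(sub["group"], sub["mean"]))
        if control_label in by_group and treated_label in by_group:
            reductions[str(region)] = percent_reduction(
                by_group[control_label], by_group[treated_label]
            )
        else:
            incomplete.append(str(region))
    return GroupSummary(
        means=means,
        reductions=reductions,
        incomplete_regions=tuple(sorted(incomplete)),
    )


def format_reduction(pct: float) -> str:
    """Render a reduction at the 1-decimal reporting precision (ties away
    from zero), flagging enlargements."""
    val = round_half_away(pct, 1)
    return f"{val:.1f}% {'reduction' if val >= 0 else 'enlargement'}"


def read_area_csv(path) -> list[AreaMeasure]:
    """Read area measures from CSV with columns subject_id, group, region,
    area_mm2."""
    df = pd.read_csv(path)
    needed = {"subject_id", "group", "region", "area_mm2"}
    if not needed <= set(df.columns):
        raise InvalidInputError(f"CSV must have columns {sorted(needed)}")
    return [
        AreaMeasure(
            region=str(r.region), group=str(r.group),
            area=float(r.area_mm2), subject_id=str(r.subject_id),
        )
        for r in df.itertuples()
    ]
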