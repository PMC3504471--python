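"""Species registry: gestation lengths and FA-clock parameters.

Built-in entries cover the species with published cortical-FA trajectories
(rat, ferret, human) plus the cat, for which only the gestation length is
needed (its developmental comparisons in the literature are expressed in
gestational days, not via an FA clock).  Registries can also be read from /
written to YAML so users can supply their own species.
"""

from __future__ import annotations

from dataclasses import dataclass

import yaml

from .errors import InvalidInputError
from .trajectory import SpeciesFAParams

__all__ = ["SpeciesRecord", "default_registry", "load_registry", "save_registry"]


@dataclass(frozen=True)
class SpeciesRecord:
    """Registry entry: gestation length plus, when known, the FA clock."""

    name: str
    gestation_days: float
    fa_params: SpeciesFAParams | None = None

    def require_fa(self) -> SpeciesFAParams:
        if self.fa_params is None:
            raise InvalidInputError(
                f"no FA trajectory parameters registered for species {self.name!r}"
            )
        return self.fa_params


def _rec(name: str, gestation: float, t_init: float | None, tau: float | None,
         fa_max: float = 1.0, fa_min: float = 0.0) -> SpeciesRecord:
    fa = None
    if t_init is not None and tau is not None:
        fa = SpeciesFAParams(name, gestation, t_init, tau, fa_max, fa_min)
    return SpeciesRecord(name, gestation, fa)


def default_registry() -> dict[str, SpeciesRecord]:
    """Built-in species table.

    t_init / tau (days post conception / days): rat 22 / 5, ferret 49 / 10.7,
    human 173 / 39.8.  Gestations: rat 21.5 d, ferret 41 d, cat 65 d, human
    280 d (40 wk nominal term; used only for rendering postnatal ages).
    FA bounds default to the nominal (1, 0) — all cross-species predictions
    depend only on decay fractions.
    """
    records = [
        _rec("rat", 21.5, 22.0, 5.0),
        _rec("ferret", 41.0, 49.0, 10.7),
        _rec("human", 280.0, 173.0, 39.8),
        _rec("cat", 65.0, None, None),
    ]
    return {r.name: r for r in records}


def load_registry(path) -> dict[str, SpeciesRecord]:
    """Read a species registry from YAML.

    Layout: ``{species: {gestation_days, t_init, tau, fa_max, fa_min}}``;
    ``t_init``/``tau`` may be omitted for species without an FA clock.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    registry: dict[str, SpeciesRecord] = {}
    for name, entry in raw.items():
        if "gestation_days" not in entry:
            raise InvalidInputError(f"species {name!r} is missing gestation_days")
        registry[name] = _rec(
            name,
            float(entry["gestation_days"]),
            entry.get("t_init"),
            entry.get("tau"),
            float(entry.get("fa_max", 1.0)),
            float(entry.get("fa_min", 0.0)),
        )
    return registry


def save_registry(registry: dict[str, SpeciesRecord], path) -> None:
    """Write a registry to YAML in the layout accepted by :func:`load_registry`."""
    out = {}
    for name, rec in registry.items():
        entry: dict[str, float] = {"gestation_days": rec.gestation_days}
        if rec.fa_params is not None:
            p = rec.fa_params
            entry.update(t_init=p.t_init, tau=p.tau, fa_max=p.fa_max, fa_min=p.fa_min)
        out[name] = entry
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=True)
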