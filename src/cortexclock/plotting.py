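"""Timeline figure: FA trajectories per species with shaded windows."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .devtime import DevWindow
from .errors import InvalidInputError
from .trajectory import SpeciesFAParams, fa_at_age

__all__ = ["plot_trajectories"]


def plot_trajectories(
    params_list: list[SpeciesFAParams],
    windows: list[DevWindow] | None = None,
    out_path=None,
    age_padding_tau: float = 4.0,
):
    """Plot each species' FA-versus-age curve with optional shaded windows.

    One panel per species (age scales differ by an order of magnitude across
    species, so a shared axis would flatten the fast developers).  Windows
    are shaded on the panel of their species.  Returns the figure; saves to
    ``out_path`` when given.
    """
    if not params_list:
        raise InvalidInputError("no species to plot")
    windows = windows or []
    fig, axes = plt.subplots(
        1, len(params_list), figsize=(4 * len(params_list), 3.2), squeeze=False
    )
    for ax, p in zip(axes[0], params_list):
        hi = p.t_init + age_padding_tau * p.tau
        ages = np.linspace(max(1e-3, p.t_init - p.tau), hi, 300)
        ax.plot(ages, fa_at_age(p, ages), color="k")
        for w in windows:
            if w.species_name == p.species_name:
                ax.axvspan(w.start_pc, w.end_pc, color="0.7", alpha=0.5)
        ax.set_title(p.species_name)
        ax.set_xlabel("age (days post conception)")
        ax.set_ylabel("cortical FA")
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
    return fig
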