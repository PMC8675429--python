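"""Generic plotting helpers for fitted trajectories and centile curves."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .fracpoly import FPFit
from .lms import LMSModel, centile_curve


def plot_trajectory(fit: FPFit, ages=None, ax=None, **plot_kwargs):
    """Plot the fitted mean age curve of one region-hemisphere."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    if ages is None:
        ages = np.arange(3.0, 90.0 + 1e-9, 0.5)
    ax.plot(ages, fit.predict(ages), **plot_kwargs)
    ax.set_xlabel("age (years)")
    ax.set_ylabel("adjusted volume (mm$^3$)")
    return ax


def plot_centiles(model: LMSModel, levels=(5, 25, 50, 75, 95), ax=None):
    """Plot centile curves of one structure/hemisphere/sex stratum."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ages = np.linspace(model.age_range[0], model.age_range[1], 200)
    for level in levels:
        ax.plot(ages, centile_curve(model, ages, level), label=f"{level:g}%")
    ax.set_xlabel("age (years)")
    ax.set_ylabel("volume (mm$^3$)")
    ax.legend(title="centile")
    return ax
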