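"""Per-run diagnostic figures (matplotlib, Agg-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def plot_csp_profile(profile, threshold=None, ax=None):
    """Bar plot of weighted Δδ vs residue number with the significance cutoff."""
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3))
    residues = [r.residue_number for r in profile.numeric_records]
    values = [r.delta_weighted for r in profile.numeric_records]
    ax.bar(residues, values, width=0.8, color="0.3")
    thr = threshold or profile.threshold
    if thr is not None:
        ax.axhline(thr.cutoff, linestyle="--", color="crimson",
                   label=f"cutoff {thr.cutoff:.3f} ppm")
        ax.legend(frameon=False)
    for res in profile.disappeared_residues:
        ax.axvline(res, color="0.8", linewidth=0.5)
    ax.set_xlabel("residue number")
    ax.set_ylabel(r"weighted $\Delta\delta$ (ppm)")
    return ax


def plot_binding_fit(results, ax=None):
    """Measured points and fitted isotherm on a log concentration axis."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    curve = results.model.curve
    ax.semilogx(curve.x, curve.y, "o", color="0.2", label="data")
    if results.kd is not None:
        xs = np.geomspace(max(curve.x[curve.x > 0].min() / 3, 1e-3),
                          curve.x.max() * 3, 200)
        ax.semilogx(xs, results.predict(xs), "-", color="crimson",
                    label=f"fit: Kd = {results.kd:.3g} nM")
    ax.set_xlabel("titrant total (nM)")
    ax.set_ylabel("signal")
    ax.legend(frameon=False)
    return ax
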