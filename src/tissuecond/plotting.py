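"""Matplotlib figures for the two characterization workflows."""

from __future__ import annotations

import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_conductivity_panels", "plot_sigma_spectra"]


def plot_conductivity_panels(results, figsize=(10, 8)):
    """Four panels: baseline sigma0, sigma(E), percent increase, adjusted sigma."""
    fig, axes = plt.subplots(2, 2, figsize=figsize)
    curve = results.curve
    t = curve.table

    ax = axes[0, 0]
    ax.bar([curve.group], [curve.baseline_mean_s_per_m], yerr=[curve.baseline_sd_s_per_m], capsize=4)
    ax.set_ylabel(r"initial $\sigma_0$ (S/m)")
    ax.set_title("Baseline conductivity")

    ax = axes[0, 1]
    ax.errorbar(t["field_V_per_cm"], t["sigma_mean_S_per_m"], yerr=t["sigma_sd"], marker="o")
    ax.set_xlabel("E (V/cm)")
    ax.set_ylabel(r"intra-pulse $\sigma$ (S/m)")
    ax.set_title("Conductivity vs field")

    ax = axes[1, 0]
    ax.plot(t["field_V_per_cm"], t["pct_increase_mean"], marker="s")
    ax.set_xlabel("E (V/cm)")
    ax.set_ylabel("increase over baseline (%)")
    ax.set_title("Percent increase")

    ax = axes[1, 1]
    ax.plot(t["field_V_per_cm"], t["sigma_adjusted"], marker="^")
    ax.axhline(curve.baseline_mean_s_per_m, ls="--", lw=0.8, color="gray")
    ax.set_xlabel("E (V/cm)")
    ax.set_ylabel(r"adjusted $\sigma$ (S/m)")
    ax.set_title("Adjusted conductivity")

    fig.suptitle(curve.group)
    fig.tight_layout()
    return fig


def plot_sigma_spectra(results, figsize=(6, 4)):
    """Per-sample conductivity spectra on a log-frequency axis."""
    fig, ax = plt.subplots(figsize=figsize)
    for sid, sub in results.spectrum_table.groupby("sample_id"):
        ax.plot(sub["frequency_Hz"], sub["sigma_S_per_m"], label=str(sid), lw=1)
    for fq in np.atleast_1d(results.model.query_frequencies_hz):
        ax.axvline(fq, ls=":", lw=0.8, color="gray")
    ax.set_xscale("log")
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel(r"$\sigma$ (S/m)")
    ax.set_title(results.model.group)
    if len(results.model.spectra) <= 8:
        ax.legend(fontsize="x-small")
    fig.tight_layout()
    return fig
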