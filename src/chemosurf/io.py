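"""Result tables, trajectory storage, and the summary report figure."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

RESULT_COLUMNS = ["alpha", "n", "captured", "P", "sd", "mean_capture_time"]


def write_results(table: pd.DataFrame, path) -> None:
    """Write a sweep table as CSV (schema-checked)."""
    missing = [c for c in RESULT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"result table missing columns {missing}")
    table.to_csv(path, index=False)


def read_results(path) -> pd.DataFrame:
    tab = pd.read_csv(path)
    missing = [c for c in RESULT_COLUMNS if c not in tab.columns]
    if missing:
        raise ValueError(f"result file {path} missing columns {missing}")
    return tab


def write_trajectories(path, trajectories: dict, metadata: dict | None = None) -> None:
    """Store sampled trajectories in an HDF5 container.

    ``trajectories`` maps names to (n_samples, k) arrays (columns such as
    t, x, y, z, hx, hy, hz, c)."""
    import h5py

    with h5py.File(path, "w") as f:
        for key, val in (metadata or {}).items():
            f.attrs[key] = val
        for name, arr in trajectories.items():
            f.create_dataset(name, data=np.asarray(arr), compression="gzip")


def read_trajectories(path) -> tuple[dict, dict]:
    import h5py

    out, meta = {}, {}
    with h5py.File(path, "r") as f:
        meta.update(f.attrs)
        for name in f:
            out[name] = f[name][...]
    return out, meta


def report(
    sweep: pd.DataFrame,
    theory: pd.DataFrame | None = None,
    filament: pd.DataFrame | None = None,
    out="report.png",
    title: str | None = None,
):
    """Render the summary figure: encounter probability vs shear rate with
    binomial error bars and optimum marker, optional theory overlay, and the
    filament scaling panel (c0, 1/k, sigma vs alpha)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_panels = 1 + (filament is not None)
    fig, axes = plt.subplots(1, n_panels, figsize=(5.2 * n_panels, 4.0))
    axes = np.atleast_1d(axes)
    ax = axes[0]
    tab = sweep.sort_values("alpha")
    ax.errorbar(
        tab["alpha"], tab["P"], yerr=2 * tab["sd"], fmt="o-", capsize=3,
        label="simulation (±2 SD)",
    )
    if tab["captured"].sum() > 0:
        i = tab["P"].idxmax()
        interior = tab.index.get_loc(i) not in (0, len(tab) - 1)
        ax.axvline(
            tab["alpha"][i], ls=":", color="gray",
            label=f"optimum α*={tab['alpha'][i]:g}/s" + ("" if interior else " (boundary)"),
        )
    if theory is not None:
        th = theory.dropna(subset=["P_theory"]).sort_values("alpha")
        ax.plot(th["alpha"], th["P_theory"], "r-", label="filament-surfing theory")
    ax.set_xlabel("shear rate α (1/s)")
    ax.set_ylabel("encounter probability P")
    ax.legend(fontsize=8)
    if title:
        ax.set_title(title)
    if filament is not None:
        ax2 = axes[1]
        fl = filament.sort_values("alpha")
        ax2.loglog(fl["alpha"], fl["c0"] / fl["c0"].iloc[0], "o-", label="c0 (norm.)")
        ax2.loglog(fl["alpha"], (1 / fl["k"]) / (1 / fl["k"]).iloc[0], "s-", label="1/k (norm.)")
        ax2.loglog(fl["alpha"], fl["sigma"] / fl["sigma"].iloc[0], "^-", label="σ (norm.)")
        ax2.set_xlabel("shear rate α (1/s)")
        ax2.set_ylabel("filament parameter (normalised)")
        ax2.legend(fontsize=8)
        ax2.set_title("filament scaling laws")
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return Path(out)
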