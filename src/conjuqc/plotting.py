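"""Plots mirroring the standard QC figures.

Log-scale (10^0 - 10^4) fluorescence histograms with overlays, and
FI-vs-month stability time courses.  All functions take an explicit
output path and use the non-interactive matplotlib backend.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .fcs_io import EventTable  # noqa: E402
from .qc_pipeline import StabilitySeries  # noqa: E402


def fluorescence_histogram(
    tables: Sequence[EventTable],
    labels: Sequence[str],
    path,
    channel: str = "FL2",
    bins: int = 128,
) -> Path:
    """Overlay log-scale fluorescence histograms (10^0 to 10^4 axis)."""
    fig, ax = plt.subplots(figsize=(6, 4))
    edges = np.logspace(0, 4, bins + 1)
    for table, label in zip(tables, labels):
        v = np.clip(table.channel(channel), edges[0], edges[-1])
        ax.hist(v, bins=edges, histtype="step", label=label)
    ax.set_xscale("log")
    ax.set_xlim(1, 1e4)
    ax.set_xlabel(f"{channel} fluorescence intensity (linear relative units)")
    ax.set_ylabel("count")
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def stability_timecourse(
    series_set: Sequence[StabilitySeries],
    path,
    standards_fi: dict | None = None,
) -> Path:
    """FI per month for each conjugate, optionally with a standard bead trace."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for s in series_set:
        ax.plot(s.timepoints, s.fi, marker="o", ms=3,
                label=f"{s.conjugate_id} (ΔFI={s.delta_fi:.0f})")
        for t in s.excluded_timepoints:
            i = s.timepoints.index(t)
            ax.plot([t], [s.fi[i]], marker="x", color="k", ms=6)
    if standards_fi:
        months = sorted(standards_fi)
        ax.plot(months, [standards_fi[m] for m in months], ls="--", color="gray",
                label="MESF bead #4")
    ax.set_xlabel("month")
    ax.set_ylabel("FI (geometric mean, linear units)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
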