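"""Optional diagnostic figures (matplotlib, imported lazily).

Scatter panels of log divergence against log evolvability per case and
direction set, and per-study evolvability-along-divergence-vector panels
with the matrix summary levels marked.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


def _pyplot():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_case_regressions(cases, outdir: str | Path) -> list[Path]:
    """One panel per case: e(v) vs d(v) on log axes per direction set."""
    from .multivariate import _project_case, direction_set

    plt = _pyplot()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    markers = {"original": "o", "G_eigen": "^", "D_eigen": "s", "P_eigen": "D"}
    for case in cases:
        fig, ax = plt.subplots(figsize=(4.5, 4))
        sets = ["original", "G_eigen", "D_eigen"] + (
            ["P_eigen"] if case.P is not None else []
        )
        for which in sets:
            dirs = np.vstack([v.values for v in direction_set(case, which)])
            e_vals, d_vals = _project_case(
                case.G.values, case.D.values, dirs, conditional=False
            )
            ok = (e_vals > 0) & (d_vals > 0)
            ax.loglog(e_vals[ok], d_vals[ok], markers[which], label=which,
                      mfc="none")
        ax.set_xlabel("evolvability e(v)")
        ax.set_ylabel("divergence d(v)")
        ax.set_title(case.case_id)
        ax.legend(fontsize=7)
        path = outdir / f"case_{case.case_id}.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(path)
    return written


def plot_divergence_vector_panels(
    records: pd.DataFrame, summaries: dict, outdir: str | Path
) -> list[Path]:
    """Per-study panels of e and c along divergence vectors against
    divergence magnitude, with the mean/min/max evolvability levels."""
    plt = _pyplot()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for study, sub in records.groupby("g_matrix_id"):
        fig, ax = plt.subplots(figsize=(4.5, 4))
        ax.semilogy(sub["d_mag"], sub["e_along"], "o", label="e(Δ)")
        ax.semilogy(sub["d_mag"], sub["c_along"], "^", mfc="none",
                    label="c(Δ)")
        s = summaries.get(study)
        if s is not None:
            for level, style, name in (
                (s.e_mean, "-", "mean"), (s.e_min, ":", "min"),
                (s.e_max, "--", "max"),
            ):
                ax.axhline(level, ls=style, color="gray", lw=0.8)
                ax.annotate(name, (0.99, level), xycoords=("axes fraction",
                                                           "data"),
                            fontsize=6, ha="right")
        ax.set_xlabel("divergence magnitude ||Δ||")
        ax.set_ylabel("evolvability along Δ")
        ax.set_title(study)
        ax.legend(fontsize=7)
        path = outdir / f"divergence_vectors_{study}.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(path)
    return written
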