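"""DLS figures: per-condition box plots with per-participant points.

Boxes show median, quartiles and range per condition; a white diamond
marks the condition mean.  Individual points are placed left (CPH) or
right (BP) of each box, shaped by test-trial first-look correctness
(triangle correct, disc incorrect) and sized by the participant's summed
window looking time.  Participants with an undefined DLS are omitted.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def _dls_figure(table: pd.DataFrame, title: str, path: Path) -> None:
    data = table.dropna(subset=["dls"])
    conditions = [c for c in ("FB1", "FB2") if (data["condition"] == c).any()]
    if not conditions:
        return
    fig, ax = plt.subplots(figsize=(5, 4))
    groups = [data.loc[data["condition"] == c, "dls"].to_numpy() for c in conditions]
    ax.boxplot(
        groups,
        positions=range(1, len(conditions) + 1),
        whis=(0, 100),
        showmeans=True,
        meanprops=dict(marker="D", markerfacecolor="white", markeredgecolor="black"),
        medianprops=dict(color="black"),
    )
    site_offset = {"CPH": -0.22, "BP": 0.22}
    rng = np.random.default_rng(0)  # cosmetic jitter only
    for pos, cond in enumerate(conditions, start=1):
        sub = data[data["condition"] == cond]
        lt = sub["correct_window_ms"] + sub["incorrect_window_ms"]
        sizes = 20 + 80 * lt / max(lt.max(), 1)
        for marker, mask in (("^", sub["first_look_correct"]), ("o", ~sub["first_look_correct"])):
            rows = sub[mask]
            if rows.empty:
                continue
            x = pos + np.array([site_offset.get(s, 0.0) for s in rows["site"]])
            x = x + rng.uniform(-0.04, 0.04, size=len(rows))
            ax.scatter(x, rows["dls"], s=sizes[mask], marker=marker,
                       alpha=0.6, edgecolor="black", linewidth=0.5, zorder=3)
    ax.axhline(0.5, color="grey", linestyle=":", linewidth=1)
    ax.set_xticks(range(1, len(conditions) + 1))
    ax.set_xticklabels(conditions)
    ax.set_ylabel("Differential looking score")
    ax.set_ylim(-0.05, 1.05)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def make_figures(report: dict, table: pd.DataFrame, output_dir: str | Path) -> list[Path]:
    """Write the per-stratum DLS figures; returns the paths written."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for stratum, title, name in (
        ("included", "Included sample", "fig_dls_included.png"),
        ("fam2_incorrect", "Fam2-incorrect sample", "fig_dls_fam2_incorrect.png"),
    ):
        sub = table[table["inclusion"] == stratum]
        if sub.dropna(subset=["dls"]).empty:
            continue
        path = out / name
        _dls_figure(sub, title, path)
        if path.exists():
            written.append(path)
    return written
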