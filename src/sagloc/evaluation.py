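"""Localization performance metrics and comparison reports.

Two standard metrics summarize a response table: the quadrant error rate
(QE, percentage of responses whose absolute polar error exceeds 90°) and the
local polar error (PE, root-mean-square polar error over the remaining
"local" responses).  Errors are circular differences of raw response angles,
never binned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LocalizationMetrics",
    "polar_error",
    "qe_pe",
    "metrics_by_subject",
    "pmv_response_report",
]


@dataclass(frozen=True)
class LocalizationMetrics:
    """QE (percent), PE (degrees RMS over local responses), and counts."""

    qe: float
    pe: float          # NaN when no local responses exist
    n_local: int
    n_total: int

    @property
    def pe_defined(self) -> bool:
        return self.n_local > 0


def polar_error(target_polar, response_polar):
    """Signed circular polar-angle disparity wrapped into [−180, 180)."""
    diff = np.asarray(response_polar, dtype=float) - np.asarray(target_polar, float)
    return (diff + 180.0) % 360.0 - 180.0


def qe_pe(responses: pd.DataFrame) -> LocalizationMetrics:
    """Quadrant error rate and local polar RMS error of a response table.

    An absolute error of exactly 90° still counts as local.
    """
    if len(responses) == 0:
        raise ValueError("empty response table")
    err = np.abs(polar_error(responses["target_pol"].to_numpy(),
                             responses["response_pol"].to_numpy()))
    local = err <= 90.0
    qe = 100.0 * float((~local).mean())
    pe = float(np.sqrt(np.mean(err[local] ** 2))) if local.any() else float("nan")
    return LocalizationMetrics(qe, pe, int(local.sum()), int(err.size))


def metrics_by_subject(responses: pd.DataFrame,
                       lateral_range=None) -> pd.DataFrame:
    """Per-subject QE/PE table, optionally restricted to a lateral range."""
    df = responses
    if lateral_range is not None:
        lo, hi = lateral_range
        df = df[(df["target_lat"] > lo) & (df["target_lat"] < hi)]
    rows = []
    for sid, grp in df.groupby("subject_id"):
        m = qe_pe(grp)
        rows.append({"subject_id": sid, "qe": m.qe, "pe": m.pe,
                     "n_local": m.n_local, "n_total": m.n_total})
    return pd.DataFrame(rows)


def pmv_response_report(pmv_matrix: np.ndarray, polar_grid: np.ndarray,
                        responses: pd.DataFrame, title: str = "PMV report",
                        path=None) -> str:
    """Markdown report: per-target PMV summary with observed responses.

    Returns the Markdown text; also writes it to ``path`` when given.  A
    companion heat-map figure is produced alongside ``path`` when matplotlib
    is importable (targets × response bins, responses overlaid).
    """
    grid = np.asarray(polar_grid, dtype=float)
    lines = [f"# {title}", "",
             f"{pmv_matrix.shape[0]} targets × {grid.size} response bins; "
             f"{len(responses)} observed responses.", "",
             "| target θ (deg) | PMV mode (deg) | PMV entropy (nats) | n responses |",
             "|---:|---:|---:|---:|"]
    tgt_bins = np.array([int(np.argmin(np.abs((grid - t + 180) % 360 - 180)))
                         for t in responses["target_pol"]])
    for i in range(pmv_matrix.shape[0]):
        p = pmv_matrix[i]
        nz = p[p > 0]
        ent = float(-(nz * np.log(nz)).sum())
        lines.append(f"| {grid[i]:.0f} | {grid[int(np.argmax(p))]:.0f} "
                     f"| {ent:.2f} | {int((tgt_bins == i).sum())} |")
    text = "\n".join(lines) + "\n"
    if path is not None:
        path = str(path)
        with open(path, "w") as fh:
            fh.write(text)
        try:
            import matplotlib
            matplotlib.use("Agg")
            import matplotlib.pyplot as plt
            fig, ax = plt.subplots(figsize=(6, 5))
            ax.imshow(pmv_matrix.T, origin="lower", aspect="auto",
                      extent=[grid[0], grid[-1], grid[0], grid[-1]],
                      cmap="magma")
            ax.scatter(responses["target_pol"], responses["response_pol"],
                       s=8, facecolors="none", edgecolors="red", linewidths=0.6)
            ax.set_xlabel("target polar angle (deg)")
            ax.set_ylabel("response polar angle (deg)")
            ax.set_title(title)
            fig.tight_layout()
            fig.savefig(path.rsplit(".", 1)[0] + ".png", dpi=120)
            plt.close(fig)
        except ImportError:
            pass
    return text
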