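"""MA and MW diagnostic plots from a result table.

MA (Bland-Altman): median between-condition difference M against the median
overall expression A.  MW: M against the maximum within-condition
difference W — the plot that separates between-condition signal from
within-condition noise; genes above the within/between equivalence diagonal
differ more between conditions than within them.

Every plot writes its plotted columns as a TSV twin next to the image, so
downstream checks can assert on numbers rather than pixels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["PlotSpec", "plot"]


@dataclass
class PlotSpec:
    kind: str                       # "MA" or "MW"
    path: str
    effect_cutoff: float = 1.5
    conservative_cutoff: float | None = 2.0

    def __post_init__(self) -> None:
        if self.kind not in ("MA", "MW"):
            raise ValueError("kind must be 'MA' or 'MW'")


def plot(results: pd.DataFrame, spec: PlotSpec) -> Path:
    """Render the requested plot and its TSV twin; returns the TSV path."""
    if results.empty:
        raise ValueError("empty result table")
    xcol = "A" if spec.kind == "MA" else "W"
    for col in (xcol, "M", "called"):
        if col not in results.columns:
            raise KeyError(f"result table lacks column {col!r}")
    df = results[["gene_id", xcol, "M", "called"]].copy()
    if spec.conservative_cutoff is not None and "E" in results.columns:
        df["called_conservative"] = results["called"] & (
            results["E"].abs() >= spec.conservative_cutoff
        )

    fig, ax = plt.subplots(figsize=(5, 5))
    bg = ~df["called"]
    ax.scatter(df.loc[bg, xcol], df.loc[bg, "M"], s=3, c="grey", alpha=0.3, label="null")
    ax.scatter(df.loc[df["called"], xcol], df.loc[df["called"], "M"], s=6, c="red",
               label="called")
    if "called_conservative" in df:
        sel = df["called_conservative"]
        ax.scatter(df.loc[sel, xcol], df.loc[sel, "M"], s=6, c="orange",
                   label="called (conservative)")
    if spec.kind == "MW":
        lim = max(1.0, float(np.nanmax(np.abs(df[["W", "M"]].to_numpy()))))
        ww = np.linspace(0, lim, 50)
        ax.plot(ww, ww, ls="--", c="grey", lw=1)      # within/between equivalence
        ax.plot(ww, -ww, ls="--", c="grey", lw=1)
        ax.plot(ww, 2 * ww, ls=":", c="grey", lw=1)   # 2x threshold
        ax.plot(ww, -2 * ww, ls=":", c="grey", lw=1)
    ax.set_xlabel("median expression (A)" if spec.kind == "MA"
                  else "max within-condition difference (W)")
    ax.set_ylabel("median between-condition difference (M)")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(spec.path, dpi=150)
    plt.close(fig)

    tsv_path = Path(spec.path).with_suffix(".tsv")
    df.to_csv(tsv_path, sep="\t", index=False, float_format="%.12g")
    return tsv_path
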