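"""Figure helpers: aging-index scatter, PCoA scatter, co-expression
heatmap. All figures are regenerated from data on every run and saved as
both SVG and PNG."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .aging import AgingIndexCurve, LengthShiftResult
from .ordination import PCoAResult


def _save(fig, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    for ext in ("svg", "png"):
        fig.savefig(path.with_suffix(f".{ext}"), dpi=150,
                    bbox_inches="tight")
    plt.close(fig)


def aging_index_scatter(curve: AgingIndexCurve, shift: LengthShiftResult,
                        path: str | Path, title: str = "") -> None:
    """I_a versus fragment length with the OLS display line."""
    fig, ax = plt.subplots(figsize=(4.2, 3.4))
    mask = curve.defined_mask
    ax.scatter(curve.lengths[mask], curve.values[mask], s=22, color="#1f6fb4")
    xs = np.array([curve.lengths[mask].min(), curve.lengths[mask].max()])
    ax.plot(xs, shift.slope * xs + shift.intercept, color="#c44e52")
    ax.axhline(0, lw=0.6, color="grey")
    ax.set_xlabel("RNA length (nt)")
    ax.set_ylabel(r"aging index $I_a$")
    ax.set_title(f"{title}  ρ={shift.rho:.2f}, P={shift.pvalue:.2g}".strip())
    _save(fig, Path(path))


def pcoa_scatter(result: PCoAResult, ages: pd.Series, path: str | Path,
                 title: str = "") -> None:
    """Axis 1 / Axis 2 scatter colored by age group."""
    coords = result.coordinates
    fig, ax = plt.subplots(figsize=(4.2, 3.6))
    cmap = plt.get_cmap("viridis")
    uniq = sorted(ages.unique())
    for i, age in enumerate(uniq):
        sel = ages.index[ages == age]
        y = (coords.loc[sel, "Axis 2"]
             if "Axis 2" in coords else pd.Series(0.0, index=sel))
        ax.scatter(coords.loc[sel, "Axis 1"], y,
                   color=cmap(i / max(1, len(uniq) - 1)), label=f"{age:g}")
    pe = result.proportion_explained
    ax.set_xlabel(f"Axis 1 ({100 * pe[0]:.1f}%)" if len(pe) else "Axis 1")
    ax.set_ylabel(f"Axis 2 ({100 * pe[1]:.1f}%)" if len(pe) > 1 else "Axis 2")
    ax.legend(title="age", fontsize=7, title_fontsize=8)
    ax.set_title(title)
    _save(fig, Path(path))


def coexpression_heatmap(C: pd.DataFrame, leaf_order: list[str],
                         origins: pd.Series, path: str | Path,
                         title: str = "") -> None:
    """Clustered Spearman heatmap with a mitochondrial side bar.

    Rows/columns follow the dendrogram leaf order; mitochondria-derived
    families are marked in orange on the side bar.
    """
    M = C.loc[leaf_order, leaf_order]
    n = len(M)
    fig, ax = plt.subplots(figsize=(5.2, 4.6))
    im = ax.imshow(M.to_numpy(), cmap="RdBu_r", vmin=-1, vmax=1)
    is_mt = [origins[f] == "mitochondrial" for f in leaf_order]
    for i, mt in enumerate(is_mt):
        if mt:
            ax.add_patch(plt.Rectangle((-1.4, i - 0.5), 0.8, 1.0,
                                       color="orange", clip_on=False))
    ax.set_xticks(range(n))
    ax.set_xticklabels(leaf_order, rotation=90, fontsize=5)
    ax.set_yticks(range(n))
    ax.set_yticklabels(leaf_order, fontsize=5)
    fig.colorbar(im, ax=ax, shrink=0.75, label="Spearman ρ")
    ax.set_title(title)
    _save(fig, Path(path))
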