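"""Power-vs-FDR curves from per-gene p-values and ground-truth labels.

Genes are ranked by ascending p-value; each prefix of the ranking is a call
set with a realized false discovery rate FP/(FP+TP) and a true positive rate
TP/(total true). The power at an FDR budget is the best TPR attainable by any
prefix whose realized FDR stays within the budget — the standard benchmark
construction for method comparison on labeled simulations. Genes with tied
p-values enter the prefix together so curves do not depend on storage order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PowerCurve",
    "power_at_fdr",
    "average_curves",
    "estimated_fdr_curve",
    "plot_curves",
]


@dataclass
class PowerCurve:
    fdr_grid: np.ndarray
    tpr: np.ndarray
    method: str = ""
    n_replicates: int = 1

    def __post_init__(self):
        self.fdr_grid = np.asarray(self.fdr_grid, dtype=float)
        self.tpr = np.asarray(self.tpr, dtype=float)
        if self.fdr_grid.shape != self.tpr.shape:
            raise ValueError("grid/tpr length mismatch")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fdr": self.fdr_grid,
                "tpr": self.tpr,
                "method": self.method,
                "n_replicates": self.n_replicates,
            }
        )


def _truth_to_bool(truth_labels) -> np.ndarray:
    truth = np.asarray(truth_labels)
    if truth.dtype == bool:
        return truth
    return np.isin(truth, ("svg", "SVG", "true", "True", "1", 1, True))


def power_at_fdr(pvalues, truth_labels, fdr_grid) -> PowerCurve:
    """True positive rate at each realized-FDR budget on the grid.

    ``truth_labels`` may be booleans (True = spatially variable) or the
    string labels ``"svg"``/``"null"``. Both classes must be present and all
    p-values finite.
    """
    p = np.asarray(pvalues, dtype=float)
    truth = _truth_to_bool(truth_labels)
    if p.shape != truth.shape:
        raise ValueError("p-values and labels must align")
    if not np.isfinite(p).all():
        raise ValueError("p-values must be finite")
    n_true = int(truth.sum())
    n_false = int((~truth).sum())
    if n_true == 0 or n_false == 0:
        raise ValueError("both classes must be present in the truth labels")

    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    tp = np.cumsum(truth[order])
    fp = np.cumsum(~truth[order])
    # tie blocks enter together: keep only the last index of each run of equal p
    block_end = np.nonzero(np.append(np.diff(p_sorted) > 0, True))[0]
    tp_b = tp[block_end].astype(float)
    fp_b = fp[block_end].astype(float)
    fdr_b = fp_b / (fp_b + tp_b)
    tpr_b = tp_b / n_true

    grid = np.asarray(fdr_grid, dtype=float)
    tpr_out = np.zeros_like(grid)
    for i, g in enumerate(grid):
        ok = fdr_b <= g
        tpr_out[i] = tpr_b[ok].max() if ok.any() else 0.0
    # monotone envelope in the budget (max over admissible prefixes already is)
    return PowerCurve(fdr_grid=grid, tpr=tpr_out)


def average_curves(curves: list[PowerCurve]) -> PowerCurve:
    """Point-wise mean TPR over replicates; grids must match exactly."""
    if not curves:
        raise ValueError("no curves to average")
    grid = curves[0].fdr_grid
    for c in curves[1:]:
        if not np.array_equal(c.fdr_grid, grid):
            raise ValueError("curves have mismatched FDR grids")
    tpr = np.mean([c.tpr for c in curves], axis=0)
    methods = {c.method for c in curves if c.method}
    return PowerCurve(
        fdr_grid=grid.copy(),
        tpr=tpr,
        method=methods.pop() if len(methods) == 1 else "",
        n_replicates=sum(c.n_replicates for c in curves),
    )


def plot_curves(curves: list[PowerCurve], path=None):
    """Plot one or more power-vs-FDR curves; optionally save to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for curve in curves:
        label = curve.method or None
        ax.plot(curve.fdr_grid, curve.tpr, marker=".", label=label)
    ax.set_xlabel("false discovery rate")
    ax.set_ylabel("true positive rate")
    ax.set_ylim(-0.02, 1.02)
    if any(c.method for c in curves):
        ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def estimated_fdr_curve(pvalues, truth_labels, fdr_grid) -> PowerCurve:
    """Power against Benjamini-Hochberg *estimated* FDR (for real-data use).

    Calls are genes with BH-adjusted p below the budget; the TPR still comes
    from the supplied labels, so on simulations this shows how conservative
    the estimate is relative to the realized-FDR curve.
    """
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    truth = _truth_to_bool(truth_labels)
    n_true = int(truth.sum())
    if n_true == 0:
        raise ValueError("no true positives in the labels")
    adj = multipletests(p, method="fdr_bh")[1]
    grid = np.asarray(fdr_grid, dtype=float)
    tpr = np.array([(truth & (adj <= g)).sum() / n_true for g in grid])
    return PowerCurve(fdr_grid=grid, tpr=tpr, method="bh_estimated")
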