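"""Result summaries and MA-plot tables.

The MA layout mirrors the study style these pipelines report: per-event
log2 mean read count on the x-axis, the PIR/PSI difference (or gene
log2 fold change) on the y-axis, significant events coloured red
(increased/up) or blue (decreased/down), and dashed guides at +-10
percentage points for splicing panels.  Plots are emitted as data tables
first — images are an optional rendering of the same table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import splicing
from . import dge as dge_mod

__all__ = ["SummaryReport", "summarize", "ma_table", "plot_ma"]

_COLORS = {
    splicing.INCREASED: "red",
    splicing.DECREASED: "blue",
    splicing.NOT_SIGNIFICANT: "grey",
    splicing.NOT_EXPRESSED: "lightgrey",
    dge_mod.UP: "red",
    dge_mod.DOWN: "blue",
    dge_mod.NS: "grey",
    dge_mod.EXCLUDED: "lightgrey",
}


@dataclass
class SummaryReport:
    """Tallies of classified events and genes for one contrast."""

    ir: dict[str, int] = field(default_factory=dict)
    es: dict[str, int] = field(default_factory=dict)
    genes: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"ir": self.ir, "es": self.es, "genes": self.genes}

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("sort_keys", True)
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kwargs)


def _tally_events(results: pd.DataFrame | None) -> dict[str, int]:
    keys = [
        splicing.INCREASED,
        splicing.DECREASED,
        splicing.NOT_SIGNIFICANT,
        splicing.NOT_EXPRESSED,
    ]
    if results is None:
        return {k: 0 for k in keys} | {"tested": 0, "total": 0}
    vc = results["classification"].value_counts()
    out = {k: int(vc.get(k, 0)) for k in keys}
    out["tested"] = int(results["p_adj"].notna().sum())
    out["total"] = len(results)
    return out


def summarize(
    ir_results: pd.DataFrame | None = None,
    es_results: pd.DataFrame | None = None,
    dge_results: pd.DataFrame | None = None,
    twofold_lfc: float = 1.0,
) -> SummaryReport:
    """Tally classifications; deterministic and row-order independent.

    The gene section counts significant up/down genes and, echoing the
    "altered more than twofold" style of reporting, the significant
    genes with |log2FC| > ``twofold_lfc`` plus their fraction of all
    tested genes.
    """
    rep = SummaryReport()
    rep.ir = _tally_events(ir_results)
    rep.es = _tally_events(es_results)
    genes: dict[str, float] = {
        "up": 0, "down": 0, "ns": 0, "excluded": 0, "tested": 0,
        "twofold": 0, "twofold_fraction": 0.0,
    }
    if dge_results is not None:
        vc = dge_results["direction"].value_counts()
        genes["up"] = int(vc.get(dge_mod.UP, 0))
        genes["down"] = int(vc.get(dge_mod.DOWN, 0))
        genes["ns"] = int(vc.get(dge_mod.NS, 0))
        genes["excluded"] = int(vc.get(dge_mod.EXCLUDED, 0))
        tested = dge_results["p_adj"].notna()
        genes["tested"] = int(tested.sum())
        sig = dge_results["direction"].isin([dge_mod.UP, dge_mod.DOWN])
        two = sig & (dge_results["log2fc"].abs() > twofold_lfc)
        genes["twofold"] = int(two.sum())
        genes["twofold_fraction"] = (
            float(two.sum() / tested.sum()) if tested.any() else 0.0
        )
    rep.genes = genes
    return rep


def ma_table(results: pd.DataFrame, kind: str = "splicing",
             delta_min: float = splicing.DEFAULT_DELTA_MIN) -> pd.DataFrame:
    """Plot-ready MA table: one row per tested event (or gene).

    For ``kind="splicing"`` x is ``mean_log2_count`` and y the PIR/PSI
    delta; for ``kind="dge"`` x is log2(1 + base_mean) and y the log2
    fold change.  ``df.attrs["guides"]`` carries the dashed guide
    positions (+-delta_min for splicing, none for expression).
    """
    if kind == "splicing":
        tested = results[results["p_adj"].notna()]
        out = pd.DataFrame(
            {
                "id": tested["event_id"].to_numpy(),
                "x": tested["mean_log2_count"].to_numpy(),
                "y": tested["delta"].to_numpy(),
                "classification": tested["classification"].to_numpy(),
            }
        )
        guides = (-float(delta_min), float(delta_min))
    elif kind == "dge":
        tested = results[results["p_adj"].notna()]
        out = pd.DataFrame(
            {
                "id": tested["gene_id"].to_numpy(),
                "x": np.log2(1.0 + tested["base_mean"].to_numpy()),
                "y": tested["log2fc"].to_numpy(),
                "classification": tested["direction"].to_numpy(),
            }
        )
        guides = ()
    else:
        raise ValueError("kind must be 'splicing' or 'dge'")
    out["color"] = out["classification"].map(_COLORS)
    out = out.reset_index(drop=True)
    out.attrs["guides"] = guides
    return out


def plot_ma(table: pd.DataFrame, path, title: str = "",
            ylabel: str = "delta (%)") -> None:
    """Render an MA table to an image file (optional convenience)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for cls, grp in table.groupby("classification", sort=True):
        ax.scatter(grp["x"], grp["y"], s=6, c=grp["color"].iloc[0],
                   label=f"{cls} (n={len(grp)})", alpha=0.6, linewidths=0)
    for g in table.attrs.get("guides", ()):
        ax.axhline(g, color="grey", linestyle="--", linewidth=0.8)
    ax.set_xlabel("log2 mean read count")
    ax.set_ylabel(ylabel)
    if title:
        ax.set_title(title)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
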