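"""Standard cost-effectiveness graphics: CE plane, CEAC, tornado diagram."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .economics import PSAResult
from .owsa import TornadoEntry

__all__ = ["plot_ce_plane", "plot_ceac", "plot_tornado"]


def plot_ce_plane(psa: PSAResult, path: str | Path) -> Path:
    """Incremental cost-effectiveness plane with the WTP threshold line."""
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(psa.delta_qalys, psa.delta_costs, s=4, alpha=0.3, color="#1f77b4")
    lim = max(abs(psa.delta_qalys).max(), 1e-6)
    ax.plot([-lim, lim], [-psa.wtp * lim, psa.wtp * lim], "r--", lw=1,
            label=f"WTP €{psa.wtp:,.0f}/QALY")
    ax.axhline(0, color="k", lw=0.5)
    ax.axvline(0, color="k", lw=0.5)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental costs (€)")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_ceac(psa: PSAResult, path: str | Path) -> Path:
    """Cost-effectiveness acceptability curve over the WTP grid."""
    curve = psa.ceac
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(list(curve.keys()), list(curve.values()), color="#1f77b4")
    ax.axvline(psa.wtp, color="r", ls="--", lw=1, label=f"WTP €{psa.wtp:,.0f}")
    ax.set_xlabel("Willingness to pay (€/QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_tornado(
    entries: list[TornadoEntry], base_inmb: float, path: str | Path
) -> Path:
    """Tornado diagram of one-way iNMB variations around the base case."""
    entries = sorted(entries, key=lambda e: e.width)
    labels = [e.name for e in entries]
    fig, ax = plt.subplots(figsize=(7, 0.5 * max(len(entries), 4) + 1.5))
    for i, e in enumerate(entries):
        lo, hi = sorted((e.inmb_lo, e.inmb_hi))
        ax.barh(i, hi - lo, left=lo, color="#1f77b4", alpha=0.8)
    ax.axvline(base_inmb, color="k", lw=1, label="base-case iNMB")
    ax.set_yticks(range(len(entries)))
    ax.set_yticklabels(labels, fontsize=8)
    ax.set_xlabel("Incremental net monetary benefit (€)")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
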