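"""Forest plot of per-method odds ratios (and optional leave-one-out panel)."""

from __future__ import annotations

import logging
from pathlib import Path

logger = logging.getLogger(__name__)


def forest_plot_data(report) -> list[dict]:
    """Rows of the forest plot: one per univariable method, OR scale."""
    rows = []
    for name, est in report.univariable.items():
        d = est.to_dict()
        rows.append(
            {
                "label": name,
                "n_snp": d["n_snp"],
                "or": d.get("odds_ratio"),
                "or_low": d.get("or_ci_low"),
                "or_high": d.get("or_ci_high"),
            }
        )
    return rows


def render_forest(report, path: str | Path, include_loo: bool = True) -> bool:
    """Write a forest plot (PNG/SVG by extension). Failures are logged,
    never raised — plotting must not affect the analysis result."""
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        rows = forest_plot_data(report)
        loo = report.leave_one_out if include_loo else []
        n_panels = 2 if loo else 1
        fig, axes = plt.subplots(
            1, n_panels, figsize=(5 * n_panels + 2, max(3, 0.4 * len(rows) + 1)),
            squeeze=False,
        )
        ax = axes[0][0]
        ys = range(len(rows))
        for y, r in zip(ys, rows):
            if r["or"] is None:
                continue
            ax.plot([r["or_low"], r["or_high"]], [y, y], color="k", lw=1.2)
            ax.plot(r["or"], y, "s", color="tab:blue")
        ax.axvline(1.0, color="grey", ls="--", lw=0.8)
        ax.set_yticks(list(ys))
        ax.set_yticklabels([f"{r['label']} (n={r['n_snp']})" for r in rows])
        ax.invert_yaxis()
        ax.set_xlabel("odds ratio per 1-unit exposure increase")
        ax.set_xscale("log")
        if loo:
            ax2 = axes[0][1]
            for y, row in enumerate(loo):
                ax2.plot([row["ci_low"], row["ci_high"]], [y, y], color="grey", lw=0.7)
                ax2.plot(row["theta"], y, ".", color="tab:red", ms=3)
            ax2.axvline(0.0, color="grey", ls="--", lw=0.8)
            ax2.set_xlabel("leave-one-out log-OR")
            ax2.set_yticks([])
        fig.tight_layout()
        fig.savefig(path)
        plt.close(fig)
        return True
    except Exception:  # pragma: no cover - defensive: plotting is best-effort
        logger.exception("forest plot rendering failed; analysis results unaffected")
        return False
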