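"""Optional figures from emitted CSV data (tornado, CEAC, PSA scatter).

Figures are convenience renderings only; every analysis result is judged on
the CSV data the pipeline writes.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def render_all(results_dir: Path) -> list[Path]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []

    tornado_csv = results_dir / "tornado.csv"
    if tornado_csv.exists():
        t = pd.read_csv(tornado_csv).sort_values("width").tail(12)
        mid = (t["icer_low"] + t["icer_high"]) / 2
        fig, ax = plt.subplots(figsize=(7, 5))
        ax.barh(t["parameter"], t["icer_high"] - t["icer_low"],
                left=t[["icer_low", "icer_high"]].min(axis=1), color="#4878d0")
        ax.set_xlabel("ICER (USD per QALY)")
        ax.set_title("One-way sensitivity analysis")
        fig.tight_layout()
        out = results_dir / "tornado.png"
        fig.savefig(out, dpi=150)
        plt.close(fig)
        written.append(out)

    ceac_csv = results_dir / "ceac.csv"
    if ceac_csv.exists():
        c = pd.read_csv(ceac_csv)
        fig, ax = plt.subplots(figsize=(7, 5))
        for col in c.columns[1:]:
            ax.plot(c["wtp"], c[col], label=col.replace("_", " "))
        ax.set_xlabel("Willingness to pay (USD per QALY)")
        ax.set_ylabel("Probability cost-effective")
        ax.set_title("Cost-effectiveness acceptability curves")
        ax.legend()
        fig.tight_layout()
        out = results_dir / "ceac.png"
        fig.savefig(out, dpi=150)
        plt.close(fig)
        written.append(out)

    scatter_csv = results_dir / "psa_scatter.csv"
    if scatter_csv.exists():
        s = pd.read_csv(scatter_csv)
        ref = "routine_care"
        fig, ax = plt.subplots(figsize=(7, 5))
        if ref in set(s["strategy"]):
            base = s[s["strategy"] == ref].set_index("iteration")
            for name, grp in s[s["strategy"] != ref].groupby("strategy"):
                grp = grp.set_index("iteration")
                ax.scatter(grp["effect"] - base["effect"], grp["cost"] - base["cost"],
                           s=3, alpha=0.3, label=name.replace("_", " "))
            ax.axhline(0, color="grey", lw=0.5)
            ax.axvline(0, color="grey", lw=0.5)
            ax.set_xlabel("Incremental QALYs vs routine care")
            ax.set_ylabel("Incremental cost (USD) vs routine care")
            ax.legend()
        ax.set_title("PSA incremental scatter")
        fig.tight_layout()
        out = results_dir / "psa_scatter.png"
        fig.savefig(out, dpi=150)
        plt.close(fig)
        written.append(out)

    return written
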