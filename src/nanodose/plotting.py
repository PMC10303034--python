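"""Figure output: DER versus depth, one panel per material, one line per
concentration (the layout of the study's result figures)."""
from __future__ import annotations

import pathlib
from collections import defaultdict

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["plot_der_study"]


def plot_der_study(curves, outdir) -> list[pathlib.Path]:
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    grouped = defaultdict(list)
    for c in curves:
        grouped[(c.meta.get("kvp"), c.meta.get("material"))].append(c)
    written = []
    for (kvp, material), group in sorted(grouped.items(),
                                         key=lambda kv: str(kv[0])):
        fig, ax = plt.subplots(figsize=(5, 4))
        for c in sorted(group, key=lambda c: c.meta.get("concentration", 0)):
            ok = ~c.undefined
            ax.errorbar(c.depth_cm[ok], c.der[ok],
                        yerr=(c.der * c.rel_unc)[ok],
                        marker="o", ms=3, capsize=2,
                        label=f"{c.meta.get('concentration', 0):g} mg/mL")
        ax.axhline(1.0, color="0.6", lw=0.8, ls="--")
        ax.set_xlabel("depth (cm)")
        ax.set_ylabel("dose enhancement ratio")
        ax.set_title(f"{material}, {kvp:g} kVp")
        ax.legend(fontsize=8)
        fig.tight_layout()
        path = outdir / f"der_{material}_{kvp:g}kVp.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        written.append(path)
    return written
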