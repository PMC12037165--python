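"""Figure assembly and a machine-readable results manifest.

Reads a completed :class:`~graspcode.io_core.ResultStore` (never writes to
it) and renders the standard summary panels: dauROC heatmaps sorted by peak
time, selectivity scatter + covariance ellipse, demixed-component
classifier traces, cross-temporal accuracy matrices with static-bin
overlays, and generalization-index curves. Key numbers go to a JSON
manifest alongside the figures.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .io_core import ResultStore
from .single_unit import ellipse_angle

__all__ = ["build_report"]

log = logging.getLogger("graspcode")


def _fig_path(outdir: Path, name: str) -> str:
    p = outdir / f"{name}.svg"
    return str(p)


def build_report(store: ResultStore, outdir: str | Path) -> dict:
    """Render available panels and return the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = store.stages()
    manifest: dict = {"stages": stages, "figures": {}, "numbers": {},
                      "provenance": store.load_config() if (store.path / "provenance.json").exists() else {}}
    missing = [s for s in ("auroc", "dpca", "decoding") if s not in stages]
    if missing:
        log.warning("report: missing stages %s; rendering partial report", missing)
        manifest["missing"] = missing

    if "auroc" in stages:
        a = store.load_arrays("auroc")
        counts = a["class_counts"]
        manifest["numbers"]["selectivity_counts"] = {
            "grip_only": int(counts[0]), "force_only": int(counts[1]),
            "mixed": int(counts[2]), "none": int(counts[3])}
        fig, axes = plt.subplots(1, 2, figsize=(10, 4))
        for ax, which in zip(axes, ("grip", "force")):
            delta = a[f"delta_{which}"]
            sel = a[f"mask_{which}"].any(axis=1)
            d = delta[sel]
            if len(d):
                order = np.argsort(np.argmax(d, axis=1))
                ax.imshow(d[order], aspect="auto", cmap="viridis",
                          extent=[a["bin_centers"][0], a["bin_centers"][-1], 0, len(d)])
            ax.set_title(f"ΔauROC {which} (selective units)")
            ax.set_xlabel("time from movement onset (ms)")
        fig.tight_layout()
        p = _fig_path(outdir, "delta_auroc_heatmaps")
        fig.savefig(p)
        plt.close(fig)
        manifest["figures"]["delta_auroc_heatmaps"] = p

        # scatter + ellipse at the bin of peak mean grip delta
        b = int(np.argmax(a["delta_grip"].mean(axis=0)))
        pts = np.column_stack([a["auroc_force"][:, b], a["auroc_grip"][:, b]])
        fig, ax = plt.subplots(figsize=(4.5, 4.5))
        ax.scatter(pts[:, 0], pts[:, 1], s=12, alpha=0.7)
        try:
            theta, semi, center = ellipse_angle(pts)
            from matplotlib.patches import Ellipse
            ax.add_patch(Ellipse(center, 2 * semi[0], 2 * semi[1], angle=theta,
                                 fill=False, color="C0"))
            manifest["numbers"]["ellipse_theta_deg"] = round(theta, 2)
        except ValueError:
            pass
        ax.set_xlabel("force auROC")
        ax.set_ylabel("grip auROC")
        ax.set_xlim(0, 1)
        ax.set_ylim(0, 1)
        fig.tight_layout()
        p = _fig_path(outdir, "auroc_scatter_ellipse")
        fig.savefig(p)
        plt.close(fig)
        manifest["figures"]["auroc_scatter_ellipse"] = p

    if "dpca" in stages:
        d = store.load_arrays("dpca")
        totals = {phi: float(d[f"explained_{phi}"].sum())
                  for phi in ("time", "grip", "force", "interaction")}
        manifest["numbers"]["explained_variance_pct"] = {k: round(v, 2) for k, v in totals.items()}
        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.5))
        ax1.bar(list(totals), list(totals.values()))
        ax1.set_ylabel("% explained variance")
        for phi, color in (("grip", "C1"), ("force", "C4")):
            acc = d[f"classifier_{phi}_accuracy"]
            ax2.plot(d["bin_centers"], acc, color=color, label=phi)
            m = d[f"classifier_{phi}_mask"].astype(bool)
            if m.any():
                ax2.plot(d["bin_centers"][m], np.full(m.sum(), 0.02 + 0.02 * (phi == "force")),
                         ".", color=color, ms=3)
            manifest["numbers"][f"first_significant_{phi}_component"] = int(
                d[f"classifier_{phi}_component"])
        ax2.axhline(0.5, ls=":", c="k")
        ax2.set_xlabel("time from movement onset (ms)")
        ax2.set_ylabel("accuracy")
        ax2.legend()
        fig.tight_layout()
        p = _fig_path(outdir, "dpca_summary")
        fig.savefig(p)
        plt.close(fig)
        manifest["figures"]["dpca_summary"] = p

    if "decoding" in stages:
        k = store.load_arrays("decoding")
        fig, axes = plt.subplots(2, 2, figsize=(9, 8))
        for col, pname in enumerate(("grip", "force")):
            M = k[f"matrix_{pname}"]
            st = k[f"static_{pname}"].astype(bool)
            ext = [k["bin_centers"][0], k["bin_centers"][-1]] * 2
            axes[0, col].imshow(M.T, origin="lower", aspect="auto", extent=ext,
                                vmin=0.3, vmax=1.0, cmap="magma")
            axes[0, col].set_title(f"{pname}: cross-temporal accuracy")
            axes[1, col].imshow(st.T, origin="lower", aspect="auto", extent=ext, cmap="cividis")
            axes[1, col].set_title(f"{pname}: static bins")
            axes[1, col].set_xlabel("train time (ms)")
            manifest["numbers"][f"static_bin_count_{pname}"] = int(st.sum())
            manifest["numbers"][f"gi_mean_prep_{pname}"] = round(float(k[f"gi_prep_{pname}"].mean()), 4)
            manifest["numbers"][f"gi_mean_exec_{pname}"] = round(float(k[f"gi_exec_{pname}"].mean()), 4)
        fig.tight_layout()
        p = _fig_path(outdir, "cross_temporal")
        fig.savefig(p)
        plt.close(fig)
        manifest["figures"]["cross_temporal"] = p

        fig, ax = plt.subplots(figsize=(6, 3.5))
        for pname, ls in (("grip", "-"), ("force", "--")):
            ax.plot(k["bin_centers"], k[f"gi_prep_{pname}"], "C0", ls=ls,
                    label=f"{pname}: trained in preparation")
            ax.plot(k["bin_centers"], k[f"gi_exec_{pname}"], "C3", ls=ls,
                    label=f"{pname}: trained in execution")
        ax.set_xlabel("test time (ms)")
        ax.set_ylabel("generalization index")
        ax.legend(fontsize=7)
        fig.tight_layout()
        p = _fig_path(outdir, "generalization_index")
        fig.savefig(p)
        plt.close(fig)
        manifest["figures"]["generalization_index"] = p

    if "behavior" in stages:
        b = store.load_arrays("behavior")
        manifest["numbers"]["rt_mean_ms"] = [round(float(x), 1) for x in b["rt_mean"]]
        manifest["numbers"]["mt_mean_ms"] = [round(float(x), 1) for x in b["mt_mean"]]
        if "prop_significant" in b:
            manifest["numbers"]["force_dpc_significant_proportion"] = {
                "time": round(float(b["prop_significant"][0]), 3),
                "force": round(float(b["prop_significant"][1]), 3)}

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
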