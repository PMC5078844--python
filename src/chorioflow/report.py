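"""Figure generation from pipeline artifacts.

Figures are side effects only — they are rendered from the exported
artifact files, never fed back into computation.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["make_report"]


def _streamline_map(art_dir: Path, out: Path) -> bool:
    topo = art_dir / "topology.json"
    gj = art_dir / "segments.geojson"
    opens = art_dir / "openings.csv"
    if not opens.exists():
        return False
    import pandas as pd

    df = pd.read_csv(opens)
    fig, ax = plt.subplots(figsize=(6, 6))
    for kind, color in (("arteriolar", "tab:red"), ("venular", "tab:blue")):
        sub = df[df["kind"] == kind]
        ax.plot(sub["x"], sub["y"], "o", color=color, ms=5, label=kind)
    if gj.exists():
        data = json.loads(gj.read_text())
        for feat in data["features"]:
            ring = np.array(feat["geometry"]["coordinates"][0])
            ax.plot(ring[:, 0], ring[:, 1], "k-", lw=0.8)
    if topo.exists():
        pts = json.loads(topo.read_text())["stagnation_points"]
        for p in pts:
            ax.plot(p["x"], p["y"], "k*", ms=10)
    ax.set_aspect("equal")
    ax.legend(loc="upper right", fontsize=8)
    ax.set_title("Functional vascular segments and stagnation points")
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return True


def _travel_time_pdf(art_dir: Path, out: Path) -> bool:
    f = art_dir / "travel_times.csv"
    if not f.exists():
        return False
    data = np.loadtxt(f, delimiter=",", skiprows=1)
    T = data[:, 1]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.hist(T, bins=60, density=True, color="tab:purple", alpha=0.8)
    ax.set_xlabel("dimensionless travel time T")
    ax.set_ylabel("pdf")
    ax.set_title("Corpuscle travel-time distribution")
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return True


def _eta_omega_curve(out: Path) -> bool:
    from chorioflow.transport import apex_angle_regular, shape_extraction_scan

    omegas = np.linspace(0.15 * math.pi, 0.85 * math.pi, 13)
    curve = shape_extraction_scan(omegas, tau=50.0, n_particles=150, seed=0)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(curve.omegas / math.pi, curve.eta, "o-", color="tab:green")
    for n, name in ((3, "triangle"), (4, "square"), (6, "hexagon")):
        om = apex_angle_regular(n)
        ax.axvline(om / math.pi, color="0.7", lw=0.8)
        ax.text(om / math.pi, ax.get_ylim()[1], name, rotation=90,
                va="top", ha="right", fontsize=8)
    ax.set_xlabel(r"$\omega/\pi$")
    ax.set_ylabel(r"mass extraction $\eta$")
    ax.set_title("Extraction vs segment shape")
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return True


def _dye_frames(art_dir: Path, out: Path) -> bool:
    frames = art_dir / "dye_frames.npy"
    meta = art_dir / "dye_meta.json"
    if not (frames.exists() and meta.exists()):
        return False
    F = np.load(frames)
    m = json.loads(meta.read_text())
    picks = np.linspace(0, len(F) - 1, 4).astype(int)
    fig, axes = plt.subplots(1, 4, figsize=(14, 3.5))
    for ax, i in zip(axes, picks):
        ax.imshow(F[i], origin="lower", cmap="inferno", vmin=0,
                  extent=m["extent"] * 2)
        ax.set_title(f"t = {m['times'][i]:.2f}")
    fig.suptitle("Dye filling / flushing")
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return True


def make_report(artifact_dir, out_dir=None) -> dict:
    """Render the figure panels available from the artifacts.

    Missing stage artifacts are listed as skipped, not fatal.  Returns a
    mapping panel name -> output path or ``None`` if skipped.
    """
    art = Path(artifact_dir)
    out = Path(out_dir) if out_dir else art
    out.mkdir(parents=True, exist_ok=True)
    results: dict[str, str | None] = {}
    panels = {
        "segment_map": lambda: _streamline_map(art, out / "segment_map.png"),
        "travel_time_pdf": lambda: _travel_time_pdf(art, out / "travel_time_pdf.png"),
        "eta_vs_omega": lambda: _eta_omega_curve(out / "eta_vs_omega.png"),
        "dye_frames": lambda: _dye_frames(art, out / "dye_frames.png"),
    }
    for name, fn in panels.items():
        ok = fn()
        results[name] = str(out / f"{name}.png") if ok else None
    return results
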