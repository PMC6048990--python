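"""Static graphical and HTML reporting for a processed plate."""

from __future__ import annotations

import base64
import html
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .kinetics import gompertz

__all__ = ["plot_well_curve", "render_html_report"]


def plot_well_curve(well, out_path) -> None:
    """Measured inside-counts and the fitted Gompertz curve for one well."""
    s, f = well.series, well.fit
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(s.times, s.inside, "o", ms=4, color="#1f77b4", label="measured")
    if f is not None and f.params is not None:
        tt = np.linspace(s.times[0], s.times[-1], 200)
        ax.plot(tt, gompertz(tt, f.params), "-", color="#d62728", label="Gompertz fit")
        txt = (
            f"A={f.params.A:.1f}  $\\mu_m$={f.params.mu_m:.2f}/min  "
            f"$\\lambda$={f.params.lam:.1f} min\n"
            f"$R^2$={f.r_squared:.4f}  RMSE={f.rmse:.2f}"
        )
        ax.set_title(
            f"{well.well_id}" + ("  [FLAGGED]" if f.flagged else ""),
            color="#b00" if f.flagged else "black",
        )
        ax.text(
            0.98, 0.05, txt, transform=ax.transAxes, ha="right", va="bottom",
            fontsize=8, bbox=dict(boxstyle="round", fc="white", alpha=0.7),
        )
    ax.set_xlabel("time (min)")
    ax.set_ylabel("cells inside scratch")
    ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=110)
    plt.close(fig)


_PAGE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>Scratch-assay report</title>
<style>
body {{ font-family: sans-serif; margin: 2em; }}
table {{ border-collapse: collapse; }}
th, td {{ border: 1px solid #999; padding: 4px 10px; text-align: right; }}
th {{ background: #eee; }}
tr.flagged td {{ background: #ffe0e0; }}
.warn {{ color: #a00; }}
img {{ max-width: 480px; margin: 6px; }}
</style></head><body>
<h1>Scratch-assay re-epithelialization report</h1>
<p>toolkit version {version}, run {timestamp}</p>
{warnings}
<h2>Kinetic parameters</h2>
{table}
<h2>Per-well curves</h2>
{plots}
{excluded}
</body></html>
"""


def render_html_report(plate, manifest) -> str:
    """One static HTML page: parameter table, embedded curve PNGs, warnings."""
    rows = []
    for w in plate.wells:
        if w.error is not None:
            rows.append(
                f'<tr class="flagged"><td>{html.escape(w.well_id)}</td>'
                f'<td colspan="7">error: {html.escape(w.error)}</td></tr>'
            )
            continue
        if w.fit is None or w.fit.params is None:
            continue
        f = w.fit
        cls = ' class="flagged"' if f.flagged else ""
        rows.append(
            f"<tr{cls}><td>{html.escape(w.well_id)}</td>"
            f"<td>{f.params.A:.1f}</td><td>{f.params.mu_m:.3f}</td>"
            f"<td>{f.params.lam:.1f}</td><td>{f.r_squared:.4f}</td>"
            f"<td>{f.rmse:.2f}</td><td>{f.converged}</td><td>{f.flagged}</td></tr>"
        )
    table = (
        "<table><tr><th>well</th><th>A (cells)</th><th>&mu;<sub>m</sub> "
        "(cells/min)</th><th>&lambda; (min)</th><th>R&sup2;</th><th>RMSE</th>"
        "<th>converged</th><th>flagged</th></tr>" + "".join(rows) + "</table>"
    )

    imgs = []
    for p in manifest.get("plots", []):
        data = base64.b64encode(Path(p).read_bytes()).decode("ascii")
        imgs.append(f'<img src="data:image/png;base64,{data}" alt="{Path(p).stem}">')

    warn_html = ""
    if plate.warnings:
        items = "".join(f"<li>{html.escape(w)}</li>" for w in plate.warnings)
        warn_html = f'<h2 class="warn">Warnings</h2><ul class="warn">{items}</ul>'

    excl_html = ""
    if plate.excluded:
        excl_html = (
            "<h2>Excluded wells</h2><p>"
            + ", ".join(html.escape(w) for w in plate.excluded)
            + "</p>"
        )

    return _PAGE.format(
        version=html.escape(str(plate.metadata.get("version", ""))),
        timestamp=html.escape(str(plate.metadata.get("timestamp", ""))),
        warnings=warn_html,
        table=table,
        plots="".join(imgs),
        excluded=excl_html,
    )
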