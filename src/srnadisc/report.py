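"""Standardized self-contained HTML report.

Four fixed sections — introduction, data exploration, differential
expression, appendix — with every embedded table also persisted as a
standalone CSV by the pipeline, figures inlined as base64 PNGs, and
client-side sortable tables (a few lines of vanilla JS, no server).
"""

from __future__ import annotations

import base64
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from jinja2 import Template

from . import __version__
from .seqio import READ_CLASSES

SECTION_ORDER = (
    "Introduction",
    "Data exploration",
    "Differential expression",
    "Appendix",
)


@dataclass
class ReportBundle:
    title: str
    intro_html: str
    exploration_html: str
    de_html: str
    appendix_html: str


def _fig_to_data_uri(fig) -> str:
    buf = io.BytesIO()
    fig.savefig(buf, format="png", dpi=110, bbox_inches="tight")
    plt.close(fig)
    return "data:image/png;base64," + base64.b64encode(buf.getvalue()).decode()


def _table(df: pd.DataFrame, max_rows: int = 60) -> str:
    shown = df.head(max_rows)
    note = (
        f"<p class='note'>showing first {max_rows} of {len(df)} rows; "
        f"the full table is persisted as CSV.</p>"
        if len(df) > max_rows else ""
    )
    return shown.to_html(classes="sortable", border=0, float_format="%.4g") + note


def _class_figure(absolute: pd.DataFrame, percent: pd.DataFrame) -> str:
    fig, axes = plt.subplots(1, 2, figsize=(11, 4))
    for ax, tab, title in ((axes[0], absolute, "absolute reads"),
                           (axes[1], percent, "percent of total")):
        bottom = np.zeros(len(tab))
        for cls in READ_CLASSES:
            vals = tab[cls].to_numpy(dtype=float)
            ax.bar(tab.index, vals, bottom=bottom, label=cls)
            bottom += vals
        ax.set_title(f"Read classification ({title})")
        ax.tick_params(axis="x", rotation=60)
    axes[1].legend(fontsize=7, bbox_to_anchor=(1.02, 1), loc="upper left")
    fig.tight_layout()
    return _fig_to_data_uri(fig)


def _distinct_figure(distinct: pd.DataFrame) -> str:
    fig, ax = plt.subplots(figsize=(7, 3.5))
    x = np.arange(len(distinct))
    ax.bar(x - 0.2, distinct["above_0"], width=0.4, color="firebrick",
           label="count > 0")
    ax.bar(x + 0.2, distinct["above_10"], width=0.4, color="seagreen",
           label="count > 10")
    ax.set_xticks(x, distinct.index, rotation=60)
    ax.set_ylabel("distinct miRNAs")
    ax.legend()
    fig.tight_layout()
    return _fig_to_data_uri(fig)


def _heatmap_figure(clustered, title: str) -> str:
    mat = clustered.scaled.loc[clustered.feature_order, clustered.sample_order]
    fig, ax = plt.subplots(
        figsize=(max(4, 0.5 * mat.shape[1] + 2), max(4, 0.14 * mat.shape[0]))
    )
    im = ax.imshow(mat.to_numpy(), aspect="auto", cmap="RdBu_r")
    ax.set_xticks(range(mat.shape[1]), mat.columns, rotation=60, fontsize=7)
    ax.set_yticks(range(mat.shape[0]), mat.index, fontsize=5)
    ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.6, label="unit-variance RPM")
    fig.tight_layout()
    return _fig_to_data_uri(fig)


def _ordination_figure(ord_res, groups: pd.DataFrame) -> Optional[str]:
    if ord_res.pca_scores is None:
        return None
    panels = [("PCA", ord_res.pca_scores, "PC1", "PC2")]
    if ord_res.tsne is not None:
        panels.append(("t-SNE", ord_res.tsne, "tSNE1", "tSNE2"))
    fig, axes = plt.subplots(1, len(panels), figsize=(5.5 * len(panels), 4))
    axes = np.atleast_1d(axes)
    gvars = list(groups.columns)[:2]  # at most two grouping variables shown
    color_var = gvars[0] if gvars else None
    marker_var = gvars[1] if len(gvars) > 1 else None
    markers = "osv^DPX*"
    for ax, (name, coords, cx, cy) in zip(axes, panels):
        if color_var:
            levels = sorted(groups[color_var].astype(str).unique())
            cmap = {lv: f"C{i}" for i, lv in enumerate(levels)}
        for i, s in enumerate(coords.index):
            color = cmap[str(groups.loc[s, color_var])] if color_var else "C0"
            if marker_var:
                mlvls = sorted(groups[marker_var].astype(str).unique())
                marker = markers[mlvls.index(str(groups.loc[s, marker_var])) % len(markers)]
            else:
                marker = "o"
            ax.scatter(coords.loc[s, cx], coords.loc[s, cy], c=color,
                       marker=marker)
            ax.annotate(s, (coords.loc[s, cx], coords.loc[s, cy]), fontsize=6)
        if name == "PCA" and ord_res.explained_variance_ratio is not None:
            evr = ord_res.explained_variance_ratio
            ax.set_xlabel(f"{cx} ({evr[0]:.1%})")
            if len(evr) > 1:
                ax.set_ylabel(f"{cy} ({evr[1]:.1%})")
        else:
            ax.set_xlabel(cx)
            ax.set_ylabel(cy)
        ax.set_title(name)
    fig.tight_layout()
    return _fig_to_data_uri(fig)


def _scan_figure(scan, name: str) -> str:
    fig, ax = plt.subplots(figsize=(5.5, 3.2))
    ax.plot(scan.grid, scan.counts, "o-", color="crimson", markersize=3)
    ax.axvline(scan.theta_star, color="grey", linestyle="--",
               label=f"chosen quantile {scan.theta_star:.2f}")
    ax.set_xlabel("abundance quantile removed")
    ax.set_ylabel(f"significant at FDR {scan.alpha:g}")
    ax.set_title(f"Independent filtering scan: {name}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    return _fig_to_data_uri(fig)


_TEMPLATE = Template("""<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>{{ title }}</title>
<style>
body { font-family: sans-serif; margin: 2em auto; max-width: 1100px; color: #222; }
h1 { border-bottom: 2px solid #444; }
h2 { border-bottom: 1px solid #bbb; margin-top: 2em; }
table.sortable { border-collapse: collapse; font-size: 0.85em; }
table.sortable th { cursor: pointer; background: #eee; padding: 4px 8px; }
table.sortable td { padding: 3px 8px; border-top: 1px solid #ddd; }
.note { color: #666; font-size: 0.8em; }
img { max-width: 100%; }
</style></head><body>
<h1>{{ title }}</h1>
<h2>1. Introduction</h2>{{ intro }}
<h2>2. Data exploration</h2>{{ exploration }}
<h2>3. Differential expression</h2>{{ de }}
<h2>4. Appendix</h2>{{ appendix }}
<script>
document.querySelectorAll("table.sortable th").forEach(function (th) {
  th.addEventListener("click", function () {
    var table = th.closest("table"), tbody = table.querySelector("tbody");
    var idx = Array.prototype.indexOf.call(th.parentNode.children, th);
    var rows = Array.from(tbody.querySelectorAll("tr"));
    var dir = th.dataset.dir === "asc" ? -1 : 1;
    th.dataset.dir = dir === 1 ? "asc" : "desc";
    rows.sort(function (a, b) {
      var x = a.children[idx].innerText, y = b.children[idx].innerText;
      var nx = parseFloat(x), ny = parseFloat(y);
      if (!isNaN(nx) && !isNaN(ny)) return (nx - ny) * dir;
      return x.localeCompare(y) * dir;
    });
    rows.forEach(function (r) { tbody.appendChild(r); });
  });
});
</script>
</body></html>
""")


def build_bundle(result, alpha: float, seed: int, config: dict) -> ReportBundle:
    """Assemble the four report sections from a pipeline result."""
    sheet = result.sheet
    intro = []
    intro.append(f"<p><b>{sheet.project.title or 'Untitled project'}</b></p>")
    if sheet.project.comments:
        intro.append(f"<p>{sheet.project.comments}</p>")
    intro.append(
        "<p>This report summarizes a small RNA-seq discovery analysis: "
        "adapter/quality trimming, hierarchical read classification, "
        "miRNA quantification, unsupervised exploration, and "
        "negative-binomial differential expression with FDR-maximizing "
        "independent filtering.</p>"
    )
    intro.append("<h3>Samples</h3>")
    intro.append(_table(sheet.samples))
    intro.append("<h3>Trimming</h3>")
    intro.append(_table(result.trim_stats))

    expl = []
    expl.append("<h3>Read classification</h3>")
    expl.append(f"<img src='{_class_figure(result.class_absolute, result.class_percent)}'>")
    expl.append(_table(result.class_absolute))
    expl.append(_table(result.class_percent.round(4)))
    expl.append("<h3>miRNA mappings</h3>")
    expl.append(_table(result.matrix.raw))
    expl.append(_table(result.matrix.rpm.round(2)))
    expl.append("<h3>Distinct miRNAs per sample</h3>")
    expl.append(f"<img src='{_distinct_figure(result.exploration.distinct)}'>")
    expl.append(_table(result.exploration.distinct))
    expl.append("<h3>Heatmaps</h3>")
    expl.append(
        f"<img src='{_heatmap_figure(result.exploration.heatmap_top, 'Top miRNAs by coefficient of variation')}'>"
    )
    if result.exploration.heatmap_all_detected is not None:
        expl.append(
            f"<img src='{_heatmap_figure(result.exploration.heatmap_all_detected, 'miRNAs detected in all samples')}'>"
        )
    ord_uri = _ordination_figure(
        result.exploration.ordination, result.matrix.groups
    )
    if ord_uri:
        expl.append("<h3>PCA and t-SNE</h3>")
        expl.append(f"<img src='{ord_uri}'>")

    de_parts = []
    if not result.de_results:
        de_parts.append("<p>No contrasts selected.</p>")
    for name, res in result.de_results.items():
        de_parts.append(f"<h3>{name}</h3>")
        if res.scan.fallback_used:
            de_parts.append(
                "<p class='note'>The quantile scan found no cutoff "
                "increasing the number of significant miRNAs; the RPM "
                "fallback pre-filter was applied instead.</p>"
            )
        de_parts.append(f"<img src='{_scan_figure(res.scan, name)}'>")
        tab = res.table.sort_values("PValue", na_position="last")
        nsig = int((res.table["FDR"] <= alpha).sum())
        de_parts.append(
            f"<p>{nsig} miRNAs significant at FDR &le; {alpha:g}; "
            f"{int(res.table['filtered'].sum())} of {len(res.table)} "
            f"filtered before adjustment.</p>"
        )
        de_parts.append(_table(tab))

    appendix = [
        "<h3>Run information</h3>",
        "<ul>",
        f"<li>srnadisc version: {__version__}</li>",
        f"<li>significance level alpha: {alpha:g}</li>",
        f"<li>random seed: {seed}</li>",
        f"<li>adapter: {sheet.project.adapter}</li>",
        f"<li>quality cutoff: {sheet.project.quality_cutoff}; "
        f"minimum length: {sheet.project.min_length}</li>",
        f"<li>configuration: {config}</li>",
        "</ul>",
        "<h3>Methods outline</h3>",
        "<p>Reads are adapter- and quality-trimmed, then classified by a "
        "hierarchical cascade: genome (2 mismatches), miRNA quantification "
        "in precursor context (isomiR-tolerant), ncRNA and cDNA (1 "
        "mismatch, first best hit); remaining reads are 'unknown genomic' "
        "or 'unmapped'. miRNA counts are RPM-normalized to each sample's "
        "total miRNA-assigned reads. Differential expression uses a "
        "TMM-normalized negative-binomial quasi-likelihood log-linear "
        "model; features are filtered before FDR adjustment by an "
        "abundance-quantile scan maximizing the number of significant "
        "miRNAs, with an RPM-rule fallback when the scan is "
        "uninformative.</p>",
        "<p class='note'>ncRNA class assignment reports the first best "
        "hit only; reads mapping to several ncRNA references are counted "
        "once, which can blur classes for highly similar references.</p>",
    ]

    return ReportBundle(
        title=sheet.project.title or "Small RNA-seq discovery report",
        intro_html="\n".join(intro),
        exploration_html="\n".join(expl),
        de_html="\n".join(de_parts),
        appendix_html="\n".join(appendix),
    )


def render_report(bundle: ReportBundle, out_path: str | Path) -> Path:
    out_path = Path(out_path)
    html = _TEMPLATE.render(
        title=bundle.title,
        intro=bundle.intro_html,
        exploration=bundle.exploration_html,
        de=bundle.de_html,
        appendix=bundle.appendix_html,
    )
    out_path.write_text(html)
    return out_path
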