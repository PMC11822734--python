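"""Cohort performance reports: delay histograms, hexbin densities,
SPREC distributions, prediction tables, and self-contained HTML output.

The report gives a biobank analyst the preanalytical fingerprint of a
sample collection — how long samples waited before centrifugation and
before freezing, how they fall into SPREC delay categories, and which
metabolic parameters are predicted to have drifted beyond a tolerable
error in which samples. Figures are embedded as SVG and tables as
sortable HTML, so a single file documents the cohort.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from string import Template

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
# fixed hashsalt so SVG element ids (and hence report bytes) are reproducible
matplotlib.rcParams["svg.hashsalt"] = "metabodrift"
import matplotlib.pyplot as plt

from .drift import ModelStore
from .preanalytics import Phase, SampleRecord, spre_distribution
from .predict import DEFAULT_TOLERABLE_ERROR_PCT, flag_tolerable, predict_pct_change

__all__ = [
    "CohortSummary",
    "summarize_cohort",
    "render_report",
    "single_sample_report",
]


@dataclass
class CohortSummary:
    """Binned overview of a cohort's processing delays.

    ``hist_edges``/``hist_counts`` map phase → histogram bin edges
    (hours) and counts; ``hexbin`` holds 2D density cell centers
    (pre-delay, post-delay) and counts; ``spre`` is the tidy SPREC
    letter distribution. All counts conserve the number of retained
    samples.
    """

    n_total: int
    n_retained: int
    n_excluded: int
    hist_edges: dict[str, np.ndarray]
    hist_counts: dict[str, np.ndarray]
    hexbin_centers: np.ndarray  # (n_cells, 2)
    hexbin_counts: np.ndarray  # (n_cells,)
    spre: pd.DataFrame


def _hexbin_counts(
    x: np.ndarray, y: np.ndarray, gridsize: int
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic hexagonal binning via matplotlib's hexbin."""
    fig, ax = plt.subplots()
    try:
        # pad the extent so boundary points are always inside a cell
        pad_x = max(1e-6, 1e-6 * max(abs(x.max()), 1.0))
        pad_y = max(1e-6, 1e-6 * max(abs(y.max()), 1.0))
        coll = ax.hexbin(
            x,
            y,
            gridsize=gridsize,
            extent=(x.min() - pad_x, x.max() + pad_x, y.min() - pad_y, y.max() + pad_y),
            mincnt=1,
        )
        centers = np.asarray(coll.get_offsets(), dtype=float)
        counts = np.asarray(coll.get_array(), dtype=float)
    finally:
        plt.close(fig)
    return centers, counts


def summarize_cohort(
    records: list[SampleRecord],
    hex_gridsize: int = 30,
    hist_binwidth_h: float = 0.25,
    n_excluded: int = 0,
) -> CohortSummary:
    """Bin a cohort's delays into histograms, hexbin cells and SPREC counts.

    ``records`` must carry delays and SPREC letters (the output of
    cohort preparation). ``n_excluded`` is carried through for the
    retained/excluded bookkeeping of the report header.
    """
    n = len(records)
    hist_edges: dict[str, np.ndarray] = {}
    hist_counts: dict[str, np.ndarray] = {}
    if n == 0:
        return CohortSummary(
            n_total=n_excluded,
            n_retained=0,
            n_excluded=n_excluded,
            hist_edges=hist_edges,
            hist_counts=hist_counts,
            hexbin_centers=np.empty((0, 2)),
            hexbin_counts=np.empty(0),
            spre=spre_distribution(records),
        )
    pre = np.array([r.pre_delay_h for r in records], dtype=float)
    post = np.array([r.post_delay_h for r in records], dtype=float)
    for phase, delays in ((Phase.pre.value, pre), (Phase.post.value, post)):
        upper = max(hist_binwidth_h, float(np.ceil(delays.max() / hist_binwidth_h)) * hist_binwidth_h)
        edges = np.arange(0.0, upper + hist_binwidth_h / 2, hist_binwidth_h)
        counts, edges = np.histogram(delays, bins=edges)
        hist_edges[phase] = edges
        hist_counts[phase] = counts
    centers, counts = _hexbin_counts(pre, post, hex_gridsize)
    return CohortSummary(
        n_total=n + n_excluded,
        n_retained=n,
        n_excluded=n_excluded,
        hist_edges=hist_edges,
        hist_counts=hist_counts,
        hexbin_centers=centers,
        hexbin_counts=counts,
        spre=spre_distribution(records),
    )


def single_sample_report(
    t_pre: float,
    t_post: float,
    store: ModelStore,
    tolerable_error: float = DEFAULT_TOLERABLE_ERROR_PCT,
    material: str | None = None,
) -> pd.DataFrame:
    """Predicted per-parameter changes for one hypothetical sample.

    Explores "what if a sample waited t_pre hours before and t_post
    hours after centrifugation": one row per parameter (restricted to
    ``material`` when given), sorted by |total change| descending with
    ties broken by parameter name.
    """
    if t_pre < 0 or t_post < 0:
        raise ValueError("delays must be non-negative")
    use = store if material is None else store.subset(material=material)
    if len(use) == 0:
        warnings.warn("empty model store; empty report", stacklevel=2)
        return pd.DataFrame(
            columns=["parameter", "material", "pct_pre", "pct_post", "pct_total", "exceeds_tolerable"]
        )
    rows = []
    seen = sorted({(m.parameter, m.material) for m in use})
    for parameter, mat in seen:
        m_pre = use.get(parameter, mat, "pre")
        m_post = use.get(parameter, mat, "post")
        pct_pre, pct_post, pct_total = predict_pct_change(m_pre, m_post, t_pre, t_post)
        rows.append(
            {
                "parameter": parameter,
                "material": mat,
                "pct_pre": pct_pre,
                "pct_post": pct_post,
                "pct_total": pct_total,
                "exceeds_tolerable": flag_tolerable(pct_total, tolerable_error),
            }
        )
    df = pd.DataFrame(rows)
    df["_abs"] = df["pct_total"].abs()
    df = (
        df.sort_values(["_abs", "parameter"], ascending=[False, True])
        .drop(columns="_abs")
        .reset_index(drop=True)
    )
    return df


def _fig_to_svg(fig) -> str:
    buf = io.StringIO()
    # strip volatile metadata so identical inputs give identical bytes
    fig.savefig(buf, format="svg", metadata={"Date": None})
    plt.close(fig)
    return buf.getvalue()


def _histogram_svg(summary: CohortSummary) -> str:
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.2))
    for ax, phase, color in zip(axes, ("pre", "post"), ("#4477aa", "#ee6677")):
        if phase in summary.hist_counts:
            edges = summary.hist_edges[phase]
            ax.bar(
                edges[:-1],
                summary.hist_counts[phase],
                width=np.diff(edges),
                align="edge",
                color=color,
            )
        ax.set_xlabel(f"{phase}centrifugation delay (h)")
        ax.set_ylabel("samples")
    fig.tight_layout()
    return _fig_to_svg(fig)


def _hexbin_svg(summary: CohortSummary) -> str:
    fig, ax = plt.subplots(figsize=(4.6, 3.8))
    if len(summary.hexbin_counts):
        sc = ax.scatter(
            summary.hexbin_centers[:, 0],
            summary.hexbin_centers[:, 1],
            c=summary.hexbin_counts,
            cmap="viridis",
            marker="h",
            s=60,
        )
        fig.colorbar(sc, ax=ax, label="samples")
    ax.set_xlabel("precentrifugation delay (h)")
    ax.set_ylabel("postcentrifugation delay (h)")
    fig.tight_layout()
    return _fig_to_svg(fig)


def _spre_svg(summary: CohortSummary) -> str:
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.0))
    for ax, phase in zip(axes, ("pre", "post")):
        sub = summary.spre[summary.spre["phase"] == phase]
        ax.bar(sub["letter"], sub["fraction"] * 100, color="#228833")
        ax.set_title(f"SPREC {phase}centrifugation")
        ax.set_ylabel("% of samples")
    fig.tight_layout()
    return _fig_to_svg(fig)


_TABLE_SORT_JS = """
function sortTable(th) {
  const table = th.closest('table');
  const idx = Array.from(th.parentNode.children).indexOf(th);
  const asc = th.dataset.asc !== 'true';
  th.dataset.asc = asc;
  const rows = Array.from(table.tBodies[0].rows);
  rows.sort((a, b) => {
    const x = a.cells[idx].innerText, y = b.cells[idx].innerText;
    const nx = parseFloat(x), ny = parseFloat(y);
    const cmp = (!isNaN(nx) && !isNaN(ny)) ? nx - ny : x.localeCompare(y);
    return asc ? cmp : -cmp;
  });
  rows.forEach(r => table.tBodies[0].appendChild(r));
}
"""

_REPORT_TEMPLATE = Template(
    """<!DOCTYPE html>
<html>
<head>
<meta charset="utf-8">
<title>Preanalytical cohort report</title>
<style>
body { font-family: system-ui, sans-serif; margin: 2em; color: #222; }
h1 { font-size: 1.5em; } h2 { font-size: 1.2em; margin-top: 1.6em; }
table { border-collapse: collapse; margin: 0.8em 0; }
th, td { border: 1px solid #bbb; padding: 0.3em 0.7em; font-size: 0.9em; }
th { background: #eef; cursor: pointer; }
tr.exceeds td { background: #fdd; }
.meta { color: #666; font-size: 0.85em; }
</style>
<script>$sort_js</script>
</head>
<body>
<h1>Preanalytical cohort report</h1>
<p class="meta">$timestamp_line</p>
<h2>Cohort</h2>
<p>$n_total samples submitted; $n_retained retained, $n_excluded excluded.</p>
<h2>Delay histograms</h2>
$hist_svg
<h2>Delay density</h2>
$hex_svg
<h2>SPREC distribution</h2>
$spre_svg
$spre_table
<h2>Predicted concentration changes</h2>
<p class="meta">Rows exceeding the tolerable error are highlighted.
Click a header to sort.</p>
$prediction_table
</body>
</html>
"""
)


def _df_to_html(df: pd.DataFrame, highlight_exceeds: bool = False) -> str:
    if df.empty:
        return "<p><em>No entries.</em></p>"
    cols = list(df.columns)
    head = "".join(f'<th onclick="sortTable(this)">{c}</th>' for c in cols)
    body_rows = []
    for _, row in df.iterrows():
        cls = ' class="exceeds"' if highlight_exceeds and row.get("exceeds_tolerable") else ""
        cells = "".join(
            f"<td>{'' if pd.isna(v) else (f'{v:.3f}' if isinstance(v, float) else v)}</td>"
            for v in row
        )
        body_rows.append(f"<tr{cls}>{cells}</tr>")
    return (
        f"<table><thead><tr>{head}</tr></thead><tbody>{''.join(body_rows)}</tbody></table>"
    )


def render_report(
    summary: CohortSummary,
    predictions: pd.DataFrame | None = None,
    out: str | Path | None = None,
    timestamp: bool = True,
) -> str:
    """Render a self-contained HTML report (figures embedded as SVG).

    With ``timestamp=False`` the generation-time line is suppressed and
    regeneration from identical inputs is byte-identical, which makes
    reports diffable and testable. Returns the HTML text; also writes
    it when ``out`` is given.
    """
    predictions = predictions if predictions is not None else pd.DataFrame()
    ts_line = (
        f"generated {datetime.now(timezone.utc).isoformat(timespec='seconds')}"
        if timestamp
        else "timestamp suppressed"
    )
    spre_tab = summary.spre.copy()
    if not spre_tab.empty:
        spre_tab["fraction"] = spre_tab["fraction"].astype(float)
    html = _REPORT_TEMPLATE.substitute(
        sort_js=_TABLE_SORT_JS,
        timestamp_line=ts_line,
        n_total=summary.n_total,
        n_retained=summary.n_retained,
        n_excluded=summary.n_excluded,
        hist_svg=_histogram_svg(summary) if summary.hist_counts else "<p><em>No delay data.</em></p>",
        hex_svg=_hexbin_svg(summary) if len(summary.hexbin_counts) else "<p><em>No delay data.</em></p>",
        spre_svg=_spre_svg(summary) if not summary.spre.empty else "<p><em>No SPREC data.</em></p>",
        spre_table=_df_to_html(summary.spre),
        prediction_table=_df_to_html(predictions, highlight_exceeds=True),
    )
    if out is not None:
        path = Path(out)
        try:
            path.write_text(html)
        except OSError as exc:
            raise OSError(f"could not write report to {path}: {exc}") from exc
    return html
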