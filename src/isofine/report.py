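"""Static HTML report of an isotope-ratio experiment.

Mirrors the three-step workflow (mzML -> per-scan records CSV -> HTML):
given record tables and an experiment design, the report shows per-sample
ratio density distributions, delta-value and between-replicate CV tables,
the ratio-vs-TIC diagnostic, the precision-vs-datapoints curve, species
contributions and, when the design encodes a titration, the deuterium
incorporation regression. Everything (including the configuration) is
embedded, so the file is self-contained and regeneration is deterministic
for fixed seeds.
"""

from __future__ import annotations

import base64
import html
import io
import json
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import __version__
from .isotope_chem import ImmoniumSpecies
from .ratio_stats import (
    ELEMENT_COLUMNS,
    StandardSet,
    cv_between_replicates,
    incorporation_regression,
    subsample_precision,
    summarize_elements,
    species_contributions,
    tic_trend,
)

__all__ = ["build_report"]

_PAGE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>isofine report</title>
<style>
body {{ font-family: sans-serif; margin: 2em; max-width: 70em; }}
table {{ border-collapse: collapse; margin: 1em 0; }}
td, th {{ border: 1px solid #999; padding: 0.3em 0.6em; text-align: right; }}
th {{ background: #eee; }}
h2 {{ border-bottom: 1px solid #ccc; padding-top: 1em; }}
.notice {{ color: #a40; }}
pre {{ background: #f6f6f6; padding: 1em; overflow-x: auto; }}
img {{ max-width: 100%; }}
</style></head>
<body>
<h1>Immonium-ion isotope-ratio report</h1>
<p>isofine version {version}</p>
{body}
<h2>Configuration</h2>
<pre>{config}</pre>
</body></html>
"""


def _fig_to_img(fig) -> str:
    buf = io.BytesIO()
    fig.savefig(buf, format="png", dpi=110)
    plt.close(fig)
    data = base64.b64encode(buf.getvalue()).decode("ascii")
    return f'<img src="data:image/png;base64,{data}"/>'


def _table(frame: pd.DataFrame, float_fmt: str = "{:.6g}") -> str:
    if frame.empty:
        return '<p class="notice">no rows</p>'
    show = frame.copy()
    for col in show.columns:
        if pd.api.types.is_float_dtype(show[col]):
            show[col] = show[col].map(
                lambda v: float_fmt.format(v) if np.isfinite(v) else ""
            )
    return show.to_html(index=False, escape=True)


def _density_section(frame: pd.DataFrame, elements: Sequence[str]) -> str:
    parts = []
    for element in elements:
        col = ELEMENT_COLUMNS[element]
        if col not in frame.columns or frame[col].dropna().empty:
            continue
        fig, axes = plt.subplots(
            1, frame["sample"].nunique(), figsize=(4 * frame["sample"].nunique(), 3),
            squeeze=False,
        )
        for ax, (sample, sub) in zip(
            axes[0], sorted(frame.groupby("sample"), key=lambda kv: str(kv[0]))
        ):
            for species, ssub in sub.groupby("species"):
                vals = ssub[col].dropna()
                if len(vals) < 5:
                    continue
                ax.hist(vals, bins=40, histtype="step", density=True, label=species)
            ax.set_title(f"{sample}")
            ax.set_xlabel(f"{element} ratio")
            ax.legend(fontsize=7)
        parts.append(f"<h3>{element} ratio distributions</h3>" + _fig_to_img(fig))
    return "\n".join(parts)


def build_report(
    records: pd.DataFrame,
    registry: Mapping[str, ImmoniumSpecies],
    config: Mapping | None = None,
    standards: StandardSet | None = None,
    elements: Sequence[str] = ("C", "N", "H"),
    reference_composition: Mapping[str, float] | None = None,
    subsample_seed: int = 0,
) -> str:
    """Build the HTML report from a tidy records frame.

    ``records`` must carry the design columns ``sample`` and ``replicate``
    (and optionally ``group``) in addition to the per-scan ratio columns.
    """
    standards = standards or StandardSet()
    body: list[str] = []

    body.append("<h2>Dataset</h2>")
    overview = (
        records.groupby(["sample", "replicate", "species"])
        .size()
        .rename("datapoints")
        .reset_index()
    )
    body.append(_table(overview))

    body.append("<h2>Ratio distributions</h2>")
    body.append(_density_section(records, elements))

    summary = summarize_elements(
        records,
        elements=elements,
        group_cols=("sample", "replicate", "species"),
        standards=standards,
    )
    body.append("<h2>Per-replicate summaries and &delta;-values (&permil;)</h2>")
    body.append(_table(summary))

    body.append("<h2>Between-replicate CVs</h2>")
    n_reps = records.groupby("sample")["replicate"].nunique()
    if (n_reps >= 2).all() and len(summary):
        try:
            cv = cv_between_replicates(summary)
            body.append(_table(cv, "{:.4g}"))
        except ValueError as exc:
            body.append(f'<p class="notice">{html.escape(str(exc))}</p>')
    else:
        singles = ", ".join(str(s) for s in n_reps.index[n_reps < 2])
        body.append(
            f'<p class="notice">n&lt;2 replicates for sample(s) {singles}; '
            "CVs not computed</p>"
        )

    body.append("<h2>Ratio vs TIC diagnostic</h2>")
    tic_rows = []
    for species in sorted(records["species"].unique()):
        for element in elements:
            try:
                slope, r, p = tic_trend(records, species, element)
                tic_rows.append(
                    {"species": species, "element": element,
                     "slope_per_decade": slope, "correlation": r, "p_slope": p}
                )
            except (ValueError, KeyError):
                continue
    if tic_rows:
        body.append(_table(pd.DataFrame(tic_rows), "{:.3g}"))
    else:
        body.append('<p class="notice">insufficient TIC spread for the diagnostic</p>')

    body.append("<h2>Precision vs number of datapoints</h2>")
    counts = records.groupby(["replicate", "species"]).size()
    max_k = int(counts.min()) if len(counts) else 0
    ks = [k for k in (10, 20, 50, 100, 200, 500, 1000) if k <= max_k]
    if len(ks) >= 2 and records["replicate"].nunique() >= 2:
        curve = subsample_precision(
            records, ks, n_draws=10, seed=subsample_seed, elements=elements
        )
        fig, ax = plt.subplots(figsize=(4.5, 3.2))
        ax.loglog(curve.ks, curve.mean_cv_pct, "o-", label="mean")
        ax.loglog(curve.ks, curve.median_cv_pct, "s--", label="median")
        ax.set_xlabel("datapoints per replicate")
        ax.set_ylabel("average CV (%)")
        ax.legend()
        body.append(_fig_to_img(fig))
        body.append(_table(curve.frame(), "{:.4g}"))
    else:
        body.append(
            '<p class="notice">not enough datapoints/replicates for the '
            "subsampling curve</p>"
        )

    body.append("<h2>Species contributions</h2>")
    try:
        contrib, r2 = species_contributions(records, reference_composition)
        contrib_df = contrib.rename("contribution_pct").reset_index()
        body.append(_table(contrib_df, "{:.3g}"))
        if r2 is not None:
            body.append(f"<p>R&sup2; against reference composition: {r2:.3g}</p>")
    except ValueError:
        body.append('<p class="notice">no records</p>')

    # Incorporation regression when the group column encodes media 2H ppm
    if "group" in records.columns:
        media = pd.to_numeric(records["group"], errors="coerce")
        if media.notna().all() and media.nunique() >= 3 and "r_h" in records.columns:
            body.append("<h2>Deuterium incorporation</h2>")
            rows = []
            per_rep = (
                records.assign(media_ppm=media)
                .groupby(["media_ppm", "replicate", "species"])["r_h"]
                .mean()
                .reset_index()
            )
            for species, sub in per_rep.groupby("species"):
                fit = incorporation_regression(
                    sub["media_ppm"], sub["r_h"] * 1e6
                )
                rows.append(
                    {
                        "species": species,
                        "incorporation_pct": fit.incorporation_pct,
                        "slope_stderr_pct": fit.slope_stderr * 100.0,
                        "r_squared": fit.r_squared,
                    }
                )
            body.append(_table(pd.DataFrame(rows), "{:.4g}"))

    return _PAGE.format(
        version=__version__,
        body="\n".join(body),
        config=html.escape(json.dumps(dict(config or {}), indent=2, default=str)),
    )
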