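"""Group-level comparisons and report generation.

Two-group mean comparison (Welch's t by default, pooled-variance Student's
t by flag), 3x2 chi-square homogeneity test for category histograms, and a
tabular report bundling the per-telomere and per-nucleus measurements.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .image_io import ValidationError

__all__ = [
    "GroupComparison",
    "compare_means",
    "compare_categories",
    "build_report",
]

CATEGORY_ORDER = ("low", "average", "high")


@dataclass
class GroupComparison:
    statistic_name: str               # "t" or "chi2"
    statistic: float
    p_value: float
    group_sizes: tuple[int, ...]
    effect_summary: dict


def compare_means(
    group_a: Sequence[float],
    group_b: Sequence[float],
    equal_var: bool = False,
) -> GroupComparison:
    """Two-sided two-sample t-test (Welch by default).

    Welch's form is the default because it stays valid under unequal group
    variances; ``equal_var=True`` gives the classical pooled-variance test.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs n >= 2")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    summary = {
        "mean_a": float(a.mean()),
        "sem_a": float(a.std(ddof=1) / np.sqrt(len(a))),
        "mean_b": float(b.mean()),
        "sem_b": float(b.std(ddof=1) / np.sqrt(len(b))),
    }
    return GroupComparison("t", float(t), float(p), (len(a), len(b)), summary)


def compare_categories(
    hist_a: Sequence[int], hist_b: Sequence[int]
) -> GroupComparison:
    """Chi-square test of homogeneity on a 3x2 category table."""
    a = np.asarray(hist_a, dtype=float)
    b = np.asarray(hist_b, dtype=float)
    if a.shape != (3,) or b.shape != (3,):
        raise ValidationError("each histogram must have exactly 3 categories")
    if a.sum() <= 0 or b.sum() <= 0:
        raise ValidationError("category totals must be > 0")
    table = np.stack([a, b], axis=1)  # 3 categories x 2 groups
    table = table[table.sum(axis=1) > 0]  # empty categories carry no signal
    total = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    if (expected < 1).any():
        raise ValidationError(
            "expected count < 1 in a cell; pool sparse categories before "
            "testing"
        )
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    summary = {
        "proportions_a": (a / a.sum()).tolist(),
        "proportions_b": (b / b.sum()).tolist(),
        "categories": list(CATEGORY_ORDER),
    }
    return GroupComparison("chi2", float(chi2), float(p),
                           (int(a.sum()), int(b.sum())), summary)


# ---------------------------------------------------------------------------
# report bundle
# ---------------------------------------------------------------------------

_TELOMERE_COLS = {"condition", "nucleus_id", "telomere_id",
                  "coverage_percent", "category", "distance_nm",
                  "within_threshold"}
_NUCLEUS_COLS = {"condition", "nucleus_id", "lap2c_percent", "sigma_percent",
                 "n_telomeres"}


def _require_columns(frame: pd.DataFrame, needed: set[str], name: str) -> None:
    missing = sorted(needed - set(frame.columns))
    if missing:
        raise ValidationError(f"{name} table missing columns: {missing}")


def build_report(
    telomere_table: pd.DataFrame,
    nucleus_table: pd.DataFrame,
    out_dir: str | Path,
    profile_table: pd.DataFrame | None = None,
    comparisons: Mapping[str, GroupComparison] | None = None,
    make_plots: bool = False,
) -> dict:
    """Write summary tables (and optional plots) for a multi-condition run.

    Produces ``coverage_summary.csv`` (per-condition LAP2alpha coverage and
    category proportions), ``lamina_summary.csv`` (fractions within/outside
    the proximity threshold), ``profile_summary.csv`` when profile curves
    are given, and ``report.json`` with the headline numbers.  An empty
    telomere table yields a report that explicitly records "no telomeres".
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"conditions": [], "comparisons": {}}

    if len(telomere_table) == 0:
        report["no_telomeres"] = True
        (out_dir / "report.json").write_text(json.dumps(report, indent=2))
        return report
    _require_columns(telomere_table, _TELOMERE_COLS, "telomere")
    _require_columns(nucleus_table, _NUCLEUS_COLS, "nucleus")

    cov_rows, lam_rows = [], []
    for cond, sub in telomere_table.groupby("condition", sort=True):
        report["conditions"].append(str(cond))
        nuc = nucleus_table[nucleus_table["condition"] == cond]
        counts = sub["category"].value_counts()
        n = len(sub)
        cov_rows.append({
            "condition": cond,
            "mean_lap2c_percent": float(nuc["lap2c_percent"].mean()),
            "mean_telomere_coverage_percent": float(
                sub["coverage_percent"].mean()),
            "n_telomeres": n,
            "n_nuclei": int(nuc["nucleus_id"].nunique()),
            **{f"prop_{c}": float(counts.get(c, 0)) / n
               for c in CATEGORY_ORDER},
        })
        frac_in = float(sub["within_threshold"].mean())
        lam_rows.append({
            "condition": cond,
            "fraction_within": frac_in,
            "fraction_outside": 1.0 - frac_in,
            "mean_distance_nm": float(sub["distance_nm"].mean()),
            "n_telomeres": n,
        })
    coverage_summary = pd.DataFrame(cov_rows)
    lamina_summary = pd.DataFrame(lam_rows)
    coverage_summary.to_csv(out_dir / "coverage_summary.csv", index=False)
    lamina_summary.to_csv(out_dir / "lamina_summary.csv", index=False)
    report["coverage_summary"] = coverage_summary.to_dict("records")
    report["lamina_summary"] = lamina_summary.to_dict("records")

    if profile_table is not None and len(profile_table):
        _require_columns(profile_table,
                         {"condition", "distance_nm", "mean", "sem"},
                         "profile")
        profile_table.to_csv(out_dir / "profile_summary.csv", index=False)
        peaks = {
            str(cond): float(sub.loc[sub["mean"].idxmax(), "distance_nm"])
            for cond, sub in profile_table.groupby("condition")
        }
        report["profile_peak_nm"] = peaks

    if comparisons:
        for name, comp in comparisons.items():
            report["comparisons"][name] = {
                "statistic_name": comp.statistic_name,
                "statistic": comp.statistic,
                "p_value": comp.p_value,
                "group_sizes": list(comp.group_sizes),
                "effect_summary": comp.effect_summary,
            }

    if make_plots:
        _make_plots(out_dir, coverage_summary, lamina_summary, profile_table)

    (out_dir / "report.json").write_text(json.dumps(report, indent=2))
    return report


def _make_plots(out_dir, coverage_summary, lamina_summary, profile_table):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3 if profile_table is not None else 2,
                             figsize=(12, 3.5))
    axes[0].bar(coverage_summary["condition"],
                coverage_summary["mean_lap2c_percent"])
    axes[0].set_ylabel("LAP2c (%)")
    axes[1].bar(lamina_summary["condition"], lamina_summary["fraction_within"])
    axes[1].set_ylabel("fraction within threshold")
    if profile_table is not None:
        for cond, sub in profile_table.groupby("condition"):
            axes[2].plot(sub["distance_nm"], sub["mean"], label=str(cond))
            axes[2].fill_between(sub["distance_nm"], sub["mean"] - sub["sem"],
                                 sub["mean"] + sub["sem"], alpha=0.3)
        axes[2].set_xlabel("distance from telomere center (nm)")
        axes[2].set_ylabel("normalized intensity")
        axes[2].legend()
    fig.tight_layout()
    fig.savefig(out_dir / "report.png", dpi=150)
    plt.close(fig)
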