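"""Paired nonparametric comparison of two experimental conditions.

Twelve per-cycle measures are compared between the active (A) and passive
(B) knee-flexion-initiation conditions with the Wilcoxon signed-rank test:
three event timings (t_SKF, t_SAPF, delta t_SAPF-LLTD) and the absolute,
horizontal, and vertical transition impulses of the trailing leg, remaining
body, and CoM.  Differences are reported as
(mean_B - mean_A) / mean_A * 100.  No multiple-testing correction is
applied; each measure is reported at the alpha = 0.001 significance
convention, which the report footer states.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .config import ConfigurationError

__all__ = [
    "PairedSample",
    "WilcoxonResult",
    "wilcoxon_signed_rank",
    "diff_percent",
    "MEASURES",
    "compare_experiments",
    "ComparisonReport",
    "render_report",
]

EXACT_N_MAX = 12
ALPHA = 0.001

MEASURES = (
    "t_SKF", "t_SAPF", "delta_SAPF_LLTD",
    "dp_TL_mag", "dp_TL_x", "dp_TL_y",
    "dp_RB_mag", "dp_RB_x", "dp_RB_y",
    "dp_CoM_mag", "dp_CoM_x", "dp_CoM_y",
)

UNITS = {m: "%GC" for m in MEASURES[:3]} | {m: "kg m/s" for m in MEASURES[3:]}


@dataclass(frozen=True)
class PairedSample:
    """Equal-length per-cycle value lists for one measure in two conditions."""

    name: str
    values_A: np.ndarray
    values_B: np.ndarray
    units: str = ""

    def __post_init__(self):
        object.__setattr__(self, "values_A", np.asarray(self.values_A, dtype=float))
        object.__setattr__(self, "values_B", np.asarray(self.values_B, dtype=float))
        if len(self.values_A) != len(self.values_B):
            raise ValueError(
                f"{self.name}: paired samples must have equal length "
                f"({len(self.values_A)} vs {len(self.values_B)})"
            )


@dataclass(frozen=True)
class WilcoxonResult:
    p_value: float
    statistic: float   # W+ (sum of ranks of positive differences)
    n_used: int
    method: str        # "exact" or "normal_approx"
    degenerate: bool = False


def wilcoxon_signed_rank(sample: PairedSample, zero_policy: str = "discard") -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired per-cycle values.

    Zero differences are handled per ``zero_policy``: ``discard`` (classic
    Wilcoxon) drops them; ``zsplit`` keeps them, splitting their ranks
    between the sign groups.  With n <= 12 after zero handling the p-value
    is computed by exact enumeration over all 2^n sign assignments of the
    observed absolute-difference ranks; otherwise by the normal
    approximation with continuity and tie corrections.
    """
    if zero_policy not in ("discard", "zsplit"):
        raise ConfigurationError(f"unknown zero_policy {zero_policy!r}")
    d = sample.values_B - sample.values_A
    if zero_policy == "discard":
        d = d[d != 0]
    if len(d) == 0 or np.all(d == 0):
        return WilcoxonResult(p_value=1.0, statistic=0.0, n_used=0,
                              method="degenerate", degenerate=True)
    n = len(d)
    if n < 5:
        raise ValueError(f"need at least 5 non-zero differences, got {n}")
    ranks = rankdata(np.abs(d))
    if zero_policy == "zsplit":
        w_plus = float(ranks[d > 0].sum() + 0.5 * ranks[d == 0].sum())
    else:
        w_plus = float(ranks[d > 0].sum())

    if n <= EXACT_N_MAX:
        # exact null distribution of W+ for these ranks (ties included)
        totals = np.fromiter(
            (sum(c) for c in itertools.product(*[(0.0, r) for r in ranks])),
            dtype=float, count=2**n,
        )
        p_lo = np.mean(totals <= w_plus + 1e-12)
        p_hi = np.mean(totals >= w_plus - 1e-12)
        p = min(1.0, 2.0 * min(p_lo, p_hi))
        return WilcoxonResult(p, w_plus, n, "exact")

    mean_w = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / 48.0
    var_w = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    diff = w_plus - mean_w
    # continuity correction toward the mean
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var_w)
    p = min(1.0, 2.0 * norm.sf(abs(z)))
    return WilcoxonResult(p, w_plus, n, "normal_approx")


def diff_percent(mean_A: float, mean_B: float) -> float:
    """(mean_B - mean_A) / mean_A * 100; undefined (NaN) when mean_A = 0."""
    if mean_A == 0:
        return float("nan")
    return (mean_B - mean_A) / mean_A * 100.0


@dataclass
class ComparisonReport:
    """Twelve-measure comparison table for two conditions."""

    table: pd.DataFrame
    alpha: float = ALPHA
    provenance: dict = field(default_factory=dict)

    def row(self, measure: str) -> pd.Series:
        return self.table.set_index("measure").loc[measure]


def _measure_frame(events: pd.DataFrame, impulses: pd.DataFrame) -> pd.DataFrame:
    """Assemble the per-cycle measure matrix from event and impulse tables."""
    df = pd.DataFrame({
        "t_SKF": events["t_SKF"].to_numpy(),
        "t_SAPF": events["t_SAPF"].to_numpy(),
        "delta_SAPF_LLTD": events["delta_SAPF_LLTD"].to_numpy(),
    })
    for part in ("TL", "RB", "CoM"):
        df[f"dp_{part}_mag"] = impulses[f"dp_{part}_mag"].to_numpy()
        df[f"dp_{part}_x"] = impulses[f"dp_{part}_x"].to_numpy()
        df[f"dp_{part}_y"] = impulses[f"dp_{part}_y"].to_numpy()
    return df


def compare_experiments(
    events_A: pd.DataFrame,
    events_B: pd.DataFrame,
    impulses_A: pd.DataFrame,
    impulses_B: pd.DataFrame,
    zero_policy: str = "discard",
    provenance: dict | None = None,
) -> ComparisonReport:
    """Run the paired comparison on the twelve standard measures.

    Cycles are paired by row order (cycle index); mismatched cycle counts
    raise.  Returns means, SDs, Diff%, and two-sided p-values per measure.
    """
    a = _measure_frame(events_A, impulses_A)
    b = _measure_frame(events_B, impulses_B)
    if len(a) != len(b):
        raise ValueError(f"mismatched cycle counts: {len(a)} vs {len(b)}")
    rows = []
    for measure in MEASURES:
        sample = PairedSample(measure, a[measure], b[measure], UNITS[measure])
        res = wilcoxon_signed_rank(sample, zero_policy)
        mean_a, mean_b = float(a[measure].mean()), float(b[measure].mean())
        rows.append({
            "measure": measure,
            "units": UNITS[measure],
            "mean_A": mean_a,
            "sd_A": float(a[measure].std(ddof=0)),
            "mean_B": mean_b,
            "sd_B": float(b[measure].std(ddof=0)),
            "diff_percent": diff_percent(mean_a, mean_b),
            "p_value": res.p_value,
            "significant": bool(res.p_value < ALPHA and not res.degenerate),
            "test_method": res.method,
            "n": res.n_used,
        })
    return ComparisonReport(table=pd.DataFrame(rows), provenance=provenance or {})


def render_report(report: ComparisonReport, fmt: str = "csv", path=None) -> str:
    """Serialize a comparison report as CSV or JSON with provenance.

    The CSV form carries provenance and the significance convention as
    ``#`` comment lines; JSON nests them.  Returns the serialized text and
    writes it to ``path`` when given.
    """
    if fmt == "csv":
        header = [
            f"# significance: two-sided Wilcoxon signed-rank, alpha={report.alpha}"
            " (no multiple-testing correction)",
        ]
        header += [f"# {k}: {json.dumps(v, default=str)}"
                   for k, v in report.provenance.items()]
        text = "\n".join(header) + "\n" + report.table.to_csv(index=False)
    elif fmt == "json":
        text = json.dumps({
            "significance": {"test": "wilcoxon_signed_rank", "alpha": report.alpha,
                             "correction": "none"},
            "provenance": report.provenance,
            "rows": report.table.to_dict(orient="records"),
        }, indent=2, default=str)
    else:
        raise ConfigurationError(f"unknown report format {fmt!r}")
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
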