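"""Ranking, per-tool contribution probabilities, and best-vs-full comparison.

Contribution probability follows the study's definition: among the
combinations achieving a given performance level (a metric bin, or the
top-k of a ranking), the proportion whose tool subset includes a given
tool.  A tool that appears in almost every high-sensitivity combination is
pulling its weight; one that is absent from them (as the distant-orthology
tools turn out to be) is dead weight or worse.

The best-vs-full comparison reproduces the headline analysis: find the
combination with the highest mean sensitivity among subsets of at most
``k_best_size`` tools (seven in the study) and test, via a Welch-type z on
the run-level sensitivities, whether it significantly beats the full
roster — the "more tools can be worse" paradox.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .feature_table import FeatureTable, ToolSubset
from .sweep import CombinationSummary, RunResult
from . import svm as _svm

_METRIC_ATTRS = {
    "sensitivity": "mean_sens",
    "specificity": "mean_spec",
    "fdr": "mean_fdr",
    "cfdr": "mean_cfdr",
}
_METRIC_ALIASES = {"sens": "sensitivity", "spec": "specificity"}


def _metric_attr(metric: str) -> str:
    metric = _METRIC_ALIASES.get(metric, metric)
    try:
        return _METRIC_ATTRS[metric]
    except KeyError:
        raise ValueError(f"unknown metric {metric!r}; one of {sorted(_METRIC_ATTRS)}") from None


def rank_combinations(
    summaries: list[CombinationSummary], metric: str = "sensitivity", descending: bool = True
) -> list[CombinationSummary]:
    """Sort combinations by mean metric; ties go to the smaller subset, then mask.

    The tie-break makes the ranking a total order, so re-ranking is always
    reproducible.
    """
    attr = _metric_attr(metric)
    sign = -1.0 if descending else 1.0
    return sorted(summaries, key=lambda s: (sign * getattr(s, attr), s.size, s.subset.mask))


def _n_tools(summaries: list[CombinationSummary], n_tools: int | None) -> int:
    if n_tools is not None:
        return n_tools
    return max(s.subset.mask for s in summaries).bit_length()


@dataclass(frozen=True)
class ContributionTable:
    """Per-tool contribution probabilities, in bar (top-k) or heat (binned) form.

    ``probabilities`` has one row per bin (a single row in top-k form) and
    one column per tool; entries are NaN for empty bins (undefined, not 0).
    """

    metric: str
    probabilities: np.ndarray       # (n_bins, n_tools)
    bin_counts: np.ndarray          # combinations per bin
    bin_edges: np.ndarray | None    # None for the top-k (bar) form
    k: int | None                   # None for the binned (heat) form

    def to_frame(self, tool_names: list[str] | None = None) -> pd.DataFrame:
        cols = tool_names if tool_names is not None else [
            f"tool_{i}" for i in range(self.probabilities.shape[1])
        ]
        if self.bin_edges is None:
            index = pd.Index([f"top_{self.k}"], name="selection")
        else:
            index = pd.IntervalIndex.from_breaks(self.bin_edges, closed="left", name=self.metric)
        return pd.DataFrame(self.probabilities, index=index, columns=cols)


def contribution_topk(
    summaries: list[CombinationSummary],
    metric: str = "sensitivity",
    k: int = 100,
    n_tools: int | None = None,
    descending: bool = True,
) -> ContributionTable:
    """Fraction of the top-k combinations (by mean metric) that include each tool."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(summaries):
        raise ValueError(f"k={k} exceeds the {len(summaries)} available combinations")
    nt = _n_tools(summaries, n_tools)
    top = rank_combinations(summaries, metric, descending)[:k]
    counts = np.zeros(nt)
    for s in top:
        for i in s.subset.indices:
            counts[i] += 1
    return ContributionTable(
        metric=_METRIC_ALIASES.get(metric, metric),
        probabilities=(counts / k)[None, :],
        bin_counts=np.array([k]),
        bin_edges=None,
        k=k,
    )


def contribution_binned(
    summaries: list[CombinationSummary],
    metric: str = "sensitivity",
    bin_edges=None,
    n_bins: int = 20,
    n_tools: int | None = None,
) -> ContributionTable:
    """Heat-map form: P(tool included | combination's mean metric falls in bin).

    Bins are half-open ``[e_i, e_{i+1})`` with the last bin closed.  With no
    edges given, 20 equal-width bins over the observed metric range are
    used.  Empty bins get NaN probabilities.
    """
    attr = _metric_attr(metric)
    values = np.array([getattr(s, attr) for s in summaries])
    if bin_edges is None:
        lo, hi = float(values.min()), float(values.max())
        if lo == hi:  # degenerate range: one thin bin around the single value
            lo, hi = lo - 0.5e-9, hi + 0.5e-9
        bin_edges = np.linspace(lo, hi, n_bins + 1)
    bin_edges = np.asarray(bin_edges, dtype=float)
    if bin_edges.ndim != 1 or len(bin_edges) < 2 or not np.all(np.diff(bin_edges) > 0):
        raise ValueError("bin edges must be a strictly increasing 1-D sequence")
    if values.min() < bin_edges[0] or values.max() > bin_edges[-1]:
        raise ValueError("bin edges must cover the observed metric range")
    nt = _n_tools(summaries, n_tools)
    nb = len(bin_edges) - 1
    which = np.clip(np.searchsorted(bin_edges, values, side="right") - 1, 0, nb - 1)
    counts = np.zeros(nb)
    incl = np.zeros((nb, nt))
    for s, b in zip(summaries, which):
        counts[b] += 1
        for i in s.subset.indices:
            incl[b, i] += 1
    with np.errstate(invalid="ignore"):
        probs = np.where(counts[:, None] > 0, incl / np.maximum(counts, 1)[:, None], np.nan)
    return ContributionTable(
        metric=_METRIC_ALIASES.get(metric, metric),
        probabilities=probs,
        bin_counts=counts,
        bin_edges=bin_edges,
        k=None,
    )


@dataclass(frozen=True)
class BestVsFullComparison:
    """Outcome of the best-subset-vs-full-roster sensitivity comparison.

    Means/SDs are percentages (e.g. 64.14 means 64.14% sensitivity).
    ``paradox`` is True when a strictly smaller subset beats the full set;
    if the full roster is itself the best, the z test degenerates and is
    reported as "no paradox" with ``z``/``p`` None.
    """

    best_mask: int
    best_size: int
    k_best_size: int
    best_mean_sens: float
    best_sd_sens: float
    full_mean_sens: float
    full_sd_sens: float
    difference: float
    n_runs_best: int
    n_runs_full: int
    z: float | None
    p: float | None
    paradox: bool

    def to_dict(self) -> dict:
        return {
            "best_mask": self.best_mask,
            "best_size": self.best_size,
            "k_best_size": self.k_best_size,
            "best_mean_sensitivity_pct": round(self.best_mean_sens, 2),
            "best_sd_sensitivity_pct": round(self.best_sd_sens, 2),
            "full_mean_sensitivity_pct": round(self.full_mean_sens, 2),
            "full_sd_sensitivity_pct": round(self.full_sd_sens, 2),
            "difference_pct": round(self.difference, 2),
            "n_runs_best": self.n_runs_best,
            "n_runs_full": self.n_runs_full,
            "z": None if self.z is None else round(self.z, 3),
            "p": self.p,
            "paradox": self.paradox,
        }


def compare_best_vs_full(
    summaries: list[CombinationSummary],
    run_results: dict[int, list[RunResult]],
    k_best_size: int = 7,
    n_tools: int | None = None,
) -> BestVsFullComparison:
    """Compare the best ≤ ``k_best_size``-tool combination against the full set.

    ``run_results`` maps subset masks to their run-level results (as
    returned by ``run_sweep(..., keep_runs=True)``) and must contain the
    best and full subsets; the Welch z uses per-run sensitivities.
    """
    nt = _n_tools(summaries, n_tools)
    full_mask = (1 << nt) - 1
    by_mask = {s.subset.mask: s for s in summaries}
    if full_mask not in by_mask:
        raise ValueError("summaries do not include the full tool set")
    candidates = [s for s in summaries if s.size <= k_best_size]
    if not candidates:
        raise ValueError(f"no combinations of size <= {k_best_size}")
    best = rank_combinations(candidates, "sensitivity")[0]
    full = by_mask[full_mask]

    def _run_sens_pct(mask: int) -> list[float]:
        try:
            runs = run_results[mask]
        except KeyError:
            raise ValueError(f"run-level results missing for subset mask {mask}") from None
        return [100.0 * r.sensitivity for r in runs]

    best_vals = _run_sens_pct(best.subset.mask)
    if best.subset.mask == full_mask:
        return BestVsFullComparison(
            best_mask=best.subset.mask, best_size=best.size, k_best_size=k_best_size,
            best_mean_sens=100 * best.mean_sens, best_sd_sens=100 * best.sd_sens,
            full_mean_sens=100 * full.mean_sens, full_sd_sens=100 * full.sd_sens,
            difference=0.0, n_runs_best=len(best_vals), n_runs_full=len(best_vals),
            z=None, p=None, paradox=False,
        )
    full_vals = _run_sens_pct(full_mask)
    m1, s1 = _metrics.aggregate(best_vals)
    m2, s2 = _metrics.aggregate(full_vals)
    diff, z, p = _metrics.welch_z(m1, s1, len(best_vals), m2, s2, len(full_vals))
    return BestVsFullComparison(
        best_mask=best.subset.mask, best_size=best.size, k_best_size=k_best_size,
        best_mean_sens=m1, best_sd_sens=s1, full_mean_sens=m2, full_sd_sens=s2,
        difference=diff, n_runs_best=len(best_vals), n_runs_full=len(full_vals),
        z=z, p=p, paradox=diff > 0,
    )


def mean_sensitivity_by_size(summaries: list[CombinationSummary]) -> pd.Series:
    """Mean of per-combination mean sensitivities, grouped by subset size.

    The signature curve of the paradox: it rises with the first few added
    tools, peaks around the optimal subset size, then falls as signal-free
    tools dilute the feature space.
    """
    df = pd.DataFrame({"size": [s.size for s in summaries],
                       "mean_sens": [s.mean_sens for s in summaries]})
    return df.groupby("size")["mean_sens"].mean()


def best_sensitivity_by_size(summaries: list[CombinationSummary]) -> pd.Series:
    """Highest per-combination mean sensitivity at each subset size.

    This is the frontier traced by the top combinations: with signal-free
    tools in the roster it rises with size, peaks, then falls once every
    combination of that size is forced to carry dead-weight columns.
    """
    df = pd.DataFrame({"size": [s.size for s in summaries],
                       "mean_sens": [s.mean_sens for s in summaries]})
    return df.groupby("size")["mean_sens"].max()


def predict_with_subset(
    table: FeatureTable,
    subset: ToolSubset,
    training_table: FeatureTable,
    svm: _svm.SVMConfig = _svm.SVMConfig(),
) -> np.ndarray:
    """Train on the full training table and label every row of ``table``.

    Both tables must carry the subset's columns under the same names; this
    is the deployment path (e.g. scoring unlabeled transcripts with the
    best-subset model).
    """
    model = _svm.train(training_table.restrict(subset), svm)
    return _svm.predict(model, table.restrict(subset))
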