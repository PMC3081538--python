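"""Exhaustive combination sweep with repeated stratified train/test splits.

For every non-empty subset of the prediction tools (2047 subsets for the
eleven-tool roster) the protocol repeats, 100 times by default: draw a test
set of exactly 100 mitochondrial and 630 non-mitochondrial proteins at
random (the study's ~10% held-out slice; the remaining 6089 rows train the
SVM), fit on the subset's columns, score the held-out proteins, and record
the confusion counts plus the support-vector count.  Run-level sensitivity,
specificity, FDR and corrected FDR are aggregated into a per-combination
mean/SD summary.

Seeding: the RNG for (combination, run) is ``numpy.random.SeedSequence(
base_seed, spawn_key=(salt, run_index))`` with ``salt`` equal to the
subset's bitmask — collision-free, independent of execution order, and
therefore safe under process parallelism.  Setting ``share_splits=True``
uses ``salt = 0`` for every combination so all 2047 combinations see the
same sequence of splits (the protocol's default is a fresh redraw per
combination).
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass

import numpy as np
from joblib import Parallel, delayed

from . import metrics as _metrics
from . import svm as _svm
from .feature_table import FeatureTable, ToolSubset

_MAX_TOOLS = 24  # 2^24-1 subsets; beyond this an exhaustive sweep is a mistake


@dataclass(frozen=True)
class SplitSpec:
    """Repeated stratified-split protocol parameters.

    Defaults are the study protocol: test sets of exactly 100 positive and
    630 negative proteins, 100 independent runs.
    """

    n_test_pos: int = 100
    n_test_neg: int = 630
    n_runs: int = 100
    base_seed: int = 0
    share_splits: bool = False

    def __post_init__(self) -> None:
        if self.n_test_pos < 1 or self.n_test_neg < 1:
            raise ValueError("test-set class counts must be >= 1")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")


@dataclass(frozen=True)
class RunResult:
    """One train/test split of one tool combination."""

    subset: ToolSubset
    run_index: int
    counts: _metrics.ConfusionCounts
    sv_count: int
    train_size: int
    overfit_flag: bool

    @property
    def sensitivity(self) -> float:
        return _metrics.sensitivity(self.counts)

    @property
    def specificity(self) -> float:
        return _metrics.specificity(self.counts)


@dataclass(frozen=True)
class CombinationSummary:
    """Mean/SD of the four metrics over all runs of one combination."""

    subset: ToolSubset
    n_runs: int
    mean_sens: float
    sd_sens: float
    mean_spec: float
    sd_spec: float
    mean_fdr: float
    sd_fdr: float
    mean_cfdr: float
    sd_cfdr: float
    n_overfit_runs: int

    @property
    def size(self) -> int:
        return self.subset.size


def enumerate_subsets(n_tools: int) -> list[ToolSubset]:
    """All non-empty tool subsets, ordered by (size ascending, mask ascending)."""
    if not 1 <= n_tools <= _MAX_TOOLS:
        raise ValueError(f"n_tools must lie in [1, {_MAX_TOOLS}], got {n_tools}")
    masks = sorted(range(1, 1 << n_tools), key=lambda m: (m.bit_count(), m))
    return [ToolSubset(m) for m in masks]


def split_rng(base_seed: int, run_index: int, salt: int = 0) -> np.random.Generator:
    """The documented per-run RNG: SeedSequence(base_seed, spawn_key=(salt, run))."""
    return np.random.default_rng(np.random.SeedSequence(base_seed, spawn_key=(salt, run_index)))


def stratified_split(
    table: FeatureTable, spec: SplitSpec, run_index: int, salt: int = 0
) -> tuple[FeatureTable, FeatureTable]:
    """Draw one exact-count stratified train/test split.

    The test set holds exactly ``n_test_pos`` positives and ``n_test_neg``
    negatives sampled without replacement; the training set is the
    complement (row order preserved).  Deterministic per
    ``(table, spec, run_index, salt)``.
    """
    pos = np.flatnonzero(table.labels == 1)
    neg = np.flatnonzero(table.labels == 0)
    if spec.n_test_pos >= pos.size or spec.n_test_neg >= neg.size:
        raise ValueError(
            f"cannot hold out {spec.n_test_pos}+/{spec.n_test_neg}- from a table with "
            f"{pos.size} positive / {neg.size} negative proteins"
        )
    rng = split_rng(spec.base_seed, run_index, salt)
    test_pos = rng.choice(pos, size=spec.n_test_pos, replace=False)
    test_neg = rng.choice(neg, size=spec.n_test_neg, replace=False)
    test_idx = np.sort(np.concatenate([test_pos, test_neg]))
    in_test = np.zeros(table.n_proteins, dtype=bool)
    in_test[test_idx] = True
    train_idx = np.flatnonzero(~in_test)
    return table.take_rows(train_idx), table.take_rows(test_idx)


def evaluate_combination(
    table: FeatureTable,
    subset: ToolSubset,
    spec: SplitSpec = SplitSpec(),
    svm: _svm.SVMConfig = _svm.SVMConfig(),
    prior_fraction: float = _metrics.DEFAULT_PRIOR_FRACTION,
    exclude_overfit_runs: bool = False,
) -> tuple[CombinationSummary, list[RunResult]]:
    """Run the full repeated train/test protocol for one tool combination.

    Runs failing the support-vector gate are flagged and counted; by default
    they still enter the summary (set ``exclude_overfit_runs`` to drop them
    from the aggregation — at least one run must then pass the gate).
    """
    if table.has_missing:
        raise ValueError("table contains missing cells; impute before sweeping")
    restricted = table.restrict(subset)
    salt = 0 if spec.share_splits else subset.mask
    runs: list[RunResult] = []
    for run_index in range(spec.n_runs):
        train_t, test_t = stratified_split(restricted, spec, run_index, salt)
        model = _svm.train(train_t, svm)
        pred = _svm.predict(model, test_t)
        counts = _metrics.ConfusionCounts.from_predictions(test_t.labels, pred)
        runs.append(
            RunResult(
                subset=subset,
                run_index=run_index,
                counts=counts,
                sv_count=model.sv_count,
                train_size=model.train_size,
                overfit_flag=not _svm.sv_gate(model, svm.sv_fraction_limit),
            )
        )
    return summarize_runs(subset, runs, prior_fraction, exclude_overfit_runs), runs


def summarize_runs(
    subset: ToolSubset,
    runs: list[RunResult],
    prior_fraction: float = _metrics.DEFAULT_PRIOR_FRACTION,
    exclude_overfit_runs: bool = False,
) -> CombinationSummary:
    n_overfit = sum(r.overfit_flag for r in runs)
    pool = [r for r in runs if not r.overfit_flag] if exclude_overfit_runs else list(runs)
    if not pool:
        raise ValueError(f"no usable runs for subset mask {subset.mask} (all flagged overfit)")
    sens = [r.sensitivity for r in pool]
    spec_ = [r.specificity for r in pool]
    fdrs = [_metrics.fdr(r.counts) for r in pool]
    cfdrs = [_metrics.cfdr(s, sp, prior_fraction) for s, sp in zip(sens, spec_)]
    (m_sens, s_sens) = _metrics.aggregate(sens)
    (m_spec, s_spec) = _metrics.aggregate(spec_)
    (m_fdr, s_fdr) = _metrics.aggregate(fdrs)
    (m_cfdr, s_cfdr) = _metrics.aggregate(cfdrs)
    return CombinationSummary(
        subset=subset,
        n_runs=len(pool),
        mean_sens=m_sens,
        sd_sens=s_sens,
        mean_spec=m_spec,
        sd_spec=s_spec,
        mean_fdr=m_fdr,
        sd_fdr=s_fdr,
        mean_cfdr=m_cfdr,
        sd_cfdr=s_cfdr,
        n_overfit_runs=n_overfit,
    )


def run_sweep(
    table: FeatureTable,
    spec: SplitSpec = SplitSpec(),
    svm: _svm.SVMConfig = _svm.SVMConfig(),
    subsets: list[ToolSubset] | None = None,
    prior_fraction: float = _metrics.DEFAULT_PRIOR_FRACTION,
    exclude_overfit_runs: bool = False,
    n_jobs: int = 1,
    keep_runs: bool = False,
    progress: bool = False,
):
    """Evaluate every tool combination (default: all of ``enumerate_subsets``).

    Output order matches the input subset order and is identical for serial
    and parallel execution, because every run's RNG depends only on
    ``(base_seed, subset mask, run index)``.  Returns the list of
    :class:`CombinationSummary`; with ``keep_runs=True`` returns
    ``(summaries, {mask: [RunResult, ...]})`` for run-level analyses.
    """
    table.require_evaluable()
    if subsets is None:
        subsets = enumerate_subsets(table.n_tools)
    for s in subsets:
        if s.mask >= 1 << table.n_tools:
            raise ValueError(f"subset mask {s.mask} out of range for {table.n_tools} tools")

    def one(subset: ToolSubset):
        return evaluate_combination(table, subset, spec, svm, prior_fraction, exclude_overfit_runs)

    if n_jobs == 1:
        iterator = subsets
        if progress:
            from tqdm import tqdm

            iterator = tqdm(subsets, desc="sweep", unit="subset")
        results = [one(s) for s in iterator]
    else:
        results = Parallel(n_jobs=n_jobs)(delayed(one)(s) for s in subsets)

    summaries = [summary for summary, _ in results]
    if keep_runs:
        return summaries, {s.subset.mask: runs for (s, runs) in results}
    return summaries


# -- results serialization ---------------------------------------------

SUMMARY_COLUMNS = [
    "mask", "tool_names", "size",
    "mean_sens", "sd_sens", "mean_spec", "sd_spec",
    "mean_fdr", "sd_fdr", "mean_cfdr", "sd_cfdr", "n_overfit_runs",
]


def _fmt(v: float) -> str:
    return repr(float(v))


def summaries_to_csv(summaries: list[CombinationSummary], tool_names: list[str], path=None) -> str:
    """Serialize summaries as CSV (one row per combination, repr-format floats).

    Float serialization is shortest-round-trip, so identical sweeps produce
    byte-identical files.  Returns the CSV text; writes it if ``path`` given.
    """
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(SUMMARY_COLUMNS)
    for s in summaries:
        writer.writerow([
            s.subset.mask,
            "|".join(s.subset.tool_names(tool_names)),
            s.size,
            _fmt(s.mean_sens), _fmt(s.sd_sens), _fmt(s.mean_spec), _fmt(s.sd_spec),
            _fmt(s.mean_fdr), _fmt(s.sd_fdr), _fmt(s.mean_cfdr), _fmt(s.sd_cfdr),
            s.n_overfit_runs,
        ])
    text = buf.getvalue()
    if path is not None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write(text)
    return text


def read_summaries_csv(path) -> tuple[list[CombinationSummary], list[list[str]]]:
    """Read a summaries CSV back; returns (summaries, per-row tool-name lists)."""
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header != SUMMARY_COLUMNS:
            raise ValueError(f"unexpected summary CSV header: {header}")
        summaries, names = [], []
        for row in reader:
            summaries.append(
                CombinationSummary(
                    subset=ToolSubset(int(row[0])),
                    n_runs=-1,  # not serialized; run-level data lives elsewhere
                    mean_sens=float(row[3]), sd_sens=float(row[4]),
                    mean_spec=float(row[5]), sd_spec=float(row[6]),
                    mean_fdr=float(row[7]), sd_fdr=float(row[8]),
                    mean_cfdr=float(row[9]), sd_cfdr=float(row[10]),
                    n_overfit_runs=int(row[11]),
                )
            )
            names.append(row[1].split("|"))
    return summaries, names
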