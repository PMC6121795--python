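"""Depth-of-coverage copy-number tests and structural calls.

The unit statistic is the median per-base read depth of a gene (or window)
per sample.  Copy number is tested as the per-sample ratio of unit depth to
that sample's mean background depth, with a one-sample t-test of the log2
ratios against 0; fold estimates and confidence intervals are reported on
the ratio scale (back-transformed), which is why a fourfold gain carries an
asymmetric CI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GeneModel


@dataclass
class CoverageTable:
    """Long-format depth table plus the identifiers used as background."""

    depths: pd.DataFrame  # columns: unit, sample, depth
    background: list[str]

    def __post_init__(self) -> None:
        required = {"unit", "sample", "depth"}
        if not required.issubset(self.depths.columns):
            raise ValueError(f"depth table needs columns {sorted(required)}")
        if (self.depths["depth"] < 0).any():
            raise ValueError("negative depths")

    def wide(self) -> pd.DataFrame:
        return self.depths.pivot_table(
            index="unit", columns="sample", values="depth"
        )


@dataclass
class CoverageTestResult:
    unit: str
    fold: float
    ci_low: float
    ci_high: float
    t_statistic: float
    df: int
    p_value: float
    mode: str  # multi-sample | single-sample
    n_used: int


@dataclass
class DeletionCall:
    scaffold: str
    start: int
    end: int
    carrier_group: str
    length: int
    genes: list[str]
    exons_lost: dict[str, tuple[int, int]]  # gene -> (lost, total)
    coding_bp_lost: int
    frameshift: bool


@dataclass
class DuplicationCall:
    unit: str
    carrier_group: str
    copies: int
    fold_by_group: dict[str, float]


def coverage_fold_test(
    cov: CoverageTable,
    unit: str,
    mode: str = "multi-sample",
    samples: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
) -> CoverageTestResult:
    """Fold change of a unit's depth over the background, with 95% CI.

    multi-sample: per-sample ratio r_i = depth(unit, i) / mean background
    depth of sample i; t-test of log2 r_i against 0 with n-1 df.
    single-sample (one library, e.g. a pooled outgroup): the unit's
    normalized depth is compared against the distribution of the background
    units' normalized depths (n_background - 1 df).
    """
    wide = cov.wide()
    if unit not in wide.index:
        raise KeyError(f"unit {unit!r} not in coverage table")
    bg = [u for u in cov.background if u != unit and u in wide.index]
    if not bg:
        raise ValueError("no background units available")
    cols = list(samples) if samples is not None else list(wide.columns)
    sub = wide.loc[:, cols]
    bg_mean = sub.loc[bg].mean(axis=0)

    if mode == "multi-sample":
        ratios = []
        for c in cols:
            if bg_mean[c] <= 0 or np.isnan(bg_mean[c]):
                warnings.warn(f"sample {c}: zero background depth, dropped")
                continue
            d = sub.loc[unit, c]
            if d <= 0:
                warnings.warn(f"sample {c}: zero unit depth, dropped")
                continue
            ratios.append(d / bg_mean[c])
        if len(ratios) < 2:
            raise ValueError("fewer than 2 usable samples for multi-sample test")
        logr = np.log2(ratios)
        n = len(logr)
        mean, se = logr.mean(), logr.std(ddof=1) / np.sqrt(n)
        df = n - 1
        t = mean / se if se > 0 else (0.0 if mean == 0 else np.inf * np.sign(mean))
        p = 2 * stats.t.sf(abs(t), df) if np.isfinite(t) else 0.0
        tcrit = stats.t.ppf(1 - alpha / 2, df)
        lo, hi = mean - tcrit * se, mean + tcrit * se
        return CoverageTestResult(
            unit=unit, fold=float(2.0 ** mean),
            ci_low=float(2.0 ** lo), ci_high=float(2.0 ** hi),
            t_statistic=float(t), df=df, p_value=float(p),
            mode=mode, n_used=n,
        )
    if mode == "single-sample":
        if len(cols) != 1:
            raise ValueError("single-sample mode expects exactly one sample")
        c = cols[0]
        bg_depths = sub.loc[bg, c]
        bg_depths = bg_depths[bg_depths > 0]
        if len(bg_depths) < 2:
            raise ValueError("single-sample mode needs >= 2 nonzero background units")
        x = np.log2(sub.loc[unit, c] / bg_depths.mean()) if sub.loc[unit, c] > 0 else -np.inf
        logbg = np.log2(bg_depths / bg_depths.mean())
        n = len(logbg)
        df = n - 1
        sd = logbg.std(ddof=1)
        se = sd * np.sqrt(1 + 1 / n)
        t = (x - logbg.mean()) / se if se > 0 else np.inf * np.sign(x - logbg.mean())
        p = 2 * stats.t.sf(abs(t), df) if np.isfinite(t) else 0.0
        tcrit = stats.t.ppf(1 - alpha / 2, df)
        return CoverageTestResult(
            unit=unit, fold=float(2.0 ** x),
            ci_low=float(2.0 ** (x - tcrit * se)), ci_high=float(2.0 ** (x + tcrit * se)),
            t_statistic=float(t), df=df, p_value=float(p),
            mode=mode, n_used=n,
        )
    raise ValueError(f"unknown mode {mode!r}")


def _window_key(unit: str) -> tuple[str, int, int]:
    scaffold, span = unit.rsplit(":", 1)
    start, end = span.split("-")
    return scaffold, int(start), int(end)


def detect_deletions(
    windows: CoverageTable,
    groups: dict[str, str],
    carrier_group: str,
    other_group: str,
    models: Sequence[GeneModel] = (),
    present_threshold: float = 1.0,
) -> list[DeletionCall]:
    """Group-specific deletions from windowed depth.

    A deletion is a maximal run of consecutive windows with zero depth in
    every carrier-group sample and depth > ``present_threshold`` in every
    sample of the other group.  Window ids must be ``scaffold:start-end``.
    Calls are annotated with the genes overlapped, whole CDS exons lost,
    and whether the coding loss shifts the frame (length mod 3).
    """
    wide = windows.wide()
    carrier = [s for s, g in groups.items() if g == carrier_group and s in wide.columns]
    other = [s for s, g in groups.items() if g == other_group and s in wide.columns]
    if not carrier or not other:
        raise ValueError("both groups need samples in the coverage table")
    keyed = sorted((_window_key(u) + (u,) for u in wide.index))
    calls: list[DeletionCall] = []
    run: list[tuple[str, int, int]] = []

    def flush() -> None:
        if not run:
            return
        scaffold = run[0][0]
        start, end = run[0][1], run[-1][2]
        genes, exons_lost, coding_lost = [], {}, 0
        for m in models:
            if m.scaffold != scaffold:
                continue
            lo, hi = m.span
            if lo < end and start < hi:
                genes.append(m.gene_id)
                lost = sum(1 for s, e in m.cds_exons if s >= start and e <= end)
                exons_lost[m.gene_id] = (lost, len(m.cds_exons))
                coding_lost += sum(
                    max(0, min(e, end) - max(s, start)) for s, e in m.cds_exons
                )
        calls.append(
            DeletionCall(
                scaffold=scaffold, start=start, end=end,
                carrier_group=carrier_group, length=end - start,
                genes=genes, exons_lost=exons_lost,
                coding_bp_lost=coding_lost,
                frameshift=coding_lost % 3 != 0,
            )
        )
        run.clear()

    prev: Optional[tuple[str, int, int]] = None
    for scaffold, start, end, unit in keyed:
        zero_in_carrier = bool((wide.loc[unit, carrier] == 0).all())
        present_in_other = bool((wide.loc[unit, other] > present_threshold).all())
        is_del = zero_in_carrier and present_in_other
        contiguous = (
            prev is not None and prev[0] == scaffold and prev[2] == start
        )
        if is_del:
            if run and not contiguous:
                flush()
            run.append((scaffold, start, end))
        else:
            flush()
        prev = (scaffold, start, end)
    flush()
    return calls


def detect_duplications(
    results_by_group: dict[str, CoverageTestResult],
    fold_threshold: float = 1.75,
) -> list[DuplicationCall]:
    """Duplication calls from per-group fold tests of one unit.

    A group carries a duplication when its fold >= threshold; when every
    group exceeds the threshold the carrier is "both".  A single-group call
    additionally requires the other group's CI to contain 1 (no gain).
    """
    items = list(results_by_group.items())
    dup = {g: r for g, r in items if r.fold >= fold_threshold}
    if not dup:
        return []
    folds = {g: r.fold for g, r in items}
    unit = items[0][1].unit
    if len(dup) == len(items):
        copies = int(round(np.mean([r.fold for r in dup.values()])))
        return [DuplicationCall(unit=unit, carrier_group="both",
                                copies=max(2, copies), fold_by_group=folds)]
    calls = []
    for g, r in dup.items():
        others = [o for og, o in items if og != g]
        if all(o.ci_low <= 1.0 <= o.ci_high for o in others):
            calls.append(
                DuplicationCall(unit=unit, carrier_group=g,
                                copies=max(2, int(round(r.fold))),
                                fold_by_group=folds)
            )
    return calls
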