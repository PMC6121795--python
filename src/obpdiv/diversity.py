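"""Windowed nucleotide diversity and selective-sweep candidate scanning.

pi is the expected per-site heterozygosity among sampled haplotypes, with
the small-sample correction n/(n-1); a window's pi is the sum of per-site
values divided by the full window length in bp, so monomorphic and
uncalled sites contribute zero and windows stay comparable genome-wide.
Regions recently swept by positive selection show depressed pi.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .genome import MISSING, GeneModel, HaploidGenotypeMatrix


@dataclass
class DiversityWindow:
    scaffold: str
    start: int
    end: int
    n_sites_called: int
    pi: float
    flagged: bool = False

    @property
    def unit(self) -> str:
        return f"{self.scaffold}:{self.start}-{self.end}"


@dataclass
class SweepRun:
    scaffold: str
    start: int
    end: int
    n_windows: int
    genes: list[str]
    min_pi: float


def site_pi(counts: Sequence[int]) -> float:
    """Unbiased per-site pi from haploid allele counts:
    (n/(n-1)) * (1 - sum p_a^2)."""
    n = sum(counts)
    if n < 2:
        return 0.0
    h = 1.0 - sum((c / n) ** 2 for c in counts)
    return n / (n - 1) * h


def pi_per_window(
    geno: HaploidGenotypeMatrix,
    group: str,
    scaffold_lengths: dict[str, int],
    window_bp: int = 10_000,
    min_called: int = 2,
) -> list[DiversityWindow]:
    """Nucleotide diversity of one haploid group in non-overlapping windows
    tiling each scaffold; terminal windows may be short, and their pi uses
    their true length."""
    idx = geno.sample_indices(group)
    if len(idx) < 2:
        raise ValueError(f"group {group!r} needs >= 2 haploid samples")
    acc: dict[tuple[str, int], tuple[float, int]] = {}
    for i, (scaffold, pos, _ref, alts) in enumerate(geno.sites):
        if scaffold not in scaffold_lengths:
            continue
        row = geno.calls[i]
        calls = [row[j] for j in idx if row[j] != MISSING]
        if len(calls) < min_called:
            continue
        counts = np.bincount(calls)
        w = pos // window_bp
        tot, n = acc.get((scaffold, w), (0.0, 0))
        acc[(scaffold, w)] = (tot + site_pi(counts.tolist()), n + 1)
    windows: list[DiversityWindow] = []
    for scaffold, length in scaffold_lengths.items():
        n_windows = (length + window_bp - 1) // window_bp
        for w in range(n_windows):
            start = w * window_bp
            end = min(start + window_bp, length)
            tot, n = acc.get((scaffold, w), (0.0, 0))
            windows.append(
                DiversityWindow(
                    scaffold=scaffold, start=start, end=end,
                    n_sites_called=n, pi=tot / (end - start),
                )
            )
    return windows


def sweep_candidates(
    windows: Sequence[DiversityWindow],
    features: Sequence[GeneModel],
    quantile: float = 0.25,
) -> tuple[float, list[SweepRun]]:
    """Flag gene-overlapping windows with pi strictly below the genome-wide
    quantile and merge adjacent flagged windows into candidate sweep runs.

    Returns the pi threshold used and the runs, each listing the features
    it overlaps.
    """
    if not windows:
        raise ValueError("empty window set")
    threshold = float(np.quantile([w.pi for w in windows], quantile))

    def overlapping(w: DiversityWindow) -> list[str]:
        out = []
        for m in features:
            if m.scaffold != w.scaffold:
                continue
            lo, hi = m.span
            if lo < w.end and w.start < hi:
                out.append(m.gene_id)
        return out

    flagged: list[tuple[DiversityWindow, list[str]]] = []
    for w in sorted(windows, key=lambda w: (w.scaffold, w.start)):
        genes = overlapping(w)
        w.flagged = w.pi < threshold and bool(genes)
        if w.flagged:
            flagged.append((w, genes))
    runs: list[SweepRun] = []
    for w, genes in flagged:
        last = runs[-1] if runs else None
        if last is not None and last.scaffold == w.scaffold and last.end == w.start:
            last.end = w.end
            last.n_windows += 1
            last.genes = sorted(set(last.genes) | set(genes))
            last.min_pi = min(last.min_pi, w.pi)
        else:
            runs.append(
                SweepRun(scaffold=w.scaffold, start=w.start, end=w.end,
                         n_windows=1, genes=sorted(genes), min_pi=w.pi)
            )
    return threshold, runs
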