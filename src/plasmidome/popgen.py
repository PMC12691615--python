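"""Nucleotide diversity, ANI, and Hudson's F_ST on core alignments.

All statistics use pairwise deletion: a site enters a pairwise comparison
only when both sequences have an unambiguous base there.  Coordinates in
window tracks are 0-based half-open on the concatenated core alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phylo import Alignment, pairwise_diff_counts


def _mean_pairwise(aln: Alignment, rows_a, rows_b=None) -> float:
    """Mean per-site difference over pairs (within rows_a, or across sets)."""
    diffs, comp = pairwise_diff_counts(aln)
    with np.errstate(invalid="ignore"):
        frac = np.where(comp > 0, diffs / np.maximum(comp, 1), np.nan)
    if rows_b is None:
        sub = frac[np.ix_(rows_a, rows_a)]
        vals = sub[np.triu_indices(len(rows_a), k=1)]
    else:
        vals = frac[np.ix_(rows_a, rows_b)].ravel()
    return float(np.nanmean(vals))


def nucleotide_diversity(aln: Alignment) -> float:
    """Per-site nucleotide diversity: the mean over all unordered sequence
    pairs of (differing sites / comparable sites)."""
    if len(aln.taxa) < 2:
        raise ValueError("need at least 2 sequences")
    return _mean_pairwise(aln, list(range(len(aln.taxa))))


def average_nucleotide_identity(aln: Alignment) -> float:
    """Mean pairwise identity over comparable positions, in percent."""
    if len(aln.taxa) < 2:
        raise ValueError("need at least 2 sequences")
    return 100.0 * (1.0 - nucleotide_diversity(aln))


def hudson_fst(aln: Alignment, pops: dict[str, str] | pd.Series) -> float:
    """Hudson's estimator F_ST = 1 - H_w / H_b for two groups.

    H_w is the mean per-site pairwise difference within groups (the two
    groups averaged), H_b the mean between groups.  Returns NaN when
    H_b = 0 (no between-group diversity).  ``pops`` maps taxon -> group
    label; exactly two labels, each with >= 2 members, are required.
    """
    pops = dict(pops)
    labels = sorted(set(pops.values()))
    if len(labels) != 2:
        raise ValueError("exactly two population labels required")
    idx = {g: [i for i, t in enumerate(aln.taxa) if pops.get(t) == g] for g in labels}
    if any(len(v) < 2 for v in idx.values()):
        raise ValueError("each population needs at least 2 sequences")
    a, b = labels
    hw = 0.5 * (_mean_pairwise(aln, idx[a]) + _mean_pairwise(aln, idx[b]))
    hb = _mean_pairwise(aln, idx[a], idx[b])
    if not np.isfinite(hb) or hb == 0.0:
        return float("nan")
    return 1.0 - hw / hb


def segregating_sites(aln: Alignment) -> int:
    """Number of columns with more than one unambiguous base present."""
    X = aln.data
    ok = X < 4
    hi = np.where(ok, X, -1).max(axis=0)
    lo = np.where(ok, X, 9).min(axis=0)
    return int(((hi != lo) & (hi >= 0) & (lo <= 3)).sum())


@dataclass
class WindowTrack:
    """Sliding-window statistic over a concatenated core alignment.

    ``windows`` has columns start, end (0-based half-open), value (NaN
    when the window has no segregating sites), n_segregating.
    """

    windows: pd.DataFrame
    window: int
    step: int

    def to_bed(self, chrom: str) -> pd.DataFrame:
        out = self.windows.copy()
        out.insert(0, "chrom", chrom)
        return out


def window_starts(length: int, window: int, step: int) -> list[tuple[int, int]]:
    """Window coordinates at fixed step; a trailing partial window is kept
    only when strictly longer than half the window."""
    if window < step or step < 1:
        raise ValueError("need window >= step >= 1")
    if window >= length:
        return [(0, length)]
    out = []
    start = 0
    while start + window <= length:
        out.append((start, start + window))
        start += step
    if start < length and (length - start) > window / 2:
        out.append((start, length))
    return out


def sliding_window_fst(
    aln: Alignment,
    pops: dict[str, str] | pd.Series,
    window: int = 10000,
    step: int = 1000,
) -> WindowTrack:
    """Hudson's F_ST in sliding windows along the alignment.

    Windows without segregating sites (or without between-group diversity)
    are flagged missing (NaN).
    """
    rows = []
    for start, end in window_starts(aln.length, window, step):
        sub = Alignment(aln.taxa, aln.data[:, start:end])
        seg = segregating_sites(sub)
        fst = hudson_fst(sub, pops) if seg > 0 else float("nan")
        rows.append((start, end, fst, seg))
    return WindowTrack(
        pd.DataFrame(rows, columns=["start", "end", "value", "n_segregating"]),
        window, step)


def replicon_summary(
    name: str,
    sizes: list[int],
    core_aln: Alignment,
    n_core_genes: int,
) -> dict:
    """One row of a per-replicon-type summary table: size range, core
    length, core gene count, nucleotide diversity, and ANI."""
    return {
        "type": name,
        "n": len(sizes),
        "size_min": int(min(sizes)) if sizes else 0,
        "size_max": int(max(sizes)) if sizes else 0,
        "core_length": core_aln.length,
        "core_genes": n_core_genes,
        "pi": nucleotide_diversity(core_aln),
        "ani": average_nucleotide_identity(core_aln),
    }
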