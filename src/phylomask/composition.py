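"""Per-codon-position nucleotide composition diagnostics.

Each gene (one sequence in the family alignment) is the sampling unit.  For
every gene the frequency of T, C, A and G is computed at each codon position
(1-3), with gaps and ambiguity codes excluded from the denominator.  Group
summaries report the mean frequency across genes with a normal-approximation
95% confidence interval, and GC content can be compared between groups (e.g.
monocots versus dicots) with a Welch two-sample t-test.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .codon_transform import CodonAlignment

logger = logging.getLogger(__name__)

BASES = ("T", "C", "A", "G")
Z_95 = 1.959963984540054  # two-sided 95% normal quantile


def position_composition(
    aln: CodonAlignment, groups: Optional[Mapping[str, str]] = None
) -> pd.DataFrame:
    """Per-gene base frequencies at each codon position.

    Returns a tidy DataFrame with columns ``gene, group, position, base,
    freq``.  Positions where a gene has no unambiguous base are excluded
    (logged).  For every included gene x position the four frequencies sum
    to 1.
    """
    rows = []
    for taxon in aln.taxa:
        seq = aln.seqs.sequence(taxon).upper()
        group = groups.get(taxon, "all") if groups else "all"
        for pos in (1, 2, 3):
            chars = seq[pos - 1 :: 3]
            counts = {b: chars.count(b) for b in BASES}
            total = sum(counts.values())
            if total == 0:
                logger.info(
                    "gene %s has no counted base at codon position %d", taxon, pos
                )
                continue
            for b in BASES:
                rows.append(
                    {
                        "gene": taxon,
                        "group": group,
                        "position": pos,
                        "base": b,
                        "freq": counts[b] / total,
                    }
                )
    return pd.DataFrame(rows, columns=["gene", "group", "position", "base", "freq"])


def composition_summary(profile: pd.DataFrame) -> pd.DataFrame:
    """Mean frequency with 95% CI per group x position x base.

    Genes are the sampling units; the CI is mean +/- 1.96 * sd / sqrt(n).
    Groups with a single gene report the mean with the CI marked unavailable
    (NaN bounds).
    """
    out = []
    for (group, pos, base), sub in profile.groupby(["group", "position", "base"]):
        vals = sub["freq"].to_numpy()
        n = len(vals)
        mean = float(np.mean(vals))
        if n >= 2:
            half = Z_95 * float(np.std(vals, ddof=1)) / math.sqrt(n)
            lo, hi = mean - half, mean + half
        else:
            lo = hi = float("nan")
        out.append(
            {
                "group": group,
                "position": pos,
                "base": base,
                "n": n,
                "mean": mean,
                "ci_lo": lo,
                "ci_hi": hi,
            }
        )
    return pd.DataFrame(out)


def gc_percent(
    aln: CodonAlignment, positions: Iterable[int] = (3,)
) -> pd.Series:
    """Per-gene G+C fraction at the requested codon positions (default: third).

    Gaps and ambiguity codes are excluded from the denominator.  Genes with no
    counted base at the requested positions are omitted.
    """
    positions = sorted(set(positions))
    if not positions or not set(positions) <= {1, 2, 3}:
        raise ValueError("positions must be a non-empty subset of {1, 2, 3}")
    out = {}
    for taxon in aln.taxa:
        seq = aln.seqs.sequence(taxon).upper()
        chars = "".join(seq[p - 1 :: 3] for p in positions)
        counted = sum(chars.count(b) for b in BASES)
        if counted == 0:
            logger.info("gene %s has no counted base at positions %s", taxon, positions)
            continue
        gc = chars.count("G") + chars.count("C")
        out[taxon] = gc / counted
    return pd.Series(out, name="gc")


def gc_ttest(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float, float]:
    """Welch two-sample t-test on GC percentages.

    Returns ``(t, df, two-sided p)``.  Welch (unequal variances) is the
    default because no variance homogeneity can be assumed between plant
    groups.  Degenerate zero-variance inputs with equal means give
    ``(0, df, 1)``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    if np.var(a) == 0 and np.var(b) == 0 and np.mean(a) == np.mean(b):
        return 0.0, float(len(a) + len(b) - 2), 1.0
    res = stats.ttest_ind(a, b, equal_var=False)
    df = float(getattr(res, "df", np.nan))
    return float(res.statistic), df, float(res.pvalue)


def plot_composition(summary: pd.DataFrame, ax=None):
    """Grouped bar chart of mean base frequencies with 95% CI error bars."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    width = 0.8 / len(BASES)
    groups = sorted(summary["group"].unique())
    slots = [
        (g, p) for g in groups for p in sorted(summary["position"].unique())
    ]
    xs = np.arange(len(slots))
    for k, base in enumerate(BASES):
        means, errs = [], []
        for g, p in slots:
            row = summary[
                (summary["group"] == g)
                & (summary["position"] == p)
                & (summary["base"] == base)
            ]
            means.append(row["mean"].iloc[0] if len(row) else np.nan)
            errs.append(
                (row["mean"].iloc[0] - row["ci_lo"].iloc[0])
                if len(row) and np.isfinite(row["ci_lo"].iloc[0])
                else 0.0
            )
        ax.bar(xs + k * width, means, width, yerr=errs, capsize=2, label=base)
    ax.set_xticks(xs + 1.5 * width)
    ax.set_xticklabels([f"{g}\npos {p}" for g, p in slots], fontsize=8)
    ax.set_ylabel("mean frequency")
    ax.legend(title="base", fontsize=8)
    return ax
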