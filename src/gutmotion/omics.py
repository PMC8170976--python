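"""Hybridisation-count miRNA workflow and proteomics downstream analysis.

The miRNA branch mirrors the digital-counting platform's standard analysis:
per-sample scaling so the geometric mean of stably expressed housekeeping
genes (Actb, B2m, Gapdh, Rpl19) is equalised across samples
(:func:`normalize_counts`), an expression filter keeping features with a mean
normalised count of at least 100 (:func:`expression_filter`), and two-group
differential expression with a Student's t-test on ``log2(count + 1)``
(:func:`differential_expression`); significance for the volcano-style output
uses the unadjusted p <= alpha, with Benjamini-Hochberg q-values reported
alongside.

The proteomics branch consumes a quantified protein intensity table (peptide
level quantification is upstream and out of scope) through the same t-test
machinery, plus set overlap counts (:func:`set_overlap`), integer-rounded
significant proportions (:func:`proportion_significant`) and the
counter-regulation pairing of significantly up-regulated miRNAs with
significantly down-regulated target proteins (:func:`counter_regulation_pairs`,
against a user-supplied target map).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "PairingResult",
    "normalize_counts",
    "expression_filter",
    "differential_expression",
    "set_overlap",
    "proportion_significant",
    "counter_regulation_pairs",
    "volcano_table",
    "read_counts_tsv",
    "read_target_map_tsv",
]


@dataclass(frozen=True)
class CountMatrix:
    """Feature x sample counts (or intensities) with group labels.

    ``groups`` maps sample id -> group label (exactly two groups, >= 2
    samples each).  ``housekeeping`` lists the reference features used for
    normalisation (required for ``kind="miRNA_counts"``).
    """

    counts: pd.DataFrame
    groups: pd.Series
    housekeeping: list
    kind: str = "miRNA_counts"

    def __post_init__(self) -> None:
        if not set(self.counts.columns) <= set(self.groups.index):
            raise ValueError("every sample column needs a group label")
        sizes = self.groups.loc[self.counts.columns].value_counts()
        if len(sizes) != 2 or sizes.min() < 2:
            raise ValueError("need exactly two groups with >= 2 samples each")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.kind == "miRNA_counts":
            missing = set(self.housekeeping) - set(self.counts.index)
            if missing:
                raise ValueError(f"housekeeping features absent from matrix: {sorted(missing)}")

    def samples_in(self, group: str) -> list:
        labels = self.groups.loc[self.counts.columns]
        return list(labels.index[labels == group])

    @property
    def group_names(self) -> list:
        return sorted(self.groups.loc[self.counts.columns].unique())


def normalize_counts(matrix: CountMatrix, method: str = "geometric") -> CountMatrix:
    """Scale each sample so its housekeeping summary equals the cohort average.

    With the default geometric method, sample ``s`` is multiplied by
    ``mean_over_samples(gm) / gm(s)`` where ``gm`` is the geometric mean of
    the housekeeping counts — the platform-standard scheme, exactly inverting
    any per-sample multiplicative scaling and idempotent on already-normalised
    data.  ``method="arithmetic"`` uses arithmetic housekeeping means instead.
    """
    if method not in ("geometric", "arithmetic"):
        raise ValueError("method must be 'geometric' or 'arithmetic'")
    hk = matrix.counts.loc[matrix.housekeeping]
    zero = hk <= 0
    if zero.to_numpy().any():
        feat = zero.index[zero.any(axis=1)][0]
        samp = zero.columns[zero.loc[feat]][0]
        raise ValueError(f"housekeeping feature {feat!r} has a non-positive count in sample {samp!r}")
    if method == "geometric":
        per_sample = np.exp(np.log(hk).mean(axis=0))
    else:
        per_sample = hk.mean(axis=0)
    scale = per_sample.mean() / per_sample
    return CountMatrix(
        counts=matrix.counts * scale,
        groups=matrix.groups,
        housekeeping=matrix.housekeeping,
        kind=matrix.kind,
    )


def expression_filter(matrix: CountMatrix, min_count: float = 100.0) -> pd.Series:
    """Robust-expression flag: mean normalised count across all samples >= min_count."""
    return matrix.counts.mean(axis=1) >= min_count


def differential_expression(
    matrix: CountMatrix,
    alpha: float = 0.05,
    min_count: float = 100.0,
    reference: str = "WT",
    expressed: pd.Series | None = None,
) -> pd.DataFrame:
    """Two-group differential expression on a normalised matrix.

    Per feature: means per group on the linear scale, fold change
    (case / reference), and a two-sided equal-variance Student's t-test on
    ``log2(count + 1)`` (the log stabilises count variance; the pseudo-count
    avoids log 0).  ``significant`` requires the expression flag and
    unadjusted ``p <= alpha``; ``q_value`` carries the Benjamini-Hochberg FDR
    over expressed features for modern use but does not feed the flag.
    Features with zero within-group variance in both groups get ``p = 1``
    when the group means agree and a missing p (``degenerate=True``)
    otherwise.
    """
    from statsmodels.stats.multitest import multipletests

    if expressed is None:
        expressed = expression_filter(matrix, min_count=min_count)
    group_names = matrix.group_names
    if reference not in group_names:
        raise ValueError(f"reference group {reference!r} not in {group_names}")
    case = next(g for g in group_names if g != reference)

    ref_cols = matrix.samples_in(reference)
    case_cols = matrix.samples_in(case)
    a = matrix.counts[case_cols].to_numpy(dtype=float)
    b = matrix.counts[ref_cols].to_numpy(dtype=float)

    mean_case = a.mean(axis=1)
    mean_ref = b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(mean_ref > 0, mean_case / np.where(mean_ref > 0, mean_ref, 1.0), np.inf)
        log2fc = np.log2(fold)

    la, lb = np.log2(a + 1.0), np.log2(b + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat, p = sps.ttest_ind(la, lb, axis=1, equal_var=True)
    degenerate = (la.var(axis=1) == 0) & (lb.var(axis=1) == 0)
    same_mean = np.isclose(la.mean(axis=1), lb.mean(axis=1))
    t_stat = np.where(degenerate & same_mean, 0.0, t_stat)
    p = np.where(degenerate & same_mean, 1.0, p)
    p = np.where(degenerate & ~same_mean, np.nan, p)

    expressed = expressed.reindex(matrix.counts.index).fillna(False).astype(bool)
    significant = expressed.to_numpy() & (p <= alpha)

    q = np.full_like(p, np.nan)
    mask = expressed.to_numpy() & np.isfinite(p)
    if mask.any():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]

    return pd.DataFrame({
        f"mean_{reference}": mean_ref,
        f"mean_{case}": mean_case,
        "fold_change": fold,
        "log2fc": log2fc,
        "t_statistic": t_stat,
        "p_value": p,
        "q_value": q,
        "expressed": expressed.to_numpy(),
        "significant": significant,
        "degenerate": degenerate & ~same_mean,
        "direction": np.where(log2fc > 0, "up", "down"),
    }, index=matrix.counts.index.rename("feature"))


def set_overlap(sig_a: Iterable, sig_b: Iterable) -> tuple[int, int, int]:
    """Partition counts (|A only|, |B only|, |A and B|) of two id sets."""
    a, b = set(sig_a), set(sig_b)
    return len(a - b), len(b - a), len(a & b)


def proportion_significant(n_sig: int, n_total: int) -> int:
    """Percent of significant features, rounded to the nearest integer."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_sig <= n_total:
        raise ValueError("need 0 <= n_sig <= n_total")
    return int(math.floor(100.0 * n_sig / n_total + 0.5))


@dataclass(frozen=True)
class PairingResult:
    """Counter-regulation pairs and their distinct tallies."""

    pairs: list  # list of (miRNA id, protein id)
    n_interactions: int
    n_mirnas: int
    n_proteins: int


def counter_regulation_pairs(
    mirna_de: pd.DataFrame,
    protein_de: pd.DataFrame,
    target_map: Mapping | pd.DataFrame,
) -> PairingResult:
    """Pair significantly up-regulated miRNAs with their significantly
    down-regulated target proteins.

    ``target_map`` is user supplied (two-column DataFrame miRNA -> protein,
    or a mapping miRNA -> iterable of proteins); no target prediction is
    performed here.
    """
    if isinstance(target_map, pd.DataFrame):
        if target_map.shape[1] < 2:
            raise ValueError("target map needs two columns (miRNA, protein)")
        items = list(zip(target_map.iloc[:, 0], target_map.iloc[:, 1]))
    else:
        items = [(m, p) for m, targets in target_map.items() for p in targets]
    if not items:
        warnings.warn("empty target map: no pairs can be formed", stacklevel=2)
        return PairingResult([], 0, 0, 0)

    up = set(mirna_de.index[(mirna_de["significant"]) & (mirna_de["direction"] == "up")])
    down = set(protein_de.index[(protein_de["significant"]) & (protein_de["direction"] == "down")])
    pairs = sorted({(m, p) for m, p in items if m in up and p in down})
    return PairingResult(
        pairs=pairs,
        n_interactions=len(pairs),
        n_mirnas=len({m for m, _ in pairs}),
        n_proteins=len({p for _, p in pairs}),
    )


def volcano_table(
    de: pd.DataFrame,
    alpha: float = 0.05,
    out_png: str | Path | None = None,
) -> pd.DataFrame:
    """Plot-ready volcano coordinates; optionally render the PNG.

    Features with a missing p-value are omitted (and logged).  The guide line
    sits at ``-log10(alpha)`` so a feature with ``p == alpha`` lies exactly
    on it.
    """
    keep = np.isfinite(de["p_value"].to_numpy(dtype=float))
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("volcano_table: omitting %d feature(s) with missing p-values", n_dropped)
    sub = de.loc[keep]
    table = pd.DataFrame({
        "log2fc": sub["log2fc"],
        "neg_log10_p": -np.log10(sub["p_value"]),
        "significant": sub["significant"],
    }, index=sub.index)

    if out_png is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4), dpi=150)
        colors = np.where(table["significant"], "purple", "black")
        ax.scatter(table["log2fc"], table["neg_log10_p"], s=12, c=colors, alpha=0.7)
        ax.axhline(-np.log10(alpha), color="grey", lw=1, ls="--")
        ax.set_xlabel("log2 fold change")
        ax.set_ylabel("-log10 p")
        fig.tight_layout()
        fig.savefig(out_png)
        plt.close(fig)
    return table


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def read_counts_tsv(
    counts_path: str | Path,
    groups_path: str | Path,
    housekeeping: Iterable = ("Actb", "B2m", "Gapdh", "Rpl19"),
    kind: str = "miRNA_counts",
) -> CountMatrix:
    """Read a feature x sample TSV plus a two-column sample -> group TSV."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    gdf = pd.read_csv(groups_path, sep="\t", header=None, names=["sample", "group"])
    groups = gdf.set_index("sample")["group"]
    hk = [h for h in housekeeping if h in counts.index] if kind != "miRNA_counts" else list(housekeeping)
    return CountMatrix(counts=counts, groups=groups, housekeeping=hk, kind=kind)


def read_target_map_tsv(path: str | Path) -> pd.DataFrame:
    """Two-column TSV (miRNA id, protein id), no header."""
    return pd.read_csv(path, sep="\t", header=None, names=["miRNA", "protein"])
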