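"""Fold-wise AUC scoring, t-based summaries, and paired significance tests.

The AUC is the rank-based (Mann-Whitney) statistic with midrank tie
handling.  Cross-validation summaries are mean +/- the 95% confidence
half-width from the Student t distribution on the fold population.
Design pairs are compared with a paired two-tailed t-test on fold-wise
AUC differences; raw p-values are reported at alpha = 0.05 by default
(an optional Bonferroni flag is provided but off by default).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from importlib import resources


import numpy as np
from scipy import stats as sps


@dataclass
class FoldResult:
    design: str
    fold: int
    test_ids: list[str]
    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if not (len(self.test_ids) == self.scores.size == self.labels.size):
            raise ValueError("ids, scores and labels must have equal length")

    @property
    def auc(self) -> float:
        return roc_auc(self.scores, self.labels)


def roc_auc(scores, labels) -> float:
    """Rank-based AUC; tied scores contribute 1/2 per positive-negative pair."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = sps.rankdata(scores)             # midranks
    r_pos = ranks[labels == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def fold_summary(aucs) -> tuple[float, float]:
    """Mean and t-based CI95 half-width of a fold AUC population."""
    a = np.asarray(aucs, dtype=float)
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 folds for a summary")
    half = float(sps.t.ppf(0.975, n - 1) * a.std(ddof=1) / np.sqrt(n))
    return float(a.mean()), half


def paired_t_matrix(results_by_design: dict[str, np.ndarray], alpha: float = 0.05,
                    bonferroni: bool = False):
    """Pairwise paired two-tailed t-tests on fold-wise AUCs.

    Returns (designs, p-value matrix, significance flags).  The matrix is
    symmetric with NaN on the diagonal.
    """
    designs = list(results_by_design)
    cols = [np.asarray(results_by_design[d], dtype=float) for d in designs]
    n = {c.size for c in cols}
    if len(n) != 1:
        raise ValueError("all designs must have the same fold count")
    k = len(designs)
    p = np.full((k, k), np.nan)
    thresh = alpha / (k * (k - 1) / 2) if bonferroni else alpha
    for i in range(k):
        for j in range(i + 1, k):
            diff = cols[i] - cols[j]
            if np.allclose(diff.std(ddof=1), 0.0):
                warnings.warn(f"zero-variance differences for "
                              f"{designs[i]} vs {designs[j]}; p set to 1")
                pij = 1.0
            else:
                pij = float(sps.ttest_rel(cols[i], cols[j]).pvalue)
            p[i, j] = p[j, i] = pij
    sig = p < thresh
    np.fill_diagonal(sig, False)
    return designs, p, sig


def summarize_runs(fold_results: list[FoldResult]) -> dict[str, dict]:
    """Aggregate fold results into per-design AUC populations and summaries."""
    by_design: dict[str, dict[int, float]] = {}
    for fr in fold_results:
        by_design.setdefault(fr.design, {})[fr.fold] = fr.auc
    out = {}
    for design, folds in by_design.items():
        aucs = np.array([folds[k] for k in sorted(folds)])
        mean, ci = fold_summary(aucs) if aucs.size >= 2 else (float(aucs.mean()), float("nan"))
        out[design] = {"fold_aucs": aucs, "mean": mean, "ci95": ci}
    return out


def write_summary_table(summary: dict[str, dict], path) -> None:
    """Delimited fold-wise AUC table with a mean +/- CI95 footer row."""
    designs = list(summary)
    n_folds = max(len(summary[d]["fold_aucs"]) for d in designs)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["fold"] + designs)
        for k in range(n_folds):
            w.writerow([k + 1] + [f"{summary[d]['fold_aucs'][k]:.3f}"
                                  if k < len(summary[d]["fold_aucs"]) else ""
                                  for d in designs])
        w.writerow(["mean±CI95"] + [f"{summary[d]['mean']:.3f}±{summary[d]['ci95']:.3f}"
                                    for d in designs])


def write_significance_matrix(designs, p, sig, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["design"] + designs)
        for i, d in enumerate(designs):
            w.writerow([d] + [("" if i == j else
                               f"{p[i, j]:.4f}{'*' if sig[i, j] else ''}")
                              for j in range(len(designs))])


def load_reference_fold_aucs() -> dict[str, np.ndarray]:
    """Packaged reference benchmark: fold-wise test AUCs of the eight designs
    from the original 222-patient clinical cross-validation, used for
    regression tests of the summary statistics."""
    with resources.files("jeps.data").joinpath("reference_fold_aucs.csv").open() as fh:
        rows = list(csv.DictReader(fh))
    return {name: np.array([float(r[name]) for r in rows])
            for name in rows[0] if name != "fold"}
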