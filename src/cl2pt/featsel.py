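"""Three-stage feature selection for cross-domain drug-response prediction.

Stage 1 (supervised domain adaptation): keep genes whose class-conditional
distributions P(X|Y) are *not* significantly different between the source
(cell-line) and target (patient/PDX) domains, by two-sample KS tests run
separately within responders and non-responders at a stringent level
p >= alpha.  This is the only place target labels are used.

Stage 2 (differential expression): Welch two-sample t-test of sensitive vs
resistant source samples, Benjamini-Hochberg FDR, keep at most the
``max_genes`` (default 1,000) genes with smallest FDR.

Stage 3: sort the survivors by the between-group to within-group
sum-of-squares ratio (BW ratio), descending.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datasets_io import DataError, DomainDataset

#: per-side class sample count at or below which the exact KS null is used
EXACT_KS_MAX_N = 10


@dataclass
class FeatureRanking:
    """Final ranked gene list with the per-gene statistics that produced it.

    Arrays are aligned with ``gene_ids`` (the BW-descending final ranking).
    ``n_passed_da`` records how many genes survived the DA filter overall.
    """

    gene_ids: list[str]
    ks_p_y1: np.ndarray
    ks_p_y0: np.ndarray
    passed_da: np.ndarray
    t_stat: np.ndarray
    fdr: np.ndarray
    bw: np.ndarray
    alpha: float
    use_da: bool = True
    n_passed_da: int | None = None

    def __len__(self) -> int:
        return len(self.gene_ids)

    def top(self, p: int) -> list[str]:
        return self.gene_ids[:p]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "ks_p_y1": self.ks_p_y1,
                "ks_p_y0": self.ks_p_y0,
                "passed_da": self.passed_da.astype(bool),
                "t_stat": self.t_stat,
                "fdr": self.fdr,
                "bw": self.bw,
                "rank": np.arange(1, len(self.gene_ids) + 1),
            }
        )


def _check_classes(ds: DomainDataset, min_per_class: int = 1) -> None:
    for label, name in ((1, "sensitive"), (0, "resistant")):
        n = int((ds.labels.y == label).sum())
        if n < min_per_class:
            raise DataError(
                f"{ds.domain} domain has {n} {name} samples; need >= {min_per_class}"
            )


def ks_domain_filter(
    source: DomainDataset,
    target: DomainDataset,
    alpha: float,
    rule: Literal["both", "either", "pooled"] = "both",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-gene class-conditional KS tests between domains.

    For each gene two two-sample KS tests are run: source-vs-target values
    among responders (Y=1) and among non-responders (Y=0).  Under the
    default ``both`` rule a gene passes iff both p-values are >= alpha,
    matching the two sup-norm distances sup|F_S(x|Y=k) - F_T(x|Y=k)|.
    The exact permutation null is used when both sides of a test have at
    most 10 samples (target cohorts have as few as 3 responders, where the
    asymptotic null is unreliable).

    Returns (ks_p_y1, ks_p_y0, passed_da) aligned with the shared gene list.
    """
    if not 0 < alpha < 1:
        raise DataError(f"alpha must be in (0,1), got {alpha}")
    if source.expr.gene_ids != target.expr.gene_ids:
        raise DataError("source and target must share gene set and order")
    _check_classes(source)
    _check_classes(target)

    n_genes = source.expr.n_genes
    p1 = np.empty(n_genes)
    p0 = np.empty(n_genes)
    masks = {
        (dom, k): (ds.labels.y == k)
        for dom, ds in (("s", source), ("t", target))
        for k in (0, 1)
    }
    for k, out in ((1, p1), (0, p0)):
        xs = source.expr.values[:, masks[("s", k)]]
        xt = target.expr.values[:, masks[("t", k)]]
        method = "exact" if max(xs.shape[1], xt.shape[1]) <= EXACT_KS_MAX_N else "asymp"
        for i in range(n_genes):
            out[i] = stats.ks_2samp(xs[i], xt[i], method=method).pvalue
    if rule == "both":
        passed = (p1 >= alpha) & (p0 >= alpha)
    elif rule == "either":
        passed = (p1 >= alpha) | (p0 >= alpha)
    elif rule == "pooled":
        passed = np.empty(n_genes, dtype=bool)
        method = (
            "exact"
            if max(source.expr.n_samples, target.expr.n_samples) <= EXACT_KS_MAX_N
            else "asymp"
        )
        for i in range(n_genes):
            p = stats.ks_2samp(
                source.expr.values[i], target.expr.values[i], method=method
            ).pvalue
            passed[i] = p >= alpha
    else:
        raise DataError(f"unknown KS rule {rule!r}")
    return p1, p0, passed


def de_rank(
    source: DomainDataset,
    candidate_genes: Sequence[str],
    max_genes: int = 1000,
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Prioritize candidates by differential expression in the source domain.

    Welch two-sample t-test (sensitive vs resistant), BH FDR across the
    candidate set, keep at most ``max_genes`` genes with smallest FDR
    (ties broken by smaller raw p, then gene id).  Returns the selected
    genes with their t statistics and FDR values, in selection order.
    """
    _check_classes(source, min_per_class=2)
    candidate_genes = list(candidate_genes)
    expr = source.expr.subset_genes(candidate_genes)
    y = source.labels.y
    a = expr.values[:, y == 1]
    b = expr.values[:, y == 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    # zero-variance-in-both-groups genes: t is nan; treat as fully null
    nan = ~np.isfinite(p)
    t[~np.isfinite(t)] = 0.0
    p[nan] = 1.0
    fdr = multipletests(p, method="fdr_bh")[1]
    order = sorted(
        range(len(candidate_genes)),
        key=lambda i: (fdr[i], p[i], candidate_genes[i]),
    )[: int(max_genes)]
    genes = [candidate_genes[i] for i in order]
    return genes, t[order], fdr[order]


def bw_ratio(values: np.ndarray, labels: np.ndarray) -> float:
    """Between-group to within-group sum-of-squares ratio for one gene.

    With group means xbar_k, overall mean xbar and group sizes n_k:

        BW = sum_k n_k (xbar_k - xbar)^2 / sum_k sum_{i in k} (x_i - xbar_k)^2

    Degenerate cases: 0/0 -> 0 (uninformative gene, ranked last); x/0 with
    x > 0 -> +inf (perfectly separating gene, ranked first).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    between = 0.0
    within = 0.0
    grand = values.mean()
    for k in (0, 1):
        grp = values[labels == k]
        if grp.size == 0:
            raise DataError(f"group {k} is empty")
        between += grp.size * (grp.mean() - grand) ** 2
        within += ((grp - grp.mean()) ** 2).sum()
    if within == 0.0:
        return 0.0 if between == 0.0 else float("inf")
    return float(between / within)


def select_features(
    source: DomainDataset,
    target: DomainDataset,
    alpha: float = 0.7,
    max_genes: int = 1000,
    use_da: bool = True,
    ks_rule: Literal["both", "either", "pooled"] = "both",
) -> FeatureRanking:
    """Run the full three-stage selection and return the BW-ranked genes.

    ``use_da=False`` skips the domain-adaptation filter (the ablation arm);
    differential-expression ranking then runs over all shared genes.
    """
    if source.expr.gene_ids != target.expr.gene_ids:
        raise DataError("source and target must share gene set and order")
    genes = source.expr.gene_ids
    if use_da:
        p1, p0, passed = ks_domain_filter(source, target, alpha, rule=ks_rule)
        survivors = [g for g, ok in zip(genes, passed) if ok]
        if not survivors:
            raise DataError(
                f"no genes passed the DA filter at alpha={alpha}; try a lower alpha"
            )
        ksmap = {g: (p1[i], p0[i]) for i, g in enumerate(genes)}
        n_passed = int(passed.sum())
    else:
        survivors = list(genes)
        ksmap = {g: (np.nan, np.nan) for g in genes}
        n_passed = len(genes)

    sel_genes, t_sel, fdr_sel = de_rank(source, survivors, max_genes=max_genes)
    stats_map = {g: (t_sel[i], fdr_sel[i]) for i, g in enumerate(sel_genes)}

    expr = source.expr.subset_genes(sel_genes)
    y = source.labels.y
    bw = np.array([bw_ratio(expr.values[i], y) for i in range(len(sel_genes))])
    # -inf never occurs (bw >= 0); sort by BW descending, gene id for ties
    order = sorted(range(len(sel_genes)), key=lambda i: (-bw[i], sel_genes[i]))
    ranked = [sel_genes[i] for i in order]
    return FeatureRanking(
        gene_ids=ranked,
        ks_p_y1=np.array([ksmap[g][0] for g in ranked]),
        ks_p_y0=np.array([ksmap[g][1] for g in ranked]),
        passed_da=np.ones(len(ranked), dtype=bool),  # ranked genes all survived
        t_stat=np.array([stats_map[g][0] for g in ranked]),
        fdr=np.array([stats_map[g][1] for g in ranked]),
        bw=bw[order],
        alpha=alpha,
        use_da=use_da,
        n_passed_da=n_passed,
    )
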