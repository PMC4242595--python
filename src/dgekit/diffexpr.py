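"""Paired differential expression for tag-count libraries.

The Audic-Claverie test asks whether observing ``x`` tags of a gene in a
library of ``N1`` clean tags and ``y`` tags in a library of ``N2`` is
compatible with equal underlying expression.  Conditional on ``x``, the
null distribution of ``y`` has the per-outcome probability

    P(y | x) = (N2/N1)^y * (x+y)! / ( x! * y! * (1 + N2/N1)^(x+y+1) )

and the two-sided p-value doubles the smaller tail, capped at 1.  Tails
are accumulated in log space from log-gamma terms, so counts up to 1e7
neither overflow nor underflow.
"""

from __future__ import annotations

import math
from math import ceil

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

__all__ = [
    "audic_claverie_pvalue",
    "bh_fdr",
    "call_pair",
    "recurrent_genes",
    "qpcr_concordance",
]


def _log_pmf(yp: np.ndarray, x: int, r: float) -> np.ndarray:
    """log P(y'|x) for the conditional tag-count distribution, ratio r = N2/N1."""
    yp = np.asarray(yp, dtype=np.float64)
    return (
        yp * math.log(r)
        - (x + yp + 1.0) * math.log1p(r)
        + gammaln(x + yp + 1.0)
        - gammaln(x + 1.0)
        - gammaln(yp + 1.0)
    )


def _tail_window(x: int, r: float) -> tuple[float, float]:
    mean = (x + 1.0) * r
    sd = math.sqrt((x + 1.0) * r * (1.0 + r))
    return mean, sd


def audic_claverie_pvalue(x: int, y: int, N1: float, N2: float) -> float:
    """Two-sided Audic-Claverie p-value for counts x (library N1) and y (N2).

    p = min(1, 2 * min(P(Y <= y | x), P(Y >= y | x))), tails summed from
    the per-outcome conditional distribution in log space.
    """
    if x < 0 or y < 0:
        raise ValueError("counts must be nonnegative")
    if N1 <= 0 or N2 <= 0:
        raise ValueError("library sizes must be positive")
    x, y = int(x), int(y)
    r = N2 / N1
    mean, sd = _tail_window(x, r)
    margin = 45.0 * sd + 100.0

    # Tails are dominated by terms near min(y, mean) resp. max(y, mean);
    # contributions more than ~45 sd beyond are below double precision.
    # A tail whose boundary lies beyond the far window is 1 to within
    # the same error and is not summed term by term.
    if y > mean + margin:
        lower = 0.0  # log P(Y <= y) ~ log 1
    else:
        lo = max(0, int(min(y, mean) - margin))
        lower = float(logsumexp(_log_pmf(np.arange(lo, y + 1), x, r)))
    if y < mean - margin:
        upper = 0.0
    else:
        hi = int(max(y, mean) + margin) + 1
        upper = float(logsumexp(_log_pmf(np.arange(y, hi), x, r)))

    log_tail = min(lower, upper)
    return float(min(1.0, 2.0 * math.exp(min(log_tail, 0.0))))


def audic_claverie_pvalues(x: np.ndarray, y: np.ndarray,
                           N1: float, N2: float) -> np.ndarray:
    """Vectorized wrapper over :func:`audic_claverie_pvalue`."""
    x = np.asarray(x)
    y = np.asarray(y)
    return np.array(
        [audic_claverie_pvalue(int(a), int(b), N1, N2) for a, b in zip(x, y)]
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, input order preserved.

    q_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1.
    """
    p = np.asarray(p_values, dtype=np.float64)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def call_pair(tumor_counts: pd.Series, normal_counts: pd.Series,
              N1: float | None = None, N2: float | None = None,
              fold_threshold: float = 1.0,
              fdr_threshold: float = 0.001) -> pd.DataFrame:
    """Per-gene differential-expression calls for one tumor/normal pair.

    ``x`` is the normal count, ``y`` the tumor count.  The p-value is
    computed on raw counts with library denominators N1 (normal) and N2
    (tumor, defaulting to the column sums); the signed log2 ratio
    (tumor over normal) is computed on TPM with a one-tag pseudocount in
    each library so zeros remain defined.  A gene is called deregulated
    when |log2ratio| > ``fold_threshold`` and BH q < ``fdr_threshold``
    (the "fold > 1 and FDR < 0.1%" rule at the defaults).
    """
    genes = normal_counts.index
    if len(genes) == 0:
        raise ValueError("empty gene universe")
    if not genes.equals(tumor_counts.index):
        tumor_counts = tumor_counts.reindex(genes)
        if tumor_counts.isna().any():
            raise ValueError("tumor and normal libraries cover different genes")
    x = normal_counts.to_numpy(dtype=np.int64)
    y = tumor_counts.to_numpy(dtype=np.int64)
    n1 = float(N1) if N1 is not None else float(x.sum())
    n2 = float(N2) if N2 is not None else float(y.sum())
    log2ratio = np.log2(((y + 1.0) / n2) / ((x + 1.0) / n1))
    p = audic_claverie_pvalues(x, y, n1, n2)
    q = bh_fdr(p)
    fold = np.abs(log2ratio)
    is_de = (fold > fold_threshold) & (q < fdr_threshold)
    direction = np.where(log2ratio > 0, "up", np.where(log2ratio < 0, "down", "flat"))
    return pd.DataFrame(
        {
            "x": x, "y": y, "N1": n1, "N2": n2,
            "log2ratio": log2ratio, "fold": fold,
            "p": p, "q": q, "is_de": is_de, "direction": direction,
        },
        index=genes,
    )


def recurrent_genes(pair_results: dict[str, pd.DataFrame] | list[pd.DataFrame],
                    min_cases: int | None = None,
                    min_avg_fold: float = 1.0,
                    over: str = "all") -> pd.DataFrame:
    """Aggregate per-pair calls into cohort-level recurrently deregulated genes.

    A gene is recurrent when it is called deregulated in at least
    ``min_cases`` patients (default: half the cohort, rounded up — the
    ">= 5 of 10 cases" rule) and the magnitude of its average signed
    log2 ratio exceeds ``min_avg_fold``.  ``over`` selects whether the
    average runs over all patients ("all", default) or only the
    deregulated pairs ("de").  Genes whose deregulated pairs disagree in
    sign are flagged ``mixed`` but still classified by the mean.
    """
    if isinstance(pair_results, dict):
        frames = [pair_results[k] for k in sorted(pair_results)]
    else:
        frames = list(pair_results)
    if not frames:
        raise ValueError("at least one patient pair required")
    if over not in ("all", "de"):
        raise ValueError("over must be 'all' or 'de'")
    n_patients = len(frames)
    if min_cases is None:
        min_cases = ceil(0.5 * n_patients)

    genes = frames[0].index
    log2 = pd.concat([f["log2ratio"] for f in frames], axis=1)
    de = pd.concat([f["is_de"] for f in frames], axis=1)
    n_de = de.sum(axis=1).astype(int)
    if over == "all":
        mean_l2 = log2.mean(axis=1)
    else:
        mean_l2 = log2.where(de.to_numpy()).mean(axis=1).fillna(0.0)
    signs = np.sign(log2.where(de.to_numpy()))
    mixed = ((signs > 0).any(axis=1) & (signs < 0).any(axis=1))
    is_rec = (n_de >= min_cases) & (mean_l2.abs() > min_avg_fold)
    direction = np.where(mean_l2 > 0, "up", np.where(mean_l2 < 0, "down", "flat"))
    return pd.DataFrame(
        {
            "n_de_pairs": n_de,
            "mean_log2ratio": mean_l2,
            "direction": direction,
            "mixed": mixed,
            "is_recurrent": is_rec,
        },
        index=genes,
    )


def qpcr_concordance(delta_ct_tumor: pd.DataFrame,
                     delta_ct_normal: pd.DataFrame,
                     pair_results: dict[str, pd.DataFrame]) -> tuple[float, pd.DataFrame]:
    """Sign concordance between qPCR -ddCt and sequencing log2 ratios.

    ``delta_ct_*`` are gene x patient tables of dCt = Ct(gene) - Ct(reference);
    -ddCt = -(dCt_tumor - dCt_normal) estimates the tumor/normal log2
    expression ratio.  A gene x patient cell is concordant when
    sign(-ddCt) equals the sign of the sequencing log2 ratio of that
    pair.  Returns (concordant fraction, per-cell table).
    """
    if not delta_ct_tumor.index.equals(delta_ct_normal.index) or \
       not delta_ct_tumor.columns.equals(delta_ct_normal.columns):
        raise ValueError("tumor and normal dCt tables must share genes and patients")
    rows = []
    for patient in delta_ct_tumor.columns:
        if patient not in pair_results:
            raise KeyError(f"no sequencing results for patient {patient!r}")
        res = pair_results[patient]
        for gene in delta_ct_tumor.index:
            if gene not in res.index:
                raise KeyError(f"no log2ratio for gene {gene!r}, patient {patient!r}")
            neg_ddct = -(delta_ct_tumor.at[gene, patient] - delta_ct_normal.at[gene, patient])
            l2 = res.at[gene, "log2ratio"]
            rows.append(
                (gene, patient, neg_ddct, l2, bool(np.sign(neg_ddct) == np.sign(l2)))
            )
    table = pd.DataFrame(
        rows, columns=["gene_id", "patient", "neg_ddct", "log2ratio", "concordant"]
    )
    return float(table["concordant"].mean()), table
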