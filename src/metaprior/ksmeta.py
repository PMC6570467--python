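"""Per-gene p-value meta-analysis against a Uniform(0,1) null.

For each gene, the raw p-values it obtained across studies are compared to
the uniform distribution with a one-sample Kolmogorov-Smirnov test. The
one-sided statistic D+ (the largest positive excursion of the empirical CDF
above the uniform CDF) captures enrichment of small p-values, i.e.
consistent differential expression across studies. With at most a handful of
studies per gene the asymptotic KS tail is invalid, so the exact
Birnbaum-Tingey (Smirnov) finite-sample tail is used:

    P(D+ >= d) = d * sum_{j=0}^{floor(n(1-d))}
                 C(n,j) (d + j/n)^(j-1) (1 - d - j/n)^(n-j)

which reduces to (1-d)^n when floor(n(1-d)) = 0 and reaches magnitudes of
1e-15 for n = 10 highly consistent studies. For a single study the statistic
degenerates to D+ = 1 - p and the meta p-value to p itself.
"""

from __future__ import annotations

import logging
from math import comb, floor

import numpy as np
import pandas as pd
from scipy import stats

from .diffstat import DiffTable

logger = logging.getLogger(__name__)


def ks_dplus(pvals) -> float:
    """One-sided KS statistic D+ = max_i (i/n - p_(i)), floored at 0."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    p = np.sort(p)
    n = p.size
    return float(max(0.0, np.max(np.arange(1, n + 1) / n - p)))


def ks_exact_p(d: float, n: int) -> float:
    """Exact one-sided tail P(D+ >= d) for sample size n (Birnbaum-Tingey)."""
    if not 0.0 <= d <= 1.0:
        raise ValueError("d must lie in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    if d == 0.0:
        return 1.0
    jmax = floor(n * (1.0 - d))
    total = 0.0
    for j in range(jmax + 1):
        a = d + j / n
        b = 1.0 - d - j / n
        if j == 0:
            term = a ** (-1) * (b ** n if b > 0 else 0.0)
        else:
            term = comb(n, j) * a ** (j - 1) * (b ** (n - j) if b > 0 else
                                                (1.0 if n == j else 0.0))
        total += term
    return float(min(1.0, max(0.0, d * total)))


def ks_two_sided_p(d: float, n: int) -> float:
    """Exact two-sided tail P(D >= d); available as an alternative mode."""
    return float(stats.kstwo.sf(d, n))


def meta_analyze(diff_tables: list[DiffTable], gene_universe: set[str],
                 min_studies: int = 3, two_sided: bool = False
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """KS meta-analysis of per-study raw p-values for each gene.

    Returns ``(meta, insufficient)``: ``meta`` has one row per gene of the
    universe measured in at least ``min_studies`` studies, with columns
    gene, n_studies, d_plus, meta_p, sorted ascending by (meta_p, gene);
    ``insufficient`` lists the remaining genes with their study counts rather
    than silently dropping them.
    """
    if not diff_tables:
        raise ValueError("at least one differential table required")
    if min_studies < 1:
        raise ValueError("min_studies must be >= 1")
    if not gene_universe:
        logger.warning("empty gene universe; no meta-analysis performed")

    pvecs: dict[str, list[float]] = {g: [] for g in gene_universe}
    for dt in diff_tables:
        sub = dt.table[dt.table["feature"].isin(pvecs)]
        for feat, p in zip(sub["feature"], sub["raw_p"]):
            pvecs[feat].append(float(p))

    rows, short = [], []
    for gene in sorted(pvecs):
        pv = pvecs[gene]
        if len(pv) < min_studies:
            short.append((gene, len(pv)))
            continue
        if two_sided:
            d = float(stats.ks_1samp(pv, stats.uniform.cdf,
                                     alternative="two-sided").statistic)
            p = ks_two_sided_p(d, len(pv))
        else:
            d = ks_dplus(pv)
            p = ks_exact_p(d, len(pv))
        rows.append((gene, len(pv), d, p))

    meta = pd.DataFrame(rows, columns=["gene", "n_studies", "d_plus", "meta_p"])
    meta = meta.sort_values(["meta_p", "gene"], ignore_index=True)
    insufficient = pd.DataFrame(short, columns=["gene", "n_studies"])
    return meta, insufficient


def write_meta_tsv(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_meta_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
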