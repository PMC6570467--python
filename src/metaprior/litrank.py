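"""Literature-count retrieval and candidate-gene prioritization.

The final ranking takes the most significant genes of the meta-analysis,
attaches their single-cohort gene/protein p-values where available, and
flags genes as under-studied when fewer than a threshold number of PubMed
abstracts (default 5) match ``"<SYMBOL>" AND "breast cancer"``. Counts come
from a fixture TSV in tests and offline runs; a live NCBI eutils mode is
provided for real use and caches its results.
"""

from __future__ import annotations

import json
import logging
import time
import urllib.parse
import urllib.request
from pathlib import Path

import numpy as np
import pandas as pd

from .diffstat import DiffTable

logger = logging.getLogger(__name__)

QUERY_TEMPLATE = '"{symbol}" AND "breast cancer"'
EUTILS_ESEARCH = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/esearch.fcgi"
UNDERSTUDIED_DEFAULT = 5  # fewer than five abstracts


def _live_count(symbol: str, delay: float = 0.4) -> int | None:
    query = QUERY_TEMPLATE.format(symbol=symbol)
    url = (EUTILS_ESEARCH + "?"
           + urllib.parse.urlencode({"db": "pubmed", "term": query,
                                     "retmode": "json", "rettype": "count"}))
    try:
        with urllib.request.urlopen(url, timeout=30) as resp:
            payload = json.load(resp)
        time.sleep(delay)
        return int(payload["esearchresult"]["count"])
    except Exception as exc:  # network failure -> unavailable, never a fake 0
        logger.warning("eutils lookup failed for %s: %s", symbol, exc)
        return None


def fetch_counts(genes: list[str], source: str = "fixture",
                 fixture: pd.DataFrame | str | Path | None = None,
                 cache_path: str | Path | None = None) -> pd.DataFrame:
    """One LitCount row per gene: gene, n_papers (nullable), query, source_tag.

    ``source="fixture"`` reads counts from a (gene, n_papers) TSV or frame;
    genes absent from the fixture are marked unavailable (NA), which is
    distinct from a genuine zero-result count. ``source="live"`` queries NCBI
    eutils, caching results to ``cache_path`` as JSON.
    """
    if source not in ("fixture", "live"):
        raise ValueError(f"unknown source {source!r}")
    counts: dict[str, int | None]
    if source == "fixture":
        if fixture is None:
            raise ValueError("fixture mode requires a counts table")
        if not isinstance(fixture, pd.DataFrame):
            fixture = pd.read_csv(fixture, sep="\t")
        counts = {str(g): int(c)
                  for g, c in zip(fixture["gene"], fixture["n_papers"])}
        tag = "fixture"
    else:
        cache: dict[str, int] = {}
        if cache_path and Path(cache_path).exists():
            cache = json.loads(Path(cache_path).read_text())
        counts = {}
        for g in genes:
            counts[g] = cache[g] if g in cache else _live_count(g)
            if counts[g] is not None:
                cache[g] = counts[g]
        if cache_path:
            Path(cache_path).write_text(json.dumps(cache, sort_keys=True))
        tag = "live:" + time.strftime("%Y-%m-%d")

    rows = [(g, counts.get(g), QUERY_TEMPLATE.format(symbol=g), tag)
            for g in genes]
    df = pd.DataFrame(rows, columns=["gene", "n_papers", "query", "source_tag"])
    df["n_papers"] = df["n_papers"].astype("Int64")
    return df


def _p_lookup(diff: DiffTable | None,
              id_map: dict[str, str] | None = None) -> dict[str, float]:
    if diff is None:
        return {}
    out = {}
    for row in diff.table.itertuples(index=False):
        gene = id_map.get(row.feature, None) if id_map else row.feature
        if gene is not None:
            out[gene] = float(row.raw_p)
    return out


def prioritize(meta: pd.DataFrame, counts: pd.DataFrame,
               diff_gene: DiffTable | None = None,
               diff_protein: DiffTable | None = None,
               protein_gene_map: dict[str, str] | None = None,
               threshold: int = UNDERSTUDIED_DEFAULT,
               top_n: int = 50) -> pd.DataFrame:
    """Rank the top genes by meta-analysis p-value and flag under-studied ones.

    Rows are the ``top_n`` smallest meta_p genes (ties broken by gene
    symbol); each carries the single-cohort gene/protein raw p-values where
    measured (NaN where absent), the literature count, ``understudied``
    (count available and < threshold) and ``count_available``.
    """
    if meta.empty:
        raise ValueError("meta-analysis table is empty")
    ranked = meta.sort_values(["meta_p", "gene"], ignore_index=True).head(top_n)
    cmap = dict(zip(counts["gene"], counts["n_papers"]))
    gene_p = _p_lookup(diff_gene)
    prot_p = _p_lookup(diff_protein, protein_gene_map)

    out = ranked.copy()
    out["rank"] = np.arange(1, len(out) + 1)
    out["cohort_gene_p"] = [gene_p.get(g, np.nan) for g in out["gene"]]
    out["cohort_protein_p"] = [prot_p.get(g, np.nan) for g in out["gene"]]
    n_papers = [cmap.get(g, pd.NA) for g in out["gene"]]
    out["n_papers"] = pd.array(n_papers, dtype="Int64")
    out["count_available"] = out["n_papers"].notna()
    out["understudied"] = (out["n_papers"] < threshold).fillna(False)
    unavailable = int((~out["count_available"]).sum())
    if unavailable:
        logger.warning("%d prioritized genes lack a literature count and are "
                       "excluded from the under-studied set", unavailable)
    cols = ["rank", "gene", "n_studies", "d_plus", "meta_p",
            "cohort_gene_p", "cohort_protein_p", "n_papers",
            "understudied", "count_available"]
    return out[cols]


def cross_omics_protein_support(prot_diff: DiffTable, meta: pd.DataFrame,
                                counts: pd.DataFrame,
                                protein_gene_map: dict[str, str],
                                alpha: float = 0.05) -> pd.DataFrame:
    """Proteins significant in proteomics whose genes are also significant in
    the meta-analysis, partitioned by direction and annotated with counts.

    Unmapped proteins are reported (logged) and excluded.
    """
    meta_p = dict(zip(meta["gene"], meta["meta_p"]))
    cmap = dict(zip(counts["gene"], counts["n_papers"]))
    rows, unmapped = [], []
    for row in prot_diff.table.itertuples(index=False):
        gene = protein_gene_map.get(row.feature)
        if gene is None:
            unmapped.append(row.feature)
            continue
        if row.raw_p < alpha and meta_p.get(gene, 1.0) < alpha:
            rows.append((row.feature, gene, row.raw_p, row.fold_change,
                         row.direction, meta_p[gene], cmap.get(gene, pd.NA)))
    if unmapped:
        logger.warning("%d proteins lacked a gene mapping and were excluded",
                       len(unmapped))
    out = pd.DataFrame(rows, columns=["protein", "gene", "protein_p",
                                      "fold_change", "direction", "meta_p",
                                      "n_papers"])
    out["n_papers"] = out["n_papers"].astype("Int64")
    return out.sort_values(["direction", "meta_p", "gene"],
                           ascending=[False, True, True], ignore_index=True)


def write_priority_tsv(priorities: pd.DataFrame, path) -> None:
    out = priorities.copy()
    # Table-style rendering: '-' marks proteins absent from the proteomics set
    out["cohort_protein_p"] = [
        "-" if pd.isna(v) else f"{v:.6g}" for v in out["cohort_protein_p"]]
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")
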