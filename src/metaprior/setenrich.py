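"""Hypergeometric over-representation analysis over pathway sets.

Tests whether a selected feature list overlaps a pathway more than expected
from drawing the same number of features from the measured universe, with
Benjamini-Hochberg correction across pathways. The multi-omics variant pools
gene, protein and metabolite lists into a shared pathway namespace and flags,
per pathway, which omics layers contribute overlapping members.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

OMICS = ("gene", "protein", "metabolite")


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper tail P(X >= k), X ~ Hypergeometric(N population, K marked, n drawn)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts K={K}, n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"overlap k={k} outside [0, min(K={K}, n={n})]")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def read_gmt(path: str | Path) -> dict[str, tuple[str, set[str]]]:
    db: dict[str, tuple[str, set[str]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        pid, name, members = parts[0], parts[1], set(parts[2:])
        if pid in db:
            raise ValueError(f"duplicate pathway id {pid}")
        db[pid] = (name, members)
    return db


def enrich(selected: set[str], universe: set[str],
           db: dict[str, tuple[str, set[str]]]) -> tuple[pd.DataFrame, dict]:
    """One-sided over-representation of ``selected`` within ``universe``.

    Pathway sizes are counted within the universe; pathways with no universe
    member are not tested but reported, as are universe features unmapped to
    any pathway. Returns (records sorted by (p, pathway), report dict).
    """
    if not selected <= universe:
        raise ValueError("selected must be a subset of the universe")
    if not selected:
        logger.warning("empty selected set; all p-values will be 1")
    N, n = len(universe), len(selected)

    mapped: set[str] = set()
    rows, untested = [], []
    for pid in sorted(db):
        name, members = db[pid]
        in_uni = members & universe
        mapped |= in_uni
        if not in_uni:
            untested.append(pid)
            continue
        K = len(in_uni)
        k = len(members & selected)
        rows.append((pid, name, k, K, n, N, hypergeom_tail(k, K, n, N)))

    rec = pd.DataFrame(rows, columns=["pathway", "name", "k", "K", "n", "N", "p"])
    if len(rec):
        rec["q"] = multipletests(rec["p"].to_numpy(), method="fdr_bh")[1]
        rec = rec.sort_values(["p", "pathway"], ignore_index=True)
    else:
        rec["q"] = pd.Series(dtype=float)
    report = {
        "unmapped_features": sorted(universe - mapped),
        "n_unmapped": len(universe - mapped),
        "untested_pathways": untested,
    }
    if report["n_unmapped"]:
        logger.info("%d universe features could not be mapped to any pathway "
                    "and were discarded", report["n_unmapped"])
    return rec, report


def multiomics_enrich(selections: dict[str, set[str]],
                      universes: dict[str, set[str]],
                      db: dict[str, tuple[str, set[str]]],
                      id_maps: dict[str, dict[str, str]] | None = None,
                      mode: str = "pooled") -> tuple[pd.DataFrame, dict]:
    """Joint multi-omics over-representation with per-omics support flags.

    ``selections``/``universes`` map omics name (gene/protein/metabolite) to
    feature-id sets; ``id_maps[omics]`` translates that omics' ids into the
    pathway namespace (identity where omitted). ``mode="pooled"`` (default)
    unions the mapped ids into one test per pathway; ``mode="per_omics"``
    tests each omics separately and combines p-values by Fisher's method.
    Either way the ``support`` column lists which omics contribute at least
    one overlapping selected member (the three-color semantics: all three /
    genes+proteins / genes only).
    """
    if mode not in ("pooled", "per_omics"):
        raise ValueError(f"unknown mode {mode!r}")
    id_maps = id_maps or {}
    mapped_sel: dict[str, set[str]] = {}
    mapped_uni: dict[str, set[str]] = {}
    for omics in selections:
        if omics not in universes:
            logger.warning("no universe for omics %r; excluded", omics)
            continue
        m = id_maps.get(omics)
        if m is None:
            mapped_sel[omics] = set(selections[omics])
            mapped_uni[omics] = set(universes[omics])
        else:
            mapped_sel[omics] = {m[i] for i in selections[omics] if i in m}
            mapped_uni[omics] = {m[i] for i in universes[omics] if i in m}
            dropped = len(selections[omics]) - len(
                {i for i in selections[omics] if i in m})
            if dropped:
                logger.warning("%d %s ids lacked an id-mapping", dropped, omics)

    if not any(mapped_sel.values()):
        logger.warning("all omics selections empty after mapping")
        return pd.DataFrame(columns=["pathway", "name", "k", "K", "n", "N",
                                     "p", "q", "support"]), {}

    joint_uni = set().union(*mapped_uni.values())
    joint_sel = set().union(*mapped_sel.values())

    if mode == "pooled":
        rec, report = enrich(joint_sel, joint_uni, db)
    else:
        per = {o: enrich(mapped_sel[o], mapped_uni[o], db)[0].set_index("pathway")
               for o in mapped_sel if mapped_uni[o]}
        rows = []
        for pid in sorted(db):
            ps = [per[o].loc[pid, "p"] for o in per if pid in per[o].index]
            if not ps:
                continue
            name, members = db[pid]
            k = len(members & joint_sel)
            K = len(members & joint_uni)
            p = float(stats.combine_pvalues(ps, method="fisher").pvalue)
            rows.append((pid, name, k, K, len(joint_sel), len(joint_uni), p))
        rec = pd.DataFrame(rows, columns=["pathway", "name", "k", "K", "n",
                                          "N", "p"])
        rec["q"] = multipletests(rec["p"].to_numpy(), method="fdr_bh")[1] \
            if len(rec) else pd.Series(dtype=float)
        rec = rec.sort_values(["p", "pathway"], ignore_index=True)
        report = {}

    support = []
    for pid in rec["pathway"]:
        members = db[pid][1]
        support.append("+".join(o for o in OMICS
                                if o in mapped_sel and members & mapped_sel[o]))
    rec = rec.assign(support=support)
    return rec, report


def write_enrich_tsv(rec: pd.DataFrame, path) -> None:
    rec.to_csv(path, sep="\t", index=False, float_format="%.6g")
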