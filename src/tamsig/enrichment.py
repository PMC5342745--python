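"""Hypergeometric over-representation analysis over GMT gene-set collections.

A generic one-sided enrichment stands in for GO-style annotation of the
signature: for each set, the upper-tail hypergeometric probability of the
observed overlap with the query, conditioned on the tested universe (the
purity-filtered gene list, not the whole annotation — conditioning on the
expression filter is the standard guard against filter bias).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_fdr


def read_gmt(path) -> dict:
    """Parse a GMT file (name TAB description TAB gene...) into an ordered
    name -> gene-list mapping.  Duplicate genes within a set are dropped;
    malformed lines raise with their line number."""
    sets = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line {lineno}: "
                                 "expected name, description, >=1 gene")
            name = parts[0]
            if name in sets:
                raise ValueError(f"duplicate set name {name!r} at line {lineno}")
            genes = list(dict.fromkeys(g for g in parts[2:] if g))
            if not genes:
                raise ValueError(f"empty gene set {name!r} at line {lineno}")
            sets[name] = genes
    return sets


def write_gmt(sets: dict, path, descriptions: dict | None = None) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def hypergeom_enrich(query, universe, sets: dict,
                     min_overlap_frac: float = 0.0) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``query`` in each set.

    p = P(X >= k) with universe size N, set size K (after intersecting the
    set with the universe), query size n and overlap k.  Sets overlapping
    less than ``min_overlap_frac`` of the query are excluded before
    testing; BH q-values are computed across the tested sets.
    """
    query = set(query)
    universe = set(universe)
    if not query <= universe:
        extra = sorted(query - universe)[:3]
        raise ValueError(f"query genes outside the universe, e.g. {extra}")
    N, n = len(universe), len(query)
    rows = []
    for name, genes in sets.items():
        members = set(genes) & universe
        K = len(members)
        k = len(members & query)
        if n > 0 and k / n < min_overlap_frac:
            continue
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append({"set": name, "overlap": k, "set_size": K, "p": min(p, 1.0)})
    table = pd.DataFrame(rows)
    if len(table):
        table["q"] = bh_fdr(table["p"].to_numpy())
        table = table.sort_values(["p", "set"]).set_index("set")
    return table
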