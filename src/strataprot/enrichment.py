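"""GO biological-process over-representation of prognostic protein sets.

For a hit set of n proteins drawn from a measured universe of N proteins,
a term annotating K universe proteins with k of them in the hit set is
scored by the hypergeometric upper tail p = P(X >= k),
X ~ Hypergeometric(N, K, n), followed by Benjamini-Hochberg adjustment
across the tested terms and top-k reporting of significant terms.

The default universe is the set of proteins surviving the presence
filter — the measured background — rather than a whole-annotation
universe; pass ``universe=None`` helpers accordingly if the
whole-annotation behaviour is wanted.
"""

from __future__ import annotations

import logging

import pandas as pd
from scipy.stats import hypergeom

from .data_io import AnnotationTable, ValidationError
from .diffabund import bh_adjust

logger = logging.getLogger("strataprot")

ENRICHMENT_COLUMNS = ["go_id", "description", "k", "K", "n", "N", "p", "q",
                      "hit_proteins"]


def hypergeom_ora(hits: set[str] | list[str], universe: set[str] | list[str],
                  annotation: AnnotationTable, min_term_size: int = 3,
                  max_term_size: int = 500) -> pd.DataFrame:
    """Hypergeometric over-representation of ``hits`` against every term.

    ``hits`` must be a subset of ``universe``; the annotation is
    restricted to the universe before term sizes are computed. Terms with
    restricted size outside [min_term_size, max_term_size] are not tested.
    Rows are sorted by q then p.
    """
    hits = set(hits)
    universe = set(universe)
    if not hits:
        logger.warning("hypergeom_ora: empty hit set")
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)
    stray = sorted(hits - universe)
    if stray:
        raise ValidationError(f"hit proteins outside the universe: {stray}")
    if not annotation.term_to_proteins:
        raise ValidationError("empty annotation: nothing to test")
    N = len(universe)
    n = len(hits)
    rows = []
    for term, members in annotation.term_to_proteins.items():
        in_universe = members & universe
        K = len(in_universe)
        if not min_term_size <= K <= max_term_size:
            continue
        hit_members = sorted(in_universe & hits)
        k = len(hit_members)
        p = float(hypergeom.sf(k - 1, N, K, n))  # P(X >= k)
        rows.append((term, annotation.descriptions.get(term, ""), k, K, n, N, p,
                     ";".join(hit_members)))
    if not rows:
        logger.warning("hypergeom_ora: no terms within size bounds [%d, %d]",
                       min_term_size, max_term_size)
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)
    df = pd.DataFrame(rows, columns=["go_id", "description", "k", "K", "n", "N",
                                     "p", "hit_proteins"])
    df["q"] = bh_adjust(df["p"].to_numpy())
    df = df.sort_values(["q", "p", "go_id"], kind="stable").reset_index(drop=True)
    return df[ENRICHMENT_COLUMNS]


def top_terms(table: pd.DataFrame, k: int = 5,
              fdr_threshold: float = 0.05) -> pd.DataFrame:
    """The k most significant terms passing the FDR threshold (fewer if
    fewer pass)."""
    if table.empty:
        return table
    sig = table[table["q"] < fdr_threshold]
    return sig.head(k).reset_index(drop=True)


def annotate_daps_in_terms(terms: pd.DataFrame, da_table: pd.DataFrame) -> pd.DataFrame:
    """Mark which term-member proteins are DAPs in a given comparison.

    One row per (term, member protein) with the protein's DA call
    ('up'/'down'/'ns'/'untestable'), or 'not tested' for members absent
    from the DA table.
    """
    calls = dict(zip(da_table["protein_id"], da_table["call"]))
    rows = []
    for _, t in terms.iterrows():
        members = t["hit_proteins"].split(";") if t["hit_proteins"] else []
        for m in members:
            rows.append((t["go_id"], t["description"], m,
                         calls.get(m, "not tested")))
    return pd.DataFrame(rows, columns=["go_id", "description", "protein_id",
                                       "da_call"])
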