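"""Over-representation analysis (ORA) against user-supplied set collections.

For a query set of size n drawn from a background of size N, the overlap k
with an annotated set of size K is tested against the hypergeometric upper
tail P(X >= k).  P-values are BH-adjusted *within each category* (pathway
collections, miRNA-function collections, ... are corrected independently).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom

from .diffexpr import bh_adjust

log = logging.getLogger(__name__)

ENRICHMENT_COLUMNS = ["set_id", "k", "K", "n", "N", "p_value", "p_adj", "significant"]


@dataclass(frozen=True)
class SetCollection:
    """A named category of annotated sets over a background universe.

    Member IDs outside the background are dropped at construction (the
    standard ORA restriction); sets left empty are removed.
    """

    category: str
    sets: dict
    background: frozenset

    @classmethod
    def from_dict(cls, category: str, sets: dict, background) -> "SetCollection":
        bg = frozenset(background)
        if not bg:
            raise ValueError("background universe is empty")
        trimmed = {}
        for set_id, members in sets.items():
            inside = frozenset(members) & bg
            dropped = len(frozenset(members)) - len(inside)
            if dropped:
                log.info("set %s: %d members outside background dropped", set_id, dropped)
            if inside:
                trimmed[set_id] = inside
        return cls(category=category, sets=trimmed, background=bg)


def ora_test(query, collection: SetCollection, alpha: float = 0.05) -> pd.DataFrame:
    """Hypergeometric upper-tail ORA of ``query`` against a collection.

    Query IDs outside the background are dropped (logged); a fully
    disjoint query is an error naming the ID-space mismatch.  Rows are
    sorted by ``p_adj`` then ``p_value`` then set ID.
    """
    q = frozenset(query)
    inside = q & collection.background
    if not inside:
        raise ValueError(
            f"query shares no IDs with the {collection.category!r} background; "
            "check that query and collection use the same ID space"
        )
    dropped = len(q) - len(inside)
    if dropped:
        log.info("query: %d IDs outside background dropped", dropped)
    n, big_n = len(inside), len(collection.background)
    rows = []
    for set_id in sorted(collection.sets):
        members = collection.sets[set_id]
        k, big_k = len(inside & members), len(members)
        p = float(hypergeom.sf(k - 1, big_n, big_k, n))
        rows.append((set_id, k, big_k, n, big_n, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["set_id", "k", "K", "n", "N", "p_value"])
    df["p_adj"] = bh_adjust(df["p_value"].values)
    df["significant"] = df["p_adj"] <= alpha
    return df.sort_values(["p_adj", "p_value", "set_id"]).reset_index(drop=True)


def read_gmt(path, category: str, background) -> SetCollection:
    """Read a GMT file (set_id <TAB> description <TAB> members...)."""
    sets: dict = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            sets[parts[0]] = frozenset(p for p in parts[2:] if p)
    return SetCollection.from_dict(category, sets, background)
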