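"""Hypergeometric overlap tests and term enrichment with BH adjustment.

Two uses in the screen: (i) is the overlap between a candidate drug's
down-regulated DEGs and the disease up-regulated DEGs larger than chance,
and (ii) which annotation terms (mechanism-of-action classes over the
top-k drugs, or pathway gene sets over a DEG list) are over-represented
in a query set. Both reduce to the upper tail of a hypergeometric
distribution; families of term tests are corrected by Benjamini-Hochberg.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def hypergeometric_overlap_p(k: int, n1: int, n2: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, n1, n2).

    The null: draw a subset of size n2 uniformly from a universe of N
    items of which n1 are marked; X counts marked draws. Over-enrichment
    only (the lower tail is not offered).
    """
    if not (0 <= k <= min(n1, n2) <= N) or min(n1, n2) < 0:
        raise ValueError(f"inconsistent counts k={k}, n1={n1}, n2={n2}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, n1, n2))


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def term_enrichment(
    query: Iterable[str],
    annotations: Mapping[str, Iterable[str]],
    background: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric enrichment of each annotation term in a query set.

    Each term's member set is intersected with the background before
    testing; terms sharing no member with the query are excluded, and BH
    adjustment runs over the tested (k >= 1) terms. Columns: term, k
    (overlap), K (term size in background), n (query size), N (background
    size), p_value, p_adjusted; sorted by ascending p then term.
    """
    background = set(background)
    if not background:
        raise ValueError("background set is empty")
    query = set(query)
    if not query <= background:
        extra = sorted(query - background)
        raise ValueError(f"query ids outside background: {extra[:5]}")
    N, n = len(background), len(query)
    records = []
    for term in sorted(annotations):
        members = set(annotations[term]) & background
        k = len(members & query)
        if k == 0:
            continue
        K = len(members)
        records.append(
            {
                "term": term,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p_value": hypergeometric_overlap_p(k, K, n, N),
            }
        )
    df = pd.DataFrame.from_records(
        records, columns=["term", "k", "K", "n", "N", "p_value"]
    )
    if len(df):
        df["p_adjusted"] = bh_adjust(df["p_value"])
    else:
        df["p_adjusted"] = pd.Series(dtype=float)
    df = df.sort_values(["p_value", "term"], kind="mergesort").reset_index(drop=True)
    return df


def moa_annotations(moa_table: pd.DataFrame) -> dict[str, set[str]]:
    """Invert a (drug_id, moa) table into term -> drug-id sets."""
    for col in ("drug_id", "moa"):
        if col not in moa_table.columns:
            raise ValueError(f"MOA table missing column {col!r}")
    out: dict[str, set[str]] = {}
    for drug, term in zip(moa_table["drug_id"].astype(str), moa_table["moa"].astype(str)):
        out.setdefault(term, set()).add(drug)
    return out


def write_enrichment_table(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["neg_log10_p_adjusted"] = -np.log10(out["p_adjusted"])
    out.to_csv(path, sep="\t", index=False)
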