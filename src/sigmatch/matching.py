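"""Jaccard reversal scoring of disease signatures against a drug library.

The reversal score between a disease signature and one drug signature is
the Jaccard index J = |A ∩ B| / |A ∪ B| between the disease *up*-regulated
DEGs and the drug *down*-regulated DEGs: a drug that switches off what the
disease switches on. A drug appears under many conditions (cell line,
dose, time); only its highest-scoring condition counts. With several
disease signatures, each contributes its own per-drug best score and the
drug is ranked by the arithmetic mean of those.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from .signatures import DiseaseSignature, Signature


class UndefinedScoreError(ValueError):
    """Jaccard of two empty sets is undefined."""


def jaccard(set_a: Iterable[str], set_b: Iterable[str]) -> float:
    """Jaccard index |A∩B|/|A∪B|; raises if both sets are empty."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        raise UndefinedScoreError("Jaccard of two empty sets is undefined")
    return len(a & b) / len(union)


def best_score_for_drug(
    disease_up: Iterable[str], drug_signatures: Sequence[Signature]
) -> float:
    """Max Jaccard(disease up, signature down) over a drug's conditions.

    Signatures with an empty down set contribute 0; the score is taken
    regardless of cell line, dose, and time point.
    """
    if not drug_signatures:
        raise ValueError("drug has no signatures")
    disease_up = set(disease_up)
    best = 0.0
    for sig in drug_signatures:
        if not sig.down_set or not disease_up:
            continue
        best = max(best, jaccard(disease_up, sig.down_set))
    return best


def score_library(
    disease_signatures: Sequence[DiseaseSignature],
    library: Sequence[Signature],
    symmetric: bool = False,
) -> pd.DataFrame:
    """Score every drug in the library against every disease signature.

    Before scoring, each comparison is restricted to the intersection of
    the disease and drug-signature gene universes, so universe mismatch
    cannot deflate unions asymmetrically. Per drug and disease signature
    the best score over conditions is kept; the drug's ``average_score``
    is the arithmetic mean over disease signatures, and ranks run 1..n in
    descending average (ties broken lexicographically by drug_id). A drug
    whose comparable universe is empty for some disease signature still
    scores (possibly 0) and is never dropped.

    With ``symmetric=True`` each signature's score is the mean of the
    up-disease/down-drug and down-disease/up-drug Jaccard terms.
    """
    if not disease_signatures:
        raise ValueError("need at least one disease signature")
    if not library:
        raise ValueError("signature library is empty")
    for dis in disease_signatures:
        if not dis.up_set:
            raise ValueError(f"disease signature {dis.name!r} has an empty up set")
    names = [d.name for d in disease_signatures]
    if len(set(names)) != len(names):
        raise ValueError("disease signature names must be unique")

    by_drug: dict[str, list[Signature]] = {}
    for sig in library:
        by_drug.setdefault(sig.drug_id, []).append(sig)

    records = []
    for drug_id in sorted(by_drug):
        row: dict[str, object] = {"drug_id": drug_id}
        scores = []
        for dis in disease_signatures:
            best = 0.0
            for sig in by_drug[drug_id]:
                common = dis.gene_universe & set(sig.gene_universe)
                s = _pair_score(dis, sig, common, symmetric)
                best = max(best, s)
            row[f"score_{dis.name}"] = best
            scores.append(best)
        row["average_score"] = sum(scores) / len(scores)
        records.append(row)

    df = pd.DataFrame.from_records(records)
    df = df.sort_values(
        ["average_score", "drug_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    df["rank"] = range(1, len(df) + 1)
    return df


def _pair_score(
    dis: DiseaseSignature, sig: Signature, common: set[str], symmetric: bool
) -> float:
    up = dis.up_set & common
    dn = sig.down_set & common
    fwd = jaccard(up, dn) if (up or dn) else 0.0
    if not symmetric:
        return fwd
    d_dn = dis.down_set & common
    s_up = sig.up_set & common
    rev = jaccard(d_dn, s_up) if (d_dn or s_up) else 0.0
    return 0.5 * (fwd + rev)


def top_k(table: pd.DataFrame, k: int) -> pd.DataFrame:
    """First k rows of a ranked reversal-score table."""
    if not 1 <= k <= len(table):
        raise ValueError(f"k={k} outside 1..{len(table)}")
    return table.iloc[:k].reset_index(drop=True)


def write_score_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_score_table_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("drug_id", "average_score", "rank"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    df["drug_id"] = df["drug_id"].astype(str)
    return df
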