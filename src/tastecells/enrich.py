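"""Gene-set (GO-style) enrichment by chi-square proportion test.

Each term is tested with a 2x2 contingency table of (in experimental list)
x (in term), using the Pearson chi-square with 1 df and no continuity
correction. The comparison column is the background *excluding* the list,
which avoids counting list genes on both sides of the proportion. Terms are
ranked by enrichment score -log10(p); the screen keeps terms with raw
p < 1e-3 (no multiple-testing correction at this stage, matching the
screen-then-summarize workflow this mirrors).

``summarize_redundancy`` collapses overlapping terms by single-linkage
clustering on the Jaccard similarity of their member sets — a gene-overlap
surrogate for semantic (ontology-graph) similarity.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = ["chi2_2x2", "enrich", "summarize_redundancy"]


def chi2_2x2(a: float, b: float, c: float, d: float) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) for a 2x2 table.

    chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)); returns (chi2, p).
    Degenerate margins give (0, 1).
    """
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0, 1.0
    chi2 = n * (a * d - b * c) ** 2 / denom
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def _term_members(annotation: pd.DataFrame) -> Mapping[str, set]:
    for col in ("term_id", "gene_id"):
        if col not in annotation.columns:
            raise ValueError(f"annotation is missing column {col!r}")
    return {t: set(g["gene_id"]) for t, g in annotation.groupby("term_id", sort=True)}


def enrich(
    gene_list: Sequence[str],
    background: Sequence[str],
    annotation: pd.DataFrame,
    p_cutoff: float = 1e-3,
    inclusive_background: bool = False,
) -> pd.DataFrame:
    """Test every annotated term for over/under-representation in the list.

    ``background`` is the declared gene universe (the experimental list must
    be a subset of it). By default the comparison column of each 2x2 table is
    background minus list; ``inclusive_background=True`` keeps list genes in
    the comparison column instead. Terms with no members in the universe are
    skipped with a warning. Returns a DataFrame sorted by enrichment score
    (-log10 p) with the 2x2 counts, chi2, p, direction and a ``significant``
    flag at ``p_cutoff``.
    """
    lst = set(gene_list)
    uni = set(background)
    missing = lst - uni
    if missing:
        raise ValueError(
            f"{len(missing)} list gene(s) absent from background, e.g. {sorted(missing)[:5]}"
        )
    names = (
        annotation.drop_duplicates("term_id").set_index("term_id")["term_name"]
        if "term_name" in annotation.columns
        else None
    )
    comparison = uni if inclusive_background else (uni - lst)
    rows = []
    for term_id, members in _term_members(annotation).items():
        members = members & uni
        if not members:
            warnings.warn(f"term {term_id!r} has no members in the universe; skipped", stacklevel=2)
            continue
        a = len(lst & members)  # list, in term
        b = len(lst) - a  # list, not in term
        c = len(comparison & members)
        d = len(comparison) - c
        chi2, p = chi2_2x2(a, b, c, d)
        prop_list = a / len(lst) if lst else 0.0
        prop_bg = c / max(len(comparison), 1)
        rows.append(
            dict(
                term_id=term_id,
                term_name=names.get(term_id, "") if names is not None else "",
                a=a,
                b=b,
                c=c,
                d=d,
                chi2=chi2,
                p_value=p,
                enrichment_score=-np.log10(max(p, np.finfo(float).tiny)),
                direction="over" if prop_list > prop_bg else "under",
                significant=p < p_cutoff,
            )
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "term_id", "term_name", "a", "b", "c", "d", "chi2",
            "p_value", "enrichment_score", "direction", "significant",
        ],
    )
    return out.sort_values(
        ["enrichment_score", "term_id"], ascending=[False, True]
    ).reset_index(drop=True)


def summarize_redundancy(
    results: pd.DataFrame,
    annotation: pd.DataFrame,
    gene_overlap_threshold: float = 0.7,
) -> pd.DataFrame:
    """Cluster overlapping terms and pick one representative per cluster.

    Single-linkage clustering on Jaccard similarity of term member sets;
    terms join a cluster when linked by overlap >= the threshold. The
    representative is the cluster's smallest p (ties broken by term_id).
    Adds ``cluster`` and ``representative`` columns.
    """
    res = results.reset_index(drop=True)
    if res.empty:
        return res.assign(cluster=pd.Series(dtype=int), representative=pd.Series(dtype=bool))
    members = _term_members(annotation)
    terms = res["term_id"].tolist()
    sets = [members.get(t, set()) for t in terms]
    n = len(terms)
    if n == 1:
        return res.assign(cluster=[1], representative=[True])
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            union = len(sets[i] | sets[j])
            jac = len(sets[i] & sets[j]) / union if union else 0.0
            dist[i, j] = dist[j, i] = 1.0 - jac
    z = linkage(squareform(dist, checks=False), method="single")
    clusters = fcluster(z, t=1.0 - gene_overlap_threshold, criterion="distance")
    res["cluster"] = clusters
    rep = np.zeros(n, dtype=bool)
    order = res.assign(_i=np.arange(n)).sort_values(["p_value", "term_id"])
    seen: set[int] = set()
    for _, row in order.iterrows():
        if row["cluster"] not in seen:
            rep[int(row["_i"])] = True
            seen.add(row["cluster"])
    res["representative"] = rep
    return res
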