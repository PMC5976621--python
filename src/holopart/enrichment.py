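"""Per-bin functional summaries.

Classic one-sided Fisher exact (hypergeometric upper-tail) term
enrichment of a focal member set against a background, normalised
log-transformed PFAM domain-count matrices for heatmap display, and
annotation-rate reporting with the rounded-percent convention.

Significance is flagged at raw p < alpha with no multiplicity
correction, matching common practice for descriptive GO summaries of
transcriptome bins; a Benjamini-Hochberg column is emitted alongside for
readers who want it, but it never drives the flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .pipeline_utils import percent

__all__ = [
    "fisher_enrichment",
    "domain_matrix",
    "annotation_rates",
]


class ConsistencyError(ValueError):
    pass


def fisher_enrichment(
    focal_members: Iterable[str],
    background_members: Iterable[str],
    term_map: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided over-representation test per term.

    For each term with c carriers among the background of size d, and a
    carriers within the focal set of size b, the enrichment p-value is
    the hypergeometric upper tail P(X >= a) with X ~ Hypergeom(d, c, b).

    Returns a DataFrame sorted by p with columns term_id, a, b, c, d,
    p_value, significant (raw p < alpha) and p_bh (Benjamini-Hochberg,
    supplementary only).
    """
    focal = set(focal_members)
    background = set(background_members)
    if not focal <= background:
        raise ConsistencyError("focal set must be a subset of the background")
    tm = term_map[term_map["member_id"].isin(background)]
    b, d = len(focal), len(background)
    rows = []
    for term, grp in tm.groupby("term_id"):
        carriers = set(grp["member_id"])
        a, c = len(carriers & focal), len(carriers)
        p = float(hypergeom.sf(a - 1, d, c, b))
        rows.append((term, a, b, c, d, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["term_id", "a", "b", "c", "d", "p_value"])
    df = df.sort_values(["p_value", "term_id"], ignore_index=True)
    df["significant"] = df["p_value"] < alpha
    df["p_bh"] = _benjamini_hochberg(df["p_value"].to_numpy())
    return df


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    if n == 0:
        return p
    order = np.argsort(p)
    adj = np.empty(n)
    adj[order] = np.minimum.accumulate((p[order] * n / np.arange(1, n + 1))[::-1])[::-1]
    return np.minimum(adj, 1.0)


def domain_matrix(
    domain_maps: Mapping[str, pd.DataFrame],
    peptide_counts: Mapping[str, int],
    focal: str | None = None,
    top_n: int = 30,
) -> pd.DataFrame:
    """Normalised, log-transformed domain-count matrix.

    Cell value = log10(1 + 10000 * count / peptide_count), i.e. domain
    occurrences per 10,000 peptides on a log scale, which removes
    library-size differences between columns.  Rows are restricted to the
    ``top_n`` domains most enriched (smallest Fisher p) in the ``focal``
    column against all other columns pooled; with no focal column every
    domain is kept.
    """
    for label, n in peptide_counts.items():
        if n <= 0:
            raise ValueError(f"peptide count for {label!r} must be positive")
    counts = pd.DataFrame({
        label: df.groupby("term_id")["member_id"].nunique()
        for label, df in domain_maps.items()
    }).fillna(0).astype(int)
    counts = counts[list(domain_maps)]

    if focal is not None:
        others = [c for c in counts.columns if c != focal]
        b = peptide_counts[focal]
        d = b + sum(peptide_counts[c] for c in others)
        pvals = {}
        for dom, row in counts.iterrows():
            a = int(row[focal])
            c = int(row.sum())
            pvals[dom] = float(hypergeom.sf(a - 1, d, c, b))
        ranked = sorted(counts.index, key=lambda x: (pvals[x], x))
        counts = counts.loc[ranked[:top_n]]

    mat = counts.astype(float).copy()
    for label in mat.columns:
        mat[label] = np.log10(1 + 1e4 * mat[label] / peptide_counts[label])
    mat.attrs["normalization"] = "log10(1 + 10000 * count / n_peptides)"
    return mat


def annotation_rates(
    bins: Mapping[str, Sequence[str]],
    annotated: Iterable[str],
) -> pd.DataFrame:
    """Annotated counts and rounded percentages per bin plus overall.

    ``bins`` maps bin label -> member ids; ``annotated`` is the set of
    ids with an annotation.  Percentages round half away from zero.
    """
    ann = set(annotated)
    universe = set()
    for members in bins.values():
        universe |= set(members)
    extra = ann - universe
    if extra:
        raise ConsistencyError(
            f"annotated ids outside any bin: {sorted(extra)[:3]}")
    rows = []
    for label, members in bins.items():
        m = set(members)
        n_ann = len(m & ann)
        rows.append((label, n_ann, len(m),
                     percent(n_ann, len(m)) if m else 0))
    rows.append(("overall", len(ann & universe), len(universe),
                 percent(len(ann & universe), len(universe)) if universe else 0))
    return pd.DataFrame(rows, columns=["bin", "n_annotated", "n_total",
                                       "pct_annotated"])
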