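"""Phenotype-specificity scoring of transcription factors.

The central statistic is a Jensen–Shannon divergence between two
distributions over the (query + background) sample axis for one gene:

* P — the *idealized* phenotype-specific profile: probability 1 at the
  query sample, 0 everywhere else;
* Q — the observed profile: the gene's expression values scaled to sum 1.

JSD(P, Q) = H((P+Q)/2) − [H(P) + H(Q)]/2 with base-2 logarithms and the
0·log 0 := 0 convention, so it lives in [0, 1] bits: 0 means the gene is
expressed *only* in the query (perfectly phenotype-specific), 1 means the
query contributes nothing. The n_top TFs with the lowest JSD are the
identity (core) TFs.

Co-factors are TFs significantly more specific than expected by chance:
each background sample is treated in turn as a pseudo-query to build the
null distribution of JSDs, the real query's JSD is ranked against it, and
the rank is z-scored against the uniform rank distribution
(mean (N+1)/2, sd sqrt((N²−1)/12)). TFs with z < z_cut that are not
already identity TFs are called co-factors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SpecificityResult:
    tf: str
    jsd: float
    query_rank: int
    zscore: float
    call: str  # identity | cofactor | none


def _xlog2x(x: np.ndarray) -> np.ndarray:
    out = np.zeros_like(x, dtype=float)
    pos = x > 0
    out[pos] = x[pos] * np.log2(x[pos])
    return out


def jsd_specificity(expr_query: float, expr_background: Sequence[float]) -> float:
    """JSD (bits) between the idealized query-only profile and the observed
    expression profile over (query + background) samples.

    Returns 1.0 when the gene is expressed nowhere — an unexpressed TF is
    maximally non-specific.
    """
    bg = np.asarray(expr_background, dtype=float)
    if expr_query < 0 or (bg < 0).any():
        raise ValueError("negative expression values")
    w = np.concatenate(([float(expr_query)], bg))
    total = w.sum()
    if total == 0:
        return 1.0
    q = w / total
    # P is a point mass at index 0: H(P) = 0 and M = (P+Q)/2 differs from
    # Q/2 only at the query position.
    m = q / 2.0
    m[0] = (1.0 + q[0]) / 2.0
    h_m = -_xlog2x(m).sum()
    h_q = -_xlog2x(q).sum()
    return float(h_m - h_q / 2.0)


def background_pseudo_jsds(expr_background: Sequence[float]) -> np.ndarray:
    """Null JSDs: each background sample in turn acts as the pseudo-query
    against the remaining samples (the distribution spans all N samples).

    Vectorized: the observed profile Q is the same for every pseudo-query;
    only the point-mass position moves.
    """
    v = np.asarray(expr_background, dtype=float)
    if (v < 0).any():
        raise ValueError("negative expression values")
    n = v.size
    total = v.sum()
    if total == 0:
        return np.ones(n)
    q = v / total
    f = _xlog2x  # shorthand
    h_q = -f(q).sum()
    s_half = f(q / 2.0).sum()
    # H(M_s) = -[ f((1+q_s)/2) + sum_{j != s} f(q_j/2) ]
    h_m = -(f((1.0 + q) / 2.0) + s_half - f(q / 2.0))
    return h_m - h_q / 2.0


def cofactor_zscores(
    query_jsd: float, background_jsds: Sequence[float]
) -> Tuple[int, float]:
    """Rank of the query's JSD within the background null and its z-score
    on the uniform rank scale.

    rank = 1 + #(null JSDs strictly below query), clamped to [1, N] so the
    z stays on the background rank scale; z = (rank − (N+1)/2) /
    sqrt((N²−1)/12).
    """
    bg = np.asarray(background_jsds, dtype=float)
    n = bg.size
    if n < 2:
        raise ValueError("need at least 2 background JSDs (rank sd undefined)")
    rank = 1 + int((bg < query_jsd).sum())
    rank = min(rank, n)
    mean = (n + 1) / 2.0
    sd = np.sqrt((n * n - 1) / 12.0)
    return rank, float((rank - mean) / sd)


def select_identity_tfs(scores: Mapping[str, float], n_top: int = 10) -> List[str]:
    """The ``n_top`` TFs with the smallest JSD, sorted ascending by
    (jsd, symbol); ties at the cutoff resolve to the lexicographically
    smaller symbol."""
    if len(scores) < n_top:
        raise ValueError(
            f"need at least {n_top} scored TFs to call identity TFs, "
            f"have {len(scores)}"
        )
    ranked = sorted(scores.items(), key=lambda kv: (kv[1], kv[0]))
    return [tf for tf, _ in ranked[:n_top]]


def select_cofactors(
    zscores: Mapping[str, float],
    identity_tfs: Sequence[str],
    z_cut: float = -1.5,
) -> set:
    """TFs with z strictly below ``z_cut``, excluding identity TFs (the two
    roles are disjoint)."""
    identity = set(identity_tfs)
    return {tf for tf, z in zscores.items() if z < z_cut and tf not in identity}


def score_tfs(
    query_tpm: pd.Series,
    background_tpm: pd.DataFrame,
    tf_symbols: Sequence[str],
    n_top: int = 10,
    z_cut: float = -1.5,
) -> pd.DataFrame:
    """Score every TF and call identity TFs and co-factors.

    ``query_tpm`` is indexed by gene_id; ``background_tpm`` is genes x
    background samples on the same index. TFs absent from the expression
    index are ignored (the universe is intersected with the measured
    genes). Returns a DataFrame (tf, jsd, rank, zscore, call) sorted
    ascending by jsd.
    """
    tfs = sorted(set(tf_symbols) & set(background_tpm.index))
    if not tfs:
        raise ValueError("no TF symbols found in the expression matrix")
    records = []
    for tf in tfs:
        bg = background_tpm.loc[tf].to_numpy(dtype=float)
        jsd = jsd_specificity(float(query_tpm.loc[tf]), bg)
        null = background_pseudo_jsds(bg)
        rank, z = cofactor_zscores(jsd, null)
        records.append((tf, jsd, rank, z))
    df = pd.DataFrame(records, columns=["tf", "jsd", "rank", "zscore"])
    identity = select_identity_tfs(dict(zip(df["tf"], df["jsd"])), n_top=n_top)
    cofactors = select_cofactors(
        dict(zip(df["tf"], df["zscore"])), identity, z_cut=z_cut
    )
    df["call"] = [
        "identity" if tf in identity else ("cofactor" if tf in cofactors else "none")
        for tf in df["tf"]
    ]
    return df.sort_values(["jsd", "tf"]).reset_index(drop=True)


def results_from_table(df: pd.DataFrame) -> List[SpecificityResult]:
    return [
        SpecificityResult(r.tf, float(r.jsd), int(r.rank), float(r.zscore), r.call)
        for r in df.itertuples(index=False)
    ]
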