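"""Gene-set context for DE results.

Over-representation analysis (upper-tail hypergeometric), preranked
gene-set enrichment with a weighted running-sum statistic and a
gene-label-permutation null for the normalised enrichment score (NES),
and signature scoring of a query DE result against the top genes of a
reference perturbation profile.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats

from httrscreen.de import DEResult, adjust_bh

__all__ = [
    "GeneSetCollection",
    "GSEAResult",
    "load_gmt",
    "write_gmt",
    "ora_hypergeom",
    "gsea_preranked",
    "signature_score",
]


@dataclass
class GeneSetCollection:
    """Named gene sets loaded from a GMT file."""

    sets: dict[str, set[str]]
    source: str = ""

    def __post_init__(self) -> None:
        empty = [name for name, s in self.sets.items() if not s]
        if empty:
            raise ValueError(f"empty gene set(s): {empty}")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


@dataclass
class GSEAResult:
    """Enrichment of one set in one ranking: running-sum ES in [-1, 1],
    permutation-normalised NES, permutation p, leading edge."""

    es: float
    nes: float
    pvalue: float
    leading_edge: list[str]
    n_perm: int
    seed: int
    flagged: bool = False
    note: str = ""


def load_gmt(path: str | Path, uppercase: bool = False) -> GeneSetCollection:
    """Read a GMT file: ``name TAB description TAB gene...`` per line.

    Duplicate genes within a set are deduplicated; malformed lines raise
    with their line number.
    """
    path = Path(path)
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected name, description and at least "
                    f"one gene, found {len(parts)} field(s)"
                )
            name = parts[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            genes = {g.upper() if uppercase else g for g in parts[2:] if g}
            if not genes:
                raise ValueError(f"{path}:{lineno}: set {name!r} has no genes")
            sets[name] = genes
    return GeneSetCollection(sets, source=str(path))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.items():
            fh.write("\t".join([name, "na", *sorted(genes)]) + "\n")


def ora_hypergeom(
    de_genes: set[str],
    universe: set[str],
    sets: GeneSetCollection,
    min_overlap: int = 1,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation test per set.

    p = P(X >= k) with population N = |universe|, K = |set ∩ universe|
    successes, n = |de_genes| draws and k the observed overlap; BH across
    sets; fold enrichment = (k/n) / (K/N).
    """
    if not universe:
        raise ValueError("empty universe")
    de_genes = set(de_genes) & universe
    n = len(de_genes)
    big_n = len(universe)
    rows = []
    for name, genes in sets.items():
        members = genes & universe
        big_k = len(members)
        k = len(de_genes & members)
        if big_k == 0 or k < min_overlap:
            continue
        # survival function gives P(X > k-1) = P(X >= k)
        p = float(scipy.stats.hypergeom.sf(k - 1, big_n, big_k, n))
        fold = (k / n) / (big_k / big_n) if n else 0.0
        rows.append(
            {"set": name, "set_size": big_k, "overlap": k, "n_de": n,
             "universe": big_n, "fold_enrichment": fold, "pvalue": min(p, 1.0)}
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["padj"] = adjust_bh(table["pvalue"].to_numpy())
    return table


def _es_from_positions(
    positions: np.ndarray, hit_weights: np.ndarray, n_total: int
) -> np.ndarray:
    """Signed-max running-sum ES for one or many position sets.

    ``positions``: (m, K) 0-based sorted positions of the set's genes in
    the ranking; ``hit_weights``: matching |stat|^p weights (unnormalised).
    The running sum gains w_i / sum(w) at each hit and loses 1/(N - K) per
    miss; the ES is the extreme deviation of larger magnitude.
    """
    positions = np.atleast_2d(positions)
    hit_weights = np.atleast_2d(hit_weights)
    m, k = positions.shape
    miss = 1.0 / (n_total - k)
    wsum = hit_weights.sum(axis=1, keepdims=True)
    wsum = np.where(wsum == 0, 1.0, wsum)
    cum_w = np.cumsum(hit_weights, axis=1) / wsum
    idx = np.arange(k)
    # value immediately after hit i, and immediately before hit i
    after = cum_w - (positions - idx) * miss
    before = np.concatenate(
        [np.zeros((m, 1)), cum_w[:, :-1]], axis=1
    ) - (positions - idx) * miss
    pos_extreme = np.maximum(after.max(axis=1), 0.0)
    neg_extreme = np.minimum(before.min(axis=1), 0.0)
    return np.where(pos_extreme >= -neg_extreme, pos_extreme, neg_extreme)


def gsea_preranked(
    ranked_stats: pd.Series | dict,
    gene_set: set[str],
    weight_exponent: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> GSEAResult:
    """Preranked GSEA for a single set.

    The ranking is walked in decreasing statistic order; set members add
    ``|stat|^p / sum_set |stat|^p``, non-members subtract ``1/(N - K)``.
    The null is gene-label permutation (random placement of K labels),
    seeded; NES = ES / mean |null ES| of matching sign and
    p = (1 + #{more extreme, same sign}) / (1 + #{same sign}).
    """
    stats = pd.Series(ranked_stats).astype(float)
    if stats.isna().any():
        raise ValueError("ranking contains NaN")
    order = np.argsort(-stats.to_numpy(), kind="stable")
    genes = stats.index.to_numpy()[order]
    values = stats.to_numpy()[order]
    n_total = len(genes)
    in_set = np.isin(genes, list(gene_set))
    k = int(in_set.sum())
    if k < 3:
        raise ValueError(f"set has only {k} genes in the ranking; need >= 3")
    if k >= n_total:
        return GSEAResult(
            es=0.0, nes=float("nan"), pvalue=float("nan"), leading_edge=[],
            n_perm=n_perm, seed=seed, flagged=True,
            note="set covers the whole ranking; ES degenerate",
        )

    abs_w = np.abs(values) ** weight_exponent
    positions = np.flatnonzero(in_set)
    es = float(_es_from_positions(positions, abs_w[positions], n_total)[0])

    rng = np.random.default_rng(seed)
    perm_pos = np.sort(
        rng.random((n_perm, n_total)).argsort(axis=1)[:, :k], axis=1
    )
    null_es = _es_from_positions(perm_pos, abs_w[perm_pos], n_total)

    same_sign = null_es >= 0 if es >= 0 else null_es < 0
    n_same = int(same_sign.sum())
    if n_same < 10:
        return GSEAResult(
            es=es, nes=float("nan"), pvalue=float("nan"), leading_edge=[],
            n_perm=n_perm, seed=seed, flagged=True,
            note=f"only {n_same} same-sign null draws; NES undefined",
        )
    mean_abs = float(np.abs(null_es[same_sign]).mean())
    nes = es / mean_abs if mean_abs > 0 else float("nan")
    p = (1 + int((np.abs(null_es[same_sign]) >= abs(es)).sum())) / (1 + n_same)

    # leading edge: hits at or before the extreme of the running sum
    hit_idx = positions
    es_all = _running_extreme_index(positions, abs_w[positions], n_total, es)
    leading = genes[hit_idx[hit_idx <= es_all]] if es >= 0 else genes[
        hit_idx[hit_idx >= es_all]
    ]
    return GSEAResult(
        es=es, nes=float(nes), pvalue=float(p), leading_edge=list(leading),
        n_perm=n_perm, seed=seed,
    )


def _running_extreme_index(
    positions: np.ndarray, weights: np.ndarray, n_total: int, es: float
) -> int:
    """Ranking index at which the running sum attains its extreme."""
    k = len(positions)
    miss = 1.0 / (n_total - k)
    wsum = weights.sum() or 1.0
    cum_w = np.cumsum(weights) / wsum
    idx = np.arange(k)
    after = cum_w - (positions - idx) * miss
    before = np.concatenate([[0.0], cum_w[:-1]]) - (positions - idx) * miss
    if es >= 0:
        return int(positions[int(np.argmax(after))])
    return int(positions[int(np.argmin(before))])


def signature_score(
    query: DEResult,
    reference_profile: pd.Series,
    top_n: int = 500,
    n_perm: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
) -> GSEAResult:
    """Score a query DE result against a reference perturbation profile.

    The signature is the ``top_n`` genes of the reference (by decreasing
    statistic); the query ranking is its per-gene DE statistic.  Requires
    the universes to overlap by at least ``top_n / 2`` genes.
    """
    ref = pd.Series(reference_profile).astype(float).sort_values(ascending=False)
    signature = set(ref.index[:top_n])
    ranking = query.table.set_index("gene_id")["stat"].dropna()
    overlap = signature & set(ranking.index)
    if len(overlap) < top_n / 2:
        raise ValueError(
            f"only {len(overlap)} signature genes present in the query "
            f"universe; need >= {top_n / 2:.0f}"
        )
    return gsea_preranked(
        ranking, signature, weight_exponent=weight_exponent, n_perm=n_perm,
        seed=seed,
    )
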