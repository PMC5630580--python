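"""Co-occurrence network inference from taxa x samples abundance tables.

A simplified, documented re-implementation of the ensemble approach used
for microbial co-occurrence analysis (in the style of CoNet, but not a
bit-compatible clone): every taxon pair is scored with both the Spearman
rank correlation and the symmetrized Kullback–Leibler dissimilarity of the
taxa's relative-abundance distributions across samples; significance comes
from a compositionality-aware permutation null (one taxon's counts are
shuffled across samples and the sample totals renormalized — the guard that
bootstrap-renormalization ("ReBoot")-style procedures use against spurious
correlations induced by relative abundances); the two permutation p-values
are merged into a single per-pair p-value (by default the dependence-robust
maximum; Fisher's combination is available); Benjamini–Hochberg keeps the
false discovery rate at the requested level; surviving edges are signed by
the Spearman correlation (positive = co-occurrence, negative = mutual
exclusion).

The fitted surface follows the Model -> fit() -> Results pattern:

>>> res = CooccurrenceModel(table).fit(n_permutations=1000, seed=1)
>>> res.edges            # tidy edge table with rho, p, q, sign
>>> res.to_networkx()    # annotated graph
>>> print(res.summary())
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import List, Optional, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AbundanceTable",
    "CooccurrenceModel",
    "CooccurrenceResults",
    "assign_functional_groups",
    "spearman_score",
    "kl_dissimilarity",
    "permutation_null",
    "build_network",
]

#: pseudocount added to every count before forming proportions for the
#: Kullback–Leibler dissimilarity (zero-handling)
KL_PSEUDOCOUNT = 0.5

#: sulfate-reducing orders (Deltaproteobacteria) recognized as group SB
SB_ORDERS = frozenset({"desulfobacterales", "desulfuromonadales", "desulfovibrionales"})


def assign_functional_groups(taxonomy: str) -> str:
    """Map a ranked taxonomy string to CB, PB, SB or OTHER.

    CB: phylum Cyanobacteria (oxygenic phototrophs). PB: phylum Chlorobi
    (green sulfur bacteria) or order Chromatiales (purple sulfur bacteria).
    SB: the sulfate-reducing orders Desulfobacterales, Desulfuromonadales,
    Desulfovibrionales. Everything else — including unparseable strings,
    with a warning — is OTHER.
    """
    if not isinstance(taxonomy, str) or not taxonomy.strip():
        warnings.warn(f"unparseable taxonomy {taxonomy!r}; assigning OTHER", stacklevel=2)
        return "OTHER"
    ranks = [r.strip().lower() for r in taxonomy.split(";") if r.strip()]
    if not ranks:
        warnings.warn(f"unparseable taxonomy {taxonomy!r}; assigning OTHER", stacklevel=2)
        return "OTHER"
    if "cyanobacteria" in ranks:
        return "CB"
    if "chlorobi" in ranks or "chromatiales" in ranks:
        return "PB"
    if any(r in SB_ORDERS for r in ranks):
        return "SB"
    return "OTHER"


@dataclass
class AbundanceTable:
    """Taxa x samples count table with taxonomy per taxon.

    ``counts``: non-negative integer array, shape (n_taxa, n_samples);
    ``taxa``: taxon identifiers; ``taxonomy``: ranked strings (semicolon-
    separated); ``samples``: sample identifiers; ``sample_metadata``:
    optional frame indexed like ``samples`` (e.g. date, depth).
    """

    counts: np.ndarray
    taxa: List[str]
    taxonomy: List[str]
    samples: List[str]
    sample_metadata: Optional[pd.DataFrame] = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D taxa x samples array")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        n_taxa, n_samples = self.counts.shape
        if len(self.taxa) != n_taxa or len(self.taxonomy) != n_taxa:
            raise ValueError("taxa/taxonomy length must match the count rows")
        if len(self.samples) != n_samples:
            raise ValueError("samples length must match the count columns")

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def functional_groups(self) -> List[str]:
        return [assign_functional_groups(t) for t in self.taxonomy]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=self.taxa, columns=self.samples)
        df.insert(0, "taxonomy", self.taxonomy)
        df.index.name = "taxon"
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AbundanceTable":
        if "taxonomy" not in df.columns:
            raise ValueError("abundance table needs a 'taxonomy' column")
        taxonomy = df["taxonomy"].tolist()
        counts = df.drop(columns="taxonomy")
        return cls(
            counts=counts.to_numpy(dtype=float),
            taxa=[str(i) for i in df.index],
            taxonomy=[str(t) for t in taxonomy],
            samples=[str(c) for c in counts.columns],
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "AbundanceTable":
        return cls.from_frame(pd.read_csv(path, index_col=0))


# -- pairwise scores -----------------------------------------------------------


def spearman_score(x, y) -> float:
    """Spearman rank correlation with average ranks for ties.

    Raises on vectors shorter than 4 or constant vectors (undefined score).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 4:
        raise ValueError("need at least 4 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman correlation is undefined for a constant vector")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def kl_dissimilarity(x, y, pseudocount: float = KL_PSEUDOCOUNT) -> float:
    """Symmetrized Kullback–Leibler divergence between two abundance vectors.

    Each vector is shifted by *pseudocount* and normalized to a probability
    distribution over samples; returns
    0.5*(KL(p||q) + KL(q||p)) in nats. Zero iff the vectors are
    proportional; scale-invariant up to the pseudocount.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("abundances must be non-negative")
    if x.sum() <= 0 or y.sum() <= 0:
        raise ValueError("each vector must have a positive total")
    p = x + (pseudocount if np.any(x == 0) or np.any(y == 0) else 0.0)
    q = y + (pseudocount if np.any(x == 0) or np.any(y == 0) else 0.0)
    p = p / p.sum()
    q = q / q.sum()
    return float(0.5 * (stats.entropy(p, q) + stats.entropy(q, p)))


def _pair_scores_matrix(xi, xj, other_totals):
    """Spearman rho and KL dissimilarity for (possibly many) permuted copies.

    ``xi``: (m, n) permuted copies of taxon i's counts; ``xj``: (n,) fixed
    counts of taxon j; sample totals are recomputed per copy (renormalization
    guard). Returns (rho[m], kl[m]).

    When the pair is the whole community (no other taxa), closure would fix
    ri + rj = 1 and make every permutation perfectly anticorrelated; there
    is no compositional context to guard in that case, so the raw counts
    are scored instead.
    """
    xj2 = np.broadcast_to(xj, xi.shape)
    if np.any(other_totals > 0):
        totals = xi + xj2 + other_totals
        totals = np.where(totals <= 0, 1.0, totals)
    else:
        totals = np.ones_like(xi)
    ri = xi / totals
    rj = xj2 / totals
    # vectorized Spearman: Pearson on ranks along axis 1
    rank_i = stats.rankdata(ri, axis=1)
    rank_j = stats.rankdata(rj, axis=1)
    rank_i = rank_i - rank_i.mean(axis=1, keepdims=True)
    rank_j = rank_j - rank_j.mean(axis=1, keepdims=True)
    denom = np.sqrt((rank_i**2).sum(axis=1) * (rank_j**2).sum(axis=1))
    denom = np.where(denom == 0, np.nan, denom)
    rho = (rank_i * rank_j).sum(axis=1) / denom
    # symmetrized KL on pseudocounted proportions
    pi = ri + KL_PSEUDOCOUNT / np.maximum(totals, 1.0)
    pj = rj + KL_PSEUDOCOUNT / np.maximum(totals, 1.0)
    pi = pi / pi.sum(axis=1, keepdims=True)
    pj = pj / pj.sum(axis=1, keepdims=True)
    kl = 0.5 * ((pi * np.log(pi / pj)).sum(axis=1) + (pj * np.log(pj / pi)).sum(axis=1))
    return rho, kl


def _two_sided_p(null: np.ndarray, observed: float) -> float:
    """Two-sided empirical p-value with the (b+1)/(n+1) correction."""
    null = null[np.isfinite(null)]
    n = len(null)
    lo = (np.sum(null <= observed) + 1) / (n + 1)
    hi = (np.sum(null >= observed) + 1) / (n + 1)
    return float(min(1.0, 2.0 * min(lo, hi)))


def permutation_null(
    table: AbundanceTable,
    pair: Tuple[int, int],
    n_permutations: int = 1000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[float, float]:
    """Permutation p-values (Spearman, KL) for one taxon pair.

    Taxon i's counts are permuted across samples ``n_permutations`` times;
    after each permutation the sample totals are recomputed and both taxa's
    relative abundances renormalized before rescoring (the compositional
    guard). Two-sided empirical p-values with the +1 correction.
    """
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    if rng is None:
        rng = np.random.default_rng(seed)
    i, j = pair
    xi = np.asarray(table.counts[i], dtype=float)
    xj = np.asarray(table.counts[j], dtype=float)
    other = table.counts.sum(axis=0) - table.counts[i] - table.counts[j]

    perm_idx = np.argsort(rng.random((n_permutations, len(xi))), axis=1)
    null_rho, null_kl = _pair_scores_matrix(xi[perm_idx], xj, other)
    # score the observed pair through the identical code path so the null
    # and the observation are exactly comparable
    obs_rho_m, obs_kl_m = _pair_scores_matrix(xi[None, :], xj, other)
    return (
        _two_sided_p(null_rho, float(obs_rho_m[0])),
        _two_sided_p(null_kl, float(obs_kl_m[0])),
    )


# -- model / results -----------------------------------------------------------


@dataclass
class CooccurrenceResults:
    """Fitted co-occurrence network.

    ``edges``: every scored pair with rho, KL, the three p-values, the BH
    q-value, the significance call at ``fdr`` and the sign of significant
    edges. ``network``/:meth:`to_networkx` expose only significant edges.
    """

    edges: pd.DataFrame
    fdr: float
    n_permutations: int
    seed: Optional[int]
    groups: List[str]
    taxa: List[str]

    @property
    def significant(self) -> pd.DataFrame:
        return self.edges[self.edges["significant"]]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(fdr=self.fdr, n_permutations=self.n_permutations)
        for taxon, group in zip(self.taxa, self.groups):
            g.add_node(taxon, functional_group=group)
        for row in self.significant.itertuples():
            g.add_edge(
                row.taxon_a,
                row.taxon_b,
                rho=float(row.spearman_rho),
                q=float(row.q),
                sign=int(row.sign),
            )
        return g

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)

    def summary(self) -> str:
        sig = self.significant
        lines = [
            "Co-occurrence network",
            "=" * 52,
            f"taxa: {len(self.taxa)}   pairs scored: {len(self.edges)}",
            f"permutations: {self.n_permutations}   FDR: {self.fdr:g}   seed: {self.seed}",
            f"significant edges: {len(sig)} "
            f"({int((sig['sign'] > 0).sum())} positive, {int((sig['sign'] < 0).sum())} negative)",
            "-" * 52,
        ]
        for row in sig.itertuples():
            kind = "co-occurrence " if row.sign > 0 else "mutual exclusion"
            lines.append(
                f"{row.taxon_a:>14} -- {row.taxon_b:<14} {kind} "
                f"rho={row.spearman_rho:+.2f} q={row.q:.3g}"
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        g = self.to_networkx()
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 6))
        pos = nx.spring_layout(g, seed=0)
        colors = {"CB": "tab:green", "PB": "tab:purple", "SB": "tab:cyan", "OTHER": "0.7"}
        nx.draw_networkx_nodes(
            g, pos, ax=ax,
            node_color=[colors[g.nodes[n]["functional_group"]] for n in g],
        )
        for sign, color in ((1, "green"), (-1, "magenta")):
            edges = [(u, v) for u, v, d in g.edges(data=True) if d["sign"] == sign]
            nx.draw_networkx_edges(g, pos, edgelist=edges, edge_color=color, ax=ax)
        nx.draw_networkx_labels(g, pos, font_size=7, ax=ax)
        ax.set_axis_off()
        return ax


class CooccurrenceModel:
    """Ensemble co-occurrence scoring of an :class:`AbundanceTable`.

    Parameters
    ----------
    table : AbundanceTable
    merge : {'max', 'fisher'}
        How the Spearman and KL permutation p-values are combined into one
        per-pair p-value. The default 'max' (intersection test: both scores
        must be individually extreme) is valid under arbitrary dependence
        between the two scores, which matters here because they are computed
        from the same data and are strongly positively dependent under the
        null; 'fisher' (chi-squared combination) assumes independence and is
        anticonservative in that setting. Both are documented
        approximations of ensemble merging.
    """

    def __init__(self, table: AbundanceTable, merge: str = "max"):
        if table.n_taxa < 2:
            raise ValueError("need at least 2 taxa")
        if merge not in ("fisher", "max"):
            raise ValueError(f"merge must be 'fisher' or 'max', got {merge!r}")
        variable = [
            i for i in range(table.n_taxa)
            if not np.all(table.counts[i] == table.counts[i][0])
        ]
        if len(variable) < 2:
            raise ValueError("need at least 2 non-constant taxa")
        self.table = table
        self.merge = merge
        self._variable = variable

    def fit(
        self,
        n_permutations: int = 4000,
        fdr: float = 0.05,
        seed: Optional[int] = None,
    ) -> CooccurrenceResults:
        """Score all taxon pairs and keep edges passing BH at *fdr*.

        Constant taxa are excluded from pairing (their scores are
        undefined). Each pair draws its permutations from an independent
        stream spawned from *seed*, so results are reproducible and
        insensitive to pair enumeration order.
        """
        table = self.table
        ss = np.random.SeedSequence(seed)
        pairs = list(itertools.combinations(self._variable, 2))
        children = ss.spawn(len(pairs))
        rows = []
        for (i, j), child in zip(pairs, children):
            rng = np.random.default_rng(child)
            other = table.counts.sum(axis=0) - table.counts[i] - table.counts[j]
            xi = np.asarray(table.counts[i], dtype=float)
            xj = np.asarray(table.counts[j], dtype=float)
            obs_rho_m, obs_kl_m = _pair_scores_matrix(xi[None, :], xj, other)
            perm_idx = np.argsort(rng.random((n_permutations, len(xi))), axis=1)
            null_rho, null_kl = _pair_scores_matrix(xi[perm_idx], xj, other)
            p_s = _two_sided_p(null_rho, float(obs_rho_m[0]))
            p_k = _two_sided_p(null_kl, float(obs_kl_m[0]))
            rows.append(
                {
                    "taxon_a": table.taxa[i],
                    "taxon_b": table.taxa[j],
                    "group_a": assign_functional_groups(table.taxonomy[i]),
                    "group_b": assign_functional_groups(table.taxonomy[j]),
                    "spearman_rho": float(obs_rho_m[0]),
                    "kl_dissimilarity": float(obs_kl_m[0]),
                    "p_spearman": p_s,
                    "p_kl": p_k,
                }
            )
        edges = pd.DataFrame(rows)
        if self.merge == "fisher":
            chi2 = -2.0 * (np.log(edges["p_spearman"]) + np.log(edges["p_kl"]))
            edges["p_merged"] = stats.chi2.sf(chi2, df=4)
        else:
            edges["p_merged"] = edges[["p_spearman", "p_kl"]].max(axis=1)
        reject, q, _, _ = multipletests(edges["p_merged"], alpha=fdr, method="fdr_bh")
        edges["q"] = q
        edges["significant"] = reject
        edges["sign"] = np.where(
            edges["significant"], np.sign(edges["spearman_rho"]).astype(int), 0
        )
        return CooccurrenceResults(
            edges=edges,
            fdr=fdr,
            n_permutations=n_permutations,
            seed=seed,
            groups=table.functional_groups(),
            taxa=list(table.taxa),
        )


def build_network(
    table: AbundanceTable,
    n_permutations: int = 4000,
    fdr: float = 0.05,
    seed: Optional[int] = None,
    merge: str = "max",
) -> CooccurrenceResults:
    """Convenience wrapper: ``CooccurrenceModel(table, merge).fit(...)``."""
    return CooccurrenceModel(table, merge=merge).fit(
        n_permutations=n_permutations, fdr=fdr, seed=seed
    )
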