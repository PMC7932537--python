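"""Information-theoretic specificity statistics and the selectome.

The specificity of a protease over P3-P1' tetramers is quantified from two
tetramer-cluster tables: the substrate selection (a partition of hexamer
substrates) and the naive library (multi-membership).  With cluster
probabilities ``P(t) = n_t / sum_i n_i`` (n_t = distinct hexamers in
cluster t):

* Shannon entropy ``H = -sum P log2 P`` measures breadth of the
  distribution (uniform over the 160,000 tetramers: log2 160,000 = 17.288
  bits).
* The relative probability ``RP(t) = P_S(t) / P_NL(t)`` is the fitness
  statistic: ~1 for a tetramer cleaved no better than background, up to
  160,000 for a perfectly specific protease.
* The Kullback-Leibler divergence ``D = sum P_S log2 RP`` measures how far
  selection moved the distribution from the library.

The **selectome** is the set of clusters above the RP value at which the
cumulative K-L contribution (clusters taken in ascending RP order) crosses
zero: clusters below that point cancel out and carry no net divergence,
those above carry all of it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clustering import ClusterTable, N_TETRAMERS

logger = logging.getLogger(__name__)


@dataclass
class ProbabilityTable:
    """Per-tetramer cluster probabilities for one sample."""

    probs: pd.Series  # index: tetramer, values: probability
    mode: str  # "selection" or "naive"
    total_hexamers: int  # denominator sum_i n_i
    counts: pd.Series | None = None  # per-cluster n_t, same index

    def __post_init__(self) -> None:
        total = float(self.probs.sum())
        if self.probs.size and not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"probabilities sum to {total}, not 1")


@dataclass
class RPTable:
    """Per-tetramer RP with K-L contributions.

    ``df`` is indexed by tetramer with columns:

    - ``n_sel``, ``n_naive`` — distinct-hexamer cluster sizes
    - ``p_sel``, ``p_naive`` — cluster probabilities
    - ``rp`` — relative probability P_S/P_NL (0 where absent from selection)
    - ``kl_contrib`` — P_S * log2(RP), zero where P_S is zero
    - ``pseudocounted`` — True where a naive count of 0 was replaced by 1
    - ``rank`` — 1-based rank by descending RP
    """

    df: pd.DataFrame
    total_sel: int
    total_naive: int

    @property
    def rp_max(self) -> float:
        return float(self.df["rp"].max())

    @property
    def n_pseudocounted(self) -> int:
        return int(self.df["pseudocounted"].sum())

    def rp_of(self, tetramer: str) -> float:
        """RP of a tetramer; 0 when the cluster is absent altogether."""
        if tetramer in self.df.index:
            return float(self.df.at[tetramer, "rp"])
        return 0.0


@dataclass
class SelectomeResult:
    """A protease's selectome and the summary statistics around it."""

    rp_threshold: float | None
    selectome: set[str]
    h_selection: float
    h_naive: float
    d_kl: float
    n_clusters_total: int
    n_clusters_selectome: int
    n_hexamers_in: int
    n_hexamers_out: int

    @property
    def hexamer_fraction_in(self) -> float:
        total = self.n_hexamers_in + self.n_hexamers_out
        return self.n_hexamers_in / total if total else 0.0


@dataclass
class SelectomeComparison:
    unique_a: set[str]
    unique_b: set[str]
    shared: set[str]

    @property
    def combined_size(self) -> int:
        return len(self.unique_a) + len(self.unique_b) + len(self.shared)

    def fractions(self) -> dict[str, float]:
        n = self.combined_size
        if n == 0:
            return {"unique_a": 0.0, "unique_b": 0.0, "shared": 0.0}
        return {
            "unique_a": len(self.unique_a) / n,
            "unique_b": len(self.unique_b) / n,
            "shared": len(self.shared) / n,
        }


def cluster_probabilities(table: ClusterTable) -> ProbabilityTable:
    """P(t) = n_t / sum_i n_i over the table's clusters.

    Selection tables use partitioned counts; naive tables use
    multi-membership counts — the denominator is whatever the table's mode
    produced.
    """
    sizes = table.sizes()
    if not sizes:
        raise ValueError("empty cluster table")
    total = sum(sizes.values())
    counts = pd.Series(sizes, dtype=float).sort_index()
    return ProbabilityTable(
        probs=counts / total, mode=table.mode, total_hexamers=total, counts=counts
    )


def shannon_entropy(p: ProbabilityTable | np.ndarray | pd.Series, base: float = 2.0) -> float:
    """H = -sum P log P with 0 log 0 := 0, in units of ``log base``.

    base=2 gives bits; base=20 gives the per-position convention used for
    residue-frequency specificity matrices.
    """
    values = np.asarray(p.probs if isinstance(p, ProbabilityTable) else p, dtype=float)
    if np.any(values < 0):
        raise ValueError("negative probability")
    nz = values[values > 0]
    return float(-(nz * np.log2(nz)).sum() / np.log2(base))


def relative_probability(sel: ProbabilityTable, naive: ProbabilityTable) -> RPTable:
    """RP(t) = P_S(t)/P_NL(t) over the union of observed clusters.

    Clusters observed in the selection but absent from the naive library
    get a naive pseudocount of one hexamer (flagged): a finite RP is
    required and with realistic library depth the case is rare.  Clusters
    absent from the selection keep RP = 0.
    """
    if naive.total_hexamers <= 0 or naive.probs.empty:
        raise ValueError("naive probability table is empty")
    index = sel.probs.index.union(naive.probs.index)
    p_sel = sel.probs.reindex(index, fill_value=0.0)
    p_naive = naive.probs.reindex(index, fill_value=0.0)
    n_sel = (sel.counts.reindex(index, fill_value=0)
             if sel.counts is not None else p_sel * sel.total_hexamers)
    n_naive = (naive.counts.reindex(index, fill_value=0)
               if naive.counts is not None else p_naive * naive.total_hexamers)

    pseudo = (p_sel > 0) & (p_naive == 0)
    if pseudo.any():
        logger.info("pseudocounting %d selection-only clusters", int(pseudo.sum()))
    p_naive_eff = p_naive.where(~pseudo, 1.0 / naive.total_hexamers)

    rp = pd.Series(0.0, index=index)
    mask = p_sel > 0
    rp[mask] = p_sel[mask] / p_naive_eff[mask]

    kl = pd.Series(0.0, index=index)
    kl[mask] = p_sel[mask] * np.log2(rp[mask])

    df = pd.DataFrame(
        {
            "n_sel": n_sel.astype(int),
            "n_naive": n_naive.astype(int),
            "p_sel": p_sel,
            "p_naive": p_naive,
            "rp": rp,
            "kl_contrib": kl,
            "pseudocounted": pseudo,
        }
    )
    df["rank"] = df["rp"].rank(ascending=False, method="first").astype(int)
    return RPTable(df=df, total_sel=sel.total_hexamers, total_naive=naive.total_hexamers)


def kl_divergence(
    sel: ProbabilityTable, naive: ProbabilityTable
) -> tuple[float, pd.Series]:
    """D_KL(P_S || P_NL) in bits, with per-cluster contributions.

    Raises if any cluster has selection mass but zero naive mass; use
    :func:`relative_probability` first when pseudocounting is wanted.
    """
    index = sel.probs.index.union(naive.probs.index)
    p_sel = sel.probs.reindex(index, fill_value=0.0)
    p_naive = naive.probs.reindex(index, fill_value=0.0)
    bad = (p_sel > 0) & (p_naive == 0)
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} clusters have selection mass but zero naive mass; "
            "pseudocount via relative_probability first"
        )
    contrib = pd.Series(0.0, index=index)
    mask = p_sel > 0
    contrib[mask] = p_sel[mask] * np.log2(p_sel[mask] / p_naive[mask])
    return float(contrib.sum()), contrib


def selectome_threshold(rp: RPTable) -> float | None:
    """RP value where the cumulative K-L contribution crosses zero.

    Clusters present in the selection are taken in ascending RP order and
    their K-L contributions accumulated; the threshold is the RP of the
    first cluster at which the running sum reaches >= 0.  Contributions
    are strictly positive above RP 1, so the crossing is unique.  Two edge
    conventions: when no cluster exceeds RP 1 there is no positive
    divergence mass and the protease has no definable specificity
    (returns None); when the running sum never dips below zero there is no
    zero-sum region at all and the threshold is 1, placing every
    overrepresented cluster (RP > 1) inside the selectome.
    """
    df = rp.df[rp.df["p_sel"] > 0].sort_values(["rp", "kl_contrib"])
    if df.empty or float(df["rp"].max()) <= 1.0:
        logger.warning("no clusters with RP > 1: no definable specificity")
        return None
    tol = 1e-12  # absorb float cancellation at an exact zero crossing
    running = df["kl_contrib"].cumsum()
    if float(running.min()) >= -tol:
        return 1.0
    crossed = running >= -tol
    if not crossed.any():
        logger.warning("cumulative K-L contribution never reaches zero")
        return None
    return float(df.loc[crossed.idxmax(), "rp"])


def extract_selectome(rp: RPTable, rp_threshold: float | None) -> SelectomeResult:
    """Selectome = clusters with RP strictly above the threshold.

    The strict inequality keeps the threshold cluster itself on the
    zero-sum side of the cumulative divergence curve.
    """
    df = rp.df
    observed = df[df["p_sel"] > 0]
    h_sel = shannon_entropy(observed["p_sel"].to_numpy())
    h_naive = shannon_entropy(df.loc[df["p_naive"] > 0, "p_naive"].to_numpy())
    d_kl = float(df["kl_contrib"].sum())
    if rp_threshold is None:
        logger.warning("no RP threshold: selectome is empty")
        members: set[str] = set()
    else:
        members = set(df.index[df["rp"] > rp_threshold])
    in_mask = df.index.isin(members)
    return SelectomeResult(
        rp_threshold=rp_threshold,
        selectome=members,
        h_selection=h_sel,
        h_naive=h_naive,
        d_kl=d_kl,
        n_clusters_total=int((df["p_sel"] > 0).sum()),
        n_clusters_selectome=len(members),
        n_hexamers_in=int(df.loc[in_mask, "n_sel"].sum()),
        n_hexamers_out=int(df.loc[~in_mask, "n_sel"].sum()),
    )


def fold_specificity(h_observed: float, h_reference: float, base: float = 2.0) -> float:
    """Fold narrowing of specificity relative to a reference entropy.

    ``base ** (h_reference - h_observed)``: how many times fewer effective
    substrates the observed distribution supports than the reference.
    """
    if h_observed < 0 or h_reference < 0:
        raise ValueError("entropies must be non-negative")
    if h_reference < h_observed:
        raise ValueError("reference entropy must be >= observed entropy")
    return float(base ** (h_reference - h_observed))


def compare_selectomes(a: SelectomeResult, b: SelectomeResult) -> SelectomeComparison:
    """Partition the combined selectome into unique and shared tetramers."""
    shared = a.selectome & b.selectome
    cmp = SelectomeComparison(
        unique_a=a.selectome - shared, unique_b=b.selectome - shared, shared=shared
    )
    fr = cmp.fractions()
    logger.info(
        "combined selectome %d tetramers: %.0f%% unique to A, %.0f%% unique to B, %.0f%% shared",
        cmp.combined_size, 100 * fr["unique_a"], 100 * fr["unique_b"], 100 * fr["shared"],
    )
    return cmp


def selection_completeness(kcat_km: float, enzyme_conc: float, time: float) -> float:
    """Fraction of substrate cleaved under pseudo-first-order kinetics.

    With [S] << K_M, cleavage is exponential with rate kcat/K_M * [E]:
    ``1 - exp(-kcat_km * enzyme_conc * time)``.  Units: M^-1 s^-1, M, s.
    """
    if kcat_km < 0 or enzyme_conc < 0 or time < 0:
        raise ValueError("arguments must be non-negative")
    return float(1.0 - math.exp(-kcat_km * enzyme_conc * time))


def stats_table(rp: RPTable) -> pd.DataFrame:
    """Full per-cluster statistics table, ranked by descending RP.

    Columns mirror the per-cluster bookkeeping used to report a selection:
    sizes, probabilities, RP, per-cluster and cumulative K-L divergence and
    entropy contributions.
    """
    df = rp.df.sort_values("rank").copy()
    p = df["p_sel"].to_numpy()
    h_contrib = np.zeros_like(p)
    mask = p > 0
    h_contrib[mask] = -p[mask] * np.log2(p[mask])
    df["h_contrib"] = h_contrib
    asc = df.sort_values(["rp", "kl_contrib"])
    df["kl_cumulative"] = asc["kl_contrib"].cumsum().reindex(df.index)
    df["h_cumulative"] = asc["h_contrib"].cumsum().reindex(df.index)
    return df


def summary_dict(result: SelectomeResult) -> dict:
    return {
        "rp_threshold": result.rp_threshold,
        "h_selection_bits": result.h_selection,
        "h_naive_bits": result.h_naive,
        "d_kl_bits": result.d_kl,
        "n_clusters_total": result.n_clusters_total,
        "n_clusters_selectome": result.n_clusters_selectome,
        "n_hexamers_in_selectome": result.n_hexamers_in,
        "n_hexamers_out_selectome": result.n_hexamers_out,
        "hexamer_fraction_in_selectome": result.hexamer_fraction_in,
    }


UNIFORM_TETRAMER_ENTROPY = math.log2(N_TETRAMERS)  # 17.288 bits
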