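"""Positional composition profiles of aligned substrates.

Cluster members are aligned on an eight-position window, P5 P4 P3 P2 P1
P1' P2' P3' (Schechter-Berger numbering around the scissile P1-P1' bond).
A hexamer whose tetramer sits at offset 0 occupies P3..P3'; offset 1 maps
to P4..P2' and offset 2 to P5..P1'.  From aligned windows we build
position frequency matrices and information-content profiles, and
substrates can be stratified into deciles of RP/RP_Max to show how
composition shifts with substrate fitness.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Mapping

import numpy as np
import pandas as pd

from .clustering import TetramerCluster, ClusterTable, TETRAMER_LENGTH
from .extract import AA_ALPHABET

WINDOW_POSITIONS = ["P5", "P4", "P3", "P2", "P1", "P1'", "P2'", "P3'"]
MAX_POSITION_INFO = float(np.log2(20))  # bits for an invariant position


@dataclass
class PositionFrequencyMatrix:
    """20 x 8 residue counts over the P5-P3' window.

    ``counts`` rows are residues, columns window positions.  Frequencies
    normalize each column by its coverage (number of hexamers occupying
    that position); columns with zero coverage hold NaN.  Information
    content per position is ``log2 20 - H(position)`` in bits.
    """

    counts: pd.DataFrame
    coverage: pd.Series

    @property
    def frequencies(self) -> pd.DataFrame:
        freq = self.counts / self.coverage.replace(0, np.nan)
        return freq

    @property
    def information(self) -> pd.Series:
        info = {}
        for pos in WINDOW_POSITIONS:
            if self.coverage[pos] == 0:
                info[pos] = np.nan
                continue
            p = (self.counts[pos] / self.coverage[pos]).to_numpy()
            nz = p[p > 0]
            info[pos] = MAX_POSITION_INFO + float((nz * np.log2(nz)).sum())
        return pd.Series(info)


def align_members(cluster: TetramerCluster) -> pd.DataFrame:
    """Map each member hexamer onto the P5-P3' window.

    Returns a DataFrame indexed by hexamer with the eight window positions
    as columns; positions a hexamer does not reach are NaN.
    """
    rows = {}
    for hexamer, off in cluster.members:
        if hexamer[off : off + TETRAMER_LENGTH] != cluster.tetramer:
            raise ValueError(
                f"{hexamer!r} lacks {cluster.tetramer!r} at offset {off}"
            )
        start = 2 - off  # offset 0 starts at P3 (window index 2)
        row = [None] * len(WINDOW_POSITIONS)
        for i, aa in enumerate(hexamer):
            row[start + i] = aa
        rows[hexamer] = row
    return pd.DataFrame.from_dict(rows, orient="index", columns=WINDOW_POSITIONS)


def build_pfm(windows: pd.DataFrame) -> PositionFrequencyMatrix:
    """Count residues per window position over aligned hexamers.

    Each distinct hexamer is weighted once, consistent with the
    distinct-hexamer accounting used for cluster sizes.
    """
    if windows.empty:
        raise ValueError("no aligned windows")
    counts = pd.DataFrame(0, index=list(AA_ALPHABET), columns=WINDOW_POSITIONS)
    for pos in WINDOW_POSITIONS:
        col = windows[pos].dropna()
        vc = col.value_counts()
        counts.loc[vc.index, pos] = vc.astype(int)
    coverage = counts.sum(axis=0)
    return PositionFrequencyMatrix(counts=counts, coverage=coverage)


def pfm_for_clusters(table: ClusterTable, tetramers=None) -> PositionFrequencyMatrix:
    """Aggregate PFM over all members of the given clusters (default: all)."""
    keys = table.clusters.keys() if tetramers is None else tetramers
    frames = [align_members(table.clusters[t]) for t in keys if t in table.clusters]
    if not frames:
        raise ValueError("no clusters to profile")
    return build_pfm(pd.concat(frames))


def rp_decile_groups(rp_by_tetramer: Mapping[str, float]) -> dict[int, list[str]]:
    """Stratify clusters into 10 groups of RP relative to the maximum.

    Group k (1..10) holds clusters with RP/RP_Max in ((k-1)/10, k/10]
    (right-closed); an exact zero falls into group 1.
    """
    if not rp_by_tetramer:
        raise ValueError("empty selectome")
    rp_max = max(rp_by_tetramer.values())
    if rp_max <= 0:
        raise ValueError("RP_Max must be positive")
    groups: dict[int, list[str]] = {k: [] for k in range(1, 11)}
    for tet, rp in rp_by_tetramer.items():
        ratio = rp / rp_max
        k = 1 if ratio <= 0 else min(10, int(np.ceil(ratio * 10 - 1e-12)))
        groups[k].append(tet)
    return groups


def decile_pfms(
    table: ClusterTable, rp_by_tetramer: Mapping[str, float]
) -> dict[int, PositionFrequencyMatrix]:
    """Per-decile aggregate PFMs (empty deciles are omitted)."""
    groups = rp_decile_groups(rp_by_tetramer)
    out = {}
    for k, tets in groups.items():
        present = [t for t in tets if t in table.clusters]
        if present:
            out[k] = pfm_for_clusters(table, present)
    return out


def write_pfm_tsv(pfm: PositionFrequencyMatrix, path, kind: str = "counts") -> None:
    """Write a PFM as TSV (rows = residues, columns = P5..P3')."""
    if kind == "counts":
        pfm.counts.to_csv(path, sep="\t", index_label="residue")
    elif kind == "frequencies":
        pfm.frequencies.to_csv(path, sep="\t", index_label="residue", float_format="%.6g")
    else:
        raise ValueError("kind must be 'counts' or 'frequencies'")


def plot_pfm(pfm: PositionFrequencyMatrix, ax=None):
    """Stacked-bar frequency plot scaled by positional information content.

    A plain rendering of the logo concept: bar height at each position is
    the information content, split among residues by frequency.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    freqs = pfm.frequencies.fillna(0.0)
    info = pfm.information.fillna(0.0)
    bottom = np.zeros(len(WINDOW_POSITIONS))
    for aa in AA_ALPHABET:
        heights = freqs.loc[aa].to_numpy() * info.to_numpy()
        ax.bar(WINDOW_POSITIONS, heights, bottom=bottom, label=aa)
        bottom += heights
    ax.set_ylabel("information (bits)")
    ax.set_xlabel("substrate position")
    return ax
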