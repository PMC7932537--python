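"""Tetramer clustering of hexamer substrates.

Matrix metalloproteinases recognize substrates mainly through the P3-P1'
tetramer spanning their S3-S1' subsites.  A hexamer carries three candidate
tetramers (offsets 0, 1, 2).  Grouping hexamers that share a tetramer into
"tetramer clusters" identifies the P3-P1' register without experimental
scissile-bond mapping, and the number of distinct hexamers per cluster
(max 1200) measures that tetramer's contribution to catalytic efficiency.

Two clustering modes exist:

* ``naive`` — every hexamer joins all of its candidate clusters; used for
  the unselected library where no pressure favors one register.
* ``selection`` — redundancy is eliminated so each hexamer ends up in the
  single most abundant cluster it can belong to, making the cluster table a
  partition of the substrate set.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .extract import AA_ALPHABET, HexamerSet

TETRAMER_LENGTH = 4
N_TETRAMERS = 20 ** TETRAMER_LENGTH  # 160,000 possible P3-P1' motifs
MAX_CLUSTER_SIZE = 1200  # 3 placements x 20^2 contexts, minus overlaps


@dataclass
class TetramerCluster:
    tetramer: str
    members: list[tuple[str, int]] = field(default_factory=list)  # (hexamer, offset)

    @property
    def n_hexamers(self) -> int:
        return len(self.members)

    def validate(self) -> None:
        seen = set()
        for hexamer, off in self.members:
            if hexamer[off : off + TETRAMER_LENGTH] != self.tetramer:
                raise ValueError(
                    f"{hexamer!r} does not contain {self.tetramer!r} at offset {off}"
                )
            if hexamer in seen:
                raise ValueError(f"duplicate member {hexamer!r} in cluster {self.tetramer}")
            seen.add(hexamer)


@dataclass
class ClusterTable:
    clusters: dict[str, TetramerCluster]
    mode: str  # "selection" or "naive"

    @property
    def total_assignments(self) -> int:
        """Total hexamer-to-cluster assignments (the denominator of cluster
        probabilities)."""
        return sum(c.n_hexamers for c in self.clusters.values())

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def sizes(self) -> dict[str, int]:
        return {t: c.n_hexamers for t, c in self.clusters.items()}


def candidate_tetramers(hexamer: str) -> list[tuple[str, int]]:
    """The three tetramer windows of a hexamer, in offset order.

    Duplicate tetramers (e.g. in ``AAAAAA``) are retained with their
    distinct offsets.
    """
    if len(hexamer) != 6:
        raise ValueError(f"expected a hexamer, got {hexamer!r}")
    return [(hexamer[o : o + TETRAMER_LENGTH], o) for o in range(3)]


def _distinct_candidates(hexamer: str) -> list[tuple[str, int]]:
    """Candidate tetramers deduplicated by sequence, keeping the smallest
    offset for each."""
    out: dict[str, int] = {}
    for tet, off in candidate_tetramers(hexamer):
        out.setdefault(tet, off)
    return [(t, o) for t, o in out.items()]


def cluster_naive(hexamers: HexamerSet) -> ClusterTable:
    """Multi-membership clustering for the unselected library.

    Each distinct hexamer joins every distinct candidate tetramer cluster
    (1-3 clusters per hexamer).
    """
    if not hexamers.counts:
        raise ValueError("empty hexamer set")
    clusters: dict[str, TetramerCluster] = {}
    for hexamer in hexamers.counts:
        for tet, off in _distinct_candidates(hexamer):
            clusters.setdefault(tet, TetramerCluster(tet)).members.append((hexamer, off))
    return ClusterTable(clusters=clusters, mode="naive")


def cluster_selection(hexamers: HexamerSet) -> ClusterTable:
    """Unique-assignment clustering with redundancy elimination.

    Stage 1 builds the multi-membership table and records each cluster's
    initial distinct-hexamer count.  Stage 2 visits clusters from least to
    most abundant (ties broken lexicographically) and removes each still
    multiply-assigned hexamer from the visited cluster unless that cluster
    is the hexamer's most abundant candidate (candidate ties broken by
    smallest offset, then tetramer sequence).  Abundances are the static
    initial counts; they are not recomputed during elimination.  The result
    partitions the distinct hexamers.
    """
    if not hexamers.counts:
        raise ValueError("empty hexamer set")
    table = cluster_naive(hexamers)
    initial = table.sizes()

    membership: dict[str, set[str]] = {h: set() for h in hexamers.counts}
    for tet, cluster in table.clusters.items():
        for hexamer, _off in cluster.members:
            membership[hexamer].add(tet)

    def winner(hexamer: str) -> str:
        cands = _distinct_candidates(hexamer)
        best = min(cands, key=lambda c: (-initial[c[0]], c[1], c[0]))
        return best[0]

    for tet in sorted(table.clusters, key=lambda t: (initial[t], t)):
        cluster = table.clusters[tet]
        kept = []
        for hexamer, off in cluster.members:
            if len(membership[hexamer]) > 1 and winner(hexamer) != tet:
                membership[hexamer].discard(tet)
            else:
                kept.append((hexamer, off))
        cluster.members = kept

    clusters = {t: c for t, c in table.clusters.items() if c.members}
    return ClusterTable(clusters=clusters, mode="selection")


def max_hexamers_containing(tetramer: str) -> int:
    """Exact number of distinct hexamers containing a tetramer.

    Inclusion-exclusion over the three placements.  Each placement leaves
    two free positions (20^2 = 400 hexamers); placements can coincide only
    when the tetramer overlaps itself, so a non-self-overlapping tetramer
    reaches the 1200 maximum.
    """
    if len(tetramer) != TETRAMER_LENGTH:
        raise ValueError(f"expected a tetramer, got {tetramer!r}")

    def pair_count(i: int, j: int) -> int:
        d = j - i
        # both placements force hexamer[i:i+4] = hexamer[j:j+4] = tetramer,
        # which requires the tetramer to have period d
        if tetramer[d:] != tetramer[: TETRAMER_LENGTH - d]:
            return 0
        covered = TETRAMER_LENGTH + d
        return 20 ** (6 - covered)

    singles = 3 * 20 ** 2
    pairs = pair_count(0, 1) + pair_count(0, 2) + pair_count(1, 2)
    triple = 1 if len(set(tetramer)) == 1 else 0
    return singles - pairs + triple


def enumerate_hexamers_containing(tetramer: str) -> set[str]:
    """Brute-force enumeration of the hexamers counted by
    :func:`max_hexamers_containing` (small: at most 1200 strings)."""
    out: set[str] = set()
    for off in range(3):
        free = [i for i in range(6) if not (off <= i < off + TETRAMER_LENGTH)]
        for fill in itertools.product(AA_ALPHABET, repeat=len(free)):
            chars = [""] * 6
            chars[off : off + TETRAMER_LENGTH] = tetramer
            for i, ch in zip(free, fill):
                chars[i] = ch
            out.add("".join(chars))
    return out


def write_cluster_tsv(table: ClusterTable, path) -> None:
    """Cluster table as TSV: tetramer, n_hexamers, semicolon-joined
    ``hexamer:offset`` members, sorted by descending size then sequence."""
    rows = sorted(table.clusters.values(), key=lambda c: (-c.n_hexamers, c.tetramer))
    with open(path, "w") as fh:
        fh.write("tetramer\tn_hexamers\tmembers\n")
        for c in rows:
            members = ";".join(f"{h}:{o}" for h, o in sorted(c.members))
            fh.write(f"{c.tetramer}\t{c.n_hexamers}\t{members}\n")


def read_cluster_tsv(path, mode: str) -> ClusterTable:
    clusters: dict[str, TetramerCluster] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("tetramer"):
            raise ValueError(f"{path}: expected cluster TSV header")
        for line in fh:
            if not line.strip():
                continue
            tet, _n, members = line.rstrip("\n").split("\t")
            pairs = []
            for item in members.split(";"):
                if item:
                    h, o = item.split(":")
                    pairs.append((h, int(o)))
            clusters[tet] = TetramerCluster(tet, pairs)
    return ClusterTable(clusters=clusters, mode=mode)
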