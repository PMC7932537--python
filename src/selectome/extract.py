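"""Hexamer extraction from substrate phage amplicon reads.

Substrate phage libraries display randomized hexapeptides between constant
flanking tags on the PIII coat protein.  Amplicon reads covering the
variable region are translated in all six frames; a frame is accepted when
the variable insert sits strictly between the two constant amino-acid
flanks, has the expected length and contains only the 20 standard residues.
Hexamers seen in the untreated (no protease) control are removed from the
selection sets before any downstream statistics, since their survival is
unrelated to cleavage.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path

from Bio.Seq import Seq
from Bio import SeqIO

logger = logging.getLogger(__name__)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AA_ALPHABET)
_DNA_SET = frozenset("ACGTN")

SAMPLE_LABELS = ("naive", "control", "selection")


@dataclass
class FlankSpec:
    """Constant amino-acid tags bracketing the randomized insert.

    The published library's exact flank peptides are configuration, not a
    built-in constant: they depend on the vector used.  Both flanks must be
    at least 3 residues so that a match anchors a unique reading frame.
    """

    left: str
    right: str
    insert_length: int = 6

    def __post_init__(self) -> None:
        for name, flank in (("left", self.left), ("right", self.right)):
            if len(flank) < 3:
                raise ValueError(f"{name} flank must be >= 3 residues, got {flank!r}")
            if not set(flank) <= _AA_SET:
                raise ValueError(f"{name} flank contains non-standard residues: {flank!r}")
        if self.insert_length < 1:
            raise ValueError("insert_length must be >= 1")


@dataclass
class ReadBatch:
    """A batch of DNA reads from one sequencing sample.

    ``reads`` holds ``(identifier, sequence)`` pairs; qualities are not
    carried because extraction is sequence-driven (low-quality reads simply
    fail the flank match).
    """

    reads: list[tuple[str, str]]
    sample_label: str = "selection"
    protease_label: str = ""

    def __post_init__(self) -> None:
        if not self.reads:
            raise ValueError("ReadBatch must contain at least one read")
        if self.sample_label not in SAMPLE_LABELS:
            raise ValueError(f"sample_label must be one of {SAMPLE_LABELS}")
        for rid, seq in self.reads:
            if not set(seq.upper()) <= _DNA_SET:
                raise ValueError(f"read {rid!r} contains non-ACGTN characters")


@dataclass
class HexamerSet:
    """Multiset of distinct insert peptides with read counts."""

    counts: dict[str, int]
    n_reads_total: int = 0
    sample_label: str = "selection"
    protease_label: str = ""
    insert_length: int = 6

    def __post_init__(self) -> None:
        for pep, n in self.counts.items():
            if len(pep) != self.insert_length:
                raise ValueError(f"peptide {pep!r} has length != {self.insert_length}")
            if not set(pep) <= _AA_SET:
                raise ValueError(f"peptide {pep!r} contains non-standard residues")
            if n < 1:
                raise ValueError(f"count for {pep!r} must be >= 1")

    @property
    def n_distinct(self) -> int:
        return len(self.counts)

    @property
    def n_counted(self) -> int:
        return sum(self.counts.values())

    def to_tsv(self, path: str | Path) -> None:
        """Write ``hexamer<TAB>count`` sorted by descending count then sequence."""
        rows = sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))
        with open(path, "w") as fh:
            fh.write("hexamer\tcount\n")
            for pep, n in rows:
                fh.write(f"{pep}\t{n}\n")

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        sample_label: str = "selection",
        protease_label: str = "",
    ) -> "HexamerSet":
        counts: dict[str, int] = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("hexamer"):
                raise ValueError(f"{path}: expected 'hexamer<TAB>count' header")
            for line in fh:
                if not line.strip():
                    continue
                pep, n = line.split("\t")
                counts[pep] = counts.get(pep, 0) + int(n)
        if not counts:
            raise ValueError(f"{path}: no hexamer rows")
        length = len(next(iter(counts)))
        return cls(
            counts=counts,
            n_reads_total=sum(counts.values()),
            sample_label=sample_label,
            protease_label=protease_label,
            insert_length=length,
        )


@dataclass
class ExtractionStats:
    reads_in: int = 0
    hexamers_out: int = 0
    rejects: dict[str, int] = field(default_factory=dict)
    multi_frame_hits: int = 0

    def reject(self, reason: str) -> None:
        self.rejects[reason] = self.rejects.get(reason, 0) + 1


def translate_six_frames(dna: str) -> list[str]:
    """Translate a DNA sequence in all six frames.

    Returns forward frames 0, 1, 2 then reverse-complement frames 0, 1, 2.
    Trailing partial codons are dropped; stop codons appear as ``*`` and
    codons containing ``N`` as ``X``.
    """
    dna = dna.upper()
    if len(dna) < 3:
        raise ValueError(f"need >= 3 nt to translate, got {len(dna)}")
    if not set(dna) <= _DNA_SET:
        raise ValueError("sequence contains non-ACGTN characters")
    frames = []
    for strand in (dna, str(Seq(dna).reverse_complement())):
        for off in range(3):
            sub = strand[off : off + 3 * ((len(strand) - off) // 3)]
            frames.append(str(Seq(sub).translate()) if sub else "")
    return frames


def extract_insert(frame: str, spec: FlankSpec) -> str | None:
    """Pull the variable insert out of one translated frame.

    The insert is the substring strictly between the first occurrence of the
    left flank and the next occurrence of the right flank.  It is accepted
    only if its length equals ``spec.insert_length`` and it consists solely
    of the 20 standard residues (a stop ``*`` or ambiguous ``X`` inside the
    insert disqualifies it).
    """
    li = frame.find(spec.left)
    if li < 0:
        return None
    start = li + len(spec.left)
    ri = frame.find(spec.right, start)
    if ri < 0:
        return None
    insert = frame[start:ri]
    if len(insert) != spec.insert_length or not set(insert) <= _AA_SET:
        return None
    return insert


def build_hexamer_set(batch: ReadBatch, spec: FlankSpec) -> tuple[HexamerSet, ExtractionStats]:
    """Extract one insert per read and accumulate counts.

    Each read contributes at most one hexamer: the first frame (forward 0,
    1, 2 then reverse 0, 1, 2) yielding a valid insert wins.  Reads whose
    other frames would also match are tallied in ``multi_frame_hits``.
    """
    stats = ExtractionStats(reads_in=len(batch.reads))
    counts: dict[str, int] = {}
    for rid, seq in batch.reads:
        if len(seq) < 3:
            stats.reject("too_short")
            continue
        hits = [h for h in (extract_insert(f, spec) for f in translate_six_frames(seq)) if h]
        if not hits:
            stats.reject("no_valid_insert")
            continue
        if len(hits) > 1:
            stats.multi_frame_hits += 1
        counts[hits[0]] = counts.get(hits[0], 0) + 1
        stats.hexamers_out += 1
    if not counts:
        raise ValueError(
            f"no inserts extracted with flanks {spec.left!r}/{spec.right!r} "
            f"(insert_length={spec.insert_length}) from {stats.reads_in} reads"
        )
    logger.info(
        "extracted %d inserts (%d distinct) from %d reads; rejects: %s",
        stats.hexamers_out, len(counts), stats.reads_in, stats.rejects,
    )
    hexset = HexamerSet(
        counts=counts,
        n_reads_total=stats.reads_in,
        sample_label=batch.sample_label,
        protease_label=batch.protease_label,
        insert_length=spec.insert_length,
    )
    return hexset, stats


def subtract_control(selection: HexamerSet, control: HexamerSet) -> HexamerSet:
    """Remove every hexamer seen in the untreated control from a selection.

    Removal is by sequence identity regardless of counts: survival of a
    hexamer without protease means its enrichment cannot be attributed to
    cleavage.
    """
    kept = {h: n for h, n in selection.counts.items() if h not in control.counts}
    removed = selection.n_distinct - len(kept)
    frac = removed / selection.n_distinct if selection.n_distinct else 0.0
    logger.info("control subtraction removed %d/%d distinct hexamers (%.2f%%)",
                removed, selection.n_distinct, 100 * frac)
    if not kept:
        logger.warning("control subtraction removed every hexamer from the selection")
    return HexamerSet(
        counts=kept,
        n_reads_total=selection.n_reads_total,
        sample_label=selection.sample_label,
        protease_label=selection.protease_label,
        insert_length=selection.insert_length,
    )


def read_batch_from_file(
    path: str | Path,
    sample_label: str = "selection",
    protease_label: str = "",
) -> ReadBatch:
    """Load a ReadBatch from FASTQ(.gz) or FASTA(.gz)."""
    path = Path(path)
    name = path.name.lower()
    gz = name.endswith(".gz")
    stem = name[:-3] if gz else name
    fmt = "fastq" if stem.endswith((".fastq", ".fq")) else "fasta"
    opener = gzip.open if gz else open
    with opener(path, "rt") as fh:
        reads = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, fmt)]
    return ReadBatch(reads=reads, sample_label=sample_label, protease_label=protease_label)
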