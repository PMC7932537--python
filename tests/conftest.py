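"""Shared fixtures: reverse translation and small simulated experiments."""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Data import CodonTable
from hypothesis import settings

from selectome import FlankSpec, HexamerSet

settings.register_profile("deterministic", derandomize=True, deadline=None,
                          database=None)
settings.load_profile("deterministic")

# one canonical codon per residue (first hit in the standard table)
_CODON: dict[str, str] = {}
for codon, aa in sorted(CodonTable.unambiguous_dna_by_id[1].forward_table.items()):
    _CODON.setdefault(aa, codon)


def reverse_translate(peptide: str) -> str:
    return "".join(_CODON[aa] for aa in peptide)


@pytest.fixture
def flank_spec() -> FlankSpec:
    return FlankSpec(left="DLA", right="GAE", insert_length=6)


def encode_read(hexamer: str, spec: FlankSpec, prefix: str = "GG", suffix: str = "CC") -> str:
    """DNA read carrying left_flank + hexamer + right_flank in frame."""
    return prefix + reverse_translate(spec.left + hexamer + spec.right) + suffix


def random_hexamer_set(rng: np.random.Generator, n: int) -> HexamerSet:
    """n distinct random hexamers, unit counts (alphabet restricted to 6
    residues so that cluster collisions actually occur at small n)."""
    alphabet = np.array(list("ACDEFG"))
    seen: dict[str, int] = {}
    while len(seen) < n:
        seen["".join(rng.choice(alphabet, size=6))] = 1
    return HexamerSet(counts=seen, n_reads_total=n)
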