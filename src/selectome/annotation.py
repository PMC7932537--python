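"""Selectome-based annotation of cleavage sites in proteins.

A cleavage site in a protein is identified by the 1-based index of P1',
the first residue after the scissile bond.  Projecting the P3-P1' tetramer
onto the protein sequence lets every site be scored against a protease's
RP table and classified against its selectome:

* ``selectome`` — RP above the selectome threshold: catalytic-cleft driven
  cleavage;
* ``sub_threshold`` — present in the substrate set but below threshold: a
  poor P3-P1' sequence, i.e. a bystander event or exosite-assisted;
* ``absent`` — tetramer never seen in the phage selection (RP = 0).

N-terminomics evidence enters as the log2 isotopic enrichment (IE) of a
labeled neo-N-terminus in protease-treated versus control samples; a site
counts as enriched when its IE lies strictly more than one standard
deviation above the population mean.  Database records in the MEROPS
style carry the P4-P4' octamer directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .clustering import TETRAMER_LENGTH
from .extract import AA_ALPHABET

logger = logging.getLogger(__name__)

_AA_SET = frozenset(AA_ALPHABET)

CATEGORIES = ("selectome", "sub_threshold", "absent")


@dataclass
class CleavageSite:
    protein_id: str
    p1prime_index: int | None = None  # 1-based index of P1'
    window: str | None = None  # P4-P4' octamer, when available
    tetramer: str | None = None  # P3-P1'
    rp: float | None = None
    rank: int | None = None
    ie_log2: float | None = None
    z: float | None = None
    category: str | None = None
    projectable: bool = True


@dataclass
class EnrichmentStats:
    mean: float
    sd: float  # sample (n-1) standard deviation
    z: list[float] = field(default_factory=list)


def project_tetramer(protein_sequence: str, p1prime_index: int) -> str:
    """P3-P1' tetramer at a cleavage site, 1-based P1' coordinates.

    Returns residues p1prime_index-3 .. p1prime_index.  Sites too close to
    the N-terminus for a full tetramer raise (callers flag them
    unprojectable rather than guessing a truncated motif).
    """
    if p1prime_index < TETRAMER_LENGTH or p1prime_index > len(protein_sequence):
        raise ValueError(
            f"P1' index {p1prime_index} out of range for a full P3-P1' tetramer"
        )
    return protein_sequence[p1prime_index - TETRAMER_LENGTH : p1prime_index]


def parse_octamer(p4_to_p4prime: str) -> str:
    """P3-P1' tetramer from a P4-P4' octamer (characters 2-5)."""
    if len(p4_to_p4prime) != 8:
        raise ValueError(f"expected a P4-P4' octamer, got {p4_to_p4prime!r}")
    if not set(p4_to_p4prime) <= _AA_SET:
        raise ValueError(f"octamer contains non-standard residues: {p4_to_p4prime!r}")
    return p4_to_p4prime[1:5]


def enrichment_stats(ie_values) -> EnrichmentStats:
    """Population mean/sd of log2 isotopic enrichment and per-site z scores.

    Uses the sample (n-1) standard deviation.  Replicate channels should
    be averaged on the log2 scale before calling.
    """
    values = np.asarray(list(ie_values), dtype=float)
    if values.size < 2 or not np.all(np.isfinite(values)):
        raise ValueError("need >= 2 finite IE values")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    if sd == 0:
        raise ValueError("IE values are all equal: sd = 0")
    return EnrichmentStats(mean=mean, sd=sd, z=list((values - mean) / sd))


def ie_positive(z: float) -> bool:
    """Strict >1 sigma enrichment cut; exactly 1 sigma does not qualify."""
    return z > 1.0


def classify_sites(
    sites: list[CleavageSite],
    rp_lookup,
    rp_threshold: float | None,
) -> tuple[list[CleavageSite], dict[str, float]]:
    """Assign each projectable site a selectome category.

    ``rp_lookup`` maps a tetramer to its RP (e.g. ``RPTable.rp_of``); a
    ``None`` threshold (no definable specificity) leaves no site in the
    ``selectome`` category.  Returns the sites (mutated in place) and the
    category fractions over projectable sites.
    """
    n_by_cat = dict.fromkeys(CATEGORIES, 0)
    n_proj = 0
    for site in sites:
        if not site.projectable or site.tetramer is None:
            site.category = None
            continue
        n_proj += 1
        site.rp = float(rp_lookup(site.tetramer))
        if site.rp == 0:
            site.category = "absent"
        elif rp_threshold is not None and site.rp > rp_threshold:
            site.category = "selectome"
        else:
            site.category = "sub_threshold"
        n_by_cat[site.category] += 1
    fractions = {c: (n / n_proj if n_proj else 0.0) for c, n in n_by_cat.items()}
    logger.info("classified %d sites: %s", n_proj, fractions)
    return sites, fractions


def selectivity_correlation(
    df: pd.DataFrame,
    group: str,
    rp_max_a: float,
    rp_max_b: float,
    criterion: str = "ie",
    ie_sigma: float = 1.0,
) -> tuple[float, float]:
    """OLS of RP/RP_Max (protease B) on RP/RP_Max (protease A) in a group.

    ``df`` needs columns ``rp_a`` and ``rp_b``; for the IE criterion also
    ``z_a`` and ``z_b``.  Groups: ``shared`` (enriched/above-threshold for
    both proteases), ``unique_a``, ``unique_b``.  For shared substrates of
    two enzymes with similar specificity the slope approaches 1; for
    substrates unique to one enzyme the other's RP carries no signal and
    the slope collapses toward 0.  Returns (slope, R^2).
    """
    if group not in ("shared", "unique_a", "unique_b"):
        raise ValueError(f"unknown group {group!r}")
    if criterion == "ie":
        pos_a = df["z_a"] > ie_sigma
        pos_b = df["z_b"] > ie_sigma
    elif criterion == "rp":
        pos_a = df["rp_a"] > df["threshold_a"]
        pos_b = df["rp_b"] > df["threshold_b"]
    else:
        raise ValueError("criterion must be 'ie' or 'rp'")
    mask = {
        "shared": pos_a & pos_b,
        "unique_a": pos_a & ~pos_b,
        "unique_b": pos_b & ~pos_a,
    }[group]
    sub = df[mask]
    if len(sub) < 3:
        raise ValueError(f"group {group!r} has fewer than 3 sites")
    x = sub["rp_a"] / rp_max_a
    y = sub["rp_b"] / rp_max_b
    if x.nunique() == 1:
        raise ValueError("no variance in RP/RP_Max for protease A")
    fit = sps.linregress(x, y)
    return float(fit.slope), float(fit.rvalue) ** 2


def sites_from_table(
    table: pd.DataFrame,
    proteome: dict[str, str] | None = None,
) -> list[CleavageSite]:
    """Build CleavageSite records from a sites table.

    Accepted columns: ``protein_id`` plus either ``p1prime_index`` (needs
    ``proteome``) or ``octamer``; optional IE replicate columns named
    ``ie_log2`` or ``ie_log2_<rep>`` (averaged on the log2 scale).
    Octamer records that are malformed are skipped with a log message;
    sites whose P1' lies before residue 4 are flagged unprojectable.
    """
    sites = []
    ie_cols = [c for c in table.columns if c == "ie_log2" or c.startswith("ie_log2_")]
    skipped = 0
    for _, row in table.iterrows():
        ie = None
        if ie_cols:
            vals = [row[c] for c in ie_cols if pd.notna(row[c])]
            ie = float(np.mean(vals)) if vals else None
        site = CleavageSite(protein_id=str(row["protein_id"]), ie_log2=ie)
        octamer = row.get("octamer")
        p1p = row.get("p1prime_index")
        if octamer is not None and pd.notna(octamer) and octamer != "":
            try:
                site.tetramer = parse_octamer(str(octamer))
                site.window = str(octamer)
            except ValueError as exc:
                logger.info("skipping octamer record: %s", exc)
                skipped += 1
                continue
        elif p1p is not None and pd.notna(p1p):
            if proteome is None:
                raise ValueError("p1prime_index records require a proteome")
            seq = proteome.get(site.protein_id)
            if seq is None:
                logger.info("skipping site in unknown protein %s", site.protein_id)
                skipped += 1
                continue
            site.p1prime_index = int(p1p)
            try:
                site.tetramer = project_tetramer(seq, site.p1prime_index)
            except ValueError:
                site.projectable = False  # N-terminal truncation
        else:
            logger.info("skipping site with neither octamer nor position")
            skipped += 1
            continue
        sites.append(site)
    if skipped:
        logger.info("skipped %d malformed site records", skipped)
    return sites


def map_peptide_to_position(proteome: dict[str, str], peptide: str) -> tuple[str, int] | None:
    """Locate a neo-N-terminal peptide in a proteome by exact prefix match.

    Returns (protein_id, 1-based index of the peptide's first residue),
    i.e. the P1' coordinate of the cleavage that created the N-terminus.
    First match wins; additional matches are logged.
    """
    hits = []
    for pid, seq in proteome.items():
        start = seq.find(peptide)
        while start >= 0:
            hits.append((pid, start + 1))
            start = seq.find(peptide, start + 1)
    if not hits:
        return None
    if len(hits) > 1:
        logger.warning("peptide %s maps to %d positions; keeping the first", peptide, len(hits))
    return hits[0]
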