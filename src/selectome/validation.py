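"""Kinetic validation of RP as a fitness statistic.

Two checks connect RP to measured catalysis:

* correlation between RP and measured catalytic constants (K_obs or
  kcat/K_M), raw and after binning substrates by ascending RP — binning
  averages out the unpredictable P5-P4/P2'-P3' context effects, so the
  correlation should strengthen;
* a confusion-matrix classification asking whether RP above a threshold
  predicts a non-zero catalytic constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .clustering import candidate_tetramers, TETRAMER_LENGTH
from .stats import RPTable


@dataclass
class KineticRecord:
    peptide: str
    constant: float  # K_obs or kcat/K_M, M^-1 s^-1 (0 = not cleaved)
    tetramer: str
    rp: float
    sd: float | None = None
    matched: bool = True


@dataclass
class ClassificationMetrics:
    tp: int
    tn: int
    fp: int
    fn: int
    mcc_undefined: bool = False

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else float("nan")

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n if self.n else float("nan")

    @property
    def fp_rate(self) -> float:
        d = self.fp + self.tn
        return self.fp / d if d else float("nan")

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else float("nan")

    @property
    def mcc(self) -> float:
        num = self.tp * self.tn - self.fp * self.fn
        den = math.sqrt(
            (self.tp + self.fp) * (self.tp + self.fn)
            * (self.tn + self.fp) * (self.tn + self.fn)
        )
        if den == 0:
            return 0.0
        return num / den

    def as_dict(self) -> dict:
        return {
            "TP": self.tp, "TN": self.tn, "FP": self.fp, "FN": self.fn,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "accuracy": self.accuracy, "fp_rate": self.fp_rate,
            "precision": self.precision, "mcc": self.mcc,
            "mcc_undefined": self.mcc_undefined,
        }


@dataclass
class BinnedCorrelation:
    pearson_r_raw: float
    bins: pd.DataFrame  # mean_rp, mean_constant, sem_constant, n per bin
    slope: float
    intercept: float
    r_squared: float

    @property
    def pearson_r_binned(self) -> float:
        return math.copysign(math.sqrt(self.r_squared), self.slope)


def resolve_tetramer(
    peptide: str, rp: RPTable, cleavage_index: int | None = None
) -> tuple[str, float]:
    """P3-P1' tetramer and RP for a kinetic peptide.

    With a known scissile position (``cleavage_index`` = 1-based index of
    P1'), the tetramer is the four residues ending at P1'.  Without one,
    hexamers are resolved by cluster lookup: among the peptide's candidate
    tetramers, the one with the highest RP wins (ties to the smallest
    offset), mirroring the most-abundant-cluster assignment rule.
    """
    if cleavage_index is not None:
        if cleavage_index < TETRAMER_LENGTH or cleavage_index > len(peptide):
            raise ValueError(
                f"cleavage index {cleavage_index} does not leave a full P3-P1' "
                f"tetramer in {peptide!r}"
            )
        tet = peptide[cleavage_index - TETRAMER_LENGTH : cleavage_index]
        return tet, rp.rp_of(tet)
    if len(peptide) != 6:
        raise ValueError(
            f"peptide {peptide!r} needs a cleavage index (only hexamers are "
            "resolvable by cluster lookup)"
        )
    best = max(
        candidate_tetramers(peptide),
        key=lambda c: (rp.rp_of(c[0]), -c[1]),
    )
    return best[0], rp.rp_of(best[0])


def match_kinetics(
    peptides: pd.DataFrame, rp: RPTable
) -> tuple[list[KineticRecord], float]:
    """Join kinetic measurements to cluster RP values.

    ``peptides`` needs columns ``peptide`` and ``constant``; optional
    ``cleavage_index`` (1-based P1') and ``sd``.  Returns the records and
    the fraction whose tetramer has no cluster in the table (they keep
    RP = 0).
    """
    records = []
    unmatched = 0
    for row in peptides.itertuples(index=False):
        ci = getattr(row, "cleavage_index", None)
        if ci is not None and (pd.isna(ci) or ci == ""):
            ci = None
        tet, rp_val = resolve_tetramer(row.peptide, rp, None if ci is None else int(ci))
        matched = tet in rp.df.index
        if not matched:
            unmatched += 1
        sd = getattr(row, "sd", None)
        records.append(
            KineticRecord(
                peptide=row.peptide,
                constant=float(row.constant),
                tetramer=tet,
                rp=rp_val,
                sd=None if sd is None or pd.isna(sd) else float(sd),
                matched=matched,
            )
        )
    frac = unmatched / len(records) if records else 0.0
    return records, frac


def binned_correlation(
    records: list[KineticRecord],
    n_per_bin: int | None = None,
    n_bins: int | None = None,
    equal_width: bool = False,
) -> BinnedCorrelation:
    """Raw and binned correlation between RP and catalytic constants.

    Records are sorted by ascending RP and grouped into bins of equal
    record count (default), or into equal-width RP bins when
    ``equal_width`` is set.  Bin means of the constant are regressed on
    bin means of RP by ordinary least squares; SEM = sd/sqrt(n) per bin.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 records")
    df = pd.DataFrame(
        {"rp": [r.rp for r in records], "k": [r.constant for r in records]}
    ).sort_values("rp", kind="stable").reset_index(drop=True)
    if df["k"].nunique() == 1:
        raise ValueError("all constants identical: correlation undefined")

    r_raw, _ = sps.pearsonr(df["rp"], df["k"])

    if n_per_bin is None and n_bins is None:
        n_per_bin = max(1, len(df) // 10)
    if equal_width:
        nb = n_bins or (len(df) // (n_per_bin or 1))
        df["bin"] = pd.cut(df["rp"], bins=nb, labels=False, include_lowest=True)
    elif n_bins is not None:
        df["bin"] = (np.arange(len(df)) * n_bins) // len(df)
    else:
        df["bin"] = np.arange(len(df)) // n_per_bin

    grouped = df.groupby("bin")
    bins = pd.DataFrame(
        {
            "mean_rp": grouped["rp"].mean(),
            "mean_constant": grouped["k"].mean(),
            "sem_constant": grouped["k"].apply(
                lambda x: x.std(ddof=1) / math.sqrt(len(x)) if len(x) > 1 else 0.0
            ),
            "n": grouped.size(),
        }
    ).dropna(subset=["mean_rp"])
    if len(bins) < 2 or bins["mean_rp"].nunique() == 1:
        raise ValueError("too few distinct bins for regression")
    fit = sps.linregress(bins["mean_rp"], bins["mean_constant"])
    return BinnedCorrelation(
        pearson_r_raw=float(r_raw),
        bins=bins.reset_index(drop=True),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
    )


def binary_classification(
    records: list[KineticRecord], rp_threshold: float
) -> ClassificationMetrics:
    """Confusion matrix of RP-above-threshold vs non-zero catalytic constant.

    TP: RP > threshold and constant > 0; TN: RP <= threshold and constant
    = 0; FP: RP > threshold, constant = 0; FN: RP <= threshold, constant
    > 0.  A zero MCC denominator is reported as MCC 0 with a flag.
    """
    if not records:
        raise ValueError("no records to classify")
    tp = tn = fp = fn = 0
    for r in records:
        above = r.rp > rp_threshold
        cleaved = r.constant > 0
        if above and cleaved:
            tp += 1
        elif above:
            fp += 1
        elif cleaved:
            fn += 1
        else:
            tn += 1
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    return ClassificationMetrics(tp=tp, tn=tn, fp=fp, fn=fn, mcc_undefined=den == 0)


def read_kinetics_tsv(path: str | Path) -> pd.DataFrame:
    """Kinetics table: ``peptide  cleavage_index  constant  [sd]``.

    ``cleavage_index`` is the 1-based position of P1'; blank means the
    peptide is a hexamer to be resolved by cluster lookup.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"peptide", "constant"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: kinetics TSV needs columns {sorted(required)}")
    if "cleavage_index" in df.columns:
        df["cleavage_index"] = df["cleavage_index"].astype("Int64")
    return df
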