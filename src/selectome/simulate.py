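"""Synthetic substrate phage display experiments.

The simulator generates every input the analysis pipeline consumes, with
the statistical structure the analysis assumes:

* a **specificity landscape**: per-tetramer kcat/K_M drawn from an
  additive position-weight energy model over P3-P1' with log-normal
  noise — the ground truth the pipeline should recover;
* a **naive library** of hexamers drawn uniformly from the 64,000,000
  possibilities, sequenced by multinomial sampling;
* **selection rounds** under pseudo-first-order cleavage kinetics: each
  hexamer is cleaved at its best tetramer site with probability
  ``1 - exp(-k * [E] * t)``, modulated by a per-hexamer log-normal context
  factor standing in for P5/P4/P2'/P3' effects; uncleaved phage leak past
  immunodepletion at a small rate, and the surviving pool is resampled to
  sequencing depth each round;
* kinetic validation tables with multiplicative measurement noise and a
  detection ceiling, and toy proteomes with cleavage sites planted at
  recorded positions.

Defaults mirror a two-round selection at 200 nM enzyme for 2 h, a regime
in which a substrate with kcat/K_M = 3,289 M^-1 s^-1 is 99% cleaved per
round.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .extract import AA_ALPHABET, HexamerSet
from .clustering import TETRAMER_LENGTH, N_TETRAMERS

logger = logging.getLogger(__name__)

N_HEXAMERS_TOTAL = 20 ** 6  # 64,000,000
_AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}


def encode_peptides(peptides, length: int) -> np.ndarray:
    """Base-20 integer codes for equal-length peptides."""
    arr = np.zeros(len(peptides), dtype=np.int64)
    for j, pep in enumerate(peptides):
        code = 0
        for ch in pep:
            code = code * 20 + _AA_INDEX[ch]
        arr[j] = code
    return arr


def decode_peptides(codes: np.ndarray, length: int) -> list[str]:
    codes = np.asarray(codes, dtype=np.int64)
    digits = np.empty((len(codes), length), dtype=np.int64)
    rem = codes.copy()
    for pos in range(length - 1, -1, -1):
        digits[:, pos] = rem % 20
        rem //= 20
    alphabet = np.array(list(AA_ALPHABET))
    return ["".join(row) for row in alphabet[digits]]


def hexamer_tetramer_codes(hex_codes: np.ndarray) -> np.ndarray:
    """(n, 3) array of candidate tetramer codes at offsets 0, 1, 2.

    A hexamer code d0..d5 (base 20) yields tetramer codes d0..d3, d1..d4,
    d2..d5.
    """
    hex_codes = np.asarray(hex_codes, dtype=np.int64)
    t0 = hex_codes // 400  # drop d4, d5
    t1 = (hex_codes // 20) % N_TETRAMERS
    t2 = hex_codes % N_TETRAMERS
    return np.stack([t0, t1, t2], axis=1)


@dataclass
class SpecificityLandscape:
    """Ground-truth kcat/K_M (M^-1 s^-1) for every one of the 160,000
    tetramers, plus the context dispersion applied per hexamer."""

    rates: np.ndarray  # shape (160000,), non-negative
    context_sd: float = 0.5
    seed: int | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.shape != (N_TETRAMERS,):
            raise ValueError(f"rates must have shape ({N_TETRAMERS},)")
        if not np.all(np.isfinite(self.rates)) or np.any(self.rates < 0):
            raise ValueError("rates must be finite and non-negative")

    def rate_of(self, tetramer: str) -> float:
        return float(self.rates[encode_peptides([tetramer], TETRAMER_LENGTH)[0]])


@dataclass
class SelectionConfig:
    """Experimental conditions of a simulated selection.

    Defaults follow the standard protocol: 200 nM active enzyme, 2 h
    incubation, two selection rounds.  Sequencing depth of the naive
    library exceeds that of the selections, as in practice.
    """

    enzyme_conc: float = 200e-9  # M
    time: float = 7200.0  # s
    n_rounds: int = 2
    naive_depth: int = 4_000_000
    selection_depth: int = 1_000_000
    immunodepletion_efficiency: float = 0.99
    seed: int = 0
    sum_rates: bool = False  # cleave at best site (default) or sum of sites

    def __post_init__(self) -> None:
        if min(self.enzyme_conc, self.time, self.n_rounds, self.naive_depth,
               self.selection_depth) < 0:
            raise ValueError("all config values must be non-negative")
        if not 0 <= self.immunodepletion_efficiency <= 1:
            raise ValueError("immunodepletion_efficiency must be in [0, 1]")


def make_landscape(
    seed: int,
    weight_sd: float = 1.5,
    scale: float = 50.0,
    noise_sd: float = 0.5,
    context_sd: float = 0.5,
    weights: np.ndarray | None = None,
    single_peak: tuple[str, float] | None = None,
) -> SpecificityLandscape:
    """Build a per-tetramer rate landscape.

    ``k(t) = scale * exp(sum of position weights + eps)`` with
    ``eps ~ N(0, noise_sd)``.  ``weights`` may supply an explicit (4, 20)
    position-weight matrix; otherwise weights are drawn N(0, weight_sd).
    ``single_peak=(tetramer, rate)`` instead makes one tetramer hot and
    every other rate zero.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    if single_peak is not None:
        tet, rate = single_peak
        rates = np.zeros(N_TETRAMERS)
        rates[encode_peptides([tet], TETRAMER_LENGTH)[0]] = rate
        return SpecificityLandscape(
            rates=rates, context_sd=context_sd, seed=seed,
            params={"single_peak": [tet, rate]},
        )
    if weights is None:
        weights = rng.normal(0.0, weight_sd, size=(TETRAMER_LENGTH, 20))
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (TETRAMER_LENGTH, 20):
        raise ValueError("weights must have shape (4, 20)")
    # energy of tetramer code d0 d1 d2 d3 = sum_p weights[p, d_p]
    energy = np.zeros(N_TETRAMERS)
    codes = np.arange(N_TETRAMERS)
    for pos in range(TETRAMER_LENGTH):
        digit = (codes // 20 ** (TETRAMER_LENGTH - 1 - pos)) % 20
        energy += weights[pos, digit]
    if noise_sd > 0:
        energy += rng.normal(0.0, noise_sd, size=N_TETRAMERS)
    rates = scale * np.exp(energy)
    return SpecificityLandscape(
        rates=rates, context_sd=context_sd, seed=seed,
        params={"weight_sd": weight_sd, "scale": scale, "noise_sd": noise_sd},
    )


def simulate_naive_library(
    n_distinct: int, depth: int, seed: int
) -> tuple[HexamerSet, np.ndarray, np.ndarray]:
    """Uniform naive hexamer library with multinomial read sampling.

    Distinct hexamers are drawn uniformly without replacement from the
    20^6 space; read counts are multinomial at ``depth`` over a uniform
    abundance vector.  Returns the HexamerSet plus the hexamer codes and
    counts arrays used by :func:`simulate_selection`.
    """
    if not 1 <= n_distinct <= N_HEXAMERS_TOTAL:
        raise ValueError("n_distinct out of range")
    rng = np.random.default_rng(seed)
    codes = np.array([], dtype=np.int64)
    while len(codes) < n_distinct:
        need = n_distinct - len(codes)
        draw = rng.integers(0, N_HEXAMERS_TOTAL, size=int(need * 1.2) + 16)
        codes = np.unique(np.concatenate([codes, draw]))
    codes = rng.permutation(codes)[:n_distinct]
    codes.sort()
    counts = rng.multinomial(depth, np.full(n_distinct, 1.0 / n_distinct))
    keep = counts > 0
    codes, counts = codes[keep], counts[keep]
    peptides = decode_peptides(codes, 6)
    hexset = HexamerSet(
        counts=dict(zip(peptides, counts.tolist())),
        n_reads_total=depth,
        sample_label="naive",
    )
    return hexset, codes, counts


def effective_rates(
    hex_codes: np.ndarray, landscape: SpecificityLandscape, rng: np.random.Generator,
    sum_rates: bool = False,
) -> np.ndarray:
    """Per-hexamer cleavage rate: best (or summed) tetramer-site rate times
    a log-normal context factor."""
    tets = hexamer_tetramer_codes(hex_codes)
    site = landscape.rates[tets]
    base = site.sum(axis=1) if sum_rates else site.max(axis=1)
    if landscape.context_sd > 0:
        base = base * rng.lognormal(0.0, landscape.context_sd, size=len(base))
    return base


def simulate_selection(
    naive_codes: np.ndarray,
    naive_counts: np.ndarray,
    landscape: SpecificityLandscape | None,
    config: SelectionConfig,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Run selection rounds; returns (codes, counts) per round.

    Each round: cleaved phage are retained binomially with the kinetic
    cleavage probability, uncleaved phage escape immunodepletion with
    probability ``1 - efficiency``, and the surviving pool is resampled
    multinomially to ``selection_depth`` reads.  ``landscape=None``
    simulates the untreated control (cleavage probability 0 everywhere).
    """
    rng = np.random.default_rng(config.seed)
    if landscape is not None:
        k_eff = effective_rates(naive_codes, landscape, rng, config.sum_rates)
        p_cleave = 1.0 - np.exp(-k_eff * config.enzyme_conc * config.time)
    else:
        p_cleave = np.zeros(len(naive_codes))

    codes, counts = naive_codes, naive_counts.astype(np.int64)
    p = p_cleave
    rounds = []
    for _ in range(config.n_rounds):
        cleaved = rng.binomial(counts, p)
        uncleaved = counts - cleaved
        leaked = rng.binomial(uncleaved, 1.0 - config.immunodepletion_efficiency)
        pool = cleaved + leaked
        total = int(pool.sum())
        if total == 0:
            raise RuntimeError(
                "no phage survived the round; raise immunodepletion leakage, "
                "enzyme concentration or library size"
            )
        counts = rng.multinomial(config.selection_depth, pool / total)
        keep = counts > 0
        codes, counts, p = codes[keep], counts[keep], p[keep]
        rounds.append((codes, counts))
    return rounds


def hexamer_set_from_codes(
    codes: np.ndarray, counts: np.ndarray, sample_label: str, protease_label: str = ""
) -> HexamerSet:
    return HexamerSet(
        counts=dict(zip(decode_peptides(codes, 6), np.asarray(counts).tolist())),
        n_reads_total=int(np.asarray(counts).sum()),
        sample_label=sample_label,
        protease_label=protease_label,
    )


@dataclass
class SimulatedExperiment:
    naive: HexamerSet
    control: HexamerSet
    selection: HexamerSet
    rounds: list[HexamerSet]
    landscape: SpecificityLandscape
    config: SelectionConfig
    n_distinct_naive: int

    def manifest(self) -> dict:
        cfg = asdict(self.config)
        return {
            "config": cfg,
            "landscape_params": self.landscape.params,
            "landscape_seed": self.landscape.seed,
            "context_sd": self.landscape.context_sd,
            "n_distinct_naive": self.n_distinct_naive,
        }


def simulate_experiment(
    landscape: SpecificityLandscape,
    config: SelectionConfig,
    n_distinct_naive: int = 1_000_000,
) -> SimulatedExperiment:
    """Full experiment: naive library, untreated control, protease selection.

    Sub-seeds for the three samples are derived from ``config.seed`` so the
    whole experiment is reproducible from one integer.
    """
    s_naive, s_ctrl, s_sel = [int(s.generate_state(1)[0] % 2**31)
                              for s in np.random.SeedSequence(config.seed).spawn(3)]
    naive, codes, counts = simulate_naive_library(n_distinct_naive, config.naive_depth, s_naive)

    ctrl_cfg = SelectionConfig(**{**asdict(config), "seed": s_ctrl})
    ctrl_rounds = simulate_selection(codes, counts, None, ctrl_cfg)
    control = hexamer_set_from_codes(*ctrl_rounds[-1], "control")

    sel_cfg = SelectionConfig(**{**asdict(config), "seed": s_sel})
    sel_rounds = simulate_selection(codes, counts, landscape, sel_cfg)
    rounds = [hexamer_set_from_codes(c, n, "selection") for c, n in sel_rounds]
    logger.info(
        "simulated experiment: %d naive, %d control, %d selection hexamers",
        naive.n_distinct, control.n_distinct, rounds[-1].n_distinct,
    )
    return SimulatedExperiment(
        naive=naive, control=control, selection=rounds[-1], rounds=rounds,
        landscape=landscape, config=config, n_distinct_naive=n_distinct_naive,
    )


def emit_kinetics_table(
    landscape: SpecificityLandscape,
    hexamers: list[str],
    noise_sd: float = 0.3,
    ceiling: float = 12_792.0,
    floor: float = 50.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Kinetic measurements for sampled hexamers.

    The constant is the hexamer's effective rate (best tetramer site times
    context factor) with multiplicative log-normal measurement noise,
    censored at the assay ceiling; rates below the detection ``floor``
    (a substrate cleaved a few percent over the assay window cannot be
    quantified) are recorded as 0.  ``cleavage_index`` records the 1-based
    P1' of the best site.
    """
    if ceiling <= 0:
        raise ValueError("ceiling must be positive")
    if floor < 0 or floor >= ceiling:
        raise ValueError("floor must be in [0, ceiling)")
    rng = np.random.default_rng(seed)
    codes = encode_peptides(hexamers, 6)
    tets = hexamer_tetramer_codes(codes)
    site = landscape.rates[tets]
    offsets = site.argmax(axis=1)
    base = site.max(axis=1)
    if landscape.context_sd > 0:
        base = base * rng.lognormal(0.0, landscape.context_sd, size=len(base))
    if noise_sd > 0:
        base = base * rng.lognormal(0.0, noise_sd, size=len(base))
    constants = np.minimum(base, ceiling)
    constants[base < floor] = 0.0
    constants[site.max(axis=1) == 0] = 0.0
    return pd.DataFrame(
        {
            "peptide": hexamers,
            # offset o puts P1' at hexamer position o+4 (1-based)
            "cleavage_index": offsets + TETRAMER_LENGTH,
            "constant": constants,
        }
    )


def plant_cleavage_sites(
    landscape: SpecificityLandscape,
    n_proteins: int = 20,
    protein_length: int = 300,
    n_sites: int = 40,
    seed: int = 0,
    hot_fraction: float = 0.5,
    ie_high: float = 3.0,
    ie_sd: float = 0.5,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Random proteome with cleavage sites planted at recorded positions.

    A ``hot_fraction`` of sites receive tetramers drawn from the top of
    the rate landscape (and IE values centered ``ie_high`` log2 units
    up); the rest receive tetramers drawn uniformly (IE near zero).
    Returns the proteome and a sites table with the ground truth.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    alphabet = np.array(list(AA_ALPHABET))
    proteome = {
        f"prot{i:03d}": "".join(rng.choice(alphabet, size=protein_length))
        for i in range(n_proteins)
    }
    order = np.argsort(landscape.rates)
    hot_pool = order[-max(1, N_TETRAMERS // 100):]  # top 1% of tetramers
    rows = []
    ids = list(proteome)
    occupied: dict[str, list[tuple[int, int]]] = {pid: [] for pid in ids}
    for j in range(n_sites):
        hot = rng.random() < hot_fraction
        tet_code = int(rng.choice(hot_pool)) if hot else int(rng.integers(N_TETRAMERS))
        tet = decode_peptides(np.array([tet_code]), TETRAMER_LENGTH)[0]
        # avoid planting on top of an earlier site
        for _ in range(100):
            pid = ids[int(rng.integers(n_proteins))]
            p1p = int(rng.integers(TETRAMER_LENGTH, protein_length + 1))
            span = (p1p - TETRAMER_LENGTH, p1p)
            if all(span[1] <= s or span[0] >= e for s, e in occupied[pid]):
                break
        else:
            raise RuntimeError("could not place all sites; enlarge the proteome")
        occupied[pid].append(span)
        seq = proteome[pid]
        proteome[pid] = seq[: p1p - TETRAMER_LENGTH] + tet + seq[p1p:]
        ie = rng.normal(ie_high if hot else 0.0, ie_sd)
        rows.append(
            {
                "protein_id": pid,
                "p1prime_index": p1p,
                "ie_log2": ie,
                "true_tetramer": tet,
                "true_hot": hot,
            }
        )
    return proteome, pd.DataFrame(rows)


def write_experiment(exp: SimulatedExperiment, out_dir: str | Path) -> None:
    """Write hexamer TSVs and a parameter manifest for an experiment."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    exp.naive.to_tsv(out / "naive.tsv")
    exp.control.to_tsv(out / "control.tsv")
    exp.selection.to_tsv(out / "selection.tsv")
    with open(out / "manifest.json", "w") as fh:
        json.dump(exp.manifest(), fh, indent=2)
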