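"""Synthetic inputs with recorded ground truth for every pipeline stage.

Four generators emulate the data the analyses consume:

* a proteome whose per-residue cysteine probability is coupled to protein
  abundance (negative coupling = depletion in abundant proteins);
* ohnolog pair tables with a tunable probability that the higher-expressed
  member carries fewer cysteines;
* labeled masks of non-overlapping elliptical cells with known axis ratios;
* logistic OD growth curves with Gaussian read noise.

Every generator is a pure function of its config (seed included) and
returns the realized ground truth alongside the data, so downstream
estimators can be tested for parameter recovery without any download.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skimage import draw

from .composition import STANDARD_AAS, ProteinRecord, expected_aa_probability
from .growth import GrowthCurve
from .ohnolog import OhnologPair

__all__ = [
    "ProteomeSimConfig",
    "OhnologSimConfig",
    "AxisRatioDistribution",
    "CellImageSimConfig",
    "GrowthSimConfig",
    "generate_proteome",
    "generate_ohnolog_pairs",
    "generate_cell_image",
    "generate_growth_curve",
    "write_fasta",
    "read_fasta",
    "write_mask",
    "read_mask",
]


def codon_expected_freqs() -> dict[str, float]:
    """Codon-table expected per-residue probabilities (sums to 1)."""
    return {aa: expected_aa_probability(aa) for aa in STANDARD_AAS}


# ---------------------------------------------------------------------------
# proteome


@dataclass
class ProteomeSimConfig:
    """Configuration of the abundance-coupled proteome generator.

    ``cys_coupling`` is the slope on the logit of the per-residue cysteine
    probability per standard deviation of log10 abundance; 0 means i.i.d.
    sampling from ``background_freqs``, negative values deplete cysteine in
    abundant proteins.  Defaults mimic a yeast-scale proteome: ~2,500
    proteins, median length ~400 residues, median abundance ~3,000
    copies/cell with a wide spread.
    """

    n_proteins: int = 2500
    length_log_mean: float = math.log(400.0)
    length_log_sd: float = 0.45
    abundance_log_mean: float = math.log(3000.0)
    abundance_log_sd: float = 2.0
    cys_coupling: float = -0.3
    background_freqs: dict[str, float] = field(default_factory=codon_expected_freqs)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        total = sum(self.background_freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"background_freqs must sum to 1 (got {total})")
        if set(self.background_freqs) != set(STANDARD_AAS):
            raise ValueError("background_freqs must cover exactly the 20 standard residues")
        if any(v <= 0 for v in self.background_freqs.values()):
            raise ValueError("background frequencies must be positive")


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def generate_proteome(
    config: ProteomeSimConfig,
) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Draw a synthetic proteome and its per-protein truth table.

    Residues are sampled i.i.d. within each protein; the cysteine
    probability is shifted on the logit scale by ``cys_coupling`` times the
    protein's standardized log10 abundance, and the other 19 frequencies
    are renormalized to fill the remainder, so probabilities stay valid at
    any coupling strength.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    lengths = np.maximum(
        1, np.round(rng.lognormal(config.length_log_mean, config.length_log_sd, n))
    ).astype(int)
    abundance = rng.lognormal(config.abundance_log_mean, config.abundance_log_sd, n)
    log_ab = np.log10(abundance)
    z = (log_ab - log_ab.mean()) / log_ab.std() if n > 1 else np.zeros(n)

    aas = np.array(list(STANDARD_AAS))
    base = np.array([config.background_freqs[aa] for aa in STANDARD_AAS])
    c_idx = STANDARD_AAS.index("C")
    base_c = base[c_idx]
    logit_c = _logit(base_c) + config.cys_coupling * z
    p_c = 1.0 / (1.0 + np.exp(-logit_c))

    records: list[ProteinRecord] = []
    truth_rows = []
    others = np.delete(np.arange(20), c_idx)
    for i in range(n):
        probs = np.empty(20)
        probs[c_idx] = p_c[i]
        probs[others] = base[others] * (1.0 - p_c[i]) / (1.0 - base_c)
        seq_idx = rng.choice(20, size=lengths[i], p=probs)
        seq = "".join(aas[seq_idx])
        gene = f"SYN{i:05d}"
        records.append(ProteinRecord(id=gene, sequence=seq, abundance=float(abundance[i])))
        n_cys = int(np.count_nonzero(seq_idx == c_idx))
        truth_rows.append(
            {
                "gene": gene,
                "length": int(lengths[i]),
                "copies_per_cell": float(abundance[i]),
                "p_cys_true": float(p_c[i]),
                "n_cys": n_cys,
                "cys_fraction": n_cys / lengths[i],
            }
        )
    return records, pd.DataFrame(truth_rows).set_index("gene")


def write_fasta(records: list[ProteinRecord], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    return [
        ProteinRecord(id=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


# ---------------------------------------------------------------------------
# ohnolog pairs


@dataclass
class OhnologSimConfig:
    """Configuration of the ohnolog-pair generator.

    ``p_class_a`` is the probability that, in a pair with unequal cysteine
    counts, the higher-expressed member has the lower count.  Defaults
    mirror the scale of the yeast ohnolog analysis: 548 pairs, a Class-A
    propensity of 228/365, and tie/missing fractions chosen so the expected
    number of analyzable pairs is ~365.
    """

    n_pairs: int = 548
    p_class_a: float = 228 / 365
    tie_fraction: float = 0.25
    missing_expression_fraction: float = 0.10
    cys_count_range: tuple[int, int] = (0, 12)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_class_a", "tie_fraction", "missing_expression_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1] (got {v})")
        lo, hi = self.cys_count_range
        if hi - lo < 1:
            raise ValueError("cys_count_range must span at least two values")
        if self.n_pairs < 0:
            raise ValueError("n_pairs must be >= 0")


def generate_ohnolog_pairs(
    config: OhnologSimConfig,
) -> tuple[list[OhnologPair], pd.DataFrame]:
    """Draw synthetic ohnolog pairs and a truth table of intended labels.

    Member expressions are continuous lognormal draws (ties have
    probability zero).  Counts for the 19 non-cysteine residues are drawn
    i.i.d. for both members, so only cysteine carries signal.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.cys_count_range
    pairs: list[OhnologPair] = []
    truth_rows = []
    for i in range(config.n_pairs):
        pid = f"pair{i:05d}"
        g1, g2 = f"{pid}a", f"{pid}b"
        e1, e2 = rng.lognormal(1.0, 1.0, 2)
        while e1 == e2:  # paranoia; continuous draws
            e2 = rng.lognormal(1.0, 1.0)
        is_tie = rng.random() < config.tie_fraction
        if is_tie:
            c = int(rng.integers(lo, hi + 1))
            c1 = c2 = c
            label = "tie"
        else:
            ca, cb = rng.choice(np.arange(lo, hi + 1), size=2, replace=False)
            c_low, c_high = int(min(ca, cb)), int(max(ca, cb))
            if rng.random() < config.p_class_a:
                label = "A"
                c1, c2 = (c_low, c_high) if e1 > e2 else (c_high, c_low)
            else:
                label = "B"
                c1, c2 = (c_high, c_low) if e1 > e2 else (c_low, c_high)
        expr1: float | None = float(e1)
        expr2: float | None = float(e2)
        if rng.random() < config.missing_expression_fraction:
            if rng.random() < 0.5:
                expr1 = None
            else:
                expr2 = None
            label = "missing"
        counts1 = {aa: int(rng.integers(lo, hi + 1)) for aa in STANDARD_AAS if aa != "C"}
        counts2 = {aa: int(rng.integers(lo, hi + 1)) for aa in STANDARD_AAS if aa != "C"}
        counts1["C"] = c1
        counts2["C"] = c2
        pairs.append(
            OhnologPair(
                pair_id=pid,
                gene1=g1,
                gene2=g2,
                aa_counts1=counts1,
                aa_counts2=counts2,
                expression1=expr1,
                expression2=expr2,
            )
        )
        truth_rows.append(
            {
                "pair_id": pid,
                "true_label": label,
                "cys1": c1,
                "cys2": c2,
                "expr1": expr1,
                "expr2": expr2,
            }
        )
    truth = pd.DataFrame(
        truth_rows, columns=["pair_id", "true_label", "cys1", "cys2", "expr1", "expr2"]
    )
    return pairs, truth.set_index("pair_id") if len(truth) else truth


# ---------------------------------------------------------------------------
# cell images


@dataclass(frozen=True)
class AxisRatioDistribution:
    """Per-strain distribution of the true cell axis ratio (>= 1).

    Ratios are normal(mean, sd) truncated below at 1 by resampling;
    ``sd=0`` gives a fixed ratio.
    """

    mean: float = 1.3
    sd: float = 0.15

    def __post_init__(self) -> None:
        if self.mean < 1.0:
            raise ValueError("axis ratio mean must be >= 1")
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")

    def sample(self, rng: np.random.Generator) -> float:
        if self.sd == 0:
            return self.mean
        while True:
            r = rng.normal(self.mean, self.sd)
            if r >= 1.0:
                return float(r)


@dataclass
class CellImageSimConfig:
    """Configuration of the labeled-mask generator (one image)."""

    n_cells: int = 30
    image_shape: tuple[int, int] = (512, 512)
    ratio_distribution: AxisRatioDistribution = field(default_factory=AxisRatioDistribution)
    semi_minor_range: tuple[float, float] = (10.0, 18.0)
    allow_overlap: bool = False
    border_margin: int = 5
    seed: int = 0
    max_tries_per_cell: int = 200

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        lo, hi = self.semi_minor_range
        if lo <= 0 or hi < lo:
            raise ValueError("invalid semi_minor_range")


class PlacementError(RuntimeError):
    """Raised when cells cannot be placed without overlap in the image."""


def generate_cell_image(
    config: CellImageSimConfig,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Rasterize non-overlapping random ellipses into a label mask.

    Pixels are included by the pixel-center test (no anti-aliasing), which
    matches the binary semantics of segmentation masks.  The truth table
    records each cell's true semi-axes, orientation and axis ratio.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.image_shape
    mask = np.zeros((h, w), dtype=np.uint16)
    truth_rows = []
    for label in range(1, config.n_cells + 1):
        placed = False
        for _ in range(config.max_tries_per_cell):
            b = rng.uniform(*config.semi_minor_range)
            ratio = config.ratio_distribution.sample(rng)
            a = b * ratio
            theta = rng.uniform(0.0, np.pi)
            margin = config.border_margin + a
            if 2 * margin >= min(h, w):
                continue
            cy = rng.uniform(margin, h - margin)
            cx = rng.uniform(margin, w - margin)
            rr, cc = draw.ellipse(cy, cx, a, b, shape=mask.shape, rotation=theta)
            if rr.size == 0:
                continue
            if not config.allow_overlap and np.any(mask[rr, cc] != 0):
                continue
            mask[rr, cc] = label
            truth_rows.append(
                {
                    "label": label,
                    "center_row": cy,
                    "center_col": cx,
                    "semi_major": a,
                    "semi_minor": b,
                    "orientation": theta,
                    "axis_ratio": ratio,
                }
            )
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place cell {label} of {config.n_cells} after "
                f"{config.max_tries_per_cell} tries; image too crowded"
            )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "label",
            "center_row",
            "center_col",
            "semi_major",
            "semi_minor",
            "orientation",
            "axis_ratio",
        ],
    )
    return mask, truth.set_index("label") if len(truth) else truth


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(str(path), mask.astype(np.uint16))


def read_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(np.int64)


# ---------------------------------------------------------------------------
# growth curves


@dataclass
class GrowthSimConfig:
    """Configuration of the logistic growth-curve generator.

    The noiseless trajectory is a logistic sigmoid riding on a baseline:
    ``od(t) = initial_od + K / (1 + exp(-r (t - t0)))`` with ``rate`` in
    per hour and times in minutes, sampled every ``sampling_interval``
    minutes (default 10, the cadence of a plate reader).  Gaussian read
    noise of ``noise_sd`` OD units is added on top.
    """

    carrying_capacity: float = 1.0
    rate: float = 0.35
    midpoint_time: float = 720.0
    initial_od: float = 0.01
    noise_sd: float = 0.005
    sampling_interval: float = 10.0
    duration: float = 1440.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_interval <= 0:
            raise ValueError("sampling interval must be positive")
        if self.carrying_capacity < 0 or self.initial_od < 0:
            raise ValueError("OD parameters must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.duration < self.sampling_interval:
            raise ValueError("duration must cover at least one interval")


def generate_growth_curve(
    config: GrowthSimConfig,
    well_id: str = "A1",
    strain_id: str = "sim",
    replicate_id: str = "1",
) -> GrowthCurve:
    """Sample one noisy logistic OD curve (nonnegative before noise)."""
    rng = np.random.default_rng(config.seed)
    t = np.arange(0.0, config.duration + 1e-9, config.sampling_interval)
    r_per_min = config.rate / 60.0
    clean = config.initial_od + config.carrying_capacity / (
        1.0 + np.exp(-r_per_min * (t - config.midpoint_time))
    )
    od = clean + rng.normal(0.0, config.noise_sd, t.size) if config.noise_sd > 0 else clean
    return GrowthCurve(
        times=t, od=od, well_id=well_id, strain_id=strain_id, replicate_id=replicate_id
    )
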