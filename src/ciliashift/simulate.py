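"""Synthetic inputs with known ground truth for every analysis stage.

Three generators emulate the statistical structure the analyses assume:

* :func:`generate_polysome_experiment` — fraction-resolved gene read-count
  tables (poly / sub / cyto x genotype x replicate) with a planted set of
  translationally shifted genes;
* :func:`generate_cilia_stack` — grayscale time-lapse stacks whose pixel
  intensities oscillate at known frequencies inside defined regions, plus
  Gaussian noise, at a stated acquisition rate;
* :func:`generate_lfq_timecourse` — log-normal label-free-quantification
  protein intensity matrices over differentiation stages with
  missing-at-random dropouts.

Each generator returns its data together with a truth object recording the
exact planted parameters, so downstream estimates can be scored against a
known answer.  All generators are deterministic given their seed.

A note on the polysome truth scale: the polysome index is defined on
per-sample TPM-normalized densities, and because both fraction columns are
forced to sum to 1e6, the abundance-weighted mean of the TPM-scale PI is
exactly 0.5 in any dataset.  The generator therefore (a) interprets its PI
parameters on that TPM scale, and (b) tilts gene masses so the drawn PIs and
the 1e6-per-column constraint are simultaneously satisfiable, which makes the
downstream estimator unbiased for the stored truth.  When the drawn PIs do
not straddle 0.5 (degenerate configurations such as a single gene with
PI = 1) the tilt is skipped and masses are used as drawn.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "PolysomeSimConfig",
    "CiliaRegion",
    "CiliaSimConfig",
    "PolysomeTruth",
    "CiliaTruth",
    "LfqTruth",
    "generate_polysome_experiment",
    "generate_cilia_stack",
    "generate_lfq_timecourse",
    "write_polysome_tsv",
    "write_truth_json",
]

GENOTYPES = ("WT", "NRS")
FRACTIONS = ("poly", "sub", "cyto")


# ---------------------------------------------------------------------------
# polysome count tables


@dataclass(frozen=True)
class PolysomeSimConfig:
    """Design of a simulated polysome-profiling experiment.

    true_delta_psr is the log2 shift in PI applied to the planted
    (``shifted_fraction``) genes in the mutant genotype; dispersion is the
    negative-binomial overdispersion (variance = mu + dispersion * mu^2;
    0 means multinomial / Poisson-like allocation).
    """

    n_genes: int = 2000
    length_range: tuple[int, int] = (300, 10_000)
    total_reads_per_sample: int = 1_000_000
    pi_baseline_mean: float = 0.5
    pi_baseline_sd: float = 0.12
    shifted_fraction: float = 0.1
    true_delta_psr: float = -1.0
    n_replicates: int = 3
    dispersion: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be at least 1")
        lo, hi = self.length_range
        if not (0 < lo <= hi):
            raise ValueError("length_range must satisfy 0 < min <= max")
        if self.total_reads_per_sample <= 0:
            raise ValueError("total_reads_per_sample must be positive")
        if self.pi_baseline_sd < 0:
            raise ValueError("pi_baseline_sd must be non-negative")
        if self.pi_baseline_sd == 0:
            # degenerate deterministic-PI configurations may sit on a boundary
            if not (0 <= self.pi_baseline_mean <= 1):
                raise ValueError("pi_baseline_mean must lie in [0, 1]")
        elif not (
            0 < self.pi_baseline_mean - 3 * self.pi_baseline_sd
            and self.pi_baseline_mean + 3 * self.pi_baseline_sd < 1
        ):
            raise ValueError("pi_baseline_mean +- 3*pi_baseline_sd must stay inside (0, 1)")
        if not (0 <= self.shifted_fraction <= 1):
            raise ValueError("shifted_fraction must lie in [0, 1]")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be at least 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")


@dataclass
class PolysomeTruth:
    """Planted per-gene parameters of a simulated polysome experiment."""

    gene_id: pd.Series
    pi_wt: np.ndarray
    pi_mut: np.ndarray
    psr: np.ndarray
    shifted: np.ndarray
    config: PolysomeSimConfig
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_id,
                "true_pi_WT": self.pi_wt,
                "true_pi_NRS": self.pi_mut,
                "true_psr": self.psr,
                "shifted": self.shifted,
            }
        )


def _tilt_masses(masses: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Reweight gene masses so the mass-weighted mean PI is exactly 0.5.

    Solves for s in m_a = masses_a * exp(-s * (pi_a - 0.5)) such that
    sum(m * (pi - 0.5)) = 0.  Returns the input unchanged when the PIs do not
    straddle 0.5 (no solution with positive masses exists).
    """
    x = pi - 0.5
    if not ((x > 0).any() and (x < 0).any()):
        return masses

    def g(s: float) -> float:
        return float(np.sum(masses * np.exp(-s * x) * x))

    lo, hi = -1.0, 1.0
    while g(lo) < 0:
        lo *= 2
        if lo < -1e6:
            return masses
    while g(hi) > 0:
        hi *= 2
        if hi > 1e6:
            return masses
    s = brentq(g, lo, hi, xtol=1e-12)
    return masses * np.exp(-s * x)


def _shift_pi(pi_wt: np.ndarray, delta: float) -> np.ndarray:
    """Shift PI by a log2 factor; fall back to a log-odds shift near 1."""
    direct = pi_wt * 2.0**delta
    ok = (direct > 0) & (direct < 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = pi_wt / (1 - pi_wt) * 2.0**delta
        fallback = np.where(np.isinf(odds), 1.0, odds / (1 + odds))
    return np.where(ok, direct, fallback)


def generate_polysome_experiment(
    config: PolysomeSimConfig,
) -> tuple[pd.DataFrame, PolysomeTruth]:
    """Simulate a fraction-resolved count table plus its ground truth.

    Expected read counts for gene *a* in a (genotype, fraction) sample are
    proportional to density(a) * length(a), where the densities realize the
    drawn TPM-scale PIs; with dispersion 0 each sample is one multinomial
    draw of ``total_reads_per_sample`` reads, otherwise counts are negative
    binomial around the same expectations.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes

    lengths = rng.integers(config.length_range[0], config.length_range[1] + 1, size=n)
    abundance = rng.lognormal(mean=0.0, sigma=1.0, size=n)

    if config.pi_baseline_sd == 0:
        pi_wt = np.full(n, float(config.pi_baseline_mean))
    else:
        pi_wt = np.clip(
            rng.normal(config.pi_baseline_mean, config.pi_baseline_sd, size=n),
            1e-4,
            1 - 1e-4,
        )
    n_shift = int(round(config.shifted_fraction * n))
    shifted = np.zeros(n, dtype=bool)
    shifted[rng.choice(n, size=n_shift, replace=False)] = True
    pi_mut = pi_wt.copy()
    if n_shift:
        pi_mut[shifted] = _shift_pi(pi_wt[shifted], config.true_delta_psr)

    gene_id = pd.Series([f"gene{i + 1:05d}" for i in range(n)], name="gene_id")
    table = pd.DataFrame({"gene_id": gene_id, "length": lengths})

    densities: dict[tuple[str, str], np.ndarray] = {}
    for genotype, pi in (("WT", pi_wt), ("NRS", pi_mut)):
        m = _tilt_masses(abundance, pi)
        d_poly, d_sub = m * pi, m * (1 - pi)
        for fraction, dens in (("poly", d_poly), ("sub", d_sub), ("cyto", m)):
            total = dens.sum()
            densities[(genotype, fraction)] = (
                dens / total * 1e6 if total > 0 else dens
            )

    for genotype in GENOTYPES:
        for fraction in FRACTIONS:
            weights = densities[(genotype, fraction)] * lengths
            wsum = weights.sum()
            for rep in range(1, config.n_replicates + 1):
                col = f"{genotype}_{fraction}_rep{rep}"
                if wsum <= 0:
                    table[col] = np.zeros(n, dtype=np.int64)
                    continue
                p = weights / wsum
                if config.dispersion == 0:
                    counts = rng.multinomial(config.total_reads_per_sample, p)
                else:
                    mu = config.total_reads_per_sample * p
                    r = 1.0 / config.dispersion
                    counts = rng.negative_binomial(r, r / (r + mu))
                table[col] = counts.astype(np.int64)

    truth = PolysomeTruth(
        gene_id=gene_id,
        pi_wt=pi_wt,
        pi_mut=pi_mut,
        psr=np.log2(pi_mut / pi_wt),
        shifted=shifted,
        config=config,
        seed=config.seed,
    )
    return table, truth


def write_polysome_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# cilia time-lapse stacks


@dataclass(frozen=True)
class CiliaRegion:
    """One oscillating region: a boolean mask beating at a fixed frequency."""

    mask: np.ndarray
    frequency: float
    amplitude: float
    phase: float = 0.0


@dataclass(frozen=True)
class CiliaSimConfig:
    """Design of a simulated high-speed ciliary-beat recording."""

    height: int = 128
    width: int = 128
    n_frames: int = 512
    acquisition_frequency: float = 250.0
    regions: tuple[CiliaRegion, ...] = ()
    baseline_intensity: float = 100.0
    noise_sd: float = 10.0
    seed: int = 0
    dtype: str = "uint8"

    def validate(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be at least 2")
        if self.acquisition_frequency <= 0:
            raise ValueError("acquisition_frequency must be positive")
        nyquist = self.acquisition_frequency / 2.0
        for region in self.regions:
            if region.frequency >= nyquist:
                raise ValueError(
                    f"region frequency {region.frequency} Hz is at or above "
                    f"the Nyquist limit ({nyquist} Hz)"
                )
            if region.mask.shape != (self.height, self.width):
                raise ValueError("region mask shape does not match the frame size")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if np.dtype(self.dtype).kind != "u":
            raise ValueError("dtype must be an unsigned integer type")


@dataclass
class CiliaTruth:
    """Per-pixel planted beat frequency (0 where non-oscillating)."""

    frequency_map: np.ndarray
    config: CiliaSimConfig
    seed: int


def generate_cilia_stack(config: CiliaSimConfig) -> tuple[np.ndarray, CiliaTruth]:
    """Simulate a T x H x W stack of sinusoidally beating regions plus noise.

    pixel(t, i, j) = baseline + sum_regions amp * sin(2 pi f t / acq + phase)
    over masked pixels, plus Gaussian(0, noise_sd) noise, rounded and clipped
    to the unsigned bit range of ``config.dtype``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    T, H, W = config.n_frames, config.height, config.width
    t = np.arange(T) / config.acquisition_frequency

    frames = np.full((T, H, W), config.baseline_intensity, dtype=np.float64)
    freq_map = np.zeros((H, W))
    for region in config.regions:
        wave = region.amplitude * np.sin(
            2 * np.pi * region.frequency * t + region.phase
        )
        frames[:, region.mask] += wave[:, None]
        freq_map[region.mask] = region.frequency
    if config.noise_sd > 0:
        frames += rng.normal(0.0, config.noise_sd, size=frames.shape)

    info = np.iinfo(np.dtype(config.dtype))
    stack = np.clip(np.round(frames), info.min, info.max).astype(config.dtype)
    return stack, CiliaTruth(frequency_map=freq_map, config=config, seed=config.seed)


# ---------------------------------------------------------------------------
# LFQ proteomics time courses


@dataclass
class LfqTruth:
    """Planted parameters of a simulated LFQ time course."""

    induced: np.ndarray
    mean_log2: pd.DataFrame
    missing_mask: pd.DataFrame
    annotations: pd.DataFrame
    seed: int


def generate_lfq_timecourse(
    n_proteins: int = 500,
    timepoints: tuple[str, ...] = ("ALI4", "ALI7", "ALI10", "ALI14", "ALI18"),
    n_replicates: int = 3,
    missing_rate: float = 0.1,
    group_effect: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, LfqTruth]:
    """Simulate a protein x sample LFQ intensity matrix over two genotypes.

    Half the proteins are "induced" along the stage axis (a log2 ramp of
    amplitude ~2, attenuated by ``group_effect`` log2 units at the final
    stage in the mutant); the rest are flat.  Intensities are log-normal
    around those profiles, with entries missing at random at ``missing_rate``
    (absent entries are NaN).  Induced proteins receive cilium-related GO
    annotation strings, the rest generic ones.
    """
    if not (0 <= missing_rate < 1):
        raise ValueError("missing_rate must lie in [0, 1)")
    if len(timepoints) < 2:
        raise ValueError("need at least 2 timepoints")
    rng = np.random.default_rng(seed)
    n_tp = len(timepoints)

    protein_id = [f"prot{i + 1:04d}" for i in range(n_proteins)]
    induced = np.zeros(n_proteins, dtype=bool)
    induced[: n_proteins // 2] = True

    base = rng.normal(25.0, 2.0, size=n_proteins)
    ramp_amp = np.where(induced, rng.normal(2.0, 0.5, size=n_proteins), 0.0)
    stage_pos = np.linspace(0.0, 1.0, n_tp)

    mean = {}
    for genotype in GENOTYPES:
        atten = group_effect if genotype == "NRS" else 0.0
        for j, tp in enumerate(timepoints):
            mean[f"{genotype}_{tp}"] = base + stage_pos[j] * (
                ramp_amp - atten * induced
            )
    mean_log2 = pd.DataFrame(mean, index=protein_id)

    cols, data = [], []
    for genotype in GENOTYPES:
        for tp in timepoints:
            for rep in range(1, n_replicates + 1):
                cols.append(f"{genotype}_{tp}_rep{rep}")
                data.append(
                    mean_log2[f"{genotype}_{tp}"].to_numpy()
                    + rng.normal(0.0, 0.3, size=n_proteins)
                )
    matrix = pd.DataFrame(
        2.0 ** np.column_stack(data), index=protein_id, columns=cols
    )
    matrix.index.name = "protein_id"

    missing = rng.random(matrix.shape) < missing_rate
    matrix = matrix.mask(missing)

    terms = np.where(
        induced,
        "cilium assembly; ciliary basal body; motile cilium",
        "mitochondrion; cytoplasmic translation",
    )
    annotations = pd.DataFrame({"protein_id": protein_id, "go_terms": terms})

    truth = LfqTruth(
        induced=induced,
        mean_log2=mean_log2,
        missing_mask=pd.DataFrame(missing, index=protein_id, columns=cols),
        annotations=annotations,
        seed=seed,
    )
    return matrix, truth


def write_truth_json(truth, path: str | Path) -> None:
    """Serialize a truth object's scalar/array fields to JSON."""

    def default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        if isinstance(obj, pd.Series):
            return obj.tolist()
        if isinstance(obj, pd.DataFrame):
            return obj.to_dict(orient="list")
        if hasattr(obj, "__dataclass_fields__"):
            return asdict(obj)
        return str(obj)

    payload = {
        name: getattr(truth, name) for name in truth.__dataclass_fields__
    }
    Path(path).write_text(json.dumps(payload, default=default))
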