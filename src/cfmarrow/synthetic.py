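"""Synthetic cf-mRNA data with known ground truth.

Every downstream stage of the package consumes one of four table types:
reference expression matrices (cell type x gene), TPM expression matrices
(gene x sample or gene x day), immunoglobulin segment read-count tables and
per-SNP allele-count tables.  The generators here produce all four under a
simple, explicit generative model so that recovery of the planted structure
can be asserted exactly:

- cell-type profiles: log-normal background expression with planted marker
  genes whose expression in their own type is ``marker_fold`` times the
  maximum over all other types;
- bulk samples: proportion-weighted mixtures of the profiles, rescaled to
  TPM (columns sum to 1e6), optionally with multinomial read sampling or
  multiplicative log-normal noise;
- ablation/reconstitution time courses: per-lineage piecewise activity
  (plateau, log-linear decay to a nadir, exponential recovery) scaling the
  lineage's profile within the mixture;
- Ig repertoires: a planted clone taking a per-day fraction of reads, the
  remainder spread symmetrically over the repertoire, counts multinomial;
- SNP allele counts: reference-allele frequency (1-m)*f_host + m*f_donor
  under a time-varying donor mixing fraction m, symmetric per-read miscall
  error, binomial counts.

Determinism: one global seed expands into per-operation substreams (via
``numpy.random.SeedSequence``), so each stage can be regenerated
independently and identical config + seed gives bitwise-identical output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "TrajectorySpec",
    "GENOTYPE_REF_FREQ",
    "generate_reference",
    "generate_mixture",
    "generate_timecourse",
    "generate_ig_counts",
    "generate_snp_counts",
]

#: reference-allele frequency implied by each genotype code
GENOTYPE_REF_FREQ = {"hom-ref": 1.0, "het": 0.5, "hom-alt": 0.0}

TPM_SCALE = 1.0e6


def _substream(seed: int, label: str) -> np.random.Generator:
    """Deterministic per-operation RNG substream derived from one global seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(label.encode("utf-8"))])
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters shared by the expression-matrix generators.

    Attributes
    ----------
    n_genes, n_celltypes, markers_per_type
        Size of the synthetic gene universe, number of cell types and number
        of planted marker genes per type.
    marker_fold
        Fold by which a marker exceeds its maximum over all other types.
        Default 50 comfortably clears the 20-fold specificity rule.
    background_level
        Median of the log-normal background expression (TPM scale before
        renormalization).
    background_sigma
        Standard deviation of background expression on the natural-log scale.
    noise_model
        One of ``none`` (exact expectation), ``multinomial`` (read
        resampling at ``read_depth``) or ``lognormal`` (mean-one
        multiplicative noise with ``noise_sigma``).
    read_depth
        Total simulated reads per sample for the multinomial model.
    time_grid
        Integer days relative to transplant day 0 for time-course output.
    """

    n_genes: int = 1000
    n_celltypes: int = 6
    markers_per_type: int = 30
    marker_fold: float = 50.0
    background_level: float = 30.0
    background_sigma: float = 0.5
    noise_model: str = "multinomial"
    noise_sigma: float = 0.5
    read_depth: int = 1_000_000
    seed: int = 0
    time_grid: tuple[int, ...] = tuple(range(-6, 15))

    def __post_init__(self) -> None:
        if self.marker_fold <= 1:
            raise ValueError("marker_fold must be > 1")
        if self.read_depth < 1:
            raise ValueError("read_depth must be >= 1")
        if self.markers_per_type * self.n_celltypes > self.n_genes:
            raise ValueError(
                f"markers_per_type * n_celltypes = "
                f"{self.markers_per_type * self.n_celltypes} exceeds "
                f"n_genes = {self.n_genes}"
            )
        grid = tuple(self.time_grid)
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("time_grid must be strictly increasing")
        if self.noise_model not in ("none", "multinomial", "lognormal"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")


@dataclass
class GroundTruth:
    """Planted truth recorded alongside each generated table.

    Only the fields relevant to the generating operation are populated.
    """

    true_proportions: pd.DataFrame | None = None  # sample x cell type
    marker_assignment: dict[str, str] = field(default_factory=dict)
    lineage_trajectories: pd.DataFrame | None = None  # day x lineage activity
    clone_fractions: pd.Series | None = None  # day -> planted clone fraction
    mixing_fraction: pd.Series | None = None  # day -> donor fraction
    genotypes: dict[str, tuple[str, str]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        """Plain-python representation for YAML serialization."""
        out: dict = {}
        if self.true_proportions is not None:
            out["true_proportions"] = {
                s: row.to_dict() for s, row in self.true_proportions.iterrows()
            }
        if self.marker_assignment:
            out["marker_assignment"] = dict(self.marker_assignment)
        if self.lineage_trajectories is not None:
            out["lineage_trajectories"] = {
                c: self.lineage_trajectories[c].to_dict()
                for c in self.lineage_trajectories.columns
            }
        if self.clone_fractions is not None:
            out["clone_fractions"] = {
                int(k): float(v) for k, v in self.clone_fractions.items()
            }
        if self.mixing_fraction is not None:
            out["mixing_fraction"] = {
                int(k): float(v) for k, v in self.mixing_fraction.items()
            }
        if self.genotypes:
            out["genotypes"] = {k: list(v) for k, v in self.genotypes.items()}
        return out


def generate_reference(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Cell-type x gene reference matrix with planted marker genes.

    Non-marker expression is log-normal around ``background_level``.  Each
    marker's expression in its own type is set to exactly ``marker_fold``
    times its maximum over all other types, so with ``marker_fold > 20``
    every planted marker passes the strict 20-fold specificity rule and with
    ``marker_fold <= 20`` none does.

    Returns
    -------
    (reference, truth)
        ``reference`` is a cell-type x gene DataFrame; ``truth`` records the
        gene -> cell type marker assignment.
    """
    rng = _substream(config.seed, "reference")
    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    celltypes = [f"CT{i + 1}" for i in range(config.n_celltypes)]

    values = config.background_level * np.exp(
        config.background_sigma * rng.standard_normal((config.n_celltypes, config.n_genes))
    )

    marker_idx = rng.choice(
        config.n_genes, size=config.markers_per_type * config.n_celltypes, replace=False
    )
    assignment: dict[str, str] = {}
    for t in range(config.n_celltypes):
        for g in marker_idx[t * config.markers_per_type : (t + 1) * config.markers_per_type]:
            others = np.delete(values[:, g], t)
            peak = others.max()
            v = config.marker_fold * peak
            # keep the computed ratio from overshooting marker_fold by rounding,
            # so a boundary fold compares exactly against a strict threshold
            while v / peak > config.marker_fold:
                v = np.nextafter(v, 0.0)
            values[t, g] = v
            assignment[genes[g]] = celltypes[t]

    reference = pd.DataFrame(values, index=celltypes, columns=genes)
    return reference, GroundTruth(marker_assignment=assignment)


def _profiles_tpm(reference: pd.DataFrame) -> pd.DataFrame:
    """Each cell-type profile rescaled so its transcriptome sums to 1e6."""
    return reference.div(reference.sum(axis=1), axis=0) * TPM_SCALE


def _apply_noise(
    expected_tpm: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Apply the configured noise model column-wise; columns stay on TPM scale."""
    if config.noise_model == "none":
        return expected_tpm
    out = np.empty_like(expected_tpm)
    if config.noise_model == "multinomial":
        for j in range(expected_tpm.shape[1]):
            p = expected_tpm[:, j] / expected_tpm[:, j].sum()
            counts = rng.multinomial(config.read_depth, p)
            out[:, j] = counts * (TPM_SCALE / config.read_depth)
        return out
    # lognormal: mean-one multiplicative factor, then renormalize to TPM
    factors = np.exp(
        config.noise_sigma * rng.standard_normal(expected_tpm.shape)
        - 0.5 * config.noise_sigma**2
    )
    noisy = expected_tpm * factors
    return noisy / noisy.sum(axis=0, keepdims=True) * TPM_SCALE


def generate_mixture(
    reference: pd.DataFrame,
    proportions: np.ndarray | Sequence[float] | pd.DataFrame,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Bulk TPM samples mixing the reference profiles at known proportions.

    Parameters
    ----------
    proportions
        Either one vector of length ``n_celltypes`` (one sample) or a
        sample x cell-type array/DataFrame.  Each row must be non-negative
        and sum to 1 within 1e-9.

    Returns
    -------
    (matrix, truth)
        ``matrix`` is gene x sample TPM (columns sum to 1e6); ``truth``
        records the per-sample true proportions.
    """
    P = np.atleast_2d(np.asarray(proportions, dtype=float))
    if P.shape[1] != reference.shape[0]:
        raise ValueError(
            f"proportions have length {P.shape[1]}, expected {reference.shape[0]}"
        )
    if np.any(P < 0) or np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError("each proportions vector must be >= 0 and sum to 1 within 1e-9")

    profiles = _profiles_tpm(reference)  # celltype x gene, rows sum to 1e6
    expected = profiles.to_numpy().T @ P.T  # gene x sample, columns sum to 1e6

    rng = _substream(config.seed, "mixture")
    values = _apply_noise(expected, config, rng)

    samples = [f"S{j + 1:03d}" for j in range(P.shape[0])]
    matrix = pd.DataFrame(values, index=profiles.columns, columns=samples)
    truth = GroundTruth(
        true_proportions=pd.DataFrame(P, index=samples, columns=reference.index)
    )
    return matrix, truth


@dataclass(frozen=True)
class TrajectorySpec:
    """Piecewise activity of one hematopoietic lineage around transplant.

    The activity multiplier is ``pre_level`` up to ``ablation_day``, decays
    log-linearly to ``nadir_level`` at ``recovery_day``, then recovers
    exponentially at ``recovery_rate`` per day (capped at ``pre_level``).
    A nadir of exactly 0 uses a linear descent to zero; recovery from zero
    restarts from a small fraction of ``pre_level``, standing in for graft
    reseeding of the lineage.
    """

    pre_level: float = 1.0
    ablation_day: int = -2
    nadir_level: float = 0.05
    recovery_day: int = 9
    recovery_rate: float = 0.5

    def __post_init__(self) -> None:
        if self.pre_level < 0 or self.nadir_level < 0:
            raise ValueError("trajectory levels must be >= 0")
        if self.recovery_day <= self.ablation_day:
            raise ValueError("recovery_day must be after ablation_day")

    def activity(self, day: float) -> float:
        """Activity multiplier at ``day`` (unitless, >= 0)."""
        if day <= self.ablation_day:
            return self.pre_level
        if day <= self.recovery_day:
            frac = (day - self.ablation_day) / (self.recovery_day - self.ablation_day)
            if self.nadir_level > 0 and self.pre_level > 0:
                return float(
                    self.pre_level * (self.nadir_level / self.pre_level) ** frac
                )
            return float(self.pre_level * (1.0 - frac) + self.nadir_level * frac)
        base = self.nadir_level if self.nadir_level > 0 else 1e-3 * self.pre_level
        return float(
            min(
                self.pre_level if self.pre_level > 0 else base,
                base * np.exp(self.recovery_rate * (day - self.recovery_day)),
            )
        )


def generate_timecourse(
    reference: pd.DataFrame,
    trajectories: Mapping[str, TrajectorySpec],
    config: SimulationConfig,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Gene x day TPM matrix for an ablation/reconstitution time course.

    Each lineage named in ``trajectories`` contributes its profile weighted
    by its activity at each day; cell types without a spec keep constant
    weight 1.  Columns are renormalized to TPM, so marker levels reflect a
    lineage's share of the circulating transcriptome, as in real cf-mRNA.
    """
    unknown = set(trajectories) - set(reference.index)
    if unknown:
        raise ValueError(f"trajectory lineages not in reference: {sorted(unknown)}")
    days = list(config.time_grid)
    if not any(d <= min(t.ablation_day for t in trajectories.values()) for d in days):
        raise ValueError("time_grid must cover the ablation day")

    profiles = _profiles_tpm(reference)
    weights = np.ones((len(days), reference.shape[0]))
    for name, spec in trajectories.items():
        i = reference.index.get_loc(name)
        weights[:, i] = [spec.activity(d) for d in days]

    mix = profiles.to_numpy().T @ weights.T  # gene x day
    col_sums = mix.sum(axis=0)
    if np.any(col_sums <= 0):
        raise ValueError("all lineage activities are zero on some day")
    expected = mix / col_sums * TPM_SCALE

    rng = _substream(config.seed, "timecourse")
    values = _apply_noise(expected, config, rng)

    matrix = pd.DataFrame(values, index=profiles.columns, columns=days)
    truth = GroundTruth(
        lineage_trajectories=pd.DataFrame(
            weights, index=pd.Index(days, name="day"), columns=reference.index
        )
    )
    return matrix, truth


def generate_ig_counts(
    clone_segments: Sequence[str],
    clone_fraction_series: Mapping[int, float] | pd.Series,
    repertoire_size: int = 50,
    total_reads: int = 10_000,
    seed: int = 0,
    segment_class: str = "IGHV",
) -> tuple[pd.DataFrame, GroundTruth]:
    """Ig segment x day read-count table with a planted clone.

    At each day the clone's segments share ``clone_fraction`` of the read
    mass equally; the remaining mass is spread uniformly over all
    ``repertoire_size + len(clone_segments)`` segments (clone segments
    included, so a clone at fraction 0 is indistinguishable from
    background).  Counts are multinomial at ``total_reads`` per day.

    Returns
    -------
    (table, truth)
        ``table`` has segments as rows, a ``class`` column, and one integer
        count column per day; ``truth`` records the planted clone fractions.
    """
    series = pd.Series(dict(clone_fraction_series)).sort_index()
    if ((series < 0) | (series > 1)).any():
        raise ValueError("clone fractions must lie in [0, 1]")
    if len(clone_segments) == 0 and (series > 0).any():
        raise ValueError("nonzero clone fraction requires at least one clone segment")
    if repertoire_size < 1:
        raise ValueError("repertoire_size must be >= 1")

    background = [f"{segment_class}bg-{i + 1:03d}" for i in range(repertoire_size)]
    segments = list(clone_segments) + background
    n_total = len(segments)
    n_clone = len(clone_segments)

    rng = _substream(seed, "ig")
    counts = np.zeros((n_total, len(series)), dtype=int)
    for j, (_, cf) in enumerate(series.items()):
        p = np.full(n_total, (1.0 - cf) / n_total)
        if n_clone:
            p[:n_clone] += cf / n_clone
        counts[:, j] = rng.multinomial(int(total_reads), p)

    table = pd.DataFrame(counts, index=pd.Index(segments, name="segment"),
                         columns=series.index.astype(int))
    table.insert(0, "class", segment_class)
    truth = GroundTruth(clone_fractions=series.astype(float))
    return table, truth


def generate_snp_counts(
    genotypes: Mapping[str, tuple[str, str]],
    mixing_fraction: Mapping[int, float] | pd.Series,
    depth: int = 200,
    error_rate: float = 0.01,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Per-SNP, per-day reference/alternative allele counts under chimerism.

    The expected reference-allele frequency at a SNP on a day with donor
    mixing fraction ``m`` is ``(1-m)*f_host + m*f_donor`` with f mapping
    hom-ref -> 1, het -> 0.5, hom-alt -> 0, adjusted for a symmetric
    per-read miscall probability.  Reference counts are binomial at
    ``depth`` reads per SNP per day.

    Parameters
    ----------
    genotypes
        Map SNP id -> (host genotype, donor genotype), codes drawn from
        ``hom-ref`` / ``het`` / ``hom-alt``.
    mixing_fraction
        Map day -> donor fraction of marrow output, each in [0, 1].

    Returns
    -------
    (table, truth)
        ``table`` is a long DataFrame with columns ``snp``, ``day``,
        ``ref_count``, ``alt_count``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not (0 <= error_rate < 0.5):
        raise ValueError("error_rate must lie in [0, 0.5)")
    series = pd.Series(dict(mixing_fraction)).sort_index()
    if ((series < 0) | (series > 1)).any():
        raise ValueError("mixing fractions must lie in [0, 1]")
    for snp, (host, donor) in genotypes.items():
        for code in (host, donor):
            if code not in GENOTYPE_REF_FREQ:
                raise ValueError(f"unknown genotype code {code!r} for SNP {snp}")

    rng = _substream(seed, "snp")
    records = []
    for snp, (host, donor) in genotypes.items():
        f_host = GENOTYPE_REF_FREQ[host]
        f_donor = GENOTYPE_REF_FREQ[donor]
        for day, m in series.items():
            p = (1.0 - m) * f_host + m * f_donor
            p_obs = p * (1.0 - error_rate) + (1.0 - p) * error_rate
            ref = int(rng.binomial(depth, p_obs))
            records.append((snp, int(day), ref, depth - ref))

    table = pd.DataFrame(records, columns=["snp", "day", "ref_count", "alt_count"])
    truth = GroundTruth(
        mixing_fraction=series.astype(float),
        genotypes={k: tuple(v) for k, v in genotypes.items()},
    )
    return table, truth
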