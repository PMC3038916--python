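"""Theoretical model linking average read coverage to assembly error.

The model treats a shotgun assembly as a mosaic of positions whose read
depth is Poisson distributed with mean ``lambda`` (the average coverage),
conditioned on depth >= 1 since zero-coverage positions are simply absent
from an assembly. The quality score of an assembled base at depth ``x`` is
the sum of the quality scores of the ``x`` contributing reads, assumed
independent draws from the single-read distribution ``p1``. Quality scores
are taken at face value, i.e. a score ``q`` means error probability
``10**(-q/10)``.

From ``p1`` and ``lambda`` follow:

* the assembly-wide quality distribution (truncated-Poisson mixture of
  depth-wise convolutions of ``p1``);
* the expected assembly quality ``Q*`` in phred units, which is the
  generalized f-mean of basewise scores with ``f(q) = 10**(-q/10)`` and is
  therefore dominated by the low-quality tail of ``p1``;
* the decomposition of expected error by read depth, in particular ``F1``,
  the fraction of all expected errors contributed by depth-1 positions.

Raw (unbinned) phred values are used throughout this module; the 5-unit
binning is purely an I/O representation. Quality sums are not capped inside
the model (capping would saturate the linear quality-vs-coverage trend);
any assembler-imposed cap applies only when scores are encoded for output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "QualityDistribution",
    "CoverageModel",
    "estimate_p1",
    "convolve",
    "quality_curve",
]


class QualityDistribution:
    """Probability mass function over integer phred scores ``0..qmax``."""

    def __init__(self, pmf: Sequence[float]):
        arr = np.asarray(pmf, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("pmf must be a non-empty 1-D array")
        if np.any(arr < 0):
            raise ValueError("pmf has negative mass")
        total = arr.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"pmf sums to {total}, not 1")
        self.pmf = arr

    # -- constructors ------------------------------------------------------

    @classmethod
    def point_mass(cls, q: int) -> "QualityDistribution":
        pmf = np.zeros(q + 1)
        pmf[q] = 1.0
        return cls(pmf)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[int, float]]) -> "QualityDistribution":
        pairs = list(pairs)
        qmax = max(q for q, _ in pairs)
        pmf = np.zeros(qmax + 1)
        for q, p in pairs:
            if q < 0:
                raise ValueError("negative phred value")
            pmf[q] += p
        pmf = pmf / pmf.sum()
        return cls(pmf)

    @classmethod
    def from_counts(cls, counts: Iterable[int]) -> "QualityDistribution":
        arr = np.asarray(list(counts), dtype=float)
        if arr.sum() <= 0:
            raise ValueError("no observations")
        return cls(arr / arr.sum())

    # -- basic quantities --------------------------------------------------

    @property
    def qmax(self) -> int:
        return self.pmf.size - 1

    def mean(self) -> float:
        return float(np.dot(np.arange(self.pmf.size), self.pmf))

    def error_mean(self) -> float:
        """Expected per-base error probability ``sum_q p(q) 10**(-q/10)``."""
        q = np.arange(self.pmf.size)
        return float(np.dot(self.pmf, 10.0 ** (-q / 10.0)))

    def phred(self) -> float:
        """Expected error expressed in phred units (the generalized f-mean)."""
        return float(-10.0 * np.log10(self.error_mean()))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.choice(self.pmf.size, size=n, p=self.pmf)

    def tv_distance(self, other: "QualityDistribution") -> float:
        n = max(self.pmf.size, other.pmf.size)
        a = np.zeros(n)
        b = np.zeros(n)
        a[: self.pmf.size] = self.pmf
        b[: other.pmf.size] = other.pmf
        return float(0.5 * np.abs(a - b).sum())


def estimate_p1(
    reads: Union[str, Path, Iterable[Sequence[int]]]
) -> QualityDistribution:
    """Empirical single-read quality distribution from FASTQ (or quality lists).

    The caller is expected to have trimmed reads to their assembled portions;
    every base of every read contributes one observation at raw phred
    resolution (no binning).
    """
    if isinstance(reads, (str, Path)):
        from .align_io import read_fastq_qualities

        reads = read_fastq_qualities(reads)
    counts: dict[int, int] = {}
    total = 0
    for quals in reads:
        for q in quals:
            counts[int(q)] = counts.get(int(q), 0) + 1
            total += 1
    if total == 0:
        raise ValueError("no quality observations in input")
    qmax = max(counts)
    arr = np.zeros(qmax + 1)
    for q, c in counts.items():
        arr[q] = c
    return QualityDistribution(arr / total)


def convolve(p1: QualityDistribution, x: int) -> QualityDistribution:
    """Distribution ``p_x`` of the sum of ``x`` independent draws from *p1*.

    Computed by the recursive relation ``p_x = p_{x-1} * p_1`` (direct
    convolution); ``p_1`` is *p1* itself.
    """
    if x < 1:
        raise ValueError(f"depth must be >= 1, got {x}")
    pmf = p1.pmf
    for _ in range(x - 1):
        pmf = np.convolve(pmf, p1.pmf)
    return QualityDistribution(pmf)


@dataclass
class CoverageModel:
    """Poisson-coverage quality model for a given ``p1`` and mean coverage."""

    p1: QualityDistribution
    lam: float
    x_max: Optional[int] = None

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError(f"coverage must be positive, got {self.lam}")
        if self.x_max is None:
            # generous truncation: 0.999 Poisson quantile, at least 10
            self.x_max = max(int(stats.poisson.ppf(0.999, self.lam)), 10)

    def depth_weights(self) -> np.ndarray:
        """P(depth = x | depth >= 1) for x = 1..x_max, renormalized."""
        x = np.arange(1, self.x_max + 1)
        w = stats.poisson.pmf(x, self.lam)
        return w / w.sum()

    def assembly_distribution(self) -> QualityDistribution:
        """Mixture ``sum_x w_x p_x`` over depths 1..x_max."""
        w = self.depth_weights()
        size = self.p1.qmax * self.x_max + 1
        mix = np.zeros(size)
        pmf = self.p1.pmf
        for i in range(self.x_max):
            mix[: pmf.size] += w[i] * pmf
            if i < self.x_max - 1:
                pmf = np.convolve(pmf, self.p1.pmf)
        return QualityDistribution(mix)

    def expected_error(self) -> float:
        return self.assembly_distribution().error_mean()

    def expected_quality(self) -> float:
        """Assembly-wide expected quality ``Q*`` in phred units."""
        return self.assembly_distribution().phred()

    def per_depth_error(self) -> pd.DataFrame:
        """Per-depth weights and expected-error contributions.

        Columns: ``depth``, ``weight`` (P(depth|>=1)), ``contribution``
        (weight times expected error probability at that depth), and the
        normalized ``fraction`` of total expected error.
        """
        w = self.depth_weights()
        contrib = np.empty(self.x_max)
        pmf = self.p1.pmf
        for i in range(self.x_max):
            q = np.arange(pmf.size)
            contrib[i] = w[i] * np.dot(pmf, 10.0 ** (-q / 10.0))
            if i < self.x_max - 1:
                pmf = np.convolve(pmf, self.p1.pmf)
        total = contrib.sum()
        return pd.DataFrame(
            {
                "depth": np.arange(1, self.x_max + 1),
                "weight": w,
                "contribution": contrib,
                "fraction": contrib / total,
            }
        )

    def error_fraction_by_depth(self, lowq_cut: int = 20) -> tuple[pd.DataFrame, float, float]:
        """Decompose expected error by depth.

        Returns ``(per_depth_table, F1, F1_lowq)`` where ``F1`` is the
        fraction of expected error contributed by depth-1 positions and
        ``F1_lowq`` the fraction contributed by depth-1 positions whose
        (single-read) score is below *lowq_cut*.
        """
        table = self.per_depth_error()
        total = table["contribution"].sum()
        f1 = float(table.loc[0, "contribution"] / total)
        w1 = float(table.loc[0, "weight"])
        q = np.arange(self.p1.pmf.size)
        err = 10.0 ** (-q / 10.0)
        low = q < lowq_cut
        f1_lowq = float(w1 * np.dot(self.p1.pmf[low], err[low]) / total)
        return table, f1, f1_lowq


def quality_curve(
    p1: QualityDistribution, lambdas: Sequence[float], lowq_cut: int = 20
) -> pd.DataFrame:
    """Tabulate ``Q*``, ``F1`` and ``F1_lowq`` over a coverage grid.

    The ``slope`` column gives the phred-per-1x increase between successive
    grid points (NaN for the first row).
    """
    lambdas = list(lambdas)
    if not lambdas:
        raise ValueError("empty coverage grid")
    rows = []
    for lam in lambdas:
        model = CoverageModel(p1, lam)
        _, f1, f1_lowq = model.error_fraction_by_depth(lowq_cut)
        rows.append(
            {"lam": lam, "Qstar": model.expected_quality(), "F1": f1, "F1_lowq": f1_lowq}
        )
    df = pd.DataFrame(rows)
    slope = np.full(len(df), np.nan)
    if len(df) > 1:
        d_q = np.diff(df["Qstar"].to_numpy())
        d_l = np.diff(df["lam"].to_numpy())
        slope[1:] = d_q / d_l
    df["slope"] = slope
    return df
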