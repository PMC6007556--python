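"""Insert-size library parameter estimation and QC.

A subsample of pairs is placed without rescue, pairs falling within one
contig give observed outer inserts, the sorted inserts are trimmed by
10% at each tail, and mean/sd are computed on the trimmed remainder.
Orientation is a majority vote over FR/RF/FF/RR; synthetic libraries are
forward-reverse by construction and skip the vote. The resulting
parameters drive pair rescue and the distance estimates on scaffold
edges.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from collections.abc import Iterable, Sequence
from itertools import islice

import numpy as np

from .index import UniqueKmerIndex
from .mapper import MapperParams, map_pair
from .synthetic import SyntheticSpec, extract_pairs, mapper_params_for

TRIM_FRACTION = 0.10
# A 10%-per-tail trimmed normal sample has sd 0.661549 * sigma
# (sqrt(1 - 2 z phi(z) / 0.8) at z = Phi^-1(0.9)); dividing by this makes
# the trimmed sd a consistent estimator of the library sd under a
# Gaussian insert distribution.
TRIM_SD_CORRECTION = 0.6615489974
MIN_USABLE_PAIRS = 50
# QC thresholds: a library is low quality when more than 30% of inserts
# are outliers or the spread exceeds 30% of the average
QC_MAX_OUTLIER_FRACTION = 0.30
QC_MAX_SD_OVER_MEAN = 0.30


@dataclass(frozen=True)
class LibraryParams:
    """Estimated insert-size distribution and orientation of one library."""

    mean_insert: float
    sd_insert: float
    orientation: str
    n_used: int = 0
    outlier_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.mean_insert <= 0:
            raise ValueError("mean_insert must be > 0")
        if self.sd_insert < 0:
            raise ValueError("sd_insert must be >= 0")
        if self.orientation not in ("FR", "RF", "FF", "RR"):
            raise ValueError(f"unknown orientation {self.orientation!r}")


@dataclass(frozen=True)
class InsertQC:
    """Observed-insert quality summary for one library."""

    n: int
    mean: float
    sd: float
    outlier_fraction: float
    low_quality: bool


def trimmed_mean_sd(inserts: Sequence[float]) -> tuple[float, float, int, int]:
    """Sort, drop floor(0.1 n) from each tail, return (mean, sd, n_kept, n_trimmed_each).

    The sd is the sample standard deviation of the trimmed values,
    rescaled by the normal-consistency factor so that on Gaussian inserts
    it estimates the untrimmed sd.
    """
    values = np.sort(np.asarray(inserts, dtype=float))
    n = values.size
    t = int(np.floor(TRIM_FRACTION * n))
    kept = values[t : n - t] if t > 0 else values
    mean = float(np.mean(kept))
    sd = float(np.std(kept, ddof=1)) / TRIM_SD_CORRECTION if kept.size > 1 else 0.0
    return mean, sd, int(kept.size), t


def _estimate_from_observations(
    inserts: list[int], orientations: list[str], orientation: str | None
) -> LibraryParams:
    if len(inserts) < MIN_USABLE_PAIRS:
        raise ValueError(
            f"only {len(inserts)} within-contig pairs were usable "
            f"(minimum {MIN_USABLE_PAIRS}); supply a larger sample"
        )
    mean, sd, n_kept, t = trimmed_mean_sd(inserts)
    if orientation is None:
        # majority vote over the four pair orientations; ties broken by
        # the fixed order FR, RF, FF, RR for input-order invariance
        counts = Counter(orientations)
        order = ("FR", "RF", "FF", "RR")
        orientation = max(order, key=lambda o: (counts.get(o, 0), -order.index(o)))
    return LibraryParams(
        mean_insert=mean,
        sd_insert=sd,
        orientation=orientation,
        n_used=n_kept,
        outlier_fraction=2 * t / len(inserts),
    )


def estimate_illumina(
    pairs: Iterable[tuple[str, str]],
    index: UniqueKmerIndex,
    n_sample: int = 100_000,
    min_report_score: int = 8,
    hit_capacity: int = 10,
) -> LibraryParams:
    """Estimate library parameters from up to ``n_sample`` short-read pairs.

    Pairs are placed with a report threshold of 8 and rescue disabled;
    only pairs with both reads on one contig inform the estimate.
    """
    params = MapperParams(
        hit_capacity=hit_capacity,
        min_report_score=min_report_score,
        lib=None,
    )
    inserts: list[int] = []
    orientations: list[str] = []
    for qf, qr in islice(pairs, n_sample):
        placement = map_pair(qf, qr, index, params)
        if placement is None or not placement.same_contig:
            continue
        inserts.append(placement.observed_insert)
        orientations.append(placement.orientation)
    return _estimate_from_observations(inserts, orientations, orientation=None)


def estimate_synthetic(
    long_reads: Iterable[tuple[str, str]],
    index: UniqueKmerIndex,
    spec: SyntheticSpec,
    n_reads: int = 1000,
) -> dict[int, LibraryParams]:
    """Estimate per-D parameters from a subsample of long reads.

    Synthetic pairs are forward-reverse by construction, so orientation
    is fixed to FR rather than estimated.
    """
    params = mapper_params_for(spec, lib=None)  # no rescue during estimation
    inserts: dict[int, list[int]] = {d: [] for d in spec.insert_sizes}
    for read_id, seq in islice(long_reads, n_reads):
        for pair in extract_pairs(read_id, seq, spec):
            placement = map_pair(pair.qf, pair.qr, index, params)
            if placement is None or not placement.same_contig:
                continue
            inserts[pair.library_tag].append(placement.observed_insert)
    out: dict[int, LibraryParams] = {}
    for d in spec.insert_sizes:
        try:
            out[d] = _estimate_from_observations(inserts[d], [], orientation="FR")
        except ValueError as exc:
            raise ValueError(f"insert size {d}: {exc}") from exc
    return out


def insert_qc(inserts: Sequence[float]) -> InsertQC:
    """Flag a library whose observed inserts look unreliable.

    The centre is the 10%-trimmed mean/sd; the outlier fraction is the
    share of all observations beyond mean +- 3 sd. A library is low
    quality when that fraction exceeds 30% or the sd exceeds 30% of the
    mean.
    """
    values = np.asarray(inserts, dtype=float)
    if values.size < 1:
        raise ValueError("at least one within-contig placement is required")
    mean, sd, _, _ = trimmed_mean_sd(values)
    if sd > 0:
        outliers = np.abs(values - mean) > 3 * sd
        outlier_fraction = float(np.mean(outliers))
    else:
        outlier_fraction = float(np.mean(values != mean))
    low_quality = (
        outlier_fraction > QC_MAX_OUTLIER_FRACTION or sd > QC_MAX_SD_OVER_MEAN * mean
    )
    return InsertQC(
        n=int(values.size),
        mean=mean,
        sd=sd,
        outlier_fraction=outlier_fraction,
        low_quality=low_quality,
    )
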