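"""Competitive fitness: the per-generation selection coefficient s_g.

In a competition assay a hybrid strain is mixed with a fluorescent
reference strain (4:1 by default), grown, and counted by flow cytometry at
two timepoints. The selection coefficient is the change in the natural log
of the hybrid:reference count ratio, normalised by the number of
generations elapsed:

    s_g = [ln(Hf / Rf) - ln(H0 / R0)] / (gf - g0)

s_g = 0 means equal fitness; positive values favour the hybrid. Natural
log is used for the ratio (the definition states ln); generations are the
standard population doublings, log2 of the total fold-change, provided as
a helper since assays may derive g from either total or reference growth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

FITNESS_COLUMNS = ["strain", "replicate", "H0", "R0", "Hf", "Rf", "g0", "gf"]


@dataclass(frozen=True)
class CompetitionObservation:
    """Hybrid (H) and reference (R) counts at two timepoints.

    ``technical_id`` distinguishes technical replicates within a biological
    replicate; leave ``None`` when each row is an independent biological
    replicate.
    """

    strain_id: str
    replicate_id: str
    h0: float
    r0: float
    hf: float
    rf: float
    g0: float
    gf: float
    technical_id: Optional[str] = None

    def __post_init__(self) -> None:
        counts = {"H0": self.h0, "R0": self.r0, "Hf": self.hf, "Rf": self.rf}
        bad = [name for name, c in counts.items() if c <= 0]
        if bad:
            raise ValueError(
                f"{self.strain_id}/{self.replicate_id}: non-positive counts "
                f"for {bad}; use the pseudocount option for simulated edge "
                "cases with empty gates"
            )
        if self.gf <= self.g0:
            raise ValueError(
                f"{self.strain_id}/{self.replicate_id}: gf ({self.gf}) must "
                f"exceed g0 ({self.g0})"
            )


@dataclass(frozen=True)
class FitnessEstimate:
    """Per-strain summary of replicate selection coefficients."""

    strain_id: str
    replicate_values: tuple[float, ...]
    mean: float
    sd: float
    n_replicates: int
    sd_defined: bool


def generations_elapsed(n0: float, nf: float) -> float:
    """Population doublings between two total counts: log2(Nf / N0)."""
    if n0 <= 0 or nf <= 0:
        raise ValueError(f"counts must be positive, got N0={n0}, Nf={nf}")
    return math.log2(nf / n0)


def selection_coefficient(
    obs: CompetitionObservation, pseudocount: float = 0.0
) -> float:
    """Per-generation selection coefficient of the hybrid vs the reference.

    The log-ratio change is evaluated through the exact rational cross-ratio
    ``(Hf * R0) / (Rf * H0)`` reduced to lowest terms, then as
    ``ln(numerator) - ln(denominator)``. This makes the calibration
    identities bit-exact in floating point: equal initial and final ratios
    give exactly 0.0, swapping the hybrid and reference roles negates the
    result exactly, and rescaling all four counts by a common (exactly
    representable) factor leaves it unchanged. ``pseudocount`` is added to
    all four counts first (escape hatch for simulated data with empty
    gates; real cytometry counts should not need it).
    """
    h0, r0 = Fraction(obs.h0) + Fraction(pseudocount), Fraction(obs.r0) + Fraction(pseudocount)
    hf, rf = Fraction(obs.hf) + Fraction(pseudocount), Fraction(obs.rf) + Fraction(pseudocount)
    cross = (hf * r0) / (rf * h0)
    log_change = math.log(cross.numerator) - math.log(cross.denominator)
    return log_change / (obs.gf - obs.g0)


def summarize_fitness(
    observations: Sequence[CompetitionObservation],
    average_technical: bool = True,
    pseudocount: float = 0.0,
) -> list[FitnessEstimate]:
    """Per-strain mean and standard deviation of replicate s_g values.

    When ``average_technical`` is set, observations sharing a
    (strain, replicate) pair but differing in ``technical_id`` are averaged
    first, so technical replicates do not inflate the apparent sample size.
    The standard deviation is the sample (n-1) deviation; with a single
    replicate it is reported as 0.0 with ``sd_defined=False``.

    Estimates are returned sorted by strain_id.
    """
    if not observations:
        raise ValueError("no observations supplied")
    by_strain: dict[str, list[CompetitionObservation]] = {}
    for obs in observations:
        by_strain.setdefault(obs.strain_id, []).append(obs)

    estimates = []
    for strain_id in sorted(by_strain):
        group = by_strain[strain_id]
        if average_technical:
            by_bio: dict[str, list[float]] = {}
            for obs in group:
                by_bio.setdefault(obs.replicate_id, []).append(
                    selection_coefficient(obs, pseudocount))
            values = [sum(v) / len(v) for _, v in sorted(by_bio.items())]
        else:
            values = [selection_coefficient(obs, pseudocount)
                      for obs in sorted(group, key=lambda o: (o.replicate_id,
                                                              o.technical_id or ""))]
        n = len(values)
        mean = sum(values) / n
        if n > 1:
            sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
            sd_defined = True
        else:
            sd, sd_defined = 0.0, False
        estimates.append(FitnessEstimate(
            strain_id=strain_id, replicate_values=tuple(values),
            mean=mean, sd=sd, n_replicates=n, sd_defined=sd_defined,
        ))
    return estimates


def read_competition_table(path: str | Path) -> list[CompetitionObservation]:
    """Read a competition-count table (TSV; optional ``tech`` column)."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in FITNESS_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"competition table {path} lacks columns {missing}")
    has_tech = "tech" in table.columns
    observations = []
    for row in table.itertuples(index=False):
        observations.append(CompetitionObservation(
            strain_id=row.strain,
            replicate_id=str(row.replicate),
            h0=float(row.H0), r0=float(row.R0),
            hf=float(row.Hf), rf=float(row.Rf),
            g0=float(row.g0), gf=float(row.gf),
            technical_id=str(row.tech) if has_tech else None,
        ))
    return observations


def estimates_to_frame(estimates: Sequence[FitnessEstimate]) -> pd.DataFrame:
    """Flatten fitness estimates to the on-disk TSV layout."""
    rows = [{
        "strain": e.strain_id,
        "mean_sg": e.mean,
        "sd_sg": e.sd,
        "n_replicates": e.n_replicates,
        "sd_defined": e.sd_defined,
    } for e in estimates]
    return pd.DataFrame(
        rows, columns=["strain", "mean_sg", "sd_sg", "n_replicates", "sd_defined"])
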