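"""Cytogenetic position statistics for FISH signal measurements.

Two coordinate systems are used for a hybridization site on a mitotic
chromosome:

* RPHC — relative position on the chromosome arm: 100 x (distance from the
  centromere to the signal) / (arm length). 0 is the centromere, 100 the
  telomere of that arm.
* FL — fractional length: 100 x (distance from the short-arm telomere to the
  signal) / (total chromosome length). This whole-chromosome coordinate is
  what map integration uses, with the short arm conventionally at the top.

With f_s the short-arm fraction of the chromosome, the two are related by

    short arm:  FL = f_s * (100 - RPHC)
    long arm:   FL = 100 * f_s + (1 - f_s) * RPHC

Aggregation mirrors how FISH mapping tables are reported: per-chromosome RPHC
measurements are summarized as mean +/- sample SD, and the detection frequency
is the percentage of analyzed metaphases in which the probe's signal was seen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "KaryotypeArm",
    "SignalRecord",
    "ProbePosition",
    "compute_rphc",
    "aggregate_position",
    "rphc_to_fl",
    "fl_to_rphc",
    "read_signal_table",
    "read_karyotype",
    "positions_to_frame",
]


@dataclass(frozen=True)
class KaryotypeArm:
    """Arm geometry of one chromosome: short-arm fraction f_s in (0, 1)."""

    chromosome_id: str
    short_arm_fraction: float
    total_length: float = 100.0

    def __post_init__(self) -> None:
        if not (0.0 < self.short_arm_fraction < 1.0):
            raise ValueError(
                f"short_arm_fraction must be in (0,1), got {self.short_arm_fraction}"
            )


@dataclass(frozen=True)
class SignalRecord:
    """One raw signal measurement on one chromosome copy in one metaphase."""

    probe_id: str
    metaphase_id: str
    chromosome_copy: str
    arm: str  # "short" | "long"
    d_centromere: float
    arm_length: float

    def __post_init__(self) -> None:
        if self.arm not in ("short", "long"):
            raise ValueError(f"arm must be 'short' or 'long', got {self.arm!r}")
        if self.arm_length <= 0:
            raise ValueError("arm_length must be > 0")
        if not (0 <= self.d_centromere <= self.arm_length):
            raise ValueError(
                f"signal distance {self.d_centromere} outside arm "
                f"[0, {self.arm_length}] for probe {self.probe_id}"
            )


@dataclass(frozen=True)
class ProbePosition:
    """Aggregated position of one probe: the row of a mapping results table."""

    probe_id: str
    rphc_mean: float
    rphc_sd: float
    arm: str
    n_chromosomes: int
    detection_frequency: float
    n_metaphases: int


def compute_rphc(d_centromere: float, arm_length: float) -> float:
    """Relative position on the chromosome arm, in percent of arm length."""
    if arm_length <= 0:
        raise ValueError("arm_length must be > 0")
    if not (0 <= d_centromere <= arm_length):
        raise ValueError(
            f"distance {d_centromere} outside arm [0, {arm_length}]"
        )
    return 100.0 * d_centromere / arm_length


def aggregate_position(
    signals: Sequence[SignalRecord],
    n_metaphases_analyzed: int,
    n_metaphases_detected: int,
    *,
    detection_denominator: str = "metaphases",
) -> ProbePosition:
    """Aggregate one probe's signal measurements into a table row.

    ``rphc_mean``/``rphc_sd`` are the sample mean and sample SD (n-1
    denominator) of per-chromosome RPHC values; a single measurement reports
    SD 0.0 with a low-n warning. ``detection_frequency`` is
    100 x detected / analyzed, rounded to 1 decimal; the denominator is the
    number of metaphases by default, or twice that when
    ``detection_denominator="chromosomes"`` (two homologs per cell).
    """
    if not signals:
        raise ValueError("no signals to aggregate")
    probe_ids = {s.probe_id for s in signals}
    if len(probe_ids) > 1:
        raise ValueError(f"signals from multiple probes: {sorted(probe_ids)}")
    arms = {s.arm for s in signals}
    if len(arms) > 1:
        raise ValueError(
            f"probe {signals[0].probe_id}: signals on mixed arms {sorted(arms)}; "
            "a probe maps to one arm"
        )
    if n_metaphases_detected > n_metaphases_analyzed:
        raise ValueError("detected metaphases exceed analyzed metaphases")

    rphc = np.array([compute_rphc(s.d_centromere, s.arm_length) for s in signals])
    if len(rphc) == 1:
        warnings.warn(
            f"probe {signals[0].probe_id}: single measurement, SD reported as 0.0",
            stacklevel=2,
        )
        sd = 0.0
    else:
        sd = float(np.std(rphc, ddof=1))

    denom = {
        "metaphases": n_metaphases_analyzed,
        "chromosomes": 2 * n_metaphases_analyzed,
    }.get(detection_denominator)
    if denom is None:
        raise ValueError(
            f"unknown detection_denominator {detection_denominator!r}"
        )
    freq = round(100.0 * n_metaphases_detected / denom, 1)

    return ProbePosition(
        probe_id=signals[0].probe_id,
        rphc_mean=float(np.mean(rphc)),
        rphc_sd=sd,
        arm=signals[0].arm,
        n_chromosomes=len(signals),
        detection_frequency=freq,
        n_metaphases=n_metaphases_analyzed,
    )


def rphc_to_fl(rphc: float, arm: str, karyotype: KaryotypeArm) -> float:
    """Convert an arm-relative position (RPHC, %) to fractional length (%)."""
    if not (0 <= rphc <= 100):
        raise ValueError(f"RPHC must be in [0, 100], got {rphc}")
    f_s = karyotype.short_arm_fraction
    if arm == "short":
        return f_s * (100.0 - rphc)
    if arm == "long":
        return 100.0 * f_s + (1.0 - f_s) * rphc
    raise ValueError(f"arm must be 'short' or 'long', got {arm!r}")


def fl_to_rphc(fl: float, karyotype: KaryotypeArm) -> tuple[str, float]:
    """Invert :func:`rphc_to_fl`: return (arm, RPHC) for a fractional length.

    FL exactly at the centromere (100 x f_s) returns ``("centromere", 0.0)``.
    """
    if not (0 <= fl <= 100):
        raise ValueError(f"FL must be in [0, 100], got {fl}")
    f_s = karyotype.short_arm_fraction
    centromere_fl = 100.0 * f_s
    if fl == centromere_fl:
        return ("centromere", 0.0)
    if fl < centromere_fl:
        return ("short", 100.0 - fl / f_s)
    return ("long", (fl - centromere_fl) / (1.0 - f_s))


def read_signal_table(path: str | Path) -> list[SignalRecord]:
    """Read a raw signal-measurement TSV (probe_id, metaphase_id,
    chromosome_copy, arm, d_centromere, arm_length)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"probe_id", "metaphase_id", "chromosome_copy", "arm",
                "d_centromere", "arm_length"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"signal table missing column(s): {sorted(missing)}")
    if df.empty:
        raise ValueError("signal table contains no measurements")
    return [
        SignalRecord(
            probe_id=str(r.probe_id),
            metaphase_id=str(r.metaphase_id),
            chromosome_copy=str(r.chromosome_copy),
            arm=str(r.arm),
            d_centromere=float(r.d_centromere),
            arm_length=float(r.arm_length),
        )
        for r in df.itertuples()
    ]


def read_karyotype(path: str | Path) -> dict[str, KaryotypeArm]:
    """Read a karyotype TSV (chromosome_id, short_arm_fraction[, total_length])."""
    df = pd.read_csv(path, sep="\t", comment="#")
    out = {}
    for r in df.itertuples():
        out[str(r.chromosome_id)] = KaryotypeArm(
            chromosome_id=str(r.chromosome_id),
            short_arm_fraction=float(r.short_arm_fraction),
            total_length=float(getattr(r, "total_length", 100.0)),
        )
    return out


def positions_to_frame(positions: Iterable[ProbePosition]) -> pd.DataFrame:
    """Tabulate positions with report rounding (RPHC to 1 decimal)."""
    rows = [
        {
            "probe_id": p.probe_id,
            "rphc_mean": round(p.rphc_mean, 1),
            "rphc_sd": round(p.rphc_sd, 1),
            "arm": p.arm,
            "n_chromosomes": p.n_chromosomes,
            "detection_frequency": p.detection_frequency,
            "n_metaphases": p.n_metaphases,
        }
        for p in positions
    ]
    return pd.DataFrame(rows)
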