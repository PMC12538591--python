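"""Derive the three module-specific training datasets from activity records.

Module 1 learns the optimum temperature T_opt (the temperature of a sequence's
highest kcat/Km). Module 2 learns log10 of the maximum efficiency
kcat/Km,max (the value at T_opt; log10 makes the heavy-tailed efficiencies
approximately normal). Module 3 learns the max-normalized
activity-temperature profile: relative activity kcat/Km / kcat/Km,max indexed
by the temperature offset dT = T - T_opt.

The processing order is: curve-based estimation (optional, upstream) ->
outlier filtering -> dataset building. Filtering defaults to the fixed
linear-scale bounds [1e-2, 1e5] mM^-1 s^-1; an IQR fence on log10 values is
available as the alternative. A sequence whose maximal record is excluded by
the filter has its T_opt recomputed from the surviving records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError, ValidationError
from .records import ActivityRecord

#: Fixed linear-scale bounds in mM^-1 s^-1: efficiencies outside this range
#: fall outside the typical range for enzymes and are treated as outliers.
DEFAULT_BOUNDS = (1e-2, 1e5)


@dataclass(frozen=True)
class ToptEntry:
    """One sequence's optimum temperature (of its highest kcat/Km)."""

    sequence_id: str
    t_opt_C: float


@dataclass(frozen=True)
class MaxEntry:
    """One sequence's log10 maximum catalytic efficiency, log10(mM^-1 s^-1)."""

    sequence_id: str
    log10_max: float


@dataclass(frozen=True)
class ProfileEntry:
    """One record's position on its sequence's normalized activity profile."""

    sequence_id: str
    delta_t_C: float
    rel_activity: float


@dataclass(frozen=True)
class FilterEvent:
    """One excluded record and the reason for its exclusion."""

    record: ActivityRecord
    reason: str


@dataclass
class DerivedDatasets:
    """The three training tables plus the exclusion log."""

    topt: list[ToptEntry]
    maxima: list[MaxEntry]
    profile: list[ProfileEntry]
    filter_log: list[FilterEvent] = field(default_factory=list)

    def topt_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.sequence_id, e.t_opt_C) for e in self.topt],
            columns=["sequence_id", "t_opt_C"],
        )

    def max_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.sequence_id, e.log10_max) for e in self.maxima],
            columns=["sequence_id", "log10_max"],
        )

    def profile_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.sequence_id, e.delta_t_C, e.rel_activity) for e in self.profile],
            columns=["sequence_id", "delta_t_C", "rel_activity"],
        )

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.topt_frame().to_csv(out / "topt.tsv", sep="\t", index=False)
        self.max_frame().to_csv(out / "max.tsv", sep="\t", index=False)
        self.profile_frame().to_csv(out / "profile.tsv", sep="\t", index=False)
        log_rows = [
            {
                "sequence_id": e.record.sequence_id,
                "temperature_C": e.record.temperature_C,
                "kcat_km_mM_s": e.record.kcat_km,
                "reason": e.reason,
            }
            for e in self.filter_log
        ]
        pd.DataFrame(
            log_rows,
            columns=["sequence_id", "temperature_C", "kcat_km_mM_s", "reason"],
        ).to_csv(out / "filter_log.tsv", sep="\t", index=False)


def filter_outliers(
    records: Sequence[ActivityRecord],
    method: str = "fixed_bounds",
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
) -> tuple[list[ActivityRecord], list[FilterEvent]]:
    """Drop records with implausibly extreme kcat/Km values.

    ``fixed_bounds`` keeps records with bounds[0] <= kcat/Km <= bounds[1]
    (linear scale). ``iqr`` computes Q1/Q3 on the log10 values and keeps
    records within the Tukey fences [Q1 - 1.5 IQR, Q3 + 1.5 IQR]. Every
    exclusion is logged with its reason.
    """
    if method not in ("fixed_bounds", "iqr"):
        raise ConfigError(f"unknown outlier filter method {method!r}")
    if bounds[0] >= bounds[1]:
        raise ConfigError(f"invalid bounds {bounds!r}: lower must be < upper")
    if not records:
        return [], []

    kept: list[ActivityRecord] = []
    log: list[FilterEvent] = []
    if method == "fixed_bounds":
        lo, hi = bounds
        for record in records:
            if lo <= record.kcat_km <= hi:
                kept.append(record)
            else:
                side = "below" if record.kcat_km < lo else "above"
                log.append(
                    FilterEvent(
                        record,
                        f"kcat_km={record.kcat_km:g} {side} fixed bounds "
                        f"[{lo:g}, {hi:g}]",
                    )
                )
    else:
        log10_values = np.log10([r.kcat_km for r in records])
        q1, q3 = np.percentile(log10_values, [25, 75])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        for record, value in zip(records, log10_values):
            if lo_fence <= value <= hi_fence:
                kept.append(record)
            else:
                log.append(
                    FilterEvent(
                        record,
                        f"log10 kcat_km={value:g} outside IQR fences "
                        f"[{lo_fence:g}, {hi_fence:g}]",
                    )
                )
    return kept, log


def estimate_profile_from_activity(
    reference: ActivityRecord,
    activity_curve: Sequence[tuple[float, float]],
    atol: float = 1e-9,
) -> list[ActivityRecord]:
    """Expand a single reference kcat/Km using a relative activity curve.

    Literature often reports kcat/Km at one temperature together with an
    activity-temperature curve at fixed substrate concentration. Each curve
    point (T, a) is converted to an estimated record with
    kcat_km = reference.kcat_km * a / a_ref, where a_ref is the curve
    activity at the reference temperature. The reference temperature point
    reproduces the reference value exactly; emitted records carry
    ``is_estimated=True``.
    """
    a_ref = None
    for temp, activity in activity_curve:
        if math.isclose(temp, reference.temperature_C, abs_tol=atol):
            a_ref = activity
            break
    if a_ref is None:
        raise ValidationError(
            f"activity curve lacks the reference temperature "
            f"{reference.temperature_C:g} C"
        )
    if a_ref == 0:
        raise ValidationError("activity at the reference temperature is zero")

    out: list[ActivityRecord] = []
    for temp, activity in activity_curve:
        if math.isclose(temp, reference.temperature_C, abs_tol=atol):
            value = reference.kcat_km  # exact, no ratio rounding
        else:
            value = reference.kcat_km * activity / a_ref
        out.append(
            replace(
                reference,
                temperature_C=temp,
                kcat_km=value,
                is_estimated=True,
            )
        )
    return out


def build_derived_datasets(
    records: Sequence[ActivityRecord],
    tie_break: str = "lowest_T",
) -> DerivedDatasets:
    """Build the T_opt, log10-max and relative-profile datasets.

    Per sequence: T_opt is the temperature of the maximal kcat/Km (ties at the
    maximum broken by ``tie_break``, default lowest temperature); log10_max is
    log10 of that maximum; every record becomes a profile entry with
    dT = T - T_opt and rel = kcat/Km / max. A sequence with a single record
    yields T_opt = its temperature and a single profile point (0, 1). Exact
    duplicates of the (dT=0, rel=1) anchor (replicate measurements equal to
    the maximum at T_opt) are collapsed so each sequence has exactly one.
    """
    if tie_break not in ("lowest_T", "highest_T"):
        raise ConfigError(f"unknown tie_break {tie_break!r}")

    by_sequence: dict[str, list[ActivityRecord]] = {}
    for record in records:
        by_sequence.setdefault(record.sequence_id, []).append(record)

    topt: list[ToptEntry] = []
    maxima: list[MaxEntry] = []
    profile: list[ProfileEntry] = []
    for sid, group in by_sequence.items():
        max_value = max(r.kcat_km for r in group)
        max_temps = [r.temperature_C for r in group if r.kcat_km == max_value]
        t_opt = min(max_temps) if tie_break == "lowest_T" else max(max_temps)
        topt.append(ToptEntry(sid, t_opt))
        maxima.append(MaxEntry(sid, math.log10(max_value)))
        seen_anchor = False
        for record in group:
            delta_t = record.temperature_C - t_opt
            rel = record.kcat_km / max_value
            if delta_t == 0 and rel == 1.0:
                if seen_anchor:
                    continue
                seen_anchor = True
            profile.append(ProfileEntry(sid, delta_t, rel))
    return DerivedDatasets(topt=topt, maxima=maxima, profile=profile)


def derive_datasets(
    records: Sequence[ActivityRecord],
    filter_method: str = "fixed_bounds",
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
    tie_break: str = "lowest_T",
) -> DerivedDatasets:
    """Filter records then build the three derived datasets, keeping the log."""
    kept, log = filter_outliers(records, method=filter_method, bounds=bounds)
    derived = build_derived_datasets(kept, tie_break=tie_break)
    derived.filter_log = log
    return derived


def records_frame(records: Iterable[ActivityRecord]) -> pd.DataFrame:
    """Records as a DataFrame with a log10 kcat/Km column appended."""
    df = pd.DataFrame(
        [
            (r.sequence_id, r.temperature_C, r.kcat_km, r.is_wild_type, r.is_estimated)
            for r in records
        ],
        columns=[
            "sequence_id",
            "temperature_C",
            "kcat_km_mM_s",
            "is_wild_type",
            "is_estimated",
        ],
    )
    df["log10_kcat_km"] = np.log10(df["kcat_km_mM_s"])
    return df
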