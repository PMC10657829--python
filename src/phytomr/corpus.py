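"""Prescription corpora and herb-attribute statistics.

Ingests long-format prescription tables (one herb per row) and an
herb-attribute dictionary (property / flavor / meridian / recommended dose),
and computes the descriptive statistics used to characterise formula usage
at each cirrhosis stage: per-herb frequency, usage rate (percent of
prescriptions), proportion (percent of all herb occurrences), dose summaries
against the pharmacopoeia-recommended range, and occurrence-weighted
attribute frequencies.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STAGES = ("compensated", "decompensated")
PROPERTIES = frozenset({"cold", "cool", "mild", "warm", "hot"})
FLAVORS = frozenset(
    {"sour", "bitter", "sweet", "pungent", "salty", "astringent", "bland"}
)
MERIDIANS = frozenset(
    {
        "liver", "heart", "spleen", "lung", "kidney", "pericardium",
        "gallbladder", "small_intestine", "stomach", "large_intestine",
        "bladder", "triple_energizer",
    }
)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (print-table convention), not banker's."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Prescription:
    """One clinical formula: a stage label plus herb/dose pairs."""

    study_id: str
    stage: str
    herbs: tuple[tuple[str, float | None], ...]

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(
                f"unknown stage {self.stage!r} for {self.study_id!r}; "
                f"expected one of {STAGES}"
            )
        names = [h for h, _ in self.herbs]
        dupes = [h for h, c in Counter(names).items() if c > 1]
        if dupes:
            raise ValueError(
                f"duplicate herbs in prescription {self.study_id!r}: {dupes}"
            )

    @property
    def herb_set(self) -> frozenset[str]:
        return frozenset(h for h, _ in self.herbs)

    def dose(self, herb: str) -> float | None:
        for h, d in self.herbs:
            if h == herb:
                return d
        return None


@dataclass(frozen=True)
class HerbAttribute:
    """Pharmacopoeia attributes of a single herb."""

    herb_name: str
    properties: frozenset[str]
    flavors: frozenset[str]
    meridians: frozenset[str]
    recommended_dose: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.properties or not self.flavors:
            raise ValueError(
                f"{self.herb_name!r}: at least one property and one flavor required"
            )
        bad = self.properties - PROPERTIES
        if bad:
            raise ValueError(f"{self.herb_name!r}: unknown properties {sorted(bad)}")
        bad = self.flavors - FLAVORS
        if bad:
            raise ValueError(f"{self.herb_name!r}: unknown flavors {sorted(bad)}")
        bad = self.meridians - MERIDIANS
        if bad:
            raise ValueError(f"{self.herb_name!r}: unknown meridians {sorted(bad)}")
        lo, hi = self.recommended_dose
        if lo > hi:
            raise ValueError(f"{self.herb_name!r}: dose range lo {lo} > hi {hi}")


@dataclass(frozen=True)
class FrequencyRecord:
    """Per-herb row of a frequency table.

    ``rate`` and ``proportion`` are exact percents; the ``*_rounded``
    companions use half-up rounding to two decimals, the convention of the
    printed tables this mirrors.
    """

    herb_name: str
    frequency: int
    rate: float
    proportion: float
    rate_rounded: float
    proportion_rounded: float
    dose_min: float | None
    dose_max: float | None
    dose_mean: float | None
    dose_sd: float | None
    exceeds_recommended: bool | None


@dataclass(frozen=True)
class AttributeFrequency:
    axis: str  # property | flavor | meridian
    level: str
    count: int
    percent: float
    percent_rounded: float


# ---------------------------------------------------------------------------
# ingestion


def read_prescriptions(
    path: str | Path,
    name_map: Mapping[str, str] | None = None,
) -> list[Prescription]:
    """Read a long-format prescription CSV (study_id, stage, herb, dose_g).

    ``name_map`` maps raw synonyms to canonical herb names; rows whose herb
    cannot be mapped and is not already canonical-looking are collected and
    reported in a single error rather than silently dropped.  A study id
    appearing under two different stage labels is an error.
    """
    df = pd.read_csv(path, dtype={"study_id": str}, comment="#")
    if df.empty:
        logger.warning("prescription file %s is empty", path)
        return []
    required = {"study_id", "stage", "herb"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns {sorted(missing)} in {path}")
    if "dose_g" not in df.columns:
        df["dose_g"] = np.nan

    name_map = dict(name_map or {})
    df["herb"] = df["herb"].astype(str).str.strip()
    df["herb"] = df["herb"].map(lambda h: name_map.get(h, h))

    conflicting = (
        df.groupby("study_id")["stage"].nunique().loc[lambda s: s > 1].index.tolist()
    )
    if conflicting:
        raise ValueError(
            f"study ids with conflicting stage labels: {conflicting}"
        )

    out: list[Prescription] = []
    for sid, grp in df.groupby("study_id", sort=False):
        herbs = tuple(
            (row.herb, None if pd.isna(row.dose_g) else float(row.dose_g))
            for row in grp.itertuples()
        )
        for _, d in herbs:
            if d is not None and d <= 0:
                raise ValueError(f"non-positive dose in prescription {sid!r}")
        out.append(Prescription(str(sid), str(grp["stage"].iloc[0]), herbs))
    return out


def read_attributes(path: str | Path) -> dict[str, HerbAttribute]:
    """Read the herb-attribute dictionary CSV.

    Columns: herb, properties, flavors, meridians (semicolon-delimited),
    dose_lo_g, dose_hi_g.
    """
    df = pd.read_csv(path, comment="#")
    out: dict[str, HerbAttribute] = {}
    for row in df.itertuples():
        split = lambda s: frozenset(x.strip() for x in str(s).split(";") if x.strip())
        out[str(row.herb).strip()] = HerbAttribute(
            herb_name=str(row.herb).strip(),
            properties=split(row.properties),
            flavors=split(row.flavors),
            meridians=split(row.meridians),
            recommended_dose=(float(row.dose_lo_g), float(row.dose_hi_g)),
        )
    return out


def write_prescriptions(
    prescriptions: Iterable[Prescription], path: str | Path
) -> None:
    rows = [
        {"study_id": p.study_id, "stage": p.stage, "herb": h, "dose_g": d}
        for p in prescriptions
        for h, d in p.herbs
    ]
    pd.DataFrame(rows, columns=["study_id", "stage", "herb", "dose_g"]).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# statistics


def frequency_table(
    prescriptions: Sequence[Prescription],
    attributes: Mapping[str, HerbAttribute] | None = None,
) -> list[FrequencyRecord]:
    """Per-herb frequency / rate / proportion / dose statistics.

    rate = 100 * frequency / n_prescriptions (percent of prescriptions that
    contain the herb); proportion = 100 * frequency / total herb occurrences.
    Dose statistics are over prescriptions where the herb carries a recorded
    dose; missing doses are excluded, not imputed.  ``exceeds_recommended``
    compares the mean dose with the upper bound of the pharmacopoeia range
    when the herb has an attribute record, else None.
    """
    if not prescriptions:
        raise ValueError("need at least one prescription")
    n = len(prescriptions)
    counts: Counter[str] = Counter()
    doses: dict[str, list[float]] = {}
    for p in prescriptions:
        for h, d in p.herbs:
            counts[h] += 1
            if d is not None:
                doses.setdefault(h, []).append(d)
    total = sum(counts.values())

    records = []
    for herb, freq in counts.items():
        ds = doses.get(herb, [])
        arr = np.asarray(ds, dtype=float)
        rate = 100.0 * freq / n
        prop = 100.0 * freq / total
        rec_range = attributes[herb].recommended_dose if attributes and herb in attributes else None
        mean = float(arr.mean()) if ds else None
        records.append(
            FrequencyRecord(
                herb_name=herb,
                frequency=freq,
                rate=rate,
                proportion=prop,
                rate_rounded=round_half_up(rate),
                proportion_rounded=round_half_up(prop),
                dose_min=float(arr.min()) if ds else None,
                dose_max=float(arr.max()) if ds else None,
                dose_mean=mean,
                dose_sd=float(arr.std(ddof=1)) if len(ds) > 1 else None,
                exceeds_recommended=(
                    None if mean is None or rec_range is None else mean > rec_range[1]
                ),
            )
        )
    records.sort(key=lambda r: (-r.frequency, r.herb_name))
    return records


def frequency_frame(records: Sequence[FrequencyRecord]) -> pd.DataFrame:
    """Frequency table as a DataFrame in printed-table column order."""
    return pd.DataFrame(
        {
            "herb": [r.herb_name for r in records],
            "frequency": [r.frequency for r in records],
            "rate_pct": [r.rate_rounded for r in records],
            "proportion_pct": [r.proportion_rounded for r in records],
            "dose_min_g": [r.dose_min for r in records],
            "dose_max_g": [r.dose_max for r in records],
            "dose_mean_g": [r.dose_mean for r in records],
            "dose_sd_g": [r.dose_sd for r in records],
            "exceeds_recommended": [r.exceeds_recommended for r in records],
        }
    )


_AXES = (("property", "properties"), ("flavor", "flavors"), ("meridian", "meridians"))


def attribute_frequencies(
    prescriptions: Sequence[Prescription],
    attributes: Mapping[str, HerbAttribute],
    herb_subset: Iterable[str],
) -> list[AttributeFrequency]:
    """Occurrence-weighted property / flavor / meridian frequencies.

    Each herb in ``herb_subset`` contributes its prescription frequency once
    per attribute level it carries, so axis totals count occurrences rather
    than herbs (an herb attributed to three meridians and used 50 times adds
    150 to the meridian axis).
    """
    subset = list(dict.fromkeys(herb_subset))
    missing = [h for h in subset if h not in attributes]
    if missing:
        raise KeyError(f"no attribute record for herbs: {missing}")
    freq: Counter[str] = Counter()
    for p in prescriptions:
        present = p.herb_set
        for h in subset:
            if h in present:
                freq[h] += 1

    out: list[AttributeFrequency] = []
    for axis, attr_field in _AXES:
        counts: Counter[str] = Counter()
        for h in subset:
            for level in getattr(attributes[h], attr_field):
                counts[level] += freq[h]
        axis_total = sum(counts.values())
        for level, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
            pct = 100.0 * c / axis_total if axis_total else 0.0
            out.append(
                AttributeFrequency(axis, level, c, pct, round_half_up(pct))
            )
    return out


def incidence_matrix(
    prescriptions: Sequence[Prescription], weighted: bool = False
) -> pd.DataFrame:
    """Prescription-by-herb matrix: presence/absence (default) or dose-weighted."""
    herbs = sorted({h for p in prescriptions for h in p.herb_set})
    idx = [p.study_id for p in prescriptions]
    mat = np.zeros((len(prescriptions), len(herbs)))
    col = {h: j for j, h in enumerate(herbs)}
    for i, p in enumerate(prescriptions):
        for h, d in p.herbs:
            mat[i, col[h]] = (d if d is not None else 1.0) if weighted else 1.0
    return pd.DataFrame(mat, index=idx, columns=herbs)
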