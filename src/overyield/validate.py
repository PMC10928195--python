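"""Validation of canonical input CSVs against the inclusion criteria.

Three study-design requirements are enforced as row/plot-level rules:
species-level biomass must be present; the study must contain
monoculture plots (the partition has no reference without them); and
first-year observations are excluded (communities need one season to
establish before mixture yields are comparable).  Sown proportions must
sum to one within each plot-year.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import schema as S

__all__ = ["ValidationReport", "validate_dataset"]

_NUMERIC = [S.YEAR, S.HARVEST, S.BIOMASS, S.SOWN, S.SOWN_PROP, S.N_RATE, S.N_TREATMENT]


@dataclass
class ValidationReport:
    """Per-rule drop counts and the dropped-row ledger."""

    rows_in: int
    rows_kept: int
    dropped: pd.DataFrame  # row index, reason
    rule_counts: dict[str, int] = field(default_factory=dict)

    @property
    def rows_dropped(self) -> int:
        return len(self.dropped)

    def summary(self) -> str:
        lines = [f"rows in: {self.rows_in}, kept: {self.rows_kept}, "
                 f"dropped: {self.rows_dropped}"]
        for rule, n in sorted(self.rule_counts.items()):
            lines.append(f"  {rule}: {n}")
        return "\n".join(lines)


def validate_dataset(df: pd.DataFrame) -> tuple[pd.DataFrame, ValidationReport]:
    """Validate and clean a canonical species-yield table.

    Returns the clean table and a report whose ledger accounts for every
    dropped row (rows_in = rows_kept + rows_dropped).  A missing required
    column is a hard error; everything else drops rows with a reason.
    """
    missing = [c for c in S.CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    df = df.copy()
    rows_in = len(df)
    reasons: dict[int, str] = {}

    def drop(mask: pd.Series, reason: str) -> None:
        for idx in df.index[mask]:
            reasons.setdefault(idx, reason)

    for col in _NUMERIC:
        coerced = pd.to_numeric(df[col], errors="coerce")
        drop(coerced.isna() & df[col].notna(), "malformed_numeric")
        df[col] = coerced

    drop(df[S.BIOMASS].isna(), "biomass_missing")
    drop(df[S.BIOMASS] < 0, "negative_biomass")

    # establishment rule: the first experiment year is excluded
    drop(df[S.YEAR] <= 1, "first_year_excluded")

    # studies without any monoculture plot cannot be partitioned
    sown = df[df[S.SOWN] == 1]
    rich = sown.groupby([S.STUDY, S.PLOT, S.YEAR])[S.SPECIES].nunique()
    studies_with_mono = set(rich[rich == 1].index.get_level_values(0))
    drop(~df[S.STUDY].isin(studies_with_mono), "no_monocultures_in_study")

    # sown proportions must sum to 1 within each plot-year
    prop_sum = sown.groupby([S.STUDY, S.PLOT, S.YEAR])[S.SOWN_PROP].sum()
    bad_keys = set(prop_sum[(prop_sum - 1.0).abs() > 1e-6].index)
    key = list(zip(df[S.STUDY], df[S.PLOT], df[S.YEAR]))
    drop(pd.Series([k in bad_keys for k in key], index=df.index),
         "proportions_not_normalized")

    dropped_idx = list(reasons)
    dropped = pd.DataFrame(
        {"row": dropped_idx, "reason": [reasons[i] for i in dropped_idx]}
    )
    clean = df.drop(index=dropped_idx).reset_index(drop=True)
    counts: dict[str, int] = {}
    for r in reasons.values():
        counts[r] = counts.get(r, 0) + 1
    report = ValidationReport(
        rows_in=rows_in,
        rows_kept=len(clean),
        dropped=dropped,
        rule_counts=counts,
    )
    return clean, report
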