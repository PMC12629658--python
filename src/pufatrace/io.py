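"""Reading and writing the long-format measurement and result tables.

The interchange format is UTF-8 CSV with one row per (bird, fatty acid):

    bird_id,species,treatment,fatty_acid,delta13c,pct_fame

Headers are matched case-insensitively and a config-supplied column mapping
can rename arbitrary source headers onto this schema, so spreadsheet
exports flatten straight in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .fatty_acids import parse_fatty_acid
from .isotope import R_VPDB, IsotopeConstants
from .pathways import ConversionProfile, FameMeasurement, Treatment

logger = logging.getLogger(__name__)

COLUMNS = ["bird_id", "species", "treatment", "fatty_acid", "delta13c", "pct_fame"]
KNOWN_SPECIES = {"barn_swallow", "purple_martin"}

#: slack on the per-bird sum of compositional shares, absorbing rounding
PCT_FAME_SUM_TOL = 0.5


class TableError(ValueError):
    """A measurement table violated the schema or an invariant."""


def read_measurements(path: str | Path, column_map: dict[str, str] | None = None) -> list[FameMeasurement]:
    """Read and validate a long-format measurement CSV.

    ``column_map`` renames source headers (matched case-insensitively) onto
    the canonical schema, e.g. ``{"d13C": "delta13c"}``.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise TableError(f"{path}: empty file, expected header {','.join(COLUMNS)}") from None
    rename = {k.lower(): v for k, v in (column_map or {}).items()}
    df.columns = [rename.get(str(c).strip().lower(), str(c).strip().lower()) for c in df.columns]
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise TableError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")

    measurements = []
    seen: dict[tuple[str, str], int] = {}
    for idx, row in df.iterrows():
        rowno = idx + 2  # header is line 1
        try:
            fa = parse_fatty_acid(str(row["fatty_acid"]))
            treatment = Treatment(str(row["treatment"]).strip())
            m = FameMeasurement(
                bird_id=str(row["bird_id"]).strip(),
                species=str(row["species"]).strip(),
                treatment=treatment,
                fatty_acid=fa,
                delta13c=float(row["delta13c"]),
                pct_fame=float(row["pct_fame"]),
            )
        except (ValueError, KeyError) as err:
            raise TableError(f"{path}:{rowno}: {err}") from None
        key = (m.bird_id, m.fatty_acid.shorthand)
        if key in seen:
            raise TableError(
                f"{path}:{rowno}: duplicate (bird, fatty acid) {key}, first seen on line {seen[key]}"
            )
        seen[key] = rowno
        if m.species not in KNOWN_SPECIES:
            logger.warning("%s:%d: unrecognised species %r (processed anyway)", path, rowno, m.species)
        measurements.append(m)

    totals = pd.Series([m.pct_fame for m in measurements]).groupby(
        pd.Series([m.bird_id for m in measurements])
    ).sum()
    over = totals[totals > 100.0 + PCT_FAME_SUM_TOL]
    if not over.empty:
        raise TableError(
            f"{path}: pct_fame sums exceed 100 for bird(s) {dict(over.round(2))}"
        )
    logger.info("%s: read %d rows, %d birds", path, len(measurements), totals.size)
    return measurements


def write_measurements(measurements: list[FameMeasurement], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (m.bird_id, m.species, m.treatment.value, m.fatty_acid.shorthand, m.delta13c, m.pct_fame)
            for m in measurements
        ],
        columns=COLUMNS,
    )
    df.to_csv(path, index=False, float_format="%.10g")


def profiles_to_frame(profiles: list[ConversionProfile]) -> pd.DataFrame:
    """Long-format per-bird CE table (one row per bird × pathway member)."""
    rows = []
    for p in profiles:
        for fa in p.pathway.members:
            rows.append(
                (
                    p.bird_id, p.species, p.pathway.name, fa.shorthand,
                    fa != p.pathway.precursor, p.per_product_ce[fa], p.total_ce, p.corrected,
                )
            )
    return pd.DataFrame(
        rows,
        columns=["bird_id", "species", "pathway", "fatty_acid", "is_product",
                 "ce_percent", "total_ce_percent", "corrected"],
    )


@dataclass(frozen=True)
class RunConfig:
    """Analysis settings shared by the command-line entry points."""

    r_standard: float = R_VPDB
    delta_meoh: float | None = None
    corrected: bool = False
    negative_ape: str = "keep"
    seed: int = 0
    column_map: dict[str, str] = field(default_factory=dict)

    @property
    def constants(self) -> IsotopeConstants:
        return IsotopeConstants(r_standard=self.r_standard, delta_meoh=self.delta_meoh)

    def log_provenance(self) -> None:
        logger.info(
            "run settings: R_standard=%.7f, methylation correction=%s, delta_MeOH=%s, "
            "negative-APE policy=%s, seed=%d",
            self.r_standard, self.corrected, self.delta_meoh, self.negative_ape, self.seed,
        )


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML config file; absent path yields defaults."""
    if path is None:
        return RunConfig()
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise TableError(f"{path}: unknown config key(s) {sorted(unknown)}; known: {sorted(known)}")
    return RunConfig(**raw)
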