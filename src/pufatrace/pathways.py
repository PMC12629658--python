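"""Label-pool bookkeeping and conversion efficiencies along PUFA pathways.

A dosed bird receives a uniformly ¹³C-labelled precursor (ALA for the
omega-3 chain, LA for omega-6).  Forty-eight hours later, every fatty acid
downstream of the precursor that the bird elongated/desaturated carries part
of the label.  For fatty acid *i* the tracer-attributable pool is

    total_label_i = %FAME_i × APE_i

(%FAME the compositional share of the acid, APE its atom-percent excess over
an undosed control bird of the same species).  The conversion efficiency
into product *i* is that pool as a share of all labelled pools in the
pathway:

    CE_i = total_label_i / Σ_pathway total_label × 100 .

CE over all pathway members (precursor included) sums to 100 whenever all
pools are non-negative; the pathway total CE is the sum over the
non-precursor members, i.e. the fraction of absorbed label the bird moved
beyond the precursor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .fatty_acids import ALA, ARA, DGLA, DHA, DPA, EPA, LA, FattyAcidId
from .isotope import (
    DEFAULT_CONSTANTS,
    IsotopeConstants,
    atom_percent_excess,
    correct_methylation,
    delta_to_atom_percent,
)

logger = logging.getLogger(__name__)


class Treatment(str, Enum):
    CONTROL = "control"
    LABELLED_ALA = "labelled_ALA"
    LABELLED_LA = "labelled_LA"


@dataclass(frozen=True)
class FameMeasurement:
    """One (bird, fatty acid) observation: δ¹³C and compositional share."""

    bird_id: str
    species: str
    treatment: Treatment
    fatty_acid: FattyAcidId
    delta13c: float  # permil vs VPDB
    pct_fame: float  # percent of total FAME identified

    def __post_init__(self) -> None:
        if not -1000.0 < self.delta13c:
            raise ValueError(f"bird {self.bird_id} {self.fatty_acid}: delta13C must be > -1000 permil")
        if not 0.0 <= self.pct_fame <= 100.0:
            raise ValueError(
                f"bird {self.bird_id} {self.fatty_acid}: pct_fame {self.pct_fame} outside [0, 100]"
            )


@dataclass(frozen=True)
class Pathway:
    """Ordered precursor-to-products chain; ``members[0]`` is the precursor."""

    name: str
    members: tuple[FattyAcidId, ...]

    @property
    def precursor(self) -> FattyAcidId:
        return self.members[0]

    @property
    def products(self) -> tuple[FattyAcidId, ...]:
        return self.members[1:]


OMEGA3 = Pathway("omega3", (ALA, EPA, DPA, DHA))
OMEGA6 = Pathway("omega6", (LA, DGLA, ARA))
PATHWAYS = {"omega3": OMEGA3, "omega6": OMEGA6}

#: which pathway each labelling treatment traces
PATHWAY_FOR_TREATMENT = {Treatment.LABELLED_ALA: OMEGA3, Treatment.LABELLED_LA: OMEGA6}


@dataclass(frozen=True)
class LabelPool:
    fatty_acid: FattyAcidId
    ape: float        # percentage points
    pct_fame: float   # percent
    total_label: float = field(init=False)  # percent x percentage points

    def __post_init__(self) -> None:
        object.__setattr__(self, "total_label", self.pct_fame * self.ape)


@dataclass(frozen=True)
class ConversionProfile:
    """Per-bird outcome: label pools and CE along one pathway."""

    bird_id: str
    species: str
    pathway: Pathway
    pools: tuple[LabelPool, ...]
    per_product_ce: dict[FattyAcidId, float]  # includes the precursor's retained share
    total_ce: float
    corrected: bool


class UndefinedConversionError(ValueError):
    """The pathway label sum is not positive, so CE is undefined."""


def total_label(pct_fame: float, ape: float) -> float:
    """Tracer pool size of one fatty acid: %FAME × APE."""
    if pct_fame < 0:
        raise ValueError("pct_fame must be non-negative")
    return pct_fame * ape


def conversion_efficiency(pool_product: LabelPool, all_pools: list[LabelPool]) -> float:
    """CE of one product: its pool over the summed pathway pools, ×100."""
    if not any(p.fatty_acid == pool_product.fatty_acid for p in all_pools):
        raise ValueError(f"{pool_product.fatty_acid} is not among the pathway pools")
    denom = sum(p.total_label for p in all_pools)
    if denom <= 0:
        raise UndefinedConversionError(
            f"pathway label sum {denom:g} is not positive; conversion efficiency undefined"
        )
    return pool_product.total_label / denom * 100.0


def control_reference(
    controls: list[FameMeasurement],
    constants: IsotopeConstants = DEFAULT_CONSTANTS,
    corrected: bool = False,
) -> dict[FattyAcidId, float]:
    """Per-FA baseline atom percent from one or more control birds.

    A single control bird per species is the typical tracer-study design;
    with several, their atom percents are averaged per fatty acid.
    """
    by_fa: dict[FattyAcidId, list[float]] = {}
    for m in controls:
        delta = m.delta13c
        if corrected:
            delta = correct_methylation(delta, constants, m.fatty_acid)
        by_fa.setdefault(m.fatty_acid, []).append(delta_to_atom_percent(delta, constants))
    return {fa: float(np.mean(v)) for fa, v in by_fa.items()}


def bird_profile(
    labelled_bird: list[FameMeasurement],
    control_ap: dict[FattyAcidId, float],
    pathway: Pathway,
    constants: IsotopeConstants = DEFAULT_CONSTANTS,
    corrected: bool = False,
    negative_ape: str = "keep",
) -> ConversionProfile:
    """Full per-bird accounting: δ¹³C + %FAME → label pools → CE.

    Parameters
    ----------
    labelled_bird:
        All measurements of one tracer-dosed bird (pathway members are
        selected from them; the precursor must be present).
    control_ap:
        Baseline atom percent per fatty acid from the undosed control(s),
        computed on the same corrected/uncorrected basis
        (see :func:`control_reference`).
    corrected:
        Apply the methyl-carbon correction to the measured deltas before
        converting to atom percent.
    negative_ape:
        ``"keep"`` retains negative excesses (logged); ``"floor"`` clamps
        them to zero before pooling.
    """
    if negative_ape not in ("keep", "floor"):
        raise ValueError(f"negative_ape must be 'keep' or 'floor', got {negative_ape!r}")
    by_fa = {m.fatty_acid: m for m in labelled_bird}
    if pathway.precursor not in by_fa:
        raise ValueError(
            f"bird {labelled_bird[0].bird_id if labelled_bird else '?'}: no measurement "
            f"for the {pathway.name} precursor {pathway.precursor}"
        )
    bird_id = by_fa[pathway.precursor].bird_id
    species = by_fa[pathway.precursor].species

    pools: list[LabelPool] = []
    for fa in pathway.members:
        m = by_fa.get(fa)
        if m is None:
            logger.warning("bird %s: no measurement for %s; it contributes zero label", bird_id, fa)
            pools.append(LabelPool(fa, 0.0, 0.0))
            continue
        if fa not in control_ap:
            raise ValueError(f"bird {bird_id}: missing control baseline for measured {fa}")
        delta = m.delta13c
        if corrected:
            delta = correct_methylation(delta, constants, fa)
        ape = atom_percent_excess(delta_to_atom_percent(delta, constants), control_ap[fa])
        if ape < 0:
            if negative_ape == "floor":
                logger.warning("bird %s %s: negative APE %.4g floored to 0", bird_id, fa, ape)
                ape = 0.0
            else:
                logger.warning(
                    "bird %s %s: negative APE %.4g retained (likely instrument noise)",
                    bird_id, fa, ape,
                )
        pools.append(LabelPool(fa, float(ape), m.pct_fame))

    ce = {p.fatty_acid: conversion_efficiency(p, pools) for p in pools}
    total = float(sum(ce[fa] for fa in pathway.products))
    return ConversionProfile(bird_id, species, pathway, tuple(pools), ce, total, corrected)


def pathway_total(profile: ConversionProfile) -> float:
    """Cumulative pathway CE: summed CE of all non-precursor members."""
    return float(sum(profile.per_product_ce[fa] for fa in profile.pathway.products))


def profiles_from_measurements(
    measurements: list[FameMeasurement],
    constants: IsotopeConstants = DEFAULT_CONSTANTS,
    corrected: bool = False,
    negative_ape: str = "keep",
) -> list[ConversionProfile]:
    """Profile every tracer-dosed bird in a measurement table.

    Control birds of each species provide the baseline atom percents; each
    labelled bird is accounted along the pathway its treatment traces.
    Birds whose pathway label sum is not positive are excluded with a log
    record rather than aborting the batch.
    """
    controls_by_species: dict[str, list[FameMeasurement]] = {}
    birds: dict[str, list[FameMeasurement]] = {}
    for m in measurements:
        if m.treatment is Treatment.CONTROL:
            controls_by_species.setdefault(m.species, []).append(m)
        else:
            birds.setdefault(m.bird_id, []).append(m)

    refs = {
        sp: control_reference(ms, constants, corrected)
        for sp, ms in controls_by_species.items()
    }
    profiles = []
    for bird_id, ms in birds.items():
        species = ms[0].species
        if species not in refs:
            raise ValueError(f"bird {bird_id}: missing control bird for species {species!r}")
        pathway = PATHWAY_FOR_TREATMENT[ms[0].treatment]
        try:
            profiles.append(
                bird_profile(ms, refs[species], pathway, constants, corrected, negative_ape)
            )
        except UndefinedConversionError as err:
            logger.warning("bird %s excluded: %s", bird_id, err)
    return profiles


@dataclass(frozen=True)
class CellSummary:
    """(species × pathway) group summary of total CE: mean, sample SD, n."""

    species: str
    pathway: str
    mean: float
    sd: float
    n: int


def summarize_group(profiles: list[ConversionProfile]) -> list[CellSummary]:
    """Group profiles by (species, pathway) and summarize total CE.

    SD uses the n−1 denominator; singleton cells report sd = nan.
    """
    cells: dict[tuple[str, str], list[float]] = {}
    for p in profiles:
        cells.setdefault((p.species, p.pathway.name), []).append(p.total_ce)
    out = []
    for (species, pathway), vals in sorted(cells.items()):
        arr = np.asarray(vals, dtype=float)
        sd = float(np.std(arr, ddof=1)) if arr.size > 1 else float("nan")
        out.append(CellSummary(species, pathway, float(arr.mean()), sd, int(arr.size)))
    return out
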