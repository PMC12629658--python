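"""Scalar isotope arithmetic for compound-specific ¹³C measurements.

Converts between the three equivalent expressions of ¹³C content used in
tracer studies:

* **delta notation** δ¹³C = (R_sample/R_standard − 1) × 1000, in ‰ vs VPDB;
* the **isotope ratio** R = ¹³C/¹²C;
* **atom percent** AP = 100 · R/(1 + R), the percentage of carbon atoms
  that are ¹³C (F = R/(1+R) is the fractional abundance).

Atom percent excess (APE) — AP of a tracer-dosed sample minus AP of an
undosed control — isolates the tracer-attributable enrichment.

Also provides the methyl-ester derivatization correction: transesterification
adds one methanol-derived carbon to an n-carbon fatty acid, so the measured
FAME delta is an (n : 1) carbon-weighted mix of the acid and the methanol,

    δ_FAME = (n·δ_FA + δ_MeOH) / (n + 1),

which :func:`correct_methylation` inverts to recover the acid-only value.

All ‰ quantities are carried as-is (never pre-divided by 1000) and atom
percent on the 0–100 scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fatty_acids import FattyAcidId

#: ¹³C/¹²C of Vienna Pee Dee Belemnite as bound to the atom-percent
#: equations in the tracer-accounting literature.  An alternative VPDB
#: value of 0.0111802 circulates in the CSIA methods literature; the two
#: differ by ~0.5% relative and either can be configured.
R_VPDB = 0.0112372
R_VPDB_ALT = 0.0111802


@dataclass(frozen=True)
class IsotopeConstants:
    """Run-level isotope constants.

    Parameters
    ----------
    r_standard:
        ¹³C/¹²C ratio of the delta-scale reference (VPDB).  Default
        0.0112372; 0.0111802 is the common alternative.
    delta_meoh:
        δ¹³C (‰ vs VPDB) of the derivatization methanol.  Instrument- and
        batch-specific, so there is no universal default; it must be
        supplied before the methylation correction can be applied.
    """

    r_standard: float = R_VPDB
    delta_meoh: float | None = None

    def __post_init__(self) -> None:
        if not self.r_standard > 0:
            raise ValueError(f"r_standard must be positive, got {self.r_standard}")


DEFAULT_CONSTANTS = IsotopeConstants()


def delta_to_ratio(delta, constants: IsotopeConstants = DEFAULT_CONSTANTS):
    """Invert delta notation: R = R_standard · (δ/1000 + 1).

    Accepts scalars or arrays.  δ must exceed −1000‰ (the ratio must stay
    positive).
    """
    delta = np.asarray(delta, dtype=float)
    if np.any(delta <= -1000.0):
        raise ValueError("delta13C must be > -1000 permil (isotope ratio must stay positive)")
    out = constants.r_standard * (delta / 1000.0 + 1.0)
    return out if out.ndim else float(out)


def ratio_to_delta(ratio, constants: IsotopeConstants = DEFAULT_CONSTANTS):
    """Forward delta notation: δ = (R/R_standard − 1) × 1000."""
    ratio = np.asarray(ratio, dtype=float)
    if np.any(ratio <= 0):
        raise ValueError("isotope ratio must be positive")
    out = (ratio / constants.r_standard - 1.0) * 1000.0
    return out if out.ndim else float(out)


def ratio_to_atom_percent(ratio):
    """AP = 100 · R/(1 + R); strictly increasing, bounded in [0, 100)."""
    ratio = np.asarray(ratio, dtype=float)
    if np.any(ratio < 0):
        raise ValueError("isotope ratio must be non-negative")
    out = 100.0 * ratio / (1.0 + ratio)
    return out if out.ndim else float(out)


def atom_percent_to_ratio(ap):
    """Invert AP: R = F/(1 − F) with F = AP/100."""
    ap = np.asarray(ap, dtype=float)
    if np.any((ap < 0) | (ap >= 100)):
        raise ValueError("atom percent must lie in [0, 100)")
    f = ap / 100.0
    out = f / (1.0 - f)
    return out if out.ndim else float(out)


def delta_to_atom_percent(delta, constants: IsotopeConstants = DEFAULT_CONSTANTS):
    """δ¹³C (‰) → atom percent, composing the two conversions."""
    return ratio_to_atom_percent(delta_to_ratio(delta, constants))


def atom_percent_to_delta(ap, constants: IsotopeConstants = DEFAULT_CONSTANTS):
    """Atom percent → δ¹³C (‰); exact inverse of :func:`delta_to_atom_percent`."""
    return ratio_to_delta(atom_percent_to_ratio(ap), constants)


def atom_percent_excess(ap_labelled, ap_control):
    """APE = AP_labelled − AP_control, in percentage points.

    Antisymmetric; may be negative when a product pool in a dosed bird is
    measured less enriched than the control (instrument noise) — callers
    decide whether to retain or floor such values.
    """
    return np.asarray(ap_labelled, dtype=float) - np.asarray(ap_control, dtype=float)


def fame_delta_from_fa(delta_fa, delta_meoh: float, fa: FattyAcidId):
    """Forward mixing relation: δ_FAME = (n·δ_FA + δ_MeOH)/(n + 1)."""
    n = fa.n_carbons
    return (n * np.asarray(delta_fa, dtype=float) + delta_meoh) / (n + 1)


def correct_methylation(delta_fame, constants: IsotopeConstants, fa: FattyAcidId):
    """Remove the methyl-group carbon: δ_FA = ((n+1)·δ_FAME − δ_MeOH)/n.

    Exact inverse of :func:`fame_delta_from_fa`.  Requires
    ``constants.delta_meoh``; raises a configuration error when it is
    missing, since the methanol delta is batch-specific and must be
    measured.
    """
    if constants.delta_meoh is None:
        raise ValueError(
            "the methylation correction needs the delta13C of the derivatization "
            "methanol; measure it for your reagent batch and supply it as "
            "IsotopeConstants(delta_meoh=...)"
        )
    n = fa.n_carbons
    out = ((n + 1) * np.asarray(delta_fame, dtype=float) - constants.delta_meoh) / n
    return out if out.ndim else float(out)
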