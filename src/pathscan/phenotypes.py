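"""Phenotype derivations: BMI, hypertension status, medication adjustment,
and X-chromosome dosage coding."""

from __future__ import annotations

import numpy as np

MED_ADJUST_SBP = 15.0
MED_ADJUST_DBP = 10.0
SBP_CUTOFF = 140.0
DBP_CUTOFF = 90.0


def compute_bmi(weight_kg, height_m):
    """BMI = weight / height**2 (kg/m^2).  Vectorized; height must be > 0."""
    height = np.asarray(height_m, dtype=float)
    if np.any(height <= 0):
        raise ValueError("height must be positive")
    out = np.asarray(weight_kg, dtype=float) / height**2
    return float(out) if out.ndim == 0 else out


def classify_hypertension(sbp, dbp, on_med):
    """True iff SBP >= 140 mmHg, DBP >= 90 mmHg, or on antihypertensive
    medication."""
    out = (np.asarray(sbp, float) >= SBP_CUTOFF) \
        | (np.asarray(dbp, float) >= DBP_CUTOFF) \
        | np.asarray(on_med, bool)
    return bool(out) if out.ndim == 0 else out


def adjust_bp_for_medication(sbp, dbp, on_med):
    """Add +15 mmHg SBP / +10 mmHg DBP for treated individuals.

    Used only when BP is analyzed as a continuous trait; never feeds the
    hypertension classification.
    """
    med = np.asarray(on_med, bool)
    sbp_adj = np.asarray(sbp, float) + np.where(med, MED_ADJUST_SBP, 0.0)
    dbp_adj = np.asarray(dbp, float) + np.where(med, MED_ADJUST_DBP, 0.0)
    if sbp_adj.ndim == 0:
        return float(sbp_adj), float(dbp_adj)
    return sbp_adj, dbp_adj


def code_x_genotype(male, raw):
    """X-chromosome additive coding.

    Males are hemizygous: 0 for the major allele, 1 for the minor allele;
    a heterozygous male call (raw dosage 1 from a diploid-coded source) is
    biologically invalid and coded missing.  Females keep autosomal 0/1/2.
    """
    male = np.asarray(male, bool)
    raw_arr = np.asarray(raw, float)
    out = raw_arr.copy()
    if out.ndim == 0:
        if male:
            if raw_arr == 2:
                return 1.0
            if raw_arr == 1:
                return float("nan")
        return float(out)
    out[male & (raw_arr == 2)] = 1.0
    out[male & (raw_arr == 1)] = np.nan
    return out


__all__ = [
    "compute_bmi", "classify_hypertension", "adjust_bp_for_medication",
    "code_x_genotype", "MED_ADJUST_SBP", "MED_ADJUST_DBP",
]
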