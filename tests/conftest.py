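import numpy as np
import pandas as pd
import pytest

from pathscan.cohort.types import GenotypeMatrix, make_variant_table, new_sample_table


def build_matrix(dosages, chroms=None, male=None, positions=None):
    """GenotypeMatrix from a plain nested list / array (NaN = missing)."""
    d = np.asarray(dosages, dtype=float)
    n, m = d.shape
    chroms = chroms or ["1"] * m
    positions = positions or [100 * (j + 1) for j in range(m)]
    variants = make_variant_table([
        {"id": f"s{j + 1}", "chrom": str(chroms[j]), "pos": positions[j],
         "minor_allele": "A", "major_allele": "G"}
        for j in range(m)
    ])
    return GenotypeMatrix(
        dosages=d,
        sample_ids=np.array([f"i{k + 1}" for k in range(n)], dtype=object),
        variants=variants,
        male=None if male is None else np.asarray(male, bool),
    )


def build_samples(n=None, htn=None, sbp=None, dbp=None, on_med=None, sex=None,
                  age=None, bmi=None, ids=None):
    """SampleTable with sensible defaults for association tests."""
    if n is None:
        n = len(htn) if htn is not None else len(sbp)
    ids = ids if ids is not None else [f"i{k + 1}" for k in range(n)]
    s = new_sample_table(ids)
    s["sex"] = sex if sex is not None else "female"
    s["age"] = age if age is not None else 50.0
    s["bmi"] = bmi if bmi is not None else 24.0
    s["weight_kg"] = 64.0
    s["height_m"] = 1.64
    s["on_med"] = on_med if on_med is not None else False
    s["sbp_raw"] = sbp if sbp is not None else 120.0
    s["dbp_raw"] = dbp if dbp is not None else 75.0
    s["sbp_adj"] = s["sbp_raw"] + np.where(s["on_med"].astype(bool), 15.0, 0.0)
    s["dbp_adj"] = s["dbp_raw"] + np.where(s["on_med"].astype(bool), 10.0, 0.0)
    s["hypertensive"] = htn if htn is not None else False
    s["phenotyped"] = True
    return s


@pytest.fixture(scope="session")
def small_null_cohort():
    """Null simulated cohort reused by read-only tests."""
    from pathscan.simulate import SimulationSpec, simulate_cohort
    spec = SimulationSpec(seed=421, n_samples=300,
                          pathways=[("A", 2, 8), ("B", 2, 8)],
                          missing_rate=0.02)
    return simulate_cohort(spec)
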