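"""Study design of the three MASLD stool-metagenome cohorts.

The analysis compares two phenotypic groups per cohort (control vs.
disease) across 554 fecal metagenomes drawn from five public shotgun
studies.  Cohort 1 contrasts healthy controls with biopsy-confirmed
early-stage fibrosis (F0-F2); Cohort 2 contains only MASLD patients and
contrasts early-stage with advanced fibrosis (F3-F4), the early-stage
group serving as the within-disease "control"; Cohort 3 contrasts
healthy controls with MASLD-related cirrhosis.

The table below is the published per-group sample bookkeeping and is
used both as the default synthetic cohort design and for totals checks.
Note that in Cohort 1 the 48-sample contribution comes from only 10
patients, so patient and sample counts differ for that row.
"""

from __future__ import annotations

import pandas as pd

#: One row per (cohort, phenotypic group, source study).  ``role`` marks
#: which side of each cohort's two-group comparison a sample belongs to.
COHORT_DESIGN_ROWS = [
    # cohort, group label, role, n_samples, n_patients, accession
    ("cohort1", "healthy control", "control", 117, 117, "PRJNA544527"),
    ("cohort1", "MASLD early-stage fibrosis (F0-F2)", "disease", 73, 73, "PRJEB14215"),
    ("cohort1", "MASLD early-stage fibrosis (F0-F2)", "disease", 48, 10, "PRJNA420817"),
    ("cohort2", "MASLD early-stage fibrosis (F0-F2)", "control", 72, 72, "PRJNA373901"),
    ("cohort2", "MASLD advanced fibrosis (F3-F4)", "disease", 14, 14, "PRJNA373901"),
    ("cohort3", "healthy control", "control", 105, 105, "PRJEB6337"),
    ("cohort3", "MASLD-related cirrhosis", "disease", 125, 125, "PRJEB6337"),
]


def cohort_design() -> pd.DataFrame:
    """Return the study-design table as a DataFrame.

    Columns: ``cohort``, ``group``, ``role`` (control/disease),
    ``n_samples``, ``n_patients``, ``accession``.
    """
    return pd.DataFrame(
        COHORT_DESIGN_ROWS,
        columns=["cohort", "group", "role", "n_samples", "n_patients", "accession"],
    )


def total_samples(design: pd.DataFrame | None = None) -> int:
    """Total number of metagenomic samples across all cohorts and groups."""
    d = cohort_design() if design is None else design
    return int(d["n_samples"].sum())


def cohort_patients(cohort: str, role: str | None = None,
                    design: pd.DataFrame | None = None) -> int:
    """Number of distinct patients in a cohort (optionally one role).

    For Cohort 1 the disease patient count (83) is smaller than the
    disease sample count (121) because one source study contributed 48
    samples from 10 patients.
    """
    d = cohort_design() if design is None else design
    mask = d["cohort"] == cohort
    if role is not None:
        mask &= d["role"] == role
    return int(d.loc[mask, "n_patients"].sum())


def cohort_samples(cohort: str, design: pd.DataFrame | None = None) -> int:
    """Number of metagenomic samples in a cohort (both groups)."""
    d = cohort_design() if design is None else design
    return int(d.loc[d["cohort"] == cohort, "n_samples"].sum())


def two_group_design(design: pd.DataFrame | None = None) -> list[tuple[str, str, str, int]]:
    """Collapse the design to (cohort, group, role, n_samples) tuples.

    Rows of the same cohort/group/role (split across source studies) are
    merged, giving the per-comparison sample sizes used by the synthetic
    generator: 117/121, 72/14 and 105/125.
    """
    d = cohort_design() if design is None else design
    g = (
        d.groupby(["cohort", "group", "role"], sort=False)["n_samples"]
        .sum()
        .reset_index()
    )
    return list(g.itertuples(index=False, name=None))
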