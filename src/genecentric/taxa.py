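"""Post-processing of merged taxonomic relative-abundance tables.

Tables are MetaPhlAn-style: one clade-lineage row (``k__...|g__Name`` or
``...|s__Name``) per taxon, one column per sample, values in percent.
Cleaning removes "unclassified" rows and clades with zero mean abundance
across all samples of any cohort, unless the clade is present in
exactly one comparison group of some cohort (group-exclusive retention,
which preserves potentially very clear markers).  Abundance thresholds
then keep genera with mean > 0.5% and species with mean > 0.2% within a
cohort, and the shared-clade computation intersects the surviving clade
names across cohorts.
"""

from __future__ import annotations

import pandas as pd


def clade_rank(lineage: str) -> str:
    """Rank of the terminal lineage element ('genus', 'species', ...)."""
    last = lineage.split("|")[-1]
    prefix = last[:3]
    return {"g__": "genus", "s__": "species", "f__": "family", "o__": "order",
            "c__": "class", "p__": "phylum", "k__": "kingdom",
            "t__": "strain"}.get(prefix, "unknown")


def clade_name(lineage: str) -> str:
    """Terminal clade name with any rank prefix stripped."""
    last = lineage.split("|")[-1]
    return last[3:] if len(last) > 3 and last[1:3] == "__" else last


def _check_metadata(table: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    meta = samples.set_index("sample_id")
    missing = [c for c in table.columns if c not in meta.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing}")
    return meta.loc[list(table.columns)]


def clean_clades(table: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Drop unclassified rows and zero-mean-per-cohort clades.

    A clade is removed if its terminal name is "unclassified"
    (case-insensitive, any rank prefix) or if its mean abundance is zero
    across all samples of at least one cohort — unless it is nonzero in
    exactly one of the two comparison groups of some cohort, in which
    case it is retained as a potential group-exclusive marker.
    """
    meta = _check_metadata(table, samples)
    keep = []
    for lineage, row in table.iterrows():
        if clade_name(str(lineage)).lower() == "unclassified":
            continue
        zero_in_some_cohort = False
        exclusive_somewhere = False
        for cohort, cols in meta.groupby("cohort").groups.items():
            vals = row[list(cols)]
            if (vals == 0).all():
                zero_in_some_cohort = True
            roles = meta.loc[list(cols), "role"]
            present_roles = {
                role for role in roles.unique()
                if (vals[roles[roles == role].index] > 0).any()
            }
            if len(present_roles) == 1:
                exclusive_somewhere = True
        if zero_in_some_cohort and not exclusive_somewhere:
            continue
        keep.append(lineage)
    return table.loc[keep]


def abundance_threshold_filter(
    table: pd.DataFrame,
    genus_min: float = 0.5,
    species_min: float = 0.2,
) -> pd.DataFrame:
    """Keep rows above the rank-specific mean-abundance threshold.

    Means are unweighted over all columns of the table (one cohort's
    samples, both groups pooled); comparisons are strict, so a genus at
    exactly 0.5% is dropped.  Rows of a rank other than genus or species
    raise.
    """
    keep = []
    means = table.mean(axis=1)
    for lineage in table.index:
        rank = clade_rank(str(lineage))
        if rank == "genus":
            cutoff = genus_min
        elif rank == "species":
            cutoff = species_min
        else:
            raise ValueError(f"unsupported rank {rank!r} for {lineage!r}")
        if means[lineage] > cutoff:
            keep.append(lineage)
    return table.loc[keep]


def split_by_cohort(table: pd.DataFrame,
                    samples: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-cohort column subsets of a merged table."""
    meta = _check_metadata(table, samples)
    return {
        cohort: table[list(cols)]
        for cohort, cols in meta.groupby("cohort").groups.items()
    }


def shared_clades(
    per_cohort: dict[str, pd.DataFrame],
) -> tuple[set[str], pd.Series]:
    """Clades surviving in every cohort, and their summed abundance share.

    Returns the intersection of (prefix-stripped) clade names across the
    per-cohort tables, plus a per-cohort Series giving the mean total
    relative abundance carried by the shared set.
    """
    if len(per_cohort) < 2:
        raise ValueError("need at least two cohorts")
    name_sets = {
        cohort: {clade_name(str(i)) for i in tbl.index}
        for cohort, tbl in per_cohort.items()
    }
    shared = set.intersection(*name_sets.values())
    totals = {}
    for cohort, tbl in per_cohort.items():
        rows = [i for i in tbl.index if clade_name(str(i)) in shared]
        totals[cohort] = float(tbl.loc[rows].sum(axis=0).mean()) if rows else 0.0
    return shared, pd.Series(totals, name="shared_abundance_pct")


def read_taxa_table(path) -> pd.DataFrame:
    """Read a merged clade x sample TSV (lineage in the first column)."""
    return pd.read_csv(path, sep="\t", index_col=0)
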