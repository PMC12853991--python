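"""Read counting and RPKSM normalization for gene families.

Per-sample protein-alignment tables (the standard 12-column tabular
dialect) are reduced to one best hit per read (E-value < 1e-10, lowest
E-value, ties broken by bit score then gene id), each retained read
increments exactly one family, and raw counts are normalized to RPKSM —
reads per kilobase per family size per million reads:

    RPKSM = count / ( Lbar_kb * S * library_size / 1e6 )

where ``Lbar_kb`` is the family's mean member gene length in kilobases
(nucleotide basis; amino-acid lengths are converted x3) and S the
number of member genes.  The normalization makes abundances comparable
across families of different sizes and lengths, and across libraries of
different depths.  A ``total_length`` basis (summed member length, no S
term) is exposed as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

ALIGNMENT_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch",
                     "gapopen", "qstart", "qend", "sstart", "send",
                     "evalue", "bitscore"]

_NUMERIC = {"pident": float, "length": int, "mismatch": int, "gapopen": int,
            "qstart": int, "qend": int, "sstart": int, "send": int,
            "evalue": float, "bitscore": float}

UNASSIGNED = "unassigned"


def parse_alignment_table(path: str | Path) -> pd.DataFrame:
    """Parse a 12-column tabular alignment file.

    Returns a DataFrame with the standard column names; any row with a
    wrong column count or an unparsable field raises with its 1-based
    line number.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path.name}:{lineno}: expected 12 columns, got {len(fields)}")
            try:
                rows.append([
                    fields[0], fields[1],
                    *[_NUMERIC[c](fields[i]) for i, c in
                      enumerate(ALIGNMENT_COLUMNS[2:], start=2)],
                ])
            except ValueError as exc:
                raise ValueError(f"{path.name}:{lineno}: malformed field ({exc})")
    df = pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS)
    if (df["evalue"] < 0).any():
        bad = int(df.index[df["evalue"] < 0][0]) + 1
        raise ValueError(f"{path.name}: negative E-value near row {bad}")
    return df


def best_hit_filter(hits: pd.DataFrame, e_max: float = 1e-10) -> pd.DataFrame:
    """Keep exactly one hit per read.

    Hits with E-value >= ``e_max`` are discarded first (strict
    inequality, matching the E-value < 1e-10 contract); among a read's
    survivors the best is the lowest E-value, ties broken by highest
    bit score, then lexicographically smallest gene id.
    """
    passing = hits[hits["evalue"] < e_max]
    if passing.empty:
        return passing.copy()
    ordered = passing.sort_values(
        ["qseqid", "evalue", "bitscore", "sseqid"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    return ordered.drop_duplicates("qseqid", keep="first").reset_index(drop=True)


def gene_to_family_map(families: pd.DataFrame) -> pd.Series:
    """Map member gene id -> family id; a gene in two families is an error."""
    dup = families["member_id"].duplicated()
    if dup.any():
        raise ValueError(
            f"gene(s) assigned to multiple families: "
            f"{sorted(families.loc[dup, 'member_id'].unique())}")
    return families.set_index("member_id")["family_id"]


def assign_reads_to_families(best_hits: pd.DataFrame,
                             families: pd.DataFrame) -> pd.Series:
    """Count retained reads per family.

    Each read increments the family of its single best gene; reads whose
    best gene belongs to no family are counted under ``unassigned``.
    Returns a Series indexed by every family id (plus ``unassigned``),
    zero-filled.
    """
    if best_hits["qseqid"].duplicated().any():
        raise AssertionError("duplicate read ids after best-hit filtering")
    gmap = gene_to_family_map(families)
    assigned = best_hits["sseqid"].map(gmap).fillna(UNASSIGNED)
    counts = assigned.value_counts()
    index = pd.Index(list(pd.unique(families["family_id"])) + [UNASSIGNED],
                     name="family_id")
    return counts.reindex(index, fill_value=0).astype(int)


def compute_rpksm(count: float, mean_length_nt: float, s: int,
                  library_size: int, basis: str = "mean") -> float:
    """RPKSM for one (family, sample) cell.

    ``basis='mean'`` uses the mean member length in kb times S (the
    default, which charges family size exactly once); ``basis='total'``
    uses the summed member length in kb times S.
    """
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    if s < 1:
        raise ValueError("family size S must be >= 1")
    if mean_length_nt <= 0:
        raise ValueError("family mean length must be > 0")
    if basis == "mean":
        denom = (mean_length_nt / 1000.0) * s * (library_size / 1e6)
    elif basis == "total":
        denom = (mean_length_nt * s / 1000.0) * s * (library_size / 1e6)
    else:
        raise ValueError(f"unknown RPKSM basis {basis!r}")
    return count / denom


@dataclass
class AbundanceTable:
    """Family x sample raw counts and RPKSM values.

    ``counts`` and ``rpksm`` share index (family ids, plus the
    ``unassigned`` bucket in ``counts`` only) and columns (sample ids);
    ``library_sizes`` is per sample, ``family_meta`` carries S and mean
    member length per family.
    """

    counts: pd.DataFrame
    rpksm: pd.DataFrame
    library_sizes: pd.Series
    family_meta: pd.DataFrame   # index family_id; columns s, mean_length_nt

    def __post_init__(self) -> None:
        if (self.rpksm.to_numpy() < 0).any() or (self.counts.to_numpy() < 0).any():
            raise ValueError("abundance values must be nonnegative")

    def write(self, outdir: str | Path, prefix: str = "abundance") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.counts.to_csv(outdir / f"{prefix}_counts.tsv", sep="\t")
        self.rpksm.to_csv(outdir / f"{prefix}_rpksm.tsv", sep="\t")


def build_abundance_table(
    hit_tables: dict[str, pd.DataFrame | str | Path],
    families: pd.DataFrame,
    samples: pd.DataFrame,
    e_max: float = 1e-10,
    basis: str = "mean",
) -> AbundanceTable:
    """End-to-end: per-sample hits -> best hits -> counts -> RPKSM.

    ``hit_tables`` maps sample_id to a parsed DataFrame or a file path;
    ``samples`` is the sample-metadata frame (sample_id, library_size,
    ...).  Every sample in the metadata must have a hit table.
    """
    missing = [s for s in samples["sample_id"] if s not in hit_tables]
    if missing:
        raise ValueError(f"missing hit tables for samples: {missing}")

    meta = (families.groupby("family_id", sort=False)
            .agg(s=("member_id", "size"), mean_length_nt=("length_nt", "mean")))
    lib = samples.set_index("sample_id")["library_size"].astype(int)

    per_sample = {}
    for sid in samples["sample_id"]:
        table = hit_tables[sid]
        if not isinstance(table, pd.DataFrame):
            table = parse_alignment_table(table)
        best = best_hit_filter(table, e_max=e_max)
        per_sample[sid] = assign_reads_to_families(best, families)
    counts = pd.DataFrame(per_sample)

    fam_counts = counts.drop(index=UNASSIGNED)
    if basis == "mean":
        denom = (meta["mean_length_nt"] / 1000.0) * meta["s"]
    elif basis == "total":
        denom = (meta["mean_length_nt"] * meta["s"] / 1000.0) * meta["s"]
    else:
        raise ValueError(f"unknown RPKSM basis {basis!r}")
    rpksm = fam_counts.div(denom.reindex(fam_counts.index), axis=0) \
                      .div(lib.reindex(fam_counts.columns) / 1e6, axis=1)
    return AbundanceTable(counts=counts, rpksm=rpksm, library_sizes=lib,
                          family_meta=meta)
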