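"""Gene presence in genomes and plasmids, and prevalence classification.

Per-domain scan tables (HMMER3 ``domtblout`` dialect, profile = gene
family, query = ORF) are reduced to presence calls: a replicon carries a
profile when at least one hit covers more than 90% of the profile with
full-sequence and per-domain independent E-values both below 0.01.
Genomes enter prevalence only if more than 95% complete with all five
universal single-copy genes; clades need more than 100 such genomes.
Prevalence is classified as core (> 80%), accessory (20-80%, both ends
inclusive), highly accessory (< 20% but present) or absent (0%).
Plasmid records are curated to drop partial sequences, unassignable
hosts and sequencing internal controls before per-gene plasmid counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

SCAN_COLUMNS = ["profile_id", "profile_length", "orf_id", "orf_length",
                "e_value_full", "e_value_independent", "hmm_from", "hmm_to"]

USCG_FLAG_PREFIX = "uscg_"


def replicon_of(orf_id: str) -> str:
    """Replicon id from an ORF id of the form ``<replicon>_<serial>``."""
    return orf_id.rsplit("_", 1)[0]


def parse_domtbl(source: str | Path) -> pd.DataFrame:
    """Parse a per-domain scan table (domtblout dialect).

    Accepts a path or raw text.  Whitespace-delimited with '#' comment
    lines; fields used are the target (profile) name and length, query
    (ORF) name and length, full-sequence E-value, per-domain independent
    E-value and the profile (hmm) coordinates of the hit, 1-based
    inclusive.  Coordinate violations raise with the offending ORF id.
    """
    if isinstance(source, Path) or "\n" not in str(source):
        text = Path(source).read_text()
    else:
        text = str(source)
    rows = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split()
        if len(f) < 22:
            raise ValueError(f"scan table line {lineno}: expected >= 22 "
                             f"whitespace-separated fields, got {len(f)}")
        profile, tlen, orf, qlen = f[0], int(f[2]), f[3], int(f[5])
        e_full, i_e = float(f[6]), float(f[12])
        hmm_from, hmm_to = int(f[15]), int(f[16])
        if not (1 <= hmm_from <= hmm_to <= tlen):
            raise ValueError(
                f"scan table line {lineno}: invalid profile coordinates "
                f"{hmm_from}..{hmm_to} (length {tlen}) for ORF {orf}")
        rows.append((profile, tlen, orf, qlen, e_full, i_e, hmm_from, hmm_to))
    return pd.DataFrame(rows, columns=SCAN_COLUMNS)


def call_presence(
    hits: pd.DataFrame,
    cov_min: float = 0.90,
    e_max: float = 0.01,
    ie_max: float = 0.01,
) -> set[tuple[str, str]]:
    """Presence calls: set of (replicon_id, profile_id) pairs.

    A hit passes when its profile coverage ``(hmm_to - hmm_from + 1) /
    profile_length`` is strictly greater than ``cov_min`` and both
    E-values are strictly below their cutoffs; any passing hit makes the
    replicon carry the profile (multiple ORF hits collapse).
    """
    if hits.empty:
        return set()
    cov = (hits["hmm_to"] - hits["hmm_from"] + 1) / hits["profile_length"]
    ok = (cov > cov_min) & (hits["e_value_full"] < e_max) \
        & (hits["e_value_independent"] < ie_max)
    passing = hits.loc[ok]
    return {
        (replicon_of(orf), prof)
        for orf, prof in zip(passing["orf_id"], passing["profile_id"])
    }


def filter_genomes(
    genomes: pd.DataFrame,
    completeness_min: float = 95.0,
    require_all_uscg: bool = True,
) -> pd.DataFrame:
    """Keep genomes above the completeness cutoff with all five USCGs.

    Completeness is strict (> 95 keeps 95.01, drops 95.0); USCG flags
    are the boolean ``uscg_*`` columns of the metadata table.
    """
    if genomes.empty:
        raise ValueError("genome metadata table is empty")
    keep = genomes["completeness"] > completeness_min
    if require_all_uscg:
        flags = [c for c in genomes.columns if c.startswith(USCG_FLAG_PREFIX)]
        if flags:
            keep &= genomes[flags].all(axis=1)
    return genomes.loc[keep].reset_index(drop=True)


def classify_prevalence(p: float) -> str:
    """Map a prevalence fraction to its class label.

    > 0.80 core; [0.20, 0.80] accessory (closed at both ends); (0, 0.20)
    highly accessory; exactly 0 absent.
    """
    if not 0 <= p <= 1:
        raise ValueError(f"prevalence {p} outside [0, 1]")
    if p > 0.80:
        return "core"
    if p >= 0.20:
        return "accessory"
    if p > 0:
        return "highly_accessory"
    return "absent"


def clade_prevalence(
    presence: set[tuple[str, str]],
    genomes: pd.DataFrame,
    rank: str = "genus",
    min_genomes: int = 100,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Per-(clade, gene) prevalence over filtered genomes of a rank.

    ``genomes`` must already have passed `filter_genomes`.  Clades with
    at most ``min_genomes`` genomes are excluded (strict >, so a clade
    with exactly 100 genomes is dropped).  Returns clade, gene,
    n_genomes, n_carrying, prevalence and class columns.
    """
    if rank not in genomes.columns:
        raise ValueError(f"rank column {rank!r} missing from genome metadata")
    if genes is None:
        genes = sorted({g for _, g in presence})
    carrier_index: dict[str, set[str]] = {}
    for replicon, gene in presence:
        carrier_index.setdefault(gene, set()).add(replicon)
    records = []
    for clade, sub in genomes.groupby(rank, sort=True):
        n = len(sub)
        if n <= min_genomes:
            continue
        ids = set(sub["genome_id"])
        for gene in genes:
            carrying = len(ids & carrier_index.get(gene, set()))
            prev = carrying / n
            records.append((clade, gene, n, carrying, prev,
                            classify_prevalence(prev)))
    return pd.DataFrame(records, columns=["clade", "gene", "n_genomes",
                                          "n_carrying", "prevalence", "class"])


def prevalence_matrix(prevalence: pd.DataFrame,
                      value: str = "class") -> pd.DataFrame:
    """Heatmap-ready clade x gene matrix of class labels or fractions."""
    return prevalence.pivot(index="clade", columns="gene", values=value)


def curate_plasmids(plasmids: pd.DataFrame) -> pd.DataFrame:
    """Drop partial sequences, unassignable hosts and internal controls."""
    if plasmids.empty:
        raise ValueError("plasmid metadata table is empty")
    host = plasmids["host_assignment"].fillna("").astype(str).str.strip().str.lower()
    keep = (~plasmids["partial_flag"].astype(bool)
            & ~plasmids["control_flag"].astype(bool)
            & ~host.isin({"", "unassigned", "na", "none"}))
    return plasmids.loc[keep].reset_index(drop=True)


def plasmid_gene_counts(
    presence: set[tuple[str, str]],
    curated_plasmids: pd.DataFrame,
    genes: list[str] | None = None,
) -> pd.Series:
    """Number of distinct curated plasmids carrying each gene.

    A plasmid counts once per gene regardless of copy number; presence
    pairs on non-curated plasmids are ignored.
    """
    curated = set(curated_plasmids["plasmid_id"])
    if genes is None:
        genes = sorted({g for _, g in presence})
    counts = {g: 0 for g in genes}
    seen = set()
    for replicon, gene in presence:
        if replicon in curated and gene in counts and (replicon, gene) not in seen:
            seen.add((replicon, gene))
            counts[gene] += 1
    return pd.Series(counts, name="n_plasmids").sort_index()


@dataclass
class ScreenResult:
    """Outputs of a full genome/plasmid screen."""

    genus_prevalence: pd.DataFrame
    species_prevalence: pd.DataFrame
    plasmid_counts: pd.Series

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.genus_prevalence.to_csv(outdir / "prevalence_genus.tsv",
                                     sep="\t", index=False)
        self.species_prevalence.to_csv(outdir / "prevalence_species.tsv",
                                       sep="\t", index=False)
        prevalence_matrix(self.genus_prevalence).to_csv(
            outdir / "prevalence_genus_matrix.tsv", sep="\t")
        self.plasmid_counts.to_csv(outdir / "plasmid_gene_counts.tsv", sep="\t")


def run_screen(
    scan: str | Path | pd.DataFrame,
    genomes: pd.DataFrame,
    plasmids: pd.DataFrame,
    cov_min: float = 0.90,
    e_max: float = 0.01,
    ie_max: float = 0.01,
    completeness_min: float = 95.0,
    min_genomes: int = 100,
    genes: list[str] | None = None,
) -> ScreenResult:
    """End-to-end screen: parse -> presence -> prevalence + plasmid counts."""
    hits = scan if isinstance(scan, pd.DataFrame) else parse_domtbl(scan)
    presence = call_presence(hits, cov_min=cov_min, e_max=e_max, ie_max=ie_max)
    retained = filter_genomes(genomes, completeness_min=completeness_min)
    genus = clade_prevalence(presence, retained, rank="genus",
                             min_genomes=min_genomes, genes=genes)
    species = clade_prevalence(presence, retained, rank="species",
                               min_genomes=min_genomes, genes=genes)
    curated = curate_plasmids(plasmids)
    counts = plasmid_gene_counts(presence, curated, genes=genes)
    return ScreenResult(genus_prevalence=genus, species_prevalence=species,
                        plasmid_counts=counts)
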